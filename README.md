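# finechrom

Fine-scale chromatin-contact analysis for bridge-linker proximity-ligation
data (CAP-C-style experiments), built around gene-level questions: which bin
pairs are contact-enriched beyond the distance decay ("stable chromatin
contacts"), which promoters touch which promoters and enhancers, how
gene-body contacts track RNA polymerase II activity around transcription
start sites and 5' splice sites across temperature conditions, and whether
loop-connected gene pairs are co-expressed.

It is written for computational biologists working with high-resolution
(~200 bp) contact maps of compact genomes such as *Arabidopsis*, and ships a
synthetic-data generator that emulates the full data structure — power-law
contact background, planted promoter-promoter loops, condition-dependent
5'SS pausing signal, correlated expression — so every stage can be validated
against known ground truth.

## The model at the core

Stable-contact calling tests each intra-chromosomal bin pair against a
distance-decay null. With N total contacts and an expected contact
probability p(s) for a bin pair at genomic separation s — estimated from
equal-occupancy distance bins and made monotone non-increasing by
pool-adjacent-violators — a pair with observed count k gets

    p-value = P(X >= k),  X ~ Binomial(N, p(s))

and Benjamini–Hochberg control is applied over the family of *all* possible
bin pairs in the tested distance range (unoccupied pairs count as p = 1).
Pairs with q <= 0.01 are reported. Promoter-promoter contacts present in
every condition ("primed") form a network whose high-degree nodes are
hotspot promoters; co-expression of connected pairs is tested against two
permutation nulls — same-count random pairs (A) and distance-matched random
pairs (B, log2-binned TSS separations) — with
p = (1 + #{null >= observed}) / (1 + n_reps).

See `docs/methods.md` for the full model description and design rationale.

## Worked example

A complete synthetic run — genome simulation, three condition libraries,
filtering, binning, VC normalization, decay fit, loop calling, condition
intersection, classification, network, profiles, co-expression:

```sh
finechrom demo --seed 7 --out demo_out
```

This takes a few seconds (two 400 kb chromosomes, 160 genes, 3x10^5 pairs
per condition) and writes TSV/JSON artifacts plus `report.json`. With seed 7
the report contains, among others:

```
conditions.22C.decay_alpha          1.0056
conditions.22C.n_calls              33
n_primed                            22
profiles.spearman_density_activity  r = 0.303, p = 9.6e-05
profiles.fivess_mean_z              22C 1.51, cold12h 1.21, cold3h 0.51
coexpression.observed_mean_r        0.505
coexpression.p_A / p_B              0.0050 / 0.0050
```

Reading the numbers: the fitted decay exponent recovers the simulated
alpha = 1; 33 stable contacts are called at 22 °C of which 22 survive
intersection across all three conditions (the generator planted 40 loops —
intersecting three independently called sets loses marginal calls); per-gene
contact density correlates with the activity track at Spearman r = 0.30
(the generator's coupling target is 0.4; attenuation reflects measurement
noise at this depth); the Z-scored first-5'SS profile means order
22C > cold12h > cold3h, the planted pausing drop-and-recovery; and the
loop-connected gene pairs' mean expression correlation (0.505) is higher
than every one of 200 replicates of both nulls (p = 1/201).

The same stages run individually on files (`finechrom contacts`, `call`,
`classify`, `network`, `profiles`, `coexpr`) or end to end from a YAML
config (`finechrom run --config cfg.yaml`), on real pair/annotation/track
inputs or synthetic ones.

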