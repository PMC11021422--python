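# Methods

`finechrom` implements a fine-scale chromatin-contact analysis pipeline for
proximity-ligation data of the bridge-linker kind: reads in which a known
linker oligonucleotide separates two genomic fragments define valid
chromatin contacts. The pipeline covers contact extraction and filtering,
binned contact matrices, distance-decay modelling, stable-contact (loop)
calling, promoter-promoter network construction, Pol II-coupled
meta-profiles around transcription landmarks, and a permutation test of
co-expression for loop-connected gene pairs. A synthetic-data generator
reproduces the statistical structure of such an experiment and supplies
ground truth for every stage.

## Contact extraction and filtering

A read is a valid contact if it contains the linker search string
(`GTCAGAAAGATATCGCGT` by default — the bridge oligo with chemistry tags
stripped; configurable, exact match by default with an optional
one-mismatch mode) and both flanks are at least 20 nt. Pairs are
canonicalized so that (chrom1, pos1) <= (chrom2, pos2) under the
chromosome order of the sizes file. Filtering drops pairs with
min(MAPQ1, MAPQ2) < 10, intra-chromosomal pairs closer than two bins
(self-ligation guard; the threshold is configurable — fragments shorter
than one bin pair carry no conformation information at the working
resolution), and exact duplicates (all coordinates and both strands equal),
a PCR-duplicate proxy in the absence of alignment metadata. Coordinates are
0-based half-open throughout; GFF3 input is converted at the boundary.

## Contact matrices and decay

Contacts are binned at 200 bp (configurable); bin index = floor(pos /
resolution). Matrices are stored sparsely per chromosome pair, upper
triangle for intra-chromosomal maps. Vanilla-coverage (VC) normalization
divides each entry by the product of its (symmetrized) row sums and
rescales to preserve total mass; zero-coverage bins stay zero. One VC pass
is *not* idempotent on general matrices (only the Sinkhorn fixed point is);
it contracts coverage nonuniformity, which is what the tests assert.

The distance-decay curve uses log-spaced bins over [1 kb, 10 Mb] by
default; density = count / (N x bin width in bp), making the curve
invariant to sequencing depth. The decay exponent alpha is the negated
least-squares slope of log density on log distance over occupied bins (at
least three required). Replicate agreement is the Pearson correlation of
log1p counts over the union of occupied bin pairs, overall and per log2
distance stratum.

## Stable-contact calling

The null model assigns every intra-chromosomal bin pair at separation s a
contact probability p(s) estimated from equal-occupancy distance bins
(approximately equal total counts per bin): p = (counts in bin) / (N x
possible locus pairs at those separations), smoothed to be monotone
non-increasing by pool-adjacent-violators (weighted by pair counts). PAVA
was preferred over a spline fit for determinism and simplicity at the
scales this package targets. Each occupied bin pair with count k is tested
with P(X >= k), X ~ Binomial(N, p(s)); Benjamini-Hochberg controls FDR and
pairs with q <= 0.01 (configurable) are reported.

Two defaults deserve explanation:

* **Testing range [1 kb, L/3].** The per-pair expected rate carries a
  placement factor 1/(L - s): a pair at separation s can sit at L - s
  positions. Within a pooled distance bin this factor is effectively
  constant only when s is well below the chromosome length L; near s ~ L
  it diverges and the piecewise-constant model becomes anti-conservative
  (bin pairs joining opposite chromosome ends look enriched by orders of
  magnitude). Below the shortest informative separations the density is
  dominated by intra-gene structure rather than the genome-wide decay.
  Both bounds are configurable.

* **BH family = all possible in-range bin pairs.** Testing only occupied
  pairs conditions the family on k >= 1, which is selection on the test
  statistic itself and measurably inflates the false-call rate at fine
  resolution where most pairs have expectation << 1. Unoccupied pairs are
  treated as implicit tests at p = 1 (they can never be rejected but
  belong in the family). The BH computation is implemented directly
  (sort, p*m/rank, cumulative minimum) because the family size exceeds the
  p-vector length; it is tested against statsmodels on ordinary inputs.

At 200 bp resolution most tested pairs have expectation far below one
count, so the p-value distribution over occupied pairs is atomic (a pair
with expectation 0.03 and one observed count already has p ~ 0.03): the
raw p-value histogram is *not* uniform and cannot be, for any correctly
computed discrete test at this sparsity. Calibration is therefore checked
as super-uniformity over the full family plus tail calibration on the
subset with expectation >= 1.

"Primed" contacts are the exact intersection of per-condition call sets on
(chromosome, bin1, bin2); a +/-1-bin slack mode is available.

## Anchor annotation, contact classes, networks

Promoter windows are strand-aware, 500 bp upstream to 100 bp downstream of
the TSS by default (the window is not a community standard; it is
configurable and recorded in outputs). Anchors take the primary label
promoter > enhancer > gene body > intergenic. Promoter-promoter (P-P)
contacts in cis are tandem (equal strands), divergent (left gene on minus
strand — transcription pointing apart) or convergent (pointing together),
with "left" decided by TSS coordinate. Enhancer-promoter (E-P) contacts
are proximal when the anchor midpoints are within 2 kb (configurable;
midpoint-based by choice, the alternative edge-based rule changes little at
bin scale) and upstream/downstream of the promoter in transcription
direction. A loop whose anchors hit several promoters yields one edge per
gene pair (Cartesian, deduplicated) — hotspot promoters genuinely contact
very many genes.

The PPI network has genes as nodes and primed P-P contacts as edges with
loop-support counts. Hotspots are nodes whose degree exceeds a percentile
of the degree distribution (default 99.9; on toy-scale networks of a few
hundred nodes the validation harness uses the 99th, since the 99.9th
percentile of a short degree vector collapses onto the maximum). Contact
enrichment over site sets (e.g. TF binding sites) is the mean contact-end
count per offset bin around site centers, against a chromosome- and
length-preserving shuffle null (100 seeded shuffles by default).

## Profiles and correlations

"Contact density" counts contact **ends** (each pair contributes two),
matching coverage-track semantics. Per-gene density is (pairs with both
ends inside the gene body) / (gene length in kb x library total / 10^6);
the formula is configurable since the normalization convention is not
standardized. Metagene profiles rescale each gene body to 100 bins,
strand-aware. 5'SS profiles cover 100 bp upstream to 200 bp downstream of
each (or each first) 5' splice site in transcription orientation; with
several conditions each profile is Z-scored over its window (population
sd) to cancel depth differences. Stratification takes the top and bottom
pct% of genes (ceil, capped to keep the sets disjoint; ties broken by gene
id for determinism). Spearman correlation uses midranks, with an exact
permutation p-value for n <= 9 and the t-approximation otherwise.

## Co-expression permutation test

The observed statistic is the mean pairwise Pearson r of expression
(conditions x replicates, 9 samples by default) over PPI-connected gene
pairs. Null model A draws the same number of uniformly random distinct
gene pairs; null model B draws same-chromosome pairs matched to the PPI
TSS-separation multiset in log2 distance bins anchored at 1 kb (widening
to the nearest non-empty bin when a bin is exhausted), plus one random
trans pair per trans PPI. Observed pairs are excluded from both control
pools — the controls are meant to be non-PPI pairs, and without exclusion
a distance bin dominated by PPI pairs would make model B resample the
observed set itself. Each null is repeated 1000 times (configurable);
p = (1 + #{null >= observed}) / (1 + n_reps), one-sided for higher
co-expression, never zero. The mean is the replicate statistic; the median
is reported alongside.

## Synthetic data

The generator builds a small plant-like genome (default two 1.5 Mb
chromosomes, 500 non-overlapping genes, 80% multi-exon with 2-5 exons) in
a deterministic layout cycle of four divergent head-to-head gene pairs
followed by one isolated gene, guaranteeing enough divergent promoter
pairs with TSS separation 1.0-1.2 kb to serve as planted loop anchors at
any seed. Arabidopsis-scale divergent promoters commonly sit about a
kilobase apart; at the default library depth this separation also puts the
background expectation per anchor bin pair near 2-3 counts, the regime in
which an 8-fold enrichment is unambiguously detectable — planting loops
much beyond ~2.5 kb separation would make them undetectable at q <= 0.01
by any caller at these counts, which would measure the simulation rather
than the method.

Contacts per library (default 2x10^6): intra-chromosomal background with
separation density proportional to s^-alpha on [1 kb, chromosome length)
drawn by inverse CDF (alpha = 1 by default), uniform placement; a small
inter-chromosomal fraction (2%); planted loops emitted at (fold - 1) x the
analytic background expectation of their anchor bin pair, so `fold` is the
*total* enrichment and fold = 1 leaves anchors exactly at background;
per-gene body contacts (both ends inside the gene) scaled by a lognormal
per-gene activity factor; and first-5'SS contacts in two blocks — a
condition-independent upstream-exon block over [-100, 0) and a
condition-weighted pausing block over [0, +50), covering the ~25 bp
downstream pausing offset. Condition weights default to 22C = 1.0,
cold3h = 0.4, cold12h = 0.7 (a sharp drop after 3 h cold, partial recovery
by 12 h); the effect size is a free parameter. The split into a shared
upstream block and a variable downstream block is deliberate: per-condition
Z-scoring cancels any profile component proportional to the condition
weight, so a generator whose entire 5'SS signal scaled with the weight
would make the ordering unrecoverable by construction; the shared block
dominates the window sd and keeps the Z-scored downstream mean monotone in
the weight, which is also the qualitative shape of the real profiles
(upstream exon-end enrichment stable, downstream pausing modulated).

Activity tracks are coupled to each gene's total expected in-gene contact
density (planted component plus the analytic background expectation,
integrated by quadrature) through a Gaussian copula with target Spearman
correlation 0.4 — the order of magnitude of published
contact-density-versus-nascent-transcription correlations. Expression for
loop-connected pairs shares a latent factor giving pairwise correlation
rho (default 0.5) across 3 conditions x 3 replicates; other genes are
independent. Linker reads are flank + linker + flank with flank lengths
uniform on [50, 200] (DNase fragment range), true coordinates encoded in
the read name, and a 20% linker-free decoy fraction.

All randomness flows through numpy Generators derived from the master seed
by stable hashing of stage labels, so fixed seeds give byte-identical
outputs and enabling one stage does not perturb another.

What the generator does **not** model: sequencing errors, mappability and
alignment artifacts, restriction/fragmentation biases, chromatin
compartments and TADs, overlapping or nested genes, condition-dependent
expression means (which would correlate all gene pairs at once), or
polymer-physics contact structure. Passing tests therefore demonstrate
that the implementations recover the structures they claim to measure at
realistic counts and noise, not that the defaults are optimal for any
particular real dataset.

## Validation experiments and problem sizes

The benchmark module runs the validation experiments end to end: loop
recovery and null calibration at the full conditions (3 Mb, 2x10^6 pairs,
200 loops at 8x; sensitivity >= 0.9 at empirical FDR <= 0.05); decay
exponents 0.8/1.0/1.2 each recovered within +-0.1 from 10^6 pairs; 5'SS
condition-ordering recovery in 20 seeded runs of a 1 Mb genome at 650k
pairs per condition (the full-scale contact density and per-gene rates);
co-expression type-I error at alpha = 0.05 over 600 null experiments of
200 permutation reps each (600 rather than 200 so the binomial noise of
the rate estimate, ~0.9 points, is small against the +-2-point target
band) and power at rho = 0.5 with 100 pairs; and two-sample KS distances
between PPI and control log-distances on a short-skewed 250-pair PPI set.
`scripts/acceptance.py` recomputes all of these from scratch for a given
seed.

## Known limitations

* The expected model is distance-only; inter-chromosomal pairs are never
  tested for enrichment.
* VC is the only matrix correction; no iterative balancing.
* The binomial test treats contacts as independent draws; overdispersion
  from PCR or proximity clusters would make q-values optimistic on real
  data.
* Model-B null sampling degrades when nearly all candidate pairs in a
  distance bin are themselves PPI pairs (it widens to neighbouring bins
  and warns).
* Hotspot detection by degree percentile is scale-sensitive; for small
  networks an absolute degree cutoff is the better tool.
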