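"""Toy-genome simulator carrying the statistical structure the analysis assumes.

The generator emulates a fine-scale proximity-ligation experiment on a small
plant-like genome:

* a power-law distance-decay contact background (density ~ s^-alpha on
  [1 kb, chromosome length));
* planted promoter-promoter loops between divergent neighbouring gene pairs,
  emitted at a configurable fold over the background expectation;
* gene-body contacts whose rate tracks a per-gene activity factor, plus
  first-5'SS-anchored contacts with a condition-independent upstream-exon
  component and a condition-weighted downstream pausing component (weights
  ordered 22C > cold12h > cold3h, i.e. a sharp drop after 3 h cold and
  partial recovery by 12 h);
* three-condition expression with elevated correlation for loop-connected
  gene pairs;
* bridge-linker reads (flank + linker + flank) with a configurable fraction
  of linker-free decoys.

All randomness flows through numpy Generators seeded from the config seed,
so fixed seeds give byte-identical outputs.  Ground truth (planted loops,
activity factors, condition weights, co-expressed pairs) is returned as a
:class:`TruthSet` for parameter-recovery tests.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (
    ChromSizes, ExpressionMatrix, GeneModel, SignalTrack, canonicalize_pairs,
)
from .contact_processing import DEFAULT_LINKER

__all__ = [
    "SimulationConfig", "TruthSet", "generate_genome", "simulate_contacts",
    "simulate_activity_and_expression", "simulate_linker_reads",
    "expected_background_rate",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment.  Defaults are the study conditions
    the package is exercised under (3 Mb genome, 500 genes, 2x10^6 contact
    pairs, 200 planted loops at 8x enrichment)."""

    n_chroms: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 500
    resolution: int = 200
    alpha: float = 1.0
    n_background_pairs: int = 2_000_000
    d_min: int = 1_000                      # lower truncation of the decay law
    inter_fraction: float = 0.02            # trans background rate
    n_loops: int = 200
    loop_fold: float = 8.0
    loop_distance_range: tuple[int, int] = (1_000, 1_200)
    multiexon_fraction: float = 0.8
    n_enhancers: int = 60
    # gene-body / 5'SS contact process (per gene, per library)
    rate_body: float = 10.0                 # intra-gene contacts at unit activity
    rate_base: float = 20.0                 # upstream-exon block, condition-independent
    rate_pause: float = 20.0                # downstream pausing block at unit weight
    pause_window: tuple[int, int] = (0, 50)     # bp downstream of the first 5'SS
    base_window: tuple[int, int] = (-100, 0)    # bp upstream (exonic side)
    condition_weights: dict = field(default_factory=lambda: {
        "22C": 1.0, "cold3h": 0.4, "cold12h": 0.7})
    activity_sd: float = 0.5                # lognormal sd of per-gene activity factor
    activity_coupling: float = 0.4          # target Spearman(activity, contact density)
    expression_rho: float = 0.5             # correlation for loop-connected pairs
    n_replicates: int = 3
    low_mapq_fraction: float = 0.05
    decoy_fraction: float = 0.2
    linker: str = DEFAULT_LINKER
    n_hotspots: int = 2
    hotspot_degree: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.loop_fold < 1:
            raise ValueError("loop enrichment fold must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, *stream: object) -> np.random.Generator:
        """Deterministic sub-stream derived from the master seed by stable
        hashing of the stream labels."""
        keys = [zlib.crc32(str(s).encode()) & 0x7FFFFFFF for s in stream]
        return np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF] + keys))


@dataclass
class TruthSet:
    """Ground truth planted by the simulator, for recovery tests."""

    loops: pd.DataFrame            # chrom, bin1, bin2, fold, geneA, geneB
    activity_factor: dict[str, float]
    condition_weights: dict[str, float]
    coexpressed_pairs: list[tuple[str, str]]
    hub_genes: list[str]
    hub_edges: list[tuple[str, str]]
    resolution: int
    expected_density: dict[str, float] = field(default_factory=dict)

    def loop_keys(self) -> set[tuple[str, int, int]]:
        return set(zip(self.loops["chrom"], self.loops["bin1"], self.loops["bin2"]))

    def primed_loop_table(self) -> pd.DataFrame:
        """Planted loops plus hub edges as a primed promoter-pair table
        (geneA, geneB) for network-level tests."""
        rows = [(a, b) for a, b in zip(self.loops["geneA"], self.loops["geneB"])]
        rows += list(self.hub_edges)
        return pd.DataFrame(rows, columns=["geneA", "geneB"])

    def to_json(self, path: str | Path) -> None:
        obj = {
            "loops": self.loops.to_dict(orient="list"),
            "activity_factor": self.activity_factor,
            "expected_density": self.expected_density,
            "condition_weights": self.condition_weights,
            "coexpressed_pairs": self.coexpressed_pairs,
            "hub_genes": self.hub_genes,
            "hub_edges": self.hub_edges,
            "resolution": self.resolution,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            loops=pd.DataFrame(obj["loops"]),
            activity_factor=obj["activity_factor"],
            expected_density=obj.get("expected_density", {}),
            condition_weights=obj["condition_weights"],
            coexpressed_pairs=[tuple(p) for p in obj["coexpressed_pairs"]],
            hub_genes=obj["hub_genes"],
            hub_edges=[tuple(p) for p in obj["hub_edges"]],
            resolution=obj["resolution"],
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _make_exons(start: int, rng: np.random.Generator,
                multiexon: bool) -> list[tuple[int, int]]:
    if not multiexon:
        return [(start, start + int(rng.integers(600, 2000)))]
    n_exons = int(rng.integers(2, 6))
    pos = start
    exons = []
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(80, 300))        # intron
        length = int(rng.integers(150, 400)) if i == 0 else int(rng.integers(100, 500))
        exons.append((pos, pos + length))
        pos += length
    return exons


def generate_genome(config: SimulationConfig,
                    ) -> tuple[ChromSizes, list[GeneModel], pd.DataFrame]:
    """Build chromosome sizes, non-overlapping gene models (a configurable
    fraction multi-exon) and intergenic enhancer intervals.

    Genes are laid out in units: divergent head-to-head pairs whose TSS
    separation falls in the planted-loop distance range (these supply the
    promoter anchors that loops are planted on), interleaved with isolated
    genes.  Deterministic for a fixed seed.
    """
    rng = config.rng("genome")
    chromsizes = ChromSizes({f"chr{i + 1}": config.chrom_length
                             for i in range(config.n_chroms)})
    genes: list[GeneModel] = []
    enhancers: list[tuple[str, int, int, str]] = []
    per_chrom = -(-config.n_genes // config.n_chroms)
    gid = 0
    lo_sep, hi_sep = config.loop_distance_range
    for chrom in chromsizes.names:
        cursor = int(rng.integers(1_000, 3_000))
        placed = 0
        unit = 0
        while placed < per_chrom and gid < config.n_genes:
            # deterministic layout cycle: four divergent pairs, one single —
            # guarantees enough promoter-pair loop anchors at any seed
            make_pair = (unit % 5 != 4) and placed + 2 <= per_chrom
            unit += 1
            if make_pair and gid + 2 <= config.n_genes:
                # divergent pair: minus-strand gene then plus-strand gene,
                # TSS separation within the loop-anchor range
                exons_a = _make_exons(cursor, rng,
                                      rng.random() < config.multiexon_fraction)
                end_a = exons_a[-1][1]
                sep = int(rng.integers(lo_sep, hi_sep + 1))
                start_b = end_a - 1 + sep   # TSS_b - TSS_a = sep
                exons_b = _make_exons(start_b, rng,
                                      rng.random() < config.multiexon_fraction)
                end_b = exons_b[-1][1]
                if end_b >= config.chrom_length - 2_000:
                    break
                genes.append(GeneModel(f"g{gid:04d}", chrom, cursor, end_a, "-",
                                       exons_a))
                genes.append(GeneModel(f"g{gid + 1:04d}", chrom, start_b, end_b,
                                       "+", exons_b))
                gid += 2
                placed += 2
                cursor = end_b + int(rng.integers(800, 3_000))
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                exons = _make_exons(cursor, rng,
                                    rng.random() < config.multiexon_fraction)
                end = exons[-1][1]
                if end >= config.chrom_length - 2_000:
                    break
                genes.append(GeneModel(f"g{gid:04d}", chrom, cursor, end, strand,
                                       exons))
                gid += 1
                placed += 1
                cursor = end + int(rng.integers(800, 3_000))
        if placed < min(per_chrom, config.n_genes - (gid - placed)):
            raise ValueError(
                f"genome too small: placed {placed} of {per_chrom} genes on {chrom}")
    # enhancers in intergenic gaps
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    eid = 0
    while eid < config.n_enhancers:
        chrom = chromsizes.names[int(rng.integers(config.n_chroms))]
        pos = int(rng.integers(0, config.chrom_length - 200))
        if any(g.start - 700 <= pos <= g.end + 200 for g in by_chrom.get(chrom, [])):
            continue
        enhancers.append((chrom, pos, pos + 200, f"enh{eid:03d}"))
        eid += 1
    enh = pd.DataFrame(enhancers, columns=["chrom", "start", "end", "name"])
    enh = enh.sort_values(["chrom", "start"]).reset_index(drop=True)
    return chromsizes, genes, enh


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _sample_powerlaw(rng: np.random.Generator, n: int, alpha: float,
                     s_min: float, s_max: float) -> np.ndarray:
    """Inverse-CDF draws from density ~ s^-alpha truncated to [s_min, s_max)."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return s_min * (s_max / s_min) ** u
    a = 1.0 - alpha
    return (s_min ** a + u * (s_max ** a - s_min ** a)) ** (1.0 / a)


def expected_background_rate(config: SimulationConfig, chrom_length: int,
                             separation: float, n_intra_chrom: float) -> float:
    """Expected background count in one bin pair at the given separation.

    Density of the truncated power law times the bin-pair footprint:
    lambda = n * f(s) * res^2 / (L - s).
    """
    a = config.alpha
    s_min, s_max = config.d_min, chrom_length
    if abs(a - 1.0) < 1e-12:
        norm = np.log(s_max / s_min)
        f = 1.0 / (norm * separation)
    else:
        norm = (s_max ** (1 - a) - s_min ** (1 - a)) / (1 - a)
        f = separation ** (-a) / norm
    return n_intra_chrom * f * config.resolution ** 2 / (chrom_length - separation)


def plant_loops(config: SimulationConfig, chromsizes: ChromSizes,
                genes: list[GeneModel]) -> TruthSet:
    """Choose planted promoter-promoter loops and network hubs.

    Loop anchors are the promoter bins of divergent neighbouring gene pairs
    whose separation lies in ``loop_distance_range``; hub promoters contact
    many other promoters (network-level truth only — hub edges are not
    emitted as extra contact pairs).
    """
    rng = config.rng("loops")
    res = config.resolution
    lo, hi = config.loop_distance_range
    candidates = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gl in by_chrom.items():
        gl = sorted(gl, key=lambda g: g.start)
        for a, b in zip(gl[:-1], gl[1:]):
            if a.strand == "-" and b.strand == "+":
                sep = b.tss - a.tss
                if lo <= sep <= hi and a.tss // res != b.tss // res:
                    candidates.append((chrom, a, b, sep))
    if len(candidates) < config.n_loops:
        raise ValueError(
            f"only {len(candidates)} divergent promoter pairs in range for "
            f"{config.n_loops} loops; enlarge the genome")
    idx = rng.choice(len(candidates), size=config.n_loops, replace=False)
    rows = []
    for i in sorted(idx):
        chrom, a, b, sep = candidates[i]
        b1, b2 = sorted((a.tss // res, b.tss // res))
        rows.append((chrom, int(b1), int(b2), config.loop_fold,
                     a.gene_id, b.gene_id))
    loops = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "fold",
                                        "geneA", "geneB"])
    loop_genes = set(loops["geneA"]) | set(loops["geneB"])
    others = [g.gene_id for g in genes if g.gene_id not in loop_genes]
    hub_genes, hub_edges = [], []
    if config.n_hotspots > 0 and len(others) > config.hotspot_degree + config.n_hotspots:
        hubs = rng.choice(len(others), size=config.n_hotspots, replace=False)
        hub_genes = [others[i] for i in hubs]
        pool = [g for g in others if g not in set(hub_genes)]
        for hub in hub_genes:
            spokes = rng.choice(len(pool), size=config.hotspot_degree, replace=False)
            hub_edges += [tuple(sorted((hub, pool[i]))) for i in spokes]
    coexpressed = [tuple(sorted((a, b)))
                   for a, b in zip(loops["geneA"], loops["geneB"])]
    factors, _ = _activity_factors_with_scores(config, genes)
    return TruthSet(loops=loops, activity_factor=factors,
                    condition_weights=dict(config.condition_weights),
                    coexpressed_pairs=coexpressed,
                    hub_genes=hub_genes, hub_edges=hub_edges, resolution=res)


def _activity_factors_with_scores(config: SimulationConfig, genes):
    """Per-gene lognormal activity factor plus its latent normal score.

    Drawn from a stream keyed only on the master seed, so the factors are
    shared between the contact and the activity/expression simulations.
    """
    rng = config.rng("activity-factor")
    z = rng.standard_normal(len(genes))
    factors = {g.gene_id: float(np.exp(config.activity_sd * zi))
               for g, zi in zip(genes, z)}
    scores = {g.gene_id: float(zi) for g, zi in zip(genes, z)}
    return factors, scores


def simulate_contacts(chromsizes: ChromSizes, genes: list[GeneModel],
                      truth: TruthSet, config: SimulationConfig,
                      condition: str, seed: int | None = None,
                      n_pairs: int | None = None) -> pd.DataFrame:
    """Simulate one library of contact pairs for *condition*.

    Components: intra-chromosomal power-law background, inter-chromosomal
    background, planted loops at fold x the background expectation, per-gene
    body contacts scaled by the gene's activity factor, and first-5'SS
    contacts (condition-independent upstream-exon block plus the
    condition-weighted downstream pausing block).

    With the same *seed*, the background and loop components are identical
    across conditions; only the 5'SS pausing component varies with the
    condition weight.
    """
    if condition not in config.condition_weights:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{sorted(config.condition_weights)}")
    weight = config.condition_weights[condition]
    if seed is None:
        seed = config.seed
    cfg_seeded = config if seed == config.seed else _reseed(config, seed)
    n_total = n_pairs if n_pairs is not None else config.n_background_pairs
    res = config.resolution
    factors, _ = _activity_factors_with_scores(config, genes)

    chunks: list[pd.DataFrame] = []

    # --- background -------------------------------------------------------
    rng = cfg_seeded.rng("background")
    n_inter = int(round(n_total * config.inter_fraction))
    n_intra = n_total - n_inter
    lengths = np.array([chromsizes[c] for c in chromsizes.names], dtype=float)
    chrom_p = lengths / lengths.sum()
    chosen = rng.choice(len(lengths), size=n_intra, p=chrom_p)
    for ci, chrom in enumerate(chromsizes.names):
        n_c = int((chosen == ci).sum())
        if n_c == 0:
            continue
        L = chromsizes[chrom]
        s = _sample_powerlaw(rng, n_c, config.alpha, config.d_min, L)
        s = np.minimum(s, L - 1).astype(np.int64)
        left = (rng.random(n_c) * (L - s)).astype(np.int64)
        chunks.append(_pairs_chunk(chrom, left, chrom, left + s, rng))
    if n_inter > 0 and len(chromsizes.names) > 1:
        c1 = rng.choice(len(lengths), size=n_inter, p=chrom_p)
        c2 = rng.choice(len(lengths), size=n_inter, p=chrom_p)
        redo = c1 == c2
        while redo.any():
            c2[redo] = rng.choice(len(lengths), size=int(redo.sum()), p=chrom_p)
            redo = c1 == c2
        p1 = (rng.random(n_inter) * lengths[c1]).astype(np.int64)
        p2 = (rng.random(n_inter) * lengths[c2]).astype(np.int64)
        names = np.array(chromsizes.names)
        chunks.append(_pairs_chunk(names[c1], p1, names[c2], p2, rng))

    # --- planted loops ----------------------------------------------------
    rng = cfg_seeded.rng("loop-emission")
    intra_per_chrom = {c: n_intra * chrom_p[i]
                       for i, c in enumerate(chromsizes.names)}
    for row in truth.loops.itertuples(index=False):
        sep = (row.bin2 - row.bin1) * res
        lam = expected_background_rate(config, chromsizes[row.chrom], max(sep, res),
                                       intra_per_chrom[row.chrom])
        # fold is the TOTAL enrichment of the anchor pair: the background
        # already contributes lam, so the loop process adds (fold - 1) x lam.
        # fold = 1 therefore leaves the anchors exactly at background.
        k = rng.poisson((row.fold - 1.0) * lam)
        if k == 0:
            continue
        p1 = row.bin1 * res + rng.integers(0, res, size=k)
        p2 = row.bin2 * res + rng.integers(0, res, size=k)
        chunks.append(_pairs_chunk(row.chrom, p1, row.chrom, p2, rng))

    # --- gene-body and 5'SS contacts -------------------------------------
    depth_scale = n_total / config.n_background_pairs
    rng = cfg_seeded.rng("gene-body")
    chunks += _gene_body_pairs(chromsizes, genes, factors, config, rng, depth_scale)
    rng = cfg_seeded.rng("fivess", condition)
    chunks += _fivess_pairs(chromsizes, genes, factors, config, weight, rng,
                            depth_scale)

    pairs = pd.concat(chunks, ignore_index=True)
    pairs = _apply_mapq_noise(pairs, config, cfg_seeded.rng("mapq", condition))
    pairs = canonicalize_pairs(pairs, chromsizes)
    # deterministic shuffle so components are not block-ordered
    order = cfg_seeded.rng("shuffle", condition).permutation(len(pairs))
    return pairs.iloc[order].reset_index(drop=True)


def _reseed(config: SimulationConfig, seed: int) -> SimulationConfig:
    import dataclasses
    return dataclasses.replace(config, seed=seed)


def _pairs_chunk(chrom1, pos1, chrom2, pos2, rng) -> pd.DataFrame:
    n = len(pos1)
    strands = np.array(["+", "-"])
    mapq = np.full(n, 60, dtype=np.int32)
    return pd.DataFrame({
        "chrom1": chrom1, "pos1": np.asarray(pos1, dtype=np.int64),
        "strand1": strands[rng.integers(0, 2, n)],
        "chrom2": chrom2, "pos2": np.asarray(pos2, dtype=np.int64),
        "strand2": strands[rng.integers(0, 2, n)],
        "mapq1": mapq, "mapq2": mapq.copy(),
    })


def _apply_mapq_noise(pairs: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    low = rng.random(len(pairs)) < config.low_mapq_fraction
    which = rng.integers(0, 2, len(pairs))
    q = rng.integers(0, 10, len(pairs))
    m1 = pairs["mapq1"].to_numpy().copy()
    m2 = pairs["mapq2"].to_numpy().copy()
    m1[low & (which == 0)] = q[low & (which == 0)]
    m2[low & (which == 1)] = q[low & (which == 1)]
    pairs = pairs.copy()
    pairs["mapq1"], pairs["mapq2"] = m1, m2
    return pairs


def _partner_positions(anchor: np.ndarray, L: int, config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Second ends at power-law distances from the anchors, reflected into
    the chromosome."""
    d = _sample_powerlaw(rng, len(anchor), config.alpha, config.d_min, L / 2)
    sign = np.where(rng.random(len(anchor)) < 0.5, 1, -1)
    pos = anchor + sign * d.astype(np.int64)
    pos = np.abs(pos)
    pos = np.where(pos >= L, 2 * (L - 1) - pos, pos)
    return np.clip(pos, 0, L - 1)


def _gene_body_pairs(chromsizes, genes, factors, config, rng, depth_scale):
    chunks = []
    for g in genes:
        if g.length < 900:
            continue
        lam = factors[g.gene_id] * config.rate_body * (g.length / 2000.0) * depth_scale
        k = rng.poisson(lam)
        if k == 0:
            continue
        d = rng.integers(400, min(g.length - 1, 1500), size=k)
        u = g.start + rng.integers(0, g.length - d.max(), size=k) \
            if g.length - d.max() > 0 else np.full(k, g.start)
        chunks.append(_pairs_chunk(g.chrom, u, g.chrom, u + d, rng))
    return chunks


def _fivess_pairs(chromsizes, genes, factors, config, weight, rng, depth_scale):
    chunks = []
    for g in genes:
        ss = g.first_five_prime_ss()
        if ss is None:
            continue
        L = chromsizes[g.chrom]
        sgn = 1 if g.strand == "+" else -1
        for (w_lo, w_hi), rate in ((config.base_window, config.rate_base),
                                   (config.pause_window, config.rate_pause * weight)):
            k = rng.poisson(factors[g.gene_id] * rate * depth_scale)
            if k == 0:
                continue
            off = rng.integers(w_lo, w_hi, size=k)
            anchor = np.clip(ss + sgn * off, 0, L - 1).astype(np.int64)
            partner = _partner_positions(anchor, L, config, rng)
            chunks.append(_pairs_chunk(g.chrom, anchor, g.chrom, partner, rng))
    return chunks


def _expected_gene_density(chromsizes: ChromSizes, genes, factors,
                           config: SimulationConfig) -> dict[str, float]:
    """Expected both-ends-in-gene contact count per kb at reference depth.

    Planted gene-body component (zero for genes too short to carry it) plus
    the analytic expectation of background pairs falling entirely inside the
    gene body, integrated over the truncated power law by quadrature.
    """
    lengths = np.array([chromsizes[c] for c in chromsizes.names], dtype=float)
    n_intra = config.n_background_pairs * (1 - config.inter_fraction)
    per_bp = n_intra / lengths.sum()
    a = config.alpha
    s_min = float(config.d_min)
    out: dict[str, float] = {}
    for g in genes:
        L = float(chromsizes[g.chrom])
        if abs(a - 1.0) < 1e-12:
            norm = np.log(L / s_min)
        else:
            norm = (L ** (1 - a) - s_min ** (1 - a)) / (1 - a)
        planted = factors[g.gene_id] * config.rate_body * (g.length / 2000.0) \
            if g.length >= 900 else 0.0
        bg = 0.0
        if g.length > s_min:
            s = np.linspace(s_min, g.length, 64)
            f = s ** (-a) / norm
            bg = per_bp * L * np.trapezoid(f * (g.length - s) / (L - s), s)
        out[g.gene_id] = (planted + bg) / (g.length / 1_000.0)
    return out


# ---------------------------------------------------------------------------
# activity + expression
# ---------------------------------------------------------------------------

def simulate_activity_and_expression(
        chromsizes: ChromSizes, genes: list[GeneModel], truth: TruthSet,
        config: SimulationConfig, track_bin: int = 50,
        ) -> tuple[dict[str, SignalTrack], ExpressionMatrix]:
    """Activity tracks per condition and a three-condition expression matrix.

    Per-gene activity is coupled to the gene's total expected in-gene
    contact density (planted gene-body component plus the analytic
    power-law background expectation) through a Gaussian copula targeting
    the configured Spearman correlation (default 0.4).  Expression for
    loop-connected gene pairs shares a latent factor giving pairwise
    correlation ``expression_rho``; background genes are independent.
    """
    rho = config.expression_rho
    if not (-1.0 < rho < 1.0):
        raise ValueError("expression_rho must lie in (-1, 1)")
    factors, _ = _activity_factors_with_scores(config, genes)
    truth.activity_factor = dict(factors)
    dens = _expected_gene_density(chromsizes, genes, factors, config)
    truth.expected_density = dict(dens)

    # --- activity tracks (copula-coupled to the expected density) ---------
    rng = config.rng("activity-noise")
    rs = config.activity_coupling
    r = 2.0 * np.sin(np.pi * rs / 6.0)   # normal-copula r for target Spearman
    tracks: dict[str, SignalTrack] = {}
    # normal scores of the density ranks (average ranks for exact ties)
    gene_ids = [g.gene_id for g in genes]
    from scipy import stats as _stats
    ranks = _stats.rankdata([dens[g] for g in gene_ids])
    z_d = _stats.norm.ppf(ranks / (len(ranks) + 1))
    noise = rng.standard_normal(len(gene_ids))
    z_act = {gid: r * zd + np.sqrt(max(0.0, 1 - r * r)) * e
             for gid, zd, e in zip(gene_ids, z_d, noise)}
    for cond, w in config.condition_weights.items():
        vals = {c: np.zeros(-(-chromsizes[c] // track_bin))
                for c in chromsizes.names}
        for g in genes:
            level = w * float(np.exp(0.5 * z_act[g.gene_id]))
            b0, b1 = g.start // track_bin, -(-g.end // track_bin)
            vals[g.chrom][b0:b1] += level
        tracks[cond] = SignalTrack(values=vals, bin_width=track_bin)

    # --- expression -------------------------------------------------------
    rng = config.rng("expression")
    conditions = list(config.condition_weights)
    samples = [(c, f"rep{i + 1}") for c in conditions
               for i in range(config.n_replicates)]
    n_s = len(samples)
    gene_ids = [g.gene_id for g in genes]
    data = rng.standard_normal((len(gene_ids), n_s))
    index = {g: i for i, g in enumerate(gene_ids)}
    used: set[str] = set()
    planted: list[tuple[str, str]] = []
    for a, b in truth.coexpressed_pairs:
        if a in used or b in used or a not in index or b not in index:
            continue
        shared = rng.standard_normal(n_s)
        for g in (a, b):
            data[index[g]] = (np.sqrt(abs(rho)) * shared
                              + np.sqrt(1 - abs(rho)) * rng.standard_normal(n_s))
        if rho < 0:
            data[index[b]] = (-np.sqrt(abs(rho)) * shared
                              + np.sqrt(1 - abs(rho)) * rng.standard_normal(n_s))
        used.update((a, b))
        planted.append((a, b))
    truth.coexpressed_pairs = planted
    table = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"),
                         columns=pd.MultiIndex.from_tuples(
                             samples, names=["condition", "replicate"]))
    return tracks, ExpressionMatrix(table)


# ---------------------------------------------------------------------------
# linker reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_linker_reads(pairs: pd.DataFrame, config: SimulationConfig,
                          min_flank: int = 50, max_flank: int = 200,
                          seed: int | None = None) -> list[tuple[str, str]]:
    """Reads of the form flank1 + bridge-linker + flank2.

    Flank lengths are uniform on [min_flank, max_flank] (DNase fragments).
    Read names encode the true pair coordinates
    (``chrom1:pos1:strand1|chrom2:pos2:strand2|i``) so the pair can be
    recovered without alignment.  A ``decoy_fraction`` of linker-free random
    reads is appended.
    """
    if min_flank < 1:
        raise ValueError("min_flank must be positive")
    cfg = config if seed is None else _reseed(config, seed)
    rng = cfg.rng("reads")
    linker = config.linker
    reads: list[tuple[str, str]] = []
    for i, row in enumerate(pairs.itertuples(index=False)):
        l1 = int(rng.integers(min_flank, max_flank + 1))
        l2 = int(rng.integers(min_flank, max_flank + 1))
        f1 = "".join(_BASES[rng.integers(0, 4, l1)])
        f2 = "".join(_BASES[rng.integers(0, 4, l2)])
        name = (f"{row.chrom1}:{row.pos1}:{row.strand1}|"
                f"{row.chrom2}:{row.pos2}:{row.strand2}|{i}")
        reads.append((name, f1 + linker + f2))
    n_decoys = rng.binomial(len(pairs), config.decoy_fraction) \
        if config.decoy_fraction > 0 else 0
    for j in range(int(n_decoys)):
        while True:
            seq = "".join(_BASES[rng.integers(0, 4, 2 * max_flank)])
            if linker not in seq:
                break
        reads.append((f"decoy|{j}", seq))
    return reads
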