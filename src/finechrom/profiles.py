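"""Gene-level contact densities and meta-profiles around TSS/TTS and 5'SS.

Contact "density" at a position counts contact ENDS (each pair contributes
two), matching coverage-track semantics.  Meta-profiles are depth-normalized
(per million library contacts) so libraries of different depth are
comparable; for cross-condition comparison a per-condition Z-score over the
profile window removes residual depth differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GeneModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-gene contact density
# ---------------------------------------------------------------------------

def gene_contact_density(pairs: pd.DataFrame, genes: list[GeneModel],
                         library_total: int | None = None) -> pd.Series:
    """Normalized contact density per gene.

    Counts pairs with BOTH ends inside the gene body, divided by
    (gene length in kb x library_total / 10^6): contacts per kb per million
    library contacts.
    """
    if library_total is None:
        library_total = len(pairs)
    if library_total == 0:
        raise ValueError("library_total must be positive")
    out = {}
    by_chrom = {c: sub for c, sub in pairs.groupby("chrom1", sort=False)}
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            out[g.gene_id] = 0.0
            continue
        inside = ((sub["chrom2"] == g.chrom)
                  & (sub["pos1"] >= g.start) & (sub["pos1"] < g.end)
                  & (sub["pos2"] >= g.start) & (sub["pos2"] < g.end))
        n = int(inside.sum())
        out[g.gene_id] = n / ((g.length / 1_000) * (library_total / 1e6))
    return pd.Series(out, name="contact_density")


def stratify_by_percentile(values: pd.Series, pct: float = 10.0,
                           ) -> tuple[list[str], list[str]]:
    """Top and bottom *pct*% gene sets, ties broken by gene id.

    Set sizes are ceil(pct% x n); top and bottom are disjoint for pct <= 50.
    """
    if not (0 < pct <= 50):
        raise ValueError("pct must be in (0, 50]")
    n = len(values)
    # ceil of the requested fraction, capped so top and bottom stay disjoint
    k = min(int(np.ceil(pct / 100 * n)), n // 2)
    if values.nunique() == 1:
        logger.warning("all values equal; stratification is tie-broken by gene id")
    ranked = values.reset_index()
    ranked.columns = ["gene_id", "value"]
    ranked = ranked.sort_values(["value", "gene_id"], ascending=[False, True])
    top = ranked["gene_id"].head(k).tolist()
    bottom = ranked.sort_values(["value", "gene_id"],
                                ascending=[True, True])["gene_id"].head(k).tolist()
    return top, bottom


# ---------------------------------------------------------------------------
# meta-profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Per-position aggregate contact density for one or more groups."""

    offsets: np.ndarray                 # bp offsets or scaled-body bin index
    profiles: dict[str, np.ndarray]     # group/condition -> mean density
    group_sizes: dict[str, int]
    zscored: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, vals in self.profiles.items():
            for off, v in zip(self.offsets, vals):
                rows.append((group, off, v, self.group_sizes[group]))
        return pd.DataFrame(rows, columns=["group", "offset", "density", "n"])


def _ends_by_chrom(pairs: pd.DataFrame) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for col_c, col_p in (("chrom1", "pos1"), ("chrom2", "pos2")):
        for chrom, sub in pairs.groupby(col_c, sort=False):
            arr = sub[col_p].to_numpy()
            out[chrom] = np.concatenate([out[chrom], arr]) if chrom in out else arr
    return {c: np.sort(v) for c, v in out.items()}


def metagene_profile(pairs: pd.DataFrame, genes: list[GeneModel],
                     group_sets: dict[str, list[str]],
                     n_body_bins: int = 100,
                     library_total: int | None = None) -> MetaProfile:
    """Scaled-gene-body meta-profile of contact-end coverage per group.

    Each gene body is rescaled to *n_body_bins* bins; per-bin end density
    (ends per bp, depth-normalized per million) is averaged over the genes
    of each group.  Minus-strand genes are reversed so bin 0 is always the
    TSS.  Genes shorter than *n_body_bins* bp are excluded (logged).
    """
    if library_total is None:
        library_total = len(pairs)
    for name, members in group_sets.items():
        if len(members) == 0:
            raise ValueError(f"empty gene group {name!r}")
    by_id = {g.gene_id: g for g in genes}
    ends = _ends_by_chrom(pairs)
    scale = library_total / 1e6
    profiles, sizes = {}, {}
    for name, members in group_sets.items():
        acc = np.zeros(n_body_bins)
        used = 0
        for gid in members:
            g = by_id[gid]
            if g.length < n_body_bins:
                logger.info("gene %s shorter than %d bp; excluded from metagene",
                            gid, n_body_bins)
                continue
            chrom_ends = ends.get(g.chrom)
            if chrom_ends is None:
                used += 1
                continue
            lo = np.searchsorted(chrom_ends, g.start)
            hi = np.searchsorted(chrom_ends, g.end)
            rel = (chrom_ends[lo:hi] - g.start) / g.length
            hist = np.bincount((rel * n_body_bins).astype(int).clip(0, n_body_bins - 1),
                               minlength=n_body_bins).astype(float)
            hist /= g.length / n_body_bins          # ends per bp
            if g.strand == "-":
                hist = hist[::-1]
            acc += hist / scale
            used += 1
        if used == 0:
            raise ValueError(f"no usable genes in group {name!r}")
        profiles[name] = acc / used
        sizes[name] = used
    return MetaProfile(offsets=np.arange(n_body_bins), profiles=profiles,
                       group_sizes=sizes)


def splice_site_profile(pairs_by_condition: dict[str, pd.DataFrame] | pd.DataFrame,
                        genes: list[GeneModel],
                        window: tuple[int, int] = (-100, 200),
                        first_only: bool = True,
                        zscore: bool | None = None) -> MetaProfile:
    """Per-bp contact-end density around 5' splice sites, per condition.

    Offsets are transcription-oriented: positive = downstream of the 5'SS
    (into the intron).  ``first_only`` restricts to each gene's first 5'SS.
    With several conditions the per-condition profiles are Z-scored over the
    window (population sd), removing sequencing-depth differences.
    """
    if isinstance(pairs_by_condition, pd.DataFrame):
        pairs_by_condition = {"all": pairs_by_condition}
    if zscore is None:
        zscore = len(pairs_by_condition) > 1
    lo, hi = window
    width = hi - lo
    anchors = []   # (chrom, site, sign)
    for g in genes:
        sites = g.five_prime_splice_sites()
        if not sites:
            continue
        if first_only:
            sites = sites[:1]
        sgn = 1 if g.strand == "+" else -1
        anchors += [(g.chrom, s, sgn) for s in sites]
    if not anchors:
        raise ValueError("no multi-exon genes: no 5' splice sites to profile")
    profiles, sizes = {}, {}
    for cond, pairs in pairs_by_condition.items():
        ends = _ends_by_chrom(pairs)
        acc = np.zeros(width)
        for chrom, site, sgn in anchors:
            chrom_ends = ends.get(chrom)
            if chrom_ends is None:
                continue
            if sgn > 0:
                a, b = site + lo, site + hi
                sel_lo = np.searchsorted(chrom_ends, a)
                sel_hi = np.searchsorted(chrom_ends, b)
                rel = chrom_ends[sel_lo:sel_hi] - a
            else:
                a, b = site - hi + 1, site - lo + 1
                sel_lo = np.searchsorted(chrom_ends, a)
                sel_hi = np.searchsorted(chrom_ends, b)
                rel = (width - 1) - (chrom_ends[sel_lo:sel_hi] - a)
            acc += np.bincount(rel, minlength=width)[:width]
        prof = acc / len(anchors) / (len(pairs) / 1e6)
        if zscore:
            sd = prof.std()   # population sd over the window
            if sd == 0:
                raise ValueError(f"flat profile for condition {cond!r}; "
                                 "cannot Z-score")
            prof = (prof - prof.mean()) / sd
        profiles[cond] = prof
        sizes[cond] = len(anchors)
    return MetaProfile(offsets=np.arange(lo, hi), profiles=profiles,
                       group_sizes=sizes, zscored=zscore)


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; two-sided p-value.

    Exact permutation p for n <= 9, t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact two-sided permutation distribution of the statistic
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(rx_c[list(perm)] @ ry_c)
            if stat >= obs - 1e-12 * denom:
                count += 1
            total += 1
        return rs, count / total
    t = rs * np.sqrt((n - 2) / max(1e-300, 1.0 - rs * rs))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rs, float(min(p, 1.0))
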