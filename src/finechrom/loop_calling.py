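"""Stable-contact (loop) calling against a distance-decay expected model.

The null model assigns every intra-chromosomal bin pair a contact probability
p(s) depending only on its genomic separation s, estimated from
equal-occupancy distance bins and smoothed to be monotone non-increasing
(pool-adjacent-violators).  Each occupied bin pair with observed count k is
tested with P(X >= k), X ~ Binomial(N, p(s)), N the library contact total;
Benjamini-Hochberg controls the FDR over all tested pairs.  Bin pairs with
q below threshold are the "stable chromatin contacts".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .contact_processing import ContactMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpectedModel:
    """Piecewise-constant expected contact probability p(s) per distance bin."""

    distance_edges: np.ndarray   # bp, len = n_bins + 1
    p: np.ndarray                # probability per distance bin, monotone non-increasing
    total: int                   # contact total N the model was fit on

    def p_of_distance(self, distances: np.ndarray) -> np.ndarray:
        """Expected per-pair contact probability at the given separations (bp)."""
        idx = np.searchsorted(self.distance_edges, distances, side="right") - 1
        idx = np.clip(idx, 0, len(self.p) - 1)
        return self.p[idx]

    @property
    def d_min(self) -> float:
        return float(self.distance_edges[0])

    @property
    def d_max(self) -> float:
        return float(self.distance_edges[-1])


def _pairs_at_distance(matrix: ContactMatrix, sep_bins: np.ndarray) -> np.ndarray:
    """Number of possible locus (bin) pairs at each separation, summed over
    chromosomes."""
    out = np.zeros(len(sep_bins), dtype=np.int64)
    for chrom in matrix.chromsizes.names:
        n = matrix.n_bins(chrom)
        out += np.maximum(n - sep_bins, 0)
    return out


def default_d_max(matrix: ContactMatrix) -> int:
    """Default upper distance bound for testing: one third of the longest
    chromosome.  The per-pair expected rate carries a placement factor
    1/(L - s) (the number of positions a pair at separation s can occupy);
    beyond ~L/3 that factor varies strongly *within* a pooled distance bin
    and the piecewise-constant expected model becomes anti-conservative, so
    longer separations (telomere-to-telomere scale) are excluded from
    significance testing."""
    longest = max(matrix.n_bins(c) for c in matrix.chromsizes.names)
    return int(longest * matrix.resolution / 3)


def fit_expected(matrix: ContactMatrix, n_distance_bins: int = 100,
                 min_distance: int = 1_000,
                 d_max: int | None = None) -> ExpectedModel:
    """Fit the distance-decay expected model on intra-chromosomal counts.

    Distances are partitioned into roughly equal-occupancy bins (equal total
    contact counts per bin) over [min_distance, d_max].  Raw p(s) =
    (contacts in bin) / (N x possible locus pairs at those separations);
    pool-adjacent-violators enforces monotone non-increase with distance.
    """
    coo = matrix.intra_coo()
    res = matrix.resolution
    N = matrix.total
    if len(coo) == 0 or N == 0:
        raise ValueError("empty matrix")
    if d_max is None:
        d_max = default_d_max(matrix)
    sep = (coo["bin2"].to_numpy() - coo["bin1"].to_numpy())
    keep = (sep * res >= min_distance) & (sep * res <= d_max)
    sep = sep[keep]
    cnt = coo["count"].to_numpy()[keep]
    if len(sep) == 0:
        raise ValueError("no contacts beyond min_distance")
    # aggregate counts per separation (in bins)
    seps, inv = np.unique(sep, return_inverse=True)
    per_sep = np.bincount(inv, weights=cnt)
    if len(seps) < n_distance_bins:
        logger.warning("only %d occupied separations; reducing distance bins "
                       "from %d", len(seps), n_distance_bins)
        n_distance_bins = max(1, len(seps))
    # equal-occupancy split on cumulative counts
    cum = np.cumsum(per_sep)
    targets = np.linspace(0, cum[-1], n_distance_bins + 1)[1:-1]
    cut = np.searchsorted(cum, targets, side="left")
    cut = np.unique(np.concatenate(([0], cut + 1, [len(seps)])))
    edges_bins = np.concatenate((seps[cut[:-1]], [seps[-1] + 1]))
    npairs = _pairs_at_distance(matrix, np.arange(seps[-1] + 1))
    bin_counts = np.add.reduceat(per_sep, cut[:-1])
    # possible pairs per distance bin
    bin_pairs = np.array([
        npairs[edges_bins[i]:edges_bins[i + 1]].sum()
        for i in range(len(edges_bins) - 1)
    ], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_p = np.where(bin_pairs > 0, bin_counts / (N * bin_pairs), 0.0)
    centers = 0.5 * (edges_bins[:-1] + edges_bins[1:]) * res
    iso = IsotonicRegression(increasing=False, y_min=np.finfo(float).tiny)
    smooth = iso.fit_transform(centers, raw_p, sample_weight=np.maximum(bin_pairs, 1))
    smooth = np.minimum(smooth, 1.0)
    return ExpectedModel(distance_edges=edges_bins * float(res), p=smooth, total=N)


def binom_pvalue(k, N: int, p) -> np.ndarray | float:
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(N, p).

    Evaluated via the survival function, stable for large N.  Vectorized over
    k and p.
    """
    k = np.asarray(k)
    p = np.asarray(p)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must be in (0, 1)")
    if np.any(k < 0) or np.any(k > N):
        raise ValueError("k must satisfy 0 <= k <= N")
    out = stats.binom.sf(k - 1, N, p)
    return float(out) if out.ndim == 0 else out


def bh_qvalues(pvalues: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    With *m* larger than ``len(pvalues)`` the correction treats the missing
    tests as p = 1 (bin pairs with zero observed contacts are implicitly
    tested and can never be rejected, but they belong in the family).
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be at least len(pvalues)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


@dataclass
class LoopCallResult:
    """Stable-contact calls plus the full table of tested bin pairs."""

    calls: pd.DataFrame     # rows passing the q threshold, sorted by (q, distance)
    tested: pd.DataFrame    # every tested bin pair with pvalue/qvalue
    q_threshold: float

    @property
    def n_tested(self) -> int:
        return len(self.tested)


CALL_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                "bin1", "bin2", "count", "p_expected", "pvalue", "qvalue"]


def call_stable_contacts(matrix: ContactMatrix, model: ExpectedModel,
                         q_threshold: float = 0.01,
                         min_distance: int = 1_000) -> LoopCallResult:
    """Test every occupied intra-chromosomal bin pair against the expected
    model; BH-correct over all tested pairs; return pairs with q <= threshold.

    Inter-chromosomal pairs are not tested (the expected model is
    distance-based).
    """
    res = matrix.resolution
    coo = matrix.intra_coo()
    if len(coo) == 0:
        empty = pd.DataFrame(columns=CALL_COLUMNS)
        return LoopCallResult(calls=empty, tested=empty.copy(), q_threshold=q_threshold)
    dist = (coo["bin2"].to_numpy() - coo["bin1"].to_numpy()) * res
    keep = (dist >= max(min_distance, model.d_min)) & (dist < model.d_max)
    coo = coo.loc[keep].reset_index(drop=True)
    dist = dist[keep]
    k = coo["count"].to_numpy()
    p_exp = model.p_of_distance(dist)
    pvals = binom_pvalue(k, model.total, p_exp)
    # family size = every possible intra-chromosomal bin pair in the tested
    # distance range; conditioning BH on occupancy alone would be
    # anti-conservative (occupancy is itself selection on the test statistic)
    lo_bins = int(np.ceil(max(min_distance, model.d_min) / res))
    hi_bins = int(model.d_max // res)
    m_total = 0
    for chrom in matrix.chromsizes.names:
        n = matrix.n_bins(chrom)
        ks = np.arange(lo_bins, min(hi_bins, n - 1) + 1)
        m_total += int(np.maximum(n - ks, 0).sum())
    qvals = bh_qvalues(pvals, m=max(m_total, len(pvals)))
    tested = pd.DataFrame({
        "chrom1": coo["chrom"], "start1": coo["bin1"] * res,
        "end1": (coo["bin1"] + 1) * res,
        "chrom2": coo["chrom"], "start2": coo["bin2"] * res,
        "end2": (coo["bin2"] + 1) * res,
        "bin1": coo["bin1"], "bin2": coo["bin2"],
        "count": k, "p_expected": p_exp, "pvalue": pvals, "qvalue": qvals,
    })
    calls = tested.loc[tested["qvalue"] <= q_threshold].copy()
    calls["distance"] = calls["start2"] - calls["start1"]
    calls = calls.sort_values(["qvalue", "distance"]).drop(columns="distance")
    return LoopCallResult(calls=calls.reset_index(drop=True), tested=tested,
                          q_threshold=q_threshold)


def intersect_conditions(calls_by_condition: dict[str, pd.DataFrame],
                         resolution: int | None = None,
                         slack_bins: int = 0) -> pd.DataFrame:
    """Bin pairs called in *every* condition ("primed" contacts).

    Matching is exact on (chrom, bin1, bin2); with ``slack_bins=1`` an anchor
    may shift by one bin.  Input frames must come from the same resolution.
    """
    if len(calls_by_condition) < 2:
        raise ValueError("need calls from at least two conditions")
    frames = list(calls_by_condition.values())
    if resolution is None:
        sizes = {int(f["end1"].iloc[0] - f["start1"].iloc[0])
                 for f in frames if len(f)}
        if len(sizes) > 1:
            raise ValueError(f"mismatched resolutions: {sorted(sizes)}")
    keysets = []
    for f in frames:
        keysets.append(set(zip(f["chrom1"], f["bin1"], f["bin2"])))
    if slack_bins == 0:
        common = set.intersection(*keysets)
        base = frames[0]
        mask = [
            (c, b1, b2) in common
            for c, b1, b2 in zip(base["chrom1"], base["bin1"], base["bin2"])
        ]
        return base.loc[mask].reset_index(drop=True)
    # slack matching: a call survives if every other condition has a call
    # within +/- slack_bins on both anchors
    base = frames[0]
    out_rows = []
    for row in base.itertuples(index=False):
        key = (row.chrom1, row.bin1, row.bin2)
        ok = True
        for ks in keysets[1:]:
            if not any(
                (key[0], key[1] + di, key[2] + dj) in ks
                for di in range(-slack_bins, slack_bins + 1)
                for dj in range(-slack_bins, slack_bins + 1)
            ):
                ok = False
                break
        if ok:
            out_rows.append(row)
    return pd.DataFrame(out_rows, columns=base.columns)
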