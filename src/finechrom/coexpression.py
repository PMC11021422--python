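"""Co-expression of PPI-connected gene pairs versus matched random pairs.

Observed statistic: the mean pairwise Pearson correlation of expression
(across conditions x replicates) over the PPI-connected gene pairs.  Two
permutation nulls:

* model A — the same number of uniformly random distinct gene pairs;
* model B — random same-chromosome gene pairs matched to the PPI pairs'
  TSS-separation distribution in log2 distance bins (trans PPI pairs are
  matched by random trans pairs).

Each null is resampled ``n_reps`` times (default 1000); the empirical
one-sided p-value uses the add-one estimator and can never be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix, GeneModel

logger = logging.getLogger(__name__)


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two (n, k) matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def pair_expression_correlation(expr: ExpressionMatrix | pd.DataFrame,
                                gene_pairs: list[tuple[str, str]],
                                conditions=None) -> np.ndarray:
    """Pearson r across the sample vector for each gene pair.

    Pairs with a constant expression vector are excluded (logged).  Requires
    at least 3 samples.
    """
    table = expr.sample_matrix(conditions) if isinstance(expr, ExpressionMatrix) \
        else expr
    if table.shape[1] < 3:
        raise ValueError("need at least 3 expression samples per gene")
    idx = {g: i for i, g in enumerate(table.index)}
    data = table.to_numpy(dtype=float)
    ia = np.array([idx[a] for a, _ in gene_pairs])
    ib = np.array([idx[b] for _, b in gene_pairs])
    r = _row_pearson(data[ia], data[ib])
    bad = np.isnan(r)
    if bad.any():
        logger.warning("excluded %d pairs with constant expression", int(bad.sum()))
    return r[~bad]


@dataclass
class PairSampler:
    """Random gene-pair sampler for both null models, with a cached
    distance-bin index for model B."""

    genes: list[GeneModel]
    d_min: float = 1_000.0

    def __post_init__(self) -> None:
        self.gene_ids = [g.gene_id for g in self.genes]
        chroms = np.array([g.chrom for g in self.genes])
        tss = np.array([g.tss for g in self.genes], dtype=float)
        self._chroms, self._tss = chroms, tss
        # all same-chromosome candidate pairs, indexed by log2 distance bin
        ii, jj, dd = [], [], []
        for chrom in np.unique(chroms):
            w = np.flatnonzero(chroms == chrom)
            if len(w) < 2:
                continue
            a, b = np.triu_indices(len(w), k=1)
            ii.append(w[a])
            jj.append(w[b])
            dd.append(np.abs(tss[w[a]] - tss[w[b]]))
        self._cis_i = np.concatenate(ii)
        self._cis_j = np.concatenate(jj)
        cis_d = np.concatenate(dd)
        self._cis_bin = self._bin_of(cis_d)
        self._by_bin = {b: np.flatnonzero(self._cis_bin == b)
                        for b in np.unique(self._cis_bin)}
        self._bins_sorted = np.array(sorted(self._by_bin))
        a, b = np.triu_indices(len(self.genes), k=1)
        trans = chroms[a] != chroms[b]
        self._trans_i, self._trans_j = a[trans], b[trans]

    def _bin_of(self, d: np.ndarray) -> np.ndarray:
        return np.floor(np.log2(np.maximum(d, self.d_min) / self.d_min)).astype(int)

    def cis_distances(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        idx = {g: k for k, g in enumerate(self.gene_ids)}
        d = []
        for a, b in pairs:
            if self._chroms[idx[a]] == self._chroms[idx[b]]:
                d.append(abs(self._tss[idx[a]] - self._tss[idx[b]]))
        return np.array(d)

    def n_trans(self, pairs: list[tuple[str, str]]) -> int:
        idx = {g: k for k, g in enumerate(self.gene_ids)}
        return sum(self._chroms[idx[a]] != self._chroms[idx[b]] for a, b in pairs)

    def exclusion_keys(self, pairs: list[tuple[str, str]]) -> set[tuple[int, int]]:
        idx = {g: k for k, g in enumerate(self.gene_ids)}
        return {tuple(sorted((idx[a], idx[b]))) for a, b in pairs}

    def sample(self, model: str, n: int | None, rng: np.random.Generator,
               cis_distances: np.ndarray | None = None,
               n_trans: int = 0,
               exclude: set[tuple[int, int]] | None = None,
               ) -> list[tuple[str, str]]:
        """Draw one replicate of random gene pairs.

        model A: *n* uniform random distinct pairs.  model B: one
        same-chromosome pair per entry of *cis_distances*, drawn from the
        matching log2 distance bin (widening to neighbouring bins when the
        bin's candidates are exhausted, with a warning), plus *n_trans*
        random trans pairs.  No pair is repeated within a replicate, and
        pairs in *exclude* (typically the observed PPI pairs — controls must
        be non-PPI pairs) are never drawn.
        """
        chosen: set[tuple[int, int]] = set(exclude) if exclude else set()
        out: list[tuple[str, str]] = []

        def _add(i: int, j: int) -> bool:
            key = (min(i, j), max(i, j))
            if key in chosen:
                return False
            chosen.add(key)
            out.append((self.gene_ids[key[0]], self.gene_ids[key[1]]))
            return True

        if model == "A":
            if n is None:
                raise ValueError("model A requires n")
            n_genes = len(self.gene_ids)
            while len(out) < n:
                i, j = rng.integers(0, n_genes, 2)
                if i != j:
                    _add(int(i), int(j))
            return out
        if model != "B":
            raise ValueError(f"unknown null model {model!r}")
        if cis_distances is None:
            raise ValueError("model B requires the PPI cis-distance multiset")
        for d in cis_distances:
            b0 = int(self._bin_of(np.array([d]))[0])
            placed = False
            for width in range(0, len(self._bins_sorted) + 1):
                bins = [b for b in (b0 - width, b0 + width) if b in self._by_bin] \
                    if width else ([b0] if b0 in self._by_bin else [])
                if width and not bins:
                    continue
                if width:
                    logger.debug("distance bin %d exhausted; widening to +/-%d",
                                 b0, width)
                for b in bins:
                    cand = self._by_bin[b]
                    tries = min(4 * len(cand), 200)
                    for _ in range(tries):
                        k = cand[rng.integers(0, len(cand))]
                        if _add(int(self._cis_i[k]), int(self._cis_j[k])):
                            placed = True
                            break
                    if placed:
                        break
                if placed:
                    break
            if not placed:
                logger.warning("could not place a control pair for distance %g",
                               float(d))
        for _ in range(n_trans):
            if len(self._trans_i) == 0:
                break
            for _ in range(200):
                k = rng.integers(0, len(self._trans_i))
                if _add(int(self._trans_i[k]), int(self._trans_j[k])):
                    break
        return out


def sample_random_pairs(genes: list[GeneModel], n: int, model: str,
                        seed: int, ppi_pairs=None,
                        sampler: PairSampler | None = None,
                        ) -> list[tuple[str, str]]:
    """One replicate of control gene pairs (see :class:`PairSampler.sample`)."""
    if sampler is None:
        sampler = PairSampler(genes)
    rng = np.random.default_rng(seed)
    if model == "A":
        return sampler.sample("A", n, rng)
    if ppi_pairs is None:
        raise ValueError("model B requires the observed PPI pairs")
    return sampler.sample("B", None, rng,
                          cis_distances=sampler.cis_distances(ppi_pairs),
                          n_trans=sampler.n_trans(ppi_pairs),
                          exclude=sampler.exclusion_keys(ppi_pairs))


@dataclass
class CoexpressionResult:
    """Observed co-expression of PPI pairs against both permutation nulls."""

    observed_mean: float
    observed_median: float
    n_pairs: int
    n_reps: int
    null_means: dict[str, np.ndarray] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {
            "observed_mean_r": self.observed_mean,
            "observed_median_r": self.observed_median,
            "n_pairs": self.n_pairs,
            "n_reps": self.n_reps,
        }
        for model, nulls in self.null_means.items():
            out[f"null_{model}_mean"] = float(np.mean(nulls))
            out[f"null_{model}_sd"] = float(np.std(nulls))
            out[f"p_{model}"] = self.p_values[model]
        return out


def compare_to_null(expr: ExpressionMatrix | pd.DataFrame,
                    genes: list[GeneModel],
                    ppi_pairs: list[tuple[str, str]],
                    n_reps: int = 1000, seed: int = 0,
                    models: tuple[str, ...] = ("A", "B"),
                    sampler: PairSampler | None = None,
                    conditions=None) -> CoexpressionResult:
    """Permutation test of PPI-pair co-expression against both null models.

    Each replicate draws fresh random pairs and records their mean pairwise
    Pearson r; p = (1 + #{null >= observed}) / (1 + n_reps), one-sided
    (the directional claim is *higher* co-expression).
    """
    if n_reps < 100:
        logger.warning("n_reps=%d is small; the empirical p-value will be "
                       "unstable", n_reps)
    if sampler is None:
        sampler = PairSampler(genes)
    observed_rs = pair_expression_correlation(expr, ppi_pairs, conditions)
    obs_mean = float(np.mean(observed_rs))
    cis_d = sampler.cis_distances(ppi_pairs)
    n_trans = sampler.n_trans(ppi_pairs)
    exclude = sampler.exclusion_keys(ppi_pairs)
    table = expr.sample_matrix(conditions) if isinstance(expr, ExpressionMatrix) \
        else expr
    result = CoexpressionResult(
        observed_mean=obs_mean,
        observed_median=float(np.median(observed_rs)),
        n_pairs=len(ppi_pairs), n_reps=n_reps)
    rng = np.random.default_rng(seed)
    for model in models:
        means = np.empty(n_reps)
        for rep in range(n_reps):
            if model == "A":
                rand = sampler.sample("A", len(ppi_pairs), rng,
                                      exclude=exclude)
            else:
                rand = sampler.sample("B", None, rng, cis_distances=cis_d,
                                      n_trans=n_trans, exclude=exclude)
            rs = pair_expression_correlation(table, rand)
            means[rep] = np.mean(rs)
        result.null_means[model] = means
        result.p_values[model] = float((1 + np.sum(means >= obs_mean))
                                       / (1 + n_reps))
    return result
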