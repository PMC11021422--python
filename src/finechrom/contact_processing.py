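"""From raw reads/pairs to filtered, binned, normalized contact matrices.

A valid chromatin contact is a read carrying the bridge-linker sequence in its
middle; the flanks on either side are the two interacting loci.  Downstream,
pairs are MAPQ- and distance-filtered, deduplicated, binned at fixed
resolution (200 bp default), and vanilla-coverage (VC) normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .formats_io import ChromSizes, PAIR_COLUMNS, canonicalize_pairs

logger = logging.getLogger(__name__)

#: Bridge-linker search string: the F-oligo sequence with chemistry tags stripped.
DEFAULT_LINKER = "GTCAGAAAGATATCGCGT"


# ---------------------------------------------------------------------------
# linker splitting
# ---------------------------------------------------------------------------

def split_linker_read(read_seq: str, linker_seq: str = DEFAULT_LINKER,
                      min_flank: int = 20, max_mismatches: int = 0,
                      ) -> tuple[str, str] | None:
    """Split a read at the first bridge-linker occurrence.

    Returns (flank1, flank2), or None if the linker is absent or either flank
    is shorter than *min_flank*.  Matching is exact by default; with
    ``max_mismatches=1`` a single substitution in the linker is tolerated.
    """
    if not linker_seq:
        raise ValueError("linker sequence must be non-empty")
    idx = read_seq.find(linker_seq)
    if idx < 0 and max_mismatches > 0:
        L = len(linker_seq)
        lk = np.frombuffer(linker_seq.encode(), dtype=np.uint8)
        rd = np.frombuffer(read_seq.encode(), dtype=np.uint8)
        for i in range(len(rd) - L + 1):
            if int((rd[i:i + L] != lk).sum()) <= max_mismatches:
                idx = i
                break
    if idx < 0:
        return None
    flank1 = read_seq[:idx]
    flank2 = read_seq[idx + len(linker_seq):]
    if len(flank1) < min_flank or len(flank2) < min_flank:
        return None
    return flank1, flank2


def pairs_from_linker_reads(records, chromsizes: ChromSizes,
                            linker_seq: str = DEFAULT_LINKER,
                            min_flank: int = 20) -> pd.DataFrame:
    """Recover contact pairs from simulated linker reads.

    Reads are (name, sequence) records whose names encode the true
    coordinates as ``chrom1:pos1:strand1|chrom2:pos2:strand2|...``; reads
    without a linker (decoys) are discarded.  No alignment is performed —
    coordinates come from the read names.
    """
    rows = []
    for name, seq in records:
        if split_linker_read(seq, linker_seq, min_flank=min_flank) is None:
            continue
        left, right = name.split("|")[:2]
        c1, p1, s1 = left.split(":")
        c2, p2, s2 = right.split(":")
        rows.append((c1, int(p1), s1, c2, int(p2), s2, 60, 60))
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return canonicalize_pairs(df, chromsizes)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of pairs removed by each filter; sums to input minus output."""

    n_input: int = 0
    n_low_mapq: int = 0
    n_short_range: int = 0
    n_duplicates: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def filter_pairs(pairs: pd.DataFrame, mapq_min: int = 10,
                 min_distance: int = 400, dedup: bool = True,
                 ) -> tuple[pd.DataFrame, FilterReport]:
    """MAPQ >= *mapq_min* on both ends; drop intra-chromosomal pairs closer
    than *min_distance* (self-ligation guard, default two 200-bp bins);
    collapse exact duplicates (all coordinates and both strands)."""
    rep = FilterReport(n_input=len(pairs))
    keep = np.minimum(pairs["mapq1"].to_numpy(), pairs["mapq2"].to_numpy()) >= mapq_min
    rep.n_low_mapq = int((~keep).sum())
    df = pairs.loc[keep]
    intra = df["chrom1"].to_numpy() == df["chrom2"].to_numpy()
    short = intra & (np.abs(df["pos2"].to_numpy() - df["pos1"].to_numpy()) < min_distance)
    rep.n_short_range = int(short.sum())
    df = df.loc[~short]
    if dedup:
        before = len(df)
        df = df.drop_duplicates(subset=PAIR_COLUMNS)
        rep.n_duplicates = before - len(df)
    rep.n_output = len(df)
    return df.reset_index(drop=True), rep


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Sparse symmetric binned contact counts at fixed resolution.

    Intra-chromosomal maps store the upper triangle (i <= j); the per-pair
    sparse matrices are keyed by (chrom1, chrom2) in chromosome order.
    """

    resolution: int
    chromsizes: ChromSizes
    maps: dict[tuple[str, str], sp.csr_matrix] = field(default_factory=dict)

    @property
    def total(self) -> int:
        """Total contact count N (sum of all stored counts)."""
        return int(sum(m.sum() for m in self.maps.values()))

    def n_bins(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.resolution)

    def intra(self, chrom: str) -> sp.csr_matrix:
        n = self.n_bins(chrom)
        return self.maps.get((chrom, chrom), sp.csr_matrix((n, n)))

    def intra_coo(self) -> pd.DataFrame:
        """All intra-chromosomal occupied bin pairs as a tidy frame."""
        rows = []
        for chrom in self.chromsizes.names:
            m = self.intra(chrom).tocoo()
            if m.nnz:
                rows.append(pd.DataFrame({
                    "chrom": chrom, "bin1": m.row, "bin2": m.col, "count": m.data}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "bin1", "bin2", "count"])
        return pd.concat(rows, ignore_index=True)

    def to_coo_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom1\tbin1\tchrom2\tbin2\tcount\n")
            for (c1, c2), m in sorted(self.maps.items()):
                coo = m.tocoo()
                for i, j, v in zip(coo.row, coo.col, coo.data):
                    fh.write(f"{c1}\t{i}\t{c2}\t{j}\t{v:.10g}\n")


def bin_contacts(pairs: pd.DataFrame, resolution: int,
                 chromsizes: ChromSizes) -> ContactMatrix:
    """Bin pairs at *resolution*; bin index = floor(pos / resolution).

    The matrix total N equals the number of input pairs.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    mat = ContactMatrix(resolution=resolution, chromsizes=chromsizes)
    b1 = pairs["pos1"].to_numpy() // resolution
    b2 = pairs["pos2"].to_numpy() // resolution
    grouped = pd.DataFrame({
        "chrom1": pairs["chrom1"].to_numpy(), "chrom2": pairs["chrom2"].to_numpy(),
        "b1": b1, "b2": b2,
    })
    for (c1, c2), sub in grouped.groupby(["chrom1", "chrom2"], sort=False):
        i = sub["b1"].to_numpy()
        j = sub["b2"].to_numpy()
        if c1 == c2:
            i, j = np.minimum(i, j), np.maximum(i, j)
        n1, n2 = mat.n_bins(c1), mat.n_bins(c2)
        m = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(n1, n2)).tocsr()
        key = (c1, c2)
        if key in mat.maps:
            mat.maps[key] = mat.maps[key] + m
        else:
            mat.maps[key] = m
    return mat


# ---------------------------------------------------------------------------
# VC normalization
# ---------------------------------------------------------------------------

def vc_normalize(matrix: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage normalization of each intra-chromosomal map.

    M'_ij = M_ij / (r_i * r_j) with r_i the full (symmetrized) row sum of bin
    i, then rescaled so the total mass of the map is preserved.  Zero-coverage
    bins stay zero.  Idempotent up to global scale on strictly positive maps.
    """
    out = ContactMatrix(resolution=matrix.resolution, chromsizes=matrix.chromsizes)
    for key, m in matrix.maps.items():
        c1, c2 = key
        if c1 != c2:
            out.maps[key] = m.copy()
            continue
        total = m.sum()
        if total == 0:
            logger.warning("vc_normalize: all-zero matrix for %s left unchanged", c1)
            out.maps[key] = m.copy()
            continue
        sym = m + m.T - sp.diags(m.diagonal())
        r = np.asarray(sym.sum(axis=1)).ravel()
        inv = np.zeros_like(r, dtype=float)
        nz = r > 0
        inv[nz] = 1.0 / r[nz]
        coo = m.tocoo()
        data = coo.data * inv[coo.row] * inv[coo.col]
        scale = total / data.sum() if data.sum() > 0 else 1.0
        out.maps[key] = sp.coo_matrix((data * scale, (coo.row, coo.col)),
                                      shape=m.shape).tocsr()
    return out


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DecayCurve:
    """Depth-normalized contact density versus genomic distance with a
    power-law fit (density ~ s^-alpha)."""

    bin_edges: np.ndarray      # distance bin edges, bp
    density: np.ndarray        # contacts per bp per contact (depth-normalized)
    alpha: float               # fitted decay exponent
    alpha_se: float

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.centers, "density": self.density})


def decay_curve(pairs: pd.DataFrame, d_min: int = 1_000, d_max: int = 10_000_000,
                n_bins: int = 50) -> DecayCurve:
    """Distance-decay curve from intra-chromosomal pairs.

    Log-spaced distance bins on [d_min, d_max]; density = count / (N x bin
    width in bp), so the curve is invariant to sequencing depth.  The decay
    exponent alpha is the negated slope of a least-squares fit of log density
    on log distance over occupied bins (at least 3 required).
    """
    intra = pairs["chrom1"].to_numpy() == pairs["chrom2"].to_numpy()
    d = np.abs(pairs["pos2"].to_numpy() - pairs["pos1"].to_numpy())[intra]
    d = d[(d >= d_min) & (d < d_max)]
    if len(d) == 0:
        raise ValueError("no intra-chromosomal contacts in distance range")
    edges = np.logspace(np.log10(d_min), np.log10(d_max), n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    density = counts / (len(pairs) * widths)
    occ = counts > 0
    if occ.sum() < 3:
        raise ValueError("fewer than 3 occupied distance bins; refusing to fit")
    centers = np.sqrt(edges[:-1] * edges[1:])
    res = stats.linregress(np.log(centers[occ]), np.log(density[occ]))
    return DecayCurve(bin_edges=edges, density=density,
                      alpha=-res.slope, alpha_se=res.stderr)


# ---------------------------------------------------------------------------
# replicate correlation
# ---------------------------------------------------------------------------

def replicate_correlation(matrix_a: ContactMatrix, matrix_b: ContactMatrix,
                          d_max: int | None = None,
                          ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of log1p counts over the union of occupied
    intra-chromosomal bin pairs, overall and per log2 distance stratum."""
    if matrix_a.resolution != matrix_b.resolution:
        raise ValueError("matrices must share a resolution")
    res = matrix_a.resolution
    xs, ys, ds = [], [], []
    for chrom in matrix_a.chromsizes.names:
        ma, mb = matrix_a.intra(chrom), matrix_b.intra(chrom)
        union = (ma != 0) + (mb != 0)
        union = union.tocoo()
        if union.nnz == 0:
            continue
        i, j = union.row, union.col
        dist = (j - i) * res
        if d_max is not None:
            keep = dist <= d_max
            i, j, dist = i[keep], j[keep], dist[keep]
        xs.append(np.asarray(ma[i, j]).ravel())
        ys.append(np.asarray(mb[i, j]).ravel())
        ds.append(dist)
    if not xs:
        raise ValueError("no occupied bin pairs in either matrix")
    x = np.log1p(np.concatenate(xs))
    y = np.log1p(np.concatenate(ys))
    d = np.concatenate(ds)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: degenerate occupancy")
    overall = float(stats.pearsonr(x, y)[0])
    strata = np.floor(np.log2(np.maximum(d, res) / res)).astype(int)
    rows = []
    for s in np.unique(strata):
        mask = strata == s
        if mask.sum() >= 3 and x[mask].std() > 0 and y[mask].std() > 0:
            r = float(stats.pearsonr(x[mask], y[mask])[0])
            rows.append((res * 2 ** s, res * 2 ** (s + 1), int(mask.sum()), r))
    per = pd.DataFrame(rows, columns=["d_lo", "d_hi", "n", "pearson_r"])
    return overall, per
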