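"""Readers and writers for every external representation the pipeline touches.

All internal coordinates are 0-based, half-open.  GFF3 (1-based, closed) is
converted at the boundary.  Contact pairs are kept in a pandas DataFrame with
the columns :data:`PAIR_COLUMNS`; a :class:`ContactPair` named tuple is
provided for scalar access.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the canonical contact-pair table.
PAIR_COLUMNS = [
    "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2",
    "mapq1", "mapq2",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length (bp) mapping.

    The order of appearance defines the chromosome order used for pair
    canonicalization.
    """

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.sizes)) != len(self.sizes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def rank(self, name: str) -> int:
        """Position of *name* in the chromosome order."""
        return self.names.index(name)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 'name length'")
                sizes[parts[0]] = int(parts[1])
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")


class ContactPair(NamedTuple):
    """One valid ligation contact: two genomic loci with strands and MAPQ."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapq1: int
    mapq2: int


@dataclass
class GeneModel:
    """A gene with exon structure; coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        """Transcription start site (0-based coordinate of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def promoter(
        self, upstream: int = 500, downstream: int = 100,
        chrom_length: int | None = None,
    ) -> tuple[int, int]:
        """Strand-aware promoter interval around the TSS, clipped to the chromosome.

        Default window: 500 bp upstream through 100 bp downstream of the TSS.
        """
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream + 1, self.tss + upstream + 1
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi

    def five_prime_splice_sites(self) -> list[int]:
        """5' splice sites (exon/intron junctions) in transcription order.

        Each site is the 0-based coordinate of the first intronic base.  Empty
        for single-exon genes.
        """
        if len(self.exons) < 2:
            return []
        if self.strand == "+":
            return [e for (_, e) in self.exons[:-1]]
        # minus strand: transcription right->left; junction at the genomic
        # start of each exon except the leftmost, first junction is rightmost
        return [s - 1 for (s, _) in self.exons[:0:-1]]

    def first_five_prime_ss(self) -> int | None:
        sites = self.five_prime_splice_sites()
        return sites[0] if sites else None


@dataclass
class SignalTrack:
    """Per-chromosome binned signal (e.g. GRO-seq / NET-seq / ChIP coverage)."""

    values: dict[str, np.ndarray]
    bin_width: int

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        arr = self.values[chrom]
        b0 = start // self.bin_width
        b1 = max(b0 + 1, -(-end // self.bin_width))
        return float(arr[b0:b1].mean())


# ---------------------------------------------------------------------------
# contact pairs
# ---------------------------------------------------------------------------

def canonicalize_pairs(pairs: pd.DataFrame, chromsizes: ChromSizes) -> pd.DataFrame:
    """Return a copy with (chrom1,pos1) <= (chrom2,pos2) by chromosome order then position."""
    rank = {name: i for i, name in enumerate(chromsizes.names)}
    r1 = pairs["chrom1"].map(rank).to_numpy()
    r2 = pairs["chrom2"].map(rank).to_numpy()
    swap = (r1 > r2) | ((r1 == r2) & (pairs["pos1"].to_numpy() > pairs["pos2"].to_numpy()))
    out = pairs.copy()
    if swap.any():
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"),
                     ("strand1", "strand2"), ("mapq1", "mapq2")):
            va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
            va[swap], vb[swap] = vb[swap], va[swap]
            out[a], out[b] = va, vb
    return out


def pairs_frame(records: Iterable[ContactPair | Sequence]) -> pd.DataFrame:
    """Build a canonical-column pair table from an iterable of records."""
    df = pd.DataFrame(list(records), columns=PAIR_COLUMNS)
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    df["mapq1"] = df["mapq1"].astype(np.int32)
    df["mapq2"] = df["mapq2"].astype(np.int32)
    return df


def iter_pairs(pairs: pd.DataFrame) -> Iterable[ContactPair]:
    for row in pairs.itertuples(index=False):
        yield ContactPair(*row)


def read_pairs(path: str | Path, chromsizes: ChromSizes) -> pd.DataFrame:
    """Read a contact-pair TSV: chrom1 pos1 strand1 chrom2 pos2 strand2 mapq1 mapq2.

    '#'-prefixed comment lines are skipped.  Pairs are canonicalized on load.
    Raises :class:`FormatError` with a line number on malformed input or
    out-of-bounds coordinates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise FormatError(f"{path}:{lineno}: expected 8 fields, got {len(parts)}")
            try:
                rec = (parts[0], int(parts[1]), parts[2],
                       parts[3], int(parts[4]), parts[5],
                       int(parts[6]), int(parts[7]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            for chrom, pos in ((rec[0], rec[1]), (rec[3], rec[4])):
                if chrom not in chromsizes:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if not (0 <= pos < chromsizes[chrom]):
                    raise FormatError(
                        f"{path}:{lineno}: position {pos} outside {chrom} "
                        f"(length {chromsizes[chrom]})")
            if rec[2] not in "+-" or rec[5] not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand")
            rows.append(rec)
    return canonicalize_pairs(pairs_frame(rows), chromsizes)


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", header=False, index=False, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/exon features) or BED12.

    The format is chosen by extension ('.bed' -> BED12, otherwise GFF3).
    A gene without exon children becomes a single-exon model spanning the
    gene body (warning logged).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> list[GeneModel]:
    import pyranges

    df = pyranges.read_gff3(str(path)).df
    genes: dict[str, GeneModel] = {}
    gdf = df[df["Feature"] == "gene"]
    for row in gdf.itertuples(index=False):
        gid = getattr(row, "ID")
        genes[gid] = GeneModel(
            gene_id=str(gid), chrom=str(row.Chromosome),
            start=int(row.Start), end=int(row.End), strand=str(row.Strand),
            exons=[],
        )
    edf = df[df["Feature"] == "exon"]
    for row in edf.itertuples(index=False):
        parent = getattr(row, "Parent", None)
        if parent is None or (isinstance(parent, float) and np.isnan(parent)):
            continue
        if parent in genes:
            genes[parent].exons.append((int(row.Start), int(row.End)))
    out = []
    for gm in genes.values():
        if not gm.exons:
            logger.warning("gene %s has no exons; using gene body as single exon", gm.gene_id)
            gm.exons = [(gm.start, gm.end)]
        gm.exons = sorted(gm.exons)
        out.append(gm)
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def _read_bed12(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise FormatError(f"{path}: BED12 requires 12 columns, got {df.shape[1]}")
    out = []
    for row in df.itertuples(index=False):
        chrom, start, end, name = str(row[0]), int(row[1]), int(row[2]), str(row[3])
        strand = str(row[5])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        starts = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        if len(sizes) != int(row[9]) or len(starts) != int(row[9]):
            raise FormatError(f"{path}: blockCount mismatch for {name}")
        exons = [(start + s, start + s + l) for s, l in zip(starts, sizes)]
        out.append(GeneModel(name, chrom, start, end, strand, exons))
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_annotation_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (converting back to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tfinechrom\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tfinechrom\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# BED intervals (enhancers, TF sites)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with columns chrom, start, end[, name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if "name" not in df.columns:
        df["name"] = [f"feat{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name"]]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False,
                     columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# bedGraph signal
# ---------------------------------------------------------------------------

def read_signal_track(path: str | Path, chromsizes: ChromSizes,
                      bin_width: int) -> SignalTrack:
    """Rasterize a bedGraph to fixed-width bins by length-weighted mean.

    Uncovered bases count as 0.  Overlapping intervals are an error (the
    value at the overlap would be ambiguous).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = {name: np.zeros(-(-length // bin_width))
              for name, length in chromsizes.sizes.items()}
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        return SignalTrack(values, bin_width)
    if len(df) == 0:
        return SignalTrack(values, bin_width)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chromsizes:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"{path}: overlapping intervals on {chrom}")
        acc = values[chrom]
        vals = sub["value"].to_numpy(dtype=float)
        for s, e, v in zip(starts, ends, vals):
            b0, b1 = s // bin_width, -(-e // bin_width)
            for b in range(b0, b1):
                lo = max(s, b * bin_width)
                hi = min(e, (b + 1) * bin_width)
                acc[b] += v * (hi - lo)
        # accumulated value*bp -> length-weighted mean over the full bin
    for chrom in values:
        values[chrom] /= bin_width
    return SignalTrack(values, bin_width)


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            for i, v in enumerate(arr):
                if v != 0:
                    fh.write(f"{chrom}\t{i * track.bin_width}\t"
                             f"{(i + 1) * track.bin_width}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# network edges
# ---------------------------------------------------------------------------

NETWORK_COLUMNS = ["geneA", "geneB", "cls", "orientation", "n_conditions", "support"]


def write_network_edges(network, path: str | Path) -> None:
    """Write a promoter-promoter network as an edge-list TSV.

    Columns: geneA geneB class orientation n_conditions support.  A
    write-then-read round trip reproduces the edge set exactly.
    """
    rows = []
    for a, b, data in network.graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append((a, b, data.get("cls", "P-P"), data.get("orientation", "."),
                     len(data.get("conditions", ())), data.get("support", 1)))
    rows.sort()
    df = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_network_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

CONDITIONS = ("22C", "cold3h", "cold12h")


@dataclass
class ExpressionMatrix:
    """Gene x (condition, replicate) expression table, library-normalized units."""

    table: pd.DataFrame  # index gene_id, MultiIndex columns (condition, replicate)

    def __post_init__(self) -> None:
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def sample_matrix(self, conditions: Sequence[str] | None = None) -> pd.DataFrame:
        """Flat gene x sample matrix restricted to *conditions* (default: all)."""
        t = self.table
        if conditions is not None:
            t = t.loc[:, [c for c in t.columns if c[0] in conditions]]
        return t

    def to_tsv(self, path: str | Path) -> None:
        long = self.table.stack([0, 1], future_stack=True).rename("value").reset_index()
        long.columns = ["gene_id", "condition", "replicate", "value"]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        long = pd.read_csv(path, sep="\t")
        table = long.pivot_table(index="gene_id", columns=["condition", "replicate"],
                                 values="value")
        return cls(table)


# ---------------------------------------------------------------------------
# FASTQ (simulated linker reads)
# ---------------------------------------------------------------------------

def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) records as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            name = fh.readline()
            if not name:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((name.strip().lstrip("@"), seq))
    return out
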