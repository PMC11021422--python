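"""Map loop anchors to genomic features and classify contacts.

Anchors are assigned a primary label with precedence
promoter > enhancer > gene body > intergenic.  Loops with both anchors in
promoters are promoter-promoter interactions (P-P); cis P-P pairs carry a
transcription-orientation label (tandem / divergent / convergent).  Loops
joining an enhancer to a promoter (E-P) are split into proximal/distal and,
for the promoter side, upstream/downstream of the TSS in transcription
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import ChromSizes, GeneModel


@dataclass
class AnchorAnnotation:
    """Feature hits of one anchor interval plus its primary label."""

    chrom: str
    start: int
    end: int
    promoter_genes: list[str] = field(default_factory=list)
    enhancers: list[str] = field(default_factory=list)
    body_genes: list[str] = field(default_factory=list)

    @property
    def primary(self) -> str:
        if self.promoter_genes:
            return "promoter"
        if self.enhancers:
            return "enhancer"
        if self.body_genes:
            return "gene_body"
        return "intergenic"


@dataclass
class ContactClass:
    """Categorical description of one classified contact."""

    kind: str                      # "P-P" | "E-P" | "other"
    cis: bool
    orientation: str | None = None     # tandem | divergent | convergent (cis P-P)
    ep_range: str | None = None        # proximal | distal (E-P)
    ep_side: str | None = None         # upstream | downstream (E-P)


class AnnotationIndex:
    """Interval index over promoters, enhancers and gene bodies.

    Promoter windows are strand-aware (default 500 bp upstream to 100 bp
    downstream of the TSS) and clipped to the chromosome.
    """

    def __init__(self, genes: list[GeneModel], enhancers: pd.DataFrame | None,
                 chromsizes: ChromSizes,
                 promoter_upstream: int = 500, promoter_downstream: int = 100):
        self.genes = {g.gene_id: g for g in genes}
        self.chromsizes = chromsizes
        self._promoters: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        self._enhancers: dict[str, IntervalTree] = {}
        for g in genes:
            lo, hi = g.promoter(promoter_upstream, promoter_downstream,
                                chromsizes[g.chrom])
            if hi > lo:
                self._promoters.setdefault(g.chrom, IntervalTree()).addi(
                    lo, hi, g.gene_id)
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id)
        if enhancers is not None:
            for row in enhancers.itertuples(index=False):
                self._enhancers.setdefault(row.chrom, IntervalTree()).addi(
                    int(row.start), int(row.end), str(row.name))

    @staticmethod
    def _hits(trees: dict[str, IntervalTree], chrom: str, start: int,
              end: int) -> list[str]:
        tree = trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def annotate(self, chrom: str, start: int, end: int) -> AnchorAnnotation:
        if chrom not in self.chromsizes or not (
                0 <= start < end <= self.chromsizes[chrom]):
            raise ValueError(f"anchor {chrom}:{start}-{end} outside genome")
        return AnchorAnnotation(
            chrom=chrom, start=start, end=end,
            promoter_genes=self._hits(self._promoters, chrom, start, end),
            enhancers=self._hits(self._enhancers, chrom, start, end),
            body_genes=self._hits(self._bodies, chrom, start, end),
        )


def annotate_anchor(chrom: str, start: int, end: int,
                    index: AnnotationIndex) -> AnchorAnnotation:
    """Annotate one anchor interval against the feature index."""
    return index.annotate(chrom, start, end)


def classify_ppi(gene_a: GeneModel, gene_b: GeneModel) -> ContactClass:
    """Orientation of a promoter-promoter contact.

    Trans if the genes sit on different chromosomes.  In cis, with A the
    left gene (smaller TSS): equal strands are tandem, (-,+) divergent
    (transcription pointing apart), (+,-) convergent (pointing together).
    Invariant to argument order.
    """
    if gene_a.gene_id == gene_b.gene_id:
        raise ValueError("self-loop: both anchors hit the same gene")
    if gene_a.chrom != gene_b.chrom:
        return ContactClass(kind="P-P", cis=False, orientation=None)
    left, right = sorted((gene_a, gene_b), key=lambda g: (g.tss, g.gene_id))
    if left.strand == right.strand:
        orientation = "tandem"
    elif left.strand == "-":
        orientation = "divergent"
    else:
        orientation = "convergent"
    return ContactClass(kind="P-P", cis=True, orientation=orientation)


def classify_ep(enh_anchor: AnchorAnnotation, prom_anchor: AnchorAnnotation,
                gene: GeneModel, proximal_max_bp: int = 2_000) -> ContactClass:
    """Range and side of an enhancer-promoter contact.

    proximal iff the anchor-midpoint separation is <= *proximal_max_bp*;
    side is upstream/downstream of the promoter's TSS in transcription
    direction (strand-aware).
    """
    if not enh_anchor.enhancers or not prom_anchor.promoter_genes:
        raise ValueError("not an E-P contact: need one enhancer-labeled and "
                         "one promoter-labeled anchor")
    mid_e = (enh_anchor.start + enh_anchor.end) // 2
    mid_p = (prom_anchor.start + prom_anchor.end) // 2
    cis = enh_anchor.chrom == prom_anchor.chrom
    sep = abs(mid_e - mid_p) if cis else None
    ep_range = "proximal" if (cis and sep <= proximal_max_bp) else "distal"
    signed = mid_e - gene.tss
    if gene.strand == "-":
        signed = -signed
    side = "upstream" if signed < 0 else "downstream"
    return ContactClass(kind="E-P", cis=cis, ep_range=ep_range, ep_side=side)


def classify_contacts(loops: pd.DataFrame, index: AnnotationIndex,
                      proximal_max_bp: int = 2_000) -> pd.DataFrame:
    """Classify a table of called loops (BEDPE-like columns).

    Returns one row per loop with kind, cis flag and the applicable labels.
    A P-P loop whose anchors each hit several promoters is classified on
    every gene pair (Cartesian), deduplicated; the output then carries one
    row per gene pair with the loop's index in ``loop_id``.
    """
    rows = []
    for loop_id, row in enumerate(loops.itertuples(index=False)):
        a1 = index.annotate(row.chrom1, int(row.start1), int(row.end1))
        a2 = index.annotate(row.chrom2, int(row.start2), int(row.end2))
        l1, l2 = a1.primary, a2.primary
        if l1 == "promoter" and l2 == "promoter":
            seen = set()
            for ga in a1.promoter_genes:
                for gb in a2.promoter_genes:
                    if ga == gb:
                        continue
                    key = tuple(sorted((ga, gb)))
                    if key in seen:
                        continue
                    seen.add(key)
                    cc = classify_ppi(index.genes[ga], index.genes[gb])
                    rows.append((loop_id, "P-P", cc.cis, cc.orientation,
                                 None, None, key[0], key[1]))
        elif {"promoter", "enhancer"} == {l1, l2}:
            enh, prom = (a1, a2) if l1 == "enhancer" else (a2, a1)
            for g in prom.promoter_genes:
                cc = classify_ep(enh, prom, index.genes[g], proximal_max_bp)
                rows.append((loop_id, "E-P", cc.cis, None,
                             cc.ep_range, cc.ep_side, enh.enhancers[0], g))
        else:
            rows.append((loop_id, "other",
                         row.chrom1 == row.chrom2, None, None, None, None, None))
    return pd.DataFrame(rows, columns=[
        "loop_id", "kind", "cis", "orientation", "ep_range", "ep_side",
        "featureA", "featureB"])


def classification_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Fraction tables per classification family; fractions in each family
    sum to 1 over its defined rows."""
    if len(classified) == 0:
        return pd.DataFrame(columns=["family", "label", "n", "fraction"])
    rows = []

    def _family(name: str, series: pd.Series) -> None:
        series = series.dropna()
        total = len(series)
        if total == 0:
            return
        for label, n in series.value_counts().items():
            rows.append((name, str(label), int(n), n / total))

    ppi = classified[classified["kind"] == "P-P"]
    if len(ppi):
        _family("ppi_cis_trans", ppi["cis"].map({True: "cis", False: "trans"}))
        _family("ppi_orientation", ppi.loc[ppi["cis"], "orientation"])
    ep = classified[classified["kind"] == "E-P"]
    if len(ep):
        _family("ep_range", ep["ep_range"])
        _family("ep_side", ep["ep_side"])
        for rng in ("proximal", "distal"):
            _family(f"ep_side_{rng}", ep.loc[ep["ep_range"] == rng, "ep_side"])
    _family("kind", classified["kind"])
    return pd.DataFrame(rows, columns=["family", "label", "n", "fraction"])
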