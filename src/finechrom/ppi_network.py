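"""Primed promoter-promoter interaction (PPI) networks.

Genes are nodes; an edge joins two genes whose promoters are in contact in
every condition ("primed").  Hotspots are promoters with exceptional degree
— in the real genome single promoters contacting thousands of other
promoters.  Contact enrichment over site sets (e.g. TF binding sites) is
profiled against a length- and chromosome-preserving shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .annotation_overlap import AnnotationIndex, classify_ppi
from .formats_io import ChromSizes


@dataclass
class PPINetwork:
    """Promoter-promoter interaction graph with per-node degrees."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree())).sort_values(ascending=False)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            rows.append((a, b, data.get("orientation"), data.get("cis"),
                         data.get("support", 1),
                         ",".join(sorted(data.get("conditions", ())))))
        rows.sort()
        return pd.DataFrame(rows, columns=["geneA", "geneB", "orientation",
                                           "cis", "support", "conditions"])


def build_ppi_network(classified: pd.DataFrame, index: AnnotationIndex,
                      conditions: tuple[str, ...] = ()) -> PPINetwork:
    """Build the PPI network from classified P-P contacts.

    One edge per unique gene pair; multiple supporting loops increment the
    edge's ``support``.  Self-loops are impossible by construction of the
    classification.
    """
    net = PPINetwork()
    ppi = classified[classified["kind"] == "P-P"]
    for row in ppi.itertuples(index=False):
        a, b = sorted((row.featureA, row.featureB))
        if net.graph.has_edge(a, b):
            net.graph[a][b]["support"] += 1
        else:
            net.graph.add_edge(a, b, orientation=row.orientation, cis=row.cis,
                               support=1, conditions=tuple(conditions),
                               cls="P-P")
    for node in net.graph.nodes:
        g = index.genes.get(node)
        if g is not None:
            net.graph.nodes[node]["chrom"] = g.chrom
            net.graph.nodes[node]["tss"] = g.tss
    return net


def network_from_gene_pairs(pairs: pd.DataFrame,
                            index: AnnotationIndex) -> PPINetwork:
    """Network directly from a (geneA, geneB) pair table (e.g. planted
    truth), classifying each pair's orientation on the fly."""
    net = PPINetwork()
    for row in pairs.itertuples(index=False):
        a, b = sorted((row.geneA, row.geneB))
        if a == b:
            continue
        if net.graph.has_edge(a, b):
            net.graph[a][b]["support"] += 1
            continue
        cc = classify_ppi(index.genes[a], index.genes[b])
        net.graph.add_edge(a, b, orientation=cc.orientation, cis=cc.cis,
                           support=1, conditions=(), cls="P-P")
    for node in net.graph.nodes:
        g = index.genes.get(node)
        if g is not None:
            net.graph.nodes[node]["chrom"] = g.chrom
            net.graph.nodes[node]["tss"] = g.tss
    return net


def detect_hotspots(network: PPINetwork, threshold_percentile: float = 99.9,
                    min_degree: int | None = None) -> pd.DataFrame:
    """Genes whose degree exceeds the threshold percentile of the degree
    distribution (or an absolute ``min_degree``), sorted by degree
    descending."""
    if network.n_edges == 0:
        return pd.DataFrame(columns=["gene_id", "degree"])
    deg = network.degrees()
    if min_degree is None:
        cut = np.percentile(deg.to_numpy(), threshold_percentile)
        hot = deg[deg > cut]
    else:
        hot = deg[deg >= min_degree]
    return pd.DataFrame({"gene_id": hot.index, "degree": hot.to_numpy()})


def signal_over_sites(pairs: pd.DataFrame, sites: pd.DataFrame,
                      chromsizes: ChromSizes, window: int = 2_000,
                      bin_width: int = 100, n_shuffles: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Mean contact-end density around site centers, with a shuffle null.

    For every site, contact ends within +/- *window* of the site center are
    histogrammed at *bin_width*; the profile is the mean over sites, per
    contact end (each pair contributes both ends).  The background repeats
    the computation on sites shuffled uniformly within their chromosome
    (length-preserving), *n_shuffles* times.
    """
    if len(sites) == 0:
        raise ValueError("no sites provided")
    rng = np.random.default_rng(seed)
    ends_by_chrom = {
        chrom: np.sort(np.concatenate([
            pairs.loc[pairs["chrom1"] == chrom, "pos1"].to_numpy(),
            pairs.loc[pairs["chrom2"] == chrom, "pos2"].to_numpy(),
        ]))
        for chrom in chromsizes.names
    }
    # one bin centred on each offset -window, ..., 0, ..., +window
    n_bins = 2 * window // bin_width + 1
    offsets = -window + np.arange(n_bins) * bin_width

    def profile(site_frame: pd.DataFrame) -> np.ndarray:
        acc = np.zeros(n_bins)
        half = bin_width // 2
        for row in site_frame.itertuples(index=False):
            ends = ends_by_chrom.get(row.chrom)
            if ends is None:
                continue
            center = (int(row.start) + int(row.end)) // 2
            lo = np.searchsorted(ends, center - window - half)
            hi = np.searchsorted(ends, center + window + bin_width - half)
            rel = ends[lo:hi] - (center - window - half)
            acc += np.bincount(rel // bin_width, minlength=n_bins)[:n_bins]
        return acc / max(len(site_frame), 1)

    observed = profile(sites)
    null = np.zeros(n_bins)
    lengths = sites["end"].to_numpy() - sites["start"].to_numpy()
    for _ in range(n_shuffles):
        starts = np.array([
            rng.integers(0, chromsizes[c] - l)
            for c, l in zip(sites["chrom"], lengths)])
        shuf = pd.DataFrame({"chrom": sites["chrom"].to_numpy(),
                             "start": starts, "end": starts + lengths})
        null += profile(shuf)
    null /= max(n_shuffles, 1)
    return pd.DataFrame({"offset": offsets, "observed": observed,
                         "background": null})
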