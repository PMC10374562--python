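"""Over-representation analysis and enrichment-map clustering.

Marker sets are tested against annotated gene sets with a one-sided
hypergeometric test over the platform background (the unique list of
proteins the assay interrogates; n = 4132 for the full menu).  Enriched
sets (BH q below a threshold, 0.25 by default) are linked into an
enrichment map: edges join set pairs whose combined Jaccard + overlap
coefficient reaches 0.375, clusters are the connected components, and
isolated sets supported by only a single model are dropped.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .screen import bh_adjust

DEFAULT_BACKGROUND_SIZE = 4132
DEFAULT_EDGE_THRESHOLD = 0.375


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    category: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path: os.PathLike | str) -> list[GeneSet]:
    """Parse a GMT file: name <TAB> description <TAB> member..."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: need name, "
                                 "description and at least one member")
            sets.append(GeneSet(parts[0], frozenset(parts[2:]), parts[1]))
    return sets


def write_gmt(gene_sets: list[GeneSet], path: os.PathLike | str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.category, *sorted(gs.members)])
                     + "\n")


def ora(
    query: set[str],
    gene_sets: list[GeneSet],
    universe: set[str] | None = None,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    With population N (*background_size*, or the universe size when a
    universe is given), K = members of the set on the platform, n = query
    size, k = overlap: ``p = P[X >= k]``.  Sets are intersected with the
    universe first; sets fully outside it are skipped with a warning.
    """
    query = set(query)
    if not query:
        raise ValueError("query set is empty")
    if universe is not None:
        universe = set(universe)
        stray = query - universe
        if stray:
            raise ValueError(f"query not within universe: {sorted(stray)[:5]}")
        big_n = len(universe)
    else:
        big_n = background_size
    rows = []
    for gs in gene_sets:
        members = gs.members if universe is None else gs.members & universe
        if not members:
            warnings.warn(f"gene set {gs.name!r} lies outside the universe; "
                          "skipped")
            continue
        k = len(query & members)
        big_k = len(members)
        n = len(query)
        # P[X >= k] = survival function at k-1
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set": gs.name, "overlap": k, "set_size": big_k,
                     "query_size": n, "background": big_n, "p": p})
    result = pd.DataFrame(rows).set_index("set")
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result


def filter_enriched(results: pd.DataFrame, q_max: float = 0.25) -> pd.DataFrame:
    """Keep gene sets with BH q strictly below *q_max*."""
    return results[results["q"] < q_max]


@dataclass(frozen=True)
class SimilarityEdge:
    pair: tuple[str, str]
    jaccard: float
    overlap: float

    @property
    def combined(self) -> float:
        return 0.5 * self.jaccard + 0.5 * self.overlap

    def is_edge(self, threshold: float = DEFAULT_EDGE_THRESHOLD) -> bool:
        return self.combined >= threshold


def combined_coefficient(set1: GeneSet, set2: GeneSet) -> SimilarityEdge:
    """Jaccard, overlap and their mean for a pair of gene sets."""
    inter = len(set1.members & set2.members)
    union = len(set1.members | set2.members)
    jaccard = inter / union
    overlap = inter / min(len(set1.members), len(set2.members))
    return SimilarityEdge((set1.name, set2.name), jaccard, overlap)


@dataclass
class EnrichmentMap:
    graph: nx.Graph
    clusters: list[frozenset[str]] = field(default_factory=list)
    removed_singletons: list[str] = field(default_factory=list)


def build_map(
    enriched: dict[str, GeneSet],
    supporting_models: dict[str, set[str]],
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> EnrichmentMap:
    """Similarity graph and clusters over enriched gene sets.

    Nodes carry the set size (weight) and supporting models; edges join
    pairs whose combined coefficient reaches *edge_threshold*, weighted by
    that coefficient.  Clusters are connected components.  A node that is
    isolated and supported by a single model is removed; isolated nodes
    supported by several models are retained as singleton clusters.
    """
    graph = nx.Graph()
    for name in sorted(enriched):
        gs = enriched[name]
        graph.add_node(name, size=len(gs.members),
                       models=frozenset(supporting_models.get(name, ())))
    names = sorted(enriched)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            edge = combined_coefficient(enriched[a], enriched[b])
            if edge.is_edge(edge_threshold):
                graph.add_edge(a, b, weight=edge.combined,
                               jaccard=edge.jaccard, overlap=edge.overlap)
    removed = [
        n for n in list(graph.nodes)
        if graph.degree(n) == 0 and len(graph.nodes[n]["models"]) <= 1
    ]
    graph.remove_nodes_from(removed)
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), sorted(c)),
    )
    return EnrichmentMap(graph, clusters, sorted(removed))
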