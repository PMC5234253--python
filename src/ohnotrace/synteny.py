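"""Gene-neighbourhood (synteny) analysis and ohnolog sub-lineage partition.

For each query gene a window of up to 15 neighbours per side is extracted and
every neighbour is labelled with its sequence-similarity family.  Two queries
are connected when their windows share neighbour families; the edge strength
combines, per shared pair,

* closeness to the query genes, ``c = 1/max(|offset_a|, |offset_b|)``,
* sequence similarity of the connecting neighbours,
  ``s = min(1, −log10(evalue)/60)`` (1 when no e-value is recorded), and
* rarity of the neighbour family, ``r = 2/cluster_size``,

each a [0, 1] factor, summed over shared pairs.  Strong edges (strength above
a cutoff) define the sub-lineage partition: after a whole-genome duplication
the two ohnolog tracks retain distinct neighbourhoods, so connected
components of the strong-edge graph recover the pre-WGD group and the two
post-WGD sub-lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genome_db import GenomeDB, get_neighbour_ids
from .simnet import SimilarityNetwork

DEFAULT_NEIGHBOUR_K = 15
DEFAULT_STRONG_CUTOFF = 0.5
#: exponent scale for the similarity factor: an e-value of 1e-60 (or better)
#: counts as maximal similarity, matching the stringent end of the sweep
SIMILARITY_SCALE = 60.0


@dataclass
class NeighbourhoodWindow:
    query_id: str
    entries: list[tuple[str, int, str]]  # (orf_id, signed offset, family_label)


@dataclass
class SharedNeighbourPair:
    family_label: str
    offset_a: int
    offset_b: int
    neighbour_id_a: str
    neighbour_id_b: str
    pair_evalue: float | None = None


@dataclass
class SyntenyEdge:
    query_a: str
    query_b: str
    shared: list[SharedNeighbourPair]
    strength: float
    strong: bool


@dataclass
class LineageGraph:
    nodes: list[str]
    wgd_flags: dict[str, str]
    roles: dict[str, str]
    edges: list[SyntenyEdge]
    partition: dict[str, int]  # query -> sublineage id

    def blocks(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, block in self.partition.items():
            out.setdefault(block, set()).add(node)
        return [out[k] for k in sorted(out)]


def _singleton_label(query_id: str, orf_id: str) -> str:
    # unique per (window, orf) so singletons can never form a shared pair
    return f"__singleton__{query_id}__{orf_id}"


def label_window(
    query_id: str,
    window_raw: Sequence[tuple[str, int]],
    clustering: Mapping[str, str],
) -> NeighbourhoodWindow:
    """Attach a family label to every neighbour in a raw window.

    Neighbours absent from the clustering receive a unique singleton label.
    """
    entries = [
        (orf_id, offset, clustering.get(orf_id, _singleton_label(query_id, orf_id)))
        for orf_id, offset in window_raw
    ]
    return NeighbourhoodWindow(query_id=query_id, entries=entries)


def extract_window(
    db: GenomeDB, query_id: str, clustering: Mapping[str, str], k: int = DEFAULT_NEIGHBOUR_K
) -> NeighbourhoodWindow:
    return label_window(query_id, get_neighbour_ids(db, query_id, k), clustering)


def _closest_instances(window: NeighbourhoodWindow) -> dict[str, tuple[str, int]]:
    """Per family label, the neighbour instance with smallest |offset|
    (ties broken toward the upstream, i.e. negative, instance)."""
    best: dict[str, tuple[str, int]] = {}
    for orf_id, offset, label in window.entries:
        if label.startswith("__singleton__"):
            continue
        cur = best.get(label)
        if cur is None or (abs(offset), offset) < (abs(cur[1]), cur[1]):
            best[label] = (orf_id, offset)
    return best


def shared_pairs(wa: NeighbourhoodWindow, wb: NeighbourhoodWindow) -> list[SharedNeighbourPair]:
    """One pair per family label present in both windows."""
    if wa.query_id == wb.query_id:
        raise ValueError("windows must belong to distinct queries")
    besta = _closest_instances(wa)
    bestb = _closest_instances(wb)
    out = []
    for label in sorted(set(besta) & set(bestb)):
        ida, offa = besta[label]
        idb, offb = bestb[label]
        out.append(SharedNeighbourPair(label, offa, offb, ida, idb))
    return out


def score_edge(
    query_a: str,
    query_b: str,
    pairs: Sequence[SharedNeighbourPair],
    cluster_sizes: Mapping[str, int],
    strong_cutoff: float = DEFAULT_STRONG_CUTOFF,
) -> SyntenyEdge:
    """Multiplicative closeness x similarity x rarity score, summed over pairs."""
    strength = 0.0
    for p in pairs:
        size = cluster_sizes.get(p.family_label)
        if size is None or size < 2:
            raise ValueError(
                f"matched family {p.family_label!r} has cluster size {size}; "
                "a shared label implies at least two members"
            )
        c = 1.0 / max(abs(p.offset_a), abs(p.offset_b))
        if p.pair_evalue is None:
            s = 1.0
        else:
            s = min(1.0, max(0.0, -math.log10(p.pair_evalue)) / SIMILARITY_SCALE)
        r = 2.0 / size
        strength += c * s * r
    return SyntenyEdge(
        query_a=query_a,
        query_b=query_b,
        shared=list(pairs),
        strength=strength,
        strong=strength >= strong_cutoff,
    )


def build_lineage_graph(
    queries: Sequence[str],
    windows: Mapping[str, NeighbourhoodWindow],
    cluster_sizes: Mapping[str, int],
    wgd_flags: Mapping[str, str],
    roles: Mapping[str, str] | None = None,
    strong_cutoff: float = DEFAULT_STRONG_CUTOFF,
    net: SimilarityNetwork | None = None,
) -> LineageGraph:
    """All-pairs synteny edges + sub-lineage partition.

    When a similarity network is supplied, each shared pair is annotated with
    the recorded e-value between its two neighbour ORFs (absent edges leave
    the pair's similarity factor at its maximum).  The partition is the set
    of connected components of the strong-edge subgraph.
    """
    queries = sorted(set(queries))
    if len(queries) < 2:
        raise ValueError("need at least two queries")
    edges: list[SyntenyEdge] = []
    g = nx.Graph()
    g.add_nodes_from(queries)
    for qa, qb in combinations(queries, 2):
        pairs = shared_pairs(windows[qa], windows[qb])
        if net is not None:
            for p in pairs:
                p.pair_evalue = net.edge_evalue(p.neighbour_id_a, p.neighbour_id_b)
        edge = score_edge(qa, qb, pairs, cluster_sizes, strong_cutoff)
        edges.append(edge)
        if edge.strong:
            g.add_edge(qa, qb)
    partition: dict[str, int] = {}
    comps = sorted(nx.connected_components(g), key=min)
    for i, comp in enumerate(comps):
        for node in comp:
            partition[node] = i
    return LineageGraph(
        nodes=queries,
        wgd_flags={q: wgd_flags[q] for q in queries},
        roles={q: roles[q] for q in queries} if roles else {},
        edges=edges,
        partition=partition,
    )


def majority_role(graph: LineageGraph) -> dict[int, str]:
    """Majority member role per sub-lineage block (alphabetical tie-break)."""
    out: dict[int, str] = {}
    for i, block in enumerate(graph.blocks()):
        counts: dict[str, int] = {}
        for q in block:
            role = graph.roles.get(q, "unknown")
            counts[role] = counts.get(role, 0) + 1
        out[i] = max(sorted(counts), key=lambda r: counts[r])
    return out


# ---------------------------------------------------------------------------
# exports


def write_edges(edges: Iterable[SyntenyEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_a\tquery_b\tn_shared\tstrength\tstrong\n")
        for e in sorted(edges, key=lambda e: (e.query_a, e.query_b)):
            fh.write(f"{e.query_a}\t{e.query_b}\t{len(e.shared)}\t{e.strength:.4f}\t{int(e.strong)}\n")


def write_partition(graph: LineageGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orf_id\tsublineage\twgd_flag\trole\n")
        for q in graph.nodes:
            fh.write(
                f"{q}\t{graph.partition[q]}\t{graph.wgd_flags.get(q, '?')}\t"
                f"{graph.roles.get(q, '?')}\n"
            )


def write_window_detail(
    windows: Mapping[str, NeighbourhoodWindow], path: str | Path, display_k: int | None = None
) -> None:
    """Full neighbourhood dump; display_k truncates per side for rendering."""
    with open(path, "w") as fh:
        fh.write("query_id\tneighbour_id\toffset\tfamily_label\n")
        for q in sorted(windows):
            for orf_id, offset, label in windows[q].entries:
                if display_k is not None and abs(offset) > display_k:
                    continue
                fh.write(f"{q}\t{orf_id}\t{offset}\t{label}\n")
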