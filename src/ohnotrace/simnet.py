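"""Pairwise-similarity network and breadth-first family retrieval.

Sequence clustering is cast as graph traversal: nodes are translated ORFs,
an undirected edge records the best (minimum) e-value between a pair, and a
family is the set of nodes reachable from a seed through edges whose e-value
passes a threshold 10^exponent.  Sweeping the exponent from −60 to −1 yields
a retrieval curve whose flat stretches ("plateaus") mark stable family
boundaries; the jump points are merge events with more remote families.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .pairwise import PairwiseHit

SWEEP_LO, SWEEP_HI = -60, -1


class SimilarityNetwork:
    """Undirected e-value-weighted graph over ORF ids (networkx-backed)."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_evalue(self, a: str, b: str) -> float | None:
        data = self.graph.get_edge_data(a, b)
        return None if data is None else data["evalue"]

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass
class RetrievalCurve:
    seed_id: str
    points: dict[int, int]  # exponent -> retrieved count

    def exponents(self) -> list[int]:
        return sorted(self.points)


@dataclass
class PlateauSegment:
    exponent_lo: int
    exponent_hi: int
    count: int

    @property
    def width(self) -> int:
        return self.exponent_hi - self.exponent_lo + 1


@dataclass
class FamilyCluster:
    seed_id: str
    exponent_cut: int
    member_ids: set[str] = field(default_factory=set)


def build_network(hits: Iterable[PairwiseHit], node_universe: Iterable[str]) -> SimilarityNetwork:
    """Collapse directed hits onto undirected min-e-value edges.

    Isolated nodes are retained; a hit naming a node outside the universe is
    an error; self-hits are discarded.
    """
    g = nx.Graph()
    g.add_nodes_from(node_universe)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in g or h.subject_id not in g:
            missing = h.query_id if h.query_id not in g else h.subject_id
            raise ValueError(f"hit references unknown node {missing!r}")
        prev = g.get_edge_data(h.query_id, h.subject_id)
        if prev is None or h.evalue < prev["evalue"]:
            g.add_edge(h.query_id, h.subject_id, evalue=h.evalue)
    return SimilarityNetwork(g)


def retrieve_cluster(net: SimilarityNetwork, seed_id: str, exponent: int) -> FamilyCluster:
    """Breadth-first traversal from the seed over edges with e ≤ 10^exponent."""
    if seed_id not in net:
        raise KeyError(f"seed {seed_id!r} not in network")
    threshold = 10.0 ** exponent
    seen = {seed_id}
    queue = deque([seed_id])
    g = net.graph
    while queue:
        node = queue.popleft()
        for nb, data in g.adj[node].items():
            if nb not in seen and data["evalue"] <= threshold:
                seen.add(nb)
                queue.append(nb)
    return FamilyCluster(seed_id=seed_id, exponent_cut=exponent, member_ids=seen)


def sweep_thresholds(
    net: SimilarityNetwork, seed_id: str, lo: int = SWEEP_LO, hi: int = SWEEP_HI
) -> RetrievalCurve:
    """One BFS per integer exponent in [lo, hi]; counts are non-decreasing."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    points = {e: len(retrieve_cluster(net, seed_id, e).member_ids) for e in range(lo, hi + 1)}
    return RetrievalCurve(seed_id=seed_id, points=points)


def detect_plateaus(curve: RetrievalCurve, tolerance: int = 0) -> list[PlateauSegment]:
    """Maximal runs of consecutive exponents whose counts stay within
    *tolerance* of the run's first count; segments tile the sweep range."""
    exps = curve.exponents()
    if not exps:
        return []
    segments: list[PlateauSegment] = []
    start = exps[0]
    ref = curve.points[start]
    prev = start
    for e in exps[1:]:
        if abs(curve.points[e] - ref) <= tolerance:
            prev = e
        else:
            segments.append(PlateauSegment(start, prev, ref))
            start = prev = e
            ref = curve.points[e]
    segments.append(PlateauSegment(start, prev, ref))
    return segments


def auto_plateau_cut(curve: RetrievalCurve, tolerance: int = 0) -> int:
    """Suggested exponent cut: the most permissive exponent of the widest
    plateau, which by construction still excludes the next merge event.

    Ties on width go to the more stringent (earlier) plateau.  This is a
    suggestion to be reviewed, mirroring an expert's choice of cut just
    before a remote family joins the retrieved set.
    """
    segments = detect_plateaus(curve, tolerance)
    widest = max(segments, key=lambda s: s.width)  # first of equal widths wins
    return widest.exponent_hi


def clustering_at(net: SimilarityNetwork, exponent: int) -> dict[str, str]:
    """Family label for every node: connected components of the thresholded
    network.  Labels are deterministic (lexicographically smallest member)."""
    threshold = 10.0 ** exponent
    sub = nx.Graph()
    sub.add_nodes_from(net.graph.nodes)
    sub.add_edges_from(
        (a, b) for a, b, d in net.graph.edges(data=True) if d["evalue"] <= threshold
    )
    labels: dict[str, str] = {}
    for comp in nx.connected_components(sub):
        rep = min(comp)
        for node in comp:
            labels[node] = rep
    return labels


# ---------------------------------------------------------------------------
# exports


def write_edge_list(net: SimilarityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tevalue\n")
        for a, b, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['evalue']:.6g}\n")


def write_graphml(net: SimilarityNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def read_edge_list(path: str | Path) -> SimilarityNetwork:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[0] == "node_a" or not line.strip():
                continue
            g.add_edge(f[0], f[1], evalue=float(f[2]))
    return SimilarityNetwork(g)


def write_curve_report(
    curve: RetrievalCurve, segments: Sequence[PlateauSegment], cut: int, path: str | Path
) -> None:
    report = {
        "seed_id": curve.seed_id,
        "points": {str(e): curve.points[e] for e in curve.exponents()},
        "plateaus": [
            {"exponent_lo": s.exponent_lo, "exponent_hi": s.exponent_hi, "count": s.count}
            for s in segments
        ],
        "exponent_cut": cut,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_membership(cluster: FamilyCluster, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orf_id\tcluster_seed\texponent\n")
        for orf_id in sorted(cluster.member_ids):
            fh.write(f"{orf_id}\t{cluster.seed_id}\t{cluster.exponent_cut}\n")
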