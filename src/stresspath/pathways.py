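"""Allosteric-pathway extraction from force-difference matrices.

A perturbation-connectivity graph is built on the residues, with edge
weights dF_ij (pN).  The analysis then asks: up to which force-change
cutoff do a designated *source* region (e.g. the cofactor-binding
residues) and *sink* region (e.g. the dimer-interface pair) remain
connected?  That largest surviving cutoff is exactly the maximin
(widest-path) bottleneck between the two regions — raising the cutoff
any further severs every source-to-sink route.  Pathways are then
extracted inside the surviving subgraph as ranked widest paths.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import DisjointSet

from .fda import DeltaForceMatrix
from .structure_io import ResidueKey


class DisconnectedError(ValueError):
    """Source and sink regions share no perturbation connectivity."""


@dataclass
class PathwayGraph:
    """Undirected residue graph weighted by dF (pN), with named regions."""

    graph: nx.Graph
    source: frozenset[ResidueKey]
    sink: frozenset[ResidueKey]

    def __post_init__(self) -> None:
        if not self.source or not self.sink:
            raise ValueError("source and sink regions must be non-empty")
        if self.source & self.sink:
            raise ValueError("source and sink regions must be disjoint")

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(_label(u), _label(v), weight_pN=float(d["weight"]))
        for n in self.graph.nodes:
            g.add_node(_label(n),
                       region=("source" if n in self.source
                               else "sink" if n in self.sink else ""))
        nx.write_graphml(g, path)

    def write_edge_tsv(self, path: str | Path,
                       cutoff: float | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tweight_pN\tsurviving_at_cutoff\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                w = float(d["weight"])
                surv = "" if cutoff is None else str(int(w >= cutoff))
                fh.write(f"{_label(u)}\t{_label(v)}\t{float(w)!r}\t{surv}\n")


def _label(key: ResidueKey) -> str:
    return f"{key[0]}:{key[1]}"


@dataclass
class PathwayResult:
    """Extracted pathways at a fixed cutoff."""

    cutoff: float
    subgraph: nx.Graph                       # edges surviving the cutoff
    paths: list[list[ResidueKey]]            # ranked source->sink paths
    bottlenecks: list[float]                 # per-path min edge weight

    def node_set(self) -> frozenset[ResidueKey]:
        out: set[ResidueKey] = set()
        for p in self.paths:
            out.update(p)
        return frozenset(out)

    def path_types(self) -> list[str]:
        """'intra' if both endpoints share a chain, else 'inter'."""
        return [
            "intra" if p[0][0] == p[-1][0] else "inter" for p in self.paths
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tbottleneck_pN\ttype\tresidues\n")
            for r, (p, b, t) in enumerate(
                zip(self.paths, self.bottlenecks, self.path_types()), 1
            ):
                fh.write(
                    f"{r}\t{float(b)!r}\t{t}\t" + "-".join(map(_label, p)) + "\n"
                )


# ---------------------------------------------------------------------------
# Graph construction


def build_graph(dF: DeltaForceMatrix, floor: float,
                source: Iterable[ResidueKey],
                sink: Iterable[ResidueKey]) -> PathwayGraph:
    """Connectivity graph on dF: edge (i,j) iff dF_ij > floor (weights pN)."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    g = nx.Graph()
    keys = dF.index
    n = len(keys)
    iu, ju = np.triu_indices(n, k=1)
    mask = dF.values[iu, ju] > floor
    if not mask.any():
        raise ValueError(
            f"no edges above floor {floor} pN; the graph is empty"
        )
    g.add_nodes_from(keys)
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(keys[int(i)], keys[int(j)],
                   weight=float(dF.values[i, j]))
    return PathwayGraph(graph=g, source=frozenset(source),
                        sink=frozenset(sink))


# ---------------------------------------------------------------------------
# Maximin cutoff


def max_connectivity_cutoff(g: PathwayGraph) -> float:
    """Largest cutoff at which some source node still reaches some sink node.

    Implemented as a binary search over the sorted unique edge weights
    with union-find connectivity at each probe, O(E log E).  Equals the
    maximin (widest-path) bottleneck between the regions.
    """
    edges = [(u, v, float(d["weight"]))
             for u, v, d in g.graph.edges(data=True)]
    weights = sorted({w for _, _, w in edges})
    if not weights or not _connected_at(g, edges, weights[0]):
        raise DisconnectedError(
            "no perturbation connectivity between source and sink regions"
        )
    # binary search for the largest threshold that keeps the regions joined
    lo, hi = 0, len(weights) - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _connected_at(g, edges, weights[mid]):
            lo = mid
        else:
            hi = mid - 1
    return weights[lo]


def _connected_at(g: PathwayGraph, edges, threshold: float) -> bool:
    ds = DisjointSet(g.graph.nodes)
    for u, v, w in edges:
        if w >= threshold:
            ds.merge(u, v)
    roots = {ds[s] for s in g.source if s in ds}
    return any(ds[t] in roots for t in g.sink if t in ds)


# ---------------------------------------------------------------------------
# Widest-path extraction


def _widest_path(graph: nx.Graph, source: frozenset, sink: frozenset
                 ) -> tuple[list, float] | None:
    """Widest (maximin) source->sink path.

    Ties on bottleneck weight are broken by fewer hops, then by
    lexicographically smallest node sequence, so extraction is fully
    deterministic.  A Dijkstra-like search where each node's label is
    the best (bottleneck, -hops, path) reachable so far.
    """
    INF = float("inf")
    # heap entries: (-bottleneck, hops, path-as-tuple); best label per node
    best: dict = {}
    heap = []
    for s in sorted(source):
        if s in graph:
            label = (-INF, 0, (s,))
            best[s] = label
            heapq.heappush(heap, label)
    while heap:
        negb, hops, path = heapq.heappop(heap)
        node = path[-1]
        if best.get(node) != (negb, hops, path):
            continue  # stale entry
        if node in sink:
            return list(path), -negb
        for nbr in sorted(graph.neighbors(node)):
            if nbr in path:
                continue
            w = graph.edges[node, nbr]["weight"]
            cand = (max(negb, -w), hops + 1, path + (nbr,))
            if nbr not in best or cand < best[nbr]:
                best[nbr] = cand
                heapq.heappush(heap, cand)
    return None


def extract_pathways(g: PathwayGraph, cutoff: float,
                     max_paths: int = 3) -> PathwayResult:
    """Ranked widest paths inside the >=cutoff subgraph.

    The first path is a widest path realising the region-to-region
    bottleneck; subsequent paths are found after removing the previous
    path's interior nodes (node-disjoint-preferred), so ranks are
    non-increasing in bottleneck weight.
    """
    limit = max_connectivity_cutoff(g)
    if cutoff > limit:
        raise ValueError(
            f"cutoff {cutoff} pN exceeds the maximal connectivity cutoff "
            f"{limit} pN"
        )
    sub = nx.Graph()
    sub.add_nodes_from(g.graph.nodes)
    for u, v, d in g.graph.edges(data=True):
        if d["weight"] >= cutoff:
            sub.add_edge(u, v, weight=d["weight"])

    work = sub.copy()
    paths: list[list[ResidueKey]] = []
    bottlenecks: list[float] = []
    for _ in range(max_paths):
        found = _widest_path(work, g.source, g.sink)
        if found is None:
            break
        path, bottleneck = found
        paths.append(path)
        bottlenecks.append(bottleneck)
        interior = path[1:-1]
        work.remove_nodes_from(interior)
        if not interior:
            # a direct source-sink edge: remove it instead
            work.remove_edge(path[0], path[-1])
    return PathwayResult(cutoff=cutoff, subgraph=sub, paths=paths,
                         bottlenecks=bottlenecks)


def robust_residues(results: Sequence[PathwayResult]) -> frozenset[ResidueKey]:
    """Residues taking part in the pathways of *every* result.

    The intersection of the results' pathway node sets; an empty
    intersection is a valid outcome.
    """
    if len(results) < 2:
        raise ValueError("need at least two pathway results to intersect")
    out = results[0].node_set()
    for r in results[1:]:
        out &= r.node_set()
    return out
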