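"""Allosteric communication pathways from a fused residue graph.

The residue distance cross-correlation graph (RDCM) fuses the contact
matrix and the DCCM: an edge joins residues i and j when they are in
contact often enough (frequency >= f_min) *and* their motions are coupled
(|C(i,j)| >= c_min); its weight is -ln|C(i,j)|, so strongly correlated
pairs are "short" and shortest paths trace chains of correlated contacts.
Dijkstra shortest paths over all residue pairs score each edge by the
number of optimal paths that traverse it (all co-optimal paths counted);
after normalising by the maximum, edges above an importance threshold form
the shortest-path map, and the hotspot residues are their endpoints.
Hotspot sets from several simulation systems are intersected (optionally
with a +-window slack in residue position) to find the communication
residues common to all systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .correlation import DCCM, ContactMatrix
from .structure_io import ValidationError

__all__ = [
    "ResidueGraph",
    "PathwayResult",
    "build_rdcm_graph",
    "shortest_paths",
    "extract_spm",
    "common_residues",
    "DEFAULT_F_MIN",
    "DEFAULT_C_MIN",
    "DEFAULT_IMPORTANCE_THRESHOLD",
]

# Defaults standing in for thresholds the method leaves open: contact in at
# least half of the frames, a small correlation floor to exclude
# noise-level couplings, and the fraction of the maximum path traffic an
# edge must carry to enter the shortest-path map.
DEFAULT_F_MIN = 0.5
DEFAULT_C_MIN = 0.05
DEFAULT_IMPORTANCE_THRESHOLD = 0.3

WEIGHT_FORMS = ("neglog", "one_minus")


ResidueGraph = nx.Graph  # nodes: global residue indices; edge attrs: weight, corr, freq


@dataclass
class PathwayResult:
    """Shortest-path map of one system.

    ``edges`` lists every graph edge with its normalised importance in
    [0, 1]; ``retained_edges`` those at or above the threshold; ``hotspots``
    the ascending global indices of retained-edge endpoints.
    """

    edges: list[tuple[int, int, float, float, float, float]]  # i, j, weight, |C|, freq, importance
    retained_edges: list[tuple[int, int, float]]  # i, j, importance
    hotspots: list[int]
    importance_threshold: float
    paths: dict[tuple[int, int], tuple[list[int], float]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("res_i\tres_j\tweight\tabs_corr\tfreq\timportance\tretained\n")
            retained = {(i, j) for i, j, _ in self.retained_edges}
            for i, j, w, c, f, imp in self.edges:
                fh.write(
                    f"{i}\t{j}\t{w:.17g}\t{c:.17g}\t{f:.17g}\t{imp:.17g}\t"
                    f"{int((i, j) in retained)}\n"
                )

    def hotspots_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\n")
            for r in self.hotspots:
                fh.write(f"{r}\n")

    def pymol_selection(self) -> str:
        """PyMOL-style selection naming the hotspot residues."""
        return "select hotspots, resi " + "+".join(str(r) for r in self.hotspots)


def build_rdcm_graph(
    correlation: DCCM,
    contacts: ContactMatrix,
    f_min: float = DEFAULT_F_MIN,
    c_min: float = DEFAULT_C_MIN,
    weight_form: str = "neglog",
    include: Iterable[int] | None = None,
) -> ResidueGraph:
    """Fuse DCCM and contact matrix into the weighted residue graph.

    Edge (i, j) exists iff i != j, contact frequency >= ``f_min`` and
    |C(i,j)| >= ``c_min``; its weight is -ln|C| (default) or 1-|C|.
    ``include`` restricts the node set (e.g. protein residues only, the
    default upstream); ``c_min`` must be positive so |C|=0 pairs (infinite
    weight) can never enter.
    """
    if correlation.C.shape != contacts.freq.shape:
        raise ValidationError(
            f"DCCM is {correlation.C.shape} but contact matrix is {contacts.freq.shape}"
        )
    if not np.array_equal(correlation.residues, contacts.residues):
        raise ValidationError("DCCM and contact matrix label different residues")
    if not 0 < c_min:
        raise ValidationError("c_min must be positive (|C|=0 edges have infinite weight)")
    if weight_form not in WEIGHT_FORMS:
        raise ValidationError(f"weight_form must be one of {WEIGHT_FORMS}")
    residues = [int(r) for r in correlation.residues]
    keep = set(residues) if include is None else set(int(r) for r in include)
    g = nx.Graph()
    g.add_nodes_from(r for r in residues if r in keep)
    absC = np.abs(correlation.C)
    n = len(residues)
    for a in range(n):
        if residues[a] not in keep:
            continue
        for b in range(a + 1, n):
            if residues[b] not in keep:
                continue
            if contacts.freq[a, b] < f_min or absC[a, b] < c_min:
                continue
            c = min(absC[a, b], 1.0)
            weight = -math.log(c) if weight_form == "neglog" else 1.0 - c
            g.add_edge(
                residues[a], residues[b],
                weight=weight, corr=float(absC[a, b]), freq=float(contacts.freq[a, b]),
            )
    return g


def shortest_paths(
    graph: ResidueGraph,
    sources: Sequence[int],
    targets: Sequence[int],
) -> dict[tuple[int, int], tuple[list[int], float] | None]:
    """Minimal-weight Dijkstra path for every (source, target) pair.

    Unreachable pairs map to ``None``.
    """
    for node in list(sources) + list(targets):
        if node not in graph:
            raise ValidationError(f"residue {node} is not a node of the graph")
    out: dict[tuple[int, int], tuple[list[int], float] | None] = {}
    for s in sources:
        dist, path = nx.single_source_dijkstra(graph, s, weight="weight")
        for t in targets:
            if s == t:
                continue
            out[(s, t)] = ([*path[t]], float(dist[t])) if t in dist else None
    return out


def _sigma_from(graph: ResidueGraph, source: int) -> tuple[dict[int, float], dict[int, float]]:
    """Dijkstra distances and shortest-path counts from one source.

    sigma[v] is the number of distinct minimum-weight source->v paths,
    accumulated over predecessors u with dist[u] + w(u,v) == dist[v]
    (float equality with a small relative tolerance for tie detection).
    """
    dist = nx.single_source_dijkstra_path_length(graph, source, weight="weight")
    # zero-weight edges (|C| numerically 1) make dist ties possible; process
    # nodes in (dist, node) order and only count predecessors settled earlier,
    # which is deterministic and independent of adjacency order
    order = {v: k for k, v in enumerate(sorted(dist, key=lambda v: (dist[v], v)))}
    sigma = {v: 0.0 for v in dist}
    sigma[source] = 1.0
    for v in sorted(dist, key=lambda v: (dist[v], v)):
        if v == source:
            continue
        total = 0.0
        for u in graph[v]:
            if u in dist and _on_path(dist[u], graph[v][u]["weight"], dist[v]):
                if dist[u] < dist[v] or order[u] < order[v]:
                    total += sigma[u]
        sigma[v] = total
    return dist, sigma


def _on_path(du: float, w: float, dv: float) -> bool:
    return math.isclose(du + w, dv, rel_tol=1e-9, abs_tol=1e-12)


def extract_spm(
    graph: ResidueGraph,
    all_pairs: bool = True,
    importance_threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
    sources: Sequence[int] | None = None,
    targets: Sequence[int] | None = None,
) -> PathwayResult:
    """Shortest-path map: score edges by shortest-path traffic and retain
    the most traversed ones.

    For every node pair (all pairs by default, or ``sources`` x ``targets``)
    the number of co-optimal shortest paths crossing each edge is counted
    exactly (ties all counted); importance is this count normalised by its
    maximum, and edges with importance >= ``importance_threshold`` are
    retained.  Hotspot residues are the endpoints of retained edges in
    ascending global order.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if graph.number_of_edges() == 0:
        raise ValidationError("graph has no edges to rank")
    nodes = sorted(graph.nodes)
    if all_pairs:
        pair_sources = nodes
        pair_targets = nodes
    else:
        if not sources or not targets:
            raise ValidationError("sources and targets required when all_pairs is off")
        for node in list(sources) + list(targets):
            if node not in graph:
                raise ValidationError(f"residue {node} is not a node of the graph")
        pair_sources = sorted(set(int(s) for s in sources))
        pair_targets = sorted(set(int(t) for t in targets))

    needed = sorted(set(pair_sources) | set(pair_targets))
    dist: dict[int, dict[int, float]] = {}
    sigma: dict[int, dict[int, float]] = {}
    for s in needed:
        dist[s], sigma[s] = _sigma_from(graph, s)

    counts: dict[tuple[int, int], float] = {tuple(sorted(e)): 0.0 for e in graph.edges}
    seen_pairs = set()
    for s in pair_sources:
        for t in pair_targets:
            if s == t or (t, s) in seen_pairs:
                continue
            seen_pairs.add((s, t))
            if t not in dist[s]:
                continue  # unreachable pair
            dst = dist[s][t]
            for u, v, data in graph.edges(data=True):
                w = data["weight"]
                through = 0.0
                if u in dist[s] and v in dist[t] and _on_path(
                    dist[s][u] + w, dist[t][v], dst
                ):
                    through += sigma[s][u] * sigma[t][v]
                if v in dist[s] and u in dist[t] and _on_path(
                    dist[s][v] + w, dist[t][u], dst
                ):
                    through += sigma[s][v] * sigma[t][u]
                counts[tuple(sorted((u, v)))] += through

    max_count = max(counts.values())
    if max_count == 0:
        raise ValidationError("no pair is connected; cannot rank edges")
    edges = []
    retained = []
    hotspots: set[int] = set()
    for (i, j), cnt in sorted(counts.items()):
        data = graph[i][j]
        imp = cnt / max_count
        edges.append((i, j, data["weight"], data["corr"], data["freq"], imp))
        if imp >= importance_threshold:
            retained.append((i, j, imp))
            hotspots.update((i, j))

    paths = {}
    if sources is not None and targets is not None:
        paths = shortest_paths(graph, sources, targets)
        paths = {k: v for k, v in paths.items() if v is not None}
    return PathwayResult(
        edges=edges, retained_edges=retained, hotspots=sorted(hotspots),
        importance_threshold=importance_threshold, paths=paths,
    )


def common_residues(
    pathways: Sequence[PathwayResult | Iterable[int]],
    window: int = 0,
) -> list[int]:
    """Residues present in every system's hotspot set, within +-window.

    With ``window=0`` this is the exact intersection.  With a positive
    window a residue counts as shared when every system has a hotspot
    within ``window`` positions of it; runs of equivalent indices are
    collapsed to their smallest member.
    """
    if len(pathways) < 2:
        raise ValidationError("need at least two systems to intersect")
    if window < 0:
        raise ValidationError("window must be non-negative")
    sets: list[set[int]] = []
    for p in pathways:
        s = set(p.hotspots) if isinstance(p, PathwayResult) else set(int(r) for r in p)
        if any(r < 1 for r in s):
            raise ValidationError("hotspot sets must use 1-based global residue indices")
        sets.append(s)
    candidates = sorted(set().union(*sets))
    kept = [
        r for r in candidates
        if all(any(abs(r - x) <= window for x in s) for s in sets)
    ]
    # collapse window-equivalent runs, reporting the smallest index of each
    out: list[int] = []
    for r in kept:
        if not out or r - out[-1] > window:
            out.append(r)
    return out
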