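"""Vascular graph construction, tree tracking, Strahler ordering and
topological abnormality detection.

The geometric vascular graph is built from a skeleton image: landmark pixels
(bifurcations and terminals) are removed, each remaining 8-connected run of
centreline pixels becomes one skeleton-segment edge, and the landmark pixel
clusters it touches become its endpoint vertices.  8-adjacent landmark pixels
are merged into a single vertex — this is why two bifurcations that fall
within a couple of pixels of each other surface as one vertex with four or
more connected edges, the signature of a merged bifurcation.

Trees are tracked by region growing on the graph: a breadth-first expansion
from every starting vertex, each edge claimed by the first tree to reach it.
A healthy arterial or venous tree is a rooted binary tree; deviations are
reported as topological abnormalities: vertices with more than three
connected edges, and graph circles found by comparing each tracked tree's
edge set with its own minimum spanning tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.ndimage as ndi

from .skeleton import LandmarkSet, OpticDisc, count_neighbors

__all__ = [
    "SkeletonSegment",
    "Vertex",
    "GeometricGraph",
    "VascularTree",
    "TopologyReport",
    "remove_od_region",
    "build_geometric_graph",
    "track_trees",
    "assign_strahler",
    "detect_topology_abnormalities",
    "path_length",
]

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def path_length(path) -> float:
    """Geodesic length of a pixel path: axial steps count 1, diagonal sqrt(2)."""
    if len(path) < 2:
        return 0.0
    p = np.asarray(path, dtype=float)
    steps = np.hypot(*(p[1:] - p[:-1]).T)
    return float(steps.sum())


@dataclass
class SkeletonSegment:
    """A centreline piece joining two landmark vertices."""

    pixel_path: list[tuple[int, int]]
    endpoints: tuple[int, int]  # vertex ids; equal for a self-loop
    length: float

    def oriented_from(self, vertex_pos) -> list[tuple[int, int]]:
        """Pixel path ordered so it leaves from the end nearer ``vertex_pos``."""
        first, last = self.pixel_path[0], self.pixel_path[-1]
        d0 = (first[0] - vertex_pos[0]) ** 2 + (first[1] - vertex_pos[1]) ** 2
        d1 = (last[0] - vertex_pos[0]) ** 2 + (last[1] - vertex_pos[1]) ** 2
        return self.pixel_path if d0 <= d1 else self.pixel_path[::-1]


@dataclass
class Vertex:
    position: tuple[float, float]  # centroid of the landmark pixel cluster
    kind: str  # start | bifurcation | end
    pixels: list[tuple[int, int]]


@dataclass
class GeometricGraph:
    vertices: dict[int, Vertex]
    edges: dict[int, SkeletonSegment]
    defects: list[str] = field(default_factory=list)

    def as_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for vid, v in self.vertices.items():
            g.add_node(vid, position=v.position, kind=v.kind)
        for eid, seg in self.edges.items():
            u, v = seg.endpoints
            g.add_edge(u, v, key=eid, length=seg.length)
        return g

    def vertex_degree(self, vid: int) -> int:
        """Number of connected edge ends at a vertex (a self-loop counts 2)."""
        deg = 0
        for seg in self.edges.values():
            deg += seg.endpoints.count(vid)
        return deg


@dataclass
class VascularTree:
    """A tracked, rooted, directed vascular tree (abstract vascular tree)."""

    tree_id: int
    root: int
    edges: dict[int, tuple[int, int]]  # edge id -> (parent vertex, child vertex)
    vertices: set[int]
    strahler: dict[int, int] = field(default_factory=dict)

    def children_edges(self, vertex: int) -> list[int]:
        return sorted(e for e, (u, _) in self.edges.items() if u == vertex)


@dataclass
class TopologyReport:
    overdegree_vertices: list[tuple[int, int]]  # (vertex id, connected-edge count)
    cycles: list[list[int]]  # each: edge ids forming one graph circle
    merged_bifurcation_candidates: list[int]
    orphan_vertices: set[int] = field(default_factory=set)

    @property
    def is_clean(self) -> bool:
        return not (self.overdegree_vertices or self.cycles)


def remove_od_region(skel: np.ndarray, od: OpticDisc | np.ndarray) -> np.ndarray:
    """Delete skeleton pixels inside the optic-disc region.

    Central vessels inside the disc are intertwined and their geometry cannot
    be estimated, so they are excluded before graph construction; cut points
    become new terminal pixels.
    """
    skel = np.asarray(skel, dtype=bool)
    if isinstance(od, OpticDisc):
        rr, cc = np.mgrid[: skel.shape[0], : skel.shape[1]]
        inside = od.contains(rr, cc)
    else:
        inside = np.asarray(od, dtype=bool)
    out = skel & ~inside
    if skel.any() and not out.any():
        warnings.warn("optic-disc region covers the entire skeleton", stacklevel=2)
    return out


def _order_component(pixels: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a degree-<=2 component into a walk."""
    if len(pixels) == 1:
        return list(pixels)
    neigh = {
        p: [q for dr, dc in _EIGHT if (q := (p[0] + dr, p[1] + dc)) in pixels]
        for p in pixels
    }
    endpoints = sorted(p for p, ns in neigh.items() if len(ns) <= 1)
    start = endpoints[0] if endpoints else min(pixels)  # closed ring: arbitrary
    path = [start]
    prev = None
    cur = start
    while True:
        nxt = [q for q in neigh[cur] if q != prev]
        if not nxt:
            break
        prev, cur = cur, min(nxt)
        if cur == start:
            break
        path.append(cur)
        if len(path) > len(pixels):  # safety: malformed component
            break
    return path


def build_geometric_graph(
    skel: np.ndarray, landmarks: LandmarkSet, merge_tolerance: float = 3.0
) -> GeometricGraph:
    """Build the geometric vascular graph from a skeleton and its landmarks.

    Landmark pixels are removed from the skeleton; every residual 8-connected
    component becomes one :class:`SkeletonSegment` edge attached to the
    landmark clusters 8-adjacent to it.  Vertices with no incident segment
    are dropped.  Segments touching fewer or more than two clusters are
    recorded in ``defects`` (one cluster: self-loop).

    Two bifurcations extremely close in Euclidean space cannot be resolved as
    separate branch points: any segment of path length at most
    ``merge_tolerance`` px joining two bifurcation vertices is contracted,
    merging its endpoints into one vertex (which then carries four or more
    connected edges and is flagged downstream as a merged bifurcation).
    """
    skel = np.asarray(skel, dtype=bool)
    lm_pixels = landmarks.all_landmarks()
    lm_mask = np.zeros_like(skel)
    for r, c in lm_pixels:
        lm_mask[r, c] = True
    lm_mask &= skel

    # vertices: 8-connected clusters of landmark pixels
    cluster_lab, n_clusters = ndi.label(lm_mask, structure=np.ones((3, 3)))
    vertices: dict[int, Vertex] = {}
    for cid in range(1, n_clusters + 1):
        rr, cc = np.nonzero(cluster_lab == cid)
        pix = sorted(zip(rr.tolist(), cc.tolist()))
        if any(p in landmarks.starts for p in pix):
            kind = "start"
        elif any(p in landmarks.bifurcations for p in pix):
            kind = "bifurcation"
        else:
            kind = "end"
        vertices[cid - 1] = Vertex(
            position=(float(rr.mean()), float(cc.mean())), kind=kind, pixels=pix
        )

    residual = skel & ~lm_mask
    seg_lab, n_segs = ndi.label(residual, structure=np.ones((3, 3)))
    edges: dict[int, SkeletonSegment] = {}
    defects: list[str] = []
    # deterministic segment ordering: by smallest pixel
    seg_order = []
    for sid in range(1, n_segs + 1):
        rr, cc = np.nonzero(seg_lab == sid)
        seg_order.append((min(zip(rr.tolist(), cc.tolist())), sid))
    seg_order.sort()

    eid = 0
    for _, sid in seg_order:
        rr, cc = np.nonzero(seg_lab == sid)
        pix = set(zip(rr.tolist(), cc.tolist()))
        path = _order_component(pix)
        # landmark clusters adjacent to each path extremity
        def _adjacent_clusters(p):
            found = set()
            for dr, dc in _EIGHT:
                q = (p[0] + dr, p[1] + dc)
                if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]:
                    lab = int(cluster_lab[q])
                    if lab:
                        found.add(lab - 1)
            return found

        head = _adjacent_clusters(path[0])
        tail = _adjacent_clusters(path[-1])
        touched = sorted(head | tail)
        if not touched:
            defects.append(f"segment {eid} touches no landmark (isolated loop)")
            continue
        if len(touched) == 1:
            endpoints = (touched[0], touched[0])
            defects.append(f"segment {eid} forms a self-loop at vertex {touched[0]}")
        else:
            u = min(head) if head else touched[0]
            tail_rest = sorted(t for t in tail if t != u)
            v = tail_rest[0] if tail_rest else next(t for t in touched if t != u)
            endpoints = (u, v)
            if len(touched) > 2:
                defects.append(
                    f"segment {eid} adjacent to {len(touched)} landmark clusters"
                )
        edges[eid] = SkeletonSegment(
            pixel_path=path, endpoints=endpoints, length=path_length(path)
        )
        eid += 1

    _contract_close_bifurcations(vertices, edges, merge_tolerance)
    incident = {vid for seg in edges.values() for vid in seg.endpoints}
    vertices = {vid: v for vid, v in vertices.items() if vid in incident}
    return GeometricGraph(vertices=vertices, edges=edges, defects=defects)


def _contract_close_bifurcations(
    vertices: dict[int, Vertex], edges: dict[int, SkeletonSegment], tol: float
) -> None:
    """Contract segments of length <= tol joining two bifurcation vertices."""
    changed = True
    while changed:
        changed = False
        for eid, seg in sorted(edges.items()):
            u, v = seg.endpoints
            if u == v or seg.length > tol:
                continue
            if vertices[u].kind != "bifurcation" or vertices[v].kind != "bifurcation":
                continue
            keep, drop = min(u, v), max(u, v)
            merged_pixels = sorted(
                set(vertices[keep].pixels)
                | set(vertices[drop].pixels)
                | set(seg.pixel_path)
            )
            arr = np.asarray(merged_pixels, dtype=float)
            vertices[keep] = Vertex(
                position=(float(arr[:, 0].mean()), float(arr[:, 1].mean())),
                kind="bifurcation",
                pixels=merged_pixels,
            )
            del edges[eid]
            del vertices[drop]
            for other in edges.values():
                a, b = other.endpoints
                other.endpoints = (
                    keep if a == drop else a,
                    keep if b == drop else b,
                )
            changed = True
            break


def track_trees(g: GeometricGraph) -> tuple[list[VascularTree], set[int]]:
    """Track vascular trees by graph region growing from the starting vertices.

    All trees grow simultaneously, breadth-first; at each step the frontier
    vertex with the lexicographically smallest (row, col) position across all
    trees is expanded, and every unclaimed incident edge is claimed by that
    tree and oriented away from the root.  An edge reaching a vertex already
    claimed by the same tree stays in the tree's edge set (it closes a graph
    circle and will be reported downstream).  Returns the trees and the set
    of orphan vertices no tree reached.
    """
    starts = sorted(
        (vid for vid, v in g.vertices.items() if v.kind == "start"),
        key=lambda vid: g.vertices[vid].position,
    )
    if not starts:
        terminals = sorted(
            vid for vid, v in g.vertices.items() if v.kind in ("start", "end")
        )
        raise ValueError(
            "no starting vertex; candidate terminal vertices: %s" % terminals
        )

    nxg = g.as_networkx()
    trees: list[VascularTree] = []
    vertex_owner: dict[int, int] = {}
    edge_owner: dict[int, int] = {}
    frontiers: list[list[int]] = []
    for tid, root in enumerate(starts):
        trees.append(VascularTree(tree_id=tid, root=root, edges={}, vertices={root}))
        vertex_owner[root] = tid
        frontiers.append([root])

    while any(frontiers):
        # pick the lexicographically smallest frontier vertex across trees
        best = None
        for tid, frontier in enumerate(frontiers):
            for vid in frontier:
                key = (g.vertices[vid].position, tid)
                if best is None or key < best[0]:
                    best = (key, tid, vid)
        _, tid, vid = best
        frontiers[tid].remove(vid)
        tree = trees[tid]
        for _, nbr, eid in sorted(nxg.edges(vid, keys=True), key=lambda t: t[2]):
            if eid in edge_owner:
                continue
            edge_owner[eid] = tid
            tree.edges[eid] = (vid, nbr)
            if nbr not in vertex_owner:
                vertex_owner[nbr] = tid
                tree.vertices.add(nbr)
                frontiers[tid].append(nbr)
            elif vertex_owner[nbr] == tid:
                tree.vertices.add(nbr)  # cycle edge within this tree

    orphans = set(g.vertices) - set(vertex_owner)
    return trees, orphans


def assign_strahler(tree: VascularTree) -> VascularTree:
    """Assign Strahler stream orders to the tree's edges.

    Leaf edges get order 1; a parent edge gets order ``k + 1`` when at least
    two of its child edges share the maximal order ``k``, otherwise ``k``.
    Raises on a graph circle (run cycle detection first).
    """
    children: dict[int, list[int]] = {}
    for eid, (_, child_v) in tree.edges.items():
        children[eid] = tree.children_edges(child_v)

    # cycle guard: each vertex except the root must have exactly one parent edge
    seen_child: set[int] = set()
    for _, child_v in tree.edges.values():
        if child_v in seen_child or child_v == tree.root:
            raise ValueError(
                "tree %d contains a graph circle; Strahler ordering undefined"
                % tree.tree_id
            )
        seen_child.add(child_v)

    order: dict[int, int] = {}
    stack = [e for e in tree.edges if tree.edges[e][0] == tree.root]
    post: list[int] = []
    visited: set[int] = set()
    while stack:
        e = stack.pop()
        if e in visited:
            continue
        visited.add(e)
        post.append(e)
        stack.extend(children[e])
    for e in reversed(post):
        kids = children[e]
        if not kids:
            order[e] = 1
        else:
            kid_orders = [order[k] for k in kids]
            top = max(kid_orders)
            order[e] = top + 1 if kid_orders.count(top) >= 2 else top
    tree.strahler = order
    return tree


def detect_topology_abnormalities(
    g: GeometricGraph, trees: list[VascularTree], orphans: set[int] | None = None
) -> TopologyReport:
    """Flag topological rule violations against the binary-tree model.

    (a) Any vertex with more than 3 connected edges is flagged; such vertices
    are candidates for two bifurcations merged into one (they arise when two
    branch points are extremely close in Euclidean space).  (b) Per tracked
    tree, a minimum spanning tree (edge weight = segment path length) of the
    tree's undirected edge set is built; every tree edge absent from the MST
    certifies a graph circle, reported as the MST path between its endpoints
    plus the edge itself.
    """
    overdegree = []
    for vid in sorted(g.vertices):
        deg = g.vertex_degree(vid)
        if deg > 3:
            overdegree.append((vid, deg))
    merged_candidates = [vid for vid, _ in overdegree]

    cycles: list[list[int]] = []
    for tree in trees:
        sub = nx.MultiGraph()
        sub.add_nodes_from(tree.vertices)
        for eid, (u, v) in tree.edges.items():
            sub.add_edge(u, v, key=eid, weight=g.edges[eid].length)
        mst_keys = {
            k for _, _, k in nx.minimum_spanning_edges(sub, keys=True, data=False)
        }
        mst = nx.Graph()
        mst.add_nodes_from(tree.vertices)
        for eid, (u, v) in tree.edges.items():
            if eid in mst_keys:
                mst.add_edge(u, v, key=eid)
        for eid in sorted(set(tree.edges) - mst_keys):
            u, v = tree.edges[eid]
            if u == v:
                cycles.append([eid])  # self-loop is a circle on its own
                continue
            node_path = nx.shortest_path(mst, u, v)
            cycle_edges = [eid]
            for a, b in zip(node_path[:-1], node_path[1:]):
                cycle_edges.append(mst.edges[a, b]["key"])
            cycles.append(cycle_edges)

    return TopologyReport(
        overdegree_vertices=overdegree,
        cycles=cycles,
        merged_bifurcation_candidates=merged_candidates,
        orphan_vertices=set(orphans or ()),
    )
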