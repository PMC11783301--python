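"""Topological and volumetric segmentation metrics.

The central quantity is the Fracture Rate (FR): the percentage of edges of
the ground truth's skeleton-derived topological graph whose middle segments
are not covered by the prediction's skeleton within a pixel tolerance delta.
An edge here is a skeleton path between junction/endpoint nodes; a fracture is
a spurious break in a predicted branch that is continuous in the truth.

Also provided: clDice (harmonic mean of topology precision/sensitivity via
skeleton-mask overlaps), Betti-number errors (beta0 = 8-connected foreground
components, beta1 = 4-connected background components minus one) and the
standard volumetric scores (accuracy, Dice, Jaccard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .famap import skeletonize, _as_mask

DEFAULT_DELTA = 5        # px matching tolerance for edge coverage
SPUR_PRUNE_PX = 5        # leaf branches shorter than this are skeleton artifacts
MIN_EDGE_PX = 3          # edges shorter than this carry no middle segment

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class TopoNode:
    coord: tuple[int, int]
    kind: str  # "endpoint" | "junction"


@dataclass(frozen=True)
class TopoEdge:
    a: int
    b: int
    path: np.ndarray  # ordered (n, 2) skeleton pixel coordinates, 8-connected


@dataclass
class TopoGraph:
    """Skeleton-derived topology: junction/endpoint nodes, skeleton-path edges."""

    nodes: dict[int, TopoNode] = field(default_factory=dict)
    edges: list[TopoEdge] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def skeleton_pixels(self, shape) -> np.ndarray:
        """Rasterize all edge paths and node coordinates back to a pixel mask."""
        out = np.zeros(shape, dtype=bool)
        for e in self.edges:
            out[e.path[:, 0], e.path[:, 1]] = True
        for n in self.nodes.values():
            out[n.coord] = True
        return out


def _neighbors(r, c, shape):
    H, W = shape
    for dr, dc in _NBRS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < H and 0 <= cc < W:
            yield rr, cc


def _trace_raw_graph(skel: np.ndarray) -> nx.MultiGraph:
    """Trace a raw multigraph: node clusters where degree != 2, path edges between."""
    H, W = skel.shape
    deg = ndimage.convolve(skel.astype(np.uint8), _STRUCT8.astype(np.uint8),
                           mode="constant") - 1
    node_mask = skel & (deg != 2)
    labels, n_clusters = ndimage.label(node_mask, structure=_STRUCT8)
    g = nx.MultiGraph()
    for cid in range(1, n_clusters + 1):
        rs, cs = np.nonzero(labels == cid)
        cen = (rs.mean(), cs.mean())
        i = int(np.argmin((rs - cen[0]) ** 2 + (cs - cen[1]) ** 2))
        kind = "junction" if deg[rs, cs].max() >= 3 else "endpoint"
        g.add_node(cid, coord=(int(rs[i]), int(cs[i])), kind=kind)

    visited = np.zeros_like(skel)
    path_mask = skel & (deg == 2)
    # walk degree-2 chains starting from every node pixel
    node_pixels = np.argwhere(node_mask)
    for r, c in map(tuple, node_pixels):
        for rr, cc in _neighbors(r, c, (H, W)):
            if not path_mask[rr, cc] or visited[rr, cc]:
                continue
            path = [(r, c), (rr, cc)]
            visited[rr, cc] = True
            prev, cur = (r, c), (rr, cc)
            while True:
                nxt_node = None
                nxt_path = None
                for p in _neighbors(*cur, (H, W)):
                    if p == prev or not skel[p]:
                        continue
                    if node_mask[p]:
                        if nxt_node is None:
                            nxt_node = p
                    elif not visited[p] and nxt_path is None:
                        nxt_path = p
                if nxt_node is not None:
                    path.append(nxt_node)
                    g.add_edge(labels[r, c], labels[nxt_node],
                               path=np.asarray(path))
                    break
                if nxt_path is None:  # dangling chain (shouldn't occur) — drop
                    break
                prev, cur = cur, nxt_path
                visited[cur] = True
                path.append(cur)
    # direct node-node adjacencies with no path pixel in between
    seen_pairs = set()
    for r, c in map(tuple, node_pixels):
        for p in _neighbors(r, c, (H, W)):
            if node_mask[p] and labels[p] != labels[r, c]:
                key = frozenset((labels[p], labels[r, c]))
                if key not in seen_pairs:
                    seen_pairs.add(key)
                    g.add_edge(labels[r, c], labels[p],
                               path=np.asarray([(r, c), p]))
    # isolated cycles: components of untouched degree-2 pixels
    rest = path_mask & ~visited.astype(bool)
    lab_rest, n_rest = ndimage.label(rest, structure=_STRUCT8)
    next_id = n_clusters + 1
    for cid in range(1, n_rest + 1):
        pix = np.argwhere(lab_rest == cid)
        start = tuple(pix[np.lexsort((pix[:, 1], pix[:, 0]))][0])
        g.add_node(next_id, coord=(int(start[0]), int(start[1])), kind="junction")
        # in a pure cycle every pixel has exactly two component neighbors:
        # walk away from the previous pixel until back at the start
        path = [start]
        comp = lab_rest == cid
        prev, cur = start, None
        for p in _neighbors(*start, (H, W)):
            if comp[p]:
                cur = p
                break
        while cur is not None and cur != start:
            path.append(cur)
            nxt = None
            for p in _neighbors(*cur, (H, W)):
                if comp[p] and p != prev:
                    nxt = p
                    break
            prev, cur = cur, nxt
        path.append(start)
        g.add_edge(next_id, next_id, path=np.asarray(path))
        next_id += 1
    return g


def _merge_degree2(g: nx.MultiGraph) -> None:
    """Contract pass-through nodes (exactly two incident non-loop edges)."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) != 2 or g.number_of_edges(n, n) > 0:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            o1 = v1 if u1 == n else u1
            o2 = v2 if u2 == n else u2
            p1 = d1["path"]
            p2 = d2["path"]
            coord = g.nodes[n]["coord"]
            if tuple(p1[0]) != coord:
                p1 = p1[::-1]
            if tuple(p2[0]) != coord:
                p2 = p2[::-1]
            newpath = np.concatenate([p1[::-1], p2[1:]])
            g.remove_edge(u1, v1, k1)
            g.remove_edge(u2, v2, k2)
            g.remove_node(n)
            g.add_edge(o1, o2, path=newpath)
            changed = True
            break


def _path_len(path: np.ndarray) -> int:
    return int(path.shape[0])


def skeleton_to_graph(skel, prune_spurs: int = SPUR_PRUNE_PX,
                      min_edge: int = MIN_EDGE_PX) -> TopoGraph:
    """Convert a one-pixel-wide skeleton to its topological graph.

    Nodes sit at skeleton pixels with != 2 neighbors (8-connectivity),
    clustered when adjacent; edges carry the ordered pixel path between their
    nodes; isolated cycles become one self-loop edge.  Leaf edges shorter than
    ``prune_spurs`` px are removed as skeletonization artifacts, then
    pass-through nodes are re-merged; edges shorter than ``min_edge`` px
    between distinct nodes are contracted into their adjacent node.
    """
    skel = _as_mask(skel)
    if not skel.any():
        return TopoGraph()
    g = _trace_raw_graph(skel)
    # spur pruning: short leaf edges hanging off junctions
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v or _path_len(d["path"]) >= prune_spurs:
                continue
            du, dv = g.degree(u), g.degree(v)
            leaf, other = (u, v) if du == 1 else (v, u) if dv == 1 else (None, None)
            if leaf is None or g.degree(other) < 3:
                continue
            g.remove_edge(u, v, k)
            g.remove_node(leaf)
            changed = True
        if changed:
            _merge_degree2(g)
    # contract stubby node-node edges
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u != v and _path_len(d["path"]) < min_edge:
                g.remove_edge(u, v, k)
                for _, x, dd in list(g.edges(v, data=True)):
                    g.add_edge(u, x if x != v else u, path=dd["path"])
                g.remove_node(v)
                changed = True
                break
        if changed:
            _merge_degree2(g)

    out = TopoGraph()
    relabel = {}
    for i, n in enumerate(sorted(g.nodes)):
        kind = "endpoint" if g.degree(n) <= 1 else "junction"
        out.nodes[i] = TopoNode(tuple(g.nodes[n]["coord"]), kind)
        relabel[n] = i
    for u, v, d in g.edges(data=True):
        out.edges.append(TopoEdge(relabel[u], relabel[v], np.asarray(d["path"])))
    return out


def mask_to_graph(mask, **kw) -> TopoGraph:
    """Skeletonize a mask and build its topological graph."""
    return skeleton_to_graph(skeletonize(_as_mask(mask)), **kw)


# ------------------------------------------------------------- fracture rate

@dataclass(frozen=True)
class FractureReport:
    n_edges: int                  # N_Y: edges in the ground-truth graph
    n_fractured: int              # N_F: edges with an uncovered middle segment
    fracture_rate: float          # FR = 100 * N_F / N_Y, percent
    fractured_edge_ids: tuple[int, ...]


def middle_segment(path: np.ndarray, delta: int = DEFAULT_DELTA) -> np.ndarray:
    """Edge path minus its endpoint neighborhoods.

    Excludes min(delta, len//3) pixels at each end so short edges keep a
    nonempty middle; endpoint neighborhoods legitimately shift between the
    prediction's and the truth's skeletons and are not evidence of fracture.
    """
    n = path.shape[0]
    excl = min(delta, n // 3)
    return path[excl:n - excl]


def fracture_rate(pred, truth, delta: int = DEFAULT_DELTA) -> FractureReport:
    """Fracture Rate of a prediction against the ground truth.

    Builds the truth's topological graph and the prediction's (spur-pruned)
    skeleton; an edge is fractured iff some pixel of its middle segment has no
    prediction-skeleton pixel within Euclidean distance delta.  An empty
    prediction therefore scores 100%; a perfect one scores 0%.
    """
    pred, truth = _as_mask(pred), _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not truth.any():
        raise ValueError("no ground-truth topology: the truth mask is empty")
    gy = mask_to_graph(truth)
    if gy.n_edges == 0:
        raise ValueError("no ground-truth topology: the truth graph has no edges")
    gp = mask_to_graph(pred)
    sp = gp.skeleton_pixels(pred.shape)
    if sp.any():
        dist = ndimage.distance_transform_edt(~sp)
    else:
        dist = np.full(pred.shape, np.inf)
    fractured = []
    for i, e in enumerate(gy.edges):
        mid = middle_segment(e.path, delta)
        if mid.size and (dist[mid[:, 0], mid[:, 1]] > delta).any():
            fractured.append(i)
    nf, ny = len(fractured), gy.n_edges
    return FractureReport(ny, nf, 100.0 * nf / ny, tuple(fractured))


# ------------------------------------------------------- classical metrics

def cl_dice(pred, truth) -> float:
    """Centerline Dice: harmonic mean of topology precision and sensitivity."""
    pred, truth = _as_mask(pred), _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not pred.any() and not truth.any():
        return 1.0
    if not pred.any() or not truth.any():
        return 0.0
    sp, st = skeletonize(pred), skeletonize(truth)
    tprec = (sp & truth).sum() / sp.sum()
    tsens = (st & pred).sum() / st.sum()
    if tprec + tsens == 0:
        return 0.0
    return float(2.0 * tprec * tsens / (tprec + tsens))


def betti_numbers(mask) -> tuple[int, int]:
    """(beta0, beta1): 8-connected foreground components, holes via 4-connected
    background components minus one (the unbounded outside)."""
    mask = _as_mask(mask)
    _, b0 = ndimage.label(mask, structure=_STRUCT8)
    _, nbg = ndimage.label(~mask, structure=_STRUCT4)
    b1 = max(nbg - 1, 0)
    return int(b0), int(b1)


def betti_errors(pred, truth) -> tuple[int, int, int]:
    """(beta, beta0, beta1) absolute errors; beta = beta0 error + beta1 error."""
    pred, truth = _as_mask(pred), _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p0, p1 = betti_numbers(pred)
    t0, t1 = betti_numbers(truth)
    e0, e1 = abs(p0 - t0), abs(p1 - t1)
    return e0 + e1, e0, e1


def volumetric_metrics(pred, truth) -> tuple[float, float, float]:
    """(accuracy, Dice, Jaccard) on the foreground; both-empty masks score 1."""
    pred, truth = _as_mask(pred), _as_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = (pred & truth).sum()
    union = (pred | truth).sum()
    acc = float((pred == truth).mean())
    if union == 0:
        return acc, 1.0, 1.0
    dice = 2.0 * inter / (pred.sum() + truth.sum())
    jac = inter / union
    return acc, float(dice), float(jac)


@dataclass(frozen=True)
class MetricReport:
    betti: int
    betti0: int
    betti1: int
    fracture_rate: float
    cl_dice: float
    accuracy: float
    dice: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return {
            "betti_error": self.betti, "betti0_error": self.betti0,
            "betti1_error": self.betti1, "fracture_rate": self.fracture_rate,
            "cl_dice": self.cl_dice, "accuracy": self.accuracy,
            "dice": self.dice, "jaccard": self.jaccard,
        }


def evaluate_pair(pred, truth, delta: int = DEFAULT_DELTA) -> MetricReport:
    """All topological and volumetric metrics for one prediction/truth pair."""
    b, b0, b1 = betti_errors(pred, truth)
    fr = fracture_rate(pred, truth, delta).fracture_rate
    acc, dice, jac = volumetric_metrics(pred, truth)
    return MetricReport(b, b0, b1, fr, cl_dice(pred, truth), acc, dice, jac)
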