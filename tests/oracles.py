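"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (per-pixel loops, exhaustive sweeps,
breadth-first floods) and shares no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def sauvola_reference(prob: np.ndarray, window: int, k: float, r: float) -> np.ndarray:
    """Per-pixel loop Sauvola threshold with reflect-padded windows."""
    h, w = prob.shape
    half = window // 2
    padded = np.pad(prob.astype(float), half, mode="reflect")
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i : i + window, j : j + window]
            m = win.mean()
            s = win.std()
            t = m * (1.0 + k * (s / r - 1.0))
            out[i, j] = prob[i, j] > t
    return out


def flood_holes(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Holes = 4-connected background components not reaching the border."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    holes = []
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] or seen[si, sj]:
                continue
            comp = []
            touches_border = False
            queue = deque([(si, sj)])
            seen[si, sj] = True
            while queue:
                i, j = queue.popleft()
                comp.append((i, j))
                if i in (0, h - 1) or j in (0, w - 1):
                    touches_border = True
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        queue.append((ni, nj))
            if not touches_border:
                holes.append(set(comp))
    return holes


def components_8(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected foreground components by BFS."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for si in range(h):
        for sj in range(w):
            if not mask[si, sj] or seen[si, sj]:
                continue
            comp = []
            queue = deque([(si, sj)])
            seen[si, sj] = True
            while queue:
                i, j = queue.popleft()
                comp.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            queue.append((ni, nj))
            comps.append(set(comp))
    return comps


def aupr_sweep(prob: np.ndarray, gt: np.ndarray) -> float:
    """Exhaustive threshold sweep + step-wise PR integration."""
    p = prob.ravel().astype(float)
    g = gt.ravel().astype(bool)
    thresholds = np.unique(p)
    pts = []  # (recall, precision), from strictest threshold downward
    n_pos = int(g.sum())
    for t in thresholds[::-1]:
        pred = p >= t
        tp = int((pred & g).sum())
        fp = int((pred & ~g).sum())
        if tp + fp == 0:
            continue
        pts.append((tp / n_pos, tp / (tp + fp)))
    area = 0.0
    prev_recall = 0.0
    for recall, precision in pts:
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def cross_section_width(mask: np.ndarray, point, direction) -> int:
    """Vessel width by counting pixels along the perpendicular at ``point``."""
    perp = np.array([-direction[1], direction[0]], dtype=float)
    perp /= np.hypot(*perp)
    count = 0
    for sign in (1.0, -1.0):
        step = 0 if sign > 0 else 1  # count the centre pixel once
        while True:
            q = np.asarray(point, dtype=float) + sign * step * perp
            i, j = int(round(q[0])), int(round(q[1]))
            if not (0 <= i < mask.shape[0] and 0 <= j < mask.shape[1] and mask[i, j]):
                break
            count += 1
            step += 1
    return count


def cyclomatic_number(n_vertices: int, edges: list[tuple[int, int]]) -> int:
    """Independent cycles of an undirected multigraph: E - V + C, where C is
    the number of connected components (DFS back-edge count)."""
    parent = list(range(n_vertices))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = n_vertices
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            comps -= 1
    return len(edges) - n_vertices + comps


def strahler_reference(edges: dict[int, tuple[int, int]], root: int) -> dict[int, int]:
    """Strahler orders by direct recursion on a (parent, child) edge dict."""
    children: dict[int, list[int]] = {}
    for eid, (u, _) in edges.items():
        children.setdefault(u, []).append(eid)

    def order(eid: int) -> int:
        kids = children.get(edges[eid][1], [])
        if not kids:
            return 1
        vals = [order(k) for k in kids]
        top = max(vals)
        return top + 1 if vals.count(top) >= 2 else top

    return {eid: order(eid) for eid in edges}
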