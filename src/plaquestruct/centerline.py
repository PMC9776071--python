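"""Lumen centerlines as least-cost paths between user seeds.

Costs are cheap where the flow-enhanced (TOF) channel is bright, so the
minimum-cost path between two intraluminal seeds runs along the vessel.
Paths are computed with Dijkstra's algorithm on the 26-connected voxel
graph; an exact A* speedup (admissible Euclidean-times-minimum-cost
heuristic) keeps large grids tractable without changing the result.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .grids import ContrastStack, index_to_world

NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)


@dataclass
class CostVolume:
    """Non-negative traversal cost per voxel (cost x mm integrates along paths)."""

    costs: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, float) * np.ones(3)
        self.origin = np.asarray(self.origin, float) * np.ones(3)
        if np.any(self.costs < 0):
            raise ValueError("costs must be non-negative")


@dataclass
class Centerline:
    """Ordered voxel path with world coordinates and cumulative arc-length."""

    points: np.ndarray      # (N, 3) world mm
    voxels: np.ndarray      # (N, 3) int indices
    arclength: np.ndarray   # (N,) cumulative mm
    branch_id: str
    total_cost: float

    def __len__(self) -> int:
        return self.points.shape[0]

    def reversed(self) -> "Centerline":
        arc = self.arclength[-1] - self.arclength[::-1]
        return Centerline(
            self.points[::-1].copy(), self.voxels[::-1].copy(), arc,
            self.branch_id, self.total_cost,
        )


def build_cost_volume(
    stack: ContrastStack,
    lumen_channel: str = "TOF",
    eps: float = 0.05,
    smooth_sigma_vox: float = 0.0,
) -> CostVolume:
    """Inverse normalized-intensity cost: bright (lumen) voxels are cheap.

    ``cost = 1 / (eps + I_norm)`` with min-max normalization, so costs are
    bounded by ``1/eps``. ``smooth_sigma_vox`` optionally Gaussian-smooths
    the channel first (noise on the cost otherwise competes with the medial
    intensity gradient and lets paths wander off-axis). A constant channel
    cannot be normalized and is rejected.
    """
    img = stack.channel(lumen_channel).astype(float)
    if smooth_sigma_vox > 0:
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, smooth_sigma_vox)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        raise ValueError(f"channel {lumen_channel!r} is constant; cost undefined")
    norm = (img - lo) / (hi - lo)
    return CostVolume(1.0 / (eps + norm), stack.spacing, stack.origin)


def _check_seed(cost: CostVolume, seed) -> tuple[int, int, int]:
    seed = tuple(int(v) for v in seed)
    shape = cost.costs.shape
    if len(seed) != 3 or any(not 0 <= s < n for s, n in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside grid {shape}")
    if not np.isfinite(cost.costs[seed]):
        raise ValueError(f"seed {seed} has non-finite cost")
    return seed


def _dijkstra(cost: CostVolume, start_idx, goals, use_heuristic: bool):
    """Single-source Dijkstra / A* over the 26-connected voxel graph.

    Returns (dist, pred) arrays over linear indices; stops once every goal
    is settled. The heuristic (minimum cost times Euclidean distance to the
    single goal) is admissible and consistent, so it never changes the
    result; it is only used with exactly one goal.
    """
    shape = cost.costs.shape
    c = np.ascontiguousarray(cost.costs, dtype=float).ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    off_lin = NEIGHBOR_OFFSETS @ strides
    step_len = np.linalg.norm(NEIGHBOR_OFFSETS * cost.spacing, axis=1)
    start = int(np.ravel_multi_index(start_idx, shape))
    goal_set = {int(np.ravel_multi_index(g, shape)) for g in goals}

    if use_heuristic and len(goal_set) == 1:
        goal_idx = np.asarray(list(goals)[0], dtype=float)
        c_min = float(np.nanmin(c[np.isfinite(c)]))

        def h(lin: int) -> float:
            idx = np.array(np.unravel_index(lin, shape), dtype=float)
            return c_min * float(np.linalg.norm((idx - goal_idx) * cost.spacing))

    else:
        def h(lin: int) -> float:
            return 0.0

    dist = np.full(c.size, np.inf)
    pred = np.full(c.size, -1, dtype=np.int64)
    done = np.zeros(c.size, dtype=bool)
    dist[start] = 0.0
    heap = [(h(start), start)]
    remaining = set(goal_set)
    nb = NEIGHBOR_OFFSETS
    while heap:
        _, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        remaining.discard(u)
        if not remaining:
            break
        idx3 = np.array(np.unravel_index(u, shape))
        inside = np.all((idx3 + nb >= 0) & (idx3 + nb < shape), axis=1)
        du = dist[u]
        cu = c[u]
        for m in np.nonzero(inside)[0]:
            v = u + int(off_lin[m])
            if done[v]:
                continue
            nd = du + 0.5 * (cu + c[v]) * step_len[m]
            # strict improvement, or an equal-cost route via a
            # lexicographically smaller predecessor (deterministic ties)
            if nd < dist[v] or (nd == dist[v] and u < pred[v]):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd + h(v), v))
    if remaining:
        raise ValueError("no finite-cost path connects the seeds")
    return dist, pred


def _walk_back(pred, start_lin: int, goal_lin: int, shape):
    path = [goal_lin]
    while path[-1] != start_lin:
        p = int(pred[path[-1]])
        if p < 0:
            raise ValueError("broken predecessor chain")
        path.append(p)
    path.reverse()
    return np.array(np.unravel_index(np.array(path), shape)).T


def least_cost_path(
    cost: CostVolume, seed_a, seed_b, use_heuristic: bool = True
) -> Centerline:
    """Minimum-total-cost 26-connected path between two voxels.

    Edge weight is the mean of the endpoint costs times the metric step
    length. Ties are broken lexicographically on the (C-order) linear voxel
    index, so the result is fully deterministic. Raises if no finite-cost
    path connects the seeds.
    """
    seed_a = _check_seed(cost, seed_a)
    seed_b = _check_seed(cost, seed_b)
    shape = cost.costs.shape
    if seed_a == seed_b:
        pt = index_to_world(seed_a, cost.spacing, cost.origin)[None, :]
        return Centerline(pt, np.array([seed_a]), np.zeros(1), "", 0.0)
    dist, pred = _dijkstra(cost, seed_a, [seed_b], use_heuristic)
    start = int(np.ravel_multi_index(seed_a, shape))
    goal = int(np.ravel_multi_index(seed_b, shape))
    voxels = _walk_back(pred, start, goal, shape)
    points = voxels * cost.spacing + cost.origin
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(points, voxels, arclength, "", float(dist[goal]))


def extract_bifurcation_centerlines(
    cost: CostVolume, seed_cca, seed_ica, seed_eca
) -> tuple[Centerline, Centerline, np.ndarray]:
    """Two least-cost paths from the CCA seed plus the bifurcation apex.

    Both paths are reconstructed from a single single-source shortest-path
    tree rooted at the CCA seed, so their common prefix is exactly the
    shared trunk; the apex is the last point they share walking from the
    CCA seed.
    """
    seeds = [_check_seed(cost, s) for s in (seed_cca, seed_ica, seed_eca)]
    if len(set(seeds)) != 3:
        raise ValueError("CCA/ICA/ECA seeds must be three distinct voxels")
    shape = cost.costs.shape
    dist, pred = _dijkstra(cost, seeds[0], [seeds[1], seeds[2]], use_heuristic=False)
    start = int(np.ravel_multi_index(seeds[0], shape))

    def build(goal_seed, branch_id):
        goal = int(np.ravel_multi_index(goal_seed, shape))
        voxels = _walk_back(pred, start, goal, shape)
        points = voxels * cost.spacing + cost.origin
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return Centerline(points, voxels, arc, branch_id, float(dist[goal]))

    p_ica = build(seeds[1], "CCA-ICA")
    p_eca = build(seeds[2], "CCA-ECA")
    n = min(len(p_ica), len(p_eca))
    same = np.all(p_ica.voxels[:n] == p_eca.voxels[:n], axis=1)
    if not same[0]:
        raise ValueError("paths share no points; seeds are likely misplaced")
    last = int(np.nonzero(same)[0].max())
    apex = p_ica.points[last].copy()
    return p_ica, p_eca, apex
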