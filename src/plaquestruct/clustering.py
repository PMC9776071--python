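"""Plaque-component classification by k-means over multi-contrast intensities.

Wall-band voxels (between the lumen and outer-wall surfaces) are clustered
in the z-scored four-channel intensity space with Lloyd's algorithm
(k-means++ seeding, several restarts), then each centroid is mapped to the
tissue whose expected multi-contrast signature it sits closest to:
calcification is hypointense on every channel, lipid hyperintense on
T1W/PDW and hypointense on T2W, everything else arterial/fibrous wall.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import CHANNELS, ContrastStack, LabelVolume, Tissue
from .phantom import DEFAULT_SIGNATURES


@dataclass
class FeatureTable:
    """Wall-band voxels with per-channel z-scored intensity features."""

    indices: np.ndarray       # (M, 3) voxel indices
    features: np.ndarray      # (M, C) z-scored intensities
    channel_names: tuple[str, ...]
    channel_mean: np.ndarray  # raw per-channel mean over the band
    channel_sd: np.ndarray    # raw per-channel SD over the band

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    def zscore(self, raw_vector) -> np.ndarray:
        """Map a raw intensity vector into this table's feature space."""
        sd = np.where(self.channel_sd > 0, self.channel_sd, 1.0)
        return (np.asarray(raw_vector, float) - self.channel_mean) / sd


@dataclass
class ClusterResult:
    assignments: np.ndarray       # (M,) cluster ids
    centroids: np.ndarray         # (k, C)
    inertia: float
    inertia_history: list[float] = field(default_factory=list)


def extract_wall_features(stack: ContrastStack, wall_mask: np.ndarray) -> FeatureTable:
    """Feature table over a boolean wall-band mask (z-score per channel)."""
    wall_mask = np.asarray(wall_mask, bool)
    if wall_mask.shape != stack.shape:
        raise ValueError("mask shape differs from stack shape")
    idx = np.argwhere(wall_mask)
    if idx.shape[0] == 0:
        raise ValueError("wall band is empty")
    raw = np.stack(
        [stack.channels[ch][wall_mask] for ch in CHANNELS], axis=1
    ).astype(float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    safe_sd = np.where(sd > 1e-12, sd, 1.0)
    feats = (raw - mean) / safe_sd
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite intensities in the wall band")
    return FeatureTable(idx, feats, CHANNELS, mean, sd)


def _kmeanspp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ initial centroids."""
    n = x.shape[0]
    centroids = [x[rng.integers(n)]]
    d2 = np.sum((x - centroids[0]) ** 2, axis=1)
    for _ in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centroids.append(x[rng.choice(n, p=probs)])
        d2 = np.minimum(d2, np.sum((x - centroids[-1]) ** 2, axis=1))
    return np.array(centroids)


def _lloyd(x, k, rng, max_iter, tol):
    c = _kmeanspp(x, k, rng)
    history = []
    assign = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(x.shape[0]), assign].sum())
        if history and inertia > history[-1] + 1e-9:
            raise AssertionError("k-means inertia increased across an iteration")
        converged = history and history[-1] - inertia < tol
        history.append(inertia)
        new_c = c.copy()
        for j in range(k):
            members = x[assign == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster at the globally farthest point
                far = int(np.argmax(d2[np.arange(x.shape[0]), assign]))
                new_c[j] = x[far]
            else:
                new_c[j] = members.mean(axis=0)
        if converged and np.allclose(new_c, c):
            break
        c = new_c
    return assign, c, history[-1], history


def kmeans_cluster(
    features: FeatureTable | np.ndarray,
    k: int = 4,
    seed: int = 17,
    n_init: int = 10,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ClusterResult:
    """Lloyd's k-means, k-means++ seeding, best of ``n_init`` restarts.

    Deterministic for a fixed seed; empty clusters are re-seeded at the
    point farthest from its current centroid. Inertia is tracked (and
    asserted non-increasing) across Lloyd iterations of each restart.
    """
    x = features.features if isinstance(features, FeatureTable) else np.asarray(features, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {x.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        assign, c, inertia, hist = _lloyd(x, k, rng, max_iter, tol)
        if best is None or inertia < best.inertia:
            best = ClusterResult(assign, c, inertia, hist)
    return best


#: Tissue classes a wall-band centroid may be mapped to.
WALL_TISSUES = (Tissue.WALL, Tissue.LIPID, Tissue.CALCIFICATION)


def assign_tissue_classes(
    result: ClusterResult,
    features: FeatureTable,
    labels: LabelVolume,
    signatures: dict[Tissue, dict[str, float]] | None = None,
) -> tuple[LabelVolume, dict]:
    """Map clusters to named tissues and relabel the wall band.

    Each centroid goes to the wall-tissue signature (z-scored into the
    band's feature space) it is nearest to; surplus centroids naturally
    fall onto the arterial-wall signature. Classes claimed by no centroid
    are reported, not raised. Only wall-band voxels change.
    """
    signatures = signatures or DEFAULT_SIGNATURES
    k = result.centroids.shape[0]
    if k < len(WALL_TISSUES):
        raise ValueError(f"need k >= {len(WALL_TISSUES)} clusters for tissue naming")
    sig_vecs = {
        t: features.zscore([signatures[t][ch] for ch in features.channel_names])
        for t in WALL_TISSUES
    }
    mapping: dict[int, Tissue] = {}
    for j in range(k):
        d = {t: float(np.linalg.norm(result.centroids[j] - v)) for t, v in sig_vecs.items()}
        mapping[j] = min(d, key=d.get)

    new = labels.labels.copy()
    idx = features.indices
    for j, tissue in mapping.items():
        sel = idx[result.assignments == j]
        new[sel[:, 0], sel[:, 1], sel[:, 2]] = int(tissue)
    unclaimed = [t.name for t in WALL_TISSUES if t not in mapping.values()]
    report = {
        "mapping": {int(j): Tissue(t).name for j, t in mapping.items()},
        "unclaimed_classes": unclaimed,
        "cluster_sizes": {
            int(j): int(np.count_nonzero(result.assignments == j)) for j in range(k)
        },
        "inertia": result.inertia,
    }
    return LabelVolume(new, labels.spacing, labels.origin), report
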