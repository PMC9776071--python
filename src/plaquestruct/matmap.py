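"""Material mapping: per-element tissue properties on a tetrahedral wall mesh.

Linear elastic constants per component — arterial tissue 0.6 MPa,
calcification 10 MPa, lipid 0.02 MPa, Poisson ratio 0.48 throughout — are
assigned by looking up the tissue label at each element centroid, then
optionally blended across component interfaces by inverse-distance
averaging of log-modulus within a transition radius (a 500x stiffness jump
between calcification and lipid is numerically hostile without one).
Constants are stored, not solved: no finite-element analysis happens here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .grids import LabelVolume, Tissue
from .phantom import VesselGeometry

log = logging.getLogger(__name__)


#: (Young's modulus MPa, Poisson ratio) per tissue class.
DEFAULT_MATERIALS: dict[Tissue, tuple[float, float]] = {
    Tissue.WALL: (0.6, 0.48),
    Tissue.CALCIFICATION: (10.0, 0.48),
    Tissue.LIPID: (0.02, 0.48),
}


@dataclass
class MaterialMesh:
    nodes: np.ndarray       # (N, 3) mm
    tets: np.ndarray        # (M, 4) node indices, positively oriented
    E: np.ndarray           # (M,) MPa
    nu: np.ndarray          # (M,)
    tissue: np.ndarray      # (M,) Tissue int of the dominant class

    def __post_init__(self) -> None:
        if np.any(self.E <= 0):
            raise ValueError("Young's modulus must be positive")
        if np.any((self.nu <= 0) | (self.nu >= 0.5)):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @property
    def volumes(self) -> np.ndarray:
        return signed_tet_volumes(self.nodes, self.tets)


def signed_tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def orient_positively(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two nodes of negatively oriented tets so all volumes are > 0."""
    tets = np.asarray(tets).copy()
    neg = signed_tet_volumes(nodes, tets) < 0
    tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()
    return tets


def edge_lengths(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    return np.concatenate(
        [np.linalg.norm(nodes[tets[:, i]] - nodes[tets[:, j]], axis=1) for i, j in pairs]
    )


# --------------------------------------------------------------------------
# phantom wall meshing

# Delaunay tetrahedra over a jittered cubic point lattice have median edge
# ~1.22x the lattice pitch (mix of axis, face- and body-diagonal edges);
# the pitch is scaled accordingly so the median edge meets target_edge.
_PITCH_PER_TARGET = 1.0 / 1.22


def mesh_phantom_wall(
    geometry: VesselGeometry,
    target_edge: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay tetrahedralization of the phantom wall band.

    Points are laid on a jittered cubic lattice restricted to the wall band
    (between lumen and outer surfaces); tetrahedra whose centroid leaves the
    band are discarded. Median edge length lands within 25% of
    ``target_edge``. Deterministic for a fixed ``seed``.
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    for b in geometry.branches.values():
        if np.any(b.wall <= 0):
            raise ValueError(f"branch {b.name} has zero wall thickness")
    pitch = target_edge * _PITCH_PER_TARGET
    lo, hi = geometry.bounding_box()
    axes = [np.arange(lo[d], hi[d] + pitch / 2, pitch) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    pts = grid + rng.uniform(-0.25, 0.25, size=grid.shape) * pitch
    pts = np.clip(pts, lo, hi)  # stay inside the geometry's bounding box

    def in_band(p):
        lumen = np.zeros(p.shape[0], dtype=bool)
        outer = np.zeros(p.shape[0], dtype=bool)
        for b in geometry.branches.values():
            d, idx = cKDTree(b.lumen_centers).query(p, workers=-1)
            lumen |= d < b.radius[idx]
            d, idx = cKDTree(b.points).query(p, workers=-1)
            outer |= d < (b.radius + b.wall)[idx]
        return outer & ~lumen

    pts = pts[in_band(pts)]
    if pts.shape[0] < 8:
        raise ValueError("wall band too thin to mesh at this target edge")
    tri = Delaunay(pts)
    tets = tri.simplices
    keep = in_band(pts[tets].mean(axis=1))
    # drop slivers left over from the convex hull
    vols = np.abs(signed_tet_volumes(pts, tets))
    keep &= vols > (pitch**3) / 60.0
    tets = orient_positively(pts, tets[keep])
    used = np.unique(tets)
    remap = -np.ones(pts.shape[0], dtype=int)
    remap[used] = np.arange(used.size)
    return pts[used], remap[tets]


# --------------------------------------------------------------------------
# material assignment


def map_materials_to_mesh(
    nodes: np.ndarray,
    tets: np.ndarray,
    labels: LabelVolume,
    table: dict[Tissue, tuple[float, float]] | None = None,
) -> MaterialMesh:
    """Per-element properties from the label at the element centroid.

    Elements whose centroid falls in lumen or background (possible at the
    rasterized boundary) get arterial-wall properties; their count is
    logged. Elements outside the label grid raise, listing offending ids.
    """
    table = table or DEFAULT_MATERIALS
    nodes = np.asarray(nodes, float)
    tets = orient_positively(nodes, np.asarray(tets))
    centroids = nodes[tets].mean(axis=1)
    ijk = np.round((centroids - labels.origin) / labels.spacing).astype(int)
    outside = np.any((ijk < 0) | (ijk >= np.array(labels.shape)), axis=1)
    if outside.any():
        raise ValueError(
            f"{int(outside.sum())} element centroids outside the label grid: "
            f"ids {np.nonzero(outside)[0][:10].tolist()}..."
        )
    tissue = labels.labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]].astype(int)
    fallback = ~np.isin(tissue, [int(t) for t in table])
    if fallback.any():
        log.info(
            "%d elements with lumen/background centroid assigned arterial wall",
            int(fallback.sum()),
        )
    tissue[fallback] = int(Tissue.WALL)
    E = np.array([table[Tissue(t)][0] for t in tissue])
    nu = np.array([table[Tissue(t)][1] for t in tissue])
    return MaterialMesh(nodes, tets, E, nu, tissue)


def smooth_transition(mesh: MaterialMesh, radius: float) -> MaterialMesh:
    """Transitional interpolation of E between components.

    Replaces each element's modulus by the inverse-distance-weighted average
    of neighbour elements within ``radius`` mm of its centroid, computed in
    log-E space (a convex combination, so the result stays between the
    extreme input moduli and varies monotonically across a flat interface).
    ``radius=0`` is the identity; ``nu`` is never altered.
    """
    if radius < 0:
        raise ValueError("transition radius must be non-negative")
    if radius == 0:
        return replace(mesh, E=mesh.E.copy())
    cent = mesh.centroids
    tree = cKDTree(cent)
    logE = np.log(mesh.E)
    out = np.empty_like(logE)
    eps = 0.1 * radius
    neighbours = tree.query_ball_point(cent, radius, workers=-1)
    for i, nb in enumerate(neighbours):
        nb = np.asarray(nb)
        d = np.linalg.norm(cent[nb] - cent[i], axis=1)
        w = 1.0 / (d + eps)
        out[i] = np.sum(w * logE[nb]) / np.sum(w)
    return replace(mesh, E=np.exp(out))
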