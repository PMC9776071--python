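"""Synthetic carotid-bifurcation phantom.

Generates a Y-shaped vessel (CCA splitting into ICA and ECA) with an
eccentric, cosine-tapered ICA stenosis, locally thickened wall (the plaque
shoulder), and ellipsoidal lipid / calcification inclusions embedded in the
wall. The phantom supplies ground-truth labels, multi-contrast renderings
and physiological waveforms so every downstream stage is testable without
patient data.

Geometry convention: branch axes are straight 3D segments meeting at the
bifurcation apex; the CCA runs along +z and the ICA/ECA tilt in the x-z
plane. Cross-sections are circles swept along each axis; the ICA lumen
center may be offset sideways (eccentric stenosis) while the outer wall
stays centered on the axis, which thickens the wall on the plaque side.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .grids import CHANNELS, ContrastStack, LabelVolume, Tissue
from .waveforms import (  # noqa: F401  (re-exported phantom interface)
    Waveform,
    make_flow_waveform,
    scale_pressure_waveform,
)

# --------------------------------------------------------------------------
# geometry types


@dataclass
class Branch:
    """Densely sampled straight branch axis with per-sample tube profile."""

    name: str
    points: np.ndarray        # (N, 3) axis samples, mm
    arclength: np.ndarray     # (N,) from branch start, mm
    radius: np.ndarray        # (N,) lumen radius, mm
    wall: np.ndarray          # (N,) wall thickness, mm
    offset: np.ndarray        # (N, 3) lumen-center offset from the axis, mm
    s_apex: float             # arclength value at the bifurcation apex

    @property
    def lumen_centers(self) -> np.ndarray:
        return self.points + self.offset

    @property
    def tangent(self) -> np.ndarray:
        d = self.points[-1] - self.points[0]
        return d / np.linalg.norm(d)

    @property
    def s_from_apex(self) -> np.ndarray:
        """Signed distance from the apex along the branch (CCA: proximal > 0)."""
        if self.name == "CCA":
            return self.s_apex - self.arclength
        return self.arclength - self.s_apex

    def profile_from_apex(self) -> tuple[np.ndarray, np.ndarray]:
        """(arclength-from-apex, lumen radius) over the downstream part."""
        s = self.s_from_apex
        keep = s >= 0
        order = np.argsort(s[keep])
        return s[keep][order], self.radius[keep][order]

    def interp(self, s_from_apex: float) -> dict:
        """Axis point, lumen center, radius, thickness at a given station."""
        s = self.s_from_apex
        order = np.argsort(s)

        def f(arr):
            a = np.asarray(arr)
            if a.ndim == 1:
                return np.interp(s_from_apex, s[order], a[order])
            return np.stack(
                [np.interp(s_from_apex, s[order], a[order, i]) for i in range(a.shape[1])]
            )

        return {
            "point": f(self.points),
            "lumen_center": f(self.lumen_centers),
            "radius": float(f(self.radius)),
            "wall": float(f(self.wall)),
        }


@dataclass
class VesselGeometry:
    """Bifurcating tube geometry; branches keyed CCA / ICA / ECA."""

    branches: dict[str, Branch]
    apex: np.ndarray
    stenosis_fraction: float

    def branch(self, name: str) -> Branch:
        return self.branches[name]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Tight axis-aligned box of the outer surface (tube, not sphere)."""
        los, his = [], []
        for b in self.branches.values():
            t = b.tangent
            # radial extent of a circular cross-section along each world axis
            lateral = np.sqrt(np.clip(1.0 - t**2, 0.0, 1.0))
            r_out = (b.radius + b.wall)[:, None] * lateral[None, :]
            los.append((b.points - r_out).min(axis=0))
            his.append((b.points + r_out).max(axis=0))
        return np.min(los, axis=0), np.max(his, axis=0)


@dataclass
class Ellipsoid:
    """Arbitrary-orientation ellipsoid: rows of ``axes`` are unit directions."""

    center: np.ndarray
    axes: np.ndarray        # (3, 3) orthonormal rows
    semi_axes: np.ndarray   # (3,) mm
    name: str = "inclusion"

    def contains(self, pts: np.ndarray) -> np.ndarray:
        local = (np.atleast_2d(pts) - self.center) @ self.axes.T
        return np.sum((local / self.semi_axes) ** 2, axis=1) <= 1.0

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return float(4.0 / 3.0 * math.pi * a * b * c)


@dataclass
class PlaqueSpec:
    lipid_regions: list[Ellipsoid] = field(default_factory=list)
    calcification_regions: list[Ellipsoid] = field(default_factory=list)
    fibrous_cap_min_target: float | None = None


# --------------------------------------------------------------------------
# configuration


@dataclass
class PhantomConfig:
    """Parameters of the default carotid-bifurcation phantom.

    Radii follow typical adult carotid calibres (CCA ~6 mm, distal ICA
    ~5 mm, ECA ~4 mm lumen diameter); the stenosis throat sits a few mm
    downstream of the apex, as in symptomatic ICA disease.
    """

    fov_mm: tuple[float, float, float] = (28.0, 16.0, 40.0)
    spacing_mm: float = 0.25
    center_xy: tuple[float, float] = (14.0, 8.0)
    apex_z: float = 18.0
    cca_radius: float = 3.1
    ica_radius: float = 2.5
    eca_radius: float = 2.0
    wall_thickness: float = 1.0
    ica_angle_deg: float = 20.0
    eca_angle_deg: float = 20.0
    stenosis_fraction: float = 0.81
    stenosis_center: float = 7.0        # mm downstream of the apex, on the ICA
    stenosis_halfwidth: float = 6.0     # cosine taper half-width, mm
    plaque_wall_thickness: float = 3.0  # wall thickness at the stenosis, mm
    eccentricity: float = 0.4           # lumen-center offset fraction
    fibrous_cap_target: float = 0.73    # mm, lipid inner surface to lumen
    back_extension: float = 3.0         # branch axis extension into the CCA, mm
    axis_ds: float = 0.1                # axis sampling step, mm
    noise_sd: float = 0.05              # per-channel additive Gaussian SD


def _cos_bump(s: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Smooth unit bump: 1 at center, 0 beyond +-halfwidth."""
    x = np.clip((s - center) / halfwidth, -1.0, 1.0)
    out = 0.5 * (1.0 + np.cos(np.pi * x))
    out[np.abs(s - center) >= halfwidth] = 0.0
    return out


def make_bifurcation_geometry(config: PhantomConfig | None = None) -> VesselGeometry:
    """Build the Y-shaped vessel geometry from a phantom config.

    The ICA minimum lumen radius equals ``ica_radius * (1 - stenosis_fraction)``
    at the throat; the lumen center is offset away from the plaque side by
    ``eccentricity`` times the radius loss.
    """
    cfg = config or PhantomConfig()
    if not (0.0 <= cfg.stenosis_fraction < 1.0):
        raise ValueError("stenosis_fraction must lie in [0, 1)")
    if cfg.ica_angle_deg <= 0 or cfg.eca_angle_deg <= 0:
        raise ValueError("branch angles must be positive")
    for r in (cfg.cca_radius, cfg.ica_radius, cfg.eca_radius):
        if r <= 0:
            raise ValueError("radii must be positive")

    x0, y0 = cfg.center_xy
    apex = np.array([x0, y0, cfg.apex_z])
    ds = cfg.axis_ds

    def sampled(start, direction, length):
        s = np.arange(0.0, length + ds / 2, ds)
        pts = start[None, :] + s[:, None] * direction[None, :]
        return s, pts

    # CCA straight up to the apex
    s, pts = sampled(np.array([x0, y0, 0.0]), np.array([0.0, 0.0, 1.0]), cfg.apex_z)
    cca = Branch(
        "CCA", pts, s,
        np.full(s.size, cfg.cca_radius),
        np.full(s.size, cfg.wall_thickness),
        np.zeros((s.size, 3)),
        s_apex=cfg.apex_z,
    )

    def daughter(name, angle_deg, r_nominal, sign):
        th = math.radians(angle_deg)
        d = np.array([sign * math.sin(th), 0.0, math.cos(th)])
        start = apex - cfg.back_extension * d
        # stop short of the axial FOV edge so the tilted tube stays inside
        z_margin = (r_nominal + cfg.wall_thickness) * math.sin(th)
        length = cfg.back_extension + (
            cfg.fov_mm[2] - cfg.apex_z - z_margin
        ) / math.cos(th)
        s, pts = sampled(start, d, length)
        s_ap = s - cfg.back_extension  # signed arc-length from the apex
        radius = np.full(s.size, r_nominal)
        wall = np.full(s.size, cfg.wall_thickness)
        offset = np.zeros((s.size, 3))
        if name == "ICA" and cfg.stenosis_fraction > 0:
            bump = _cos_bump(s_ap, cfg.stenosis_center, cfg.stenosis_halfwidth)
            radius = r_nominal * (1.0 - cfg.stenosis_fraction * bump)
            wall = cfg.wall_thickness + (
                cfg.plaque_wall_thickness - cfg.wall_thickness
            ) * bump
            # plaque grows at -y; lumen center is pushed toward +y... the
            # plaque side is +y here, so offset the lumen toward -y.
            offset = np.zeros((s.size, 3))
            offset[:, 1] = -cfg.eccentricity * (r_nominal - radius)
        return Branch(name, pts, s, radius, wall, offset, s_apex=cfg.back_extension)

    ica = daughter("ICA", cfg.ica_angle_deg, cfg.ica_radius, +1)
    eca = daughter("ECA", cfg.eca_angle_deg, cfg.eca_radius, -1)
    return VesselGeometry(
        {"CCA": cca, "ICA": ica, "ECA": eca}, apex, cfg.stenosis_fraction
    )


# --------------------------------------------------------------------------
# plaque placement


def place_wall_inclusion(
    geometry: VesselGeometry,
    branch: str,
    s_from_apex: float,
    gap_mm: float,
    semi_axes,
    azimuth: float = 0.0,
    name: str = "inclusion",
) -> Ellipsoid:
    """Place an ellipsoid in the wall, its inner pole ``gap_mm`` outside the
    lumen surface.

    ``azimuth`` rotates the radial anchor direction about the branch tangent;
    azimuth 0 points toward +y (the thick, plaque-side wall of the default
    ICA). Semi-axes are (radial, circumferential, axial).
    """
    b = geometry.branch(branch)
    st = b.interp(s_from_apex)
    t = b.tangent
    base = np.array([0.0, 1.0, 0.0])
    e_r = math.cos(azimuth) * base + math.sin(azimuth) * np.cross(t, base)
    e_r /= np.linalg.norm(e_r)
    e_c = np.cross(t, e_r)
    semi = np.asarray(semi_axes, float)
    center = st["lumen_center"] + (st["radius"] + gap_mm + semi[0]) * e_r
    return Ellipsoid(center, np.stack([e_r, e_c, t]), semi, name=name)


def default_plaque(geometry: VesselGeometry, config: PhantomConfig) -> PlaqueSpec:
    """Lipid core under the stenosis throat plus a proximal calcification.

    The lipid's inner pole sits ``fibrous_cap_target`` mm outside the lumen
    at the throat station; its axial semi-axis is short enough that the
    throat remains the closest approach, so the configured cap is the
    ground-truth thinnest cap.
    """
    lipid = place_wall_inclusion(
        geometry, "ICA", config.stenosis_center,
        gap_mm=config.fibrous_cap_target,
        semi_axes=(0.9, 1.8, 1.0), azimuth=0.0, name="lipid_core",
    )
    calc = place_wall_inclusion(
        geometry, "ICA", config.stenosis_center - 3.5,
        gap_mm=0.6, semi_axes=(0.45, 0.8, 0.8), azimuth=0.35,
        name="calcification",
    )
    return PlaqueSpec([lipid], [calc], fibrous_cap_min_target=config.fibrous_cap_target)


# --------------------------------------------------------------------------
# rasterization


def rasterize_labels(
    geometry: VesselGeometry,
    plaque: PlaqueSpec | None,
    spacing,
    shape=None,
    origin=(0.0, 0.0, 0.0),
    return_aux: bool = False,
):
    """Voxelize the phantom onto an axis-aligned grid.

    Lumen voxels lie inside any branch's lumen tube; wall voxels lie inside
    an outer tube but outside every lumen; inclusion voxels override wall
    voxels. An inclusion that escapes the wall band raises a ``ValueError``
    naming the region.

    With ``return_aux=True`` a third dict is returned carrying
    ``lumen_rho``, the normalized radial coordinate (0 on the centerline,
    1 at the lumen surface; NaN outside), used for flow-profile shading.
    """
    spacing = np.asarray(spacing, float) * np.ones(3)
    origin = np.asarray(origin, float)
    lo, hi = geometry.bounding_box()
    if shape is None:
        shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 1)
    extent = origin + (np.asarray(shape) - 1) * spacing
    if np.any(lo < origin - spacing) or np.any(hi > extent + spacing):  # 1-voxel slack
        raise ValueError(
            f"grid [{origin}, {extent}] does not enclose geometry [{lo}, {hi}]"
        )

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing + origin

    lumen = np.zeros(pts.shape[0], dtype=bool)
    outer = np.zeros(pts.shape[0], dtype=bool)
    rho = np.full(pts.shape[0], np.inf)  # normalized radial coordinate d/r
    for b in geometry.branches.values():
        d, idx = cKDTree(b.lumen_centers).query(pts, workers=-1)
        lumen |= d < b.radius[idx]
        # flow-channel coordinate: daughter cores begin at the apex (their
        # back-extension into the CCA is geometry glue, not a flow channel)
        downstream = b.s_from_apex >= 0 if b.name != "CCA" else np.ones(
            b.radius.size, dtype=bool
        )
        dc, idc = cKDTree(b.lumen_centers[downstream]).query(pts, workers=-1)
        rho = np.minimum(rho, dc / b.radius[downstream][idc])
        d, idx = cKDTree(b.points).query(pts, workers=-1)
        outer |= d < (b.radius + b.wall)[idx]

    labels = np.zeros(pts.shape[0], dtype=np.int16)
    labels[outer] = int(Tissue.WALL)
    labels[lumen] = int(Tissue.LUMEN)
    wall_mask = labels == int(Tissue.WALL)

    plaque = plaque or PlaqueSpec()
    for tissue, regions in (
        (Tissue.LIPID, plaque.lipid_regions),
        (Tissue.CALCIFICATION, plaque.calcification_regions),
    ):
        for region in regions:
            inside = region.contains(pts)
            escaped = inside & ~wall_mask & (labels != int(tissue))
            if np.any(escaped & (labels == int(Tissue.LUMEN))) or np.any(
                escaped & (labels == int(Tissue.BACKGROUND))
            ):
                raise ValueError(
                    f"inclusion {region.name!r} escapes the wall band "
                    f"({int(np.count_nonzero(escaped))} voxels outside)"
                )
            labels[inside] = int(tissue)

    vol = LabelVolume(labels.reshape(shape), spacing, origin)
    if return_aux:
        aux = {"lumen_rho": np.where(lumen, rho, np.nan).reshape(shape)}
        return vol, vol.class_counts(), aux
    return vol, vol.class_counts()


# --------------------------------------------------------------------------
# contrast rendering

#: Normalized per-class signal means for each contrast. TOF is brightest in
#: the lumen (flow enhancement); lipid is hyperintense on T1W/PDW and
#: hypointense on T2W; calcification is hypointense on every channel.
DEFAULT_SIGNATURES: dict[Tissue, dict[str, float]] = {
    Tissue.BACKGROUND: {"T1W": 0.05, "T2W": 0.05, "PDW": 0.05, "TOF": 0.05},
    Tissue.LUMEN: {"T1W": 0.30, "T2W": 0.35, "PDW": 0.30, "TOF": 0.95},
    Tissue.WALL: {"T1W": 0.55, "T2W": 0.55, "PDW": 0.55, "TOF": 0.25},
    Tissue.LIPID: {"T1W": 0.80, "T2W": 0.25, "PDW": 0.75, "TOF": 0.20},
    Tissue.CALCIFICATION: {"T1W": 0.10, "T2W": 0.10, "PDW": 0.10, "TOF": 0.10},
}


def render_contrasts(
    labels: LabelVolume,
    signatures: dict[Tissue, dict[str, float]] | None = None,
    noise_sd: float | dict[str, float] = 0.05,
    seed: int = 0,
    lumen_rho: np.ndarray | None = None,
    flow_shading: float = 0.4,
    flow_exponent: float = 1.0,
) -> ContrastStack:
    """Render the four contrast channels: class mean + additive Gaussian noise.

    If ``lumen_rho`` (normalized radial coordinate from :func:`rasterize_labels`)
    is supplied, the TOF lumen signal is shaded by
    ``1 - flow_shading * rho**flow_exponent``, emulating flow-related
    enhancement that peaks mid-lumen (the default cone profile keeps a
    non-zero medial intensity gradient, so least-cost paths run along the
    vessel axis); without it every channel is piecewise constant at the
    class means (plus noise).
    """
    signatures = signatures or DEFAULT_SIGNATURES
    present = {Tissue(v) for v in np.unique(labels.labels)}
    missing = present - set(signatures)
    if missing:
        raise ValueError(f"no intensity signature for classes {sorted(missing)}")
    if isinstance(noise_sd, dict):
        sd = {ch: float(noise_sd[ch]) for ch in CHANNELS}
    else:
        sd = {ch: float(noise_sd) for ch in CHANNELS}
    if any(v < 0 for v in sd.values()):
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    channels = {}
    for ch in CHANNELS:
        img = np.zeros(labels.shape, dtype=float)
        for t in present:
            img[labels.labels == int(t)] = signatures[t][ch]
        if ch == "TOF" and lumen_rho is not None:
            in_lumen = labels.labels == int(Tissue.LUMEN)
            shade = 1.0 - flow_shading * np.power(lumen_rho, flow_exponent)
            img[in_lumen] *= shade[in_lumen]
        if sd[ch] > 0:
            img = img + rng.normal(0.0, sd[ch], size=labels.shape)
        channels[ch] = img
    return ContrastStack(channels, labels.spacing, labels.origin)


def classify_by_signature(
    stack: ContrastStack, signatures: dict[Tissue, dict[str, float]] | None = None
) -> np.ndarray:
    """Nearest-signature classification (exact inverse of noise-free rendering)."""
    signatures = signatures or DEFAULT_SIGNATURES
    tissues = sorted(signatures, key=int)
    sig = np.array([[signatures[t][ch] for ch in CHANNELS] for t in tissues])
    data = np.stack([stack.channels[ch] for ch in CHANNELS], axis=-1)
    d2 = ((data[..., None, :] - sig) ** 2).sum(axis=-1)
    return np.array([int(t) for t in tissues], dtype=np.int16)[np.argmin(d2, axis=-1)]


def make_phantom_case(
    config: PhantomConfig | None = None,
    plaque: PlaqueSpec | None = None,
    seed: int = 0,
):
    """Geometry + labels + rendered stack for one phantom case."""
    cfg = config or PhantomConfig()
    geom = make_bifurcation_geometry(cfg)
    if plaque is None:
        plaque = default_plaque(geom, cfg)
    labels, counts, aux = rasterize_labels(
        geom, plaque, cfg.spacing_mm, return_aux=True
    )
    stack = render_contrasts(
        labels, noise_sd=cfg.noise_sd, seed=seed, lumen_rho=aux["lumen_rho"]
    )
    return geom, plaque, labels, counts, stack
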