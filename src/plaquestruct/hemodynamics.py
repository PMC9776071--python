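"""Wall-shear-stress surrogate and cycle descriptors (TAWSS, OSI, peak WSS).

The CFD participant of a fluid–structure simulation is replaced by a
transparent quasi-steady surrogate: at every instant the wall shear stress
magnitude on a branch follows the Poiseuille law ``tau = 4 mu Q / (pi r^3)``
with the instantaneous branch flow and local lumen radius, directed along
the local axis tangent. Branch flow splits at the bifurcation in proportion
to the fourth power of the distal radii (parallel-resistance rule). Fields
are flagged ``surrogate`` in every output; externally computed WSS time
series can be substituted and all descriptor operations apply unchanged.

Descriptors over one cardiac cycle of period T:
  TAWSS = (1/T) * integral |tau(t)| dt
  OSI   = 1/2 * (1 - |integral tau dt| / integral |tau| dt)   in [0, 1/2]
peak-systole WSS is |tau| at the instant of maximum inlet flow.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import VesselGeometry
from .waveforms import Waveform

BLOOD_VISCOSITY_PA_S = 0.00345
BLOOD_DENSITY_KG_M3 = 1050.0


@dataclass
class SurfaceWSSField:
    """Time-resolved WSS vectors on luminal surface points over one cycle."""

    points: np.ndarray      # (P, 3) mm
    branch: np.ndarray      # (P,) branch name per point
    arclength: np.ndarray   # (P,) mm from the bifurcation apex (>= 0)
    times: np.ndarray       # (Nt,) s spanning [0, T]
    tau: np.ndarray         # (P, Nt, 3) Pa
    period: float
    surrogate: bool = True

    def __post_init__(self) -> None:
        if self.times.size < 8:
            raise ValueError("need at least 8 time samples over the cycle")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("non-finite WSS values")
        if np.any(self.arclength < -1e-9):
            raise ValueError("arc-lengths from the apex must be >= 0")

    @property
    def magnitude(self) -> np.ndarray:
        """(P, Nt) |tau|."""
        return np.linalg.norm(self.tau, axis=2)


@dataclass
class DescriptorMap:
    """Per-surface-point scalar descriptor with validity mask."""

    values: np.ndarray
    branch: np.ndarray
    arclength: np.ndarray
    name: str
    units: str
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    surrogate: bool = True

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)


@dataclass
class ROISpec:
    """Arc-length window on one branch, anchored at the bifurcation apex."""

    branch: str = "ICA"
    start: float = 0.0
    length: float = 17.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("ROI length must be positive")


def sample_branch_surface(
    geometry: VesselGeometry, ds: float = 0.5, n_circ: int = 12
):
    """Luminal surface rings along each branch, downstream of the apex.

    Returns (points, branch, arclength, tangent_per_point, radius_per_point);
    the CCA is parameterized by distance proximal of the apex.
    """
    pts, branches, arcs, tangents, radii = [], [], [], [], []
    for b in geometry.branches.values():
        t = b.tangent
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - t * (ref @ t)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        s_ap = b.s_from_apex
        stations = np.arange(0.0, s_ap.max(), ds)
        for s in stations:
            st = b.interp(s)
            th = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
            ring = st["lumen_center"][None, :] + st["radius"] * (
                np.cos(th)[:, None] * e1[None, :] + np.sin(th)[:, None] * e2[None, :]
            )
            pts.append(ring)
            branches.extend([b.name] * n_circ)
            arcs.extend([s] * n_circ)
            tangents.extend([t] * n_circ)
            radii.extend([st["radius"]] * n_circ)
    return (
        np.concatenate(pts, axis=0),
        np.array(branches),
        np.array(arcs, float),
        np.array(tangents, float),
        np.array(radii, float),
    )


def branch_flow_fractions(geometry: VesselGeometry) -> dict[str, float]:
    """Bifurcation flow split proportional to distal radius^4."""
    r_ica = float(geometry.branch("ICA").radius[-1])
    r_eca = float(geometry.branch("ECA").radius[-1])
    total = r_ica**4 + r_eca**4
    return {"CCA": 1.0, "ICA": r_ica**4 / total, "ECA": r_eca**4 / total}


def surrogate_wss_field(
    geometry: VesselGeometry,
    flow: Waveform,
    mu: float = BLOOD_VISCOSITY_PA_S,
    ds: float = 0.5,
    n_circ: int = 12,
) -> SurfaceWSSField:
    """Quasi-steady Poiseuille WSS field over one cycle.

    ``tau(s, t) = 4 mu Q_branch(t) / (pi r(s)^3)`` along the local tangent;
    flow in mL/s, radii in mm, output in Pa.
    """
    pts, branch, arcs, tangents, radii = sample_branch_surface(geometry, ds, n_circ)
    if np.any(radii <= 0):
        raise ValueError("zero lumen radius in the sampled surface (infinite WSS)")
    frac = branch_flow_fractions(geometry)
    q = flow.values * 1e-6  # mL/s -> m^3/s
    r_m = radii * 1e-3
    frac_per_point = np.array([frac[b] for b in branch])
    mag = (
        4.0 * mu * (frac_per_point[:, None] * q[None, :])
        / (np.pi * r_m[:, None] ** 3)
    )  # (P, Nt) Pa
    tau = mag[:, :, None] * np.asarray(tangents)[:, None, :]
    return SurfaceWSSField(
        pts, branch, arcs, flow.times.copy(), tau, flow.period, surrogate=True
    )


def _check_cycle(field: SurfaceWSSField) -> None:
    if field.times[0] > 1e-9 or field.times[-1] < field.period - 1e-9:
        raise ValueError("field does not cover the full cycle [0, T]")


def tawss(field: SurfaceWSSField) -> DescriptorMap:
    """Time-averaged WSS magnitude by trapezoidal quadrature."""
    _check_cycle(field)
    vals = np.trapezoid(field.magnitude, field.times, axis=1) / field.period
    return DescriptorMap(
        vals, field.branch, field.arclength, "TAWSS", "Pa", surrogate=field.surrogate
    )


def osi(field: SurfaceWSSField, tol: float = 1e-12) -> DescriptorMap:
    """Oscillatory shear index, masked where total shear exposure vanishes."""
    _check_cycle(field)
    num = np.linalg.norm(
        np.trapezoid(field.tau, field.times, axis=1), axis=1
    )
    den = np.trapezoid(field.magnitude, field.times, axis=1)
    valid = den > tol
    vals = np.zeros(den.shape)
    vals[valid] = 0.5 * (1.0 - num[valid] / den[valid])
    vals = np.clip(vals, 0.0, 0.5)
    if not valid.any():
        warnings.warn("all-zero WSS field: OSI undefined everywhere", stacklevel=2)
    return DescriptorMap(
        vals, field.branch, field.arclength, "OSI", "-",
        valid=valid, surrogate=field.surrogate,
    )


def peak_systole_map(field: SurfaceWSSField, flow: Waveform) -> DescriptorMap:
    """|tau| at the instant of peak flow (earliest sample on ties)."""
    t_star, _ = flow.peak()
    mags = field.magnitude
    if np.isclose(field.times, t_star).any():
        col = int(np.argmin(np.abs(field.times - t_star)))
        vals = mags[:, col]
    else:
        if t_star < field.times[0] or t_star > field.times[-1]:
            raise ValueError("peak time outside the field's time grid")
        vals = np.array(
            [np.interp(t_star, field.times, mags[i]) for i in range(mags.shape[0])]
        )
    return DescriptorMap(
        vals, field.branch, field.arclength, "peak_systole_WSS", "Pa",
        surrogate=field.surrogate,
    )


@dataclass
class ROIStats:
    mean: float
    sd: float
    n: int
    values: np.ndarray


def roi_stats(dmap: DescriptorMap, roi: ROISpec) -> ROIStats:
    """Unweighted mean / sample SD over points inside the ROI window."""
    sel = (
        (dmap.branch == roi.branch)
        & (dmap.arclength >= roi.start)
        & (dmap.arclength <= roi.start + roi.length)
        & dmap.valid
    )
    vals = dmap.values[sel]
    if vals.size == 0:
        raise ValueError(f"ROI {roi} contains no surface points")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(float(np.mean(vals)), sd, int(vals.size), vals)
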