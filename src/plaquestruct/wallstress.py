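"""Wall-stress surrogate (Laplace hoop stress) and cross-case comparisons.

True maximum-principal plaque stress requires a finite-element solve; here
a thin-wall Laplace surrogate ``sigma = p r / h`` stands in, clearly
flagged, to exercise the stress ROI statistics (a window of fixed length
centered on the peak-stress plane) and the comparison arithmetic between
cases. Surrogate magnitudes are NOT expected to reproduce patient-specific
finite-element values.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import VesselGeometry
from .waveforms import Waveform, mmhg_to_pa


@dataclass
class StressField:
    """Circumferential stress per cross-section over the pressure cycle."""

    branch: str
    arclength: np.ndarray    # (S,) mm from the apex
    times: np.ndarray        # (Nt,) s
    sigma: np.ndarray        # (S, Nt) kPa
    peak_systole: np.ndarray  # (S,) kPa at the pressure peak
    surrogate: bool = True

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("non-finite stress values")


def laplace_stress(
    geometry: VesselGeometry,
    pressure: Waveform,
    branch: str = "ICA",
    ds: float = 0.25,
    concentration: dict | None = None,
) -> StressField:
    """Thin-wall hoop stress field ``sigma(s, t) = p(t) r(s) / h(s)`` in kPa.

    Pressure is supplied in mmHg and converted internally; ``concentration``
    may scale stress per tissue for qualitative exploration (off by
    default). Zero wall thickness raises.
    """
    b = geometry.branch(branch)
    s_max = float(b.s_from_apex.max())
    stations = np.arange(0.0, s_max, ds)
    r = np.empty(stations.size)
    h = np.empty(stations.size)
    for i, s in enumerate(stations):
        st = b.interp(s)
        r[i], h[i] = st["radius"], st["wall"]
    if np.any(h <= 0):
        raise ValueError("zero wall thickness; Laplace stress undefined")
    p_pa = mmhg_to_pa(pressure.values)
    sigma = (p_pa[None, :] * r[:, None] / h[:, None]) / 1000.0  # kPa
    t_peak, _ = pressure.peak()
    col = int(np.argmin(np.abs(pressure.times - t_peak)))
    return StressField(branch, stations, pressure.times.copy(), sigma, sigma[:, col])


@dataclass
class StressROIStats:
    mean: float
    sd: float
    max: float
    central_arclength: float
    truncated: bool
    n: int
    values: np.ndarray


def stress_roi_stats(field: StressField, length: float = 13.0) -> StressROIStats:
    """Statistics over a window centered on the peak-systole stress plane.

    The cross-section with the maximal peak-systole stress (ties: smallest
    arc-length) becomes the central plane; a window of ``length`` mm around
    it is truncated (with a warning) where the vessel is shorter.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    s = field.arclength
    center_i = int(np.argmax(field.peak_systole))
    center = float(s[center_i])
    half = length / 2.0
    lo, hi = center - half, center + half
    truncated = lo < s.min() - 1e-9 or hi > s.max() + 1e-9
    if truncated:
        warnings.warn(
            "stress ROI window truncated at the vessel extent", stacklevel=2
        )
    sel = (s >= lo) & (s <= hi)
    vals = field.peak_systole[sel]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return StressROIStats(
        float(np.mean(vals)), sd, float(np.max(vals)), center, truncated,
        int(vals.size), vals,
    )


# --------------------------------------------------------------------------
# cross-case comparison arithmetic


def truncate(x: float, decimals: int) -> float:
    """Truncation (not rounding) to a number of decimals, as printed
    summary figures in clinical reports often are."""
    factor = 10.0**decimals
    return math.floor(x * factor + 1e-9) / factor


def fold_ratio(a: float, b: float) -> float:
    """a / b; NaN when the denominator is zero."""
    return float("nan") if b == 0 else a / b


def percent_difference(a: float, b: float) -> float:
    """100 * (hi - lo) / lo — relative to the smaller value."""
    lo, hi = min(a, b), max(a, b)
    return float("nan") if lo == 0 else 100.0 * (hi - lo) / lo


#: report keys compared pairwise: metric -> comparison type
COMPARISON_METRICS = {
    "calcification_volume_mm3": "fold",
    "lipid_volume_mm3": "fold",
    "tawss_roi_mean_pa": "fold",
    "stress_p1_max_kpa": "percent",
}


def compare_patients(
    reports: list[dict], case_ids: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise comparison table across case summary reports.

    Volumes and mean TAWSS are compared as fold ratios (larger over
    smaller); maximum stress as a percent difference relative to the
    smaller value. Raw values are reported alongside 1- and 2-decimal
    truncations (printed-precision renderings). Zero denominators yield
    NaN rather than an error.
    """
    if len(reports) < 2:
        raise ValueError("need at least two case reports to compare")
    ids = case_ids or [f"case{i + 1}" for i in range(len(reports))]
    rows = []
    for metric, kind in COMPARISON_METRICS.items():
        if not all(metric in r for r in reports):
            continue
        for i in range(len(reports)):
            for j in range(i + 1, len(reports)):
                a, b = float(reports[i][metric]), float(reports[j][metric])
                hi_id, lo_id = (ids[i], ids[j]) if a >= b else (ids[j], ids[i])
                value = fold_ratio(max(a, b), min(a, b)) if kind == "fold" else percent_difference(a, b)
                rows.append(
                    {
                        "metric": metric,
                        "kind": kind,
                        "case_hi": hi_id,
                        "case_lo": lo_id,
                        "value": value,
                        "trunc_1dp": truncate(value, 1) if np.isfinite(value) else value,
                        "trunc_2dp": truncate(value, 2) if np.isfinite(value) else value,
                    }
                )
    return pd.DataFrame(rows)
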