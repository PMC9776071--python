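"""Physiological waveforms: pulsatile inlet flow and scaled pressure.

A :class:`Waveform` holds one cardiac cycle sampled on ``[0, T]`` inclusive,
so the last sample duplicates the phase of the first (periodic closure) and
trapezoidal quadrature over the samples integrates exactly one cycle.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Waveform:
    """One-cycle time series; flow in mL/s or pressure in mmHg."""

    times: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 2 or self.times.size != self.values.size:
            raise ValueError("need >= 2 (time, value) samples of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.times[0]) > 1e-12 or abs(self.times[-1] - self.period) > 1e-9:
            raise ValueError("times must start at 0 and end at the period T")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def cycle_mean(self) -> float:
        """Trapezoidal mean over the cycle, (1/T) * integral."""
        return float(np.trapezoid(self.values, self.times) / self.period)

    def peak(self) -> tuple[float, float]:
        """(time, value) of the maximum; earliest sample wins ties."""
        i = int(np.argmax(self.values))
        return float(self.times[i]), float(self.values[i])

    def to_csv(self, path: str | Path, value_name: str = "value") -> None:
        pd.DataFrame({"time_s": self.times, value_name: self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Waveform":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        return cls(t, df.iloc[:, 1].to_numpy(float), period=float(t[-1]))


def _pulse_template(t: np.ndarray, period: float) -> np.ndarray:
    """Systolic peak plus dicrotic bump, both Gaussian, on a zero baseline."""
    tn = t / period
    main = np.exp(-0.5 * ((tn - 0.16) / 0.055) ** 2)
    dicrotic = 0.28 * np.exp(-0.5 * ((tn - 0.45) / 0.085) ** 2)
    return main + dicrotic


def make_flow_waveform(
    period: float,
    q_mean: float,
    q_peak: float,
    n_frames: int = 40,
    seed: int | None = None,
    jitter_sd: float = 0.0,
) -> Waveform:
    """Pulsatile one-cycle flow waveform with exact discrete mean and peak.

    ``n_frames`` equidistant frames span the cycle (sample times ``k*T/n``,
    k = 0..n, so the array carries ``n_frames + 1`` samples with the last
    closing the period). The template is mapped affinely so the trapezoidal
    cycle mean equals ``q_mean`` and the sampled maximum equals ``q_peak``.
    ``jitter_sd`` (fraction of T) optionally perturbs the bump timings,
    reproducibly under ``seed``.
    """
    if not (q_peak > q_mean > 0):
        raise ValueError("require q_peak > q_mean > 0")
    if n_frames < 8:
        raise ValueError("need at least 8 frames per cycle")
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.linspace(0.0, period, n_frames + 1)
    g = _pulse_template(t, period)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        shift = rng.normal(0.0, jitter_sd) * period
        g = _pulse_template(np.clip(t - shift, 0, period), period)
    g_mean = np.trapezoid(g, t) / period
    g_max = g.max()
    a = (q_peak - q_mean) / (g_max - g_mean)
    b = q_mean - a * g_mean
    q = a * g + b
    if q.min() <= 0:
        raise ValueError(
            "waveform dips non-positive; raise q_mean or lower q_peak"
        )
    return Waveform(t, q, period)


def scale_pressure_waveform(flow: Waveform, p_dia: float, p_sys: float) -> Waveform:
    """Affine map of a flow waveform onto [p_dia, p_sys] mmHg (same grid)."""
    if not (p_sys > p_dia > 0):
        raise ValueError("require p_sys > p_dia > 0")
    lo, hi = float(flow.values.min()), float(flow.values.max())
    if hi - lo <= 0:
        raise ValueError("flow waveform has zero range; pressure scaling undefined")
    p = p_dia + (flow.values - lo) * (p_sys - p_dia) / (hi - lo)
    return Waveform(flow.times.copy(), p, flow.period)


MMHG_TO_PA = 133.322

def mmhg_to_pa(p):
    return np.asarray(p, dtype=float) * MMHG_TO_PA
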