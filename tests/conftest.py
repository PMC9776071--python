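"""Shared fixtures: synthetic slices and the three-case phantom study.

The three-case pipeline fixture is session-scoped — it drives the full
segmentation-to-report pipeline at 0.25 mm for stenoses of 81/83/82% and is
reused by the report-level and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


PX = 0.25  # mm, synthetic slice pixel size


def disk_image(
    r_mm: float,
    shape=(80, 80),
    bg: float = 0.05,
    fg: float = 0.95,
    shade: float = 0.4,
    noise: float = 0.0,
    seed: int = 0,
):
    """Flow-shaded bright disk on a dark background (TOF-like slice)."""
    c = (np.array(shape) - 1) / 2 * PX
    yy, xx = np.meshgrid(
        np.arange(shape[0]) * PX, np.arange(shape[1]) * PX, indexing="ij"
    )
    d = np.hypot(xx - c[1], yy - c[0])
    img = np.full(shape, bg)
    inside = d < r_mm
    img[inside] = fg * (1 - shade * (d[inside] / r_mm))
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, shape)
    return img, c


def annulus_image(
    r_in: float = 2.0,
    r_out: float = 3.0,
    shape=(96, 96),
    bg: float = 0.05,
    wall: float = 0.55,
    lumen: float = 0.8,
    noise: float = 0.05,
    seed: int = 0,
):
    """Bright-wall annulus around a lumen (T1W-like slice)."""
    c = (np.array(shape) - 1) / 2 * PX
    yy, xx = np.meshgrid(
        np.arange(shape[0]) * PX, np.arange(shape[1]) * PX, indexing="ij"
    )
    d = np.hypot(xx - c[1], yy - c[0])
    img = np.full(shape, bg)
    img[d < r_out] = wall
    img[d < r_in] = lumen
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, shape)
    return img, c


def circle_vertices(center, r, n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)], axis=1)


@pytest.fixture(scope="session")
def default_phantom():
    """Default 81%-stenosis phantom at 0.25 mm (geometry + labels + stack)."""
    from plaquestruct.phantom import PhantomConfig, make_phantom_case

    cfg = PhantomConfig(stenosis_fraction=0.81, spacing_mm=0.25)
    geom, plaque, labels, counts, stack = make_phantom_case(cfg, seed=1)
    return {
        "config": cfg,
        "geometry": geom,
        "plaque": plaque,
        "labels": labels,
        "counts": counts,
        "stack": stack,
    }


STUDY_STENOSES = (0.81, 0.83, 0.82)  # the three-case study conditions


@pytest.fixture(scope="session")
def three_case_reports():
    """Full-pipeline reports for the three phantom cases at 0.25 mm."""
    from plaquestruct.phantom import PhantomConfig
    from plaquestruct.report import CaseConfig, run_pipeline

    reports = []
    for i, f in enumerate(STUDY_STENOSES):
        cfg = CaseConfig(
            case_id=f"case{i + 1}",
            phantom=PhantomConfig(stenosis_fraction=f, spacing_mm=0.25),
            run_meshing=False,
            seed=i + 1,
        )
        reports.append(run_pipeline(cfg))
    return reports
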