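"""WSS surrogate and cycle descriptors: TAWSS, OSI, peak-systole maps."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from plaquestruct.hemodynamics import (
    DescriptorMap,
    ROISpec,
    SurfaceWSSField,
    osi,
    peak_systole_map,
    roi_stats,
    surrogate_wss_field,
    tawss,
)
from plaquestruct.phantom import PhantomConfig, make_bifurcation_geometry
from plaquestruct.waveforms import Waveform, make_flow_waveform


def vector_field(times, tau_of_t, period=1.0, n_points=1):
    """Single-point (or repeated) field from a tau(t) -> (3,) function."""
    tau = np.stack([np.stack([tau_of_t(t) for t in times])] * n_points)
    return SurfaceWSSField(
        np.zeros((n_points, 3)),
        np.array(["ICA"] * n_points),
        np.linspace(0, 10, n_points),
        np.asarray(times, float),
        tau,
        period,
    )


def constant_flow(q=5.0, n=40, T=1.0):
    t = np.linspace(0, T, n + 1)
    v = np.full(n + 1, q)
    v[1] += 1e-12  # strictly a waveform; effectively steady
    return Waveform(t, v, T)


class TestSurrogate:
    def test_poiseuille_hand_value(self):
        # mu=0.00345 Pa*s, Q=5 mL/s, r=2.5 mm -> tau ~ 1.406 Pa on the CCA
        geom = make_bifurcation_geometry(
            PhantomConfig(cca_radius=2.5, stenosis_fraction=0.0)
        )
        field = surrogate_wss_field(geom, constant_flow(5.0))
        cca = field.branch == "CCA"
        assert field.magnitude[cca].mean() == pytest.approx(1.4057, rel=1e-3)

    def test_halving_radius_multiplies_tau_by_eight(self):
        tau = {}
        for r in (2.0, 1.0):
            geom = make_bifurcation_geometry(
                PhantomConfig(cca_radius=r, stenosis_fraction=0.0)
            )
            f = surrogate_wss_field(geom, constant_flow(5.0))
            tau[r] = f.magnitude[f.branch == "CCA"].mean()
        assert tau[1.0] / tau[2.0] == pytest.approx(8.0, rel=1e-6)

    def test_stenotic_throat_carries_maximum_everywhere_in_time(self):
        geom = make_bifurcation_geometry(PhantomConfig(stenosis_fraction=0.81))
        flow = make_flow_waveform(1.0, 6.0, 18.0)
        field = surrogate_wss_field(geom, flow)
        ica = field.branch == "ICA"
        throat = np.argmin(
            np.abs(field.arclength[ica] - 7.0)
        )
        mags = field.magnitude[ica]
        assert np.all(mags[throat] >= mags.max(axis=0) - 1e-9)

    def test_flow_split_follows_r4(self):
        geom = make_bifurcation_geometry(PhantomConfig(stenosis_fraction=0.0))
        from plaquestruct.hemodynamics import branch_flow_fractions

        frac = branch_flow_fractions(geom)
        r_i, r_e = 2.5, 2.0
        assert frac["ICA"] == pytest.approx(r_i**4 / (r_i**4 + r_e**4))
        assert frac["ICA"] + frac["ECA"] == pytest.approx(1.0)


class TestTawss:
    def test_constant_magnitude_is_identity(self):
        t = np.linspace(0, 1, 41)
        f = vector_field(t, lambda _: np.array([3.0, 0, 0]))
        assert tawss(f).values[0] == pytest.approx(3.0)

    def test_rectified_sine_closed_form(self):
        # |A sin(2 pi t / T)| has cycle mean 2A/pi; A = pi gives 2.0
        t = np.linspace(0, 1, 41)
        f = vector_field(t, lambda tt: np.array([np.pi * np.sin(2 * np.pi * tt), 0, 0]))
        assert tawss(f).values[0] == pytest.approx(2.0, rel=0.005)

    def test_quadrature_converges_with_sampling(self):
        vals = []
        for n in (40, 80):
            t = np.linspace(0, 1, n + 1)
            f = vector_field(
                t, lambda tt: np.array([2 + np.sin(2 * np.pi * tt), 0, 0])
            )
            vals.append(tawss(f).values[0])
        assert abs(vals[1] - vals[0]) / vals[1] < 0.001

    def test_non_monotone_times_rejected(self):
        t = np.array([0, 0.5, 0.4, 1.0])
        with pytest.raises(ValueError):
            vector_field(t, lambda _: np.array([1.0, 0, 0]))

    def test_homogeneity_and_osi_invariance_under_scaling(self):
        t = np.linspace(0, 1, 41)
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=3)

        def tau(tt):
            return np.array(
                [np.sin(2 * np.pi * tt) + 0.5, np.cos(2 * np.pi * tt), 0.2]
            ) * coeffs

        f1 = vector_field(t, tau)
        f3 = vector_field(t, lambda tt: 3.0 * tau(tt))
        assert tawss(f3).values[0] == pytest.approx(3 * tawss(f1).values[0])
        assert osi(f3).values[0] == pytest.approx(osi(f1).values[0], abs=1e-12)


class TestOsi:
    def test_unidirectional_shear_is_zero(self):
        t = np.linspace(0, 1, 41)
        f = vector_field(t, lambda tt: np.array([1.5 + np.sin(2 * np.pi * tt), 0, 0]))
        assert osi(f).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_mean_oscillation_is_half(self):
        t = np.linspace(0, 1, 41)
        f = vector_field(t, lambda tt: np.array([np.sin(2 * np.pi * tt), 0, 0]))
        assert osi(f).values[0] == pytest.approx(0.5, abs=1e-9)

    def test_monotone_decrease_with_steady_component(self):
        t = np.linspace(0, 1, 41)
        values = []
        for s in (0.0, 0.3, 0.8, 1.5, 3.0):
            f = vector_field(
                t, lambda tt, s=s: np.array([s + np.sin(2 * np.pi * tt), 0, 0])
            )
            values.append(osi(f).values[0])
        assert np.all(np.diff(values) < 1e-12)

    def test_all_zero_field_masked_with_warning(self):
        t = np.linspace(0, 1, 41)
        f = vector_field(t, lambda _: np.zeros(3))
        with pytest.warns(UserWarning, match="OSI undefined"):
            m = osi(f)
        assert not m.valid.any()

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.0, max_value=5.0),
    )
    def test_osi_always_in_unit_half_interval(self, seed, steady):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 33)
        base = rng.normal(size=(1, 33, 3))
        base[:, :, 0] += steady
        base[:, -1] = base[:, 0]
        f = SurfaceWSSField(
            np.zeros((1, 3)), np.array(["ICA"]), np.zeros(1), t, base, 1.0
        )
        m = osi(f)
        if m.valid[0]:
            assert 0.0 <= m.values[0] <= 0.5


class TestPeakAndRoi:
    def test_peak_time_is_constructed_peak(self):
        geom = make_bifurcation_geometry(PhantomConfig())
        flow = make_flow_waveform(1.0, 6.0, 18.0)
        field = surrogate_wss_field(geom, flow)
        pk = peak_systole_map(field, flow)
        t_star, _ = flow.peak()
        col = int(np.argmin(np.abs(field.times - t_star)))
        assert np.allclose(pk.values, field.magnitude[:, col])

    def test_peak_map_dominates_cycle_mean(self):
        geom = make_bifurcation_geometry(PhantomConfig())
        flow = make_flow_waveform(1.0, 6.0, 18.0)
        field = surrogate_wss_field(geom, flow)
        assert np.all(
            peak_systole_map(field, flow).values >= tawss(field).values - 1e-9
        )

    def test_flow_tie_takes_earliest_instant(self):
        t = np.linspace(0, 1, 11)
        v = np.ones(11)
        v[3] = v[7] = 2.0
        flow = Waveform(t, v, 1.0)
        assert flow.peak()[0] == pytest.approx(t[3])

    def test_roi_stats_two_point_example(self):
        m = DescriptorMap(
            np.array([1.0, 3.0]), np.array(["ICA", "ICA"]),
            np.array([1.0, 2.0]), "TAWSS", "Pa",
        )
        s = roi_stats(m, ROISpec("ICA", 0.0, 5.0))
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(np.sqrt(2.0))
        assert s.n == 2

    def test_constant_map_has_zero_sd(self):
        m = DescriptorMap(
            np.full(10, 4.2), np.array(["ICA"] * 10),
            np.linspace(0, 9, 10), "TAWSS", "Pa",
        )
        s = roi_stats(m, ROISpec("ICA", 0.0, 17.0))
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.mean == pytest.approx(4.2)

    def test_empty_roi_raises(self):
        m = DescriptorMap(
            np.ones(5), np.array(["ICA"] * 5), np.linspace(0, 4, 5), "TAWSS", "Pa"
        )
        with pytest.raises(ValueError, match="no surface points"):
            roi_stats(m, ROISpec("ECA", 0.0, 17.0))
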