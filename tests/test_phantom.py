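"""Phantom generator: geometry, rasterization, rendering, waveforms."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from plaquestruct.grids import CHANNELS, Tissue
from plaquestruct.phantom import (
    DEFAULT_SIGNATURES,
    Ellipsoid,
    PhantomConfig,
    PlaqueSpec,
    classify_by_signature,
    default_plaque,
    make_bifurcation_geometry,
    rasterize_labels,
    render_contrasts,
)
from plaquestruct.waveforms import (
    Waveform,
    make_flow_waveform,
    scale_pressure_waveform,
)


class TestGeometry:
    def test_zero_stenosis_keeps_ica_radius_constant(self):
        geom = make_bifurcation_geometry(PhantomConfig(stenosis_fraction=0.0))
        r = geom.branch("ICA").radius
        assert np.allclose(r, r[0])

    def test_throat_radius_follows_stenosis_fraction(self):
        geom = make_bifurcation_geometry(
            PhantomConfig(stenosis_fraction=0.81, ica_radius=2.5)
        )
        assert geom.branch("ICA").radius.min() == pytest.approx(0.475, abs=1e-9)

    def test_apex_lies_on_all_three_axes(self):
        cfg = PhantomConfig()
        geom = make_bifurcation_geometry(cfg)
        for b in geom.branches.values():
            d = np.linalg.norm(b.points - geom.apex, axis=1).min()
            assert d <= cfg.spacing_mm

    @pytest.mark.parametrize(
        "kwargs",
        [dict(stenosis_fraction=1.0), dict(stenosis_fraction=1.3),
         dict(ica_angle_deg=0.0), dict(ica_angle_deg=-5.0),
         dict(cca_radius=-1.0)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_bifurcation_geometry(PhantomConfig(**kwargs))


class TestRasterize:
    def test_empty_plaque_has_no_inclusion_voxels(self):
        geom = make_bifurcation_geometry(PhantomConfig())
        labels, counts = rasterize_labels(geom, PlaqueSpec(), spacing=0.5)
        assert counts[Tissue.LIPID] == 0
        assert counts[Tissue.CALCIFICATION] == 0

    def test_inclusion_volumes_match_analytic(self, default_phantom):
        counts = default_phantom["counts"]
        plaque = default_phantom["plaque"]
        vv = default_phantom["labels"].voxel_volume
        for tissue, regions in (
            (Tissue.LIPID, plaque.lipid_regions),
            (Tissue.CALCIFICATION, plaque.calcification_regions),
        ):
            analytic = sum(e.volume for e in regions)
            assert counts[tissue] * vv == pytest.approx(analytic, rel=0.05)

    def test_volume_error_shrinks_with_spacing(self):
        cfg = PhantomConfig()
        geom = make_bifurcation_geometry(cfg)
        plaque = default_plaque(geom, cfg)
        analytic = plaque.lipid_regions[0].volume
        errs = []
        for sp in (0.5, 0.25):
            labels, counts = rasterize_labels(geom, plaque, spacing=sp)
            errs.append(abs(counts[Tissue.LIPID] * labels.voxel_volume - analytic))
        assert errs[1] < errs[0]

    def test_escaping_inclusion_raises_with_region_name(self):
        cfg = PhantomConfig()
        geom = make_bifurcation_geometry(cfg)
        st_ = geom.branch("ICA").interp(18.0)
        rogue = Ellipsoid(
            st_["lumen_center"], np.eye(3), np.array([1.5, 1.5, 1.5]),
            name="rogue",
        )
        with pytest.raises(ValueError, match="rogue"):
            rasterize_labels(geom, PlaqueSpec(lipid_regions=[rogue]), spacing=0.5)

    def test_placed_inclusions_stay_between_lumen_and_outer_wall(
        self, default_phantom
    ):
        # rasterization itself enforces this; reaching here means no escape
        labels = default_phantom["labels"]
        assert labels.mask(Tissue.LIPID).any()
        assert labels.mask(Tissue.CALCIFICATION).any()


class TestRender:
    @pytest.fixture(scope="class")
    def small_labels(self):
        geom = make_bifurcation_geometry(PhantomConfig())
        labels, _ = rasterize_labels(
            geom, default_plaque(geom, PhantomConfig()), spacing=0.5
        )
        return labels

    def test_noise_free_channels_are_piecewise_constant(self, small_labels):
        stack = render_contrasts(small_labels, noise_sd=0.0)
        for ch in CHANNELS:
            means = {DEFAULT_SIGNATURES[Tissue(t)][ch] for t in np.unique(small_labels.labels)}
            assert set(np.unique(stack.channels[ch])) <= means

    def test_fixed_seed_is_bit_identical(self, small_labels):
        a = render_contrasts(small_labels, noise_sd=0.05, seed=42)
        b = render_contrasts(small_labels, noise_sd=0.05, seed=42)
        for ch in CHANNELS:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_class_sample_means_within_three_se(self, small_labels):
        sd = 0.05
        stack = render_contrasts(small_labels, noise_sd=sd, seed=7)
        for t in (Tissue.WALL, Tissue.LUMEN, Tissue.BACKGROUND):
            mask = small_labels.labels == int(t)
            n = mask.sum()
            assert n >= 1000
            for ch in ("T1W", "T2W", "PDW"):  # TOF lumen may be flow-shaded
                got = stack.channels[ch][mask].mean()
                want = DEFAULT_SIGNATURES[t][ch]
                assert abs(got - want) <= 3 * sd / np.sqrt(n)

    def test_missing_signature_raises(self, small_labels):
        partial = {Tissue.BACKGROUND: DEFAULT_SIGNATURES[Tissue.BACKGROUND]}
        with pytest.raises(ValueError, match="signature"):
            render_contrasts(small_labels, signatures=partial)

    def test_noise_free_rendering_inverts_exactly(self, small_labels):
        stack = render_contrasts(small_labels, noise_sd=0.0)
        recovered = classify_by_signature(stack)
        assert np.array_equal(recovered, small_labels.labels)


class TestWaveforms:
    def test_forty_frames_are_equidistant(self):
        w = make_flow_waveform(1.0, 6.0, 18.0, n_frames=40)
        assert w.n_samples == 41
        assert np.allclose(np.diff(w.times), 1.0 / 40)

    def test_mean_and_peak_match_within_one_percent(self):
        w = make_flow_waveform(0.8, 5.0, 20.0)
        assert w.cycle_mean() == pytest.approx(5.0, rel=0.01)
        assert w.values.max() == pytest.approx(20.0, rel=0.01)

    def test_single_systolic_peak(self):
        w = make_flow_waveform(1.0, 6.0, 18.0)
        peaks = np.flatnonzero(
            (w.values[1:-1] > w.values[:-2]) & (w.values[1:-1] > w.values[2:])
        )
        prominent = [
            p for p in peaks
            if w.values[p + 1] > w.values.min() + 0.5 * np.ptp(w.values)
        ]
        assert len(prominent) == 1

    def test_nearly_flat_limit_still_meets_mean(self):
        w = make_flow_waveform(1.0, 6.0, 6.0 + 1e-6)
        assert w.cycle_mean() == pytest.approx(6.0, rel=0.01)
        assert np.ptp(w.values) < 1e-5

    def test_peak_not_above_mean_rejected(self):
        with pytest.raises(ValueError):
            make_flow_waveform(1.0, 6.0, 6.0)

    def test_pressure_scaling_maps_endpoints_and_midpoint(self):
        t = np.linspace(0, 1, 9)
        flow = Waveform(t, np.array([2, 4, 6, 8, 10, 8, 6, 4, 2.0]), 1.0)
        p = scale_pressure_waveform(flow, 80, 120)
        assert p.values.min() == pytest.approx(80.0)
        assert p.values.max() == pytest.approx(120.0)
        assert p.values[2] == pytest.approx(100.0)  # flow 6 -> mid-range

    def test_constant_flow_cannot_be_scaled(self):
        t = np.linspace(0, 1, 9)
        with pytest.raises(ValueError, match="zero range"):
            scale_pressure_waveform(Waveform(t, np.full(9, 5.0), 1.0), 80, 120)

    @given(
        vals=st.lists(
            st.floats(min_value=0.1, max_value=50, allow_nan=False),
            min_size=3, max_size=30,
        ).filter(lambda v: max(v) > min(v))
    )
    def test_affine_scaling_preserves_order_and_grid(self, vals):
        t = np.linspace(0, 1, len(vals))
        flow = Waveform(t, np.array(vals), 1.0)
        p = scale_pressure_waveform(flow, 70, 110)
        assert p.n_samples == flow.n_samples
        assert np.array_equal(p.times, flow.times)
        assert np.array_equal(np.argsort(p.values, kind="stable"),
                              np.argsort(flow.values, kind="stable"))
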