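"""Synthetic aneurysm generator, pseudo-CFD oracle, and TAWSS arithmetic."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from multiview_wss.mesh import mean_curvature
from multiview_wss.synthetic import (
    AortaParams,
    FlowWaveform,
    WSSSeries,
    build_dataset,
    default_waveform,
    generate_aorta,
    pseudo_cfd_wss,
    tawss,
)
from multiview_wss.synthetic import ParameterError


SMALL = dict(axial_resolution=48, circumferential_resolution=20)


class TestGenerateAorta:
    def test_deterministic_given_seed(self):
        p = AortaParams(seed=11, **SMALL)
        a, b = generate_aorta(p), generate_aorta(p)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.faces, b.faces)

    def test_no_bulge_max_diameter_equals_base(self):
        p = AortaParams(bulge_factor=0.0, radius_noise=0.0,
                        centerline_curvature=0.0, **SMALL)
        m = generate_aorta(p)
        r = m.metadata["local_radius"]
        step = p.base_radius * 2 / p.axial_resolution
        assert abs(2 * r.max() - 2 * p.base_radius) <= step

    def test_default_dilatation_exceeds_aneurysm_threshold(self):
        # diagnostic definition: dilatation surpassing 50% of normal diameter
        p = AortaParams(**SMALL)
        m = generate_aorta(p)
        r = m.metadata["local_radius"]
        assert r.max() / p.base_radius >= 1.5

    def test_watertight_and_outward(self):
        m = generate_aorta(AortaParams(seed=5, **SMALL))
        tm = m.to_trimesh()
        assert tm.is_watertight
        assert tm.volume > 0

    def test_self_intersecting_params_rejected(self):
        with pytest.raises(ParameterError):
            AortaParams(bulge_width=200.0, centerline_length=100.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            AortaParams(base_radius=-1.0)
        with pytest.raises(ParameterError):
            AortaParams(bulge_center=1.5)


class TestPseudoCfd:
    def test_constant_radius_tube_uniform_tawss(self):
        p = AortaParams(bulge_factor=0.0, radius_noise=0.0, **SMALL)
        m = generate_aorta(p)
        f = tawss(pseudo_cfd_wss(m, p, noise_sd=0.0), 3)
        cv = f.values.std() / f.values.mean()
        assert cv < 1e-6

    def test_sac_to_tube_ratio_follows_cubed_law(self):
        # sac radius 2x base -> stress ratio (1/2)^3 at the apex
        p = AortaParams(bulge_factor=1.0, radius_noise=0.0,
                        centerline_curvature=0.0, bulge_center=0.5, **SMALL)
        m = generate_aorta(p)
        f = tawss(pseudo_cfd_wss(m, p, noise_sd=0.0), 3)
        s = m.metadata["arclength_frac"]
        apex = f.values[np.abs(s - 0.5) < 0.02].mean()
        tube = f.values[(s < 0.05)].mean()
        assert abs(apex / tube - 1 / 8) < 0.02 / 8 + 0.01

    def test_curvature_anticorrelated_with_stress_in_sac(self, aorta_mesh,
                                                         aorta_params):
        H = np.abs(aorta_mesh.fields["curvature"].values)
        f = aorta_mesh.fields["tawss"].values
        s = aorta_mesh.metadata["arclength_frac"]
        p = aorta_params
        sac = np.abs(s - p.bulge_center) < p.bulge_width / p.centerline_length / 2
        rho = spearmanr(H[sac], f[sac]).statistic
        assert rho < 0

    def test_waveform_scaling_scales_tawss_linearly(self):
        p = AortaParams(seed=2, **SMALL)
        m = generate_aorta(p)
        w = default_waveform()
        f1 = tawss(pseudo_cfd_wss(m, p, w, noise_sd=0.0), 3).values
        f2 = tawss(pseudo_cfd_wss(m, p, w.scaled(2.5), noise_sd=0.0), 3).values
        np.testing.assert_allclose(f2, 2.5 * f1, rtol=1e-6)

    def test_noise_sd_doubling_doubles_tawss_scatter(self):
        p = AortaParams(seed=2, **SMALL)
        m = generate_aorta(p)
        clean = tawss(pseudo_cfd_wss(m, p, noise_sd=0.0), 3).values
        sds = []
        for sd in (0.05, 0.10):
            devs = []
            for k in range(5):
                noisy = tawss(pseudo_cfd_wss(m, p, noise_sd=sd, seed=100 + k), 3)
                devs.append(noisy.values - clean)
            sds.append(np.concatenate(devs).std())
        assert abs(sds[1] / sds[0] - 2.0) < 0.25

    def test_strictly_positive_without_noise(self, aorta_mesh):
        assert aorta_mesh.fields["tawss"].values.min() > 0

    def test_rigid_transform_leaves_tawss_attached(self, aorta_mesh):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = aorta_mesh.transformed(rotation=Q, translation=[1, 2, 3])
        np.testing.assert_array_equal(moved.fields["tawss"].values,
                                      aorta_mesh.fields["tawss"].values)


class TestTawss:
    def test_constant_vector_series(self):
        vals = np.zeros((30, 5, 3))
        vals[..., 0] = 2.0
        f = tawss(WSSSeries(vals, dt=0.1, cycle_period=1.0), 2)
        np.testing.assert_allclose(f.values, 2.0)

    def test_three_second_series_bookkeeping(self):
        p = AortaParams(**SMALL)
        m = generate_aorta(p)
        s = pseudo_cfd_wss(m, p, dt=0.01, n_cycles=3)
        assert s.n_steps == 300
        f = tawss(s, cycle_index=3)
        assert f.meta["steps_averaged"] == 100

    def test_matches_bruteforce_norm_average(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 7, 3))
        series = WSSSeries(vals, dt=0.05, cycle_period=0.5)
        f = tawss(series, 2)
        # independent loop: mean of per-step Euclidean norms, second cycle
        expected = np.zeros(7)
        for v in range(7):
            acc = 0.0
            for step in range(10, 20):
                acc += np.sqrt(sum(vals[step, v, c] ** 2 for c in range(3)))
            expected[v] = acc / 10
        np.testing.assert_allclose(f.values, expected, atol=1e-12)

    def test_identical_cycles_give_identical_tawss(self):
        rng = np.random.default_rng(1)
        cycle = rng.normal(size=(10, 4, 3))
        series = WSSSeries(np.tile(cycle, (3, 1, 1)), dt=0.1, cycle_period=1.0)
        ref = tawss(series, 1).values
        for k in (2, 3):
            np.testing.assert_allclose(tawss(series, k).values, ref, atol=1e-12)

    def test_cycle_out_of_range_rejected(self):
        series = WSSSeries(np.ones((20, 3, 3)), dt=0.1, cycle_period=1.0)
        with pytest.raises(IndexError):
            tawss(series, 3)

    def test_incomplete_cycle_series_rejected(self):
        with pytest.raises(ValueError):
            WSSSeries(np.ones((15, 3, 3)), dt=0.1, cycle_period=1.0)


class TestWaveform:
    def test_template_is_periodic_with_peak_at_30pct(self):
        w = default_waveform()
        assert w.velocities[0] == w.velocities[-1]
        tau_peak = w.times[np.argmax(w.velocities)] / w.period
        assert abs(tau_peak - 0.30) < 0.02

    def test_nonperiodic_rejected(self):
        with pytest.raises(ValueError):
            FlowWaveform(np.linspace(0, 1, 20), np.linspace(0, 1, 20))


class TestBuildDataset:
    def test_cohort_of_23_bases_with_10_variants_totals_253(self):
        man = build_dataset(23, 10, seed=0)
        assert len(man) == 253
        assert len({r["family"] for r in man}) == 23

    def test_zero_variants(self):
        assert len(build_dataset(5, 0, seed=0)) == 5

    def test_deterministic(self):
        assert build_dataset(4, 2, seed=9) == build_dataset(4, 2, seed=9)

    def test_variant_params_stay_in_ranges(self):
        from multiview_wss.synthetic import DEFAULT_PARAM_RANGES

        man = build_dataset(6, 4, seed=3)
        for rec in man:
            for key, (lo, hi) in DEFAULT_PARAM_RANGES.items():
                assert lo - 1e-12 <= rec["params"][key] <= hi + 1e-12

    def test_manifest_jsonl_round_trip(self, tmp_path):
        from multiview_wss.synthetic import load_manifest, save_manifest

        man = build_dataset(3, 2, seed=1)
        save_manifest(man, tmp_path / "m.jsonl")
        assert load_manifest(tmp_path / "m.jsonl") == man

    def test_realize_geometry_writes_vtk_with_fields(self, tmp_path):
        from multiview_wss.mesh import load_mesh
        from multiview_wss.synthetic import realize_geometry

        rec = build_dataset(1, 0, seed=2)[0]
        rec["params"].update(axial_resolution=32, circumferential_resolution=12)
        mesh = realize_geometry(rec, out_dir=tmp_path)
        back = load_mesh(rec["paths"]["mesh"])
        assert back.n_vertices == mesh.n_vertices
        np.testing.assert_allclose(back.fields["tawss"].values,
                                   mesh.fields["tawss"].values, rtol=1e-14)
        assert "curvature" in back.fields


class TestWssSeriesIO:
    def test_hdf5_round_trip(self, tmp_path):
        from multiview_wss.synthetic import read_wss_series, write_wss_series

        rng = np.random.default_rng(0)
        series = WSSSeries(rng.normal(size=(20, 6, 3)).astype(np.float32),
                           dt=0.05, cycle_period=0.5)
        write_wss_series(series, tmp_path / "s.h5")
        back = read_wss_series(tmp_path / "s.h5")
        np.testing.assert_array_equal(back.values, series.values)
        assert back.dt == series.dt
        assert back.cycle_period == series.cycle_period
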