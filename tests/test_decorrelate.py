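"""Reference extraction, PCC maps, the Gram solve, and noise-power logic."""

import numpy as np
import pytest

from qpifluct.core_io import RegionMask
from qpifluct.decorrelate import (
    ReferenceSet,
    apply_decorrelation,
    decorrelate_movie,
    estimate_noise_power,
    extract_references,
    fit_decorrelation,
    intracellular_power_map,
    pcc_map,
    spatial_averaging_variance,
)
from qpifluct.simulate import FluctuationModel, SimulationConfig, synthesize_movie

from conftest import make_movie


def _bg_mask_16():
    img = np.zeros((16, 16), np.int32)
    img[1:5, 1:5] = 2
    img[1:5, 11:15] = 3
    img[11:15, 1:5] = 4
    return RegionMask(img, {2: "background", 3: "background", 4: "background"})


class TestExtractReferences:
    def test_constant_region_gives_zero_series(self):
        movie = make_movie(np.full((40, 16, 16), 7.0))
        refs = extract_references(movie, _bg_mask_16())
        assert refs.n_refs == 3
        np.testing.assert_allclose(refs.series, 0.0, atol=1e-12)

    def test_uniform_time_signal_recovered_mean_removed(self):
        t = np.arange(40)
        f = np.sin(0.3 * t)
        movie = make_movie(np.tile(f[:, None, None], (1, 16, 16)))
        refs = extract_references(movie, _bg_mask_16())
        np.testing.assert_allclose(refs.series[0], f - f.mean(), atol=1e-12)

    def test_three_regions_give_three_references(self, small_sim):
        movie, _, mask = small_sim
        assert extract_references(movie, mask).n_refs == 3

    def test_no_background_rejected(self):
        img = np.zeros((8, 8), np.int32)
        img[2:4, 2:4] = 1
        mask = RegionMask(img, {1: "cell"})
        movie = make_movie(np.zeros((10, 8, 8)))
        with pytest.raises(ValueError, match="background"):
            extract_references(movie, mask)

    def test_gram_matrix_symmetric_psd(self, small_sim):
        movie, _, mask = small_sim
        G = extract_references(movie, mask).gram()
        np.testing.assert_allclose(G, G.T, atol=1e-12)
        assert np.linalg.eigvalsh(G).min() >= -1e-12


class TestPCCMap:
    def test_pixel_equal_to_reference_gives_one(self):
        r = np.sin(np.arange(100) * 0.2)
        data = np.zeros((100, 4, 4))
        data[:, 1, 1] = r
        data[:, 2, 2] = -2.0 * r
        out = pcc_map(make_movie(data), r)
        assert out[1, 1] == pytest.approx(1.0)
        assert out[2, 2] == pytest.approx(-1.0)

    def test_zero_variance_pixel_flagged_nan(self):
        r = np.sin(np.arange(100) * 0.2)
        out = pcc_map(make_movie(np.zeros((100, 3, 3))), r)
        assert np.isnan(out).all()

    def test_null_distribution_scale(self):
        # independent white pixels: PCC sd ~ 1/sqrt(T), so |PCC| < 0.08 a.s.
        rng = np.random.default_rng(0)
        movie = make_movie(rng.normal(size=(2000, 20, 20)))
        r = rng.normal(size=2000)
        out = pcc_map(movie, r)
        assert (np.abs(out) < 0.08).mean() >= 0.99


class TestFitApply:
    def test_single_reference_closed_form(self):
        r = np.sin(np.arange(200) * 0.1)
        data = np.zeros((200, 4, 4))
        data[:, 0, 0] = 2.0 * r
        movie = make_movie(data)
        refs = ReferenceSet(r[None], labels=[2])
        model = fit_decorrelation(movie, refs)
        assert model.coefficient_maps[0, 0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_exact_combination_residual_is_constant(self):
        r = np.cos(np.arange(300) * 0.07)
        r -= r.mean()
        data = 3.0 * np.tile(r[:, None, None], (1, 5, 5)) + 10.0
        movie = make_movie(data)
        refs = ReferenceSet(r[None], labels=[2])
        res = apply_decorrelation(movie, refs, fit_decorrelation(movie, refs))
        assert np.ptp(res.data, axis=0).max() < 1e-10
        # the static OPD level survives decorrelation
        assert res.data.mean() == pytest.approx(10.0)

    def test_recovers_ground_truth_maps_without_noise(self):
        cfg = SimulationConfig(
            seed=5, n_frames=300, height=16, width=16, cell_radius_um=1.5,
            white_noise_nm=0.0, n_hotspots=0,
            background=FluctuationModel("passive", amp=0.0),
        )
        movie, truth = synthesize_movie(cfg)
        refs = ReferenceSet(truth.references, labels=[2, 3, 4])
        model = fit_decorrelation(movie, refs)
        np.testing.assert_allclose(
            model.coefficient_maps, truth.coefficient_maps, rtol=1e-6, atol=1e-9
        )

    def test_matches_per_pixel_least_squares(self, small_sim):
        movie, _, mask = small_sim
        refs = extract_references(movie, mask)
        model = fit_decorrelation(movie, refs)
        rng = np.random.default_rng(3)
        X = np.column_stack([refs.series.T, np.ones(movie.n_frames)])
        for _ in range(10):
            i, j = rng.integers(0, movie.frame_shape[0]), rng.integers(0, movie.frame_shape[1])
            beta, *_ = np.linalg.lstsq(X, movie.data[:, i, j], rcond=None)
            np.testing.assert_allclose(
                model.coefficient_maps[:, i, j], beta[:-1], rtol=1e-8, atol=1e-10
            )

    def test_residual_orthogonal_to_references(self, small_sim):
        movie, _, mask = small_sim
        refs = extract_references(movie, mask)
        res = apply_decorrelation(movie, refs, fit_decorrelation(movie, refs))
        centred = res.data - res.data.mean(axis=0)
        cov = np.einsum("nt,thw->nhw", refs.series, centred) / movie.n_frames
        scale = np.sqrt((refs.series**2).mean()) * centred.std() + 1e-30
        assert np.abs(cov).max() / scale < 1e-9

    def test_idempotent_on_decorrelated_movie(self, small_sim):
        movie, _, mask = small_sim
        refs = extract_references(movie, mask)
        res = apply_decorrelation(movie, refs, fit_decorrelation(movie, refs))
        model2 = fit_decorrelation(res, refs)
        assert np.abs(model2.coefficient_maps).max() < 1e-9
        res2 = apply_decorrelation(res, refs, model2)
        np.testing.assert_allclose(res2.data, res.data, atol=1e-8)

    def test_collinear_references_warn_and_use_pinv(self):
        r = np.sin(np.arange(100) * 0.1)
        refs = ReferenceSet(np.vstack([r, 2 * r]), labels=[2, 3])
        movie = make_movie(np.tile(r[:, None, None], (1, 4, 4)))
        with pytest.warns(UserWarning, match="cond"):
            model = fit_decorrelation(movie, refs)
        res = apply_decorrelation(movie, refs, model)
        assert np.ptp(res.data, axis=0).max() < 1e-8


class TestNoisePower:
    def test_white_noise_power_recovered(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1.0, size=(2000, 16, 16))
        noise = estimate_noise_power(make_movie(data), _bg_mask_16())
        assert noise == pytest.approx(1.0, abs=0.05)

    def test_zero_residual_gives_zero(self):
        assert estimate_noise_power(make_movie(np.zeros((50, 16, 16))), _bg_mask_16()) == 0.0

    def test_per_pixel_map_restricted_to_background(self):
        rng = np.random.default_rng(1)
        movie = make_movie(rng.normal(size=(200, 16, 16)))
        mask = _bg_mask_16()
        out = estimate_noise_power(movie, mask, per_pixel=True)
        assert np.isfinite(out[mask.background_mask()]).all()
        assert np.isnan(out[~mask.background_mask()]).all()

    def test_spatial_averaging_variance_scales_inversely(self):
        rng = np.random.default_rng(2)
        movie = make_movie(rng.normal(0, 1.0, size=(2000, 16, 16)))
        region = np.ones((16, 16), bool)
        ns = np.array([1, 2, 4, 8, 16, 32, 64])
        var = spatial_averaging_variance(movie, region, ns, seed=0)
        slope = np.polyfit(np.log(ns), np.log(var), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)


class TestPowerMap:
    def test_variance_equal_to_noise_gives_zero_power(self):
        data = np.zeros((100, 4, 4))
        data[:, 1, 1] = np.sqrt(2.0) * np.sin(np.arange(100) * 2 * np.pi / 10)
        movie = make_movie(data)
        var = movie.data[:, 1, 1].var()
        cell = np.ones((4, 4), bool)
        power, active = intracellular_power_map(movie, var, cell, threshold_factor=2.0)
        assert power[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert not active[1, 1]

    def test_power_arithmetic_and_activity(self):
        rng = np.random.default_rng(0)
        data = np.sqrt(5.0) * rng.normal(size=(100000, 1, 1))
        movie = make_movie(data)
        cell = np.ones((1, 1), bool)
        power, active = intracellular_power_map(movie, 1.0, cell, threshold_factor=2.0)
        assert power[0, 0] == pytest.approx(4.0, rel=0.05)
        assert active[0, 0]

    def test_corrected_power_unbiased_on_simulation(self):
        # mean corrected power over hotspot pixels vs realized clean variance
        ratios = []
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, height=32, width=32, cell_radius_um=3.0,
                n_hotspots=1, template_peak_nm=20.0,
            )
            movie, truth = synthesize_movie(cfg)
            from qpifluct.simulate import default_region_mask

            mask = default_region_mask(cfg, bg_size=4)
            dec = decorrelate_movie(movie, mask)
            power, _ = intracellular_power_map(
                dec.residual, dec.noise_power, mask.cell_mask()
            )
            hot = truth.class_map == 2
            ratios.append(np.nanmean(power[hot]) / truth.clean_movie[:, hot].var(axis=0).mean())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)
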