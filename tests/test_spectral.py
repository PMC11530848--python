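"""Periodogram normalization, floor filter, and the A f^-m + B fit."""

import numpy as np
import pytest

from qpifluct.core_io import AnalysisConfig, RegionMask
from qpifluct.spectral import (
    PSDFloor,
    filter_pixels,
    fit_psd,
    pixel_psd,
    psd_floor,
    slope_amplitude_maps,
)
from qpifluct.simulate import gen_active_series, gen_powerlaw_series

from conftest import make_movie


class TestPixelPSD:
    def test_sine_power_concentrates_at_its_bin(self):
        t = np.arange(2000) * 0.05
        x = np.sin(2 * np.pi * 1.0 * t)
        psd = pixel_psd(x, 0.05)
        df = psd.frequencies[1] - psd.frequencies[0]
        total = psd.values.sum() * df
        assert total == pytest.approx(0.5, rel=1e-6)
        peak = psd.frequencies[np.argmax(psd.values)]
        assert peak == pytest.approx(1.0, abs=df)
        # essentially all power in the 1 Hz bin
        assert psd.values.max() * df == pytest.approx(0.5, rel=1e-6)

    def test_white_noise_parseval(self):
        x = np.random.default_rng(0).normal(0, 1.0, 2000)
        psd = pixel_psd(x, 0.05)
        df = psd.frequencies[1] - psd.frequencies[0]
        assert psd.values.sum() * df == pytest.approx(x.var(), rel=1e-9)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=64)
        dt = 0.1
        psd = pixel_psd(x, dt)
        xc = x - x.mean()
        n = 64
        for k in range(1, n // 2 + 1):
            X = sum(xc[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))
            expected = (2.0 if k < n // 2 else 1.0) * abs(X) ** 2 * dt / n
            assert psd.values[k - 1] == pytest.approx(expected, rel=1e-8)

    def test_constant_series_flagged(self):
        psd = pixel_psd(np.full(64, 3.0), 0.05)
        assert psd.constant_input
        np.testing.assert_allclose(psd.values, 0.0, atol=1e-20)

    def test_parseval_for_synthetic_spectra(self):
        for gamma in (0.5, 1.15, 2.0):
            x = gen_powerlaw_series(1000, 0.05, gamma, 2.0, seed=1)
            psd = pixel_psd(x, 0.05)
            df = psd.frequencies[0]
            assert psd.values.sum() * df == pytest.approx(x.var(), rel=1e-9)


def _bg_mask():
    img = np.zeros((10, 10), np.int32)
    img[1:5, 1:5] = 2
    return RegionMask(img, {2: "background"})


class TestFloorAndFilter:
    def test_white_background_floor_is_flat_at_known_level(self):
        rng = np.random.default_rng(0)
        sd = 1.5
        movie = make_movie(rng.normal(0, sd, size=(2000, 10, 10)))
        floor = psd_floor(movie, _bg_mask())
        # flat one-sided density: sd^2 / (10 Hz band)
        assert floor.values.mean() == pytest.approx(sd**2 / 10.0, rel=0.1)
        assert not floor.degenerate

    def test_zero_background_flagged(self):
        floor = psd_floor(make_movie(np.zeros((64, 10, 10))), _bg_mask())
        assert floor.degenerate

    def test_psd_double_floor_kept_and_equal_floor_rejected(self):
        f = np.linspace(0.01, 10, 50)
        floor = PSDFloor(f, np.ones(50))
        assert filter_pixels(2.0 * np.ones(50), floor, ratio=1.25, min_frac=0.7)
        assert not filter_pixels(np.ones(50), floor, ratio=1.25, min_frac=0.7)

    def test_exact_70_percent_boundary_is_inclusive(self):
        f = np.linspace(0.01, 10, 10)
        floor = PSDFloor(f, np.ones(10))
        psd = np.ones(10)
        psd[:7] = 2.0  # above threshold at exactly 70% of bins
        assert filter_pixels(psd, floor, ratio=1.25, min_frac=0.7)
        psd[6] = 1.0  # 60% -> rejected
        assert not filter_pixels(psd, floor, ratio=1.25, min_frac=0.7)


class TestFitPSD:
    def test_exact_model_recovered(self):
        f = np.linspace(0.01, 10, 1000)
        fit = fit_psd(f, 1.0 * f**-1.5)
        assert fit.A == pytest.approx(1.0, abs=1e-6)
        assert fit.m == pytest.approx(1.5, abs=1e-6)
        assert fit.B == pytest.approx(0.0, abs=1e-6)
        assert fit.amp_eval == pytest.approx(0.01**-1.5, rel=1e-4)

    def test_exact_model_with_offset_recovered(self):
        f = np.linspace(0.01, 10, 1000)
        fit = fit_psd(f, 2.0 * f**-1.2 + 0.5)
        assert fit.m == pytest.approx(1.2, abs=1e-5)
        assert fit.B == pytest.approx(0.5, rel=1e-4)

    def test_white_differential_psd_has_zero_slope(self):
        slopes = []
        for s in range(10):
            x = np.random.default_rng(s).normal(0, 1.0, 2000)
            psd = pixel_psd(x, 0.05)
            slopes.append(fit_psd(psd.frequencies, psd.values).m)
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 1.5, 2.0])
    def test_powerlaw_slope_recovery(self, gamma):
        slopes = []
        for s in range(100):
            x = gen_powerlaw_series(2000, 0.05, gamma, 1.0, seed=s)
            psd = pixel_psd(x, 0.05)
            slopes.append(fit_psd(psd.frequencies, psd.values).m)
        assert np.mean(slopes) == pytest.approx(gamma, abs=0.1)

    def test_passive_beta_slope(self):
        # beta = 0.15 passive pixels: mean fitted slope 1 + beta
        slopes = []
        for s in range(100):
            x = gen_powerlaw_series(2000, 0.05, 1.15, 1.0, seed=s)
            psd = pixel_psd(x, 0.05)
            slopes.append(fit_psd(psd.frequencies, psd.values).m)
        assert np.mean(slopes) == pytest.approx(1.15, abs=0.1)

    def test_amplitude_scales_with_input_power(self):
        x = gen_powerlaw_series(2000, 0.05, 1.3, 1.0, seed=4)
        p1 = pixel_psd(x, 0.05)
        p2 = pixel_psd(2.0 * x, 0.05)
        a1 = fit_psd(p1.frequencies, p1.values).amp_eval
        a2 = fit_psd(p2.frequencies, p2.values).amp_eval
        assert a2 / a1 == pytest.approx(4.0, rel=0.05)

    def test_too_few_positive_bins_fails_gracefully(self):
        f = np.linspace(0.01, 10, 20)
        fit = fit_psd(f, -np.ones(20))
        assert not fit.success
        assert fit.n_excluded == 20


class TestSlopeMaps:
    @staticmethod
    def _movie_with_classes(kind: str, seed: int = 0):
        """16x16 movie: white background; cell rows with passive or active pixels."""
        rng = np.random.default_rng(seed)
        T = 1000
        data = rng.normal(0, 0.5, size=(T, 16, 16))
        cell = np.zeros((16, 16), bool)
        cell[6:13, 6:13] = True
        n = int(cell.sum())
        if kind == "passive":
            series = gen_powerlaw_series(T, 0.05, 1.0, 8.0, seed=seed + 1, size=n)
        else:
            series = gen_active_series(T, 0.05, 0.0, 10.0, 8.0, seed=seed + 1, size=n)
        data[:, cell] += series.T
        img = np.zeros((16, 16), np.int32)
        img[cell] = 1
        img[1:4, 1:4] = 2
        img[1:4, 12:15] = 3
        mask = RegionMask(img, {1: "cell", 2: "background", 3: "background"})
        return make_movie(data), mask, cell

    @pytest.mark.parametrize("kind,expected", [("passive", 1.0), ("active", 2.0)])
    def test_uniform_cell_mean_slope(self, kind, expected):
        movie, mask, cell = self._movie_with_classes(kind)
        floor = psd_floor(movie, mask)
        cfg = AnalysisConfig(amplitude_eval_freq=0.02)
        m_map, a_map, fitted = slope_amplitude_maps(movie, cell, floor, cfg)
        assert fitted.sum() > 0.8 * cell.sum()
        assert np.nanmean(m_map) == pytest.approx(expected, abs=0.2)

    def test_mixed_cell_separates_classes(self):
        # active disk inside a passive cell: slope map ~2 inside, ~1 outside
        rng = np.random.default_rng(7)
        T = 1000
        data = rng.normal(0, 0.5, size=(T, 20, 20))
        cell = np.zeros((20, 20), bool)
        cell[5:16, 5:16] = True
        rr, cc = np.mgrid[0:20, 0:20]
        disk = (np.hypot(rr - 10, cc - 10) <= 2.5) & cell
        passive_px = cell & ~disk
        data[:, passive_px] += gen_powerlaw_series(
            T, 0.05, 1.0, 8.0, seed=1, size=int(passive_px.sum())
        ).T
        data[:, disk] += gen_active_series(
            T, 0.05, 0.0, 10.0, 12.0, seed=2, size=int(disk.sum())
        ).T
        img = np.zeros((20, 20), np.int32)
        img[cell] = 1
        img[1:4, 1:4] = 2
        img[17:20, 1:4] = 3
        mask = RegionMask(img, {1: "cell", 2: "background", 3: "background"})
        movie = make_movie(data)
        floor = psd_floor(movie, mask)
        cfg = AnalysisConfig(amplitude_eval_freq=0.02)
        m_map, _, _ = slope_amplitude_maps(movie, cell, floor, cfg)
        assert np.nanmean(m_map[disk]) == pytest.approx(2.0, abs=0.2)
        assert np.nanmean(m_map[passive_px]) == pytest.approx(1.0, abs=0.2)
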