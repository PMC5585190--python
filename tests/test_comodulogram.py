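"""Comodulogram sweep, trial-shuffle surrogates, and normalization."""

import numpy as np
import pytest

from crossfreq import (
    ComodulogramGrid,
    GridSpec,
    SimulationSpec,
    TrialSeries,
    compute_comodulogram,
    generate_surrogates,
    normalize_mi,
    simulate_pac_trials,
)
from crossfreq.comodulogram import random_derangement
from crossfreq.simulate import study_trim

SMALL_GRID = dict(phase_centers=np.array([8.0, 10.0, 12.0]),
                  amp_centers=np.array([40.0, 60.0, 80.0]),
                  trim=study_trim(1.2))

ALL_METHODS = ["mvl_canolty", "mvl_ozkurt", "plv_cohen", "kl_tort"]


class TestGridSpec:
    def test_default_grid_is_7_by_34(self):
        spec = GridSpec()
        assert spec.shape == (7, 34)
        assert spec.phase_centers[0] == 7 and spec.phase_centers[-1] == 13
        assert spec.amp_centers[0] == 34 and spec.amp_centers[-1] == 100

    def test_default_grid_fully_sideband_admissible(self):
        # 0.4 * 34 = 13.6 >= 13 Hz, so every default cell can carry the
        # sidebands of the highest phase frequency
        assert GridSpec().admissible_cells().all()

    def test_inadmissible_cells_flagged(self):
        spec = GridSpec(phase_centers=np.array([13.0]),
                        amp_centers=np.array([20.0, 40.0]))
        assert list(spec.admissible_cells()[0]) == [False, True]

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(phase_centers=np.array([10.0, 9.0]))


class TestComodulogram:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_simulated_coupling_peak_located(self, coupled_trials, method):
        grid = compute_comodulogram(coupled_trials,
                                    GridSpec(method=method, **SMALL_GRID))
        fp, fa = grid.peak()
        assert fp == 10.0
        assert fa == 60.0

    def test_single_trial_per_trial_equals_average(self):
        trials = simulate_pac_trials(SimulationSpec(n_trials=1, seed=3))
        grid = compute_comodulogram(trials, GridSpec(method="mvl_ozkurt", **SMALL_GRID))
        assert np.array_equal(grid.per_trial[0], grid.mi)

    def test_analysis_window_restricts_samples(self, coupled_trials):
        spec = dict(SMALL_GRID)
        spec["analysis_window"] = (0.3, 0.9)
        g_win = compute_comodulogram(coupled_trials, GridSpec(method="mvl_ozkurt", **spec))
        g_all = compute_comodulogram(coupled_trials,
                                     GridSpec(method="mvl_ozkurt", **SMALL_GRID))
        assert not np.allclose(g_win.mi, g_all.mi)


class TestSurrogates:
    def test_derangement_has_no_fixed_points(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 8, 64):
            p = random_derangement(rng, n)
            assert not np.any(p == np.arange(n))
            assert sorted(p) == list(range(n))

    def test_seed_reproducibility_and_distinct_draws(self, coupled_trials):
        spec = GridSpec(method="mvl_ozkurt", **SMALL_GRID)
        s1 = generate_surrogates(coupled_trials, spec, n=5, seed=7)
        s2 = generate_surrogates(coupled_trials, spec, n=5, seed=7)
        s3 = generate_surrogates(coupled_trials, spec, n=5, seed=8)
        assert np.array_equal(s1.values, s2.values)
        assert s1.values.shape == s3.values.shape
        assert not np.array_equal(s1.values, s3.values)

    def test_identical_trials_make_shuffle_a_noop(self):
        t = np.arange(1200) / 1000.0
        row = np.cos(2 * np.pi * 10 * t) + 0.5 * np.cos(2 * np.pi * 60 * t)
        trials = TrialSeries(np.tile(row, (6, 1)), fs=1000.0)
        spec = GridSpec(method="mvl_canolty",
                        phase_centers=np.array([10.0]),
                        amp_centers=np.array([60.0]), trim=0.12)
        observed = compute_comodulogram(trials, spec)
        surr = generate_surrogates(trials, spec, n=10, seed=1)
        assert np.allclose(surr.values, observed.mi[None])

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_coupled_cell_exceeds_surrogates(self, coupled_trials, method):
        spec = GridSpec(method=method, phase_centers=np.array([10.0]),
                        amp_centers=np.array([60.0]), trim=study_trim(1.2))
        observed = compute_comodulogram(coupled_trials, spec)
        surr = generate_surrogates(coupled_trials, spec, n=50, seed=2)
        assert observed.mi[0, 0] > surr.mean[0, 0] + 2 * surr.sd[0, 0]

    def test_too_few_trials_rejected(self):
        trials = TrialSeries(np.random.default_rng(0).standard_normal((1, 1200)),
                             fs=1000.0)
        with pytest.raises(ValueError, match="at least 2 trials"):
            generate_surrogates(trials, GridSpec(**SMALL_GRID), n=3, seed=0)


class TestNormalization:
    def _toy_grid(self, mi):
        return ComodulogramGrid(mi=mi, phase_centers=np.array([10.0]),
                                amp_centers=np.array([60.0, 62.0]),
                                method="mvl_ozkurt", n_trials=4)

    def _toy_surr(self, mean, sd):
        from crossfreq import SurrogateEnsemble
        values = np.stack([mean - sd, mean + sd])
        return SurrogateEnsemble(values=values, mean=mean, sd=sd,
                                 method="mvl_ozkurt", seed=0,
                                 permutations=np.zeros((2, 4), dtype=int))

    def test_observed_equal_to_mean_gives_zero(self):
        mean = np.array([[0.3, 0.4]])
        z = normalize_mi(self._toy_grid(mean.copy()), self._toy_surr(mean, np.ones_like(mean)))
        assert np.allclose(z.mi, 0.0)
        assert z.normalized

    def test_one_sd_above_gives_exactly_one(self):
        mean = np.array([[0.3, 0.4]])
        sd = np.array([[0.05, 0.1]])
        z = normalize_mi(self._toy_grid(mean + sd), self._toy_surr(mean, sd))
        assert np.allclose(z.mi, 1.0)

    def test_zero_spread_cell_flagged_nan(self):
        mean = np.array([[0.3, 0.4]])
        sd = np.array([[0.0, 0.1]])
        z = normalize_mi(self._toy_grid(mean + 0.1), self._toy_surr(mean, sd))
        assert np.isnan(z.mi[0, 0]) and np.isfinite(z.mi[0, 1])

    def test_normalized_peak_matches_raw_peak_on_coupled_data(self, coupled_trials):
        spec = GridSpec(method="kl_tort", **SMALL_GRID)
        observed = compute_comodulogram(coupled_trials, spec)
        surr = generate_surrogates(coupled_trials, spec, n=30, seed=5)
        z = normalize_mi(observed, surr)
        assert z.peak() == observed.peak() == (10.0, 60.0)


class TestNullBehavior:
    def test_white_noise_rarely_exceeds_surrogate_tail(self):
        """Uncoupled noise: observed MI should sit inside its own surrogate
        distribution; bound the rate of 95th-percentile exceedances across
        seeds and cells."""
        spec = GridSpec(method="mvl_ozkurt", phase_centers=np.array([8.0, 12.0]),
                        amp_centers=np.array([45.0, 75.0]), trim=0.12)
        rng = np.random.default_rng(12)
        exceed = total = 0
        for _ in range(6):
            trials = TrialSeries(rng.standard_normal((16, 1200)), fs=1000.0)
            observed = compute_comodulogram(trials, spec)
            surr = generate_surrogates(trials, spec, n=60,
                                       seed=int(rng.integers(2 ** 31)))
            q95 = np.quantile(surr.values, 0.95, axis=0)
            exceed += int(np.sum(observed.mi > q95))
            total += observed.mi.size
        assert exceed / total <= 0.15
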