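"""Cluster permutation test and sinusoidality diagnostic."""

import itertools

import numpy as np
import pytest
from scipy import signal as sps

from crossfreq import (
    TrialSeries,
    cluster_permutation_test,
    paired_t,
    rise_decay_ratio,
)

FS = 1000.0


class TestPairedT:
    def test_identical_inputs_flagged(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.t == 0.0 and np.isnan(res.p)

    def test_constant_offset_flagged_infinite(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isinf(res.t) and res.t > 0

    def test_matches_direct_formula_on_toy_vectors(self):
        a = np.array([3.1, 2.7, 4.0, 3.3, 2.9])
        b = np.array([2.8, 2.9, 3.1, 3.0, 2.5])
        # independent oracle: the textbook formula evaluated step by step
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t(a, b)
        assert res.t == pytest.approx(t_expect, rel=1e-12)
        from scipy.stats import ttest_rel
        assert res.p == pytest.approx(ttest_rel(a, b).pvalue, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


def _noise_grids(rng, n_subj, shape=(7, 34), scale=1.0):
    return [rng.standard_normal(shape) * scale for _ in range(n_subj)]


class TestClusterPermutation:
    def test_identical_conditions_empty_result(self):
        rng = np.random.default_rng(0)
        grids = _noise_grids(rng, 8)
        res = cluster_permutation_test(grids, [g.copy() for g in grids],
                                       n_perm=100, seed=1)
        assert len(res.clusters) == 0
        assert not res.sig_mask.any()
        assert np.all(res.t_map == 0)

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(5)
        shape = (7, 34)
        block = (slice(2, 5), slice(10, 15))  # 3 x 5 cells
        grids_a, grids_b = [], []
        for _ in range(16):
            eff = rng.standard_normal(shape)
            eff[block] += 1.5
            grids_a.append(eff)
            grids_b.append(rng.standard_normal(shape))
        res = cluster_permutation_test(grids_a, grids_b, n_perm=500, seed=3)
        sig = res.sig_mask
        inside = np.zeros(shape, dtype=bool)
        inside[block] = True
        sensitivity = sig[inside].mean()
        assert sensitivity >= 0.8
        # false positives outside the block stay at the nominal rate
        assert sig[~inside].mean() <= 0.05

    def test_exhaustive_sign_flip_oracle_four_subjects(self):
        """With 4 subjects the label permutation space is 2^4 = 16; the
        Monte-Carlo p must agree with full enumeration within 1/16."""
        rng = np.random.default_rng(7)
        shape = (3, 4)
        diffs = rng.standard_normal((4,) + shape)
        diffs[:, 1, 1] += 2.0
        grids_a = list(diffs)
        grids_b = [np.zeros(shape)] * 4

        res = cluster_permutation_test(grids_a, grids_b, n_perm=4096,
                                       cluster_alpha=0.05, seed=9)
        assert len(res.clusters) >= 1
        k = int(np.argmax(res.cluster_stats))

        # brute-force enumeration oracle
        def tmap(d):
            sd = d.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = d.mean(axis=0) / (sd / np.sqrt(4))
            t[sd == 0] = 0
            return t

        from scipy.stats import t as tdist
        tc = tdist.ppf(1 - 0.05 / 2, df=3)
        null = []
        for signs in itertools.product([1, -1], repeat=4):
            t = tmap(np.asarray(signs)[:, None, None] * diffs)
            supra = np.abs(t) > tc
            null.append(np.abs(t[supra]).max() if supra.any() else 0.0)
        p_exact = np.mean(np.asarray(null) >= res.cluster_stats[k])
        assert res.p_values[k] == pytest.approx(p_exact, abs=1 / 16)

    def test_condition_exchange_flips_signs_preserves_p(self):
        rng = np.random.default_rng(11)
        grids_a = _noise_grids(rng, 10, shape=(5, 6))
        grids_b = [g + rng.standard_normal((5, 6)) * 0.5 for g in grids_a]
        r_ab = cluster_permutation_test(grids_a, grids_b, n_perm=200, seed=4)
        r_ba = cluster_permutation_test(grids_b, grids_a, n_perm=200, seed=4)
        assert np.allclose(r_ab.t_map, -r_ba.t_map)
        assert np.allclose(np.sort(r_ab.null_distribution),
                           np.sort(r_ba.null_distribution))
        assert np.allclose(np.sort(r_ab.p_values), np.sort(r_ba.p_values))

    def test_subject_order_leaves_p_values_stable(self):
        rng = np.random.default_rng(13)
        grids_a = _noise_grids(rng, 12, shape=(5, 6))
        grids_b = [g + 0.8 for g in _noise_grids(rng, 12, shape=(5, 6))]
        r1 = cluster_permutation_test(grids_a, grids_b, n_perm=800, seed=5)
        order = rng.permutation(12)
        r2 = cluster_permutation_test([grids_a[i] for i in order],
                                      [grids_b[i] for i in order],
                                      n_perm=800, seed=5)
        assert np.allclose(r1.t_map, r2.t_map)
        for p1, p2 in zip(np.sort(r1.p_values), np.sort(r2.p_values)):
            assert abs(p1 - p2) <= 0.05

    def test_mass_statistic_available(self):
        rng = np.random.default_rng(17)
        grids_a = [g + 1.0 for g in _noise_grids(rng, 8, shape=(4, 5))]
        grids_b = _noise_grids(rng, 8, shape=(4, 5))
        res = cluster_permutation_test(grids_a, grids_b, n_perm=100, seed=6,
                                       statistic="mass")
        assert res.statistic == "mass"
        assert res.null_distribution.shape == (100,)

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test([np.zeros((2, 2))] * 3,
                                     [np.zeros((2, 2))] * 4)


def _oscillation_trials(rng, waveform, n_trials=6, dur=3.0, f=10.0, noise=0.02):
    t = np.arange(int(dur * FS)) / FS
    rows = []
    for _ in range(n_trials):
        phi = rng.uniform(0, 2 * np.pi)
        arg = 2 * np.pi * f * t + phi
        if waveform == "sine":
            x = np.cos(arg)
        elif waveform == "rising_saw":
            x = sps.sawtooth(arg, width=0.9)    # slow rise, fast fall
        elif waveform == "falling_saw":
            x = sps.sawtooth(arg, width=0.1)    # fast rise, slow decay
        rows.append(x + noise * rng.standard_normal(t.size))
    return TrialSeries(np.asarray(rows), fs=FS)


class TestRiseDecay:
    def test_sinusoid_ratio_is_one(self):
        trials = _oscillation_trials(np.random.default_rng(0), "sine")
        res = rise_decay_ratio(trials, phase_freqs=[10.0])
        assert res.ratio[0] == pytest.approx(1.0, rel=0.02)
        assert res.rise[0] > 0 and res.decay[0] > 0

    def test_sawtooth_asymmetry_signs(self):
        rng = np.random.default_rng(1)
        rising = rise_decay_ratio(_oscillation_trials(rng, "rising_saw"),
                                  phase_freqs=[10.0])
        falling = rise_decay_ratio(_oscillation_trials(rng, "falling_saw"),
                                   phase_freqs=[10.0])
        assert rising.ratio[0] > 1.1
        assert falling.ratio[0] < 0.9

    def test_too_short_trials_rejected(self):
        trials = TrialSeries(np.zeros((2, 1200)), fs=FS)
        with pytest.raises(ValueError, match="cycles"):
            rise_decay_ratio(trials, phase_freqs=[7.0])
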