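"""Significance tests: F on normalized power, Rayleigh, empirical null,
FDR, condition comparison, topography classification, behavior correlation."""

import numpy as np
import pytest
from scipy import stats

from freqtag import (
    behavioral_outlier_mask,
    classify_topographies,
    compare_conditions,
    correlate_behavior,
    empirical_null_test,
    fdr_correct,
    ftest_normalized_power,
    normalize_power,
    null_bin_pool,
    rayleigh_test,
)


def simulate_null_grand_en(rng, n_subjects=16, n_bins=120, n_rep=1):
    """Grand-average normalized power under the null: complex Gaussian DFT
    coefficients per subject, power averaged over subjects, Eq.-4
    normalization. Returns (n_rep, n_bins) En values."""
    z = rng.standard_normal((n_rep, n_subjects, n_bins)) \
        + 1j * rng.standard_normal((n_rep, n_subjects, n_bins))
    power = (np.abs(z) ** 2).mean(axis=1)
    return np.stack([normalize_power(p, resolution=1 / 14.08) for p in power])


class TestFTestNormalizedPower:
    def test_dof_at_16_subjects(self):
        res = ftest_normalized_power(0.1, n_subjects=16)
        assert res.dof == (32, 448)

    def test_flat_spectrum_statistic_is_one(self):
        res = ftest_normalized_power(1 / 14, n_subjects=16)
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(stats.f.sf(1.0, 32, 448))
        assert 0.4 < res.p < 0.55

    def test_single_subject_dof(self):
        assert ftest_normalized_power(0.1, n_subjects=1).dof == (2, 28)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ftest_normalized_power(0.1, n_subjects=0)
        with pytest.raises(ValueError):
            ftest_normalized_power(float("nan"), n_subjects=16)

    def test_null_calibration_matches_f_32_448(self):
        """2000 null grand averages: 14*En ~ F(32, 448) by KS, and the 0.05
        rejection rate lands in [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        en = simulate_null_grand_en(rng, n_rep=2000)
        stat_bin = 30  # any interior bin
        f_stats = 14.0 * en[:, stat_bin]
        ks = stats.kstest(f_stats, "f", args=(32, 448))
        assert ks.pvalue > 0.01
        crit = stats.f.isf(0.05, 32, 448)
        rate = float((f_stats > crit).mean())
        assert 0.03 <= rate <= 0.07


class TestRayleigh:
    def test_zero_statistic_gives_p_one(self):
        assert rayleigh_test(0.0, K=30).p == pytest.approx(1.0)

    def test_maximal_coherence_is_overwhelming(self):
        res = rayleigh_test(30.0, K=30)
        assert res.statistic == 30.0
        assert res.p < 1e-12

    def test_small_sample_correction_formula(self):
        z, K = 2.5, 10
        expected = np.exp(-z) * (1 + (2 * z - z * z) / (4 * K))
        assert rayleigh_test(z, K).p == pytest.approx(expected)

    def test_uniform_null_rejection_rate(self, rng):
        """5000 replicates of K=30 uniform phases: alpha=0.05 rejections in
        [0.035, 0.065]."""
        K, n_rep = 30, 5000
        phases = rng.uniform(0, 2 * np.pi, size=(n_rep, K))
        C = np.cos(phases).sum(axis=1)
        S = np.sin(phases).sum(axis=1)
        z = (C**2 + S**2) / K
        p = np.array([rayleigh_test(zi, K).p for zi in z])
        rate = float((p < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestEmpiricalNull:
    def test_add_one_rule_with_extreme_observation(self, rng):
        null = rng.uniform(0, 1, 199)
        res = empirical_null_test(null.max() + 1.0, null)
        assert res.p == pytest.approx(1 / 200)

    def test_median_observation_near_half(self, rng):
        null = rng.standard_normal(999)
        res = empirical_null_test(float(np.median(null)), null)
        assert res.p == pytest.approx(0.5, abs=0.01)

    def test_empty_or_small_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            empirical_null_test(1.0, np.arange(10))

    def test_nan_pool_values_dropped(self, rng):
        null = np.r_[rng.uniform(0, 1, 60), [np.nan] * 20]
        res = empirical_null_test(2.0, null)
        assert res.dof == 60

    def test_null_p_values_are_uniform(self, rng):
        """Observed drawn from the null itself: p-values uniform on (0,1]
        (KS at alpha=0.01 in >= 95% of meta-replicates)."""
        n_meta, fails = 20, 0
        for _ in range(n_meta):
            null = rng.standard_normal(400)
            obs = rng.standard_normal(200)
            p = np.array([empirical_null_test(o, null).p for o in obs])
            if stats.kstest(p, "uniform").pvalue < 0.01:
                fails += 1
        assert fails <= 1

    def test_pool_excludes_harmonics_and_guard(self):
        freqs = np.arange(200) / 14.08
        pool = null_bin_pool(freqs, sentential_bin=11)
        for h in (11, 22, 33, 44, 55, 66, 77):
            assert h not in pool and h - 1 not in pool and h + 1 not in pool
        assert pool.size >= 50
        assert freqs[pool].min() >= 0.3 and freqs[pool].max() <= 5.5


class TestFdr:
    def test_all_small_p_all_significant(self):
        q, mask = fdr_correct([0.01] * 12, q=0.05)
        assert mask.all()

    def test_hand_computed_step_up(self):
        q, _ = fdr_correct([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_unchanged(self):
        q, _ = fdr_correct([0.3])
        assert q[0] == pytest.approx(0.3)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        q, _ = fdr_correct(p)
        assert (q >= p - 1e-12).all()

    def test_false_discovery_proportion_controlled_under_null(self, rng):
        """Global null, independent p-values: mean FDP <= q."""
        fdp = []
        for _ in range(400):
            p = rng.uniform(0, 1, 16)
            _, mask = fdr_correct(p, q=0.05)
            fdp.append(mask.mean())
        assert np.mean(fdp) <= 0.05 + 0.01


class TestCompareConditions:
    def test_equal_powers_give_f_one_p_half(self):
        res = compare_conditions(2.0, 2.0, n_subjects=16)
        assert res.statistic == pytest.approx(1.0)
        assert res.dof == (32, 32)
        assert res.p == pytest.approx(0.5, abs=0.01)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions(1.0, 0.0, 16)

    def test_null_rejection_rate(self, rng):
        """Both conditions pure noise: chi2(32)/chi2(32) ratio rejects at
        alpha=0.05 in [0.03, 0.07] of 2000 replicates."""
        n_rep, n_subj = 2000, 16
        a = rng.chisquare(2 * n_subj, n_rep) / (2 * n_subj)
        b = rng.chisquare(2 * n_subj, n_rep) / (2 * n_subj)
        p = np.array([compare_conditions(x, y, n_subj).p for x, y in zip(a, b)])
        rate = float((p < 0.05).mean())
        assert 0.03 <= rate <= 0.07


def make_maps(rng, n_subjects=16, n_channels=32, separation=0.0, noise=1.0):
    """Split-half topography pairs; classes differ on disjoint channels by
    ``separation``."""
    base = rng.standard_normal((n_subjects, 2, n_channels)) * noise
    second = rng.standard_normal((n_subjects, 2, n_channels)) * noise
    base[:, 0, : n_channels // 2] += separation
    base[:, 1, n_channels // 2 :] += separation
    second[:, 0, : n_channels // 2] += separation
    second[:, 1, n_channels // 2 :] += separation
    return base, second


class TestClassifyTopographies:
    def test_disjoint_supports_classified_perfectly(self, rng):
        first, second = make_maps(rng, separation=5.0, noise=0.0)
        acc, res = classify_topographies(first, second)
        assert acc == 1.0
        assert res.p == pytest.approx(0.5**16, rel=1e-9)

    def test_identical_distributions_usually_nonsignificant(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            first, second = make_maps(rng, separation=0.0)
            _, res = classify_topographies(first, second)
            hits += res.p <= 0.05
        assert hits <= 0.1 * n_seeds

    def test_label_symmetry(self, rng):
        first, second = make_maps(rng, separation=1.0)
        acc1, _ = classify_topographies(first, second)
        acc2, _ = classify_topographies(first[:, ::-1], second[:, ::-1])
        assert acc1 == pytest.approx(acc2)

    def test_zero_variance_features_survive_via_ridge(self, rng):
        first, second = make_maps(rng, separation=2.0)
        first[:, :, 0] = 0.0
        second[:, :, 0] = 0.0
        acc, _ = classify_topographies(first, second)
        assert np.isfinite(acc)

    def test_mismatched_shapes_rejected(self, rng):
        first, second = make_maps(rng)
        with pytest.raises(ValueError):
            classify_topographies(first, second[:, :, :-1])


class TestBehaviorCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        res = correlate_behavior(x, x, exclude_outliers=False)
        assert res.statistic == pytest.approx(1.0)

    def test_planted_low_scorer_flagged(self, rng):
        """A 33%-scoring subject inside an 84 +- 6 cluster trips the >3 SD
        rule; nobody else does."""
        scores = np.clip(rng.normal(84, 6, 16), 0, 100)
        scores[5] = 33.0
        mask = behavioral_outlier_mask(scores)
        assert mask[5]
        assert mask.sum() == 1

    def test_outlier_exclusion_reported(self, rng):
        neural = rng.uniform(0, 1, 16)
        scores = np.clip(rng.normal(84, 6, 16), 0, 100)
        scores[3] = 33.0
        res = correlate_behavior(neural, scores)
        assert res.extra["excluded_subjects"] == [3]
        assert res.extra["n"] == 15

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_behavior(np.ones(8), np.arange(8.0), exclude_outliers=False)

    def test_generative_r_recovered_within_sampling_interval(self):
        """200 reruns at true r = 0.7, n = 16: the sample r falls inside the
        95% Fisher-z sampling interval of 0.7 in >= 90% of reruns."""
        true_r = 0.7
        n = 16
        z0 = np.arctanh(true_r)
        half = 1.96 / np.sqrt(n - 3)
        hits = 0
        n_rep = 200
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            amp = rng.normal(10.0, 2.0, n)
            noise_sd = 2.0 * np.sqrt(1 / true_r**2 - 1)  # slope 1
            score = 50.0 + amp + rng.normal(0, noise_sd, n)
            res = correlate_behavior(amp, score, exclude_outliers=False)
            hits += abs(np.arctanh(res.statistic) - z0) <= half
        assert hits >= 0.9 * n_rep

    def test_zero_slope_r_stays_below_threshold(self, rng):
        """No neural-behavior coupling: |r| under the two-sided 95% critical
        value for n=16 in >= 90% of reruns."""
        crit = stats.t.isf(0.025, 14)
        r_crit = crit / np.sqrt(14 + crit**2)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            amp = rng.uniform(0, 1, 16)
            score = rng.normal(70, 5, 16)
            res = correlate_behavior(amp, score, exclude_outliers=False)
            hits += abs(res.statistic) < r_crit
        assert hits >= 0.9 * n_rep
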