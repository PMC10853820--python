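"""Welch t-tests, power sizing, recovery onset, translation-time arithmetic."""

import numpy as np
import pytest

from centrofish import (QuantRecord, TimeCourse, recovery_onset, required_n,
                        translation_time, two_sample_t)
from centrofish.stats import simulated_power


def make_timecourse(means, n=20, sd=1.0, seed=0, channel="rna"):
    """TimeCourse with normal enrichment at given {timepoint: mean}."""
    rng = np.random.default_rng(seed)
    groups = {}
    for t, mu in means.items():
        recs = []
        for i in range(n):
            r = QuantRecord(cell_id=i // 2, centrosome_id=i % 2, timepoint=t)
            r.enrichment[channel] = float(rng.normal(mu, sd))
            recs.append(r)
        groups[t] = recs
    return TimeCourse(groups=groups, channel=channel)


class TestTwoSampleT:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        t, p = two_sample_t(a, a)
        assert t == 0.0 and p == 1.0

    def test_shifted_samples_significant(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        t, p = two_sample_t(a, [x + 10 for x in a])
        assert p < 0.001

    def test_degenerate_zero_variance(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_matches_statsmodels_reference(self, rng):
        """Independent route: statsmodels' unequal-variance t-test."""
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.3, 2, rng.integers(3, 30))
            t, p = two_sample_t(a, b)
            t_ref, p_ref, _ = sm_ttest(a, b, usevar="unequal")
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestRequiredN:
    def test_large_effect_small_n(self):
        n = required_n(2.0, alpha=0.05, power=0.8)
        assert n <= 7
        assert simulated_power(2.0, n, n_sim=4000, seed=1) >= 0.8 - 0.03

    def test_returned_n_is_minimal(self):
        from statsmodels.stats.power import TTestIndPower

        n = required_n(0.8)
        solver = TTestIndPower()
        assert solver.power(effect_size=0.8, nobs1=n, alpha=0.05) >= 0.8
        assert solver.power(effect_size=0.8, nobs1=n - 1, alpha=0.05) < 0.8

    def test_monotone_in_power(self):
        assert required_n(1.0, power=0.999) > required_n(1.0, power=0.8)

    def test_nonpositive_effect_errors(self):
        with pytest.raises(ValueError):
            required_n(0.0)


class TestRecoveryOnset:
    def test_lag_three_hours_detected(self):
        """Groups elevated from 3 h on -> onset exactly 3 h."""
        tc = make_timecourse({0.0: 0, 10 / 60: 0, 45 / 60: 0, 1.0: 0,
                              2.0: 0, 3.0: 3.0, 4.0: 6.0}, seed=2)
        res = recovery_onset(tc, alpha=0.05)
        assert res.onset == 3.0
        assert res.p_value[3.0] < 0.05 < res.p_value[2.0]

    def test_negative_shift_is_not_onset(self):
        tc = make_timecourse({0.0: 0, 1.0: -5.0}, seed=3)
        assert recovery_onset(tc).onset is None

    def test_missing_zero_group_errors(self):
        tc = make_timecourse({0.0: 0, 1.0: 1}, seed=4)
        del tc.groups[0.0]
        with pytest.raises(ValueError, match="0-hour"):
            recovery_onset(tc)

    def test_null_false_onset_rate(self):
        """All groups null: false-onset rate bounded by 1 - (1-alpha)^k."""
        k = 6
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            tc = make_timecourse(
                {t: 0.0 for t in (0.0, 10 / 60, 45 / 60, 1.0, 2.0, 3.0, 4.0)},
                seed=100 + s)
            hits += recovery_onset(tc, alpha=0.05).onset is not None
        bound = 1 - 0.95**k
        assert hits / n_sim <= bound + 3 * np.sqrt(bound * (1 - bound) / n_sim)

    def test_alpha_monotonicity(self):
        """Shrinking alpha never yields an earlier onset."""
        for s in range(30):
            tc = make_timecourse({0.0: 0, 1.0: 0.4, 2.0: 0.6, 3.0: 0.9},
                                 n=10, seed=500 + s)
            loose = recovery_onset(tc, alpha=0.05).onset
            strict = recovery_onset(tc, alpha=0.005).onset
            if strict is not None:
                assert loose is not None and strict >= loose

    def test_baseline_recovery_flag(self):
        tc = make_timecourse({0.0: 0, 4.0: 6.0}, seed=6)
        res = recovery_onset(tc, baseline_mean=10.0)
        assert res.recovered_to_baseline is False
        res2 = recovery_onset(tc, baseline_mean=5.0)
        assert res2.recovered_to_baseline is True

    def test_holm_flag_never_earlier(self):
        tc = make_timecourse({0.0: 0, 1.0: 0.7, 2.0: 1.5, 3.0: 3.0},
                             n=10, seed=7)
        raw = recovery_onset(tc, alpha=0.05).onset
        holm = recovery_onset(tc, alpha=0.05, holm=True).onset
        if holm is not None:
            assert raw is not None and holm >= raw


class TestFullPipelineRecovery:
    def test_onset_recovered_in_18_of_20_replicates(self):
        """Simulation -> detection -> quantification -> onset returns the
        3-hour relocalization point in at least 18 of 20 replicate
        experiments (20 centrosomes per timepoint).

        Onset calling uses the Holm family-wise correction here: with five
        pre-recovery timepoints tested uncorrected at alpha = 0.05, an early
        false onset is expected in ~1 in 8 replicates by chance alone, which
        is a property of the testing scheme, not of the pipeline's parameter
        recovery."""
        from centrofish import (RunConfig, SceneConfig, WashoutKinetics,
                                simulate_timecourse)
        from centrofish.pipeline import quantify_scenes

        scene = SceneConfig()
        kinetics = WashoutKinetics()
        hits = 0
        for rep in range(20):
            scenes = simulate_timecourse(scene, kinetics, 10, seed=300 + rep)
            recs = quantify_scenes(scenes, scene, RunConfig(seed=300 + rep))
            tc = TimeCourse.from_records(recs, channel="rna")
            hits += recovery_onset(tc, alpha=0.05, holm=True).onset == 3.0
        assert hits >= 18


class TestTranslationTime:
    def test_worked_arithmetic(self):
        minutes, rounded = translation_time(3600, 6.0)
        assert minutes == pytest.approx(10.0)
        assert rounded == 10.0

    def test_packaged_orf_constant(self):
        minutes, rounded = translation_time()
        assert minutes == pytest.approx(3477 / 6 / 60)
        assert rounded == 10.0

    def test_rate_scaling(self):
        m1, _ = translation_time(3477, 6.0)
        m2, _ = translation_time(3477, 12.0)
        assert m2 == pytest.approx(m1 / 2)

    def test_validation(self):
        with pytest.raises(ValueError):
            translation_time(3477, 0.0)
        with pytest.raises(ValueError):
            translation_time(0, 6.0)
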