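"""Hierarchical paired time-course test and the Student-t tail."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gammaln

from plategrowth import (
    doubling_time_paired_test,
    paired_differences,
    paired_timecourse_test,
    student_t_two_sided_p,
)
from plategrowth.paired_stats import PairedDifferenceSet


def t_density(x, df):
    """Student-t pdf written out from the gamma-function formula (oracle)."""
    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)
    return math.exp(logc) * (1 + x * x / df) ** (-(df + 1) / 2)


def two_sided_p_by_quadrature(t_obs, df):
    tail, _ = quad(t_density, abs(t_obs), np.inf, args=(df,))
    return 2 * tail


def df2_closed_form(t_obs):
    return 1 - abs(t_obs) / math.sqrt(2 + t_obs**2)


def make_diffs(per_trial_matrices, times=None):
    trials = tuple(range(1, len(per_trial_matrices) + 1))
    mats = {j: np.asarray(m, float) for j, m in zip(trials, per_trial_matrices)}
    n_rep, n_t = next(iter(mats.values())).shape
    times = tuple(times or np.arange(12.0, 12.0 + 2 * n_t, 2.0))
    reps = tuple((1 + i // 3, 1 + i % 3) for i in range(n_rep))
    return PairedDifferenceSet(
        strain="WT", treatment_after="mixer", treatment_before="no_mix",
        trials=trials, replicates=reps, times=times, d=mats,
    )


class TestStudentTTail:
    def test_t_zero_gives_p_one(self):
        for df in (1, 2, 3, 10):
            assert student_t_two_sided_p(0.0, df) == pytest.approx(1.0)

    def test_df2_closed_form_sqrt2(self):
        assert student_t_two_sided_p(math.sqrt(2), 2) == pytest.approx(
            1 - math.sqrt(2) / 2, abs=1e-12
        )
        assert student_t_two_sided_p(math.sqrt(2), 2) == pytest.approx(0.29289, abs=5e-6)

    def test_df2_matches_closed_form_everywhere(self):
        for t in np.linspace(0, 10, 41):
            assert student_t_two_sided_p(t, 2) == pytest.approx(
                df2_closed_form(t), abs=1e-10
            )

    @pytest.mark.parametrize("df", [1, 2, 3, 10, 30])
    def test_matches_numeric_quadrature_of_the_density(self, df):
        for t in (0.0, 0.5, 1.0, 2.0, 3.4641, 5.0, 10.0):
            assert student_t_two_sided_p(t, df) == pytest.approx(
                two_sided_p_by_quadrature(t, df), abs=1e-8
            )

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            student_t_two_sided_p(1.0, 0)


class TestPairedDifferences:
    def _ln(self, plate):
        return plate.log_transform()

    def test_identical_conditions_give_zero(self, zero_noise_plate):
        diffs = paired_differences(self._ln(zero_noise_plate), "WT", "mixer", "no_mix")
        for mat in diffs.d.values():
            np.testing.assert_array_equal(mat, 0.0)
        assert len(diffs.replicates) == 9
        assert all(mat.shape == (9, 13) for mat in diffs.d.values())

    def test_constant_offset_appears_elementwise(self, zero_noise_plate):
        from dataclasses import replace as dreplace
        from plategrowth import PlateSet
        ln = self._ln(zero_noise_plate)
        shifted = PlateSet(
            [
                dreplace(c, od=c.od + 0.3) if c.key.treatment == "mixer" else c
                for c in ln
            ],
            metadata=ln.metadata,
        )
        diffs = paired_differences(shifted, "WT", "mixer", "no_mix")
        for mat in diffs.d.values():
            np.testing.assert_allclose(mat, 0.3, rtol=0, atol=1e-12)

    def test_swapped_arguments_negate(self, noisy_plate):
        ln = self._ln(noisy_plate)
        fwd = paired_differences(ln, "WT", "mixer", "no_mix")
        rev = paired_differences(ln, "WT", "no_mix", "mixer")
        for j in fwd.trials:
            np.testing.assert_array_equal(fwd.d[j], -rev.d[j])

    def test_requires_ln_space(self, noisy_plate):
        with pytest.raises(ValueError, match="ln-transform"):
            paired_differences(noisy_plate, "WT", "mixer", "no_mix")

    def test_unknown_labels(self, noisy_plate):
        ln = self._ln(noisy_plate)
        with pytest.raises(KeyError):
            paired_differences(ln, "nope", "mixer", "no_mix")
        with pytest.raises(KeyError):
            paired_differences(ln, "WT", "vortex", "no_mix")

    def test_mismatched_replicates_rejected(self, noisy_plate):
        from plategrowth import PlateSet
        ln = self._ln(noisy_plate)
        pruned = PlateSet(
            [c for c in ln
             if not (c.key.treatment == "mixer" and c.key.trial == 1
                     and c.key.replicate == (2, 2))],
        )
        with pytest.raises(ValueError, match="mismatched replicate"):
            paired_differences(pruned, "WT", "mixer", "no_mix")


class TestPairedTimecourseTest:
    def test_trial_means_1_2_3_oracle(self):
        # one replicate per trial whose constant rows make Dbar_j = 1, 2, 3
        diffs = make_diffs([np.full((1, 4), 1.0), np.full((1, 4), 2.0),
                            np.full((1, 4), 3.0)])
        res = paired_timecourse_test(diffs)
        assert res.effect == pytest.approx(2.0)
        assert res.effect_sd == pytest.approx(1.0)
        assert res.df == 2
        assert res.t_obs == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert res.t_obs == pytest.approx(3.4641, abs=1e-4)
        assert res.p == pytest.approx(df2_closed_form(res.t_obs), abs=1e-12)
        assert res.p == pytest.approx(0.0742, abs=1e-4)

    def test_all_zero_differences_degenerate(self, zero_noise_plate):
        diffs = paired_differences(
            zero_noise_plate.log_transform(), "WT", "mixer", "no_mix"
        )
        res = paired_timecourse_test(diffs)
        assert res.degenerate and res.t_obs == 0.0 and res.p == 1.0

    def test_nonzero_effect_with_zero_variance(self):
        diffs = make_diffs([np.full((2, 3), 0.5)] * 3)
        res = paired_timecourse_test(diffs)
        assert res.degenerate and res.p == 0.0 and math.isinf(res.t_obs)

    def test_negation_flips_t_keeps_p(self, noisy_plate):
        ln = noisy_plate.log_transform()
        fwd = paired_timecourse_test(paired_differences(ln, "WT", "mixer", "no_mix"))
        rev = paired_timecourse_test(paired_differences(ln, "WT", "no_mix", "mixer"))
        assert rev.t_obs == pytest.approx(-fwd.t_obs, rel=1e-12)
        assert rev.p == pytest.approx(fwd.p, rel=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        mats = [rng.normal(0, 1, (9, 13)) for _ in range(3)]
        base = paired_timecourse_test(make_diffs(mats))
        shifted = paired_timecourse_test(make_diffs([m + 0.7 for m in mats]))
        assert shifted.effect == pytest.approx(base.effect + 0.7, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        mats = [rng.normal(0, 1, (9, 13)) for _ in range(3)]
        base = paired_timecourse_test(make_diffs(mats))
        rows = rng.permutation(9)
        cols = rng.permutation(13)
        perm = paired_timecourse_test(make_diffs([m[rows][:, cols] for m in mats]))
        assert perm.effect == pytest.approx(base.effect, rel=1e-12)
        assert perm.t_obs == pytest.approx(base.t_obs, rel=1e-12)
        assert perm.p == pytest.approx(base.p, rel=1e-12)

    def test_replicate_time_average_uses_all_matched_points(self):
        # D_i averages the full grid, stationary phase included
        mat = np.zeros((1, 4))
        mat[0] = [0.0, 0.0, 0.0, 4.0]
        diffs = make_diffs([mat, mat + 1, mat + 2])
        res = paired_timecourse_test(diffs)
        assert res.trial_effects == pytest.approx((1.0, 2.0, 3.0))

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError, match=">= 2 trials"):
            paired_timecourse_test(make_diffs([np.zeros((2, 3))]))


class TestDoublingTimePairedTest:
    def test_identical_vectors_degenerate_p_one(self):
        res = doubling_time_paired_test([5.2, 5.3, 5.1], [5.2, 5.3, 5.1])
        assert res.degenerate and res.p == 1.0

    def test_differences_1_2_3_match_the_timecourse_oracle(self):
        res = doubling_time_paired_test([6.0, 7.0, 8.0], [5.0, 5.0, 5.0])
        assert res.t_obs == pytest.approx(3.4641, abs=1e-4)
        assert res.p == pytest.approx(0.0742, abs=1e-4)
        assert res.df == 2

    def test_swap_negates_t_keeps_p(self):
        a, b = [6.0, 7.0, 8.0], [5.0, 5.5, 5.2]
        fwd = doubling_time_paired_test(a, b)
        rev = doubling_time_paired_test(b, a)
        assert rev.t_obs == pytest.approx(-fwd.t_obs)
        assert rev.p == pytest.approx(fwd.p)

    @pytest.mark.parametrize("a,b", [([5.0], [5.1]), ([5, 6], [5, 6, 7])])
    def test_bad_shapes_rejected(self, a, b):
        with pytest.raises(ValueError):
            doubling_time_paired_test(a, b)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=3, max_size=6))
    def test_agrees_with_scipy_one_sample_t(self, diffs):
        # independent route: scipy.stats.ttest_1samp on the differences
        from scipy import stats

        b = np.zeros(len(diffs))
        if np.std(diffs, ddof=1) == 0:
            return
        res = doubling_time_paired_test(diffs, b)
        ref = stats.ttest_1samp(diffs, 0.0)
        assert res.t_obs == pytest.approx(ref.statistic, rel=1e-10, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-12)
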