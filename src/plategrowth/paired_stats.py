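"""Hierarchical paired time-course testing.

The study design measures the same replicate layout under two treatment
conditions on parallel plates, in ``n_bio`` independent trials.  Whether a
treatment shifts the growth trajectory is tested on ln(OD) through a
hierarchy of averages:

1. ``d_i(t) = a_i,after(t) - a_i,before(t)`` — paired difference for
   replicate *i* at matched time *t*;
2. ``D_i`` — mean of ``d_i(t)`` over all matched time points (one value per
   replicate);
3. ``Dbar_j`` — mean of the ``D_i`` within trial *j* (one value per trial);
4. ``Dbar_bio`` — mean of the trial-level values, with ``S_bio`` their
   sample SD (ddof = 1).

The null (no treatment effect) is tested with a one-sample two-sided
Student's t on the trial means: ``t_obs = Dbar_bio / (S_bio / sqrt(n_bio))``
with ``df = n_bio - 1`` (df = 2 for the canonical three-trial design).  The
same machinery tests trial-level doubling times pairwise between two
treatments.

With zero between-trial variance the t statistic is undefined; such results
are flagged degenerate and assigned p = 1 when the effect is exactly zero,
else p = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plate_model import PlateSet, SampleKey

__all__ = [
    "PairedDifferenceSet",
    "PairedTestResult",
    "paired_differences",
    "paired_timecourse_test",
    "doubling_time_paired_test",
    "student_t_two_sided_p",
]


@dataclass(frozen=True)
class PairedDifferenceSet:
    """Per-trial matrices of paired ln(OD) differences (after - before).

    ``d[j]`` has one row per replicate — ordered by (bio_rep, tech_rep) —
    and one column per matched time point.
    """

    strain: str
    treatment_after: str
    treatment_before: str
    trials: tuple[int, ...]
    replicates: tuple[tuple[int, int], ...]  # (bio_rep, tech_rep), shared across trials
    times: tuple[float, ...]
    d: dict[int, np.ndarray] = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of the hierarchical paired t-test.

    ``replicate_effects`` holds the per-replicate time-averaged differences
    D_i by trial (None for tests that start from trial-level values);
    ``trial_effects`` are the Dbar_j; ``effect`` is Dbar_bio; ``effect_sd``
    is S_bio.
    """

    trial_effects: tuple[float, ...]
    effect: float
    effect_sd: float
    n: int
    df: int
    t_obs: float
    p: float
    degenerate: bool
    replicate_effects: dict[int, np.ndarray] | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "Dbar_bio": self.effect,
            "Sbio": self.effect_sd,
            "t_obs": self.t_obs,
            "df": self.df,
            "p": self.p,
            "degenerate": self.degenerate,
        }


def student_t_two_sided_p(t_obs: float, df: float) -> float:
    """Two-sided tail probability 2*Pr(T_df >= |t_obs|) of Student's t.

    For df = 2 this equals the closed form 1 - |t| / sqrt(2 + t^2).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if math.isnan(t_obs):
        raise ValueError("t_obs is NaN")
    return float(2.0 * stats.t.sf(abs(t_obs), df))


def paired_differences(
    plate_set: PlateSet,
    strain: str,
    treatment_after: str,
    treatment_before: str,
) -> PairedDifferenceSet:
    """Elementwise ln(OD) differences, paired by (trial, bio_rep, tech_rep, time).

    The plate set must already be in ln space (see ``PlateSet.log_transform``)
    and both conditions must cover identical trials and replicate keys.
    """
    if not plate_set.log_space:
        raise ValueError("paired differences require ln-transformed curves; "
                         "call PlateSet.log_transform() first")
    if strain not in plate_set.strains():
        raise KeyError(f"unknown strain {strain!r}")
    for tr in (treatment_after, treatment_before):
        if tr not in plate_set.treatments():
            raise KeyError(f"unknown treatment {tr!r}")

    trials = tuple(
        sorted({k.trial for k in plate_set.keys()
                if k.strain == strain and k.treatment in (treatment_after, treatment_before)})
    )
    d: dict[int, np.ndarray] = {}
    replicates: tuple[tuple[int, int], ...] | None = None
    for trial in trials:
        after_keys = plate_set.replicate_keys(strain, treatment_after, trial)
        before_keys = plate_set.replicate_keys(strain, treatment_before, trial)
        reps_after = tuple(k.replicate for k in after_keys)
        reps_before = tuple(k.replicate for k in before_keys)
        if reps_after != reps_before or not reps_after:
            raise ValueError(
                f"mismatched replicate sets for {strain} trial {trial}: "
                f"{treatment_after}={reps_after}, {treatment_before}={reps_before}"
            )
        if replicates is None:
            replicates = reps_after
        elif reps_after != replicates:
            raise ValueError(
                f"replicate sets differ across trials for {strain}: "
                f"{reps_after} vs {replicates}"
            )
        a = np.stack([plate_set.get(k).od for k in after_keys])
        b = np.stack([plate_set.get(k).od for k in before_keys])
        d[trial] = a - b
    assert replicates is not None
    return PairedDifferenceSet(
        strain=strain,
        treatment_after=treatment_after,
        treatment_before=treatment_before,
        trials=trials,
        replicates=replicates,
        times=plate_set.schedule.times,
        d=d,
    )


def _one_sample_t(
    trial_effects: np.ndarray,
    replicate_effects: dict[int, np.ndarray] | None = None,
) -> PairedTestResult:
    n = len(trial_effects)
    if n < 2:
        raise ValueError(f"need >= 2 trials, got {n}")
    effect = float(np.mean(trial_effects))
    sd = float(np.std(trial_effects, ddof=1))
    df = n - 1
    if sd == 0.0:
        degenerate = True
        if effect == 0.0:
            t_obs, p = 0.0, 1.0
        else:
            t_obs, p = math.copysign(math.inf, effect), 0.0
    else:
        degenerate = False
        t_obs = effect / (sd / math.sqrt(n))
        p = student_t_two_sided_p(t_obs, df)
    return PairedTestResult(
        trial_effects=tuple(float(x) for x in trial_effects),
        effect=effect,
        effect_sd=sd,
        n=n,
        df=df,
        t_obs=t_obs,
        p=p,
        degenerate=degenerate,
        replicate_effects=replicate_effects,
    )


def paired_timecourse_test(diffs: PairedDifferenceSet) -> PairedTestResult:
    """Run the full D_i -> Dbar_j -> Dbar_bio hierarchy on a difference set."""
    if diffs.n_trials < 2:
        raise ValueError(f"need >= 2 trials, got {diffs.n_trials}")
    n_times = len(diffs.times)
    replicate_effects: dict[int, np.ndarray] = {}
    trial_means = []
    for trial in diffs.trials:
        mat = diffs.d[trial]
        if mat.ndim != 2 or mat.shape[1] != n_times:
            raise ValueError(f"ragged difference grid in trial {trial}: {mat.shape}")
        D_i = mat.mean(axis=1)  # time-average per replicate, all matched points
        replicate_effects[trial] = D_i
        trial_means.append(D_i.mean())
    return _one_sample_t(np.asarray(trial_means), replicate_effects)


def doubling_time_paired_test(
    td_by_trial_a, td_by_trial_b
) -> PairedTestResult:
    """Paired t-test of trial-level mean doubling times between two treatments.

    Operates on the per-trial differences (a - b) with df = n_trials - 1.
    """
    a = np.asarray(td_by_trial_a, dtype=float)
    b = np.asarray(td_by_trial_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"trial vectors must be 1-D of equal length: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError(f"need >= 2 trials, got {len(a)}")
    return _one_sample_t(a - b)
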