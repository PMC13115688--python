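"""End-to-end orchestration: simulate -> kinetics -> paired tests -> FDR -> reports.

``run_analysis`` turns one PlateSet into four tabular reports:

* **kinetics** — per-well growth rate, doubling time, R^2 and fit window;
* **td_summary** — per strain x treatment mean doubling time with SDs both
  across all replicate estimates and across trial means, plus the percent
  difference versus the reference treatment;
* **timecourse** — the hierarchical paired time-course test per strain x
  comparison, BH-FDR adjusted under the configured family policy;
* **td_tests** — the trial-level paired doubling-time test per strain x
  comparison, likewise adjusted;
* **curve_summary** — mean +/- SD ln(OD) per strain x treatment x time,
  aggregated over trial means (error bars mean "+/- SD, N = trials").

``run_null_calibration`` and ``run_power_curve`` are Monte-Carlo operating-
characteristic studies of the paired test on synthetic designs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import IO, Sequence

import numpy as np
import pandas as pd

from . import fdr as fdr_mod
from .kinetics import WindowConfig, estimate_growth_fit, percent_diff
from .paired_stats import (
    doubling_time_paired_test,
    paired_differences,
    paired_timecourse_test,
)
from .plate_model import PlateSet
from .synthetic_growth import SimDesign, simulate_plate_set

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "OperatingCharacteristics",
    "run_analysis",
    "run_null_calibration",
    "run_power_curve",
    "render_report",
]

DEFAULT_COMPARISONS = (("mixer", "no_mix"), ("pipette", "no_mix"), ("pipette", "mixer"))


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one analysis run."""

    window: WindowConfig = WindowConfig()
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    reference_treatment: str = "no_mix"
    fdr_policy: str = "per_comparison"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fdr_policy not in fdr_mod.POLICIES:
            raise ValueError(f"unknown fdr policy {self.fdr_policy!r}")


@dataclass
class AnalysisResult:
    """Bundle of the tabular reports produced by ``run_analysis``."""

    kinetics: pd.DataFrame
    td_summary: pd.DataFrame
    timecourse: pd.DataFrame
    td_tests: pd.DataFrame
    curve_summary: pd.DataFrame
    config: AnalysisConfig


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the paired test."""

    scenario: str
    n_sims: int
    alpha: float
    rejection_rate_raw: float
    rejection_rate_fdr: float
    mean_pct_diff: float | None = None

    @property
    def mc_se(self) -> float:
        r = self.rejection_rate_raw
        return math.sqrt(r * (1.0 - r) / self.n_sims)


def _comparison_label(after: str, before: str) -> str:
    return f"{after}_vs_{before}"


def _check_conditions(plate_set: PlateSet, config: AnalysisConfig) -> None:
    present = set(plate_set.treatments())
    needed = {t for pair in config.comparisons for t in pair}
    needed.add(config.reference_treatment)
    missing = needed - present
    if missing:
        raise ValueError(f"plate set lacks treatment(s) {sorted(missing)}")


def run_analysis(plate_set: PlateSet, config: AnalysisConfig = AnalysisConfig()) -> AnalysisResult:
    """Run the full analysis on a plate set (raw OD space).

    Deterministic given inputs and config.  Wells whose best window misses
    the R^2 threshold are flagged in the kinetics table, not dropped.
    """
    _check_conditions(plate_set, config)
    ln_set = plate_set.log_transform() if not plate_set.log_space else plate_set
    strains = plate_set.strains()
    trials = plate_set.trials()

    # --- per-well kinetics ---------------------------------------------------
    kin_rows = []
    td_by = {}  # (strain, treatment, trial) -> list of td
    for key in plate_set.keys():
        fit = estimate_growth_fit(plate_set.get(key), config.window)
        kin_rows.append({
            "strain": key.strain, "treatment": key.treatment, "trial": key.trial,
            "bio_rep": key.bio_rep, "tech_rep": key.tech_rep,
            "mu": fit.slope, "td": fit.td, "r2": fit.r2,
            "window_start": fit.window.start, "window_end": fit.window.end,
            "flagged": fit.below_threshold_flag,
        })
        td_by.setdefault((key.strain, key.treatment, key.trial), []).append(fit.td)
    kinetics = pd.DataFrame(kin_rows)

    # --- doubling-time summary ----------------------------------------------
    summary_rows = []
    trial_mean_td = {}  # (strain, treatment) -> np.ndarray over trials
    for strain in strains:
        for treatment in plate_set.treatments():
            per_trial = [np.mean(td_by[(strain, treatment, j)]) for j in trials]
            pooled = np.concatenate([td_by[(strain, treatment, j)] for j in trials])
            trial_mean_td[(strain, treatment)] = np.asarray(per_trial)
            summary_rows.append({
                "strain": strain, "treatment": treatment,
                "td_mean": float(pooled.mean()),
                "td_sd_replicates": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
                "td_sd_trials": float(np.std(per_trial, ddof=1)) if len(per_trial) > 1 else 0.0,
            })
    td_summary = pd.DataFrame(summary_rows)
    ref_mean = td_summary.set_index(["strain", "treatment"])["td_mean"]
    td_summary["pct_diff_vs_ref"] = [
        percent_diff(row.td_mean, ref_mean[(row.strain, config.reference_treatment)])
        for row in td_summary.itertuples()
    ]

    # --- paired tests ---------------------------------------------------------
    tc_rows, td_rows = [], []
    for strain in strains:
        for after, before in config.comparisons:
            label = _comparison_label(after, before)
            diffs = paired_differences(ln_set, strain, after, before)
            res = paired_timecourse_test(diffs)
            tc_rows.append({
                "strain": strain, "comparison": label,
                "Dbar_bio": res.effect, "Sbio": res.effect_sd,
                "t_obs": res.t_obs, "df": res.df, "p_raw": res.p,
                "degenerate": res.degenerate,
            })
            td_res = doubling_time_paired_test(
                trial_mean_td[(strain, after)], trial_mean_td[(strain, before)]
            )
            td_rows.append({
                "strain": strain, "comparison": label,
                "td_diff_mean": td_res.effect, "td_diff_sd": td_res.effect_sd,
                "t_obs": td_res.t_obs, "df": td_res.df, "p_raw": td_res.p,
                "degenerate": td_res.degenerate,
            })
    timecourse = _with_fdr(pd.DataFrame(tc_rows), config)
    td_tests = _with_fdr(pd.DataFrame(td_rows), config)

    # --- mean +/- SD ln(OD) curves (trial-level aggregation) ------------------
    cs_rows = []
    times = np.asarray(plate_set.schedule.times)
    for strain in strains:
        for treatment in plate_set.treatments():
            per_trial = []
            for j in trials:
                keys = ln_set.replicate_keys(strain, treatment, j)
                per_trial.append(np.stack([ln_set.get(k).od for k in keys]).mean(axis=0))
            mat = np.stack(per_trial)  # trials x times
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros_like(mean)
            for t, m, s in zip(times, mean, sd):
                cs_rows.append({
                    "strain": strain, "treatment": treatment, "time_h": float(t),
                    "mean_ln_od": float(m), "sd_ln_od": float(s),
                    "n_trials": len(trials),
                })
    curve_summary = pd.DataFrame(cs_rows)

    return AnalysisResult(
        kinetics=kinetics,
        td_summary=td_summary,
        timecourse=timecourse,
        td_tests=td_tests,
        curve_summary=curve_summary,
        config=config,
    )


def _with_fdr(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    labelled = [((row.strain, row.comparison), row.p_raw) for row in df.itertuples()]
    families = fdr_mod.apply_family_policy(labelled, policy=config.fdr_policy,
                                           alpha=config.alpha)
    by_id = {item.id: (item.q, item.significant, fam.policy_label, fam.m)
             for fam in families for item in fam.items}
    q, sig, pol, m = zip(*(by_id[(r.strain, r.comparison)] for r in df.itertuples()))
    return df.assign(q=q, significant=sig, family_policy=pol, m=m)


# ---------------------------------------------------------------------------
# Operating-characteristic studies
# ---------------------------------------------------------------------------

def _sim_seeds(seed: int, n_sims: int) -> np.ndarray:
    """Derive one sub-2^31 design seed per simulation from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return ss.generate_state(n_sims, dtype=np.uint32) & 0x7FFFFFFF


def _design_pairs(design: SimDesign) -> list[tuple[str, str]]:
    names = list(design.treatments)
    return [(b, a) for i, a in enumerate(names) for b in names[i + 1:]]


def run_null_calibration(
    design: SimDesign,
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
) -> OperatingCharacteristics:
    """Type-I error of the paired time-course test under the null design.

    Each simulation draws a fresh plate set, runs the test for every strain
    and treatment pair, and counts rejections at raw p < alpha and at
    BH q < alpha (within-simulation family).
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    if any(e.td_multiplier != 1.0 for e in design.treatments.values()):
        warnings.warn("design is not null (some td_multiplier != 1); "
                      "calibration measures power, not level", stacklevel=2)
    seeds = _sim_seeds(seed, n_sims)
    pairs = _design_pairs(design)
    n_tests = raw_rej = fdr_rej = 0
    for s in seeds:
        ln_set = simulate_plate_set(design.with_seed(int(s))).log_transform()
        labelled = []
        for strain in ln_set.strains():
            for after, before in pairs:
                res = paired_timecourse_test(
                    paired_differences(ln_set, strain, after, before)
                )
                labelled.append(((strain, _comparison_label(after, before)), res.p))
        n_tests += len(labelled)
        raw_rej += sum(p < alpha for _, p in labelled)
        fams = fdr_mod.apply_family_policy(labelled, policy="pooled", alpha=alpha)
        fdr_rej += sum(f.n_significant() for f in fams)
    return OperatingCharacteristics(
        scenario="null",
        n_sims=n_sims,
        alpha=alpha,
        rejection_rate_raw=raw_rej / n_tests,
        rejection_rate_fdr=fdr_rej / n_tests,
    )


def run_power_curve(
    design: SimDesign,
    effect_multipliers: Sequence[float],
    n_sims: int,
    seed: int,
    effect_treatment: str | None = None,
    alpha: float = 0.05,
    window: WindowConfig = WindowConfig(),
) -> list[OperatingCharacteristics]:
    """Rejection rate and mean estimated %Dt_d versus effect size.

    For each multiplier, the *effect_treatment* (default: the first
    non-reference treatment of the design) gets that doubling-time factor
    while the others stay null; the paired time-course test supplies the
    rejection rate and the kinetics fits supply the estimated percent
    difference in doubling time against the first treatment.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    mults = [float(m) for m in effect_multipliers]
    if any(m <= 0 for m in mults):
        raise ValueError("multipliers must be > 0")
    names = list(design.treatments)
    if len(names) < 2:
        raise ValueError("power study needs >= 2 treatments")
    reference = names[0]
    target = effect_treatment or names[1]
    if target not in design.treatments or target == reference:
        raise ValueError(f"effect treatment {target!r} invalid for this design")

    out = []
    for mult in mults:
        treatments = {
            name: replace(e, td_multiplier=mult if name == target else 1.0)
            for name, e in design.treatments.items()
        }
        d_eff = replace(design, treatments=treatments)
        seeds = _sim_seeds(seed, n_sims)
        rej = fdr_rej = 0
        pct_diffs = []
        for s in seeds:
            plate = simulate_plate_set(d_eff.with_seed(int(s)))
            ln_set = plate.log_transform()
            ps = []
            for strain in ln_set.strains():
                res = paired_timecourse_test(
                    paired_differences(ln_set, strain, target, reference)
                )
                ps.append(res.p)
            rej += sum(p < alpha for p in ps)
            q = fdr_mod.bh_adjust(ps)
            fdr_rej += int(np.sum(q < alpha))
            td = {name: [] for name in (reference, target)}
            for key in plate.keys():
                if key.treatment in td:
                    td[key.treatment].append(estimate_growth_fit(plate.get(key), window).td)
            pct_diffs.append(
                percent_diff(float(np.mean(td[target])), float(np.mean(td[reference])))
            )
        n_tests = n_sims * len(design.strains)
        out.append(OperatingCharacteristics(
            scenario=f"multiplier={mult:g}",
            n_sims=n_sims,
            alpha=alpha,
            rejection_rate_raw=rej / n_tests,
            rejection_rate_fdr=fdr_rej / n_tests,
            mean_pct_diff=float(np.mean(pct_diffs)),
        ))
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_THREE_DECIMALS = ("p_raw", "q", "p")


def render_report(report: pd.DataFrame, fmt: str, dest: IO) -> None:
    """Write a report table as TSV (p/q to 3 decimals) or JSON (full precision)."""
    if fmt == "tsv":
        df = report.copy()
        for col in _THREE_DECIMALS:
            if col in df.columns:
                df[col] = df[col].map(lambda v: f"{v:.3f}")
        df.to_csv(dest, sep="\t", index=False)
    elif fmt == "json":
        records = report.to_dict(orient="records")
        json.dump(records, dest, indent=1, default=_json_default)
        dest.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}; expected 'tsv' or 'json'")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report_json(source: IO) -> pd.DataFrame:
    """Inverse of ``render_report(..., 'json', ...)``."""
    return pd.DataFrame(json.load(source))
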