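"""Synthetic 96-well growth-assay generator.

Emulates the replicate structure of a three-trial plate study: for every
strain x treatment condition, ``n_trials x n_bio x n_tech`` wells are
simulated on a shared measurement schedule.  The mean curve is piecewise
log-linear — flat lag at ln(n0) up to ``t_lag``, exponential growth at rate
``mu`` (so ln OD rises linearly), then a plateau at ln(k) once the carrying
capacity is reached.  Exact ln-linearity inside the exponential phase makes
the downstream window-selection estimator provably exact on noiseless data.

Replicate variability acts multiplicatively on the growth rate through a
hierarchy of log-normal perturbations::

    mu_eff = mu * exp(eps_trial + eps_bio + eps_tech) / td_multiplier

where the trial effect is shared by all wells of a strain in one trial (a
"day" effect — one culture is split across the treatment plates), the
biological effect is shared by the technical replicates of one culture, and
the technical effect is per well.  Measurement noise is additive Gaussian on
ln(OD).  A treatment's ``td_multiplier`` scales doubling time (1.10 means
10% slower growth).

Randomness is counter-based: every effect is drawn from its own
``numpy.random.SeedSequence(seed, spawn_key=...)`` stream keyed by the
sample labels, so the same design and seed reproduce a bit-identical plate
set and adding a strain or treatment never perturbs another's draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .plate_model import (
    GrowthCurve,
    PlateSet,
    SampleKey,
    TimePointSchedule,
    default_schedule,
)

__all__ = [
    "GrowthParams",
    "NoiseModel",
    "TreatmentEffect",
    "SimDesign",
    "default_design",
    "mean_ln_od",
    "simulate_plate_set",
    "DEFAULT_STRAINS",
]

#: Default study strains: wild type plus seven single-gene deletions.
DEFAULT_STRAINS = ("WT", "ssb3", "dad2", "rhp55", "arp42", "apl6", "clr5", "erd2")


@dataclass(frozen=True)
class GrowthParams:
    """Per-strain kinetics of the piecewise log-linear growth model.

    Parameters
    ----------
    n0 : initial OD600 of the diluted culture (default 0.05).
    t_lag : end of the lag phase, hours (default 12).
    mu : exponential growth rate, 1/h (default ln2/5.2, a 5.2 h doubling time).
    k : plateau (carrying-capacity) OD600 (default 2.0).
    """

    n0: float = 0.05
    t_lag: float = 12.0
    mu: float = math.log(2.0) / 5.2
    k: float = 2.0

    def __post_init__(self) -> None:
        if not (self.n0 > 0):
            raise ValueError(f"n0 must be > 0, got {self.n0}")
        if not (self.k > self.n0):
            raise ValueError(f"k must exceed n0, got k={self.k}, n0={self.n0}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be finite and > 0, got {self.mu}")
        if self.t_lag < 0:
            raise ValueError(f"t_lag must be >= 0, got {self.t_lag}")

    @property
    def doubling_time(self) -> float:
        """Implied doubling time ln2/mu, hours per cycle."""
        return math.log(2.0) / self.mu

    @property
    def t_sat(self) -> float:
        """Time at which the mean curve reaches the plateau."""
        return self.t_lag + (math.log(self.k) - math.log(self.n0)) / self.mu


@dataclass(frozen=True)
class NoiseModel:
    """Hierarchical noise magnitudes.

    sigma_trial, sigma_bio, sigma_tech are SDs of the Gaussian perturbations
    of ln(mu) at trial, biological-replicate and technical-replicate level;
    sigma_meas is the SD of additive noise on each ln(OD) reading.
    """

    sigma_trial: float = 0.01
    sigma_bio: float = 0.01
    sigma_tech: float = 0.005
    sigma_meas: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sigma_trial", "sigma_bio", "sigma_tech", "sigma_meas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (
            self.sigma_trial == self.sigma_bio
            == self.sigma_tech == self.sigma_meas == 0.0
        )


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative effect of a treatment on doubling time.

    ``td_multiplier`` of 1.10 lengthens doubling time by 10% (mu is divided
    by the factor); 1.0 is the null.
    """

    td_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (self.td_multiplier > 0):
            raise ValueError(f"td_multiplier must be > 0, got {self.td_multiplier}")


@dataclass(frozen=True)
class SimDesign:
    """Full layout of a simulated study."""

    strains: Mapping[str, GrowthParams]
    treatments: Mapping[str, TreatmentEffect]
    noise: NoiseModel = NoiseModel()
    n_trials: int = 3
    n_bio: int = 3
    n_tech: int = 3
    schedule: TimePointSchedule = field(default_factory=default_schedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strains or not self.treatments:
            raise ValueError("design needs at least one strain and one treatment")
        for n, v in (("n_trials", self.n_trials), ("n_bio", self.n_bio),
                     ("n_tech", self.n_tech)):
            if v < 1:
                raise ValueError(f"{n} must be >= 1, got {v}")

    @property
    def curves_per_condition_per_trial(self) -> int:
        return self.n_bio * self.n_tech

    def with_seed(self, seed: int) -> "SimDesign":
        return replace(self, seed=int(seed))


def default_design(
    td_multipliers: Mapping[str, float] | None = None,
    seed: int = 0,
    strains: tuple[str, ...] = DEFAULT_STRAINS,
) -> SimDesign:
    """The default eight-strain, three-treatment study layout.

    All strains share the default kinetics; ``td_multipliers`` overrides the
    per-treatment doubling-time factor (default: null effect everywhere).
    """
    mult = dict(td_multipliers or {})
    treatments = {
        name: TreatmentEffect(td_multiplier=mult.get(name, 1.0))
        for name in ("no_mix", "mixer", "pipette")
    }
    return SimDesign(
        strains={s: GrowthParams() for s in strains},
        treatments=treatments,
        seed=seed,
    )


def mean_ln_od(params: GrowthParams, t) -> np.ndarray | float:
    """Noise-free mean ln(OD) of the piecewise model at time(s) *t*.

    Continuous and non-decreasing: ln(n0) through the lag phase, linear with
    slope ``mu`` through the exponential phase, ln(k) on the plateau.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    ln_n0 = math.log(params.n0)
    ln_k = math.log(params.k)
    out = ln_n0 + params.mu * np.clip(t_arr - params.t_lag, 0.0, None)
    out = np.minimum(out, ln_k)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _stream(seed: int, *key_parts: object) -> np.random.Generator:
    """Independent generator keyed by (seed, labels) via a SeedSequence spawn key."""
    parts = tuple(
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in key_parts
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=parts))


def _normal(rng: np.random.Generator, sigma: float) -> float:
    # scale 0 must yield exactly 0.0 regardless of seed
    return float(rng.standard_normal()) * sigma


def simulate_plate_set(design: SimDesign) -> PlateSet:
    """Simulate every well of *design* into a PlateSet.

    Deterministic: identical design and seed give a bit-identical PlateSet.
    Metadata records the seed and the generator parameters.
    """
    times = design.schedule.as_array()
    n_times = len(times)
    curves = []
    for strain, params in design.strains.items():
        for trial in range(1, design.n_trials + 1):
            eps_trial = _normal(
                _stream(design.seed, 1, strain, trial), design.noise.sigma_trial
            )
            for bio in range(1, design.n_bio + 1):
                eps_bio = _normal(
                    _stream(design.seed, 2, strain, trial, bio),
                    design.noise.sigma_bio,
                )
                for treatment, effect in design.treatments.items():
                    for tech in range(1, design.n_tech + 1):
                        eps_tech = _normal(
                            _stream(design.seed, 3, strain, treatment, trial, bio, tech),
                            design.noise.sigma_tech,
                        )
                        mu_eff = (
                            params.mu
                            * math.exp(eps_trial + eps_bio + eps_tech)
                            / effect.td_multiplier
                        )
                        p_eff = replace(params, mu=mu_eff)
                        ln_od = np.asarray(mean_ln_od(p_eff, times))
                        if design.noise.sigma_meas > 0:
                            rng = _stream(
                                design.seed, 4, strain, treatment, trial, bio, tech
                            )
                            ln_od = ln_od + rng.standard_normal(n_times) * design.noise.sigma_meas
                        key = SampleKey(strain, treatment, trial, bio, tech)
                        curves.append(
                            GrowthCurve(key, design.schedule, np.exp(ln_od))
                        )
    metadata = {
        "generator": "plategrowth.synthetic_growth",
        "seed": design.seed,
        "n_trials": design.n_trials,
        "n_bio": design.n_bio,
        "n_tech": design.n_tech,
        "noise": {
            "sigma_trial": design.noise.sigma_trial,
            "sigma_bio": design.noise.sigma_bio,
            "sigma_tech": design.noise.sigma_tech,
            "sigma_meas": design.noise.sigma_meas,
        },
        "strains": {
            s: {"n0": p.n0, "t_lag": p.t_lag, "mu": p.mu, "k": p.k}
            for s, p in design.strains.items()
        },
        "treatments": {
            name: {"td_multiplier": e.td_multiplier}
            for name, e in design.treatments.items()
        },
    }
    return PlateSet(curves, metadata=metadata)
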