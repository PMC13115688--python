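"""Shared fixtures: small synthetic designs and hand-built plate sets."""

from __future__ import annotations

import numpy as np
import pytest

from plategrowth import (
    GrowthCurve,
    GrowthParams,
    NoiseModel,
    PlateSet,
    SampleKey,
    SimDesign,
    TreatmentEffect,
    default_schedule,
    simulate_plate_set,
)

ZERO_NOISE = NoiseModel(sigma_trial=0, sigma_bio=0, sigma_tech=0, sigma_meas=0)


@pytest.fixture
def two_treatment_design() -> SimDesign:
    """One strain, two treatments, the canonical 3x3x3 replicate layout."""
    return SimDesign(
        strains={"WT": GrowthParams()},
        treatments={"no_mix": TreatmentEffect(), "mixer": TreatmentEffect()},
        seed=42,
    )


@pytest.fixture
def zero_noise_design(two_treatment_design) -> SimDesign:
    from dataclasses import replace

    return replace(two_treatment_design, noise=ZERO_NOISE)


@pytest.fixture
def zero_noise_plate(zero_noise_design) -> PlateSet:
    return simulate_plate_set(zero_noise_design)


@pytest.fixture
def noisy_plate(two_treatment_design) -> PlateSet:
    return simulate_plate_set(two_treatment_design)


@pytest.fixture
def tiny_plate() -> PlateSet:
    """Hand-built two-well plate set on a short schedule."""
    sched = default_schedule()
    t = sched.as_array()
    curves = []
    for i, treatment in enumerate(("no_mix", "mixer")):
        od = 0.05 * np.exp(0.13 * np.clip(t - 12, 0, 8)) * (1.0 + 0.1 * i)
        curves.append(
            GrowthCurve(SampleKey("WT", treatment, 1, 1, 1), sched, od)
        )
    return PlateSet(curves, metadata={"origin": "conftest"})
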