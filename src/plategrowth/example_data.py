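"""Worked-example inputs: raw p-values for an eight-strain mixing study.

Twenty-four paired time-course tests — eight fission-yeast strains (wild
type and seven deletion mutants) under three pairwise mixing comparisons —
used by the documentation examples and regression checks of the FDR stage.
"""

from __future__ import annotations

__all__ = ["EXAMPLE_STRAINS", "EXAMPLE_COMPARISONS", "EXAMPLE_RAW_PVALUES"]

EXAMPLE_STRAINS = ("WT", "ssb3", "dad2", "rhp55", "arp42", "apl6", "clr5", "erd2")

EXAMPLE_COMPARISONS = ("no_vs_mix", "no_vs_pipette", "mix_vs_pipette")

#: Raw two-sided p-values keyed by (strain, comparison).
EXAMPLE_RAW_PVALUES: dict[tuple[str, str], float] = {
    ("WT", "no_vs_mix"): 0.667,
    ("WT", "no_vs_pipette"): 0.257,
    ("WT", "mix_vs_pipette"): 0.054,
    ("ssb3", "no_vs_mix"): 0.863,
    ("ssb3", "no_vs_pipette"): 0.227,
    ("ssb3", "mix_vs_pipette"): 0.030,
    ("dad2", "no_vs_mix"): 0.931,
    ("dad2", "no_vs_pipette"): 0.235,
    ("dad2", "mix_vs_pipette"): 0.034,
    ("rhp55", "no_vs_mix"): 0.306,
    ("rhp55", "no_vs_pipette"): 0.496,
    ("rhp55", "mix_vs_pipette"): 0.167,
    ("arp42", "no_vs_mix"): 0.067,
    ("arp42", "no_vs_pipette"): 0.066,
    ("arp42", "mix_vs_pipette"): 0.395,
    ("apl6", "no_vs_mix"): 0.603,
    ("apl6", "no_vs_pipette"): 0.566,
    ("apl6", "mix_vs_pipette"): 0.965,
    ("clr5", "no_vs_mix"): 0.072,
    ("clr5", "no_vs_pipette"): 0.050,
    ("clr5", "mix_vs_pipette"): 0.042,
    ("erd2", "no_vs_mix"): 0.482,
    ("erd2", "no_vs_pipette"): 0.426,
    ("erd2", "mix_vs_pipette"): 0.044,
}


def family(comparison: str) -> dict[str, float]:
    """The eight raw p-values of one comparison type, keyed by strain."""
    if comparison not in EXAMPLE_COMPARISONS:
        raise KeyError(f"unknown comparison {comparison!r}")
    return {
        strain: EXAMPLE_RAW_PVALUES[(strain, comparison)]
        for strain in EXAMPLE_STRAINS
    }
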