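"""Benjamini-Hochberg step-up false-discovery-rate adjustment.

Raw p-values are sorted ascending (stable, so ties keep input order) and
assigned ranks i = 1..m; the raw adjusted value is q(i) = min(1, m*p(i)/i),
then monotonicity is enforced from the largest p downward via
q(i) = min(q(i), q(i+1)).  A test is significant when q < alpha
(default 0.05).

Two family policies are supported for a strains x comparisons grid of
tests: ``per_comparison`` adjusts each comparison type across strains as
its own family (m = number of strains), and ``pooled`` adjusts all tests as
one family (m = strains x comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = ["FdrItem", "FdrFamily", "bh_adjust", "apply_family_policy"]

POLICIES = ("per_comparison", "pooled")


@dataclass(frozen=True)
class FdrItem:
    """One test inside a family: its label, raw p, rank, q, and call."""

    id: tuple[str, str]  # (strain, comparison)
    p_raw: float
    rank: int
    q: float
    significant: bool


@dataclass(frozen=True)
class FdrFamily:
    """A jointly adjusted family of tests."""

    items: tuple[FdrItem, ...]
    m: int
    alpha: float
    policy_label: str

    def n_significant(self) -> int:
        return sum(item.significant for item in self.items)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values, aligned to the input order and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, m * p[order] / ranks)
    # enforce monotone non-decreasing q in p, from largest p downward
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _ranks(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def apply_family_policy(
    results: Iterable[tuple[tuple[str, str], float]],
    policy: str = "per_comparison",
    alpha: float = 0.05,
) -> list[FdrFamily]:
    """Group labelled p-values into families and adjust each independently.

    *results* yields ``((strain, comparison), p_raw)`` pairs.  Policy
    ``per_comparison`` makes one family per comparison type across strains;
    ``pooled`` makes a single family of every test.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    items = list(results)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (strain, comparison) labels")

    if policy == "pooled":
        groups = {"pooled": items}
    else:
        groups = {}
        for (strain, comparison), p in items:
            groups.setdefault(comparison, []).append(((strain, comparison), p))

    families = []
    for name, members in groups.items():
        p = np.array([pv for _, pv in members])
        q = bh_adjust(p)
        ranks = _ranks(p)
        fam_items = tuple(
            FdrItem(
                id=lab,
                p_raw=float(pv),
                rank=int(r),
                q=float(qv),
                significant=bool(qv < alpha),
            )
            for (lab, pv), r, qv in zip(members, ranks, q)
        )
        families.append(
            FdrFamily(items=fam_items, m=len(members), alpha=alpha,
                      policy_label=f"{policy}:{name}" if policy == "per_comparison" else policy)
        )
    return families
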