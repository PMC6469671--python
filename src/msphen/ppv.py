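"""Simulated chart-review adjudication and positive-predictive-value (PPV).

A validation study for a phenotyping algorithm samples classified cases,
adjudicates each against an external source of truth (questionnaires or
chart review in a real study; the generator's ground-truth labels here,
optionally flipped with a configurable adjudication error rate), and
reports the fraction confirmed true — overall and per certainty tier.
The overall PPV is, by construction, the tier-size-weighted average of the
tier PPVs on the same sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .classify import TIER_GROUPS, CaseClassification, Tier

__all__ = [
    "AdjudicationSample",
    "PpvResult",
    "tier_group",
    "sample_for_adjudication",
    "compute_ppv",
    "wilson_interval",
]


def tier_group(tier: Tier) -> str:
    """Coarse certainty stratum: probable / possible / unlikely."""
    return TIER_GROUPS[tier]


@dataclass(frozen=True)
class AdjudicationSample:
    patient_id: str
    tier: str  # stratum label at sampling
    adjudicated_ms: bool


def sample_for_adjudication(
    classifications: Iterable[CaseClassification],
    truth: Mapping[str, bool],
    n_per_tier: int,
    seed: int = 0,
    adjudication_error: float = 0.0,
    grouping: Callable[[Tier], str] = tier_group,
) -> list[AdjudicationSample]:
    """Stratified uniform sample of classified cases, without replacement.

    Classified cases of every tier, including UNLIKELY, may be sampled;
    NON_CASE patients never are.  A stratum smaller than *n_per_tier* is
    sampled in full, with a warning.
    """
    if n_per_tier < 1:
        raise ValueError("n_per_tier must be >= 1")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[CaseClassification]] = {}
    for cls in classifications:
        if cls.tier == Tier.NON_CASE:
            continue
        strata.setdefault(grouping(cls.tier), []).append(cls)
    out: list[AdjudicationSample] = []
    for label in sorted(strata):
        members = sorted(strata[label], key=lambda c: c.patient_id)
        if len(members) <= n_per_tier:
            if len(members) < n_per_tier:
                warnings.warn(
                    f"stratum {label!r} has only {len(members)} members; sampling all",
                    stacklevel=2,
                )
            chosen = members
        else:
            idx = rng.choice(len(members), size=n_per_tier, replace=False)
            chosen = [members[i] for i in sorted(idx)]
        for cls in chosen:
            true = bool(truth[cls.patient_id])
            if adjudication_error > 0 and rng.random() < adjudication_error:
                true = not true
            out.append(AdjudicationSample(cls.patient_id, label, true))
    return out


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (math.nan, math.nan)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class PpvResult:
    overall: float
    by_tier: dict[str, float]
    n_sampled: dict[str, int]
    n_true: dict[str, int]
    ci_by_tier: dict[str, tuple[float, float]]


def compute_ppv(samples: Sequence[AdjudicationSample]) -> PpvResult:
    """Overall and per-tier PPV of an adjudicated sample.

    The overall PPV equals the tier-size-weighted average of tier PPVs
    exactly (same sample, same arithmetic); empty tiers are absent from
    ``by_tier``.
    """
    if not samples:
        raise ValueError("compute_ppv needs at least one sample")
    seen = {s.patient_id for s in samples}
    if len(seen) != len(samples):
        raise ValueError("duplicate patients in adjudication sample")
    n_sampled: dict[str, int] = {}
    n_true: dict[str, int] = {}
    for s in samples:
        n_sampled[s.tier] = n_sampled.get(s.tier, 0) + 1
        n_true[s.tier] = n_true.get(s.tier, 0) + int(s.adjudicated_ms)
    by_tier = {t: n_true[t] / n_sampled[t] for t in n_sampled}
    overall = sum(n_true.values()) / sum(n_sampled.values())
    ci = {t: wilson_interval(n_true[t], n_sampled[t]) for t in n_sampled}
    return PpvResult(overall, by_tier, n_sampled, n_true, ci)
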