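"""MS versus non-MS comparison tables and 2x2 inference.

Proportions are compared with a Pearson chi-square test (1 df, no
continuity correction, matching the SAS PROC FREQ default) or, when any
observed cell is below 5, a two-sided Fisher exact test (p = sum of table
probabilities no larger than the observed table's).  No multiplicity
adjustment is applied.  Percentages are rounded half-away-from-zero to one
decimal, so every rendered percentage recomputes exactly from the printed
count and cohort N.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "PrevalenceComparison",
    "round_half_up",
    "pct_str",
    "compare_proportions",
    "symptom_burden",
    "median_rx_among_users",
    "format_cell",
    "render_comparison_table",
]

FISHER_MIN_CELL = 5


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_str(count: int, total: int, decimals: int = 1) -> str:
    return f"{round_half_up(100.0 * count / total, decimals):.{decimals}f}"


@dataclass(frozen=True)
class PrevalenceComparison:
    outcome: str
    a: int  # MS, outcome present
    b: int  # MS, outcome absent
    c: int  # non-MS, present
    d: int  # non-MS, absent
    pct_ms: float
    pct_nonms: float
    test_used: str  # "chi_square" | "fisher_exact"
    p_value: float

    def flag(self, threshold: float) -> str:
        return "*" if self.p_value < threshold else ""


def compare_proportions(
    a: int, b: int, c: int, d: int, outcome: str = ""
) -> PrevalenceComparison:
    """Compare present/absent proportions between the MS and non-MS arms.

    ``a + b`` is the MS cohort size and ``c + d`` the control cohort size.
    The Fisher test is selected iff the minimum *observed* cell is < 5.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("undefined comparison: an arm has size zero")
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if min(a, b, c, d) < FISHER_MIN_CELL:
        _, p = _sps.fisher_exact(table, alternative="two-sided")
        test = "fisher_exact"
    else:
        res = _sps.chi2_contingency(table, correction=False)
        p = float(res.pvalue)
        test = "chi_square"
    return PrevalenceComparison(
        outcome,
        a,
        b,
        c,
        d,
        round_half_up(100.0 * a / (a + b)),
        round_half_up(100.0 * c / (c + d)),
        test,
        float(min(p, 1.0)),
    )


def symptom_burden(
    outcome_df: pd.DataFrame, symptom_outcomes: Sequence[str]
) -> pd.DataFrame:
    """Per-arm counts of patients with >=1 and >=2 distinct present symptoms.

    *outcome_df* is the tidy ascertainment frame (patient_id, arm, outcome,
    present, ...).
    """
    sub = outcome_df[outcome_df["outcome"].isin(symptom_outcomes)]
    per_patient = (
        sub.groupby(["patient_id", "arm"], sort=True)["present"].sum().reset_index()
    )
    rows = []
    for arm, grp in per_patient.groupby("arm"):
        n = len(grp)
        rows.append(
            {
                "arm": arm,
                "n": n,
                "ge1": int((grp["present"] >= 1).sum()),
                "ge2": int((grp["present"] >= 2).sum()),
            }
        )
    return pd.DataFrame(rows)


def median_rx_among_users(n_rx_values: Iterable[int]) -> Optional[int]:
    """Median prescription count among patients with >=1 prescription.

    Returns ``None`` with no users.  Even-sized user sets take the lower
    median so every reported median is an attainable integer count.
    """
    users = sorted(int(v) for v in n_rx_values if v >= 1)
    if not users:
        return None
    return users[(len(users) - 1) // 2]


def format_cell(
    count: int, total: int, suppress_below: int = 0, flag: str = ""
) -> str:
    """Render ``"1,875 (21.6)"``-style cells, suppressing small counts as NR."""
    if 0 < count < suppress_below:
        return "NR"
    return f"{count:,} ({pct_str(count, total)}){flag}"


def render_comparison_table(
    rows: Sequence[tuple[str, PrevalenceComparison]],
    significance_threshold: float,
    suppress_below: int = 0,
) -> pd.DataFrame:
    """Build one printed-table-shaped frame from labelled comparisons."""
    out = []
    for label, cmp_ in rows:
        flag = cmp_.flag(significance_threshold)
        out.append(
            {
                "row": label,
                "ms": format_cell(cmp_.a, cmp_.a + cmp_.b, suppress_below, flag),
                "nonms": format_cell(cmp_.c, cmp_.c + cmp_.d, suppress_below),
                "test": cmp_.test_used,
                "p_value": cmp_.p_value,
            }
        )
    return pd.DataFrame(out)
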