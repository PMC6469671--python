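"""Assembly of the printed-style comparison tables from tidy outcome results.

Five outputs mirror the structure of a descriptive MS-at-diagnosis study:

* table2 — demographics and matching characteristics (age band, sex,
  smoking, BMI band), significance marked at p < 0.0001;
* table3 — MS symptoms any time before entry plus the ">=1 / >=2 of the
  symptoms" burden rows, marked at p < 0.001;
* table4 — chronic comorbidities and treated conditions, p < 0.01;
* table5 — infections in the year before entry, p < 0.01;
* table6 — concomitant medications in the year before entry with the
  median prescription count among users, p < 0.01.

Cells render as ``"1,875 (21.6)"``; counts below a configurable threshold
are suppressed as ``NR`` (not reportable).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .codelist import CAT_SYMPTOM, Codelist
from .outcomes import BMI_BANDS, SMOKING_VALUES
from .stats import (
    PrevalenceComparison,
    compare_proportions,
    median_rx_among_users,
    render_comparison_table,
    symptom_burden,
)

__all__ = ["build_comparisons", "build_tables"]

TABLE_P_THRESHOLDS = {
    "table2": 1e-4,
    "table3": 1e-3,
    "table4": 1e-2,
    "table5": 1e-2,
    "table6": 1e-2,
}

_TABLE4_ROWS = [
    "treated_depression",
    "suicidal_behaviors",
    "asthma_copd",
    "autoimmune_disorders",
    "epilepsy",
    "cancer",
    "liver_disease",
    "treated_diabetes",
    "treated_hypertension",
    "dyslipidemia",
    "osteoporosis",
    "fracture",
]


def _arm_counts(outcome_df: pd.DataFrame, outcome: str) -> tuple[int, int, int, int]:
    sub = outcome_df[outcome_df["outcome"] == outcome]
    ms = sub[sub["arm"] == "ms"]
    nonms = sub[sub["arm"] == "nonms"]
    a = int(ms["present"].sum())
    c = int(nonms["present"].sum())
    return a, len(ms) - a, c, len(nonms) - c


def build_comparisons(outcome_df: pd.DataFrame) -> list[PrevalenceComparison]:
    """One 2x2 comparison per binary outcome, in stable outcome order."""
    out = []
    for outcome in sorted(outcome_df["outcome"].unique()):
        if outcome in ("smoking", "bmi_band"):
            continue
        a, b, c, d = _arm_counts(outcome_df, outcome)
        if a + b == 0 or c + d == 0:
            continue
        out.append(compare_proportions(a, b, c, d, outcome))
    return out


def _categorical_rows(
    outcome_df: pd.DataFrame, outcome: str, values: Sequence[str]
) -> list[tuple[str, PrevalenceComparison]]:
    sub = outcome_df[outcome_df["outcome"] == outcome]
    ms = sub[sub["arm"] == "ms"]
    nonms = sub[sub["arm"] == "nonms"]
    rows = []
    for value in values:
        a = int((ms["category_value"] == value).sum())
        c = int((nonms["category_value"] == value).sum())
        if len(ms) == 0 or len(nonms) == 0:
            continue
        rows.append(
            (
                f"{outcome}:{value}",
                compare_proportions(a, len(ms) - a, c, len(nonms) - c),
            )
        )
    return rows


def build_tables(
    outcome_df: pd.DataFrame,
    codelist: Codelist,
    demographics: Optional[pd.DataFrame] = None,
    suppress_below: int = 0,
) -> dict[str, pd.DataFrame]:
    """Build table2..table6 frames plus the machine-readable comparisons.

    *demographics*, when given, has columns ``patient_id, arm, age_band,
    sex`` and feeds the top of table2; smoking and BMI rows come from the
    categorical covariate outcomes.
    """
    comparisons = {c.outcome: c for c in build_comparisons(outcome_df)}
    labels = {f"symptom:{c.name}": c.label for c in codelist.concepts.values()
              if c.category == CAT_SYMPTOM}

    tables: dict[str, pd.DataFrame] = {}

    # table 2: demographics + covariates
    t2_rows: list[tuple[str, PrevalenceComparison]] = []
    if demographics is not None and len(demographics):
        ms = demographics[demographics["arm"] == "ms"]
        nonms = demographics[demographics["arm"] == "nonms"]
        for col, values in (("age_band", sorted(demographics["age_band"].unique())),
                            ("sex", ["F", "M"])):
            for value in values:
                a = int((ms[col] == value).sum())
                c = int((nonms[col] == value).sum())
                t2_rows.append(
                    (f"{col}:{value}",
                     compare_proportions(a, len(ms) - a, c, len(nonms) - c))
                )
    t2_rows += _categorical_rows(outcome_df, "smoking", SMOKING_VALUES)
    t2_rows += _categorical_rows(outcome_df, "bmi_band", BMI_BANDS)
    tables["table2"] = render_comparison_table(
        t2_rows, TABLE_P_THRESHOLDS["table2"], suppress_below
    )

    # table 3: symptoms + burden
    symptom_outcomes = sorted(k for k in comparisons if k.startswith("symptom:"))
    t3_rows = [(labels.get(k, k), comparisons[k]) for k in symptom_outcomes]
    burden = symptom_burden(outcome_df, symptom_outcomes)
    if len(burden) == 2:
        b = burden.set_index("arm")
        for field, label in (("ge1", "At least one of the symptoms above"),
                             ("ge2", "At least two of the symptoms above")):
            t3_rows.append(
                (
                    label,
                    compare_proportions(
                        int(b.loc["ms", field]),
                        int(b.loc["ms", "n"] - b.loc["ms", field]),
                        int(b.loc["nonms", field]),
                        int(b.loc["nonms", "n"] - b.loc["nonms", field]),
                    ),
                )
            )
    tables["table3"] = render_comparison_table(
        t3_rows, TABLE_P_THRESHOLDS["table3"], suppress_below
    )

    # table 4: comorbidities
    t4_rows = [(k, comparisons[k]) for k in _TABLE4_ROWS if k in comparisons]
    tables["table4"] = render_comparison_table(
        t4_rows, TABLE_P_THRESHOLDS["table4"], suppress_below
    )

    # table 5: infections
    t5_keys = ["hospitalized_infections"] + sorted(
        k for k in comparisons if k.startswith("infection:")
    )
    t5_rows = [(k, comparisons[k]) for k in t5_keys if k in comparisons]
    tables["table5"] = render_comparison_table(
        t5_rows, TABLE_P_THRESHOLDS["table5"], suppress_below
    )

    # table 6: medications, with medians among users
    med_keys = sorted(k for k in comparisons if k.startswith("medication:"))
    t6 = render_comparison_table(
        [(k, comparisons[k]) for k in med_keys],
        TABLE_P_THRESHOLDS["table6"],
        suppress_below,
    )
    med_df = outcome_df[outcome_df["outcome"].isin(med_keys)]
    med_ms, med_nonms = [], []
    for k in med_keys:
        sub = med_df[med_df["outcome"] == k]
        med_ms.append(
            median_rx_among_users(sub.loc[sub["arm"] == "ms", "n_rx"])
        )
        med_nonms.append(
            median_rx_among_users(sub.loc[sub["arm"] == "nonms", "n_rx"])
        )
    t6["median_ms"] = med_ms
    t6["median_nonms"] = med_nonms
    tables["table6"] = t6

    tables["comparisons"] = pd.DataFrame(
        [
            {
                "outcome": c.outcome,
                "a": c.a,
                "b": c.b,
                "c": c.c,
                "d": c.d,
                "pct_ms": f"{c.pct_ms:.1f}",
                "pct_nonms": f"{c.pct_nonms:.1f}",
                "test": c.test_used,
                "p_value": f"{c.p_value:.6g}",
            }
            for c in comparisons.values()
        ]
    ).sort_values("outcome").reset_index(drop=True)
    return tables
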