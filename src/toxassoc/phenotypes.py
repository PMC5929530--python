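"""Dichotomization of NCI-CTC toxicity grades into the four analysis outcomes.

Outcomes:

* **DMN** — diarrhoea, mucositis or neutropenia, all patients; severe if the
  maximum grade over the three symptoms is 3-4.
* **DM** — diarrhoea or mucositis, Capecitabine subgroup; severe at grade 3-4.
* **HFS** — hand-and-foot syndrome, Capecitabine subgroup; affected at
  grade 2-3 (vs 0-1).
* **sHFS** — severe HFS, Capecitabine subgroup; affected at grade 3 only.

Grade 4 HFS, were it ever present, maps to affected for both HFS outcomes.
Samples outside an outcome's treatment subgroup are *excluded*, never counted
as unaffected; samples missing a required grade are *missing*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Outcome status codes in the returned series.
AFFECTED, UNAFFECTED, EXCLUDED, MISSING_STATUS = 1, 0, -2, -3


@dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    symptoms: tuple
    affected_grades: frozenset
    capecitabine_only: bool


OUTCOMES: dict[str, OutcomeDefinition] = {
    "DMN": OutcomeDefinition("DMN", ("diarrhoea", "mucositis", "neutropenia"),
                             frozenset({3, 4}), False),
    "DM": OutcomeDefinition("DM", ("diarrhoea", "mucositis"),
                            frozenset({3, 4}), True),
    "HFS": OutcomeDefinition("HFS", ("hfs",), frozenset({2, 3, 4}), True),
    "sHFS": OutcomeDefinition("sHFS", ("hfs",), frozenset({3, 4}), True),
}


def dichotomize(grades: pd.DataFrame, outcome: str | OutcomeDefinition) -> pd.Series:
    """Binary outcome per sample: 1 affected, 0 unaffected, -2 excluded
    (outside the treatment subgroup), -3 missing (required grade absent).

    Multi-symptom outcomes use the maximum grade over their symptoms.
    """
    if isinstance(outcome, str):
        try:
            outcome = OUTCOMES[outcome]
        except KeyError:
            raise KeyError(
                f"unknown outcome {outcome!r}; expected one of {list(OUTCOMES)}"
            ) from None

    grade_cols = grades[list(outcome.symptoms)].astype("Float64")
    any_missing = grade_cols.isna().any(axis=1)
    max_grade = grade_cols.max(axis=1)

    status = np.where(
        max_grade.isin(list(outcome.affected_grades)), AFFECTED, UNAFFECTED
    )
    status = np.where(any_missing, MISSING_STATUS, status)
    if outcome.capecitabine_only:
        outside = (grades["treatment"] != "Capecitabine").to_numpy()
        status = np.where(outside, EXCLUDED, status)
    return pd.Series(status, index=grades.index, name=outcome.name, dtype=int)


def outcome_summary(grades: pd.DataFrame,
                    outcomes: list[str] | None = None) -> pd.DataFrame:
    """Cohort-characteristics table: one row per outcome with affected and
    unaffected N, % male and mean (sd) age, mirroring a study Table 1 layout.

    ``sex`` is coded 1 = male, 2 = female when present.
    """
    outcomes = outcomes or list(OUTCOMES)
    rows = []
    for name in outcomes:
        status = dichotomize(grades, name)
        row: dict = {"outcome": name}
        for label, code in (("affected", AFFECTED), ("unaffected", UNAFFECTED)):
            sel = status == code
            row[f"{label}_n"] = int(sel.sum())
            if "sex" in grades:
                sexes = grades.loc[sel, "sex"]
                row[f"{label}_pct_male"] = (
                    round(100.0 * (sexes == 1).mean(), 1) if sel.any() else np.nan
                )
            if "age" in grades:
                ages = grades.loc[sel, "age"]
                row[f"{label}_age_mean"] = round(ages.mean(), 1) if sel.any() else np.nan
                row[f"{label}_age_sd"] = round(ages.std(), 1) if sel.sum() > 1 else np.nan
        row["excluded_n"] = int((status == EXCLUDED).sum())
        row["missing_n"] = int((status == MISSING_STATUS).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("outcome")
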