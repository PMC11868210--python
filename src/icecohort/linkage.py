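"""Person-level linkage into the hierarchical "iceberg" outcome.

Register and self-reported suicidality are combined into one mutually
exclusive category per person at their highest experienced level:

    none < ideation < plans < self-reported attempt
         < hospital-recorded attempt < suicide

A respondent with both a self-reported and a hospital-recorded attempt is
categorised solely as hospital-recorded.  The plans level exists only in
analyses of the sub-population asked about plans.  Suicide is the highest
level overall but, since the deceased cannot respond, it is quantified on
the background population rather than the respondent set.
"""

from __future__ import annotations

from enum import IntEnum

import pandas as pd

__all__ = ["IcebergLevel", "CATEGORY_LABELS", "assign_category", "cohort_table"]


class IcebergLevel(IntEnum):
    NONE = 0
    IDEATION = 1
    PLANS = 2
    ATTEMPT_SELF = 3
    ATTEMPT_HOSPITAL = 4
    SUICIDE = 5


CATEGORY_LABELS = {
    IcebergLevel.NONE: "none",
    IcebergLevel.IDEATION: "ideation",
    IcebergLevel.PLANS: "plans",
    IcebergLevel.ATTEMPT_SELF: "attempt_self",
    IcebergLevel.ATTEMPT_HOSPITAL: "attempt_hospital",
    IcebergLevel.SUICIDE: "suicide",
}


def assign_category(
    ideation: bool,
    plans: bool,
    attempt: bool,
    has_hospital_episode: bool,
    include_plans: bool = False,
) -> IcebergLevel:
    """Highest level of suicidality for one respondent."""
    if has_hospital_episode:
        return IcebergLevel.ATTEMPT_HOSPITAL
    if attempt:
        return IcebergLevel.ATTEMPT_SELF
    if include_plans and plans:
        return IcebergLevel.PLANS
    if ideation:
        return IcebergLevel.IDEATION
    return IcebergLevel.NONE


def cohort_table(
    persons: pd.DataFrame,
    indicators: pd.DataFrame,
    episodes: pd.DataFrame,
    include_plans: bool = False,
) -> pd.DataFrame:
    """Per-respondent category table.

    ``indicators`` is the recoded survey table (indexed by person_id);
    ``episodes`` the eligible attempt-episode table (already age-filtered
    and censored at the completion date).  Respondents with a missing
    indicator on an item the analysis uses (plans only when
    ``include_plans``; any item dropped under the do-not-know exclusion)
    are omitted.  The returned categories partition the remaining
    respondents: every person appears exactly once.
    """
    if indicators.index.duplicated().any():
        dup = indicators.index[indicators.index.duplicated()][0]
        raise ValueError(f"duplicate indicators for person {dup!r}")
    used = ["ideation", "attempt"] + (["plans"] if include_plans else [])
    complete = indicators.dropna(subset=used)
    hospital_ids = set(episodes["person_id"]) if len(episodes) else set()
    meta = persons.set_index("person_id")
    missing = complete.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"respondents missing from persons table, e.g. {missing[0]!r}")
    rows = []
    for pid, row in complete.iterrows():
        level = assign_category(
            bool(row["ideation"]),
            bool(row["plans"]) if include_plans else False,
            bool(row["attempt"]),
            pid in hospital_ids,
            include_plans=include_plans,
        )
        rows.append((pid, level))
    out = pd.DataFrame(rows, columns=["person_id", "level"])
    out["category"] = out["level"].map(lambda lv: CATEGORY_LABELS[IcebergLevel(lv)])
    for col in ("sex", "income_quartile"):
        if col in meta.columns:
            out[col] = meta.loc[out["person_id"], col].to_numpy()
    return out
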