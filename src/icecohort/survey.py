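"""Self-reported suicidality items: encoding, skip patterns and recoding.

The 18-year questionnaire asks three lifetime items (suicide ideation,
suicide plans, suicide attempt) with answers yes / no / do-not-know; an
affirmative answer triggers a follow-up item about the last year.  The
plans items entered the questionnaire partway through data collection, so
they are only available for respondents completing after the rollout date.

Two recodings of "do not know" are supported: the main analysis treats it
as "no" (``dk_as_no``); the sensitivity analysis drops the respondent for
that item (``dk_excluded``).
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

__all__ = ["ANSWERS", "ITEMS", "recode_survey", "plans_subset", "PLANS_ROLLOUT_DATE"]

YES, NO, DONT_KNOW, NOT_ASKED = "Y", "N", "DK", "NA"
ANSWERS = (YES, NO, DONT_KNOW, NOT_ASKED)
ITEMS = ("ideation", "plans", "attempt")

#: date after which the suicide-plans items were part of the questionnaire
PLANS_ROLLOUT_DATE = dt.date(2019, 5, 31)

WINDOWS = ("lifetime", "last_year")
RECODINGS = ("dk_as_no", "dk_excluded")


def _clean(ans) -> str:
    if ans is None or (isinstance(ans, float) and pd.isna(ans)) or ans is pd.NA:
        return NOT_ASKED
    ans = str(ans).strip().upper()
    if ans not in ANSWERS:
        raise ValueError(f"unknown survey answer {ans!r} (expected one of {ANSWERS})")
    return ans


def _recode_item(ever: str, year: str, window: str, recoding: str, item: str, pid):
    """One item for one respondent -> True / False / pd.NA (dropped or not asked)."""
    if ever == NOT_ASKED:
        if item == "plans":
            return pd.NA  # pre-rollout respondent: item genuinely unavailable
        raise ValueError(
            f"person {pid!r}: lifetime {item} item unanswered; record ineligible"
        )
    if recoding == "dk_excluded" and ever == DONT_KNOW:
        return pd.NA
    lifetime = ever == YES
    if window == "lifetime":
        return lifetime
    # last-year window: the follow-up item is only asked after an affirmative
    # lifetime answer; the skip pattern maps to "no last-year suicidality".
    if not lifetime:
        return False
    if recoding == "dk_excluded" and year == DONT_KNOW:
        return pd.NA
    return year == YES


def recode_survey(
    survey: pd.DataFrame, window: str = "lifetime", recoding: str = "dk_as_no"
) -> pd.DataFrame:
    """Respondent-level boolean indicators for the three suicidality items.

    Returns a DataFrame indexed by person_id with nullable-boolean columns
    ``ideation``, ``plans``, ``attempt``.  ``pd.NA`` means the item is
    unavailable for that respondent (plans before rollout, or a
    do-not-know answer under ``dk_excluded``); under ``dk_as_no`` no
    respondent is ever dropped on a non-plans item.
    """
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    if recoding not in RECODINGS:
        raise ValueError(f"recoding must be one of {RECODINGS}")
    if survey["person_id"].duplicated().any():
        dup = survey.loc[survey["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"duplicate survey response for person {dup!r}")
    out = {}
    for item in ITEMS:
        vals = []
        for row in survey.itertuples(index=False):
            ever = _clean(getattr(row, f"{item}_ever"))
            year = _clean(getattr(row, f"{item}_year"))
            vals.append(_recode_item(ever, year, window, recoding, item, row.person_id))
        out[item] = pd.array(vals, dtype="boolean")
    return pd.DataFrame(out, index=pd.Index(survey["person_id"], name="person_id"))


def plans_subset(survey: pd.DataFrame, rollout_date=PLANS_ROLLOUT_DATE) -> pd.DataFrame:
    """Respondents who completed the questionnaire after the plans rollout.

    A strict filter: only rows with completion_date after ``rollout_date``
    are returned, unchanged.  Idempotent.
    """
    completion = pd.to_datetime(survey["completion_date"])
    return survey[completion > pd.Timestamp(rollout_date)]
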