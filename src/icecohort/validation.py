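"""Validity of the register algorithm against self-report.

Among respondents the register algorithm flags as having a hospital
-recorded suicide attempt, what share themselves report (answer "yes")
a lifetime — or last-year — suicide attempt or suicide ideation?  The
proportions are reported overall, by definition subgroup and by sex,
unweighted (they condition on register positivity), with
normal-approximation 95% CIs.

Definition subgroups: a person whose episodes include at least one
triggered by definition (a) — explicitly recorded suicidal intent — is
assigned to ``def_a``; everyone else (only (b)-(d) episodes, intent
inferred from diagnosis combinations) to ``def_bcd``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prevalence import prevalence_from_counts

__all__ = ["definition_subgroup", "validity", "validity_table", "SUBGROUPS", "OUTCOMES"]

SUBGROUPS = ("all", "def_a", "def_bcd", "girls", "boys")
OUTCOMES = ("self_ideation", "self_attempt")


def definition_subgroup(episodes: pd.DataFrame) -> pd.Series:
    """Map each register-positive person to ``def_a`` or ``def_bcd``."""
    has_a = episodes["definitions"].str.split(",").map(lambda ds: "a" in ds)
    per_person = has_a.groupby(episodes["person_id"].to_numpy()).any()
    return per_person.map({True: "def_a", False: "def_bcd"}).rename("subgroup")


def validity(positive_outcomes: pd.Series, alpha: float = 0.05) -> dict:
    """Proportion of register positives self-reporting the outcome, with CI."""
    vals = positive_outcomes.astype("boolean")
    if len(vals) == 0:
        raise ValueError("empty register-positive set")
    est = prevalence_from_counts(int(vals.fillna(False).sum()), len(vals), alpha=alpha)
    est["n_positive"] = est.pop("n")
    del est["n_eff"]
    return est


def validity_table(
    indicators: pd.DataFrame,
    episodes: pd.DataFrame,
    sex: pd.Series,
    window: str = "lifetime",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Self-report concordance for every subgroup and outcome.

    ``indicators`` is the recoded survey table for the requested window
    (indexed by person_id); ``episodes`` the eligible episode table (its
    person_ids define the register positives among respondents — persons
    without a survey row are ignored); ``sex`` maps person_id to
    "girl"/"boy".  Returns one row per subgroup x outcome.
    """
    positives = pd.Index(sorted(set(episodes["person_id"])))
    positives = positives.intersection(indicators.index)
    if len(positives) == 0:
        raise ValueError("no register-positive respondents")
    subgroup = definition_subgroup(episodes[episodes["person_id"].isin(positives)])
    sex = sex.reindex(positives)
    members = {
        "all": positives,
        "def_a": positives[subgroup.reindex(positives) == "def_a"],
        "def_bcd": positives[subgroup.reindex(positives) == "def_bcd"],
        "girls": positives[(sex == "girl").to_numpy()],
        "boys": positives[(sex == "boy").to_numpy()],
    }
    outcome_col = {"self_ideation": "ideation", "self_attempt": "attempt"}
    rows = []
    for name in SUBGROUPS:
        idx = members[name]
        if len(idx) == 0:
            continue
        for outcome in OUTCOMES:
            est = validity(indicators.loc[idx, outcome_col[outcome]], alpha=alpha)
            rows.append({"subgroup": name, "window": window, "outcome": outcome, **est})
    return pd.DataFrame(rows)
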