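"""End-to-end orchestration: phenotype, link, weight, estimate, validate.

Stages communicate through documented pandas DataFrames (and, via the CLI,
through the corresponding CSV files), so each stage can be re-run in
isolation.  Record counts in and out of every filter (age filter,
censoring, recoding exclusions) are logged, making the exclusion flow
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .linkage import CATEGORY_LABELS, IcebergLevel, cohort_table
from .phenotyping import attempt_histories, suicide_deaths
from .prevalence import hidden_ratio, prevalence_from_counts, stratified_prevalence
from .survey import PLANS_ROLLOUT_DATE, plans_subset, recode_survey
from .validation import validity_table
from .weighting import DEFAULT_PREDICTORS, stratified_weights

logger = logging.getLogger(__name__)

__all__ = ["AnalysisOptions", "derive_income_quartiles", "run_pipeline", "write_outputs"]

FULL_ORDER = ("none", "ideation", "attempt_self", "attempt_hospital")
PLANS_ORDER = ("none", "ideation", "plans", "attempt_self", "attempt_hospital")


@dataclass
class AnalysisOptions:
    recoding: str = "dk_as_no"
    min_age_years: int = 10
    merge_window_days: int = 0
    truncation_multiplier: float = 5.0
    plans_rollout_date: object = PLANS_ROLLOUT_DATE
    strip_national_prefix: bool = False
    predictors: tuple = DEFAULT_PREDICTORS
    last_year_days: int = 365


def derive_income_quartiles(persons: pd.DataFrame) -> pd.Series:
    """Parental-income quartiles from the background-population distribution.

    Quartile cut points come from all background persons with a known
    income (quartiles describe the population, not the respondent sample);
    missing income forms its own level.
    """
    income = persons["parental_income"]
    q = pd.Series("Missing", index=persons.index, dtype=object)
    known = income.notna()
    if known.any():
        cuts = income[known].quantile([0.25, 0.5, 0.75]).to_numpy()
        q[known] = np.array(["Q1", "Q2", "Q3", "Q4"])[
            np.searchsorted(cuts, income[known].to_numpy(), side="left")
        ]
    return q.rename("income_quartile")


def _labels(order) -> list:
    return list(order)


def _last_year_episodes(episodes: pd.DataFrame, completion: pd.Series, days: int):
    if len(episodes) == 0:
        return episodes
    comp = completion.reindex(episodes["person_id"]).to_numpy()
    start = pd.to_datetime(pd.Series(comp)) - pd.to_timedelta(days, unit="D")
    keep = pd.to_datetime(episodes["date"]).to_numpy() >= start.to_numpy()
    return episodes[keep]


def run_pipeline(
    persons: pd.DataFrame,
    contacts: pd.DataFrame,
    deaths: pd.DataFrame,
    survey: pd.DataFrame,
    options: AnalysisOptions | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs.

    Returns a dict with ``estimates`` (tidy prevalence table over all
    analyses), ``validity``, ``ratios``, ``cohort`` (the respondent
    category table of the main analysis), ``weights`` and stage ``counts``.
    """
    opt = options or AnalysisOptions()
    counts: dict = {"background_n": len(persons), "contacts_in": len(contacts)}

    persons = persons.copy()
    persons["income_quartile"] = derive_income_quartiles(persons).to_numpy()

    # --- phenotype ---------------------------------------------------------
    deaths_cls = suicide_deaths(deaths, strip_national_prefix=opt.strip_national_prefix)
    completion = pd.Series(
        pd.to_datetime(survey["completion_date"]).to_numpy(),
        index=survey["person_id"],
    )
    episodes = attempt_histories(
        contacts,
        persons,
        completion,
        min_age_years=opt.min_age_years,
        merge_window_days=opt.merge_window_days,
        strip_national_prefix=opt.strip_national_prefix,
    )
    counts["attempt_episodes"] = len(episodes)
    counts["suicide_deaths"] = int(deaths_cls["is_suicide"].sum())
    logger.info("phenotype: %d contacts -> %d eligible attempt episodes",
                len(contacts), len(episodes))

    # --- link --------------------------------------------------------------
    indicators_life = recode_survey(survey, "lifetime", opt.recoding)
    indicators_year = recode_survey(survey, "last_year", opt.recoding)
    table_life = cohort_table(persons, indicators_life, episodes, include_plans=False)
    episodes_year = _last_year_episodes(episodes, completion, opt.last_year_days)
    table_year = cohort_table(persons, indicators_year, episodes_year,
                              include_plans=False)
    counts["respondents"] = len(survey)
    counts["respondents_linked"] = len(table_life)
    logger.info("link: %d respondents -> %d categorised (%s recoding)",
                len(survey), len(table_life), opt.recoding)

    plans_survey = plans_subset(survey, opt.plans_rollout_date)
    counts["plans_subset"] = len(plans_survey)
    table_plans = None
    if len(plans_survey):
        indicators_plans = recode_survey(plans_survey, "lifetime", opt.recoding)
        table_plans = cohort_table(persons, indicators_plans, episodes,
                                   include_plans=True)

    # --- weight ------------------------------------------------------------
    responded = set(survey["person_id"])
    background = persons.set_index("person_id")
    background["participated"] = background.index.isin(responded)
    weights_sex = stratified_weights(
        background, "sex", predictors=opt.predictors,
        truncation_multiplier=opt.truncation_multiplier,
    )
    weights_income = stratified_weights(
        background, "income_quartile", predictors=opt.predictors,
        truncation_multiplier=opt.truncation_multiplier,
    )
    weights_plans = None
    if table_plans is not None and len(table_plans):
        bg_plans = background.copy()
        bg_plans["participated"] = bg_plans.index.isin(set(plans_survey["person_id"]))
        weights_plans = stratified_weights(
            bg_plans, "sex", predictors=opt.predictors,
            truncation_multiplier=opt.truncation_multiplier,
        )
    counts["weights_sex_n"] = len(weights_sex)
    logger.info("weight: %d sex-stratum weights, %d income-stratum weights",
                len(weights_sex), len(weights_income))

    # --- estimate ----------------------------------------------------------
    pieces = []

    def run_est(table, by, weights, window, analysis, order):
        w = weights["weight"] if weights is not None else None
        est = stratified_prevalence(table, by, w, order=_labels(order))
        est.insert(0, "weighted", weights is not None)
        est.insert(0, "window", window)
        est.insert(0, "analysis", analysis)
        pieces.append(est)
        return est

    est_sex = run_est(table_life, "sex", weights_sex, "lifetime", "sex", FULL_ORDER)
    run_est(table_life, "sex", None, "lifetime", "sex_unweighted", FULL_ORDER)
    run_est(table_year, "sex", weights_sex, "last_year", "sex", FULL_ORDER)
    est_income = run_est(table_life, "income_quartile", weights_income, "lifetime",
                         "income", FULL_ORDER)
    if table_plans is not None and weights_plans is not None:
        run_est(table_plans, "sex", weights_plans, "lifetime", "plans_subset",
                PLANS_ORDER)

    # suicide prevalence on the full background population, by sex, unweighted
    suicide_ids = set(deaths_cls.loc[deaths_cls["is_suicide"], "person_id"])
    for sex_label, grp in persons.groupby("sex"):
        n_sui = len(suicide_ids & set(grp["person_id"]))
        est = prevalence_from_counts(n_sui, len(grp))
        pieces.append(pd.DataFrame([{
            "analysis": "suicide_background", "window": "lifetime",
            "weighted": False, "stratum": sex_label, "category": "suicide",
            **est,
        }]))
    estimates = pd.concat(pieces, ignore_index=True)

    ratios = {}
    for _, est, key in ((0, est_sex, "sex"), (1, est_income, "income_quartile")):
        for stratum in est["stratum"].unique():
            sub = est[est["stratum"] == stratum]
            hr = hidden_ratio(sub)
            ratios[f"{key}:{stratum}"] = {
                "p_self": hr.p_self, "p_hospital": hr.p_hospital,
                "ratio": hr.ratio if hr.defined else None,
                "one_to_k": str(hr),
            }

    # --- validate ----------------------------------------------------------
    sex_by_person = persons.set_index("person_id")["sex"]
    validity_parts = [
        validity_table(indicators_life, episodes, sex_by_person, window="lifetime")
    ]
    if len(episodes_year):
        year_ok = indicators_year.index.intersection(
            pd.Index(episodes_year["person_id"].unique())
        )
        if len(year_ok):
            validity_parts.append(
                validity_table(indicators_year, episodes_year, sex_by_person,
                               window="last_year")
            )
    validity = pd.concat(validity_parts, ignore_index=True)
    counts["register_positive_respondents"] = int(
        validity.loc[validity["subgroup"].eq("all")
                     & validity["window"].eq("lifetime"), "n_positive"].iloc[0]
    ) if len(validity) else 0

    return {
        "estimates": estimates,
        "validity": validity,
        "ratios": ratios,
        "cohort": table_life,
        "weights": weights_sex,
        "counts": counts,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: dict, out_dir, manifest_extra: dict | None = None) -> dict:
    """Write estimates.csv, validity.csv, ratios.json and manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "estimates": out_dir / "estimates.csv",
        "validity": out_dir / "validity.csv",
        "ratios": out_dir / "ratios.json",
        "manifest": out_dir / "manifest.json",
    }
    results["estimates"].to_csv(paths["estimates"], index=False)
    results["validity"].to_csv(paths["validity"], index=False)
    with open(paths["ratios"], "w") as fh:
        json.dump(results["ratios"], fh, indent=2)
    manifest = {
        "package_version": __version__,
        "counts": results["counts"],
        "output_checksums": {
            name: _sha256(paths[name]) for name in ("estimates", "validity", "ratios")
        },
    }
    manifest.update(manifest_extra or {})
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return paths
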