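"""Synthetic birth cohort with registry, death and survey files.

The generator emulates the structure the analysis assumes: a background
population of births with sociodemographic covariates; latent lifetime
suicidality states (nested by default: attempt => plans => ideation) that
depend on sex and parental income; imperfect, sex-specific hospital
presentation after an attempt; ICD-coded hospital contacts that trigger a
configurable mix of the four attempt definitions plus decoy contacts that
must not match; covariate-driven survey participation; and sex-specific
under-reporting with do-not-know answers and the plans-item rollout.

Everything is a pure function of (config, seed): identical inputs yield
identical cohorts.  A truth table of the latent states is emitted next to
the four analysis input files so estimators can be checked against known
quantities, and :func:`expected_category_proportions` gives the exact
closed-form category distribution the configured cohort targets.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortConfig",
    "CohortData",
    "generate",
    "fixture_small",
    "expected_category_proportions",
]

SEXES = ("girl", "boy")
QUARTILES = ("Q1", "Q2", "Q3", "Q4", "Missing")

# day counts used for date arithmetic (completed-year precision is enough here)
_DAYS_PER_YEAR = 365.25
_QUESTIONNAIRE_AGE_DAYS = 6665  # 18 years and three months


def _marg(**kv) -> dict:
    total = sum(kv.values())
    return {k: v / total for k, v in kv.items()}


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    Covariate marginals follow the background population of Danish births
    1996-2003; participation coefficients produce the observed selection
    (girls and high-income families over-represented among respondents);
    suicidality, presentation and reporting parameters target the
    published prevalence landscape (girls ~5.7% lifetime attempt of which
    ~30% hospital-presented; boys ~2.7% / ~15%).
    """

    n_population: int = 100_000
    birth_year_range: tuple = (1996, 2003)
    seed: int = 42

    covariate_marginals: dict = field(default_factory=lambda: {
        "sex": _marg(girl=0.49, boy=0.51),
        "income_quartile": _marg(Q1=0.2454, Q2=0.2462, Q3=0.2464, Q4=0.2466, Missing=0.0154),
        "education": _marg(elementary=0.07, vocational=0.32, high_school=0.06,
                           higher=0.46, Missing=0.09),
        "job_status": _marg(in_job=0.726, not_in_job=0.244, absent_leave=0.014,
                            Missing=0.016),
        "maternal_age_band": _marg(**{"<=25": 0.204, "26-30": 0.391, "31-36": 0.332,
                                      ">36": 0.073}),
        "parity_band": _marg(**{"1": 0.42, "2": 0.36, ">=3": 0.19, "Missing": 0.03}),
        "co_living": _marg(no=0.45, yes=0.53, Missing=0.02),
        "out_of_home": _marg(no=0.967, yes=0.033),
        "child_psych_dx": _marg(no=0.878, yes=0.122),
        "parental_psych_dx": _marg(no=0.801, yes=0.199),
    })
    # income value bands (yearly parental income, DKK) per latent quartile
    income_bands: dict = field(default_factory=lambda: {
        "Q1": (100_000, 250_000), "Q2": (250_001, 400_000),
        "Q3": (400_001, 550_000), "Q4": (550_001, 900_000),
    })

    participation_intercept: float = 0.15
    participation_coefs: dict = field(default_factory=lambda: {
        "sex": {"girl": 0.78, "boy": 0.0},
        "income_quartile": {"Q1": -1.00, "Q2": -0.20, "Q3": 0.10, "Q4": 0.35,
                            "Missing": -3.00},
        "education": {"elementary": -0.80, "vocational": -0.30, "high_school": -0.10,
                      "higher": 0.20, "Missing": -0.60},
        "job_status": {"in_job": 0.20, "not_in_job": -0.40, "absent_leave": 0.0,
                       "Missing": -1.50},
        "maternal_age_band": {"<=25": -0.40, "26-30": 0.0, "31-36": 0.10, ">36": 0.0},
        "parity_band": {"1": 0.10, "2": 0.0, ">=3": -0.20, "Missing": 0.0},
        "co_living": {"no": 0.0, "yes": 0.20, "Missing": -1.50},
        "out_of_home": {"no": 0.0, "yes": -1.20},
        "child_psych_dx": {"no": 0.0, "yes": -0.15},
        "parental_psych_dx": {"no": 0.0, "yes": -0.50},
    })

    nested_states: bool = True
    # lifetime latent-state probabilities: ideation, plans given ideation,
    # attempt given plans (per sex)
    suicidality: dict = field(default_factory=lambda: {
        "girl": {"ideation": 0.42, "plans_given_ideation": 0.38,
                 "attempt_given_plans": 0.43},
        "boy": {"ideation": 0.311, "plans_given_ideation": 0.38,
                "attempt_given_plans": 0.35},
    })
    # odds multiplier on the attempt-given-plans stage per income quartile
    # (social gradient: attempts concentrate in low-income families)
    income_attempt_odds: dict = field(default_factory=lambda: {
        "Q1": 1.9, "Q2": 1.2, "Q3": 0.9, "Q4": 0.55, "Missing": 1.0,
    })
    # probability of >=1 hospital presentation given a lifetime attempt
    presentation_prob: dict = field(default_factory=lambda: {"girl": 0.25, "boy": 0.094})
    # probability of answering "yes" given the true state (under-reporting)
    report_prob: dict = field(default_factory=lambda: {
        "ideation": 0.92, "plans": 0.80,
        "attempt": {"girl": 0.78, "boy": 0.62},
    })
    # P(last-year "yes" | lifetime "yes") per item
    lastyear_given_lifetime: dict = field(default_factory=lambda: {
        "ideation": 0.60, "plans": 0.50, "attempt": 0.25,
    })
    # P(answer "do not know" | answer is not "yes") per item
    dont_know_prob: dict = field(default_factory=lambda: {
        "ideation": 0.05, "plans": 0.02, "attempt": 0.01,
    })

    suicide_prob: dict = field(default_factory=lambda: {"girl": 0.00011, "boy": 0.00016})
    other_death_prob: float = 0.0005

    # hospital coding profile
    definition_mix: dict = field(default_factory=lambda: {"a": 0.55, "b": 0.18,
                                                          "c": 0.17, "d": 0.10})
    reason_flag_only_share: float = 0.20  # within (a): flag with non-X main dx
    extra_episode_mean: dict = field(default_factory=lambda: {"girl": 0.5, "boy": 0.2})
    same_date_transfer_prob: float = 0.10
    childhood_contact_prob: float = 0.004   # attempt-coded contact before age 10
    post_completion_contact_prob: float = 0.003
    decoy_contact_prob: float = 0.05

    plans_rollout_date: dt.date = dt.date(2019, 5, 31)
    completion_jitter_days: int = 90

    def validate(self) -> None:
        def chk(p, name):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        for sex in SEXES:
            s = self.suicidality[sex]
            for k, v in s.items():
                chk(v, f"suicidality[{sex}][{k}]")
            if not self.nested_states:
                # non-nested mode interprets the products as marginals; the
                # marginal hierarchy must still be orderable
                pi = s["ideation"]
                pp = pi * s["plans_given_ideation"]
                pa = pp * s["attempt_given_plans"]
                if not pa <= pp <= pi:
                    raise ValueError("attempt probability exceeds plans/ideation "
                                     "probability; infeasible hierarchy")
            chk(self.presentation_prob[sex], f"presentation_prob[{sex}]")
        for cov, marg in self.covariate_marginals.items():
            if abs(sum(marg.values()) - 1.0) > 1e-9:
                raise ValueError(f"marginals for {cov} do not sum to 1")
        if abs(sum(self.definition_mix.values()) - 1.0) > 1e-9:
            raise ValueError("definition_mix must sum to 1")
        y0, y1 = self.birth_year_range
        if y1 < y0:
            raise ValueError("birth_year_range end before start")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plans_rollout_date"] = self.plans_rollout_date.isoformat()
        d["birth_year_range"] = list(self.birth_year_range)
        d["income_bands"] = {k: list(v) for k, v in self.income_bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "plans_rollout_date" in d and isinstance(d["plans_rollout_date"], str):
            d["plans_rollout_date"] = dt.date.fromisoformat(d["plans_rollout_date"])
        if "birth_year_range" in d:
            d["birth_year_range"] = tuple(d["birth_year_range"])
        if "income_bands" in d:
            d["income_bands"] = {k: tuple(v) for k, v in d["income_bands"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CohortData:
    """The generated cohort: four analysis inputs plus the latent truth table."""

    persons: pd.DataFrame
    contacts: pd.DataFrame
    deaths: pd.DataFrame
    survey: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("persons", "contacts", "deaths", "survey", "truth"):
            path = out_dir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def _adjust_odds(p: float, multiplier: float) -> float:
    if multiplier == 1.0:
        return p
    odds = multiplier * p / (1.0 - p)
    return odds / (1.0 + odds)


def _cell_probs(config: CohortConfig, sex: str, quartile: str) -> tuple:
    """(P(ideation), P(plans), P(attempt)) lifetime marginals for one cell."""
    s = config.suicidality[sex]
    p_att_given_plans = _adjust_odds(
        s["attempt_given_plans"], config.income_attempt_odds.get(quartile, 1.0)
    )
    p_i = s["ideation"]
    p_p = p_i * s["plans_given_ideation"]
    p_a = p_p * p_att_given_plans
    return p_i, p_p, p_a


def expected_category_proportions(
    config: CohortConfig, sex: str, include_plans: bool = False
) -> dict:
    """Exact lifetime category distribution implied by the configuration.

    Mixes the per-income-cell probabilities over the background income
    marginals (the estimand a correctly weighted analysis targets).
    Category probabilities refer to what the survey measures: hospital
    presentation is recorded regardless of reporting, every lower level
    passes through the sex-specific reporting filter, and an answered
    "yes" to a higher item forces the ideation answer to "yes".
    """
    rep = config.report_prob
    rep_att = rep["attempt"][sex]
    rep_plans, rep_idea = rep["plans"], rep["ideation"]
    pres = config.presentation_prob[sex]
    out = {k: 0.0 for k in ("none", "ideation", "plans", "attempt_self",
                            "attempt_hospital")}
    for quartile, share in config.covariate_marginals["income_quartile"].items():
        p_i, p_p, p_a = _cell_probs(config, sex, quartile)
        hospital = p_a * pres
        self_att = p_a * (1.0 - pres) * rep_att
        # mass of true-plans persons not already captured by an attempt category
        plans_mass = p_a * (1.0 - pres) * (1.0 - rep_att) + (p_p - p_a)
        if include_plans:
            plans_cat = plans_mass * rep_plans
            ideation_cat = plans_mass * (1.0 - rep_plans) * rep_idea \
                + (p_i - p_p) * rep_idea
        else:
            plans_cat = 0.0
            # a reported plan forces the ideation answer to "yes" even when
            # the plans item itself is not part of the analysis
            ideation_cat = plans_mass * (rep_plans + (1.0 - rep_plans) * rep_idea) \
                + (p_i - p_p) * rep_idea
        none = 1.0 - hospital - self_att - plans_cat - ideation_cat
        out["attempt_hospital"] += share * hospital
        out["attempt_self"] += share * self_att
        out["plans"] += share * plans_cat
        out["ideation"] += share * ideation_cat
        out["none"] += share * none
    if not include_plans:
        del out["plans"]
    return out


def _choice(rng, marg: dict, n: int) -> np.ndarray:
    keys = list(marg)
    return rng.choice(keys, size=n, p=[marg[k] for k in keys])


def _x_code(rng) -> str:
    return f"X{rng.integers(60, 85)}{rng.integers(0, 10)}"


def _episode_contact(rng, config: CohortConfig, definition: str) -> tuple:
    """(main_dx, sub_dx, reason_flag) realising one attempt definition."""
    if definition == "a":
        if rng.random() < config.reason_flag_only_share:
            return "R458", "", True  # flag-only contact, non-specific main dx
        return _x_code(rng), "", bool(rng.random() < 0.3)
    if definition == "b":
        base = rng.choice(["T39", "T40", "T42", "T43", "T58"])
        digits = [d for d in range(10) if not (base == "T40" and d == 1)]
        return f"{base}{rng.choice(digits)}", "", False
    main = f"F{rng.integers(10, 100)}"
    if definition == "c":
        t = rng.choice([t for t in range(36, 61) if t != 51])
        return main, f"T{t}{rng.integers(0, 10)}", False
    s = rng.choice(["S51", "S55", "S59", "S61", "S65", "S69"])
    return main, f"{s}{rng.integers(0, 10)}", False


_DECOYS = [
    ("T401", "", False),   # heroin intoxication: explicitly excluded from (b)
    ("S512", "", False),   # forearm wound without psychiatric main dx
    ("J189", "", False),   # pneumonia
    ("F329", "", False),   # depression without qualifying sub-dx
    ("F101", "T510", False),  # psychiatric main + alcohol intox (T51 excluded)
    ("X459", "", False),   # accidental alcohol poisoning, outside X60-X84
    ("R104", "", False),   # abdominal pain
]


def _survey_answers(rng, reported, year_reported, dk_prob, asked=None):
    n = len(reported)
    ever = np.where(reported, "Y",
                    np.where(rng.random(n) < dk_prob, "DK", "N"))
    year = np.where(ever != "Y", "NA",
                    np.where(year_reported, "Y",
                             np.where(rng.random(n) < dk_prob, "DK", "N")))
    if asked is not None:
        ever = np.where(asked, ever, "NA")
        year = np.where(asked, year, "NA")
    return ever, year


def generate(config: CohortConfig | None = None, seed: int | None = None) -> CohortData:
    """Generate a full synthetic cohort; deterministic in (config, seed)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_population

    person_id = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    cov = {name: _choice(rng, marg, n)
           for name, marg in config.covariate_marginals.items()}
    sex = cov["sex"]
    quartile = cov["income_quartile"]

    income = np.full(n, np.nan)
    for q, (lo, hi) in config.income_bands.items():
        mask = quartile == q
        income[mask] = rng.integers(lo, hi + 1, size=mask.sum())

    y0, y1 = config.birth_year_range
    start = pd.Timestamp(f"{y0}-01-01")
    span = (pd.Timestamp(f"{y1}-12-31") - start).days
    birth_offset = rng.integers(0, span + 1, size=n)
    birth = start + pd.to_timedelta(birth_offset, unit="D")

    # latent lifetime suicidality
    p_i = np.empty(n)
    p_pgi = np.empty(n)
    p_agp = np.empty(n)
    for s in SEXES:
        for q in QUARTILES:
            mask = (sex == s) & (quartile == q)
            if not mask.any():
                continue
            su = config.suicidality[s]
            p_i[mask] = su["ideation"]
            p_pgi[mask] = su["plans_given_ideation"]
            p_agp[mask] = _adjust_odds(su["attempt_given_plans"],
                                       config.income_attempt_odds.get(q, 1.0))
    if config.nested_states:
        ideation = rng.random(n) < p_i
        plans = ideation & (rng.random(n) < p_pgi)
        attempt = plans & (rng.random(n) < p_agp)
    else:
        ideation = rng.random(n) < p_i
        plans = rng.random(n) < p_i * p_pgi
        attempt = rng.random(n) < p_i * p_pgi * p_agp

    # deaths before 18 (independent of the latent states; suicide prevalence
    # is a separate background-population quantity)
    p_sui = np.where(sex == "girl", config.suicide_prob["girl"],
                     config.suicide_prob["boy"])
    suicide = rng.random(n) < p_sui
    other_death = ~suicide & (rng.random(n) < config.other_death_prob)
    dead = suicide | other_death
    death_offset = np.where(
        suicide, rng.integers(3653, 6574, size=n), rng.integers(30, 6574, size=n)
    )

    # participation (alive persons only)
    logit = np.full(n, config.participation_intercept)
    for name, coefs in config.participation_coefs.items():
        values = cov[name]
        logit += np.vectorize(lambda v: coefs.get(v, 0.0))(values)
    pi_true = 1.0 / (1.0 + np.exp(-logit))
    participated = (~dead) & (rng.random(n) < pi_true)

    completion_offset = _QUESTIONNAIRE_AGE_DAYS + rng.integers(
        0, config.completion_jitter_days + 1, size=n
    )
    completion = birth + pd.to_timedelta(completion_offset, unit="D")
    completion_dates = pd.Series(completion).where(participated, pd.NaT)

    # self-report propensities (reported attempt/plans force ideation "yes")
    rep_att_p = np.where(sex == "girl", config.report_prob["attempt"]["girl"],
                         config.report_prob["attempt"]["boy"])
    rep_att = attempt & (rng.random(n) < rep_att_p)
    rep_plans = plans & (rng.random(n) < config.report_prob["plans"])
    rep_idea = rep_att | rep_plans | (ideation & (rng.random(n) < config.report_prob["ideation"]))
    ly = config.lastyear_given_lifetime
    year_idea = rep_idea & (rng.random(n) < ly["ideation"])
    year_plans = rep_plans & (rng.random(n) < ly["plans"])
    year_att = rep_att & (rng.random(n) < ly["attempt"])

    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "birth_date": birth.date,
        "parental_income": income,
        "education": cov["education"],
        "job_status": cov["job_status"],
        "maternal_age_band": cov["maternal_age_band"],
        "parity_band": cov["parity_band"],
        "co_living": cov["co_living"],
        "out_of_home": cov["out_of_home"],
        "child_psych_dx": cov["child_psych_dx"],
        "parental_psych_dx": cov["parental_psych_dx"],
    })

    # hospital contacts
    presented = attempt & ~dead & (
        rng.random(n) < np.where(sex == "girl", config.presentation_prob["girl"],
                                 config.presentation_prob["boy"])
    )
    rows = []

    def add_contact(idx, offset, main, sub, reason):
        rows.append((person_id[idx], (birth[idx] + pd.Timedelta(days=int(offset))).date(),
                     main, sub, int(reason)))

    def_labels = list(config.definition_mix)
    def_p = [config.definition_mix[k] for k in def_labels]
    for idx in np.flatnonzero(presented):
        n_ep = 1 + rng.poisson(config.extra_episode_mean[sex[idx]])
        offsets = rng.integers(4383, 6574, size=n_ep)  # ages 12 to <18
        for off in offsets:
            d = rng.choice(def_labels, p=def_p)
            add_contact(idx, off, *_episode_contact(rng, config, d))
            if rng.random() < config.same_date_transfer_prob:
                d2 = rng.choice(def_labels, p=def_p)
                add_contact(idx, off, *_episode_contact(rng, config, d2))

    for idx in np.flatnonzero(~dead & (rng.random(n) < config.childhood_contact_prob)):
        # early-childhood accidental ingestion, coded like an attempt
        add_contact(idx, rng.integers(365, 1461), _x_code(rng), "", False)
    for idx in np.flatnonzero(participated
                              & (rng.random(n) < config.post_completion_contact_prob)):
        off = completion_offset[idx] + rng.integers(10, 300)
        add_contact(idx, off, _x_code(rng), "", False)
    for idx in np.flatnonzero(~dead & (rng.random(n) < config.decoy_contact_prob)):
        main, sub, reason = _DECOYS[rng.integers(0, len(_DECOYS))]
        add_contact(idx, rng.integers(1825, 6574), main, sub, reason)

    contacts = pd.DataFrame(
        rows, columns=["person_id", "date", "main_dx", "sub_dx",
                       "reason_suicide_attempt"]
    ).sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)

    # death records
    drec = []
    for idx in np.flatnonzero(dead):
        date = (birth[idx] + pd.Timedelta(days=int(death_offset[idx]))).date()
        if suicide[idx]:
            u = rng.random()
            if u < 0.85:
                drec.append((person_id[idx], date, _x_code(rng), "suicide"))
            elif u < 0.95:
                drec.append((person_id[idx], date, "Y870", "unknown"))
            else:  # cause not codable, but the manner is registered
                drec.append((person_id[idx], date, "", "suicide"))
        else:
            drec.append((person_id[idx], date,
                         rng.choice(["C911", "J189", "V892"]),
                         rng.choice(["other", "unknown"])))
    deaths = pd.DataFrame(drec, columns=["person_id", "date", "cause", "manner"])

    # survey file (respondents only)
    resp = np.flatnonzero(participated)
    rollout = pd.Timestamp(config.plans_rollout_date)
    asked_plans = completion[resp] > rollout
    dk = config.dont_know_prob
    idea_ever, idea_year = _survey_answers(rng, rep_idea[resp], year_idea[resp],
                                           dk["ideation"])
    plans_ever, plans_year = _survey_answers(rng, rep_plans[resp], year_plans[resp],
                                             dk["plans"], asked=np.asarray(asked_plans))
    att_ever, att_year = _survey_answers(rng, rep_att[resp], year_att[resp],
                                         dk["attempt"])
    survey = pd.DataFrame({
        "person_id": person_id[resp],
        "completion_date": completion[resp].date,
        "ideation_ever": idea_ever, "ideation_year": idea_year,
        "plans_ever": plans_ever, "plans_year": plans_year,
        "attempt_ever": att_ever, "attempt_year": att_year,
    })

    truth = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "income_quartile": quartile,
        "true_ideation": ideation.astype(int),
        "true_plans": plans.astype(int),
        "true_attempt": attempt.astype(int),
        "presented": presented.astype(int),
        "reported_ideation": rep_idea.astype(int),
        "reported_plans": rep_plans.astype(int),
        "reported_attempt": rep_att.astype(int),
        "suicide": suicide.astype(int),
        "other_death": other_death.astype(int),
        "participation_prob": pi_true,
        "participated": participated.astype(int),
        "completion_date": completion_dates.dt.date,
    })
    return CohortData(persons, contacts, deaths, survey, truth)


def fixture_small() -> CohortData:
    """Deterministic hand-written 12-person cohort for unit tests.

    One person per iceberg level in each sex (none, ideation, plans,
    self-reported attempt, hospital-recorded attempt, suicide), plus a
    do-not-know respondent, a pre-rollout respondent, decoy contacts, a
    T40.1 contact, an under-age contact, a post-completion contact and a
    same-day transfer.
    """
    d = dt.date
    completion = d(2019, 7, 1)
    pre_rollout = d(2018, 10, 1)

    def person(pid, sex, income):
        return {"person_id": pid, "sex": sex, "birth_date": d(2001, 3, 15),
                "parental_income": income, "education": "higher",
                "job_status": "in_job", "maternal_age_band": "26-30",
                "parity_band": "1", "co_living": "yes", "out_of_home": "no",
                "child_psych_dx": "no", "parental_psych_dx": "no"}

    persons = pd.DataFrame([
        person("P01", "girl", 150_000), person("P02", "boy", 150_000),
        person("P03", "girl", 300_000), person("P04", "boy", 300_000),
        person("P05", "girl", 450_000), person("P06", "boy", 450_000),
        person("P07", "girl", 600_000), person("P08", "boy", 600_000),
        person("P09", "girl", 150_000), person("P10", "boy", 300_000),
        person("P11", "girl", 450_000), person("P12", "boy", 600_000),
    ])

    def resp(pid, comp, idea, plans, att):
        (ie, iy), (pe, py), (ae, ay) = idea, plans, att
        return {"person_id": pid, "completion_date": comp,
                "ideation_ever": ie, "ideation_year": iy,
                "plans_ever": pe, "plans_year": py,
                "attempt_ever": ae, "attempt_year": ay}

    survey = pd.DataFrame([
        # P01: "do not know" + pre-rollout (plans not asked) -> none
        resp("P01", pre_rollout, ("DK", "NA"), ("NA", "NA"), ("N", "NA")),
        resp("P02", completion, ("N", "NA"), ("N", "NA"), ("N", "NA")),
        resp("P03", completion, ("Y", "Y"), ("N", "NA"), ("N", "NA")),
        resp("P04", completion, ("Y", "N"), ("N", "NA"), ("N", "NA")),
        resp("P05", completion, ("Y", "Y"), ("Y", "Y"), ("N", "NA")),
        resp("P06", completion, ("Y", "N"), ("Y", "N"), ("N", "NA")),
        resp("P07", completion, ("Y", "Y"), ("Y", "N"), ("Y", "Y")),
        resp("P08", completion, ("Y", "N"), ("N", "NA"), ("Y", "N")),
        resp("P09", completion, ("Y", "Y"), ("Y", "Y"), ("Y", "Y")),
        # P10: hospital-recorded but denies the attempt (under-reporting)
        resp("P10", completion, ("Y", "Y"), ("N", "NA"), ("N", "NA")),
    ])

    contacts = pd.DataFrame([
        # decoys
        {"person_id": "P01", "date": d(2017, 2, 1), "main_dx": "T40.1",
         "sub_dx": "", "reason_suicide_attempt": 0},
        {"person_id": "P02", "date": d(2016, 8, 12), "main_dx": "S512",
         "sub_dx": "", "reason_suicide_attempt": 0},
        # P09: childhood contact (age 9, excluded), then a same-day pair
        {"person_id": "P09", "date": d(2010, 6, 1), "main_dx": "X60",
         "sub_dx": "", "reason_suicide_attempt": 0},
        {"person_id": "P09", "date": d(2018, 5, 2), "main_dx": "X64",
         "sub_dx": "", "reason_suicide_attempt": 0},
        {"person_id": "P09", "date": d(2018, 5, 2), "main_dx": "T43.9",
         "sub_dx": "", "reason_suicide_attempt": 0},
        # P10: definition (d) contact plus a post-completion contact (censored)
        {"person_id": "P10", "date": d(2019, 1, 20), "main_dx": "F32",
         "sub_dx": "S611", "reason_suicide_attempt": 0},
        {"person_id": "P10", "date": d(2019, 9, 1), "main_dx": "X61",
         "sub_dx": "", "reason_suicide_attempt": 0},
    ])

    deaths = pd.DataFrame([
        {"person_id": "P11", "date": d(2018, 4, 4), "cause": "X70",
         "manner": "suicide"},
        {"person_id": "P12", "date": d(2017, 11, 9), "cause": "Y87.0",
         "manner": "unknown"},
    ])

    truth = pd.DataFrame({
        "person_id": persons["person_id"],
        "sex": persons["sex"],
        "level": ["none", "none", "ideation", "ideation", "plans", "plans",
                  "attempt_self", "attempt_self", "attempt_hospital",
                  "attempt_hospital", "suicide", "suicide"],
    })
    return CohortData(persons, contacts, deaths, survey, truth)
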