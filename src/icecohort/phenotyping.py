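"""Register-based ascertainment of suicides and probable suicide attempts.

Deaths are classified as suicide when the cause-of-death code is in
X60-X84 or Y87.0, or when the registered manner of death is "suicide".
Hospital contacts are classified as probable suicide attempts by a
four-part algorithm:

a) a main or supplementary diagnosis of intentional self-harm (X60-X84),
   or "suicide attempt" recorded as the reason of contact;
b) a main diagnosis of accidental intoxication with selected drugs or
   carbon monoxide (T39, T40 except T40.1, T42, T43, T58);
c) a psychiatric main diagnosis (F00-F99) combined with a sub-diagnosis of
   intoxication with drugs and biological substances except alcohol
   (T36-T50, T52-T60);
d) a psychiatric main diagnosis (F00-F99) combined with a sub-diagnosis of
   injury to the lower forearm (S51, S55, S59, S61, S65, S69).

A contact can trigger several definitions.  Attempt-classified contacts
are assembled into per-person episode histories: contacts on the same day
(or within a configurable merge window) are merged into one episode, and
episodes before the tenth birthday or on/after a censoring date (the
questionnaire completion date) are dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .codes import CodeConfig, default_code_config, normalize_code

__all__ = [
    "DEFINITIONS",
    "AttemptClassification",
    "classify_contact",
    "classify_contacts",
    "is_suicide_death",
    "suicide_deaths",
    "build_attempt_history",
    "attempt_histories",
]

DEFINITIONS = ("a", "b", "c", "d")

_DEFAULT = default_code_config()


@dataclass(frozen=True)
class AttemptClassification:
    definitions_triggered: frozenset
    @property
    def is_attempt(self) -> bool:
        return bool(self.definitions_triggered)


def classify_contact(
    main_dx: str,
    sub_dx: Sequence[str] = (),
    reason_suicide_attempt: bool = False,
    config: CodeConfig | None = None,
    strip_national_prefix: bool = False,
) -> AttemptClassification:
    """Classify one hospital contact against definitions (a)-(d).

    ``main_dx`` is the single main diagnosis; ``sub_dx`` the supplementary
    diagnoses.  Codes are normalized before matching.
    """
    cfg = config or _DEFAULT
    main = normalize_code(main_dx, strip_national_prefix)
    subs = [normalize_code(s, strip_national_prefix) for s in sub_dx if str(s).strip()]

    triggered = set()
    if (
        reason_suicide_attempt
        or cfg.attempt_main_or_sub_a.matches(main)
        or any(cfg.attempt_main_or_sub_a.matches(s) for s in subs)
    ):
        triggered.add("a")
    if cfg.attempt_main_b.matches(main):
        triggered.add("b")
    if cfg.psychiatric_main.matches(main):
        if any(cfg.intoxication_sub_c.matches(s) for s in subs):
            triggered.add("c")
        if any(cfg.forearm_sub_d.matches(s) for s in subs):
            triggered.add("d")
    return AttemptClassification(frozenset(triggered))


def is_suicide_death(
    cause: str | None = None,
    manner: str | None = None,
    config: CodeConfig | None = None,
    strip_national_prefix: bool = False,
) -> bool:
    """True iff a death record qualifies as suicide.

    Either the cause-of-death code matches the suicide code list or the
    registered manner of death is "suicide"; a missing cause with
    manner "suicide" still qualifies.
    """
    cfg = config or _DEFAULT
    if manner is not None and str(manner).strip().lower() == "suicide":
        return True
    if cause is None or not str(cause).strip():
        return False
    return cfg.suicide_cause.matches(normalize_code(cause, strip_national_prefix))


def suicide_deaths(deaths: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Add a boolean ``is_suicide`` column to a deaths table."""
    out = deaths.copy()
    if out["person_id"].duplicated().any():
        dup = out.loc[out["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValueError(f"multiple death records for person {dup!r}")
    out["is_suicide"] = [
        is_suicide_death(c if pd.notna(c) else None, m if pd.notna(m) else None, **kwargs)
        for c, m in zip(out["cause"], out["manner"])
    ]
    return out


def _split_subs(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value if str(v).strip()]
    return [p for p in str(value).split(";") if p.strip()]


def classify_contacts(
    contacts: pd.DataFrame,
    config: CodeConfig | None = None,
    strip_national_prefix: bool = False,
) -> pd.DataFrame:
    """Classify every contact in a contacts table.

    Returns a copy with ``definitions`` (string such as ``"a,c"``, empty if
    none) and boolean ``is_attempt`` columns.
    """
    defs = []
    for i, row in enumerate(contacts.itertuples(index=False)):
        try:
            cls = classify_contact(
                row.main_dx,
                _split_subs(getattr(row, "sub_dx", None)),
                bool(getattr(row, "reason_suicide_attempt", False)),
                config=config,
                strip_national_prefix=strip_national_prefix,
            )
        except ValueError as exc:
            raise ValueError(f"contacts row {i}: {exc}") from exc
        defs.append(",".join(sorted(cls.definitions_triggered)))
    out = contacts.copy()
    out["definitions"] = defs
    out["is_attempt"] = [bool(d) for d in defs]
    return out


def age_in_years(birth_date: dt.date, at: dt.date) -> int:
    """Completed years between birth and ``at`` (registry convention, floored)."""
    birth_date = pd.Timestamp(birth_date).date()
    at = pd.Timestamp(at).date()
    return at.year - birth_date.year - ((at.month, at.day) < (birth_date.month, birth_date.day))


def build_attempt_history(
    classified: pd.DataFrame,
    birth_date,
    censor_date=None,
    min_age_years: int = 10,
    merge_window_days: int = 0,
) -> list[dict]:
    """Episode history for one person from their classified contacts.

    Keeps attempt-classified contacts at age >= ``min_age_years`` and, when
    ``censor_date`` is given (questionnaire completion), strictly before it.
    Contacts whose dates are within ``merge_window_days`` of the previous
    kept contact are merged into one episode (same-day transfers merge by
    default); an episode carries the union of triggered definitions and the
    date of its first contact.
    """
    birth = pd.Timestamp(birth_date)
    censor = pd.Timestamp(censor_date) if censor_date is not None else None
    rows = classified[classified["is_attempt"]].sort_values("date")
    episodes: list[dict] = []
    for row in rows.itertuples(index=False):
        date = pd.Timestamp(row.date)
        if date < birth:
            raise ValueError(
                f"contact on {date.date()} precedes birth date {birth.date()}"
            )
        age = age_in_years(birth, date)
        if age < min_age_years:
            continue
        if censor is not None and date >= censor:
            continue
        defs = set(row.definitions.split(","))
        if episodes and (date - episodes[-1]["_last"]).days <= merge_window_days:
            episodes[-1]["definitions"] |= defs
            episodes[-1]["_last"] = date
        else:
            episodes.append(
                {"date": date, "age_years": age, "definitions": set(defs), "_last": date}
            )
    for ep in episodes:
        del ep["_last"]
        ep["definitions"] = frozenset(ep["definitions"])
    return episodes


def attempt_histories(
    contacts: pd.DataFrame,
    persons: pd.DataFrame,
    completion_dates: pd.Series | None = None,
    config: CodeConfig | None = None,
    min_age_years: int = 10,
    merge_window_days: int = 0,
    strip_national_prefix: bool = False,
) -> pd.DataFrame:
    """Cohort-wide episode table: one row per person per attempt episode.

    ``completion_dates`` maps person_id -> questionnaire completion date for
    participants; persons absent from it are not censored.
    Returns columns person_id, date, age_years, definitions.
    """
    classified = classify_contacts(
        contacts, config=config, strip_national_prefix=strip_national_prefix
    )
    births = persons.set_index("person_id")["birth_date"]
    unknown = set(classified["person_id"]) - set(births.index)
    if unknown:
        raise ValueError(f"contacts for unknown persons, e.g. {sorted(unknown)[:3]}")
    records = []
    for pid, grp in classified[classified["is_attempt"]].groupby("person_id", sort=False):
        censor = None
        if completion_dates is not None and pid in completion_dates.index:
            censor = completion_dates.loc[pid]
            if pd.isna(censor):
                censor = None
        for ep in build_attempt_history(
            grp, births.loc[pid], censor, min_age_years, merge_window_days
        ):
            records.append(
                {
                    "person_id": pid,
                    "date": ep["date"],
                    "age_years": ep["age_years"],
                    "definitions": ",".join(sorted(ep["definitions"])),
                }
            )
    return pd.DataFrame(
        records, columns=["person_id", "date", "age_years", "definitions"]
    )
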