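"""Weighted prevalence with Wald confidence intervals, and hidden-number ratios.

For a category c with weights w_i the prevalence is the weighted share
p = sum(w_i 1[cat_i = c]) / sum(w_i), with a normal-approximation 95% CI
p +/- z * sqrt(p(1-p)/n_eff) where n_eff is the Kish effective sample
size (sum w)^2 / sum w^2 — equal to n for unweighted analyses (w = 1).
The "hidden number" of suicide attempts is reported as 1:k, the rounded
ratio of self-reported-only to hospital-recorded attempt prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "weighted_prevalence",
    "prevalence_from_counts",
    "HiddenRatio",
    "hidden_ratio",
    "stratified_prevalence",
]

Z95 = float(stats.norm.ppf(0.975))


def _wald(p: float, n_eff: float, z: float) -> tuple[float, float]:
    if n_eff <= 0:
        return (np.nan, np.nan)
    half = z * np.sqrt(p * (1.0 - p) / n_eff)
    return (max(0.0, p - half), min(1.0, p + half))


def weighted_prevalence(
    categories: pd.Series,
    weights: pd.Series | np.ndarray | None = None,
    order=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Prevalence of each category with Wald CIs.

    ``categories`` is one label per respondent; ``weights`` one positive
    weight per respondent (omitted = unweighted, w = 1).  ``order`` fixes
    the rows of the output (categories absent from the data get p = 0);
    by default the observed categories are reported in sorted order.
    Estimates within the table sum to 1 across categories.
    """
    categories = pd.Series(categories).reset_index(drop=True)
    if len(categories) == 0:
        raise ValueError("empty stratum: no respondents to estimate from")
    if weights is None:
        w = np.ones(len(categories))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(categories):
            raise ValueError("weights and categories must align")
        if (w < 0).any():
            raise ValueError("negative weight")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights zero in stratum")
    n_eff = total**2 / np.square(w).sum()
    z = float(stats.norm.ppf(1 - alpha / 2))
    labels = list(order) if order is not None else sorted(categories.unique())
    rows = []
    for lab in labels:
        mask = (categories == lab).to_numpy()
        p = float(w[mask].sum() / total)
        lo, hi = _wald(p, n_eff, z)
        rows.append(
            {
                "category": lab,
                "p_hat": p,
                "ci_low": lo,
                "ci_high": hi,
                "n": int(mask.sum()),
                "n_eff": float(n_eff),
            }
        )
    return pd.DataFrame(rows)


def prevalence_from_counts(count: int, total: int, alpha: float = 0.05) -> dict:
    """Unweighted Wald estimate from a count and a denominator."""
    if total <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= total:
        raise ValueError("count outside [0, total]")
    p = count / total
    z = float(stats.norm.ppf(1 - alpha / 2))
    lo, hi = _wald(p, total, z)
    return {"p_hat": p, "ci_low": lo, "ci_high": hi, "n": total, "n_eff": float(total)}


@dataclass(frozen=True)
class HiddenRatio:
    """1:k ratio of self-reported-only to hospital-recorded attempt prevalence."""

    p_self: float
    p_hospital: float

    @property
    def defined(self) -> bool:
        return self.p_hospital > 0

    @property
    def ratio(self) -> float:
        return self.p_self / self.p_hospital if self.defined else float("nan")

    @property
    def k(self) -> int | None:
        return int(round(self.ratio)) if self.defined else None

    def __str__(self) -> str:
        return f"1:{self.k}" if self.defined else "undefined (no hospital-recorded attempts)"


def hidden_ratio(
    p_self: float | pd.DataFrame, p_hospital: float | None = None
) -> HiddenRatio:
    """Hidden-number ratio from two prevalences or from an estimates table.

    Accepts either the two proportions directly, or a
    :func:`weighted_prevalence` table containing the ``attempt_self`` and
    ``attempt_hospital`` categories.
    """
    if isinstance(p_self, pd.DataFrame):
        est = p_self.set_index("category")["p_hat"]
        for cat in ("attempt_self", "attempt_hospital"):
            if cat not in est.index:
                raise ValueError(f"estimates table lacks category {cat!r}")
        return HiddenRatio(float(est["attempt_self"]), float(est["attempt_hospital"]))
    return HiddenRatio(float(p_self), float(p_hospital))


def stratified_prevalence(
    table: pd.DataFrame,
    by: str,
    weights: pd.Series | None = None,
    order=None,
    alpha: float = 0.05,
    allow_joint: bool = False,
) -> pd.DataFrame:
    """Per-stratum prevalence tables stacked with a ``stratum`` column.

    ``table`` is a cohort table with a ``category`` column and the
    stratification column ``by``; ``weights`` maps person_id -> weight
    (unweighted when omitted).  Joint sex-by-income stratification is
    refused by default (hospital-recorded attempts are too sparse for it)
    unless ``allow_joint`` is set; pass a composite column to force it.
    """
    if isinstance(by, (list, tuple)):
        if len(by) > 1 and not allow_joint:
            raise ValueError(
                "joint stratification refused by default; pass allow_joint=True"
            )
        by = by[0] if len(by) == 1 else by
    pieces = []
    group_cols = list(by) if isinstance(by, (list, tuple)) else [by]
    for label, grp in table.groupby(group_cols, sort=True, observed=True):
        w = None
        if weights is not None:
            w = weights.reindex(grp["person_id"])
            if w.isna().any():
                missing = grp["person_id"][w.isna().to_numpy()].iloc[0]
                raise ValueError(f"no weight for respondent {missing!r}")
        est = weighted_prevalence(grp["category"], w, order=order, alpha=alpha)
        if isinstance(label, tuple):
            label = "/".join(map(str, label)) if len(label) > 1 else label[0]
        est.insert(0, "stratum", str(label))
        pieces.append(est)
    return pd.concat(pieces, ignore_index=True)
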