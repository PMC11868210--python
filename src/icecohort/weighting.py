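"""Participation weights against the background population.

Survey participation is selective, so respondent-only proportions are
biased for the population.  The probability of participating is modelled
by logistic regression on background-population covariates (every person
born in the recruitment window, participants and non-participants alike);
each participant then receives the inverse of their fitted probability as
a weight, so under-represented groups count for more.  Weights are
computed separately within analysis strata (sex, or parental income
quartile) with the stratification variable excluded from the predictors,
truncated at median + 5*IQR of the untruncated stratum weights, and
rescaled so they sum to the stratum's participant count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "SeparationError",
    "ParticipationModel",
    "fit_participation",
    "make_weights",
    "stratified_weights",
    "DEFAULT_PREDICTORS",
]

DEFAULT_PREDICTORS = (
    "sex",
    "income_quartile",
    "education",
    "job_status",
    "maternal_age_band",
    "parity_band",
    "co_living",
    "out_of_home",
    "child_psych_dx",
    "parental_psych_dx",
)

MISSING_LEVEL = "Missing"


class SeparationError(RuntimeError):
    """Logistic fit failed by complete separation; names the covariate."""


@dataclass
class ParticipationModel:
    predictors: tuple
    result: object = field(repr=False)
    pi: pd.Series = field(repr=False)  # fitted probability per background person

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params


def _as_categorical(frame: pd.DataFrame, predictors) -> pd.DataFrame:
    out = frame[list(predictors)].copy()
    for col in predictors:
        out[col] = out[col].astype("object").where(frame[col].notna(), MISSING_LEVEL)
        out[col] = out[col].astype(str)
    return out


def fit_participation(
    background: pd.DataFrame,
    participated: pd.Series | str = "participated",
    predictors=DEFAULT_PREDICTORS,
) -> ParticipationModel:
    """Maximum-likelihood logistic fit of participation on covariates.

    ``background`` holds one row per background-population person, indexed
    by (or containing) person_id.  Categorical covariates get an explicit
    "Missing" level.  Complete separation (a covariate level whose members
    all participate, or none do) is reported as :class:`SeparationError`
    naming the covariate.
    """
    if isinstance(participated, str):
        participated = background[participated]
    y = participated.astype(int).to_numpy()
    predictors = tuple(p for p in predictors if p in background.columns)
    X = _as_categorical(background, predictors)
    for col in predictors:
        rates = pd.Series(y).groupby(X[col].to_numpy()).mean()
        bad = rates[(rates == 0.0) | (rates == 1.0)]
        if len(bad):
            raise SeparationError(
                f"complete separation in covariate {col!r}, level {bad.index[0]!r}"
            )
    data = X.assign(_participated=y)
    formula = "_participated ~ " + " + ".join(f"C({p})" for p in predictors)
    try:
        result = smf.logit(formula, data=data).fit(disp=False, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    pi = pd.Series(result.predict(data), index=background.index, name="pi")
    if not ((pi > 0) & (pi < 1)).all():
        pi = pi.clip(1e-10, 1 - 1e-10)
    return ParticipationModel(predictors=predictors, result=result, pi=pi)


@dataclass
class WeightSet:
    """Participation weights for one stratum."""

    weights: pd.Series  # final (truncated, rescaled) weight per participant
    stratum: str
    tau: float  # truncation threshold median + multiplier*IQR
    truncation_multiplier: float
    n_truncated: int
    scale: float  # rescaling factor applied after truncation


def make_weights(
    pi: pd.Series,
    stratum: str = "all",
    truncation_multiplier: float = 5.0,
    rescale: bool = True,
) -> WeightSet:
    """Inverse-probability weights for the participants of one stratum.

    w = 1/pi, truncated at tau = median(w) + multiplier*IQR(w) computed on
    the untruncated weights, then rescaled so the weights sum to the
    number of participants (familiar denominators for percentages).
    """
    if ((pi <= 0) | (pi >= 1)).any():
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")
    w = 1.0 / pi
    q1, med, q3 = np.percentile(w, [25, 50, 75])
    tau = med + truncation_multiplier * (q3 - q1)
    truncated = w.clip(upper=tau)
    n_trunc = int((w > tau).sum())
    scale = len(truncated) / truncated.sum() if rescale else 1.0
    final = truncated * scale
    if n_trunc:
        logger.info("stratum %s: truncated %d weights at tau=%.3f", stratum, n_trunc, tau)
    return WeightSet(
        weights=final.rename("weight"),
        stratum=str(stratum),
        tau=float(tau),
        truncation_multiplier=truncation_multiplier,
        n_truncated=n_trunc,
        scale=float(scale),
    )


def stratified_weights(
    background: pd.DataFrame,
    stratum_col: str,
    participated: str = "participated",
    predictors=DEFAULT_PREDICTORS,
    truncation_multiplier: float = 5.0,
) -> pd.DataFrame:
    """Per-stratum participation models and weights.

    Fits the logistic model separately on each stratum's background
    sub-population with the stratification covariate excluded from the
    predictor set, and returns a participant-level table
    (person_id index, columns stratum and weight).
    """
    preds = tuple(p for p in predictors if p != stratum_col)
    strata = (
        background[stratum_col]
        .astype("object")
        .where(background[stratum_col].notna(), MISSING_LEVEL)
    )
    pieces = []
    for label, idx in background.groupby(strata.to_numpy()).groups.items():
        sub = background.loc[idx]
        usable = tuple(
            p for p in preds
            if p in sub.columns and _as_categorical(sub, [p])[p].nunique() > 1
        )
        # sparse strata can separate on rare covariate levels; drop the
        # offending covariate (logged) rather than fail the whole stratum
        mask = sub[participated].astype(bool)
        if not mask.any():
            logger.warning("stratum %s: no participants, no weights", label)
            continue
        while True:
            if not usable:
                # degenerate stratum: constant participation probability
                rate = min(float(mask.mean()), 1.0 - 1e-9)
                model = ParticipationModel(
                    predictors=(), result=None,
                    pi=pd.Series(rate, index=sub.index, name="pi"),
                )
                break
            try:
                model = fit_participation(sub, participated, usable)
                break
            except SeparationError as exc:
                dropped = next((p for p in usable if f"{p!r}" in str(exc)), None)
                if dropped is None:
                    raise
                logger.warning("stratum %s: dropping covariate %r (%s)",
                               label, dropped, exc)
                usable = tuple(p for p in usable if p != dropped)
        ws = make_weights(
            model.pi[mask.to_numpy()], stratum=str(label),
            truncation_multiplier=truncation_multiplier,
        )
        piece = pd.DataFrame({"stratum": str(label), "weight": ws.weights})
        piece.index = sub.index[mask.to_numpy()]
        pieces.append(piece)
    out = pd.concat(pieces)
    out.index.name = background.index.name or "person_id"
    return out
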