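"""Participation models and truncated inverse-probability weights."""

import numpy as np
import pandas as pd
import pytest

from icecohort.weighting import (
    SeparationError,
    fit_participation,
    make_weights,
    stratified_weights,
)


def _background(n, rng, p_participate):
    df = pd.DataFrame({
        "sex": rng.choice(["girl", "boy"], n),
        "income_quartile": rng.choice(["Q1", "Q2", "Q3", "Q4"], n),
    })
    df["participated"] = rng.random(n) < p_participate
    df.index = pd.Index([f"P{i}" for i in range(n)], name="person_id")
    return df


def test_null_model_recovers_constant_probability():
    rng = np.random.default_rng(0)
    bg = _background(4000, rng, 0.5)
    model = fit_participation(bg, predictors=("sex", "income_quartile"))
    assert model.pi.between(0, 1).all()
    assert np.allclose(model.pi.mean(), bg["participated"].mean(), atol=1e-6)
    assert abs(model.coefficients["Intercept"]) < 0.15


def test_two_by_two_logit_matches_closed_form():
    # participation 0.25 vs 0.75 by a binary covariate: log-odds ratio log(9)
    n = 20000
    rng = np.random.default_rng(1)
    bg = _background(n, rng, 0.5)
    low = bg["sex"] == "boy"
    bg["participated"] = np.where(
        low, rng.random(n) < 0.25, rng.random(n) < 0.75
    )
    model = fit_participation(bg, predictors=("sex",))
    slope = [v for k, v in model.coefficients.items() if "girl" in k]
    # exact closed form from the realised 2x2 table
    tab = pd.crosstab(bg["sex"], bg["participated"])
    expected = np.log(tab.loc["girl", True] / tab.loc["girl", False]) - np.log(
        tab.loc["boy", True] / tab.loc["boy", False]
    )
    assert slope[0] == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(np.log(9), abs=0.15)


def test_simulated_coefficients_recovered_within_three_se():
    n = 50_000
    rng = np.random.default_rng(2)
    bg = _background(n, rng, 0.5)
    beta = {"Q1": -0.8, "Q2": -0.2, "Q3": 0.0, "Q4": 0.4}
    logit = 0.3 + bg["income_quartile"].map(beta) + 0.5 * (bg["sex"] == "girl")
    bg["participated"] = rng.random(n) < 1 / (1 + np.exp(-logit))
    model = fit_participation(bg, predictors=("sex", "income_quartile"))
    params, bse = model.coefficients, model.result.bse
    # treatment coding against the alphabetically first levels (boy, Q1)
    targets = {
        "C(sex)[T.girl]": 0.5,
        "C(income_quartile)[T.Q2]": beta["Q2"] - beta["Q1"],
        "C(income_quartile)[T.Q3]": beta["Q3"] - beta["Q1"],
        "C(income_quartile)[T.Q4]": beta["Q4"] - beta["Q1"],
    }
    for name, truth in targets.items():
        assert abs(params[name] - truth) < 3 * bse[name]


def test_complete_separation_names_the_covariate():
    rng = np.random.default_rng(3)
    bg = _background(500, rng, 0.5)
    bg.loc[bg["income_quartile"] == "Q1", "participated"] = True
    with pytest.raises(SeparationError, match="income_quartile"):
        fit_participation(bg, predictors=("sex", "income_quartile"))


def test_uniform_probabilities_give_unit_weights():
    pi = pd.Series([0.4] * 50)
    ws = make_weights(pi)
    assert np.allclose(ws.weights, 1.0)
    assert ws.n_truncated == 0


def test_truncation_hand_example():
    # weights {1,1,1,1,100}: median 1, IQR 0 -> tau = 1, outlier truncated
    pi = pd.Series([0.999999] * 4 + [0.01])
    ws = make_weights(pi, rescale=False)
    assert ws.tau == pytest.approx(1.0, rel=1e-5)
    assert ws.n_truncated == 1
    assert ws.weights.max() <= ws.tau * (1 + 1e-9)


def test_weights_rescale_to_participant_count():
    rng = np.random.default_rng(4)
    pi = pd.Series(rng.uniform(0.05, 0.95, size=1000))
    ws = make_weights(pi)
    assert ws.weights.sum() == pytest.approx(len(pi), abs=1e-8)
    assert (ws.weights > 0).all()
    # truncation bound holds on the pre-rescale scale
    assert (ws.weights / ws.scale <= ws.tau * (1 + 1e-12)).all()


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError):
        make_weights(pd.Series([0.5, 1.0]))
    with pytest.raises(ValueError):
        make_weights(pd.Series([0.0, 0.5]))


def _tv_distance(a: pd.Series, b: pd.Series) -> float:
    pa, pb = a / a.sum(), b / b.sum()
    return 0.5 * float((pa - pb).abs().sum())


def test_weighting_moves_sample_toward_background(synthetic_cohort):
    """Informative participation: the weighted covariate distribution is
    closer (total variation) to the background than the unweighted one."""
    persons = synthetic_cohort.persons.set_index("person_id")
    from icecohort.pipeline import derive_income_quartiles

    persons["income_quartile"] = derive_income_quartiles(
        persons.reset_index()
    ).to_numpy()
    responded = set(synthetic_cohort.survey["person_id"])
    persons["participated"] = persons.index.isin(responded)
    weights = stratified_weights(persons, "sex")
    part = persons[persons["participated"]]
    w = weights["weight"].reindex(part.index)
    for cov in ("income_quartile", "education", "parental_psych_dx"):
        background = persons[cov].value_counts()
        unweighted = part[cov].value_counts()
        weighted = w.groupby(part[cov].to_numpy()).sum()
        weighted = weighted.reindex(background.index).fillna(0.0)
        unweighted = unweighted.reindex(background.index).fillna(0.0)
        assert _tv_distance(weighted, background) < _tv_distance(
            unweighted, background
        )
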