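"""Step-wise second-order fitting: exact recovery, TW, pooling, prediction."""

import numpy as np
import pandas as pd
import pytest

from tgmo import (
    FitError,
    assemble_oacd,
    expand_second_order,
    fit_combined,
    fit_second_order,
    fit_stepwise_second_order,
    fit_therapeutic_window,
    predict,
)
from tgmo.synthetic import GroundTruth, SurfaceTruth, simulate_screen


def surface(design, coef):
    """Evaluate a {term: beta} truth on the design's coded rows."""
    codes = design.codes.astype(float)
    names = list(design.factor_names)
    y = np.zeros(design.n_rows)
    for term, b in coef.items():
        if term == "Intercept":
            y += b
        elif "^2" in term:
            y += b * codes[:, names.index(term[:-2])] ** 2
        elif ":" in term:
            a, c = term.split(":")
            y += b * codes[:, names.index(a)] * codes[:, names.index(c)]
        else:
            y += b * codes[:, names.index(term)]
    return y


def test_expand_second_order_column_counts(design4, design11):
    assert expand_second_order(assemble_oacd(2)).shape[1] == 6
    assert expand_second_order(design11).shape[1] == 78
    X4 = expand_second_order(design4)
    # over the two-level part, every squared column equals the intercept
    ff = np.array([p == "two_level_ff" for p in design4.part_labels])
    for name in design4.factor_names:
        assert (X4.loc[ff, f"{name}^2"] == 1.0).all()


@pytest.mark.parametrize(
    "truth",
    [
        {"Intercept": 100.0, "drug1": -20.0},
        {"Intercept": 80.0, "drug1": -10.0, "drug2": -8.0, "drug1:drug2": -6.0},
        {"Intercept": 90.0, "drug2": -12.0, "drug3^2": 7.0, "drug1:drug4": -9.0},
        {"Intercept": 95.0, "drug1": -15.0, "drug2": -5.0, "drug3": 6.0, "drug2:drug4": -8.0},
    ],
)
def test_stepwise_recovers_noise_free_truth_exactly(design4, truth):
    """On noiseless data, selection finds the active set and OLS-exact betas."""
    y = surface(design4, truth)
    model = fit_stepwise_second_order(design4, y)
    active = sorted(t for t in truth if t != "Intercept")
    assert sorted(model.term_names) == active
    for term, b in truth.items():
        assert model.coef[term] == pytest.approx(b, abs=1e-8)
    assert model.r2 == pytest.approx(1.0)
    # independent oracle: plain OLS on the true term set
    oracle = fit_second_order(
        design4,
        y,
        terms=[t for t in model.terms],
    )
    for term in truth:
        assert model.coef[term] == pytest.approx(oracle.coef[term], abs=1e-10)


def test_constant_response_gives_intercept_only(design4):
    model = fit_stepwise_second_order(design4, np.full(design4.n_rows, 100.0))
    assert model.term_names == []
    assert model.r2 == 0.0
    assert model.coef["Intercept"] == pytest.approx(100.0)


def test_fitting_equivariant_to_drug_permutation(design4):
    truth = {"Intercept": 90.0, "drug1": -14.0, "drug2:drug4": -9.0}
    y = surface(design4, truth)
    m = fit_stepwise_second_order(design4, y)
    perm = [2, 0, 3, 1]  # new column order
    permuted = assemble_oacd(4)
    permuted = type(permuted)(
        codes=design4.codes[:, perm],
        part_labels=design4.part_labels,
        factor_names=tuple(design4.factor_names[j] for j in perm),
        defining_words=None,
    )
    m2 = fit_stepwise_second_order(permuted, y)

    def lookup(model, term):
        want = set(term.split(":"))
        for name, v in model.coef.items():
            if set(name.split(":")) == want:
                return v
        raise KeyError(term)

    for term in ["drug1", "drug2:drug4"]:
        assert lookup(m2, term) == pytest.approx(lookup(m, term), abs=1e-8)


def _resp_df(design, y, replicate=0, population="tumor"):
    return pd.DataFrame(
        {
            "design_row_id": np.arange(design.n_rows),
            "replicate": replicate,
            "population": population,
            "viability_pct": y,
        }
    )


def test_therapeutic_window_difference(design4):
    tumor = _resp_df(design4, surface(design4, {"Intercept": 100.0, "drug1": -20.0}))
    normal = _resp_df(
        design4, np.full(design4.n_rows, 100.0), population="nonmalignant"
    )
    tw = fit_therapeutic_window(design4, tumor, normal)
    assert tw.coef["drug1"] == pytest.approx(20.0, abs=1e-8)

    # identical populations: all-zero window, intercept only
    tw0 = fit_therapeutic_window(design4, tumor, tumor.assign(population="nonmalignant"))
    assert tw0.term_names == []

    # tumor-only synergy propagates with flipped sign
    tum = _resp_df(
        design4,
        surface(design4, {"Intercept": 100.0, "drug1": -10.0, "drug1:drug2": -15.0}),
    )
    tw2 = fit_therapeutic_window(design4, tum, normal)
    assert tw2.coef["drug1:drug2"] == pytest.approx(15.0, abs=1e-8)


def test_therapeutic_window_requires_matching_rows(design4):
    tumor = _resp_df(design4, np.full(design4.n_rows, 90.0))
    with pytest.raises(FitError):
        fit_therapeutic_window(design4, tumor, tumor.iloc[:-3])


def test_combined_fit_pools_replicates(design4):
    y = surface(design4, {"Intercept": 85.0, "drug1": -12.0, "drug1:drug2": -8.0})
    clean = [_resp_df(design4, y, replicate=k) for k in range(3)]
    cf = fit_combined(design4, clean)
    single = fit_stepwise_second_order(design4, y)
    for term, b in single.coef.items():
        assert cf.combined.coef[term] == pytest.approx(b, abs=1e-8)

    rng = np.random.default_rng(5)
    noisy = [
        _resp_df(design4, y + rng.normal(0, 5, design4.n_rows), replicate=k)
        for k in range(3)
    ]
    cf = fit_combined(design4, noisy)
    shared = set(cf.combined.term_names)
    for m in cf.per_dataset:
        shared &= set(m.term_names)
    assert shared  # strong terms survive in every dataset
    for term in shared:
        for m in cf.per_dataset:
            assert cf.combined.se[term] < m.se[term]

    with pytest.raises(FitError):
        fit_combined(design4, [clean[0]])


def test_predict_control_and_surface(design4):
    y = surface(design4, {"Intercept": 88.0, "drug1": -12.0, "drug2": -6.0})
    m = fit_stepwise_second_order(design4, y)
    control = predict(m, {n: -1 for n in design4.factor_names})
    assert control == pytest.approx(88.0 + 12.0 + 6.0, abs=1e-8)  # = y at all -1
    assert predict(m, np.array([1, -1, -1, -1])) == pytest.approx(88.0 - 12.0 + 6.0, abs=1e-8)

    with pytest.raises(FitError, match="unknown drug"):
        predict(m, {"drugX": 0, **{n: -1 for n in design4.factor_names}})
    with pytest.raises(FitError):
        predict(m, np.array([0.5, -1, -1, -1]))  # fractional without flag

    grid = np.stack(np.meshgrid(np.linspace(-1, 1, 21), np.linspace(-1, 1, 21)), -1).reshape(-1, 2)
    codes = -np.ones((441, 4))
    codes[:, :2] = grid
    vals = predict(m, codes, allow_fractional=True)
    assert vals.shape == (441,)


def test_interaction_recovery_with_noise(design11):
    """A strong synergistic pair is found and estimated without gross bias."""
    truth = GroundTruth(
        tumor=SurfaceTruth.anchored(
            design11.factor_names,
            linear={"drug1": -15.0, "drug2": -12.0},
            interaction={("drug1", "drug2"): -12.0},
        ),
        nonmalignant=SurfaceTruth.anchored(design11.factor_names),
        noise_sd=5.0,
        n_replicates=3,
    )
    data = simulate_screen(truth, design11, seed=42)
    m = fit_stepwise_second_order(design11, data["tumor"])
    assert "drug1:drug2" in m.term_names
    assert m.coef["drug1:drug2"] == pytest.approx(-12.0, abs=3.0)
    assert m.pvalues["drug1:drug2"] < 0.05
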