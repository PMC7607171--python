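"""Lack-of-fit ANOVA, Cook's distance (vs. leave-one-out oracle), variants."""

import numpy as np
import pandas as pd
import pytest

from tgmo import (
    FitError,
    assemble_oacd,
    build_model_variants,
    cooks_distances,
    diagnostics_report,
    fit_second_order,
    fit_stepwise_second_order,
    lack_of_fit_test,
    robust_terms,
)
from tgmo.synthetic import GroundTruth, SurfaceTruth, simulate_screen


def _resp(design, y_per_rep):
    frames = []
    for k, y in enumerate(y_per_rep):
        frames.append(
            pd.DataFrame(
                {
                    "design_row_id": np.arange(design.n_rows),
                    "replicate": k,
                    "viability_pct": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def loo_cooks(model):
    """Leave-one-out refitting oracle for Cook's distance."""
    X, y = model.X, model.y
    p = X.shape[1]
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - p)
    out = np.empty(len(y))
    yhat = X @ beta
    for k in range(len(y)):
        keep = np.arange(len(y)) != k
        beta_k = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
        diff = X @ beta_k - yhat
        out[k] = diff @ diff / (p * s2)
    return out


def test_cooks_equals_leave_one_out_oracle(design4):
    rng = np.random.default_rng(7)
    y = 90 - 10 * design4.codes[:, 0] + rng.normal(0, 5, design4.n_rows)
    model = fit_second_order(design4, y, terms=[("lin", 0), ("lin", 1)])
    d = cooks_distances(model)
    assert np.allclose(d, loo_cooks(model), atol=1e-10)


def test_cooks_flags_perturbed_row(design4):
    y = (90 - 10 * design4.codes[:, 0]).astype(float)
    y_clean = y + np.random.default_rng(1).normal(0, 1, len(y))
    y_out = y_clean.copy()
    y_out[12] += 50.0
    model = fit_second_order(design4, y_out, terms=[("lin", 0)])
    d = cooks_distances(model)
    assert int(np.argmax(d)) == 12
    # responses exactly on the fitted plane: every distance is zero
    exact = fit_second_order(design4, y, terms=[("lin", 0)])
    assert np.allclose(cooks_distances(exact), 0.0, atol=1e-20)


def test_lack_of_fit_zero_for_exact_model(design4):
    y = 100 - 15 * design4.codes[:, 0]
    model = fit_stepwise_second_order(design4, _resp(design4, [y, y, y]))
    lof = lack_of_fit_test(model)
    assert lof.f_statistic == 0.0 and lof.p_value == 1.0


def test_ss_decomposition_exact(design4):
    rng = np.random.default_rng(3)
    base = 90 - 12 * design4.codes[:, 0]
    reps = [base + rng.normal(0, 5, design4.n_rows) for _ in range(3)]
    model = fit_stepwise_second_order(design4, _resp(design4, reps))
    lof = lack_of_fit_test(model)
    ss_resid = float(model.residuals @ model.residuals)
    assert lof.ss_lack_of_fit + lof.ss_pure_error == pytest.approx(ss_resid, rel=1e-12)


def test_lack_of_fit_requires_replicates(design4):
    y = 90 - 12 * design4.codes[:, 0] + np.random.default_rng(0).normal(0, 3, design4.n_rows)
    model = fit_stepwise_second_order(design4, y)
    with pytest.raises(FitError, match="pure error"):
        lack_of_fit_test(model)


def test_lack_of_fit_detects_three_drug_interaction(design4):
    """A third-order truth fit with the quadratic model triggers the test."""
    codes = design4.codes.astype(float)
    base = 90 - 10 * codes[:, 0] - 8 * codes[:, 1] + 8 * codes[:, 0] * codes[:, 1] * codes[:, 2]
    second_order = [("lin", 0), ("lin", 1), ("int", 0, 1)]
    hits = 0
    n_sims = 100
    for seed in range(n_sims):
        rng = np.random.default_rng(seed)
        reps = [base + rng.normal(0, 1, design4.n_rows) for _ in range(3)]
        model = fit_second_order(design4, _resp(design4, reps), terms=second_order)
        if lack_of_fit_test(model).p_value < 0.05:
            hits += 1
    assert hits > n_sims / 2


def _screen(design, seed, outlier=None):
    truth = GroundTruth(
        tumor=SurfaceTruth.anchored(
            design.factor_names,
            linear={"drug1": -15.0, "drug2": -10.0},
            interaction={("drug1", "drug2"): -12.0},
        ),
        nonmalignant=SurfaceTruth.anchored(design.factor_names),
        noise_sd=5.0,
        n_replicates=1,
    )
    df = simulate_screen(truth, design, seed=seed)["tumor"]
    if outlier is not None:
        df.loc[outlier, "viability_pct"] += 60.0
    return df


def test_variants_identical_on_clean_data(design4):
    variants = build_model_variants(design4, _screen(design4, seed=2))
    assert variants.high_cooks_removed is not None
    # idempotence: clean data leave the above-threshold set empty or tiny,
    # and the stable set keeps the strong true terms
    stable = robust_terms(variants)
    assert "drug1" in stable and "drug1:drug2" in stable


def test_variant_removes_gross_outlier_and_improves_fit(design4):
    variants = build_model_variants(design4, _screen(design4, seed=8, outlier=5))
    assert 5 in variants.removed_high
    assert 5 in variants.removed_max
    full_b = variants.full.coef.get("drug1:drug2")
    clean_b = variants.high_cooks_removed.coef.get("drug1:drug2")
    assert clean_b is not None
    assert abs(clean_b - (-12.0)) < abs(full_b - (-12.0))


def test_variants_no_rows_above_threshold_returns_full():
    design = assemble_oacd(4)
    y = (95 - 10 * design.codes[:, 0]).astype(float)
    # exact fit: all Cook's distances zero, nothing exceeds 3x mean
    variants = build_model_variants(design, y + 0.0)
    assert variants.removed_high == []
    assert variants.high_cooks_removed is variants.full


def test_robust_terms_rules(design4):
    variants = build_model_variants(design4, _screen(design4, seed=2))
    # identical variants -> the full term set minus anything non-significant
    stable = robust_terms(variants)
    for t in stable:
        assert variants.full.pvalues[t] < 0.05


def test_diagnostics_report_gaussian_residuals(design11):
    rng = np.random.default_rng(4)
    y = 90 - 10 * design11.codes[:, 0] + rng.normal(0, 5, design11.n_rows)
    model = fit_stepwise_second_order(design11, y)
    rep = diagnostics_report(model)
    assert rep["qq"]["correlation"] >= 0.98
    assert sum(rep["histogram"]["counts"]) == design11.n_rows
    # heavy-tailed noise scores lower on the same check
    y_t = 90 - 10 * design11.codes[:, 0] + 5 * rng.standard_t(2, design11.n_rows)
    rep_t = diagnostics_report(fit_stepwise_second_order(design11, y_t))
    assert rep_t["qq"]["correlation"] < rep["qq"]["correlation"]


def test_diagnostics_report_perfect_fit(design4):
    y = 100 - 10 * design4.codes[:, 0]
    model = fit_stepwise_second_order(design4, y)
    rep = diagnostics_report(model)
    assert rep["residual_summary"]["max"] == pytest.approx(0.0, abs=1e-9)
    assert rep["qq"]["correlation"] == 1.0
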