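"""Interaction labeling, drug elimination, ODC selection and dose refinement."""

import numpy as np
import pytest

from tgmo import (
    DoseEntry,
    DoseTable,
    SelectionError,
    classify_interactions,
    eliminate_drugs,
    refine_doses,
    select_odc,
)
from tgmo.selection import ScoreWeights
from conftest import make_model

DRUGS4 = ("drug1", "drug2", "drug3", "drug4")


def efficacy_model(coef, pvalues):
    terms = []
    for name in coef:
        if name == "Intercept":
            continue
        if name.endswith("^2"):
            terms.append(("quad", DRUGS4.index(name[:-2])))
        elif ":" in name:
            a, b = name.split(":")
            terms.append(("int", DRUGS4.index(a), DRUGS4.index(b)))
        else:
            terms.append(("lin", DRUGS4.index(name)))
    return make_model(DRUGS4, terms, coef, pvalues)


def test_interaction_labels_follow_sign_and_significance():
    model = efficacy_model(
        {"Intercept": 90.0, "drug1": -10.0, "drug2": 6.0, "drug3^2": 4.0,
         "drug1:drug2": -12.0, "drug1:drug3": 9.0, "drug2:drug3": -7.0},
        {"drug1": 0.001, "drug2": 0.04, "drug3^2": 0.01,
         "drug1:drug2": 0.003, "drug1:drug3": 0.04, "drug2:drug3": 0.3},
    )
    calls = {c.term: c for c in classify_interactions(model)}
    assert calls["drug1"].label == "efficacious"
    assert calls["drug2"].label == "stimulatory"
    assert calls["drug3^2"].label == "stable_over_range"
    assert calls["drug1:drug2"].label == "synergistic"
    assert calls["drug1:drug3"].label == "antagonistic"
    assert calls["drug2:drug3"].label is None  # not significant


def test_optimal_flag_requires_opposite_signs():
    model = efficacy_model(
        {"Intercept": 90.0, "drug1:drug2": -12.0}, {"drug1:drug2": 0.003}
    )
    tw = efficacy_model(
        {"Intercept": 0.0, "drug1:drug2": 8.0}, {"drug1:drug2": 0.01}
    )
    calls = classify_interactions(model, tw)
    assert calls[0].optimal
    assert calls[0].tw_label == "antagonistic"  # same vocabulary on TW coefs
    tw_neg = efficacy_model(
        {"Intercept": 0.0, "drug1:drug2": -8.0}, {"drug1:drug2": 0.01}
    )
    assert not classify_interactions(model, tw_neg)[0].optimal


def test_eliminate_scoring_and_determinism():
    model = efficacy_model(
        {"Intercept": 90.0, "drug1": -10.0, "drug2": -8.0,
         "drug1:drug2": -12.0, "drug3:drug4": 9.0},
        {"drug1": 0.001, "drug2": 0.01, "drug1:drug2": 0.002, "drug3:drug4": 0.01},
    )
    calls = classify_interactions(model)
    kept = eliminate_drugs(calls, list(DRUGS4), 3)
    # drug1/drug2: +2 synergy +1 efficacy = 3; drug3/drug4: -2 antagonism;
    # tie between drug3 and drug4 broken by panel order
    assert kept == ["drug1", "drug2", "drug3"]
    with pytest.raises(SelectionError):
        eliminate_drugs(calls, list(DRUGS4), 2)
    with pytest.raises(SelectionError):
        eliminate_drugs(calls, list(DRUGS4), 4)


def test_eliminate_mixed_membership_nets_weights():
    model = efficacy_model(
        {"Intercept": 90.0, "drug1:drug2": -12.0, "drug1:drug3": 10.0, "drug4": -9.0},
        {"drug1:drug2": 0.001, "drug1:drug3": 0.001, "drug4": 0.001},
    )
    calls = classify_interactions(model)
    w = ScoreWeights()
    # drug1 nets synergy + antagonism = 0; drug2 +2; drug3 -2; drug4 +1
    kept = eliminate_drugs(calls, list(DRUGS4), 3, weights=w)
    assert kept == ["drug1", "drug2", "drug4"]


def test_select_odc_contains_dominant_pair():
    model = efficacy_model(
        {"Intercept": 70.0, "drug1": -10.0, "drug2": -8.0, "drug1:drug2": -15.0},
        {"drug1": 0.001, "drug2": 0.001, "drug1:drug2": 0.001},
    )
    odc = select_odc(model)
    assert {"drug1", "drug2"} <= set(odc.drugs)
    assert odc.warning is None
    # the winning doses put the synergistic pair at the high dose
    assert odc.codes["drug1"] == 1.0 and odc.codes["drug2"] == 1.0


def test_select_odc_tw_tie_band():
    # two drugs with identical efficacy; TW prefers drug2-containing subsets
    model = efficacy_model(
        {"Intercept": 80.0, "drug1": -10.0, "drug2": -10.0},
        {"drug1": 0.001, "drug2": 0.001},
    )
    tw = efficacy_model({"Intercept": 0.0, "drug2": 6.0}, {"drug2": 0.01})
    odc = select_odc(model, tw, tw_band=5.0)
    assert "drug2" in odc.drugs
    assert odc.predicted_tw is not None and odc.predicted_tw > 0


def test_select_odc_all_inert_warns():
    model = efficacy_model({"Intercept": 100.0}, {})
    odc = select_odc(model)
    assert odc.warning is not None


def test_refine_doses_flat_direction_spares_dose():
    # surface flat along drug3: refinement should park it at the lowest code
    model = efficacy_model(
        {"Intercept": 70.0, "drug1": -10.0, "drug2": -8.0, "drug1:drug2": -10.0},
        {"drug1": 0.001, "drug2": 0.001, "drug1:drug2": 0.001},
    )
    odc = select_odc(model, subset_sizes=(3,))
    refined = refine_doses(model, odc, n_grid=5)
    flat = [d for d in refined.drugs if d not in ("drug1", "drug2")]
    assert all(refined.codes[d] == -1.0 for d in flat)
    assert refined.codes["drug1"] == 1.0 and refined.codes["drug2"] == 1.0


def test_refine_doses_concentrations_respect_caps():
    model = efficacy_model(
        {"Intercept": 70.0, "drug1": -10.0, "drug2": -8.0, "drug3": -6.0},
        {"drug1": 0.001, "drug2": 0.001, "drug3": 0.001},
    )
    doses = DoseTable(
        {d: DoseEntry(dose1=1.0, dose2=2.0, pcl=2.0) for d in DRUGS4}
    )
    odc = select_odc(model, subset_sizes=(3,))
    refined = refine_doses(model, odc, constraints=doses, n_grid=5)
    for d, conc in refined.concentrations.items():
        assert 0.0 <= conc <= doses[d].pcl
    assert refined.dose_reduction is not None
    # monotone surface: cutting doses costs activity (predicted viability rises)
    assert refined.dose_reduction["reduction_50_delta_pct"] >= 0


def test_refine_doses_moves_each_dose_in_correct_direction():
    # quadratic truth with interior optimum on drug1 (dose-sparing) and
    # monotone benefit on drug2
    model = efficacy_model(
        {"Intercept": 70.0, "drug1": -4.0, "drug1^2": 8.0, "drug2": -10.0},
        {"drug1": 0.001, "drug1^2": 0.001, "drug2": 0.001},
    )
    odc = select_odc(model, subset_sizes=(3,))
    refined = refine_doses(model, odc, n_grid=9)
    # minimum of -4x + 8x^2 at x = 0.25
    assert refined.codes["drug1"] == pytest.approx(0.25)
    assert refined.codes["drug2"] == 1.0
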