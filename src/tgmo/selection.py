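"""Interaction classification, drug elimination and ODC selection.

The coefficient sign conventions on the tumor-efficacy model:

* linear terms — negative = inhibitory ("efficacious"), positive =
  stimulatory;
* interaction terms — negative = synergistic, positive = antagonistic;
* quadratic (drug^2) terms — negative = dose-dependent contribution,
  positive = effect stable over the tested dose range.

Only terms significant at ``alpha`` receive a label.  On the
therapeutic-window (TW) model the same vocabulary is applied to the TW
coefficients; the most desirable pattern ("optimal" flag) is a
significant negative efficacy coefficient whose TW counterpart is
positive — the combination hits tumor cells harder than nonmalignant
cells.

Elimination across search rounds ranks drugs with an explicit additive
score codifying "most active and synergistic in, most inactive and
antagonistic out": membership in a significant synergistic pair +2 per
pair, a significant negative linear efficacy term +1, a TW-widening
(positive, significant) term +1, membership in a significant
antagonistic pair -2 per pair, and -1 when a drug carries no significant
term at all.  The weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, product

import numpy as np

from .design import CodedDesign, DoseTable, code_to_concentration
from .errors import SelectionError
from .regression import FittedModel, predict, term_name

__all__ = [
    "InteractionCall",
    "ODCResult",
    "ScoreWeights",
    "classify_interactions",
    "eliminate_drugs",
    "select_odc",
    "refine_doses",
]


@dataclass(frozen=True)
class InteractionCall:
    """A labeled regression term from the efficacy and TW models."""

    term: str
    kind: str  # linear | quadratic | interaction
    drugs: tuple[str, ...]
    coef: float
    pvalue: float
    label: str | None
    tw_coef: float | None = None
    tw_pvalue: float | None = None
    tw_label: str | None = None
    optimal: bool = False


@dataclass(frozen=True)
class ScoreWeights:
    """Additive per-drug scoring weights for elimination."""

    synergy: float = 2.0
    efficacy: float = 1.0
    tw_positive: float = 1.0
    antagonism: float = -2.0
    inert: float = -1.0


@dataclass
class ODCResult:
    """An optimized drug combination with doses and predicted effects."""

    drugs: tuple[str, ...]
    codes: dict[str, float]
    predicted_viability: float
    predicted_tw: float | None
    warning: str | None = None
    concentrations: dict[str, float] | None = None
    calls: list[InteractionCall] = field(default_factory=list)
    dose_reduction: dict[str, float] | None = None

    def to_report(self) -> dict:
        return {
            "schema": "tgmo.odc/1",
            "drugs": list(self.drugs),
            "codes": self.codes,
            "concentrations": self.concentrations,
            "predicted_tumor_viability_pct": self.predicted_viability,
            "predicted_therapeutic_window_pct": self.predicted_tw,
            "warning": self.warning,
            "dose_reduction_check": self.dose_reduction,
            "interaction_calls": [
                {
                    "term": c.term,
                    "kind": c.kind,
                    "coef": c.coef,
                    "p": c.pvalue,
                    "label": c.label,
                    "tw_coef": c.tw_coef,
                    "tw_p": c.tw_pvalue,
                    "tw_label": c.tw_label,
                    "optimal": c.optimal,
                }
                for c in self.calls
            ],
        }


def _label(kind: str, coef: float, p: float, alpha: float) -> str | None:
    if p >= alpha:
        return None
    if kind == "interaction":
        return "synergistic" if coef < 0 else "antagonistic"
    if kind == "linear":
        return "efficacious" if coef < 0 else "stimulatory"
    if kind == "quadratic":
        return "dose_dependent" if coef < 0 else "stable_over_range"
    raise SelectionError(f"unknown term kind {kind!r}")


def _term_drugs(model: FittedModel, name: str) -> tuple[str, ...]:
    for t in model.terms:
        if term_name(t, model.factor_names) == name:
            if t[0] == "int":
                return (model.factor_names[t[1]], model.factor_names[t[2]])
            return (model.factor_names[t[1]],)
    raise SelectionError(f"term {name!r} not in model")


def classify_interactions(
    model: FittedModel,
    tw: FittedModel | None = None,
    alpha: float = 0.05,
) -> list[InteractionCall]:
    """Label every selected efficacy term, attaching TW labels where fit.

    Models must share the drug panel.  A term gets the ``optimal`` flag
    when its efficacy coefficient is significantly negative and the TW
    model carries the same term with a positive coefficient.
    """
    if tw is not None and tw.factor_names != model.factor_names:
        raise SelectionError("efficacy and TW models are fit on different drug panels")
    calls: list[InteractionCall] = []
    for name in model.term_names:
        kind = model.term_kind(name)
        coef = model.coef[name]
        p = model.pvalues[name]
        tw_coef = tw_p = tw_lab = None
        if tw is not None and name in tw.term_names:
            tw_coef = tw.coef[name]
            tw_p = tw.pvalues[name]
            tw_lab = _label(kind, tw_coef, tw_p, alpha)
        optimal = bool(coef < 0 and p < alpha and tw_coef is not None and tw_coef > 0)
        calls.append(
            InteractionCall(
                term=name,
                kind=kind,
                drugs=_term_drugs(model, name),
                coef=coef,
                pvalue=p,
                label=_label(kind, coef, p, alpha),
                tw_coef=tw_coef,
                tw_pvalue=tw_p,
                tw_label=tw_lab,
                optimal=optimal,
            )
        )
    return calls


def eliminate_drugs(
    calls: list[InteractionCall],
    panel: list[str],
    target_size: int,
    weights: ScoreWeights = ScoreWeights(),
) -> list[str]:
    """Keep the ``target_size`` best-scoring drugs for the next round.

    Deterministic: ties are broken by panel order.  Returns the retained
    drugs in panel order.
    """
    if target_size < 3:
        raise SelectionError("final combinations are 3-4 drugs; target_size must be >= 3")
    if target_size >= len(panel):
        raise SelectionError("target_size must be smaller than the current panel")
    scores = {d: 0.0 for d in panel}
    has_significant = {d: False for d in panel}
    for c in calls:
        if c.label is None and c.tw_label is None:
            continue
        for d in c.drugs:
            if d not in scores:
                raise SelectionError(f"call references drug {d!r} outside the panel")
        if c.label is not None:
            for d in c.drugs:
                has_significant[d] = True
            if c.kind == "interaction":
                w = weights.synergy if c.label == "synergistic" else weights.antagonism
                for d in c.drugs:
                    scores[d] += w
            elif c.kind == "linear" and c.label == "efficacious":
                scores[c.drugs[0]] += weights.efficacy
        if c.tw_coef is not None and c.tw_pvalue is not None:
            if c.tw_coef > 0 and c.tw_pvalue < 0.05:
                for d in c.drugs:
                    scores[d] += weights.tw_positive
    for d in panel:
        if not has_significant[d]:
            scores[d] += weights.inert
    order = sorted(panel, key=lambda d: (-scores[d], panel.index(d)))
    kept = set(order[:target_size])
    return [d for d in panel if d in kept]


def _subset_code_matrix(
    drugs: tuple[str, ...], subset: tuple[str, ...], member_codes: np.ndarray
) -> np.ndarray:
    """Full-panel code matrix with non-members at -1 (absent)."""
    mat = -np.ones((member_codes.shape[0], len(drugs)))
    for k, d in enumerate(subset):
        mat[:, drugs.index(d)] = member_codes[:, k]
    return mat


def select_odc(
    model: FittedModel,
    tw_model: FittedModel | None = None,
    subset_sizes: tuple[int, ...] = (3, 4),
    dose_codes: tuple[float, ...] = (0.0, 1.0),
    tw_band: float = 5.0,
    min_effect: float = 5.0,
    calls: list[InteractionCall] | None = None,
) -> ODCResult:
    """Pick the best 3-4-drug combination from the final-round model.

    Enumerates drug subsets and per-drug dose codes (non-members absent
    at -1), minimizing predicted tumor viability; among candidates within
    ``tw_band`` percentage points of the best efficacy, the largest
    predicted therapeutic window wins.  If even the best candidate fails
    to beat the predicted control viability by ``min_effect`` points the
    result carries a warning instead of failing.
    """
    drugs = model.factor_names
    sizes = [s for s in subset_sizes if s <= len(drugs)]
    if not sizes:
        raise SelectionError("no feasible subset size for this panel")
    control = predict(model, -np.ones(len(drugs)))
    candidates = []  # (viability, tw, subset, codes)
    for size in sizes:
        for subset in combinations(drugs, size):
            member = np.array(list(product(dose_codes, repeat=size)))
            # drop the all-absent assignment if -1 is ever in dose_codes
            mat = _subset_code_matrix(drugs, subset, member)
            via = predict(model, mat, allow_fractional=True)
            tw_vals = (
                predict(tw_model, mat, allow_fractional=True)
                if tw_model is not None
                else np.zeros(len(mat))
            )
            for row, v, t in zip(member, via, tw_vals):
                candidates.append((float(v), float(t), subset, row))
    best_v = min(c[0] for c in candidates)
    in_band = [c for c in candidates if c[0] <= best_v + tw_band]
    # maximize TW within the efficacy band; deterministic tie-break on
    # (viability, subset order, codes)
    win = min(in_band, key=lambda c: (-c[1], c[0], c[2], tuple(c[3])))
    warning = None
    if best_v > control - min_effect:
        warning = (
            f"no combination beats control by {min_effect:g} points "
            f"(best predicted viability {best_v:.1f} vs control {control:.1f})"
        )
    return ODCResult(
        drugs=win[2],
        codes={d: float(c) for d, c in zip(win[2], win[3])},
        predicted_viability=win[0],
        predicted_tw=win[1] if tw_model is not None else None,
        warning=warning,
        calls=calls or [],
    )


def _code_to_conc(code: float, dose1: float, dose2: float) -> float:
    return dose1 * (code + 1) if code <= 0 else dose1 + (dose2 - dose1) * code


def _conc_to_code(conc: float, dose1: float, dose2: float) -> float:
    if conc <= dose1:
        return conc / dose1 - 1.0
    return (conc - dose1) / (dose2 - dose1)


def refine_doses(
    model: FittedModel,
    odc: ODCResult,
    constraints: DoseTable | None = None,
    tw_model: FittedModel | None = None,
    n_grid: int = 9,
    tw_band: float = 5.0,
) -> ODCResult:
    """Search-4 dose refinement over fractional codes in [-1, +1].

    Grid search (default 9 points per drug) over the ODC drugs with all
    other drugs absent; minimizes predicted tumor viability with the same
    TW tie-band as :func:`select_odc`.  With a dose table the refined
    codes are converted to concentrations (which then respect the PCL by
    construction, since dose2 was capped).  Also reports how much
    predicted activity is lost when every refined dose is cut by 25% and
    50% — a small loss means the combination is dose-sparing.
    """
    drugs = model.factor_names
    subset = odc.drugs
    if n_grid < 2:
        raise SelectionError("dose-refinement grid needs at least 2 points per drug")
    if len(subset) == 0:
        raise SelectionError("empty combination cannot be refined")
    axes = [np.linspace(-1.0, 1.0, n_grid)] * len(subset)
    member = np.array(list(product(*axes)))
    mat = _subset_code_matrix(drugs, subset, member)
    via = predict(model, mat, allow_fractional=True)
    tw_vals = (
        predict(tw_model, mat, allow_fractional=True)
        if tw_model is not None
        else np.zeros(len(mat))
    )
    best_v = float(via.min())
    band = via <= best_v + tw_band
    idx_band = np.flatnonzero(band)
    order = sorted(
        idx_band, key=lambda i: (-tw_vals[i], via[i], tuple(member[i]))
    )
    win = order[0]
    codes = {d: float(c) for d, c in zip(subset, member[win])}

    concentrations = None
    if constraints is not None:
        missing = [d for d in subset if d not in constraints]
        if missing:
            raise SelectionError(f"no dose entry for drug(s): {', '.join(missing)}")
        concentrations = {
            d: _code_to_conc(codes[d], constraints[d].dose1, constraints[d].dose2)
            for d in subset
        }

    # dose-reduction check: scale refined concentrations by 0.75 / 0.50
    reduction = {}
    base_pred = float(via[win])
    for factor, key in ((0.75, "reduction_25_delta_pct"), (0.50, "reduction_50_delta_pct")):
        red_codes = {}
        for d in subset:
            d1, d2 = (
                (constraints[d].dose1, constraints[d].dose2)
                if constraints is not None and d in constraints
                else (0.5, 1.0)  # relative scale when no table is given
            )
            conc = _code_to_conc(codes[d], d1, d2) * factor
            red_codes[d] = max(-1.0, min(1.0, _conc_to_code(conc, d1, d2)))
        red_mat = _subset_code_matrix(drugs, subset, np.array([[red_codes[d] for d in subset]]))
        reduction[key] = float(predict(model, red_mat, allow_fractional=True)[0] - base_pred)

    return replace(
        odc,
        codes=codes,
        predicted_viability=base_pred,
        predicted_tw=float(tw_vals[win]) if tw_model is not None else odc.predicted_tw,
        concentrations=concentrations,
        dose_reduction=reduction,
    )
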