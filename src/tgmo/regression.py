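"""Step-wise second-order regression of viability screens.

The viability of a drug combination is modeled as a quadratic response
surface in the coded dose levels x_i of the drugs::

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j + eps

with y in % of vehicle control (%CTRL) and eps mean-zero noise.  Negative
linear or interaction coefficients mean inhibitory / synergistic activity,
positive ones stimulatory / antagonistic activity; negative quadratic
terms mean a dose-dependent contribution, positive ones a contribution
stable over the tested dose range.

Term selection is bidirectional step-wise on partial F tests, starting
from the intercept-plus-linear model: p-to-enter 0.05, p-to-remove 0.10,
with the hierarchical constraint that a linear term cannot be removed
while one of its quadratic/interaction children is in the model (parents
are not forced in at entry).  Ties are broken by smaller p-value, then by
the deterministic term ordering (drugs in panel order, pairs
lexicographic).  The selected model is refit by ordinary least squares
through statsmodels, which supplies standard errors, per-term t-test
p-values and R^2.

The therapeutic window (TW) is the per-row difference (nonmalignant -
tumor) viability, modeled with the same machinery: a positive TW
coefficient is selectivity-enhancing, and the most desirable pattern is a
negative efficacy coefficient paired with a positive TW coefficient for
the same term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .design import CodedDesign
from .errors import FitError

__all__ = [
    "Term",
    "second_order_terms",
    "term_name",
    "expand_second_order",
    "FittedModel",
    "CombinedFit",
    "fit_second_order",
    "fit_stepwise_second_order",
    "fit_therapeutic_window",
    "fit_combined",
    "predict",
]

# A model term: ("lin", i), ("quad", i) or ("int", i, j) with i < j,
# indices into the design's factor columns.
Term = tuple


def second_order_terms(n_factors: int) -> list[Term]:
    """Full second-order term pool in canonical order."""
    terms: list[Term] = [("lin", i) for i in range(n_factors)]
    terms += [("quad", i) for i in range(n_factors)]
    terms += [("int", i, j) for i in range(n_factors) for j in range(i + 1, n_factors)]
    return terms


def term_name(term: Term, names: Sequence[str]) -> str:
    kind = term[0]
    if kind == "lin":
        return names[term[1]]
    if kind == "quad":
        return f"{names[term[1]]}^2"
    if kind == "int":
        return f"{names[term[1]]}:{names[term[2]]}"
    raise FitError(f"unknown term kind {kind!r}")


def _term_column(term: Term, codes: np.ndarray) -> np.ndarray:
    kind = term[0]
    if kind == "lin":
        return codes[:, term[1]]
    if kind == "quad":
        return codes[:, term[1]] ** 2
    if kind == "int":
        return codes[:, term[1]] * codes[:, term[2]]
    raise FitError(f"unknown term kind {kind!r}")


def expand_second_order(design: CodedDesign) -> pd.DataFrame:
    """Model matrix with intercept and every second-order term.

    Columns: ``Intercept``, all linear terms, all quadratic terms, all
    pairwise interaction terms, in canonical order.  Note that over the
    two-level part (codes +/-1) every x_i^2 column equals the intercept
    column: quadratic effects are estimable only through the three-level
    orthogonal-array part.
    """
    codes = np.asarray(design.codes, dtype=float)
    terms = second_order_terms(design.n_factors)
    data = {"Intercept": np.ones(codes.shape[0])}
    for t in terms:
        data[term_name(t, design.factor_names)] = _term_column(t, codes)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# observation handling


def _as_observations(
    design: CodedDesign,
    responses,
    population: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize responses to (row_ids, y, dataset_ids).

    Accepts either a plain array of length n_design_rows (one observation
    per row) or a DataFrame with columns ``design_row_id``,
    ``viability_pct`` and optionally ``replicate`` and ``population``.
    """
    if isinstance(responses, pd.DataFrame):
        df = responses
        if population is not None and "population" in df.columns:
            df = df[df["population"] == population]
            if df.empty:
                raise FitError(f"no responses for population {population!r}")
        row_ids = df["design_row_id"].to_numpy(dtype=int)
        y = df["viability_pct"].to_numpy(dtype=float)
        reps = (
            df["replicate"].to_numpy()
            if "replicate" in df.columns
            else np.zeros(len(df), dtype=int)
        )
    else:
        y = np.asarray(responses, dtype=float).ravel()
        if len(y) != design.n_rows:
            raise FitError(
                f"expected one response per design row ({design.n_rows}), got {len(y)}"
            )
        row_ids = np.arange(design.n_rows)
        reps = np.zeros(len(y), dtype=int)
    if (row_ids < 0).any() or (row_ids >= design.n_rows).any():
        raise FitError("design_row_id outside the design")
    if np.isnan(y).any():
        raise FitError("responses contain NaN")
    return row_ids, y, reps


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedModel:
    """A fitted (step-wise selected) second-order viability model."""

    factor_names: tuple[str, ...]
    terms: list[Term]
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    nobs: int
    fitted: np.ndarray
    residuals: np.ndarray
    row_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray  # intercept + selected-term columns, observation rows
    trace: list[dict] = field(default_factory=list)
    population: str | None = None
    sm_results: object | None = field(default=None, repr=False)

    @property
    def term_names(self) -> list[str]:
        return [term_name(t, self.factor_names) for t in self.terms]

    def term_kind(self, name: str) -> Literal["linear", "quadratic", "interaction"]:
        for t in self.terms:
            if term_name(t, self.factor_names) == name:
                return {"lin": "linear", "quad": "quadratic", "int": "interaction"}[t[0]]
        raise FitError(f"term {name!r} not in model")

    def predict(self, codes, allow_fractional: bool = False) -> float | np.ndarray:
        return predict(self, codes, allow_fractional=allow_fractional)

    def to_report(self) -> dict:
        """JSON-serializable model report."""
        return {
            "schema": "tgmo.model/1",
            "population": self.population,
            "drugs": list(self.factor_names),
            "terms": [
                {
                    "name": n,
                    "coef": self.coef[n],
                    "se": self.se.get(n),
                    "p": self.pvalues.get(n),
                }
                for n in ["Intercept"] + self.term_names
            ],
            "r2": self.r2,
            "nobs": self.nobs,
            "selection_trace": self.trace,
        }


@dataclass
class CombinedFit:
    """Pooled fit over replicate datasets plus the per-dataset fits."""

    combined: FittedModel
    per_dataset: list[FittedModel]


# ---------------------------------------------------------------------------
# OLS plumbing

_RSS_TOL_SCALE = 1e-9


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and matrix rank via least squares."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _partial_f_p(
    rss_reduced: float, rss_full: float, df_extra: int, df_resid_full: int, tol: float
) -> float:
    """p-value of the partial F test comparing nested models.

    Degenerate (noise-free) cases are resolved by the residual tolerance:
    if the full model fits exactly, a term whose removal leaves an exact
    fit is useless (p = 1) and one whose removal breaks the fit is
    indispensable (p = 0).
    """
    if df_resid_full <= 0:
        return np.nan
    if rss_full <= tol:
        return 1.0 if rss_reduced - rss_full <= tol else 0.0
    f = max(rss_reduced - rss_full, 0.0) / df_extra / (rss_full / df_resid_full)
    return float(scipy.stats.f.sf(f, df_extra, df_resid_full))


def _build_X(
    terms: Sequence[Term], codes: np.ndarray, row_ids: np.ndarray
) -> np.ndarray:
    cols = [np.ones(len(row_ids))]
    obs_codes = codes[row_ids].astype(float)
    for t in terms:
        cols.append(_term_column(t, obs_codes))
    return np.column_stack(cols)


def _finalize(
    design: CodedDesign,
    terms: list[Term],
    row_ids: np.ndarray,
    y: np.ndarray,
    trace: list[dict],
    population: str | None,
) -> FittedModel:
    X = _build_X(terms, design.codes, row_ids)
    names = ["Intercept"] + [term_name(t, design.factor_names) for t in terms]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            "rank-deficient model after selection; aliased terms: " + ", ".join(names)
        )
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if (not terms or tss <= 1e-12) else float(res.rsquared)
    return FittedModel(
        factor_names=design.factor_names,
        terms=terms,
        coef={n: float(res.params[n]) for n in names},
        se={n: float(res.bse[n]) for n in names},
        pvalues={n: float(res.pvalues[n]) for n in names},
        r2=r2,
        nobs=len(y),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        row_ids=row_ids,
        y=y,
        X=X,
        trace=trace,
        population=population,
        sm_results=res,
    )


def fit_second_order(
    design: CodedDesign,
    responses,
    terms: Sequence[Term] | None = None,
    population: str | None = None,
) -> FittedModel:
    """OLS fit of a fixed set of second-order terms (no selection).

    With ``terms=None`` the full estimable second-order model is fit
    (collinear columns are pruned greedily in canonical order).
    """
    row_ids, y, _ = _as_observations(design, responses, population)
    if terms is None:
        pool = second_order_terms(design.n_factors)
        kept: list[Term] = []
        X = np.ones((len(y), 1))
        for t in pool:
            cand = np.column_stack([X, _term_column(t, design.codes[row_ids].astype(float))])
            if np.linalg.matrix_rank(cand) == cand.shape[1] and cand.shape[1] <= len(y):
                kept.append(t)
                X = cand
        terms = kept
    return _finalize(design, list(terms), row_ids, y, [], population)


def fit_stepwise_second_order(
    design: CodedDesign,
    responses,
    population: str | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_steps: int = 500,
) -> FittedModel:
    """Bidirectional step-wise selection over the second-order term pool.

    Starts from the intercept-plus-linear model; candidate entries are all
    unused quadratic and interaction terms (and previously removed linear
    terms); removals respect the hierarchy (a linear parent stays while a
    child term is present).
    """
    row_ids, y, _ = _as_observations(design, responses, population)
    codes = design.codes
    pool = second_order_terms(design.n_factors)
    current: list[Term] = [t for t in pool if t[0] == "lin"]
    tss = float(((y - y.mean()) ** 2).sum())
    tol = max(_RSS_TOL_SCALE * max(tss, 1.0), 1e-12)
    trace: list[dict] = []

    def order_key(t: Term) -> int:
        return pool.index(t)

    def removable(t: Term, members: Sequence[Term]) -> bool:
        if t[0] != "lin":
            return True
        i = t[1]
        for m in members:
            if m[0] == "quad" and m[1] == i:
                return False
            if m[0] == "int" and i in m[1:]:
                return False
        return True

    for _ in range(max_steps):
        changed = False
        # removal sweep first: prunes the generous linear start
        while True:
            X_full = _build_X(current, codes, row_ids)
            rss_full, rank_full = _rss(X_full, y)
            df_resid = len(y) - rank_full
            worst: tuple[float, int, Term] | None = None
            for t in current:
                if not removable(t, [m for m in current if m != t]):
                    continue
                reduced = [m for m in current if m != t]
                rss_red, _ = _rss(_build_X(reduced, codes, row_ids), y)
                p = _partial_f_p(rss_red, rss_full, 1, df_resid, tol)
                if np.isnan(p):
                    p = 1.0  # saturated fit: the term is not testable, drop it
                key = (-p, order_key(t))
                if p > alpha_remove and (worst is None or key < (-worst[0], worst[1])):
                    worst = (p, order_key(t), t)
            if worst is None:
                break
            current = [m for m in current if m != worst[2]]
            trace.append(
                {"step": "remove", "term": term_name(worst[2], design.factor_names), "p": worst[0]}
            )
            changed = True
        # entry step: best single addition below alpha_enter
        X_cur = _build_X(current, codes, row_ids)
        rss_cur, rank_cur = _rss(X_cur, y)
        best: tuple[float, int, Term] | None = None
        for t in pool:
            if t in current:
                continue
            cand = current + [t]
            X_cand = _build_X(cand, codes, row_ids)
            rss_cand, rank_cand = _rss(X_cand, y)
            if rank_cand <= rank_cur or rank_cand >= len(y):
                continue  # aliased with current model, or no residual df left
            p = _partial_f_p(rss_cur, rss_cand, 1, len(y) - rank_cand, tol)
            if np.isnan(p):
                continue
            key = (p, order_key(t))
            if p < alpha_enter and (best is None or key < (best[0], best[1])):
                best = (p, order_key(t), t)
        if best is not None:
            current.append(best[2])
            trace.append(
                {"step": "enter", "term": term_name(best[2], design.factor_names), "p": best[0]}
            )
            changed = True
        if not changed:
            break
    else:
        # entry/removal cycling is possible with aggressive thresholds;
        # stop at the current model rather than failing the whole screen
        trace.append({"step": "stopped", "term": None, "p": None})

    current.sort(key=order_key)
    model = _finalize(design, current, row_ids, y, trace, population)
    return model


def fit_therapeutic_window(
    design: CodedDesign,
    tumor_responses: pd.DataFrame,
    normal_responses: pd.DataFrame,
    **kwargs,
) -> FittedModel:
    """Fit the therapeutic-window model on (nonmalignant - tumor) viability.

    Observations are matched on (design_row_id, replicate); both response
    sets must cover exactly the same rows.  A positive coefficient means
    the term widens the window (hits tumor harder than normal cells).
    """
    keys = ["design_row_id"]
    for df in (tumor_responses, normal_responses):
        if not isinstance(df, pd.DataFrame):
            raise FitError("therapeutic-window fitting requires response DataFrames")
    if "replicate" in tumor_responses.columns and "replicate" in normal_responses.columns:
        keys.append("replicate")
    t = tumor_responses[keys + ["viability_pct"]].rename(columns={"viability_pct": "tumor"})
    n = normal_responses[keys + ["viability_pct"]].rename(columns={"viability_pct": "normal"})
    merged = t.merge(n, on=keys, how="outer", validate="one_to_one")
    if merged["tumor"].isna().any() or merged["normal"].isna().any():
        raise FitError("tumor and nonmalignant responses do not cover the same rows")
    tw = merged.assign(viability_pct=merged["normal"] - merged["tumor"])
    model = fit_stepwise_second_order(
        design, tw[keys + ["viability_pct"]], population="tw", **kwargs
    )
    return model


def fit_combined(
    design: CodedDesign,
    response_sets: Sequence[pd.DataFrame],
    population: str | None = None,
    **kwargs,
) -> CombinedFit:
    """Fit each replicate dataset separately and all pooled together.

    The pooled ("combined") model is the one used for final calls; the
    per-dataset fits support cross-model term comparison (a term seen in
    every dataset with the same sign is more trustworthy).
    """
    if len(response_sets) < 2:
        raise FitError("fit_combined needs at least 2 replicate datasets")
    per = [
        fit_stepwise_second_order(design, r, population=population, **kwargs)
        for r in response_sets
    ]
    frames = []
    for k, r in enumerate(response_sets):
        df = r if isinstance(r, pd.DataFrame) else pd.DataFrame(
            {"design_row_id": np.arange(design.n_rows), "viability_pct": np.asarray(r)}
        )
        df = df.copy()
        df["replicate"] = k
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    combined = fit_stepwise_second_order(design, pooled, population=population, **kwargs)
    return CombinedFit(combined=combined, per_dataset=per)


def predict(
    model: FittedModel,
    codes,
    allow_fractional: bool = False,
):
    """Evaluate the fitted surface at coded dose levels.

    ``codes`` is a mapping drug -> code, a vector (one code per drug in
    panel order), or a matrix of such vectors.  Fractional codes (surface
    plotting, dose refinement) require ``allow_fractional=True``.
    """
    names = model.factor_names
    if isinstance(codes, Mapping):
        unknown = set(codes) - set(names)
        if unknown:
            raise FitError(f"unknown drug(s) in codes: {', '.join(sorted(unknown))}")
        missing = set(names) - set(codes)
        if missing:
            raise FitError(f"missing code(s) for: {', '.join(sorted(missing))}")
        vec = np.array([codes[n] for n in names], dtype=float)[None, :]
        scalar = True
    else:
        vec = np.asarray(codes, dtype=float)
        scalar = vec.ndim == 1
        vec = np.atleast_2d(vec)
        if vec.shape[1] != len(names):
            raise FitError(f"expected {len(names)} codes per row, got {vec.shape[1]}")
    if ((vec < -1 - 1e-9) | (vec > 1 + 1e-9)).any():
        raise FitError("codes must lie within [-1, +1]")
    if not allow_fractional and not np.isin(vec, (-1.0, 0.0, 1.0)).all():
        raise FitError("fractional codes require allow_fractional=True")
    out = np.full(vec.shape[0], model.coef["Intercept"], dtype=float)
    for t in model.terms:
        out += model.coef[term_name(t, names)] * _term_column(t, vec)
    return float(out[0]) if scalar else out
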