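"""Model validation: lack-of-fit ANOVA, Cook's distance, variant models.

A fitted screen model is trusted only after (i) an ANOVA lack-of-fit test
that is *not* significant (replicate pure error explains the residual),
(ii) residual/Q-Q summaries consistent with i.i.d. Gaussian errors, and
(iii) stability of its terms under influential-point removal.  Influence
is measured by Cook's distance; two outlier-removed refits accompany the
full fit:

* ``max_outlier_removed`` — the single most influential observation
  dropped;
* ``high_cooks_removed`` — every observation with Cook's D above 3x the
  mean distance of the full fit dropped (simultaneously, not
  iteratively).

Terms that keep their selection, coefficient sign and significance across
all variants are the "robust" terms used to guide drug elimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .design import CodedDesign
from .errors import FitError
from .regression import FittedModel, fit_stepwise_second_order, fit_second_order

__all__ = [
    "LackOfFitResult",
    "ModelVariants",
    "lack_of_fit_test",
    "cooks_distances",
    "build_model_variants",
    "robust_terms",
    "diagnostics_report",
]

_SS_TOL = 1e-9


@dataclass(frozen=True)
class LackOfFitResult:
    f_statistic: float
    p_value: float
    ss_lack_of_fit: float
    ss_pure_error: float
    df_lack_of_fit: int
    df_pure_error: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def lack_of_fit_test(model: FittedModel) -> LackOfFitResult:
    """ANOVA lack-of-fit test using replicate pure error.

    Splits the residual sum of squares into a pure-error component
    (replicate scatter around per-design-row means) and a lack-of-fit
    component (row means vs. fitted surface)::

        SS_resid = SS_lof + SS_pe,  F = (SS_lof/df_lof) / (SS_pe/df_pe)

    Non-significance supports the second-order model; significance
    suggests a higher-order surface is needed.
    """
    row_ids = model.row_ids
    y = model.y
    uniq, inv, counts = np.unique(row_ids, return_inverse=True, return_counts=True)
    if not (counts >= 2).any():
        raise FitError("pure error not estimable: no design row has replicates")
    group_mean = np.bincount(inv, weights=y) / counts
    ss_pe = float(((y - group_mean[inv]) ** 2).sum())
    ss_resid = float((model.residuals**2).sum())
    ss_lof = max(ss_resid - ss_pe, 0.0)
    n_params = model.X.shape[1]
    df_pe = int((counts - 1).sum())
    df_lof = len(uniq) - n_params
    if df_lof <= 0:
        raise FitError(
            "lack of fit not testable: the model has as many parameters as "
            "distinct design rows"
        )
    scale = max(ss_resid, 1.0)
    if ss_pe <= _SS_TOL * scale:
        if ss_lof <= _SS_TOL * scale:
            return LackOfFitResult(0.0, 1.0, ss_lof, ss_pe, df_lof, df_pe)
        return LackOfFitResult(np.inf, 0.0, ss_lof, ss_pe, df_lof, df_pe)
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    p = float(scipy.stats.f.sf(f, df_lof, df_pe))
    return LackOfFitResult(float(f), p, ss_lof, ss_pe, df_lof, df_pe)


def cooks_distances(model: FittedModel) -> np.ndarray:
    """Cook's distance per observation.

    D_k = r_k^2 / p * h_k / (1 - h_k)^2 * 1/s^2 with r_k the residual,
    h_k the leverage and p the parameter count — equivalent to the scaled
    squared shift of the coefficient vector when observation k is left
    out.  Computed through statsmodels' influence machinery.
    """
    if model.sm_results is None:
        raise FitError("model carries no regression results; refit required")
    if model.sm_results.df_resid <= 0:
        raise FitError("saturated model: Cook's distance undefined (zero residual df)")
    ssr = float(model.residuals @ model.residuals)
    tss = float(((model.y - model.y.mean()) ** 2).sum())
    if ssr <= 1e-12 * max(tss, 1.0):
        return np.zeros(len(model.y))  # exact fit: no observation is influential
    d = model.sm_results.get_influence().cooks_distance[0]
    return np.asarray(d, dtype=float)


@dataclass
class ModelVariants:
    """The three model variants used to judge term stability."""

    full: FittedModel
    max_outlier_removed: FittedModel | None
    high_cooks_removed: FittedModel | None
    removed_max: list[int]
    removed_high: list[int]
    cooks: np.ndarray
    threshold: float
    unavailable: dict[str, str]

    def available(self) -> list[FittedModel]:
        out = [self.full]
        if self.max_outlier_removed is not None:
            out.append(self.max_outlier_removed)
        if self.high_cooks_removed is not None:
            out.append(self.high_cooks_removed)
        return out


def build_model_variants(
    design: CodedDesign,
    responses,
    population: str | None = None,
    cooks_multiplier: float = 3.0,
    reselect: bool = True,
    **fit_kwargs,
) -> ModelVariants:
    """Fit the full model and the two outlier-removed variants.

    ``reselect=True`` re-runs step-wise selection on the reduced data;
    with ``False`` the full model's terms are refit as-is.  The removal
    threshold is ``cooks_multiplier`` x mean Cook's distance of the full
    fit; all rows above it are removed at once.
    """
    full = fit_stepwise_second_order(design, responses, population=population, **fit_kwargs)
    d = cooks_distances(full)
    threshold = cooks_multiplier * float(d.mean())
    idx_max = [int(np.argmax(d))] if len(d) else []
    idx_high = [int(i) for i in np.flatnonzero(d > threshold)]

    def refit(drop: list[int]) -> FittedModel | None:
        keep = np.setdiff1d(np.arange(len(full.y)), drop)
        min_rows = full.X.shape[1] + 1
        if len(keep) < min_rows:
            return None
        sub = pd.DataFrame(
            {
                "design_row_id": full.row_ids[keep],
                "viability_pct": full.y[keep],
            }
        )
        if reselect:
            return fit_stepwise_second_order(design, sub, population=population, **fit_kwargs)
        return fit_second_order(design, sub, terms=full.terms, population=population)

    unavailable: dict[str, str] = {}
    m_max = refit(idx_max)
    if m_max is None:
        unavailable["max_outlier_removed"] = "too few rows left after removal"
    if idx_high:
        m_high = refit(idx_high)
        if m_high is None:
            unavailable["high_cooks_removed"] = "too few rows left after removal"
    else:
        m_high = full  # nothing above threshold: variant identical to full
    return ModelVariants(
        full=full,
        max_outlier_removed=m_max,
        high_cooks_removed=m_high,
        removed_max=idx_max,
        removed_high=idx_high,
        cooks=d,
        threshold=threshold,
        unavailable=unavailable,
    )


def robust_terms(variants: ModelVariants, alpha: float = 0.05) -> list[str]:
    """Terms stable under outlier removal.

    A term qualifies if it is selected in every available variant, its
    coefficient keeps one sign, and it stays significant (p < alpha)
    everywhere.  These are the coefficients trusted for drug selection
    and elimination.
    """
    models = variants.available()
    if len(models) < 2:
        raise FitError("need at least two available variants to assess stability")
    stable: list[str] = []
    for name in models[0].term_names:
        coefs, ps = [], []
        ok = True
        for m in models:
            if name not in m.term_names:
                ok = False
                break
            coefs.append(m.coef[name])
            ps.append(m.pvalues[name])
        if not ok:
            continue
        signs = {np.sign(c) for c in coefs}
        if len(signs) > 1:
            continue
        if any(p >= alpha for p in ps):
            continue
        stable.append(name)
    return stable


def diagnostics_report(model: FittedModel, n_hist_bins: int = 10) -> dict:
    """Numeric residual diagnostics (no rendering).

    Returns R^2, residual summary statistics, Q-Q quantile pairs against
    the normal distribution with the Q-Q correlation (normality check),
    and histogram bins, ready for plotting or JSON export.
    """
    r = np.asarray(model.residuals, dtype=float)
    (osm, osr), _ = scipy.stats.probplot(r, dist="norm")
    if np.std(osr) > 0 and np.std(osm) > 0:
        qq_corr = float(np.corrcoef(osm, osr)[0, 1])
    else:
        qq_corr = 1.0  # perfect fit: all residual quantiles are zero
    counts, edges = np.histogram(r, bins=n_hist_bins)
    return {
        "r2": model.r2,
        "nobs": model.nobs,
        "residual_summary": {
            "mean": float(r.mean()),
            "sd": float(r.std(ddof=1)) if len(r) > 1 else 0.0,
            "min": float(r.min()),
            "max": float(r.max()),
        },
        "qq": {
            "theoretical": osm.tolist(),
            "ordered_residuals": osr.tolist(),
            "correlation": qq_corr,
        },
        "histogram": {"counts": counts.tolist(), "bin_edges": edges.tolist()},
    }
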