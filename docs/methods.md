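# Methods

## The optimization problem

Given a panel of up to 11 candidate drugs, each available at two low
screening doses, the goal is to find a 3–4-drug combination (with
specific doses) that minimizes tumor-cell viability while sparing
nonmalignant cells. Exhaustive screening is infeasible (3^11 dose
combinations), so the search is driven by design of experiments: a small,
information-dense set of combinations is screened, a quadratic
response-surface model is fit, and the model — not the raw data — guides
which drugs survive into the next, smaller round. Three search rounds
(11 → 7 → 4 drugs by default) are followed by a dose-refinement step on
the final combination.

## Experimental design

Each round screens an orthogonal-array composite design (OACD) over the
current panel:

* **Two-level fractional factorial part** — codes −1/+1 (drug absent /
  high dose). All built-in fractions are regular with resolution ≥ IV,
  so main effects are never aliased with two-drug interactions. For 11
  drugs the package uses a 2^(11−4) fraction (128 runs; generators
  H=ABCD, J=ABEF, K=ACEG, L=BDFG, verified resolution V by exhaustive
  word enumeration). For 7 drugs: 2^(7−2) (32 runs); for 4 drugs:
  2^(4−1) with I=ABCD (8 runs). The sub-designs are configurable via
  explicit generator words.
* **Three-level orthogonal array part** — OA(27, 3^13) of strength 2,
  built from the nonzero linear functionals on GF(3)^3 (one
  representative per projective direction) and restricted to the first
  n columns; recoded to −1/0/+1 (absent / dose 1 / dose 2). This part
  makes quadratic terms estimable: over the ±1 part every x² column is
  constant.

For 11 drugs the two parts give 128 + 27 = 155 combinations. The OA's
origin run recodes to the all-(−1) row, so the design always contains a
vehicle-control combination; responses are expressed in % of that
control (%CTRL).

Dose-level coding fixes "no drug" at −1. This orientation is a
convention; it matters only for interpreting the intercept (the model's
centre, not the control) and is applied consistently everywhere,
including when a drug eliminated between rounds is folded out of a
simulation truth (substituting x = −1, not 0).

## Screening doses

Dose 2 is the ED20 — the dose at which single-drug viability falls to
80% of the untreated plateau — and dose 1 is half of it. ED values come
from a four-parameter logistic fit of the single-drug dose-response
curve; the ED_L is defined against the top plateau (target viability
top·(1−L)) and declared unattainable when the bottom plateau sits above
the target. Dose 2 is additionally capped at the plasma concentration
limit PCL = AUC₀₋₂₄ₕ/24 h, the time-averaged clinically attainable
plasma concentration (converted to molar units when a molecular weight
is supplied). AUC is computed by the trapezoidal rule over the observed
sampling window only — no extrapolation beyond the last sample.

## Regression model and term selection

Viability is modeled as a full quadratic surface in the coded doses:
y = β₀ + Σβᵢxᵢ + Σβᵢᵢxᵢ² + Σβᵢⱼxᵢxⱼ + ε. Signs carry the biology:
negative linear/interaction coefficients mean inhibition/synergy,
positive ones stimulation/antagonism; negative quadratic terms mean a
dose-dependent contribution, positive ones an effect stable over the
dose range.

Term selection is bidirectional step-wise on partial F tests with
p-to-enter 0.05 and p-to-remove 0.10, starting from the
intercept-plus-linear model. Hierarchy is enforced at removal only (a
linear term cannot leave while one of its children is in the model);
parents are not forced in at entry. Ties break on smaller p then on the
canonical term order (panel order, pairs lexicographic), making
selection deterministic. Exact (zero-residual) fits are handled by a
residual tolerance of 1e−9 × TSS: a term whose removal leaves an exact
fit gets p = 1, one whose removal breaks it gets p = 0. The selected
terms are refit by OLS for standard errors, per-term t-test p-values and
plain (unadjusted) R²; an intercept-only model reports R² = 0. If
entry/removal ever cycles (possible in principle with these thresholds)
selection stops at the current model and records that in the trace
rather than failing the screen.

The therapeutic window (TW) is the per-observation difference
(nonmalignant − tumor) viability, matched on design row and replicate
and modeled with the same machinery on the raw difference (no
re-normalization — an assumption, since only the difference's sign
structure is used). A positive TW coefficient is selectivity-enhancing;
the most desirable pattern is a negative efficacy coefficient with a
positive TW counterpart.

Replicate datasets are modeled separately and pooled ("combined" model);
the combined fit makes the final calls, and agreement of a term across
the per-replicate fits is additional evidence of robustness.

## Diagnostics

* **Lack-of-fit ANOVA** — residual SS is split exactly into pure error
  (replicate scatter around per-row means) and lack of fit;
  F = (SS_lof/df_lof)/(SS_pe/df_pe). Non-significance supports the
  quadratic model; significance flags a higher-order surface (e.g. a
  three-drug interaction), which this package detects but does not
  auto-fit.
* **Cook's distance** — computed via the standard leverage formula
  (statsmodels influence); an exact fit returns all-zero distances by
  convention. The test suite proves the analytic values equal explicit
  leave-one-out refits to 1e−10.
* **Variant models** — (i) the full fit on all data, (ii) the single
  most influential observation removed, (iii) all observations with
  D > 3 × mean(D) removed simultaneously (threshold computed on the full
  fit; not iterated). "A model without outliers" is read as the full,
  untrimmed fit — the reading that makes the three variants well-ordered.
  Step-wise selection is re-run per variant by default (configurable to
  refit fixed terms). Terms selected in every available variant with
  unchanged sign and p < 0.05 throughout are the *robust* terms used for
  elimination decisions.
* **Residual reports** — Q-Q quantile pairs with their correlation, and
  histogram bins; numbers only, rendering is left to the caller.

## Elimination and combination selection

The elimination rule "most active and synergistic in, most inactive and
antagonistic out" is codified as an additive per-drug score: +2 per
significant synergistic pair membership, +1 for a significant negative
linear efficacy term, +1 for a significant TW-widening term, −2 per
significant antagonistic pair membership, −1 if the drug carries no
significant term at all. Weights are configurable; ties break on panel
order. Round sizes (11 → 7 → 4) are configuration, not inference.

The final combination is chosen by enumerating 3- and 4-drug subsets at
the available dose codes (non-members at −1), minimizing predicted tumor
viability, with the predicted TW deciding among candidates within a
5-percentage-point efficacy band (lexicographic efficacy-then-TW rather
than an invented weighted composite). If nothing beats the predicted
control by at least 5 points the result is returned with a warning flag.

Dose refinement (the final search step) is a grid search over fractional
codes in [−1, 1] (default 9 points per drug) on the fitted surface —
the surface is quadratic and the space tiny, so a grid beats gradient
methods on robustness. Fractional codes map to concentrations piecewise
linearly (0 at −1, dose 1 at 0, dose 2 at +1), so refined doses respect
the PCL automatically. The refinement also reports the predicted
activity cost of cutting all refined doses by 25% and 50%, a
dose-sparing check.

## Bliss independence and in-vivo scoring

For in-vivo combinations the Bliss prediction is the product of the
single-drug fractions remaining, IR = ∏Fᵢ (fractions > 1 allowed — a
drug may stimulate growth). Because the product of remaining fractions
is itself a remaining fraction, while some reports quote it on an
"inhibition" percent scale, the result object exposes `product`,
`product_pct` (product × 100) and `complement_pct` ((1 − product) × 100)
under explicit names and takes no side. Classification of an observed
combination effect against the prediction uses a ±5-percentage-point
additivity band by default (no standard tolerance exists). Caliper tumor
volume uses the standard ellipsoid approximation d_small²·d_big/2; the
literal sum reading of the commonly printed formula string is available
behind a flag for traceability only.

## Synthetic data

The generator produces exactly what the model assumes: a second-order
truth surface per cell population plus homoscedastic mean-zero Gaussian
noise on the %CTRL scale, i.i.d. across replicates and populations
(heteroscedastic noise behind a flag). Surfaces are anchored so the
vehicle-control row evaluates to exactly 100 %CTRL. Default noise sd is
5 %CTRL with 3 replicates. Scenario effect sizes (linear −10…−20,
interactions −6…−15 %CTRL) are fixtures chosen to resemble realistic
low-dose screen effect magnitudes. Because generated data satisfy the
model assumptions exactly, calibration checks (e.g. lack-of-fit type-I
error) are well-posed — and, symmetrically, passing recovery tests
demonstrates correctness of the machinery, not that real screens are
quadratic, noise-homogeneous or plate-effect-free.

When a drug is eliminated between rounds, the truth for the next round
substitutes x = −1 (absent) for it: its linear and quadratic terms fold
into the intercept and its interactions fold into the partners' linear
terms. Skipping this substitution would simulate the wrong experiment.

## Problem sizes and numerical choices

The recovery study in the acceptance tests runs 200 seeded
Search-1→3 pipelines (155/59/35-row designs, 3 replicates, noise sd
5 %CTRL) using pooled fits per round; the lack-of-fit calibration uses
200 simulations on the 6-drug design. Key tolerances: residual-exactness
threshold 1e−9 × TSS in selection, 1e−12 × TSS for the all-zero Cook's
guard, significance α = 0.05 throughout, Cook's removal multiplier 3.

## Known limitations

* Step-wise selection inherits the usual post-selection caveats:
  reported p-values are conditional on selection and optimistic.
* Only regular two-level fractions are supported (no Plackett–Burman),
  and quadratic effects rest entirely on the 27-run OA part.
* The TW model assumes the raw viability difference is the right scale.
* Third-order models are flagged by lack of fit but never fit.
* In-vitro→in-vivo dose conversion and multi-cell-line consensus
  combinations are out of scope.
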