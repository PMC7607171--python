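# tgmo

Therapeutically guided multidrug optimization: a design-of-experiments
workflow for finding low-dose, synergistic, tumor-selective drug
combinations from a larger candidate panel.

Screening every dose combination of an 11-drug panel is impossible
(3^11 conditions), so the search is model-guided. Each round screens an
**orthogonal-array composite design** — a resolution-IV (or better)
two-level fractional factorial concatenated with the 27-run orthogonal
array OA(27, 3^13) — over the current panel at three dose levels per
drug (absent, ED10-like, ED20-like, the top dose capped at the plasma
concentration limit AUC₀₋₂₄ₕ/24 h). Measured viability (% of vehicle
control) is fit with a **step-wise second-order regression**

y = β₀ + Σᵢ βᵢxᵢ + Σᵢ βᵢᵢxᵢ² + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + ε

whose signs carry the pharmacology: βᵢⱼ < 0 is synergy, βᵢⱼ > 0
antagonism, βᵢ < 0 single-drug efficacy. A parallel fit of the
**therapeutic window** (nonmalignant − tumor viability) scores
selectivity; lack-of-fit ANOVA, Q-Q/residual summaries and
Cook's-distance outlier-removal variants decide which coefficients to
trust. Scored terms drive drug elimination across rounds
(11 → 7 → 4 by default), ending in a 3–4-drug optimized combination
whose doses are refined on the fitted surface. In-vivo combination
effects are scored against **Bliss independence** (IR = ∏Fᵢ over
single-drug fractions remaining).

A synthetic-data module generates screens from known quadratic truths,
so every stage is testable end to end with exact ground truth.

## Worked example

Run the full three-round search on a simulated screen in which drugs 1
and 2 are truly synergistic in tumor cells only:

```python
from tgmo import PanelConfig, run_pipeline, bliss_ir

cfg = PanelConfig(drugs=[f"drug{i+1}" for i in range(11)],
                  scenario="selective_synergy", seed=7)
report = run_pipeline(cfg)
odc = report["odc"]
print("rounds:", " -> ".join(str(len(r["panel"])) for r in report["rounds"]), "drugs")
print("ODC drugs:", ", ".join(odc["drugs"]))
print("predicted tumor viability: %.1f %%CTRL" % odc["predicted_tumor_viability_pct"])
print("predicted therapeutic window: %.1f points" % odc["predicted_therapeutic_window_pct"])

ir = bliss_ir([0.90, 0.82, 0.62, 1.06])
print("Bliss product: %.4f (%.1f%% remaining predicted)" % (ir.product, ir.product_pct))
```

prints

```
rounds: 11 -> 7 -> 4 drugs
ODC drugs: drug1, drug2, drug10
predicted tumor viability: 53.5 %CTRL
predicted therapeutic window: 43.7 points
Bliss product: 0.4850 (48.5% remaining predicted)
```

The truly synergistic pair (drug1, drug2) survives all elimination
rounds and anchors the final combination; predicted tumor viability is
roughly half of control while nonmalignant cells are predicted ~44
points less affected — the tumor-selective low-dose behavior the
workflow is designed to find. (The third drug is a noise passenger: on a
simulated screen an inert drug can ride along when its fitted
coefficients are slightly negative.)

The same steps are available as a CLI for file-based work:

```bash
tgmo design --n-drugs 11 --out design.csv
tgmo simulate --scenario selective_synergy --seed 7 --out screen.csv
tgmo fit --design design.csv --responses screen.csv --population tumor --out model.json
tgmo diagnose --design design.csv --responses screen.csv --out report.json
tgmo optimize --design design.csv --responses screen.csv --out odc.json
tgmo bliss --fractions fractions.csv
tgmo run --config panel.yaml --out results/
```

## Layout

- `src/tgmo/design.py` — fractional factorials, OA(27, 3^13), composite
  assembly, code→concentration mapping
- `src/tgmo/dose_response.py` — 4PL fits, ED10/ED20, PCL capping,
  trapezoidal AUC / C_max
- `src/tgmo/regression.py` — step-wise second-order fits, therapeutic
  window, combined models, prediction
- `src/tgmo/diagnostics.py` — lack-of-fit ANOVA, Cook's distance,
  outlier-removal variants, robust terms
- `src/tgmo/selection.py` — interaction calls, drug elimination, ODC
  selection, dose refinement
- `src/tgmo/metrics.py` — Bliss independence, combination-effect labels,
  tumor volume
- `src/tgmo/synthetic.py` — ground-truth surfaces and screen simulation
- `src/tgmo/io.py`, `src/tgmo/cli.py` — file formats, pipeline driver,
  CLI

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
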