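"""File formats, panel configuration and the end-to-end pipeline driver.

All tabular artifacts are UTF-8 comma-separated with a mandatory header
and '.' decimals; concentrations always travel with an explicit unit
column.  JSON reports carry a ``schema`` tag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CodedDesign, DoseEntry, DoseTable, assemble_oacd, code_to_concentration
from .diagnostics import build_model_variants, diagnostics_report, lack_of_fit_test, robust_terms
from .errors import PipelineError, TgmoError
from .regression import fit_combined, fit_stepwise_second_order, fit_therapeutic_window
from .selection import ScoreWeights, classify_interactions, eliminate_drugs, refine_doses, select_odc
from .synthetic import preset_scenarios, simulate_screen

log = logging.getLogger("tgmo")

__all__ = [
    "PanelConfig",
    "read_design_csv",
    "write_design_csv",
    "read_responses_csv",
    "write_responses_csv",
    "read_panel_yaml",
    "write_json_report",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# formats


def write_design_csv(design: CodedDesign, path) -> None:
    design.to_frame().to_csv(path, index=True)


def read_design_csv(path) -> CodedDesign:
    df = pd.read_csv(path, index_col="design_row_id")
    labels = tuple(df.pop("part"))
    names = tuple(df.columns)
    # designs read back from disk lose their generator words; resolution()
    # will refuse rather than guess
    return CodedDesign(
        codes=df.to_numpy(dtype=int),
        part_labels=labels,
        factor_names=names,
        defining_words=None,
    )


def write_responses_csv(responses: pd.DataFrame, path) -> None:
    cols = ["design_row_id", "replicate", "population", "viability_pct"]
    responses[[c for c in cols if c in responses.columns]].to_csv(path, index=False)


def read_responses_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"design_row_id", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise TgmoError(f"response CSV lacks column(s): {', '.join(sorted(missing))}")
    return df


@dataclass
class PanelConfig:
    """Run configuration: the drug panel plus pipeline thresholds."""

    drugs: list[str]
    round_sizes: list[int] = field(default_factory=lambda: [11, 7, 4])
    alpha: float = 0.05
    cooks_multiplier: float = 3.0
    tw_band: float = 5.0
    refine_grid: int = 9
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    doses: DoseTable | None = None
    scenario: str | None = None
    noise_sd: float = 5.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.drugs)) != len(self.drugs):
            raise TgmoError("drug names must be unique")
        if self.alpha <= 0 or self.cooks_multiplier <= 0 or self.tw_band <= 0:
            raise TgmoError("thresholds must be positive")
        if self.round_sizes and self.round_sizes[0] != len(self.drugs):
            raise TgmoError("first round size must equal the panel size")


def read_panel_yaml(path) -> PanelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    drugs = [d["name"] if isinstance(d, dict) else str(d) for d in raw["drugs"]]
    doses = None
    entries = {}
    for d in raw["drugs"]:
        if isinstance(d, dict) and "dose1" in d:
            entries[d["name"]] = DoseEntry(
                dose1=float(d["dose1"]),
                dose2=float(d["dose2"]),
                pcl=float(d["pcl"]) if d.get("pcl") is not None else None,
                unit=str(d.get("unit", "uM")),
            )
    if entries:
        doses = DoseTable(entries)
    kwargs = {k: raw[k] for k in (
        "round_sizes", "alpha", "cooks_multiplier", "tw_band", "refine_grid",
        "scenario", "noise_sd", "n_replicates", "seed",
    ) if k in raw}
    if "weights" in raw:
        kwargs["weights"] = ScoreWeights(**raw["weights"])
    return PanelConfig(drugs=drugs, doses=doses, **kwargs)


def write_json_report(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    config: PanelConfig,
    out_dir=None,
    responses_by_round: list[dict[str, pd.DataFrame]] | None = None,
) -> dict:
    """Run the full search: design -> fit -> diagnose -> eliminate -> ODC.

    Data either come from the named synthetic scenario in ``config`` or
    from ``responses_by_round`` (one ``{"tumor": df, "nonmalignant": df}``
    mapping per search round).  Every round fits the combined tumor and
    nonmalignant models and the therapeutic window, builds the
    outlier-removal variants, classifies terms and eliminates drugs down
    to the next round size; the final round feeds combination selection
    and dose refinement.  Artifacts are written under ``out_dir`` when
    given; the returned report contains every decision made.
    """
    truth = None
    if responses_by_round is None:
        if config.scenario is None:
            raise PipelineError("stage=data: no scenario and no response data given")
        scenarios = preset_scenarios(noise_sd=config.noise_sd, n_replicates=config.n_replicates)
        if config.scenario not in scenarios:
            raise PipelineError(
                f"stage=data: unknown scenario {config.scenario!r} "
                f"(have: {', '.join(sorted(scenarios))})"
            )
        truth = scenarios[config.scenario]
        if list(truth.drugs) != list(config.drugs):
            truth = None if len(config.drugs) != 11 else truth
            if truth is None:
                raise PipelineError("stage=data: scenario panels are 11 drugs")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema": "tgmo.run/1", "seed": config.seed, "rounds": []}
    panel = list(config.drugs)
    current_truth = truth
    last_models = None

    for rnd, size in enumerate(config.round_sizes, start=1):
        if len(panel) != size:
            raise PipelineError(
                f"stage=search{rnd}: panel has {len(panel)} drugs, round expects {size}"
            )
        design = assemble_oacd(len(panel), factor_names=panel)
        if out is not None:
            write_design_csv(design, out / f"search{rnd}_design.csv")
            if config.doses is not None:
                code_to_concentration(design, config.doses).to_csv(
                    out / f"search{rnd}_concentrations.csv"
                )
        if responses_by_round is not None:
            try:
                data = responses_by_round[rnd - 1]
            except IndexError as exc:
                raise PipelineError(f"stage=search{rnd}: no responses supplied") from exc
        else:
            data = simulate_screen(current_truth, design, seed=config.seed + rnd)
        for pop in ("tumor", "nonmalignant"):
            if pop not in data:
                raise PipelineError(f"stage=search{rnd}: missing {pop} responses")

        tumor_sets = [g for _, g in data["tumor"].groupby("replicate")]
        tumor_fit = (
            fit_combined(design, tumor_sets, population="tumor")
            if len(tumor_sets) >= 2
            else None
        )
        tumor = (
            tumor_fit.combined
            if tumor_fit is not None
            else fit_stepwise_second_order(design, data["tumor"], population="tumor")
        )
        normal = fit_stepwise_second_order(
            design, data["nonmalignant"], population="nonmalignant"
        )
        tw = fit_therapeutic_window(design, data["tumor"], data["nonmalignant"])

        variants = build_model_variants(
            design, data["tumor"], population="tumor",
            cooks_multiplier=config.cooks_multiplier,
        )
        stable = robust_terms(variants, alpha=config.alpha)
        lof = lack_of_fit_test(tumor)
        calls = classify_interactions(tumor, tw, alpha=config.alpha)
        round_report = {
            "round": rnd,
            "panel": list(panel),
            "n_rows": design.n_rows,
            "tumor_r2": tumor.r2,
            "lack_of_fit_p": lof.p_value,
            "stable_terms": stable,
            "calls": [
                {"term": c.term, "coef": c.coef, "p": c.pvalue, "label": c.label,
                 "tw_label": c.tw_label, "optimal": c.optimal}
                for c in calls
            ],
            "selection_trace": tumor.trace,
            "rows_removed_high_cooks": variants.removed_high,
        }
        if out is not None:
            write_json_report(tumor.to_report(), out / f"search{rnd}_tumor_model.json")
            write_json_report(normal.to_report(), out / f"search{rnd}_normal_model.json")
            write_json_report(tw.to_report(), out / f"search{rnd}_tw_model.json")
            write_json_report(
                diagnostics_report(tumor), out / f"search{rnd}_tumor_diagnostics.json"
            )
            for pop, df in data.items():
                write_responses_csv(df, out / f"search{rnd}_{pop}_responses.csv")
        last_models = (design, tumor, tw, calls)

        if rnd < len(config.round_sizes):
            next_size = config.round_sizes[rnd]
            kept = eliminate_drugs(calls, panel, next_size, weights=config.weights)
            dropped = [d for d in panel if d not in kept]
            round_report["eliminated"] = dropped
            log.info("search%d: eliminated %s", rnd, ", ".join(dropped) or "nothing")
            panel = kept
            if current_truth is not None:
                current_truth = current_truth.subset(panel)
        report["rounds"].append(round_report)

    design, tumor, tw, calls = last_models
    odc = select_odc(tumor, tw, tw_band=config.tw_band, calls=calls)
    final_doses = None
    if config.doses is not None:
        final_doses = DoseTable({d: config.doses[d] for d in panel if d in config.doses})
    odc = refine_doses(
        tumor, odc, constraints=final_doses, tw_model=tw,
        n_grid=config.refine_grid, tw_band=config.tw_band,
    )
    report["odc"] = odc.to_report()
    if out is not None:
        write_json_report(report, out / "run_report.json")
    return report
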