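"""Synthetic screen and dose-response generators with known ground truth.

Every input the pipeline consumes can be generated here, so each stage —
design, fitting, diagnostics, elimination, dose refinement — is testable
against a known quadratic truth without any experimental data.

A :class:`SurfaceTruth` is an exact second-order surface in the coded
dose levels (the same family the regression fits); the generated
viability is the surface plus homoscedastic mean-zero Gaussian noise on
the %CTRL scale, i.i.d. per replicate and per cell population.  Surfaces
are anchored so that the all-(-1) row (vehicle control, every drug
absent) evaluates exactly to 100 %CTRL, keeping the %CTRL semantics of
the coded model self-consistent.

What this emulates: the quadratic mean structure and replicate noise the
regression assumes.  What it does not: plate/edge effects, heteroscedastic
or correlated biological noise, deviations from a quadratic surface —
passing recovery tests here shows the machinery is correct, not that real
screens obey the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CodedDesign
from .dose_response import four_param_logistic
from .errors import TgmoError

__all__ = [
    "SurfaceTruth",
    "GroundTruth",
    "simulate_screen",
    "simulate_dose_response",
    "preset_scenarios",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """An exact second-order response surface over coded dose levels."""

    drugs: tuple[str, ...]
    beta0: float
    linear: Mapping[str, float] = field(default_factory=dict)
    quadratic: Mapping[str, float] = field(default_factory=dict)
    interaction: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "linear", dict(self.linear))
        object.__setattr__(self, "quadratic", dict(self.quadratic))
        inter = {}
        for (a, b), v in dict(self.interaction).items():
            if a == b:
                raise TgmoError("interaction terms need two distinct drugs")
            key = tuple(sorted((a, b), key=self.drugs.index))
            inter[key] = v
        object.__setattr__(self, "interaction", inter)
        known = set(self.drugs)
        for d in list(self.linear) + list(self.quadratic):
            if d not in known:
                raise TgmoError(f"unknown drug {d!r} in truth surface")
        for a, b in self.interaction:
            if a not in known or b not in known:
                raise TgmoError(f"unknown drug pair ({a}, {b}) in truth surface")

    @classmethod
    def anchored(
        cls,
        drugs: Sequence[str],
        linear: Mapping[str, float] | None = None,
        quadratic: Mapping[str, float] | None = None,
        interaction: Mapping[tuple[str, str], float] | None = None,
        control_viability: float = 100.0,
    ) -> "SurfaceTruth":
        """Build a surface whose all-(-1) (vehicle control) value is fixed.

        Solves for beta0 so that f(-1, ..., -1) = ``control_viability``:
        at the control row each linear term contributes -beta_i and each
        quadratic/interaction term +beta.
        """
        linear = dict(linear or {})
        quadratic = dict(quadratic or {})
        interaction = dict(interaction or {})
        beta0 = (
            control_viability
            + sum(linear.values())
            - sum(quadratic.values())
            - sum(interaction.values())
        )
        return cls(tuple(drugs), beta0, linear, quadratic, interaction)

    def evaluate(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=float))
        idx = {d: j for j, d in enumerate(self.drugs)}
        y = np.full(codes.shape[0], self.beta0)
        for d, b in self.linear.items():
            y = y + b * codes[:, idx[d]]
        for d, b in self.quadratic.items():
            y = y + b * codes[:, idx[d]] ** 2
        for (a, b_), v in self.interaction.items():
            y = y + v * codes[:, idx[a]] * codes[:, idx[b_]]
        return y

    def subset(self, keep: Sequence[str]) -> "SurfaceTruth":
        """Truth restricted to a drug subset, with the rest *absent*.

        An eliminated drug sits at code -1 (no dose), not 0, so its terms
        do not simply vanish: its linear and quadratic terms fold into the
        intercept and its interactions fold into the partners' linear
        terms (beta_i - beta_ri for removed drug r).
        """
        keep = tuple(keep)
        for d in keep:
            if d not in self.drugs:
                raise TgmoError(f"unknown drug {d!r}")
        removed = [d for d in self.drugs if d not in keep]
        beta0 = self.beta0
        linear = {d: v for d, v in self.linear.items() if d in keep}
        quadratic = {d: v for d, v in self.quadratic.items() if d in keep}
        interaction = {}
        for d in removed:
            beta0 -= self.linear.get(d, 0.0)  # x_r = -1
            beta0 += self.quadratic.get(d, 0.0)  # x_r^2 = 1
        for (a, b), v in self.interaction.items():
            a_in, b_in = a in keep, b in keep
            if a_in and b_in:
                interaction[(a, b)] = v
            elif a_in:
                linear[a] = linear.get(a, 0.0) - v  # partner at -1
            elif b_in:
                linear[b] = linear.get(b, 0.0) - v
            else:
                beta0 += v  # (-1) * (-1)
        return SurfaceTruth(keep, beta0, linear, quadratic, interaction)


@dataclass(frozen=True)
class GroundTruth:
    """Tumor and nonmalignant truth surfaces plus the noise model."""

    tumor: SurfaceTruth
    nonmalignant: SurfaceTruth
    noise_sd: float = 5.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise TgmoError("noise sd must be nonnegative")
        if self.n_replicates < 1:
            raise TgmoError("at least one replicate is required")
        if self.tumor.drugs != self.nonmalignant.drugs:
            raise TgmoError("tumor and nonmalignant truths must share the drug panel")

    @property
    def drugs(self) -> tuple[str, ...]:
        return self.tumor.drugs

    def subset(self, keep: Sequence[str]) -> "GroundTruth":
        return replace(
            self, tumor=self.tumor.subset(keep), nonmalignant=self.nonmalignant.subset(keep)
        )


def simulate_screen(
    truth: GroundTruth,
    design: CodedDesign,
    seed: int,
    heteroscedastic: bool = False,
) -> dict[str, pd.DataFrame]:
    """Simulate a combination screen on both cell populations.

    Returns ``{"tumor": df, "nonmalignant": df}`` in the response-CSV
    layout (design_row_id, replicate, population, viability_pct).  With
    ``heteroscedastic=True`` the noise sd scales with the mean response
    (sd * y/100) instead of being constant.
    """
    if tuple(design.factor_names) != truth.drugs:
        raise TgmoError("design drugs do not match the ground truth panel")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for pop, surface in (("tumor", truth.tumor), ("nonmalignant", truth.nonmalignant)):
        mean = surface.evaluate(design.codes)
        rows = []
        for rep in range(truth.n_replicates):
            sd = truth.noise_sd * (np.abs(mean) / 100.0 if heteroscedastic else 1.0)
            y = mean + rng.normal(0.0, 1.0, size=len(mean)) * sd
            rows.append(
                pd.DataFrame(
                    {
                        "design_row_id": np.arange(design.n_rows),
                        "replicate": rep,
                        "population": pop,
                        "viability_pct": y,
                    }
                )
            )
        out[pop] = pd.concat(rows, ignore_index=True)
    return out


def simulate_dose_response(
    top: float,
    bottom: float,
    ec50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy samples of a forward 4PL curve (dose, replicate, viability)."""
    if noise_sd < 0:
        raise TgmoError("noise sd must be nonnegative")
    if n_replicates < 1:
        raise TgmoError("at least one replicate is required")
    d = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = four_param_logistic(d, top, bottom, ec50, hill)
        y = y + rng.normal(0.0, noise_sd, size=len(d)) if noise_sd > 0 else y
        rows.append(pd.DataFrame({"dose": d, "replicate": rep, "viability_pct": y}))
    return pd.concat(rows, ignore_index=True)


def _drugs11() -> tuple[str, ...]:
    return tuple(f"drug{i + 1}" for i in range(11))


def preset_scenarios(noise_sd: float = 5.0, n_replicates: int = 3) -> dict[str, GroundTruth]:
    """Named ground-truth scenarios for an 11-drug panel.

    * ``one_synergistic_pair`` — one truly synergistic pair (drug1:drug2)
      among additive actives and inert drugs; the canonical recovery
      benchmark.
    * ``selective_synergy`` — the interaction exists in tumor cells only,
      so the therapeutic-window model shows it with a positive sign.
    * ``flat_surface_synergy`` — a dose-robust pair: synergy plus positive
      quadratic (stable-over-range) terms.
    * ``hormetic_single`` — one drug increases viability at low dose
      (positive linear term), a pattern seen with some kinase inhibitors.
    * ``null`` — no active drug at all; the pipeline should end with a
      warning-flagged combination.
    """
    drugs = _drugs11()
    inert_normal = SurfaceTruth.anchored(drugs, linear={"drug3": -4.0, "drug5": -3.0})

    def gt(tumor: SurfaceTruth, normal: SurfaceTruth | None = None) -> GroundTruth:
        return GroundTruth(
            tumor=tumor,
            nonmalignant=normal if normal is not None else inert_normal,
            noise_sd=noise_sd,
            n_replicates=n_replicates,
        )

    scenarios: dict[str, GroundTruth] = {}
    scenarios["one_synergistic_pair"] = gt(
        SurfaceTruth.anchored(
            drugs,
            linear={"drug1": -15.0, "drug2": -12.0, "drug3": -10.0, "drug4": -8.0, "drug5": -6.0},
            interaction={("drug1", "drug2"): -12.0},
        )
    )
    scenarios["selective_synergy"] = gt(
        SurfaceTruth.anchored(
            drugs,
            linear={"drug1": -12.0, "drug2": -10.0, "drug4": -6.0},
            interaction={("drug1", "drug2"): -15.0},
        ),
        SurfaceTruth.anchored(drugs, linear={"drug4": -4.0}),
    )
    scenarios["flat_surface_synergy"] = gt(
        SurfaceTruth.anchored(
            drugs,
            linear={"drug1": -14.0, "drug2": -11.0, "drug3": -7.0},
            quadratic={"drug1": 6.0, "drug2": 5.0},
            interaction={("drug1", "drug2"): -10.0},
        )
    )
    scenarios["hormetic_single"] = gt(
        SurfaceTruth.anchored(
            drugs,
            linear={"drug1": -15.0, "drug2": -12.0, "drug6": 8.0, "drug3": -9.0},
            interaction={("drug1", "drug2"): -10.0},
        )
    )
    scenarios["null"] = gt(SurfaceTruth.anchored(drugs), SurfaceTruth.anchored(drugs))
    return scenarios
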