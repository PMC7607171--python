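"""Combination-effect scoring outside the regression models.

Bliss independence is the multiplicative null model for a combination:
if drug i alone leaves a fraction F_i of tumor volume (or viability)
relative to untreated control, independent action predicts the
combination leaves prod_i F_i.  An observed effect beyond that prediction
is synergy; short of it, antagonism.

A note on scales: the product of remaining fractions is itself a
*remaining* fraction.  Some reports nevertheless quote the product
directly on a percent "inhibition" scale; :class:`BlissResult` therefore
exposes the raw product, that percent convention (``product * 100``) and
the complement (``(1 - product) * 100``) under unambiguous names so the
two readings can never be confused downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import TgmoError

__all__ = [
    "BlissResult",
    "bliss_ir",
    "classify_combination_effect",
    "tumor_volume",
]


@dataclass(frozen=True)
class BlissResult:
    """Bliss-independence prediction for a drug combination."""

    fractions: tuple[float, ...]
    product: float  # predicted fraction remaining under independence

    @property
    def product_pct(self) -> float:
        """The product on a percent scale (the convention some reports use
        when quoting the predicted 'inhibition rate')."""
        return self.product * 100.0

    @property
    def complement_pct(self) -> float:
        """Predicted percent inhibition: (1 - product) * 100."""
        return (1.0 - self.product) * 100.0


def bliss_ir(fractions: Iterable[float]) -> BlissResult:
    """Bliss-independence product of single-drug remaining fractions.

    ``fractions`` are F_i = (volume or viability after drug i alone) /
    (untreated control), so F_i > 1 is a growth-stimulating drug and is
    allowed.  At least two drugs are required.
    """
    f = tuple(float(x) for x in fractions)
    if len(f) < 2:
        raise TgmoError("Bliss independence needs at least 2 single-drug fractions")
    if any(x <= 0 for x in f):
        raise TgmoError("remaining fractions must be strictly positive")
    return BlissResult(fractions=f, product=float(np.prod(f)))


def classify_combination_effect(
    observed: float,
    predicted: float,
    tolerance: float = 5.0,
    scale: Literal["fraction", "inhibition_pct"] = "fraction",
) -> str:
    """Label a combination synergistic / additive / antagonistic.

    ``observed`` and ``predicted`` must share a scale: either fractions
    remaining (both in (0, inf)) or percent inhibition.  Both are
    converted to percent inhibition internally; the combination is
    synergistic when observed inhibition exceeds the Bliss prediction by
    more than ``tolerance`` percentage points, antagonistic when it falls
    short by more, additive within the band.
    """
    if scale == "fraction":
        if observed <= 0 or predicted <= 0:
            raise TgmoError("fractions remaining must be strictly positive")
        obs_inh = (1.0 - observed) * 100.0
        pred_inh = (1.0 - predicted) * 100.0
    elif scale == "inhibition_pct":
        obs_inh, pred_inh = float(observed), float(predicted)
    else:
        raise TgmoError(f"unknown scale {scale!r}; mismatched scales are not guessed")
    if obs_inh > pred_inh + tolerance:
        return "synergistic"
    if obs_inh < pred_inh - tolerance:
        return "antagonistic"
    return "additive"


def tumor_volume(d_small: float, d_big: float, literal_sum: bool = False) -> float:
    """Caliper tumor volume from two perpendicular diameters (mm).

    Default is the standard ellipsoid approximation
    V = d_small^2 * d_big / 2.  ``literal_sum=True`` instead evaluates
    d_small^2 + d_big / 2, the word-for-word reading of the formula as it
    is sometimes printed; it is provided for traceability only.
    """
    if d_small <= 0 or d_big <= 0:
        raise TgmoError("diameters must be strictly positive")
    if d_small > d_big:
        raise TgmoError("smallest diameter exceeds biggest diameter")
    if literal_sum:
        return d_small**2 + d_big / 2.0
    return d_small**2 * d_big / 2.0
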