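"""Orthogonal-array composite designs (OACD) for multidrug screening.

An OACD concatenates two parts:

* a regular two-level fractional factorial (codes -1/+1) that exposes
  single-drug linear effects and two-drug interactions over a large search
  space, and
* the 27-run strength-2 orthogonal array OA(27, 3^13) (codes -1/0/+1)
  that makes quadratic (dose-range) effects estimable.

Dose-level coding throughout: ``-1`` = drug absent ("dose 0"), ``0`` =
dose 1 (the lower screening dose), ``+1`` = dose 2 (the higher screening
dose).  The two-level part uses only {-1, +1}, i.e. absent vs. highest
dose; this orientation is fixed here so that the all-(-1) row is the
vehicle control.

All two-level fractions built here are regular and of resolution >= IV:
main effects are never aliased with two-factor interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = [
    "CodedDesign",
    "DoseEntry",
    "DoseTable",
    "build_two_level_ff",
    "build_three_level_oa",
    "assemble_oacd",
    "resolution",
    "code_to_concentration",
    "FULL_FACTORIAL",
]

# Factor letters for generator notation; I is skipped (reserved for the
# identity element of the defining relation), O resembles zero.
LETTERS = "ABCDEFGHJKLMNPQRSTUVWXYZ"

#: Sentinel returned by :func:`resolution` for a full factorial.
FULL_FACTORIAL = math.inf

# Generator words for the "auto" two-level fractions, n_factors -> list of
# "NEW=BASE..." strings.  Chosen from standard resolution-IV (or better)
# regular fractions; each set is verified by brute-force word enumeration
# in the test suite.  Empty list = full factorial.
_AUTO_GENERATORS: dict[int, list[str]] = {
    2: [],
    3: [],  # 2^(3-1) would be resolution III; use the full 8-run factorial
    4: ["D=ABC"],
    5: ["E=ABCD"],
    6: ["E=ABC", "F=BCD"],
    7: ["F=ABCD", "G=ABCE"],
    8: ["F=ABC", "G=ABD", "H=BCDE"],
    9: ["F=ABC", "G=ABD", "H=ACD", "J=BCD"],
    10: ["F=ABC", "G=ABD", "H=ACD", "J=BCD", "K=ABCDE"],
    11: ["H=ABCD", "J=ABEF", "K=ACEG", "L=BDFG"],
}


@dataclass(frozen=True)
class CodedDesign:
    """A coded dose-level design matrix.

    Parameters
    ----------
    codes
        Integer matrix, rows = drug combinations, columns = drugs; entries
        in {-1, 0, +1}.
    part_labels
        Per-row tag, ``"two_level_ff"`` or ``"three_level_oa"``.
    factor_names
        Drug identifier per column.
    defining_words
        For a regular two-level fraction, the generator words as frozensets
        of column indices (empty tuple for a full factorial); ``None`` when
        the two-level part is not a known regular fraction (e.g. a design
        read back from CSV), in which case :func:`resolution` refuses.
    """

    codes: np.ndarray
    part_labels: tuple[str, ...]
    factor_names: tuple[str, ...]
    defining_words: tuple[frozenset[int], ...] | None = field(default=())

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "part_labels", tuple(self.part_labels))
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        if codes.ndim != 2:
            raise DesignError("codes must be a 2-D matrix")
        if codes.shape[0] != len(self.part_labels):
            raise DesignError("one part label per design row is required")
        if codes.shape[1] != len(self.factor_names):
            raise DesignError("one factor name per design column is required")
        if not np.isin(codes, (-1, 0, 1)).all():
            raise DesignError("dose-level codes must be in {-1, 0, +1}")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_factors(self) -> int:
        return self.codes.shape[1]

    def part(self, label: str) -> np.ndarray:
        """Rows of one part of the composite design."""
        mask = np.array([p == label for p in self.part_labels])
        return self.codes[mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=list(self.factor_names))
        df.insert(0, "part", list(self.part_labels))
        df.index.name = "design_row_id"
        return df


def _default_names(n_factors: int) -> tuple[str, ...]:
    return tuple(f"drug{i + 1}" for i in range(n_factors))


def _parse_generator(word: str, n_base: int) -> tuple[int, frozenset[int]]:
    """Parse ``"E=ABC"`` into (new column letter index, base column set)."""
    try:
        lhs, rhs = word.replace(" ", "").split("=")
    except ValueError as exc:
        raise DesignError(f"malformed generator {word!r}; expected 'NEW=BASES'") from exc
    if len(lhs) != 1 or lhs not in LETTERS:
        raise DesignError(f"generator {word!r}: left side must be a single factor letter")
    new_idx = LETTERS.index(lhs)
    base: set[int] = set()
    for ch in rhs:
        if ch not in LETTERS or LETTERS.index(ch) >= n_base:
            raise DesignError(
                f"generator {word!r} references {ch!r}, which is not one of the "
                f"{n_base} base columns"
            )
        base.add(LETTERS.index(ch))
    if len(base) < 2:
        raise DesignError(f"generator {word!r} must use at least two base columns")
    return new_idx, frozenset(base)


def build_two_level_ff(
    n_factors: int,
    generators: Sequence[str] | str = "auto",
    factor_names: Sequence[str] | None = None,
) -> CodedDesign:
    """Build a regular two-level fractional factorial of resolution >= IV.

    Parameters
    ----------
    n_factors
        Number of drugs (2..11 for the built-in generator table).
    generators
        ``"auto"`` to use the built-in resolution-IV generator sets, or an
        explicit list of defining words such as ``["D=ABC"]``.  An empty
        list requests the full factorial.
    factor_names
        Optional drug names (defaults to ``drug1..drugN``).

    Raises
    ------
    DesignError
        If no resolution-IV regular fraction is known for the request, or
        the supplied generators yield resolution < IV.
    """
    if n_factors < 2:
        raise DesignError("a two-level factorial needs at least 2 factors")
    if generators == "auto":
        if n_factors not in _AUTO_GENERATORS:
            raise DesignError(
                f"no built-in resolution-IV fraction for {n_factors} factors "
                f"(supported: {sorted(_AUTO_GENERATORS)})"
            )
        generators = _AUTO_GENERATORS[n_factors]
    generators = list(generators)
    n_base = n_factors - len(generators)
    if n_base < 2:
        raise DesignError("too many generators: fewer than 2 base columns left")

    base = np.array(list(product((-1, 1), repeat=n_base)), dtype=int)
    columns = [base[:, i] for i in range(n_base)]
    words: list[frozenset[int]] = []
    for k, word in enumerate(generators):
        new_idx, base_set = _parse_generator(word, n_base)
        if new_idx != n_base + k:
            raise DesignError(
                f"generator {word!r}: expected new factor {LETTERS[n_base + k]!r} "
                f"(generators must define columns in order)"
            )
        columns.append(np.prod([base[:, i] for i in sorted(base_set)], axis=0))
        words.append(frozenset(base_set | {new_idx}))

    codes = np.column_stack(columns)
    design = CodedDesign(
        codes=codes,
        part_labels=("two_level_ff",) * codes.shape[0],
        factor_names=tuple(factor_names) if factor_names else _default_names(n_factors),
        defining_words=tuple(words),
    )
    res = resolution(design)
    if res < 4:
        raise DesignError(
            f"requested generators give resolution {res} < IV; main effects "
            f"would be aliased with two-factor interactions"
        )
    return design


def resolution(design: CodedDesign) -> float:
    """Resolution of the two-level fractional-factorial part.

    Returns the length of the shortest word in the defining relation,
    found by brute-force enumeration of all products of the generator
    words.  A full factorial returns the ``FULL_FACTORIAL`` (infinity)
    sentinel.
    """
    words = design.defining_words
    if words is None:
        raise DesignError(
            "design is not a known regular fraction; resolution is undefined"
        )
    if len(words) == 0:
        return FULL_FACTORIAL
    best = None
    for r in range(1, len(words) + 1):
        for combo in combinations(words, r):
            prod_word: frozenset[int] = frozenset()
            for w in combo:
                prod_word = prod_word.symmetric_difference(w)
            if best is None or len(prod_word) < best:
                best = len(prod_word)
    return int(best)


def _oa27_coefficients() -> list[tuple[int, int, int]]:
    """Column-defining coefficient vectors of OA(27, 3^13).

    The 27 runs are all points of GF(3)^3; each of the 13 columns is a
    nonzero linear functional, one representative per projective
    direction (first nonzero coefficient equal to 1).  Any two such
    functionals are linearly independent, which yields the strength-2
    property: every ordered level pair appears 27/9 = 3 times.
    """
    coeffs = []
    for v in product(range(3), repeat=3):
        if v == (0, 0, 0):
            continue
        first = next(x for x in v if x != 0)
        if first == 1:
            coeffs.append(v)
    return coeffs  # 13 vectors


def build_three_level_oa(
    n_factors: int, factor_names: Sequence[str] | None = None
) -> CodedDesign:
    """27-run three-level orthogonal array, recoded to {-1, 0, +1}.

    Constructs OA(27, 3^13) of strength 2 and keeps the first
    ``n_factors`` columns.  Level recoding is 0 -> -1 (no drug),
    1 -> 0 (dose 1), 2 -> +1 (dose 2), so the run at the origin of
    GF(3)^3 becomes the all-(-1) vehicle-control row.
    """
    if n_factors < 2:
        raise DesignError("the orthogonal array needs at least 2 factors")
    if n_factors > 13:
        raise DesignError(
            f"OA(27, 3^13) supports at most 13 factors, got {n_factors}"
        )
    coeffs = _oa27_coefficients()[:n_factors]
    runs = np.array(list(product(range(3), repeat=3)), dtype=int)
    levels = np.column_stack([runs @ np.array(c) % 3 for c in coeffs])
    codes = levels - 1  # {0,1,2} -> {-1,0,+1}
    return CodedDesign(
        codes=codes,
        part_labels=("three_level_oa",) * 27,
        factor_names=tuple(factor_names) if factor_names else _default_names(n_factors),
        defining_words=None,
    )


def assemble_oacd(
    n_factors: int,
    generators: Sequence[str] | str = "auto",
    factor_names: Sequence[str] | None = None,
) -> CodedDesign:
    """Assemble the composite design: two-level fraction + 27-run OA.

    For 11 drugs this is a 2^(11-4) resolution-V fraction (128 runs) plus
    OA(27, 3^13) restricted to 11 columns — 155 combinations in total.
    A vehicle-control row (all codes -1) is appended once if neither part
    already contains it; with the built-in OA construction it is always
    present (the array's origin run), so no row is added.
    """
    names = tuple(factor_names) if factor_names else _default_names(n_factors)
    ff = build_two_level_ff(n_factors, generators=generators, factor_names=names)
    oa = build_three_level_oa(n_factors, factor_names=names)
    codes = np.vstack([ff.codes, oa.codes])
    labels = ff.part_labels + oa.part_labels
    control = -np.ones(n_factors, dtype=int)
    if not (codes == control).all(axis=1).any():
        codes = np.vstack([codes, control])
        labels = labels + ("control",)
    return CodedDesign(
        codes=codes,
        part_labels=labels,
        factor_names=names,
        defining_words=ff.defining_words,
    )


@dataclass(frozen=True)
class DoseEntry:
    """Screening doses for one drug.

    ``dose1`` is the low dose (ED10-like, typically dose2/2), ``dose2``
    the high dose (ED20 capped at the plasma concentration limit).
    """

    dose1: float
    dose2: float
    pcl: float | None = None
    unit: str = "uM"

    def __post_init__(self) -> None:
        if not (0 < self.dose1 < self.dose2):
            raise DesignError(
                f"doses must satisfy 0 < dose1 < dose2, got ({self.dose1}, {self.dose2})"
            )
        if self.pcl is not None and self.dose2 > self.pcl * (1 + 1e-12):
            raise DesignError(
                f"dose2 = {self.dose2} exceeds the plasma concentration limit {self.pcl}"
            )


@dataclass(frozen=True)
class DoseTable:
    """Per-drug screening doses, keyed by drug name."""

    entries: Mapping[str, DoseEntry]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    def __getitem__(self, drug: str) -> DoseEntry:
        return self.entries[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"drug": d, "dose1": e.dose1, "dose2": e.dose2, "pcl": e.pcl, "unit": e.unit}
            for d, e in self.entries.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseTable":
        entries = {}
        for _, r in df.iterrows():
            pcl = r.get("pcl")
            entries[str(r["drug"])] = DoseEntry(
                dose1=float(r["dose1"]),
                dose2=float(r["dose2"]),
                pcl=None if pcl is None or pd.isna(pcl) else float(pcl),
                unit=str(r.get("unit", "uM")),
            )
        return cls(entries)


def code_to_concentration(
    design: CodedDesign,
    doses: DoseTable,
    allow_fractional: bool = False,
    codes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Translate coded dose levels into plate concentrations.

    Integer codes map as -1 -> 0 (no drug), 0 -> dose1, +1 -> dose2.  With
    ``allow_fractional`` the map is continuous and piecewise linear in the
    code (0 at -1, dose1 at 0, dose2 at +1), which is how refined
    fractional doses are converted back to concentrations.

    Returns a DataFrame (rows in design order, one column per drug) with a
    ``unit`` column recording each drug's concentration unit.
    """
    missing = [d for d in design.factor_names if d not in doses]
    if missing:
        raise DesignError(f"no dose entry for drug(s): {', '.join(missing)}")
    mat = np.asarray(design.codes if codes is None else codes, dtype=float)
    if not allow_fractional and not np.isin(mat, (-1, 0, 1)).all():
        raise DesignError("fractional codes require allow_fractional=True")
    if ((mat < -1 - 1e-9) | (mat > 1 + 1e-9)).any():
        raise DesignError("codes must lie within [-1, +1]")
    out = {}
    for j, drug in enumerate(design.factor_names):
        e = doses[drug]
        c = mat[:, j]
        conc = np.where(c <= 0, e.dose1 * (c + 1), e.dose1 + (e.dose2 - e.dose1) * c)
        out[drug] = conc
    df = pd.DataFrame(out)
    df.index.name = "design_row_id"
    units = {doses[d].unit for d in design.factor_names}
    df.attrs["units"] = {d: doses[d].unit for d in design.factor_names}
    df["unit"] = [",".join(sorted(units))] * len(df) if len(units) > 1 else next(iter(units))
    return df
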