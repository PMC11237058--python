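"""Exact monoisotopic masses, ion m/z and isotopologue bookkeeping.

This module is the mass-arithmetic core: neutral molecular formulas,
stable-isotope label specifications (¹³C, ¹⁵N, ²H with an explicit flag for
the α-carbon deuterium that transamination removes), singly charged ±H
adduct m/z, and the combinatorics of isotopologue distributions such as the
self-convolution that predicts dipeptide labeling from a free amino-acid
pool.

Masses come exclusively from :mod:`isodrift.constants`. All internal
arithmetic is full double precision; :func:`round_mz` provides the
half-up 4-decimal rounding used when values are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterator, Mapping

from .constants import LABEL_SHIFT, MONOISOTOPIC_MASS, PROTON_MASS, SUPPORTED_ELEMENTS

__all__ = [
    "ChemistryError",
    "MolecularFormula",
    "LabelSpec",
    "Polarity",
    "Adduct",
    "IonSpecies",
    "IsotopologueDistribution",
    "monoisotopic_mass",
    "ion_mz",
    "label_mass_shift",
    "ppm_delta",
    "condense_formulas",
    "dipeptide_label_distribution",
    "round_mz",
    "WATER",
]


class ChemistryError(ValueError):
    """Invalid formula, label specification or ion request."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_mz(value: float, ndigits: int = 4) -> float:
    """Round half-up to `ndigits` decimals (reporting convention for m/z)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MolecularFormula:
    """Neutral molecular formula over C, H, N, O, S, P.

    Parameters
    ----------
    element_counts
        Mapping element symbol -> non-negative count. At least one element
        must have a positive count.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = {}
        for el, n in self.element_counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise ChemistryError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ChemistryError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n:
                counts[el] = n
        if not counts:
            raise ChemistryError("formula must contain at least one atom")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse Hill-like notation, e.g. ``"C5H9NO4"`` (case sensitive)."""
        if not text or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
            raise ChemistryError(f"cannot parse formula string {text!r}")
        counts: dict[str, int] = {}
        for el, digits in _FORMULA_TOKEN.findall(text):
            if not el:
                continue
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        return cls(counts)

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ChemistryError(
                    f"subtraction would leave a negative {el} count ({new})"
                )
            if new == 0:
                counts.pop(el, None)
            else:
                counts[el] = new
        return MolecularFormula(counts)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        order = ["C", "H"] + sorted(set(self.element_counts) - {"C", "H"})
        return "".join(
            f"{el}{self.element_counts[el] if self.element_counts[el] > 1 else ''}"
            for el in order
            if el in self.element_counts
        )


WATER = MolecularFormula({"H": 2, "O": 1})


@dataclass(frozen=True)
class LabelSpec:
    """Counts of stable-isotope substitutions on one molecule.

    ``alpha_D`` marks that one of the ``n_D`` deuteriums sits on the
    α-carbon — the only position-specific chemistry the transaminase model
    needs, because that deuterium is lost to solvent on deamination.
    """

    n_13C: int = 0
    n_15N: int = 0
    n_D: int = 0
    alpha_D: bool = False

    def __post_init__(self) -> None:
        for name in ("n_13C", "n_15N", "n_D"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ChemistryError(f"{name} must be a non-negative integer, got {v!r}")
        if self.alpha_D and self.n_D < 1:
            raise ChemistryError("alpha_D requires n_D >= 1")

    @property
    def unlabeled(self) -> bool:
        return self.n_13C == 0 and self.n_15N == 0 and self.n_D == 0

    @property
    def nominal_shift(self) -> int:
        """Nominal mass shift in Da (the M+n index of the isotopologue)."""
        return self.n_13C + self.n_15N + self.n_D

    def validate_against(self, formula: MolecularFormula) -> None:
        limits = {"n_13C": ("C", self.n_13C), "n_15N": ("N", self.n_15N), "n_D": ("H", self.n_D)}
        for name, (el, n) in limits.items():
            if n > formula.count(el):
                raise ChemistryError(
                    f"{name}={n} exceeds the {el} count ({formula.count(el)}) of {formula}"
                )


NO_LABELS = LabelSpec()


class Polarity(Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"


class Adduct(Enum):
    M_MINUS_H = "[M-H]-"
    M_PLUS_H = "[M+H]+"


_ADDUCT_POLARITY = {Adduct.M_MINUS_H: Polarity.NEGATIVE, Adduct.M_PLUS_H: Polarity.POSITIVE}


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ±H adduct ion."""

    adduct: Adduct
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ChemistryError("only singly charged ions are supported (charge must be 1)")

    @property
    def polarity(self) -> Polarity:
        return _ADDUCT_POLARITY[self.adduct]


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Distribution of nominal mass shifts (Da above unlabeled) -> fraction."""

    fractions: Mapping[int, float]

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        cleaned: dict[int, float] = {}
        for shift, frac in self.fractions.items():
            if not isinstance(shift, int) or shift < 0:
                raise ChemistryError(f"mass shift keys must be non-negative integers, got {shift!r}")
            if frac < 0:
                raise ChemistryError(f"fraction for M+{shift} is negative")
            if frac > 0:
                cleaned[shift] = float(frac)
        total = sum(cleaned.values())
        if abs(total - 1.0) > self._SUM_TOL:
            raise ChemistryError(f"fractions must sum to 1 (got {total!r})")
        object.__setattr__(self, "fractions", cleaned)

    def __getitem__(self, shift: int) -> float:
        return self.fractions.get(shift, 0.0)

    def items(self) -> Iterator[tuple[int, float]]:
        return iter(sorted(self.fractions.items()))

    def probability(self, shifts) -> float:
        """Total probability mass on a collection of shifts."""
        return sum(self.fractions.get(int(s), 0.0) for s in shifts)

    def convolve(self, other: "IsotopologueDistribution") -> "IsotopologueDistribution":
        out: dict[int, float] = {}
        for s1, f1 in self.fractions.items():
            for s2, f2 in other.fractions.items():
                out[s1 + s2] = out.get(s1 + s2, 0.0) + f1 * f2
        total = sum(out.values())
        return IsotopologueDistribution({k: v / total for k, v in out.items()})


def monoisotopic_mass(formula: MolecularFormula, labels: LabelSpec = NO_LABELS) -> float:
    """Neutral monoisotopic mass in Da including isotope-label shifts."""
    labels.validate_against(formula)
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.element_counts.items())
    return mass + label_mass_shift(labels)


def label_mass_shift(labels: LabelSpec) -> float:
    """Total exact-mass shift (Da) of a label specification, linear in counts."""
    return (
        labels.n_13C * LABEL_SHIFT["13C"]
        + labels.n_15N * LABEL_SHIFT["15N"]
        + labels.n_D * LABEL_SHIFT["D"]
    )


def ion_mz(
    formula: MolecularFormula,
    labels: LabelSpec = NO_LABELS,
    ion: IonSpecies = IonSpecies(Adduct.M_MINUS_H),
) -> float:
    """m/z of a singly charged [M-H]- or [M+H]+ ion (full precision)."""
    mass = monoisotopic_mass(formula, labels)
    if ion.adduct is Adduct.M_MINUS_H:
        return mass - PROTON_MASS
    return mass + PROTON_MASS


def ppm_delta(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ChemistryError("theoretical m/z must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def condense_formulas(
    a: MolecularFormula,
    b: MolecularFormula,
    loss: MolecularFormula = WATER,
) -> MolecularFormula:
    """Elementwise a + b − loss, e.g. peptide-bond condensation of two residues."""
    return (a + b) - loss


def dipeptide_label_distribution(pool: IsotopologueDistribution) -> IsotopologueDistribution:
    """Isotopologue distribution of a dipeptide whose two residues are drawn
    independently from ``pool`` (discrete self-convolution).

    Used as the null model for dipeptide formation sourced entirely from a
    free amino-acid pool: e.g. a pool with 25% D4, 25% D5 and 50% unlabeled
    glutamate predicts 25% of the dipeptide at M+8/M+9/M+10.
    """
    return pool.convolve(pool)
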