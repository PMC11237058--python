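"""Internal-standard calibration, label-ratio quantitation and tracer
mole balance.

Two quantitation routes are provided. The standard route fits a
calibration curve of the ISTD-to-analyte peak-area ratio against known
concentrations and interpolates unknowns. When the internal standard
itself is being interconverted by residual enzyme activity (the situation
this package exists for), that route is invalid; the workaround multiplies
the labeled/unlabeled area ratio in the sample by an independently
determined endogenous concentration.

:func:`mole_balance` sums tracer skeleton-equivalents (whole ¹³C₅
backbones, or ¹⁵N atoms) across labeled species per replicate, so that
conservation of the spiked tracer across metabolic neighbors can be
demonstrated or refuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem import LabelSpec

__all__ = [
    "QuantError",
    "CalibrationModel",
    "QuantResult",
    "BalanceTable",
    "fit_calibration",
    "concentration_from_ratio",
    "quantify_by_label_ratio",
    "mole_balance",
    "tissue_normalize",
]


class QuantError(ValueError):
    """Invalid quantitation input."""


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line of area ratio on known concentration, with diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    analyte: str = ""
    istd: str = ""
    standards_uM: tuple = ()
    standards_ratio: tuple = ()

    @property
    def concentration_range(self) -> tuple[float, float]:
        return (min(self.standards_uM), max(self.standards_uM))


@dataclass(frozen=True)
class QuantResult:
    """One quantified analyte concentration with provenance."""

    analyte: str
    concentration_uM: float
    method: str  # "calibration" | "label_ratio"
    reference: str = ""
    clamped: bool = False
    extrapolated: bool = False


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    analyte: str = "",
    istd: str = "",
    weighting: str | None = None,
) -> CalibrationModel:
    """Fit the calibration line ratio = slope * known_uM + intercept.

    ``standards`` are (known µM, area ratio) pairs; at least three points
    over at least two distinct concentrations are required. Unweighted OLS
    by default; ``weighting`` of ``"1/x"`` or ``"1/x2"`` enables inverse-
    concentration weighted least squares (zero-concentration standards get
    the smallest positive concentration's weight).
    """
    if len(standards) < 3:
        raise QuantError("need at least 3 calibration standards")
    x = np.array([s[0] for s in standards], dtype=float)
    y = np.array([s[1] for s in standards], dtype=float)
    if np.unique(x).size < 2:
        raise QuantError("calibration standards must span >= 2 distinct concentrations")
    X = sm.add_constant(x)
    if weighting is None:
        res = sm.OLS(y, X).fit()
    else:
        xw = np.where(x > 0, x, x[x > 0].min() if np.any(x > 0) else 1.0)
        if weighting == "1/x":
            w = 1.0 / xw
        elif weighting in ("1/x2", "1/x^2"):
            w = 1.0 / xw**2
        else:
            raise QuantError(f"unknown weighting {weighting!r}")
        res = sm.WLS(y, X, weights=w).fit()
    return CalibrationModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        analyte=analyte,
        istd=istd,
        standards_uM=tuple(x),
        standards_ratio=tuple(y),
    )


def concentration_from_ratio(model: CalibrationModel, ratio: float) -> QuantResult:
    """Invert the calibration line; clamp negative interpolations to 0."""
    if model.slope <= 0:
        raise QuantError("calibration slope must be positive to interpolate")
    conc = (ratio - model.intercept) / model.slope
    clamped = conc < 0
    if clamped:
        warnings.warn(
            f"negative interpolated concentration ({conc:.4g} µM) clamped to 0",
            stacklevel=2,
        )
        conc = 0.0
    lo, hi = model.concentration_range
    return QuantResult(
        analyte=model.analyte,
        concentration_uM=float(conc),
        method="calibration",
        reference=model.istd,
        clamped=bool(clamped),
        extrapolated=bool(conc < lo or conc > hi),
    )


def quantify_by_label_ratio(
    labeled_area: float,
    unlabeled_area: float,
    reference_endogenous_uM: float,
    analyte: str = "",
) -> QuantResult:
    """Quantify a labeled species against the unlabeled pool.

    concentration = (labeled area / unlabeled area) x endogenous µM of the
    unlabeled compound determined in a protein-free reference condition.
    This sidesteps ISTD interconversion because the areas come from the
    same sample and chromatographic peak. Scale-invariant in the areas.
    """
    if unlabeled_area <= 0:
        raise QuantError("unlabeled peak area must be positive (undefined ratio)")
    if reference_endogenous_uM < 0:
        raise QuantError("reference endogenous concentration must be non-negative")
    if labeled_area < 0:
        raise QuantError("labeled peak area must be non-negative")
    return QuantResult(
        analyte=analyte,
        concentration_uM=float(labeled_area / unlabeled_area * reference_endogenous_uM),
        method="label_ratio",
        reference=f"endogenous {reference_endogenous_uM} µM",
    )


def _tracer_equivalents(labels: LabelSpec, element: str) -> int:
    """Skeleton-equivalents of a tracer element carried by one molecule.

    A whole ¹³C₅ backbone counts once (not five times); a ¹⁵N atom counts
    once. Doubly labeled species count once per element.
    """
    if element == "13C":
        return 1 if labels.n_13C > 0 else 0
    if element == "15N":
        return labels.n_15N
    raise QuantError(f"unsupported tracer element {element!r} (expected '13C' or '15N')")


@dataclass
class BalanceTable:
    """Per-replicate tracer molar accounting.

    ``table`` is tidy: replicate, species, isotopologue, concentration_uM,
    tracer_equiv_uM. ``totals`` sums tracer µM per replicate and reports
    the deviation from the reference spiked input, both per replicate and
    on the group mean.
    """

    element: str
    table: pd.DataFrame
    reference_input_uM: float | None = None

    @property
    def totals(self) -> pd.DataFrame:
        out = (
            self.table.groupby("replicate", sort=False)["tracer_equiv_uM"]
            .sum()
            .rename("total_uM")
            .reset_index()
        )
        if self.reference_input_uM is not None:
            out["deviation_uM"] = out["total_uM"] - self.reference_input_uM
        return out

    @property
    def mean_total_uM(self) -> float:
        if self.table.empty:
            return 0.0
        return float(self.totals["total_uM"].mean())

    @property
    def mean_deviation_uM(self) -> float | None:
        if self.reference_input_uM is None:
            return None
        return float(self.mean_total_uM - self.reference_input_uM)


def mole_balance(
    quants: Sequence[tuple[str, LabelSpec, float]] | Mapping,
    element: str,
    reference_input_uM: float | None = None,
    replicate: Sequence | None = None,
) -> BalanceTable:
    """Tracer-element molar accounting across labeled species.

    ``quants`` is a sequence of (species name, LabelSpec, concentration µM)
    entries — every entry must carry its label annotation so tracer content
    is unambiguous. ``replicate`` assigns each entry to a replicate
    (default: all in replicate 0). Unlabeled species contribute zero and
    are retained in the table for completeness.
    """
    entries = list(quants)
    if replicate is None:
        replicate = [0] * len(entries)
    if len(replicate) != len(entries):
        raise QuantError("replicate annotation length mismatch")
    rows = []
    for rep, entry in zip(replicate, entries):
        try:
            species, labels, conc = entry
        except (TypeError, ValueError) as exc:
            raise QuantError(
                "each entry must be (species, LabelSpec, concentration_uM)"
            ) from exc
        if not isinstance(labels, LabelSpec):
            raise QuantError(f"missing label annotation for {species!r}")
        if conc < 0:
            raise QuantError(f"negative concentration for {species!r}")
        eq = _tracer_equivalents(labels, element)
        rows.append(
            dict(
                replicate=rep,
                species=species,
                isotopologue=f"M+{labels.nominal_shift}",
                concentration_uM=float(conc),
                tracer_equiv_uM=float(conc) * eq,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["replicate", "species", "isotopologue", "concentration_uM", "tracer_equiv_uM"],
    )
    return BalanceTable(element=element, table=table, reference_input_uM=reference_input_uM)


def tissue_normalize(
    result: QuantResult, sample_mg: float, solvent_mL: float, reference_mg: float = 40.0
) -> float:
    """Convert µM in resuspension to per-mg-tissue equivalents.

    Extraction solvent volume scales as (sample mg / reference mg) x mL, so
    the normalized amount is concentration x solvent volume / sample mass,
    reported as nmol per mg tissue.
    """
    if sample_mg <= 0 or solvent_mL <= 0:
        raise QuantError("sample mass and solvent volume must be positive")
    return result.concentration_uM * solvent_mL / sample_mg
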