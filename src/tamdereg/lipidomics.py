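"""Calibration-based quantification helpers and unit conversion for the
ascites lipid panel.

Targeted LC-MS/MS quantification reports mass concentrations (ug/ml or
ng/ml) via per-analyte calibration lines; molar concentrations follow from
the molar mass, and agonist sufficiency is judged against literature
receptor-activation concentrations (IC50).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Analyte",
    "CohortConcentrations",
    "CalibrationLine",
    "fit_calibration",
    "mass_to_molar",
    "present_rounded",
    "fold_over_ic50",
    "PANEL",
]


@dataclass(frozen=True)
class Analyte:
    name: str
    molar_mass: float  # g/mol
    ic50: float | None = None  # uM, literature receptor binding/activation

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar mass must be positive for {self.name}")
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError(f"IC50 must be positive for {self.name}")


#: molar masses (g/mol) for the panel's named analytes; IC50 only where a
#: literature value is established (linoleic acid: 0.75 uM receptor binding)
PANEL: dict[str, Analyte] = {
    a.name: a
    for a in [
        Analyte("linoleic acid", 280.45, ic50=0.75),
        Analyte("arachidonic acid", 304.47),
        Analyte("docosahexaenoic acid", 328.49),
        Analyte("eicosapentaenoic acid", 302.45),
        Analyte("alpha-linolenic acid", 278.43),
        Analyte("15-HETE", 320.47),
        Analyte("6-keto-PGF1alpha", 370.48),
    ]
}


@dataclass(frozen=True)
class CohortConcentrations:
    """Measured concentrations of one analyte across a patient cohort."""

    analyte: Analyte
    values: tuple[float, ...]
    unit: str  # 'ug/ml' or 'ng/ml'

    def __post_init__(self) -> None:
        if self.unit not in ("ug/ml", "ng/ml"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if len(self.values) == 0:
            raise ValueError("empty cohort")

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass(frozen=True)
class CalibrationLine:
    slope: float
    intercept: float
    r2: float

    def predict_concentration(self, response: float) -> float:
        """Inverse prediction: concentration at an observed response."""
        if self.slope == 0:
            raise ZeroDivisionError("zero calibration slope")
        return (response - self.intercept) / self.slope


def fit_calibration(known_conc, response) -> CalibrationLine:
    """Ordinary least-squares line of instrument response on concentration
    (a 12-point curve in routine use; >= 3 points required)."""
    x = np.asarray(list(known_conc), dtype=float)
    y = np.asarray(list(response), dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 matched calibration points")
    if (x <= 0).any():
        raise ValueError("calibration concentrations must be positive")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations must not all be equal")
    res = stats.linregress(x, y)
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def mass_to_molar(conc: float, unit: str, analyte: Analyte) -> float:
    """Convert a mass concentration to molar units.

    ug/ml -> uM and ng/ml -> nM, both via conc * 1000 / molar_mass.
    Rounding is left to the presentation layer.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if unit not in ("ug/ml", "ng/ml"):
        raise ValueError(f"unknown unit {unit!r}")
    return conc * 1000.0 / analyte.molar_mass


def molar_to_mass(conc: float, unit: str, analyte: Analyte) -> float:
    """Inverse of :func:`mass_to_molar` (uM -> ug/ml, nM -> ng/ml)."""
    if unit not in ("uM", "nM"):
        raise ValueError(f"unknown unit {unit!r}")
    return conc * analyte.molar_mass / 1000.0


def present_rounded(value: float, nearest: float = 10.0) -> float:
    """Round to the nearest multiple of ``nearest`` for '~' style reporting."""
    return float(nearest * round(value / nearest))


def fold_over_ic50(molar_conc: float, analyte: Analyte) -> float:
    """Ratio of a molar concentration (uM) to the analyte's IC50 (uM)."""
    if analyte.ic50 is None:
        raise ValueError(f"no IC50 recorded for analyte {analyte.name!r}")
    return molar_conc / analyte.ic50
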