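"""Spectrophotometric standard-curve accounting for loading and release.

The drug concentration in the buffer is inferred from absorbance through
a linear standard curve (absorbance = slope * concentration + intercept,
fitted at a fixed wavelength, 484 nm by default).  From concentrations
the module computes the percentage of drug adsorbed onto the carrier
during loading and the percentage released into the medium, and
assembles measured time courses into :class:`~nanorelease.kinetics.ReleaseCurve`
objects on the fraction scale for kinetic fitting.

Concentrations carry explicit unit tags (``"mg/mL"`` or ``"ug/mL"``):
loading protocols routinely juxtapose initial concentrations in mg/mL
with post-filtration supernatants in ug/mL, which makes silent unit
mixing the chief foreseeable bug.  All conversions are explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import InputError, ReleaseCurve

__all__ = [
    "CalibrationCurve",
    "LoadingRecord",
    "fit_calibration",
    "conc_from_absorbance",
    "percent_adsorbed",
    "percent_released",
    "timecourse_from_concs",
    "dox_cnt_mass_ratio",
    "to_ug_per_ml",
]

_UNIT_TO_UG_PER_ML = {"ug/mL": 1.0, "ug/ml": 1.0, "μg/mL": 1.0,
                      "mg/mL": 1000.0, "mg/ml": 1000.0}


def to_ug_per_ml(value: float, unit: str) -> float:
    """Convert a concentration to ug/mL given its unit tag."""
    try:
        return float(value) * _UNIT_TO_UG_PER_ML[unit]
    except KeyError:
        raise InputError(f"unknown concentration unit {unit!r}") from None


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: absorbance = slope * conc(ug/mL) + intercept."""

    slope: float
    intercept: float
    wavelength_nm: float = 484.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InputError("calibration slope must be positive")


@dataclass(frozen=True)
class LoadingRecord:
    """One carrier-loading experiment.

    Concentrations carry explicit units; ``final_conc`` is the drug left
    in the supernatant after filtering off the loaded carrier.
    """

    carrier_mass_mg: float
    solution_volume_mL: float
    initial_conc: float
    final_conc: float
    initial_unit: str = "mg/mL"
    final_unit: str = "ug/mL"

    def __post_init__(self) -> None:
        if min(self.carrier_mass_mg, self.solution_volume_mL,
               self.initial_conc) <= 0 or self.final_conc < 0:
            raise InputError("loading record fields must be positive")
        if self.final_ug_per_ml > self.initial_ug_per_ml:
            raise InputError("final concentration exceeds initial")

    @property
    def initial_ug_per_ml(self) -> float:
        return to_ug_per_ml(self.initial_conc, self.initial_unit)

    @property
    def final_ug_per_ml(self) -> float:
        return to_ug_per_ml(self.final_conc, self.final_unit)


def fit_calibration(concentrations, absorbances,
                    wavelength_nm: float = 484.0) -> CalibrationCurve:
    """Ordinary least-squares standard curve from known concentrations.

    Requires at least two distinct concentrations (in ug/mL).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.size < 2:
        raise InputError("need >= 2 (concentration, absorbance) pairs")
    if np.unique(c).size < 2:
        raise InputError("concentrations must include >= 2 distinct values")
    A = np.column_stack([c, np.ones_like(c)])
    (slope, intercept), *_ = np.linalg.lstsq(A, a, rcond=None)
    return CalibrationCurve(float(slope), float(intercept), wavelength_nm)


def conc_from_absorbance(cal: CalibrationCurve, absorbance: float) -> float:
    """Invert the standard curve: concentration in ug/mL.

    Absorbances below the intercept (blank) are clipped to zero
    concentration with a warning rather than returning a negative value.
    """
    conc = (float(absorbance) - cal.intercept) / cal.slope
    if conc < 0:
        warnings.warn(
            "absorbance below calibration intercept; clipping to 0",
            stacklevel=2,
        )
        return 0.0
    return conc


def percent_adsorbed(rec: LoadingRecord) -> float:
    """Percentage of drug removed from solution by the carrier.

    100 * (1 - C_final / C_initial), units reconciled first.
    """
    return 100.0 * (1.0 - rec.final_ug_per_ml / rec.initial_ug_per_ml)


def percent_released(released_mass_ug: float, loaded_mass_ug: float) -> float:
    """Percentage of the loaded drug found in the release medium.

    ``released_mass_ug`` is measured concentration x buffer volume.  A
    value exceeding the loaded amount by more than 5% is flagged as a
    calibration inconsistency.
    """
    if loaded_mass_ug <= 0:
        raise InputError("loaded mass must be positive")
    if released_mass_ug < 0:
        raise InputError("released mass must be non-negative")
    pct = 100.0 * released_mass_ug / loaded_mass_ug
    if pct > 105.0:
        raise InputError(
            f"released {pct:.1f}% of loaded mass: calibration inconsistency"
        )
    return pct


def timecourse_from_concs(concs_ug_per_ml, volume_mL: float,
                          loaded_mass_ug: float, times_min) -> ReleaseCurve:
    """Build a fraction-scale release curve from measured concentrations.

    Each fraction is conc * volume / loaded mass, i.e. percent_released
    divided by 100, applied per time point.
    """
    c = np.asarray(concs_ug_per_ml, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if c.shape != t.shape:
        raise InputError("concentrations and times must align")
    fractions = np.array(
        [percent_released(ci * volume_mL, loaded_mass_ug) / 100.0 for ci in c]
    )
    return ReleaseCurve(t, fractions, value_kind="fraction")


def dox_cnt_mass_ratio(carrier_mass_mg: float, solution_volume_mL: float,
                       drug_conc_mg_per_mL: float) -> float:
    """Drug-to-carrier mass ratio implied by a loading protocol.

    (volume x drug concentration) / carrier mass, all in mg.  For the
    reference protocol (100 mg carrier in 10 mL of 40 mg/mL drug
    solution) this is 4.0, the ratio used to size the simulated systems.
    """
    if min(carrier_mass_mg, solution_volume_mL, drug_conc_mg_per_mL) <= 0:
        raise InputError("protocol quantities must be positive")
    return solution_volume_mL * drug_conc_mg_per_mL / carrier_mass_mg
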