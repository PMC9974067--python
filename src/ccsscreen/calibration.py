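"""Travelling-wave IMS drift-time ↔ CCS conversion.

Vendor TWIMS calibrations are proprietary; this module implements the
standard published protocol, which is what the community uses when the
instrument software is not available and — crucially for the simulator —
is exactly invertible:

1. correct each calibrant drift time for the mass-dependent transit time
   outside the mobility cell:  t′d = td − c·√(m/z)/1000  (c the EDC delay
   coefficient, ms per √(m/z), fixed by instrument configuration, not
   fitted);
2. remove the charge/reduced-mass dependence of the literature CCS:
   Ω′ = Ω · √μ / z  with μ = m·M_gas/(m + M_gas) the ion–gas reduced mass
   (N₂, 28.00615 Da, by default);
3. fit the power law  Ω′ = A · t′d^B  as a straight line in log–log space.

Decoding a drift time then reads  Ω = A · t′d^B · z/√μ, and the inverse
(CCS → drift time) follows algebraically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N2_MASS",
    "CalibrantPoint",
    "CalibrationModel",
    "CalibrationError",
    "corrected_drift",
    "reduced_mass_factor",
    "fit_calibration",
    "dt_to_ccs",
    "ccs_to_dt",
    "read_calibrants",
]

#: Monoisotopic mass of the N2 drift gas, Da.
N2_MASS = 28.00615


class CalibrationError(ValueError):
    """Drift time outside the calibration domain, or an unfittable point set."""


@dataclass(frozen=True)
class CalibrantPoint:
    """One calibrant ion: measured drift time plus its reference CCS."""

    mz: float
    charge: int
    drift_time: float  # ms
    reference_ccs: float  # Å²

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.charge < 1:
            raise ValueError("calibrant needs positive m/z and charge")
        if self.drift_time <= 0:
            raise ValueError("calibrant drift time must be positive")
        if self.reference_ccs <= 0:
            raise ValueError("calibrant reference CCS must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted power-law calibration Ω′ = A·t′d^B with fixed EDC correction.

    Attributes
    ----------
    coefficient_a : Å²·ms^(−B) scale factor, > 0.
    exponent_b : dimensionless power-law exponent, > 0.
    edc_coefficient : ms·(m/z)^(−1/2)·1000 — transit (enhanced-duty-cycle)
        delay coefficient; the correction applied is c·√(m/z)/1000 ms.
    gas_mass : drift-gas monoisotopic mass in Da (N₂ by default).
    residuals : per-calibrant relative residuals of the log–log fit
        (empty tuple for a model constructed directly from parameters).
    """

    coefficient_a: float
    exponent_b: float
    edc_coefficient: float = 0.0
    gas_mass: float = N2_MASS
    residuals: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0:
            raise ValueError("coefficient_a must be positive")
        if self.exponent_b <= 0:
            raise ValueError("exponent_b must be positive")
        if self.gas_mass <= 0:
            raise ValueError("gas_mass must be positive")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficient_a": self.coefficient_a,
            "exponent_b": self.exponent_b,
            "edc_coefficient": self.edc_coefficient,
            "gas_mass": self.gas_mass,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            coefficient_a=float(d["coefficient_a"]),
            exponent_b=float(d["exponent_b"]),
            edc_coefficient=float(d.get("edc_coefficient", 0.0)),
            gas_mass=float(d.get("gas_mass", N2_MASS)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def corrected_drift(drift_time: float, mz: float, model: CalibrationModel) -> float:
    """Drift time minus the mass-dependent transit delay, ms; must stay > 0."""
    td = drift_time - model.edc_coefficient * math.sqrt(mz) / 1000.0
    if td <= 0:
        raise CalibrationError(
            f"corrected drift time non-positive ({td:.4f} ms) for "
            f"dt={drift_time} ms at m/z {mz}"
        )
    return td


def reduced_mass_factor(mz: float, charge: int, gas_mass: float = N2_MASS) -> float:
    """√μ/z with μ the ion–gas reduced mass; strictly increasing in m/z."""
    if mz <= 0 or charge < 1 or gas_mass <= 0:
        raise ValueError("mz, charge and gas_mass must be positive")
    ion_mass = mz * charge
    mu = ion_mass * gas_mass / (ion_mass + gas_mass)
    return math.sqrt(mu) / charge


def fit_calibration(
    points: Sequence[CalibrantPoint],
    gas_mass: float = N2_MASS,
    edc_coefficient: float = 0.0,
) -> CalibrationModel:
    """Least-squares log–log fit of Ω′ against t′d over ≥3 calibrants.

    Returns a model whose ``residuals`` hold the relative misfit
    (Ω_predicted/Ω_reference − 1) per calibrant, a cheap fit diagnostic.
    """
    if len(points) < 3:
        raise CalibrationError(
            f"need at least 3 calibrant points, got {len(points)}"
        )
    stub = CalibrationModel(1.0, 1.0, edc_coefficient, gas_mass)
    td = np.array([corrected_drift(p.drift_time, p.mz, stub) for p in points])
    omega_prime = np.array(
        [p.reference_ccs * reduced_mass_factor(p.mz, p.charge, gas_mass) for p in points]
    )
    x = np.log(td)
    if np.ptp(x) < 1e-12:
        raise CalibrationError("degenerate calibrant set: all corrected drift times equal")
    y = np.log(omega_prime)
    slope, intercept = np.polyfit(x, y, 1)
    model = CalibrationModel(
        coefficient_a=float(np.exp(intercept)),
        exponent_b=float(slope),
        edc_coefficient=edc_coefficient,
        gas_mass=gas_mass,
    )
    predicted = [
        dt_to_ccs(p.drift_time, p.mz, p.charge, model) for p in points
    ]
    residuals = tuple(
        pred / p.reference_ccs - 1.0 for pred, p in zip(predicted, points)
    )
    object.__setattr__(model, "residuals", residuals)
    return model


def dt_to_ccs(
    drift_time: float, mz: float, charge: int, model: CalibrationModel
) -> float:
    """CCS in Å²: Ω = A · t′d^B · z/√μ. Strictly increasing in drift time."""
    td = corrected_drift(drift_time, mz, model)
    return (
        model.coefficient_a
        * td**model.exponent_b
        / reduced_mass_factor(mz, charge, model.gas_mass)
    )


def ccs_to_dt(
    ccs: float, mz: float, charge: int, model: CalibrationModel
) -> float:
    """Exact algebraic inverse of :func:`dt_to_ccs`, transit delay included."""
    if ccs <= 0:
        raise ValueError(f"ccs must be positive, got {ccs}")
    omega_prime = ccs * reduced_mass_factor(mz, charge, model.gas_mass)
    td = (omega_prime / model.coefficient_a) ** (1.0 / model.exponent_b)
    return td + model.edc_coefficient * math.sqrt(mz) / 1000.0


def read_calibrants(path: str | Path) -> list[CalibrantPoint]:
    """Load a calibrant table (CSV: mz, charge, drift_time_ms, reference_ccs)."""
    df = pd.read_csv(path)
    required = {"mz", "charge", "drift_time_ms", "reference_ccs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibrant table missing columns: {sorted(missing)}")
    return [
        CalibrantPoint(
            mz=float(row.mz),
            charge=int(row.charge),
            drift_time=float(row.drift_time_ms),
            reference_ccs=float(row.reference_ccs),
        )
        for row in df.itertuples()
    ]
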