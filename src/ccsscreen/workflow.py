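"""End-to-end screening pipeline: features → calibrated spectra → annotations.

Glue over the individual modules for the common case — a two-function
feature table, a fitted calibration and a single-mode library: detect LE
precursors, align HE fragments by drift time and co-elution, convert
precursor drift times to CCS, and screen against the library.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .alignment import (
    DT_TOLERANCE_MS,
    RT_TOLERANCE_MIN,
    AlignedSpectrum,
    Feature,
    assign_fragments,
    detect_precursors,
)
from .calibration import CalibrationModel, dt_to_ccs
from .chem import ElementalFormula, IonDescriptor, Species
from .library import (
    CompoundClass,
    CompoundRecord,
    FragmentSpec,
    LibraryEntry,
    Mode,
)
from .screening import Annotation, ToleranceSet, screen

__all__ = ["align_and_calibrate", "run_screening", "synthetic_library"]


def align_and_calibrate(
    le_features: Sequence[Feature],
    he_features: Sequence[Feature],
    calibration: CalibrationModel,
    min_intensity: float = 0.0,
    dt_tolerance: float = DT_TOLERANCE_MS,
    rt_tolerance: float = RT_TOLERANCE_MIN,
    charge: int = 1,
) -> tuple[list[AlignedSpectrum], list[Feature]]:
    """Detect precursors, align fragments, and fill precursor CCS values."""
    precursors = detect_precursors(le_features, min_intensity)
    spectra, residual = assign_fragments(
        precursors, he_features, dt_tolerance, rt_tolerance
    )
    calibrated = []
    for s in spectra:
        p = s.precursor
        ccs = dt_to_ccs(p.dt, p.mz, charge, calibration)
        calibrated.append(
            AlignedSpectrum(
                precursor=p.with_ccs(ccs),
                fragments=s.fragments,
                fragment_flags=s.fragment_flags,
                dt_tolerance=s.dt_tolerance,
                rt_tolerance=s.rt_tolerance,
                flags=s.flags,
            )
        )
    return calibrated, residual


def run_screening(
    le_features: Sequence[Feature],
    he_features: Sequence[Feature],
    library: Sequence[LibraryEntry],
    calibration: CalibrationModel,
    tol: ToleranceSet = ToleranceSet(),
    mode: Optional[Mode] = None,
    min_intensity: float = 0.0,
) -> list[Annotation]:
    """The full target-screening pipeline on one acquisition."""
    spectra, _residual = align_and_calibrate(
        le_features,
        he_features,
        calibration,
        min_intensity=min_intensity,
        dt_tolerance=tol.dt_ms,
        rt_tolerance=RT_TOLERANCE_MIN,
    )
    return screen(spectra, library, tol, mode=mode)


def synthetic_library(
    n: int,
    seed: int,
    mode: Mode = Mode.WET,
    rt_range: tuple[float, float] = (5.0, 15.0),
) -> list[LibraryEntry]:
    """A randomized but reproducible n-compound library for simulation studies.

    Compounds get random CHNOClS compositions (hence realistic, distinct
    m/z), retention times spread uniformly over ``rt_range``, CCS values
    following a loose size–mobility trend (Ω ≈ 0.45·M + jitter, the slope
    of small-molecule TWIMS trend lines), and two fragment specs at fixed
    fractions of the precursor m/z. Entirely synthetic — no relation to any
    measured compound.
    """
    rng = np.random.default_rng(seed)
    species = Species.PROTONATED if mode is Mode.WET else Species.MOLECULAR_ION
    entries = []
    rts = np.sort(rng.uniform(*rt_range, size=n))
    for i in range(n):
        counts = {
            "C": int(rng.integers(8, 25)),
            "H": int(rng.integers(6, 30)),
            "O": int(rng.integers(1, 5)),
        }
        if rng.random() < 0.5:
            counts["Cl"] = int(rng.integers(1, 5))
        if rng.random() < 0.3:
            counts["N"] = int(rng.integers(1, 3))
        formula = ElementalFormula(counts)
        ion = IonDescriptor(formula, species)
        mass = ion.mz
        ccs = float(0.45 * mass + rng.normal(0.0, 8.0) + 40.0)
        entry = LibraryEntry(
            compound=CompoundRecord(
                name=f"synthetic_{i:03d}",
                compound_class=CompoundClass.PEST,
                formula=formula,
                isomer_group=None,
            ),
            ion=ion,
            mode=mode,
            retention_time=float(rts[i]),
            ccs=ccs,
            fragments=(
                FragmentSpec(mz=round(mass * 0.7, 5)),
                FragmentSpec(mz=round(mass * 0.45, 5)),
            ),
        )
        entries.append(entry)
    return entries
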