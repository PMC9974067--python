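"""Ground-truthed two-function acquisition simulator.

Generates LE/HE feature tables that look like a GC-APCI-IMS-HRMS run built
from a CCS library: each spiked library entry contributes one LE precursor
at its library RT and m/z whose drift time encodes the library CCS through
the calibration, plus HE fragment features sharing that drift time; matrix
interference contributes unrelated features on both functions. A manifest
of ground truth maps every feature back to the entry (or matrix) that
produced it, so alignment and screening can be scored exactly.

Noise model (all Gaussian, all driven by the single stated seed):

* m/z — per feature, proportional (ppm-scale) error;
* RT — per chromatographic peak: a spike's precursor and its fragments are
  one eluting peak, so they share a single RT draw (fragments co-elute with
  their precursor by construction of the experiment);
* CCS — per feature, percent-scale; propagated to drift time through the
  calibration, so fragment and precursor drift times diverge slightly, as
  they do on instrument;
* intensity — log-normal, cosmetic (screening uses only thresholds).

Default magnitudes (1 ppm, 0.02 min, 0.3% CCS) sit inside the measured
precision envelope of the technique (CCS repeatability under 0.3–0.5%)
while still exercising the tolerance logic at 5 ppm / 0.1 min / 2%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import Feature
from .calibration import CalibrationModel, ccs_to_dt
from .library import LibraryEntry, ReplicateMeasurement

__all__ = [
    "NoiseModel",
    "MatrixModel",
    "GroundTruth",
    "simulate_sample",
    "simulate_replicates",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes for the simulator."""

    mz_ppm_sd: float = 1.0
    rt_sd: float = 0.02  # min
    ccs_sd_percent: float = 0.3
    intensity_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mz_ppm_sd, self.rt_sd, self.ccs_sd_percent, self.intensity_log_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, seed)


@dataclass(frozen=True)
class MatrixModel:
    """Matrix-interference model: unrelated features at a constant rate.

    ``peaks_per_minute`` is the rate per acquisition function. When
    ``exclusion_margin`` is positive, matrix peaks landing within that many
    identification tolerances (5 ppm on m/z, 0.1 min on RT, 0.2 ms on DT)
    of any spiked coordinate are re-drawn, guaranteeing a clean separation
    between matrix and truth for oracle tests.
    """

    peaks_per_minute: float = 50.0
    mz_range: tuple[float, float] = (60.0, 900.0)
    dt_range: tuple[float, float] = (2.0, 12.0)
    intensity_mean_log: float = 9.0
    intensity_log_sd: float = 1.0
    exclusion_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.peaks_per_minute < 0:
            raise ValueError("matrix peak rate must be non-negative")
        if self.mz_range[0] >= self.mz_range[1] or self.dt_range[0] >= self.dt_range[1]:
            raise ValueError("matrix ranges must be non-degenerate")

    @classmethod
    def none(cls) -> "MatrixModel":
        return cls(peaks_per_minute=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Which features came from which spiked entry, and which are matrix."""

    spikes: dict  # key -> {"precursor_id", "fragment_ids", "rt", "mz", "ccs", "dt"}
    matrix_ids: tuple[str, ...]

    def spike_key(self, entry: LibraryEntry) -> str:
        return f"{entry.compound.name}|{entry.ion.species.value}"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"spikes": self.spikes, "matrix_ids": list(self.matrix_ids)},
                indent=2,
            )
            + "\n"
        )


# identification tolerances used only for the matrix exclusion zone
_EXCL_PPM = 5.0
_EXCL_RT = 0.1
_EXCL_DT = 0.2


def _synthetic_fragment_mzs(entry: LibraryEntry) -> list[float]:
    """Expected fragment m/z list; fixed fractions of the precursor when the
    library carries no fragment assignments (fragmentation chemistry is not
    modeled)."""
    if entry.fragments:
        return [f.expected_mz for f in entry.fragments]
    return [entry.mz * 0.7, entry.mz * 0.45]


def simulate_sample(
    entries: Sequence[LibraryEntry],
    noise: NoiseModel,
    matrix: MatrixModel,
    calibration: CalibrationModel,
) -> tuple[list[Feature], list[Feature], GroundTruth]:
    """Simulate one acquisition of a sample spiked with ``entries``.

    Returns (LE features, HE features, ground truth). Entries must carry a
    retention time. Fully reproducible from ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    le: list[Feature] = []
    he: list[Feature] = []
    spikes: dict[str, dict] = {}

    rt_min, rt_max = np.inf, -np.inf
    truth_coords: list[tuple[float, float, float]] = []  # (mz, rt, dt)

    for entry in entries:
        if entry.retention_time is None:
            raise ValueError(
                f"entry {entry.compound.name!r} has no retention time; "
                "the simulator needs one"
            )
        key = f"{entry.compound.name}|{entry.ion.species.value}"
        rt_true = entry.retention_time
        rt_peak = rt_true + rng.normal(0.0, noise.rt_sd)  # shared by the peak
        dt_true = ccs_to_dt(entry.ccs, entry.mz, entry.ion.charge, calibration)

        def jitter_mz(mz: float) -> float:
            return mz * (1.0 + rng.normal(0.0, noise.mz_ppm_sd) * 1e-6)

        def jitter_dt() -> float:
            # fragments inherit the precursor's drift, so the conversion
            # always uses the precursor m/z
            ccs_obs = entry.ccs * (1.0 + rng.normal(0.0, noise.ccs_sd_percent) / 100.0)
            return ccs_to_dt(ccs_obs, entry.mz, entry.ion.charge, calibration)

        prec_id = f"spike:{key}:LE"
        prec_mz = jitter_mz(entry.mz)
        prec_dt = jitter_dt()
        intensity = float(
            np.exp(rng.normal(10.0, noise.intensity_log_sd))
        )
        le.append(
            Feature(
                rt=rt_peak,
                dt=prec_dt,
                mz=prec_mz,
                intensity=intensity,
                function="LE",
                feature_id=prec_id,
            )
        )
        fragment_ids = []
        for k, frag_mz in enumerate(_synthetic_fragment_mzs(entry)):
            fid = f"spike:{key}:HE{k}"
            he.append(
                Feature(
                    rt=rt_peak,
                    dt=jitter_dt(),
                    mz=jitter_mz(frag_mz),
                    intensity=float(np.exp(rng.normal(9.0, noise.intensity_log_sd))),
                    function="HE",
                    feature_id=fid,
                )
            )
            fragment_ids.append(fid)
        spikes[key] = {
            "precursor_id": prec_id,
            "fragment_ids": fragment_ids,
            "rt": rt_true,
            "mz": entry.mz,
            "ccs": entry.ccs,
            "dt": dt_true,
        }
        truth_coords.append((entry.mz, rt_true, dt_true))
        for frag_mz in _synthetic_fragment_mzs(entry):
            truth_coords.append((frag_mz, rt_true, dt_true))
        rt_min = min(rt_min, rt_true)
        rt_max = max(rt_max, rt_true)

    # matrix features: uniform RT over the run span (padded), uniform m/z
    # and DT over the stated ranges, independent of the spikes
    matrix_ids: list[str] = []
    if matrix.peaks_per_minute > 0 and entries:
        lo, hi = rt_min - 0.5, rt_max + 0.5
        n_per_fn = int(round(matrix.peaks_per_minute * (hi - lo)))
        coords = np.array(truth_coords) if truth_coords else np.empty((0, 3))

        def excluded(mz: float, rt: float, dt: float) -> bool:
            if matrix.exclusion_margin <= 0 or coords.size == 0:
                return False
            m = matrix.exclusion_margin
            close = (
                (np.abs(coords[:, 0] - mz) <= coords[:, 0] * m * _EXCL_PPM * 1e-6)
                & (np.abs(coords[:, 1] - rt) <= m * _EXCL_RT)
                & (np.abs(coords[:, 2] - dt) <= m * _EXCL_DT)
            )
            return bool(close.any())

        for fn in ("LE", "HE"):
            for k in range(n_per_fn):
                for _attempt in range(100):
                    mz = float(rng.uniform(*matrix.mz_range))
                    rt = float(rng.uniform(lo, hi))
                    dt = float(rng.uniform(*matrix.dt_range))
                    if not excluded(mz, rt, dt):
                        break
                fid = f"matrix:{fn}:{k}"
                matrix_ids.append(fid)
                feature = Feature(
                    rt=rt,
                    dt=dt,
                    mz=mz,
                    intensity=float(
                        np.exp(rng.normal(matrix.intensity_mean_log, matrix.intensity_log_sd))
                    ),
                    function=fn,
                    feature_id=fid,
                )
                (le if fn == "LE" else he).append(feature)

    truth = GroundTruth(spikes=spikes, matrix_ids=tuple(matrix_ids))
    return le, he, truth


def simulate_replicates(
    true_ccs: float, rsd_percent: float, n: int, seed: int
) -> list[ReplicateMeasurement]:
    """n Gaussian CCS replicates: mean ``true_ccs``, sd ``true_ccs·rsd/100``.

    Replicates are labelled as triplicates alternating between the high and
    low concentration levels (high first), matching the library-building
    protocol; feeds :func:`ccsscreen.library.aggregate_ccs`.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    values = true_ccs * (1.0 + rng.normal(0.0, rsd_percent / 100.0, size=n))
    return [
        ReplicateMeasurement(
            ccs=float(v),
            concentration_level="low" if 3 <= i < 6 else "high",
            injection_index=i % 3 + 1,
        )
        for i, v in enumerate(values)
    ]
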