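"""HDMSᴱ-style drift-time alignment of fragment and precursor features.

A two-function acquisition records precursors at low collision energy (LE)
and their fragments at high energy (HE) in alternating scans; because
fragmentation happens after the mobility cell, a fragment keeps its
precursor's drift time. Matching HE features to LE precursors inside a
drift-time window (±0.2 ms) and a retention-time co-elution window
therefore reassembles clean per-precursor fragment spectra and strips
co-eluting matrix ions, which share the retention time but rarely the
drift time.

Windows are symmetric and boundary-inclusive (≤) throughout; a fragment
falling inside the windows of more than one precursor is assigned to all
of them and flagged ambiguous rather than arbitrated — downstream
screening re-scores fragments per candidate anyway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Feature",
    "AlignedSpectrum",
    "DT_TOLERANCE_MS",
    "RT_TOLERANCE_MIN",
    "FLAG_AMBIGUOUS",
    "FLAG_UNRESOLVED",
    "FLAG_ABOVE_PRECURSOR",
    "detect_precursors",
    "assign_fragments",
    "split_species",
    "cleanup_gain",
    "read_features",
    "write_features",
    "write_aligned_spectra",
]

#: default drift-time alignment half-window, ms
DT_TOLERANCE_MS = 0.2
#: default RT co-elution half-window, min — half the identification RT
#: tolerance; the acquisition interleaves LE/HE every 0.25 s so true
#: fragments co-elute far tighter than the chromatographic peak width
RT_TOLERANCE_MIN = 0.05

FLAG_AMBIGUOUS = "ambiguous_fragment"
FLAG_UNRESOLVED = "unresolved_species"
FLAG_ABOVE_PRECURSOR = "mz_above_precursor"


@dataclass(frozen=True)
class Feature:
    """One detected 4-D peak: retention time, drift time, m/z, intensity."""

    rt: float  # min
    dt: float  # ms
    mz: float
    intensity: float
    function: str  # "LE" | "HE"
    ccs: Optional[float] = None  # Å², filled via calibration
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rt <= 0 or self.dt <= 0 or self.mz <= 0:
            raise ValueError("rt, dt and mz must all be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.function not in ("LE", "HE"):
            raise ValueError(f"function must be 'LE' or 'HE', got {self.function!r}")

    def with_ccs(self, ccs: float) -> "Feature":
        return replace(self, ccs=ccs)


@dataclass(frozen=True)
class AlignedSpectrum:
    """One LE precursor with the HE fragments that share its RT and DT."""

    precursor: Feature
    fragments: tuple[Feature, ...]
    fragment_flags: tuple[frozenset[str], ...]
    dt_tolerance: float = DT_TOLERANCE_MS
    rt_tolerance: float = RT_TOLERANCE_MIN
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.fragments) != len(self.fragment_flags):
            raise ValueError("one flag set per fragment required")
        if FLAG_UNRESOLVED in self.flags:
            return  # merged spectra intentionally break the window invariant
        for frag, fl in zip(self.fragments, self.fragment_flags):
            if abs(frag.dt - self.precursor.dt) > self.dt_tolerance:
                raise ValueError("fragment outside the drift-time window")
            if abs(frag.rt - self.precursor.rt) > self.rt_tolerance:
                raise ValueError("fragment outside the co-elution window")
            if frag.mz >= self.precursor.mz and FLAG_ABOVE_PRECURSOR not in fl:
                raise ValueError(
                    "fragment above precursor m/z must be explicitly flagged"
                )


def detect_precursors(
    le_features: Sequence[Feature], min_intensity: float = 0.0
) -> list[Feature]:
    """LE features at or above the intensity threshold, brightest first."""
    if any(f.function != "LE" for f in le_features):
        raise ValueError("precursor detection expects LE features only")
    kept = [f for f in le_features if f.intensity >= min_intensity]
    return sorted(kept, key=lambda f: (-f.intensity, f.mz))


def assign_fragments(
    precursors: Sequence[Feature],
    he_features: Sequence[Feature],
    dt_tolerance: float = DT_TOLERANCE_MS,
    rt_tolerance: float = RT_TOLERANCE_MIN,
) -> tuple[list[AlignedSpectrum], list[Feature]]:
    """Assign every HE feature to each precursor whose windows it satisfies.

    Returns (spectra, residual): one AlignedSpectrum per precursor — in a
    deterministic order independent of input ordering — and the HE features
    matching no precursor (matrix/residual ions). A fragment inside several
    precursor windows appears in each, flagged ``ambiguous_fragment``; an
    assigned ion with m/z at or above its precursor's is kept but flagged
    ``mz_above_precursor``.
    """
    if dt_tolerance < 0 or rt_tolerance < 0:
        raise ValueError("tolerances must be non-negative")
    if any(f.function != "LE" for f in precursors):
        raise ValueError("precursors must be LE features")
    if any(f.function != "HE" for f in he_features):
        raise ValueError("fragment candidates must be HE features")

    prec = sorted(precursors, key=lambda f: (f.rt, f.dt, f.mz, -f.intensity))
    frags = sorted(he_features, key=lambda f: (f.rt, f.dt, f.mz, -f.intensity))
    if not prec:
        return [], list(frags)

    p_dt = np.array([p.dt for p in prec])
    p_rt = np.array([p.rt for p in prec])
    f_dt = np.array([f.dt for f in frags])
    f_rt = np.array([f.rt for f in frags])
    # boolean (n_frag, n_prec) window membership, boundary inclusive
    inside = (np.abs(f_dt[:, None] - p_dt[None, :]) <= dt_tolerance) & (
        np.abs(f_rt[:, None] - p_rt[None, :]) <= rt_tolerance
    )

    n_owners = inside.sum(axis=1)
    residual = [f for f, n in zip(frags, n_owners) if n == 0]

    spectra = []
    for j, p in enumerate(prec):
        idx = np.nonzero(inside[:, j])[0]
        members = []
        flags = []
        for i in idx:
            f = frags[i]
            fl = set()
            if n_owners[i] > 1:
                fl.add(FLAG_AMBIGUOUS)
            if f.mz >= p.mz:
                fl.add(FLAG_ABOVE_PRECURSOR)
            members.append(f)
            flags.append(frozenset(fl))
        spectra.append(
            AlignedSpectrum(
                precursor=p,
                fragments=tuple(members),
                fragment_flags=tuple(flags),
                dt_tolerance=dt_tolerance,
                rt_tolerance=rt_tolerance,
            )
        )
    return spectra, residual


def split_species(
    spectrum_a: AlignedSpectrum, spectrum_b: AlignedSpectrum
) -> tuple[AlignedSpectrum, ...]:
    """Resolve the co-formed ion species of one compound by mobility.

    Two co-eluting precursors (e.g. M+• and [M+H]+ of the same molecule)
    give clean per-species fragment spectra only when their drift times are
    farther apart than twice the alignment tolerance — otherwise the two
    alignment windows overlap and fragments cannot be attributed. Returns
    the two spectra unchanged (their fragment sets are provably disjoint)
    when resolved, or a single merged spectrum flagged ``unresolved_species``
    when the separation is ≤ 2 × tolerance (boundary counted unresolved).
    """
    tol = max(spectrum_a.dt_tolerance, spectrum_b.dt_tolerance)
    separation = abs(spectrum_a.precursor.dt - spectrum_b.precursor.dt)
    if separation > 2 * tol:
        return (spectrum_a, spectrum_b)
    lead, tail = sorted(
        (spectrum_a, spectrum_b), key=lambda s: (s.precursor.dt, s.precursor.mz)
    )
    seen = {id(f) for f in lead.fragments}
    extra = [
        (f, fl)
        for f, fl in zip(tail.fragments, tail.fragment_flags)
        if id(f) not in seen
    ]
    return (
        AlignedSpectrum(
            precursor=lead.precursor,
            fragments=lead.fragments + tuple(f for f, _ in extra),
            fragment_flags=lead.fragment_flags + tuple(fl for _, fl in extra),
            dt_tolerance=lead.dt_tolerance,
            rt_tolerance=lead.rt_tolerance,
            flags=frozenset({FLAG_UNRESOLVED}),
        ),
    )


def cleanup_gain(
    aligned: AlignedSpectrum, raw_he: Sequence[Feature]
) -> float:
    """Fraction of co-eluting HE ions removed by drift-time alignment.

    ``raw_he`` is the unaligned HE ion population; the co-eluting subset is
    taken with the spectrum's own RT window. Returns
    1 − |aligned fragments| / |co-eluting raw ions|, in [0, 1] — the
    spectral-cleanup figure of merit.
    """
    coeluting = [
        f
        for f in raw_he
        if abs(f.rt - aligned.precursor.rt) <= aligned.rt_tolerance
    ]
    if not coeluting:
        raise ValueError("no co-eluting HE ions to measure cleanup against")
    return 1.0 - len(aligned.fragments) / len(coeluting)


# ---------------------------------------------------------------------------
# feature-table I/O

_FEATURE_COLUMNS = ["rt_min", "dt_ms", "mz", "intensity", "function"]


def read_features(path: str | Path, sep: str = "\t") -> list[Feature]:
    """Load a delimited feature table (rt_min, dt_ms, mz, intensity, function)."""
    df = pd.read_csv(path, sep=sep)
    missing = set(_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    has_id = "feature_id" in df.columns
    return [
        Feature(
            rt=float(r.rt_min),
            dt=float(r.dt_ms),
            mz=float(r.mz),
            intensity=float(r.intensity),
            function=str(r.function),
            feature_id=str(r.feature_id) if has_id else None,
        )
        for r in df.itertuples()
    ]


def write_features(
    features: Iterable[Feature], path: str | Path, sep: str = "\t"
) -> None:
    rows = [
        {
            "rt_min": f.rt,
            "dt_ms": f.dt,
            "mz": f.mz,
            "intensity": f.intensity,
            "function": f.function,
            "feature_id": f.feature_id or "",
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS + ["feature_id"]).to_csv(
        path, sep=sep, index=False
    )


def _feature_to_dict(f: Feature) -> dict:
    d = {
        "rt_min": f.rt,
        "dt_ms": f.dt,
        "mz": f.mz,
        "intensity": f.intensity,
        "function": f.function,
    }
    if f.ccs is not None:
        d["ccs_A2"] = f.ccs
    if f.feature_id:
        d["feature_id"] = f.feature_id
    return d


def write_aligned_spectra(
    spectra: Sequence[AlignedSpectrum], path: str | Path
) -> None:
    """Export aligned spectra as JSON: precursor plus fragment arrays."""
    payload = [
        {
            "precursor": _feature_to_dict(s.precursor),
            "fragments": [
                {**_feature_to_dict(f), "flags": sorted(fl)}
                for f, fl in zip(s.fragments, s.fragment_flags)
            ],
            "flags": sorted(s.flags),
            "dt_tolerance_ms": s.dt_tolerance,
            "rt_tolerance_min": s.rt_tolerance,
        }
        for s in spectra
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
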