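"""4-dimensional target screening against a CCS library.

A candidate annotation is judged on three precursor axes — accurate mass
(<5 ppm), retention time (<0.1 min) and CCS (<2% of the reference-standard
value) — plus fragment evidence from the drift-aligned HE spectrum. The
confidence lattice, applied in one place (:func:`classify_level`):

* level 1 (confirmation): all three precursor criteria met and at least
  one expected fragment found within the fragment mass tolerance;
* level 2: precursor criteria met but fragment evidence absent or only
  present beyond the mass tolerance (the latter flagged
  ``fragment_mass_out_of_tolerance`` and kept — with CCS inside 2% such
  hits remain reportable positives rather than rejections);
* level 3 (suspect): no usable retention time (library or feature), mass
  and CCS within tolerance;
* otherwise no match.

All tolerance comparisons are strict (<): an error exactly at the bound
fails. Candidate ranking uses the normalized error sum over the three
axes, with matched-fragment count then compound name as tie-breakers, so
output ordering is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alignment import FLAG_UNRESOLVED, AlignedSpectrum, Feature
from .chem import ppm_error
from .library import FragmentSpec, LibraryEntry, LibraryError, Mode

__all__ = [
    "ToleranceSet",
    "FragmentMatch",
    "Annotation",
    "FLAG_FRAGMENT_OUT_OF_TOLERANCE",
    "match_entry",
    "screen",
    "classify_level",
    "annotations_table",
    "write_report",
    "render_report",
]

FLAG_FRAGMENT_OUT_OF_TOLERANCE = "fragment_mass_out_of_tolerance"

#: how far beyond the strict ppm tolerance a fragment is still considered
#: "observed (out of tolerance)" rather than absent, as a multiple of the
#: mass tolerance
_RELAXED_FRAGMENT_FACTOR = 4.0


@dataclass(frozen=True)
class ToleranceSet:
    """Identification tolerances; defaults are the screening criteria."""

    mass_ppm: float = 5.0
    rt_min: float = 0.1
    ccs_percent: float = 2.0
    dt_ms: float = 0.2
    min_fragments_for_confirmation: int = 1

    def __post_init__(self) -> None:
        if min(self.mass_ppm, self.rt_min, self.ccs_percent, self.dt_ms) <= 0:
            raise ValueError("all tolerances must be strictly positive")
        if self.min_fragments_for_confirmation < 1:
            raise ValueError("min_fragments_for_confirmation must be >= 1")


@dataclass(frozen=True)
class FragmentMatch:
    """Best observed HE feature for one expected fragment, if any."""

    expected: FragmentSpec
    observed: Optional[Feature]
    ppm: Optional[float]

    @property
    def within_tolerance(self) -> bool:
        return self.ppm is not None and self._in_tol

    # set at construction by match_entry
    _in_tol: bool = False


@dataclass(frozen=True)
class Annotation:
    """One library match with its errors, confidence level and flags."""

    entry: LibraryEntry
    feature: Feature
    mass_error_ppm: float
    rt_error_min: Optional[float]
    ccs_error_percent: float
    fragment_matches: tuple[FragmentMatch, ...]
    level: int
    flags: frozenset[str]

    @property
    def n_fragments_matched(self) -> int:
        return sum(1 for m in self.fragment_matches if m.within_tolerance)

    def score(self, tol: ToleranceSet) -> float:
        """Normalized error sum over the three precursor axes (lower = better)."""
        rt_term = (
            abs(self.rt_error_min) / tol.rt_min
            if self.rt_error_min is not None
            else 1.0
        )
        return (
            abs(self.mass_error_ppm) / tol.mass_ppm
            + rt_term
            + abs(self.ccs_error_percent) / tol.ccs_percent
        )


def _match_fragments(
    spectrum: AlignedSpectrum, entry: LibraryEntry, tol: ToleranceSet
) -> tuple[tuple[FragmentMatch, ...], bool]:
    """Pair each expected fragment with its closest aligned HE feature.

    A fragment is "observed" when some aligned feature lies within
    4 × mass_ppm of its expected m/z; within mass_ppm it counts toward
    confirmation. Returns the matches and whether any observed fragment
    fell in the relaxed (flagged) band.
    """
    matches = []
    any_out = False
    for spec in entry.fragments:
        expected_mz = spec.expected_mz
        best: Optional[Feature] = None
        best_ppm: Optional[float] = None
        for f in spectrum.fragments:
            err = ppm_error(f.mz, expected_mz)
            if abs(err) < tol.mass_ppm * _RELAXED_FRAGMENT_FACTOR and (
                best_ppm is None or abs(err) < abs(best_ppm)
            ):
                best, best_ppm = f, err
        in_tol = best_ppm is not None and abs(best_ppm) < tol.mass_ppm
        if best_ppm is not None and not in_tol:
            any_out = True
        matches.append(
            FragmentMatch(expected=spec, observed=best, ppm=best_ppm, _in_tol=in_tol)
        )
    return tuple(matches), any_out


def classify_level(
    mass_ok: bool,
    rt_ok: Optional[bool],
    ccs_ok: bool,
    n_fragments_in_tol: int,
    tol: ToleranceSet,
) -> Optional[int]:
    """The confidence lattice. ``rt_ok`` is None when no RT is available.

    Returns 1, 2, 3 or None (no match)."""
    if not (mass_ok and ccs_ok):
        return None
    if rt_ok is None:
        return 3
    if not rt_ok:
        return None
    if n_fragments_in_tol >= tol.min_fragments_for_confirmation:
        return 1
    return 2


def match_entry(
    spectrum: AlignedSpectrum,
    entry: LibraryEntry,
    tol: ToleranceSet = ToleranceSet(),
    mode: Optional[Mode] = None,
) -> Optional[Annotation]:
    """Evaluate one precursor spectrum against one library entry.

    Error conventions: mass error in ppm against the m/z computed from the
    entry's formula; RT error = observed − library RT in min; CCS error
    = (observed − library)/library × 100. Returns None when the precursor
    fails mass, RT or CCS; otherwise an Annotation at the classified level.
    Raises on a dry-library/wet-run (or vice versa) mix-up.
    """
    if mode is not None and entry.mode is not mode:
        raise LibraryError(
            f"library entry {entry.compound.name!r} is {entry.mode.value}-mode "
            f"but the run was screened as {mode.value}"
        )
    feature = spectrum.precursor
    if feature.ccs is None:
        raise ValueError(
            "precursor has no CCS: run calibration before screening"
        )
    mass_err = ppm_error(feature.mz, entry.mz)
    ccs_err = (feature.ccs - entry.ccs) / entry.ccs * 100.0
    rt_err: Optional[float] = None
    rt_ok: Optional[bool] = None
    if entry.retention_time is not None:
        rt_err = feature.rt - entry.retention_time
        rt_ok = abs(rt_err) < tol.rt_min
    mass_ok = abs(mass_err) < tol.mass_ppm
    ccs_ok = abs(ccs_err) < tol.ccs_percent
    if not (mass_ok and ccs_ok) or rt_ok is False:
        return None
    fragment_matches, any_out = _match_fragments(spectrum, entry, tol)
    n_in = sum(1 for m in fragment_matches if m.within_tolerance)
    level = classify_level(mass_ok, rt_ok, ccs_ok, n_in, tol)
    if level is None:
        return None
    flags = set()
    if any_out:
        flags.add(FLAG_FRAGMENT_OUT_OF_TOLERANCE)
    flags |= spectrum.flags & {FLAG_UNRESOLVED}
    return Annotation(
        entry=entry,
        feature=feature,
        mass_error_ppm=mass_err,
        rt_error_min=rt_err,
        ccs_error_percent=ccs_err,
        fragment_matches=fragment_matches,
        level=level,
        flags=frozenset(flags),
    )


def screen(
    spectra: Sequence[AlignedSpectrum],
    library: Sequence[LibraryEntry],
    tol: ToleranceSet = ToleranceSet(),
    mode: Optional[Mode] = None,
) -> list[Annotation]:
    """Screen aligned spectra against a library; deterministic output.

    Every spectrum × entry pair inside a coarse m/z prescreen is evaluated
    with :func:`match_entry`; per precursor, annotations are ordered by the
    composite score (normalized error sum, then matched fragments
    descending, then compound name). The run mode, when given, must match
    every library entry's mode.
    """
    if not library:
        raise LibraryError("cannot screen against an empty library")
    if mode is not None:
        for e in library:
            if e.mode is not mode:
                raise LibraryError(
                    f"library entry {e.compound.name!r} is {e.mode.value}-mode "
                    f"but the run was screened as {mode.value}"
                )
    # coarse prescreen: skip pairs > 4x the ppm window apart in mass
    window = 4.0 * tol.mass_ppm * 1e-6
    annotations: list[Annotation] = []
    ordered = sorted(
        spectra, key=lambda s: (s.precursor.rt, s.precursor.dt, s.precursor.mz)
    )
    for spectrum in ordered:
        mz = spectrum.precursor.mz
        hits = []
        for entry in library:
            if abs(mz - entry.mz) > entry.mz * window:
                continue
            ann = match_entry(spectrum, entry, tol, mode=None)
            if ann is not None:
                hits.append(ann)
        hits.sort(
            key=lambda a: (
                a.score(tol),
                -a.n_fragments_matched,
                a.entry.compound.name,
                a.entry.ion.species.value,
            )
        )
        annotations.extend(hits)
    return annotations


# ---------------------------------------------------------------------------
# reporting

_REPORT_COLUMNS = [
    "compound",
    "species",
    "mode",
    "level",
    "mz_observed",
    "mass_error_ppm",
    "rt_error_min",
    "ccs_error_percent",
    "n_fragments_matched",
    "flags",
]


def annotations_table(annotations: Iterable[Annotation]) -> pd.DataFrame:
    rows = [
        {
            "compound": a.entry.compound.name,
            "species": a.entry.ion.species.value,
            "mode": a.entry.mode.value,
            "level": a.level,
            "mz_observed": a.feature.mz,
            "mass_error_ppm": a.mass_error_ppm,
            "rt_error_min": a.rt_error_min,
            "ccs_error_percent": a.ccs_error_percent,
            "n_fragments_matched": a.n_fragments_matched,
            "flags": ";".join(sorted(a.flags)),
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Write the annotation report CSV (header-only when empty)."""
    try:
        annotations_table(annotations).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def render_report(annotations: Sequence[Annotation]) -> str:
    """Human-readable rendering of the annotation table."""
    df = annotations_table(annotations)
    if df.empty:
        return "no annotations"
    return df.to_string(
        index=False,
        float_format=lambda x: f"{x:.4f}",
        na_rep="-",
    )
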