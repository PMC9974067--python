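"""CCS library construction, storage and analytics.

A GC-APCI CCS library is split by source condition: a "dry" (charge
transfer) list whose entries are radical molecular cations or in-source
fragments, and a "wet" (proton transfer) list of protonated molecules or
fragments. Each entry carries the compound, its selected ion species, the
chromatographic retention time, the replicate-averaged CCS with its %RSD,
and the expected high-energy fragment ions.

The analytics here answer the questions a library builder asks:

* how repeatable are the CCS measurements (replicate aggregation, %RSD);
* how far apart are the CCS of the two ion species of one compound
  (inter-species ΔCCS, the ±2% comparability question);
* which isomers are discriminable by mobility alone (pairwise ΔCCS against
  the 2% screening tolerance);
* how well do two libraries agree (cross-platform robustness buckets).

ΔCCS denominator conventions are fixed per use and documented on each
function; the in-bound/out-of-bound verdicts at the 2% threshold are
insensitive to the choice for the magnitudes involved.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chem import (
    ElementalFormula,
    IonDescriptor,
    Species,
    format_formula,
    ion_mz,
    parse_formula,
)

__all__ = [
    "Mode",
    "CompoundClass",
    "CompoundRecord",
    "ReplicateMeasurement",
    "FragmentSpec",
    "LibraryEntry",
    "LibraryError",
    "aggregate_ccs",
    "select_best_species",
    "interspecies_delta",
    "isomer_pair_deltas",
    "compare_libraries",
    "read_library",
    "write_library",
    "reference_library",
    "INTERSPECIES_TOLERANCE_PCT",
    "DISCRIMINABILITY_THRESHOLD_PCT",
]

#: Inter-platform / inter-species CCS comparability tolerance, percent.
INTERSPECIES_TOLERANCE_PCT = 2.0
#: Isomer discriminability threshold, percent (the screening CCS tolerance).
DISCRIMINABILITY_THRESHOLD_PCT = 2.0


class LibraryError(ValueError):
    """Schema violation, mode/species mismatch or unusable replicate set."""


class Mode(str, Enum):
    """APCI source condition: dry = charge transfer, wet = proton transfer."""

    DRY = "dry"
    WET = "wet"


class CompoundClass(str, Enum):
    PCB = "PCB"
    BFR = "BFR"
    OPFR = "OPFR"
    PAH = "PAH"
    PEST = "Pest"
    EMERG = "Emerg"


#: which ion species are legal in each source condition (fragments in both)
_MODE_SPECIES = {
    Mode.DRY: {Species.MOLECULAR_ION, Species.FRAGMENT},
    Mode.WET: {Species.PROTONATED, Species.FRAGMENT},
}


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    compound_class: CompoundClass
    formula: ElementalFormula
    isomer_group: Optional[str] = None


@dataclass(frozen=True)
class ReplicateMeasurement:
    """A single CCS reading at one concentration level of one injection."""

    ccs: float
    concentration_level: str  # "low" | "high"
    injection_index: int  # 1..3

    def __post_init__(self) -> None:
        if self.ccs <= 0:
            raise ValueError("replicate ccs must be positive")
        if self.concentration_level not in ("low", "high"):
            raise ValueError(
                f"concentration_level must be 'low' or 'high', got "
                f"{self.concentration_level!r}"
            )


@dataclass(frozen=True)
class FragmentSpec:
    """An expected HE fragment: an elemental formula or a bare m/z.

    Formula-specified fragments get their m/z from the odd-electron cation
    convention; bare-m/z fragments are taken at face value (for fragments
    whose composition was never assigned).
    """

    formula: Optional[ElementalFormula] = None
    mz: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.mz is None):
            raise ValueError("fragment needs exactly one of formula or mz")
        if self.mz is not None and self.mz <= 0:
            raise ValueError("fragment m/z must be positive")

    @property
    def expected_mz(self) -> float:
        if self.mz is not None:
            return self.mz
        return ion_mz(IonDescriptor(self.formula, Species.FRAGMENT))

    def token(self) -> str:
        return format_formula(self.formula) if self.formula else f"{self.mz:.5f}"

    @classmethod
    def from_token(cls, token: str) -> "FragmentSpec":
        token = token.strip()
        try:
            return cls(mz=float(token))
        except ValueError:
            return cls(formula=parse_formula(token))


@dataclass(frozen=True)
class LibraryEntry:
    """One ionized species of one compound in one source condition."""

    compound: CompoundRecord
    ion: IonDescriptor
    mode: Mode
    retention_time: Optional[float]  # min; None for suspect-only entries
    ccs: float  # Å²
    ccs_rsd_percent: float = 0.0
    fragments: tuple[FragmentSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ccs <= 0:
            raise LibraryError(f"{self.compound.name}: ccs must be positive")
        if self.ccs_rsd_percent < 0:
            raise LibraryError(f"{self.compound.name}: %RSD must be non-negative")
        if self.ion.species not in _MODE_SPECIES[self.mode]:
            raise LibraryError(
                f"{self.compound.name}: species {self.ion.species.value!r} is not "
                f"valid in {self.mode.value} mode (charge transfer gives M+., "
                f"proton transfer gives [M+H]+)"
            )

    @property
    def mz(self) -> float:
        return ion_mz(self.ion)


# ---------------------------------------------------------------------------
# replicate aggregation


def aggregate_ccs(
    replicates: Sequence[ReplicateMeasurement],
) -> tuple[float, float, int]:
    """Average replicate CCS readings into (mean, %RSD, n_used).

    The library convention is triplicate injection at two concentration
    levels: when a full triplicate exists at both levels all six values are
    averaged; when the low level gave no signal, the three high-level values
    alone are used. %RSD uses the sample (n−1) standard deviation, the
    sensible estimator at n = 3–6.
    """
    high = [r.ccs for r in replicates if r.concentration_level == "high"]
    low = [r.ccs for r in replicates if r.concentration_level == "low"]
    if len(high) < 3:
        raise LibraryError(
            f"need at least 3 high-level replicates, got {len(high)}"
        )
    values = high + low if len(low) >= 3 else high
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd / mean * 100.0, n


def select_best_species(
    candidates: dict[Species, Sequence[float]],
) -> Species:
    """Pick the species with the highest median replicate intensity.

    Helper for library builders who do hold raw intensities; the species
    actually stored in a library file is otherwise declared input, since
    sensitivity comparison is a qualitative judgement on real data.
    """
    if not candidates:
        raise ValueError("no candidate species")

    def median(xs: Sequence[float]) -> float:
        s = sorted(xs)
        m = len(s) // 2
        return s[m] if len(s) % 2 else (s[m - 1] + s[m]) / 2

    return max(candidates, key=lambda sp: (median(candidates[sp]), sp.value))


# ---------------------------------------------------------------------------
# ΔCCS analytics


def interspecies_delta(
    entry_h: LibraryEntry, entry_m: LibraryEntry
) -> tuple[float, bool]:
    """Signed ΔCCS% between the two ion species of one compound.

    Convention: (CCS([M+H]+) − CCS(M+•)) / CCS(M+•) × 100 — the molecular
    ion is the denominator. Returns the signed percentage and whether its
    magnitude exceeds the ±2% comparability tolerance (the compounds a
    common dry/wet CCS database cannot merge).
    """
    if entry_h.compound.name != entry_m.compound.name:
        raise LibraryError(
            f"inter-species delta needs one compound, got "
            f"{entry_h.compound.name!r} and {entry_m.compound.name!r}"
        )
    if entry_h.ion.species is not Species.PROTONATED:
        raise LibraryError("first entry must be the protonated molecule")
    if entry_m.ion.species is not Species.MOLECULAR_ION:
        raise LibraryError("second entry must be the molecular ion")
    delta = (entry_h.ccs - entry_m.ccs) / entry_m.ccs * 100.0
    return delta, abs(delta) > INTERSPECIES_TOLERANCE_PCT


def isomer_pair_deltas(entries: Sequence[LibraryEntry]) -> pd.DataFrame:
    """Pairwise ΔCCS% within one isomer group, one species kind, one mode.

    Convention: |CCS₁ − CCS₂| / min(CCS₁, CCS₂) × 100 (symmetric in the
    pair). A pair is discriminable by mobility when its ΔCCS exceeds the 2%
    screening tolerance. The returned frame has one row per unordered pair
    (name_a, name_b, ccs_a, ccs_b, delta_pct, discriminable) plus, via
    ``df.attrs["per_entry_min"]``, each entry's minimum pairwise delta —
    the number that says whether that isomer stands apart from *all* its
    siblings.
    """
    if len(entries) < 2:
        raise LibraryError("isomer group must contain at least 2 entries")
    groups = {e.compound.isomer_group for e in entries}
    kinds = {(e.ion.species, e.mode) for e in entries}
    if len(groups) != 1 or None in groups:
        raise LibraryError("entries must share one non-empty isomer_group")
    if len(kinds) != 1:
        raise LibraryError("entries must share one species kind and mode")
    ordered = sorted(entries, key=lambda e: e.compound.name)
    rows = []
    per_entry: dict[str, float] = {}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            delta = abs(a.ccs - b.ccs) / min(a.ccs, b.ccs) * 100.0
            rows.append(
                {
                    "name_a": a.compound.name,
                    "name_b": b.compound.name,
                    "ccs_a": a.ccs,
                    "ccs_b": b.ccs,
                    "delta_pct": delta,
                    "discriminable": delta > DISCRIMINABILITY_THRESHOLD_PCT,
                }
            )
            for name in (a.compound.name, b.compound.name):
                per_entry[name] = min(per_entry.get(name, math.inf), delta)
    df = pd.DataFrame(rows)
    df.attrs["per_entry_min"] = per_entry
    return df


def compare_libraries(
    lib_a: Iterable[LibraryEntry], lib_b: Iterable[LibraryEntry]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross-library ΔCCS% joined on (compound name, ion species).

    Convention: (CCS_a − CCS_b) / CCS_b × 100 — library b is the reference.
    Returns the per-compound table and summary counts in the robustness
    buckets |Δ| < 1, 1 ≤ |Δ| ≤ 2 and |Δ| > 2 percent.
    """
    index_b = {(e.compound.name, e.ion.species): e for e in lib_b}
    rows = []
    for e in lib_a:
        other = index_b.get((e.compound.name, e.ion.species))
        if other is None:
            continue
        delta = (e.ccs - other.ccs) / other.ccs * 100.0
        rows.append(
            {
                "name": e.compound.name,
                "species": e.ion.species.value,
                "ccs_a": e.ccs,
                "ccs_b": other.ccs,
                "delta_pct": delta,
            }
        )
    if not rows:
        raise LibraryError("libraries share no (compound, species) pairs")
    df = pd.DataFrame(rows).sort_values(["name", "species"], ignore_index=True)
    abs_delta = df["delta_pct"].abs()
    summary = {
        "lt_1": int((abs_delta < 1.0).sum()),
        "1_to_2": int(((abs_delta >= 1.0) & (abs_delta <= 2.0)).sum()),
        "gt_2": int((abs_delta > 2.0).sum()),
    }
    return df, summary


# ---------------------------------------------------------------------------
# persistence

_CSV_COLUMNS = [
    "name",
    "class",
    "formula",
    "species",
    "mode",
    "rt_min",
    "ccs_A2",
    "ccs_rsd_pct",
    "fragments",
    "mz",
    "isomer_group",
]

#: stored-vs-recomputed m/z agreement required on read, Da
_MZ_CHECK_TOLERANCE = 1e-4


def _entry_to_row(e: LibraryEntry) -> dict:
    return {
        "name": e.compound.name,
        "class": e.compound.compound_class.value,
        "formula": format_formula(e.compound.formula),
        "species": e.ion.species.value,
        "mode": e.mode.value,
        "rt_min": e.retention_time,
        "ccs_A2": e.ccs,
        "ccs_rsd_pct": e.ccs_rsd_percent,
        "fragments": ";".join(f.token() for f in e.fragments),
        "mz": round(e.mz, 5),
        "isomer_group": e.compound.isomer_group or "",
    }


def _row_to_entry(row: dict, row_id: str) -> LibraryEntry:
    try:
        formula = parse_formula(str(row["formula"]))
        species = Species(str(row["species"]))
        mode = Mode(str(row["mode"]))
        rt_raw = row.get("rt_min")
        rt = None if rt_raw in (None, "") or pd.isna(rt_raw) else float(rt_raw)
        frag_raw = row.get("fragments") or ""
        if pd.isna(frag_raw):
            frag_raw = ""
        fragments = tuple(
            FragmentSpec.from_token(tok)
            for tok in str(frag_raw).split(";")
            if tok.strip()
        )
        iso_raw = row.get("isomer_group")
        isomer_group = (
            None if iso_raw in (None, "") or pd.isna(iso_raw) else str(iso_raw)
        )
        entry = LibraryEntry(
            compound=CompoundRecord(
                name=str(row["name"]),
                compound_class=CompoundClass(str(row["class"])),
                formula=formula,
                isomer_group=isomer_group,
            ),
            ion=IonDescriptor(formula=formula, species=species),
            mode=mode,
            retention_time=rt,
            ccs=float(row["ccs_A2"]),
            ccs_rsd_percent=float(row.get("ccs_rsd_pct") or 0.0),
            fragments=fragments,
        )
    except (KeyError, ValueError) as exc:
        raise LibraryError(f"{row_id}: {exc}") from exc
    stored_mz = row.get("mz")
    if stored_mz not in (None, "") and not pd.isna(stored_mz):
        stored_mz = float(stored_mz)
        if abs(stored_mz - entry.mz) > _MZ_CHECK_TOLERANCE:
            warnings.warn(
                f"{row_id}: stored m/z {stored_mz} disagrees with the value "
                f"recomputed from {format_formula(formula)} "
                f"({entry.mz:.5f}) by more than {_MZ_CHECK_TOLERANCE} Da",
                stacklevel=3,
            )
    return entry


def write_library(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write a library as CSV or JSON (by extension), identical field names."""
    path = Path(path)
    rows = [_entry_to_row(e) for e in entries]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a library file; m/z is recomputed from each formula and any
    stored m/z is cross-checked to 1e-4 Da (disagreement warns, carrying
    both values). Schema violations raise with the offending row."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        return [
            _row_to_entry(row, f"{path.name} entry {i}")
            for i, row in enumerate(rows)
        ]
    df = pd.read_csv(path)
    missing = {"name", "class", "formula", "species", "mode", "ccs_A2"} - set(
        df.columns
    )
    if missing:
        raise LibraryError(f"{path.name}: missing columns {sorted(missing)}")
    return [
        _row_to_entry(row, f"{path.name} row {i + 2}")
        for i, row in enumerate(df.to_dict("records"))
    ]


# ---------------------------------------------------------------------------
# bundled reference entries


def _entry(
    name: str,
    cls: CompoundClass,
    formula: str,
    species: Species,
    mode: Mode,
    rt: float,
    ccs: float,
    fragments: Sequence[str] = (),
    isomer_group: Optional[str] = None,
) -> LibraryEntry:
    f = parse_formula(formula)
    return LibraryEntry(
        compound=CompoundRecord(name, cls, f, isomer_group),
        ion=IonDescriptor(f, species),
        mode=mode,
        retention_time=rt,
        ccs=ccs,
        fragments=tuple(FragmentSpec.from_token(t) for t in fragments),
    )


def reference_library() -> list[LibraryEntry]:
    """The published reference set used throughout tests and docs.

    CCS values (Å²), ion species and source conditions are the published
    measurements for quintozene, the tritolyl phosphate trio, endrin,
    dieldrin, aldrin and isodrin. Retention times are printed only for the
    tolyl phosphates; the remaining RTs are synthetic plausible DB-5 values,
    as are the fragment formula lists (the full supplementary tables are
    not public). Those placeholders never enter a CCS or m/z assertion.
    """
    P, W, D = Species.PROTONATED, Mode.WET, Mode.DRY
    M = Species.MOLECULAR_ION
    Pest, OPFR = CompoundClass.PEST, CompoundClass.OPFR
    return [
        # quintozene (pentachloronitrobenzene): both species, well separated
        _entry("quintozene", Pest, "C6Cl5NO2", P, W, 20.60, 146.24, ["C6HCl4NO2"]),
        _entry("quintozene", Pest, "C6Cl5NO2", M, D, 20.60, 139.56, ["C6Cl5"]),
        # tritolyl phosphate positional isomers, printed RT | CCS
        _entry("TOTP", OPFR, "C21H21O4P", P, W, 31.05, 180.58, ["C14H14O3P"],
               isomer_group="tritolyl_phosphate"),
        _entry("TMTP", OPFR, "C21H21O4P", P, W, 32.16, 187.69, ["C14H14O3P"],
               isomer_group="tritolyl_phosphate"),
        _entry("TPTP", OPFR, "C21H21O4P", P, W, 33.48, 188.78, ["C14H14O3P"],
               isomer_group="tritolyl_phosphate"),
        # endrin / dieldrin regioisomers, wet and dry conditions
        _entry("endrin", Pest, "C12H8Cl6O", P, W, 30.10, 163.84, ["C12H9Cl5O"],
               isomer_group="drin_epoxide"),
        _entry("dieldrin", Pest, "C12H8Cl6O", P, W, 29.20, 157.92, ["C12H9Cl5O"],
               isomer_group="drin_epoxide"),
        _entry("endrin", Pest, "C12H8Cl6O", M, D, 30.10, 155.20, ["C12H8Cl5O"],
               isomer_group="drin_epoxide"),
        _entry("dieldrin", Pest, "C12H8Cl6O", M, D, 29.20, 160.93, ["C12H8Cl5O"],
               isomer_group="drin_epoxide"),
        # aldrin / isodrin: inseparable as [M+H]+, separable as M+.
        _entry("aldrin", Pest, "C12H8Cl6", P, W, 26.30, 155.10, ["C12H9Cl5"],
               isomer_group="drin"),
        _entry("isodrin", Pest, "C12H8Cl6", P, W, 27.10, 154.65, ["C12H9Cl5"],
               isomer_group="drin"),
        _entry("aldrin", Pest, "C12H8Cl6", M, D, 26.30, 161.65, ["C12H8Cl5"],
               isomer_group="drin"),
        _entry("isodrin", Pest, "C12H8Cl6", M, D, 27.10, 153.87, ["C12H8Cl5"],
               isomer_group="drin"),
    ]
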