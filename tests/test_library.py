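"""CCS library aggregation, ΔCCS analytics and persistence."""

import statistics

import numpy as np
import pytest

from ccsscreen.chem import IonDescriptor, Species, parse_formula
from ccsscreen.library import (
    CompoundClass,
    CompoundRecord,
    FragmentSpec,
    LibraryEntry,
    LibraryError,
    Mode,
    ReplicateMeasurement,
    aggregate_ccs,
    compare_libraries,
    interspecies_delta,
    isomer_pair_deltas,
    read_library,
    select_best_species,
    write_library,
)


def _reps(values, level="high"):
    return [
        ReplicateMeasurement(v, level, i % 3 + 1) for i, v in enumerate(values)
    ]


class TestAggregateCcs:
    def test_six_replicates_two_levels(self):
        values = [146.20, 146.25, 146.27, 146.22, 146.24, 146.26]
        reps = _reps(values[:3], "high") + _reps(values[3:], "low")
        mean, rsd, n = aggregate_ccs(reps)
        assert mean == pytest.approx(146.24, abs=1e-10)
        assert rsd == pytest.approx(0.018, abs=1e-3)
        assert n == 6

    def test_zero_variance(self):
        mean, rsd, n = aggregate_ccs(_reps([150.0] * 3) + _reps([150.0] * 3, "low"))
        assert (mean, rsd, n) == (150.0, 0.0, 6)

    def test_high_level_fallback(self):
        mean, rsd, n = aggregate_ccs(_reps([150.0, 150.2, 150.1]))
        assert mean == pytest.approx(150.1)
        assert n == 3

    def test_insufficient_high_replicates(self):
        with pytest.raises(LibraryError):
            aggregate_ccs(_reps([150.0, 150.1]) + _reps([150.0] * 3, "low"))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_mean_sd(self, seed):
        rng = np.random.default_rng(seed)
        values = list(150.0 + rng.normal(0, 0.5, size=6))
        reps = _reps(values[:3], "high") + _reps(values[3:], "low")
        mean, rsd, n = aggregate_ccs(reps)
        assert mean == pytest.approx(statistics.fmean(values))
        assert rsd == pytest.approx(
            statistics.stdev(values) / statistics.fmean(values) * 100
        )


def test_select_best_species_prefers_higher_median():
    picked = select_best_species(
        {
            Species.MOLECULAR_ION: [100.0, 200.0, 150.0],
            Species.PROTONATED: [300.0, 250.0, 400.0],
        }
    )
    assert picked is Species.PROTONATED


class TestInterspeciesDelta:
    def test_quintozene_flagged(self, ref_library):
        wet = next(
            e for e in ref_library
            if e.compound.name == "quintozene" and e.mode is Mode.WET
        )
        dry = next(
            e for e in ref_library
            if e.compound.name == "quintozene" and e.mode is Mode.DRY
        )
        delta, flagged = interspecies_delta(wet, dry)
        assert delta == pytest.approx(4.79, abs=0.005)
        assert flagged

    def test_aldrin_negative_delta(self, ref_library):
        wet = next(
            e for e in ref_library
            if e.compound.name == "aldrin" and e.mode is Mode.WET
        )
        dry = next(
            e for e in ref_library
            if e.compound.name == "aldrin" and e.mode is Mode.DRY
        )
        delta, flagged = interspecies_delta(wet, dry)
        assert delta == pytest.approx(-4.05, abs=0.005)
        assert flagged

    def test_equal_ccs_gives_zero(self):
        f = parse_formula("C12H8Cl6")
        c = CompoundRecord("x", CompoundClass.PEST, f)
        h = LibraryEntry(c, IonDescriptor(f, Species.PROTONATED), Mode.WET, 10.0, 150.0)
        m = LibraryEntry(
            c, IonDescriptor(f, Species.MOLECULAR_ION), Mode.DRY, 10.0, 150.0
        )
        delta, flagged = interspecies_delta(h, m)
        assert delta == 0.0 and not flagged

    def test_compound_mismatch_rejected(self, ref_library):
        wet_aldrin = next(
            e for e in ref_library
            if e.compound.name == "aldrin" and e.mode is Mode.WET
        )
        dry_quintozene = next(
            e for e in ref_library
            if e.compound.name == "quintozene" and e.mode is Mode.DRY
        )
        with pytest.raises(LibraryError):
            interspecies_delta(wet_aldrin, dry_quintozene)

    def test_denominator_convention_is_molecular_ion(self, ref_library):
        """The delta is not antisymmetric under swapping the roles: the
        documented convention fixes M+. as denominator."""
        wet = next(
            e for e in ref_library
            if e.compound.name == "quintozene" and e.mode is Mode.WET
        )
        dry = next(
            e for e in ref_library
            if e.compound.name == "quintozene" and e.mode is Mode.DRY
        )
        delta, _ = interspecies_delta(wet, dry)
        assert delta == pytest.approx((wet.ccs - dry.ccs) / dry.ccs * 100)


class TestIsomerDeltas:
    def test_tolyl_phosphate_trio(self, ref_library):
        """TOTP stands apart from both other tritolyl isomers (>2%);
        TMTP and TPTP are not mobility-separable (0.58%)."""
        trio = [
            e for e in ref_library
            if e.compound.isomer_group == "tritolyl_phosphate"
        ]
        df = isomer_pair_deltas(trio)
        per_entry = df.attrs["per_entry_min"]
        assert per_entry["TOTP"] == pytest.approx(3.94, abs=0.005)
        pair = df[(df.name_a == "TMTP") & (df.name_b == "TPTP")]
        assert pair.delta_pct.iloc[0] == pytest.approx(0.58, abs=0.005)
        assert not pair.discriminable.iloc[0]
        assert per_entry["TOTP"] > 2.0

    def test_aldrin_isodrin_species_dependence(self, ref_library):
        """Inseparable as [M+H]+ (0.29%) but separable as M+. (5.06%)."""
        wet = [
            e for e in ref_library
            if e.compound.isomer_group == "drin" and e.mode is Mode.WET
        ]
        dry = [
            e for e in ref_library
            if e.compound.isomer_group == "drin" and e.mode is Mode.DRY
        ]
        df_wet = isomer_pair_deltas(wet)
        df_dry = isomer_pair_deltas(dry)
        assert df_wet.delta_pct.iloc[0] == pytest.approx(0.29, abs=0.005)
        assert not df_wet.discriminable.iloc[0]
        assert df_dry.delta_pct.iloc[0] == pytest.approx(5.06, abs=0.005)
        assert df_dry.discriminable.iloc[0]

    def test_symmetric_and_order_invariant(self, ref_library):
        trio = [
            e for e in ref_library
            if e.compound.isomer_group == "tritolyl_phosphate"
        ]
        a = isomer_pair_deltas(trio)
        b = isomer_pair_deltas(list(reversed(trio)))
        assert a.equals(b)

    def test_singleton_group_rejected(self, ref_library):
        with pytest.raises(LibraryError):
            isomer_pair_deltas(ref_library[:1])


class TestCompareLibraries:
    def test_identical_libraries_all_below_1pct(self, wet_library):
        df, summary = compare_libraries(wet_library, wet_library)
        assert (df.delta_pct == 0).all()
        assert summary == {"lt_1": len(df), "1_to_2": 0, "gt_2": 0}

    def test_shifted_entry_lands_in_gt2_bucket(self, wet_library):
        import dataclasses

        shifted = [wet_library[0]] + list(wet_library[1:])
        shifted[0] = dataclasses.replace(shifted[0], ccs=shifted[0].ccs * 1.025)
        _df, summary = compare_libraries(shifted, wet_library)
        assert summary["gt_2"] == 1

    def test_seeded_noise_mostly_below_1pct(self):
        import dataclasses

        from ccsscreen.workflow import synthetic_library

        lib = synthetic_library(80, seed=5)
        rng = np.random.default_rng(99)
        noisy = [
            dataclasses.replace(e, ccs=e.ccs * (1 + rng.normal(0, 0.005)))
            for e in lib
        ]
        df, summary = compare_libraries(noisy, lib)
        # 1% bound is 2 sd of the 0.5% noise: ~95% inside
        assert summary["lt_1"] / len(df) >= 0.90

    def test_empty_join_rejected(self, wet_library, dry_library):
        with pytest.raises(LibraryError):
            compare_libraries(wet_library, dry_library)


class TestPersistence:
    def test_round_trip_csv_and_json(self, tmp_path, ref_library):
        for ext in ("csv", "json"):
            path = tmp_path / f"lib.{ext}"
            write_library(ref_library, path)
            loaded = read_library(path)
            assert loaded == ref_library

    def test_mode_species_invariant_enforced(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "name,class,formula,species,mode,rt_min,ccs_A2,ccs_rsd_pct,fragments\n"
            "x,Pest,C10F8,protonated,dry,10.0,150.0,0.1,\n"
        )
        with pytest.raises(LibraryError, match="dry"):
            read_library(path)

    def test_stored_mz_checked_against_formula(self, tmp_path):
        header = "name,class,formula,species,mode,rt_min,ccs_A2,ccs_rsd_pct,fragments,mz\n"
        good = tmp_path / "good.csv"
        good.write_text(
            header + "TOTP,OPFR,C21H21O4P,protonated,wet,31.05,180.58,0.1,,369.12502\n"
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            read_library(good)  # printed m/z agrees to 1e-5
        bad = tmp_path / "bad.csv"
        bad.write_text(
            header + "TOTP,OPFR,C21H21O4P,protonated,wet,31.05,180.58,0.1,,369.13000\n"
        )
        with pytest.warns(UserWarning, match="369.13"):
            read_library(bad)

    def test_fragment_tokens_round_trip(self, tmp_path):
        f = parse_formula("C12H8Cl6O")
        entry = LibraryEntry(
            compound=CompoundRecord("x", CompoundClass.PEST, f),
            ion=IonDescriptor(f, Species.PROTONATED),
            mode=Mode.WET,
            retention_time=10.0,
            ccs=150.0,
            fragments=(
                FragmentSpec(formula=parse_formula("C12H8Cl5O")),
                FragmentSpec(mz=123.45678),
            ),
        )
        path = tmp_path / "lib.csv"
        write_library([entry], path)
        (loaded,) = read_library(path)
        assert loaded.fragments[0].formula == entry.fragments[0].formula
        assert loaded.fragments[1].mz == pytest.approx(123.45678)
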