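"""Specimen parsing, eye averaging, species means, and log rounding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefeye import core_data
from reefeye.core_data import (
    EyeMeasurements,
    SchemaError,
    ValidationError,
    log_transform,
    read_specimen_table,
    round_sig,
    species_means,
    specimen_eye_average,
    subset,
    write_specimen_table,
)

from conftest import make_specimen


def _write_csv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


class TestReadSpecimenTable:
    def test_well_formed_rows_parse_one_to_one(self, tmp_path):
        records = [make_specimen(specimen_id=f"s{i}", species_id=f"sp{i}")
                   for i in range(3)]
        path = tmp_path / "t.csv"
        write_specimen_table(records, path)
        assert len(read_specimen_table(path)) == 3

    def test_pdmin_exceeding_pdmax_names_the_specimen(self, tmp_path):
        rec = make_specimen()
        rec.left.pdmin = rec.left.pdmax + 1.0
        path = tmp_path / "t.csv"
        write_specimen_table([rec], path)
        with pytest.raises(ValidationError, match="s1"):
            read_specimen_table(path)

    def test_left_only_columns_leave_right_side_absent(self, tmp_path):
        path = tmp_path / "t.csv"
        cols = ["specimen_id", "species", "family", "diel",
                "standard_length_mm", "body_mass_g"] + \
               [f"left_{t}_mm" for t in core_data.EYE_TRAITS]
        _write_csv(path, [["s1", "sp1", "Labridae", "diurnal", 100.0, 25.0,
                           10.0, 9.5, 4.5, 5.0, 4.4]], cols)
        (rec,) = read_specimen_table(path)
        assert rec.right.is_empty()
        assert rec.left.ed == 10.0

    def test_round_trip_preserves_values_exactly(self, tmp_path):
        records = [make_specimen(specimen_id=f"s{i}", species_id=f"sp{i}",
                                 body_mass=25.0 + i * 0.123456789)
                   for i in range(4)]
        records[1].right = EyeMeasurements()  # one-sided specimen
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_specimen_table(records, p1)
        back = read_specimen_table(p1)
        write_specimen_table(back, p2)
        assert p1.read_text() == p2.read_text()

    def test_missing_required_column_is_schema_error(self, tmp_path):
        path = tmp_path / "t.csv"
        _write_csv(path, [["s1", "sp1", "Labridae", 100.0]],
                   ["specimen_id", "species", "family", "standard_length_mm"])
        with pytest.raises(SchemaError, match="diel|body_mass"):
            read_specimen_table(path)

    def test_duplicate_specimen_id_rejected(self, tmp_path):
        records = [make_specimen(specimen_id="dup"),
                   make_specimen(specimen_id="dup", species_id="sp2")]
        path = tmp_path / "t.csv"
        write_specimen_table(records, path)
        with pytest.raises(ValidationError, match="dup"):
            read_specimen_table(path)


class TestEyeAverage:
    @pytest.mark.parametrize(
        "left_ed,right_ed,expected",
        [(10.0, 12.0, 11.0), (10.0, None, 10.0), (None, 12.0, 12.0)],
    )
    def test_side_averaging(self, left_ed, right_ed, expected):
        rec = make_specimen(
            left=EyeMeasurements(ed=left_ed, al=9.0, ld=4.0, pdmax=5.0,
                                 pdmin=4.0) if left_ed else EyeMeasurements(),
            right=EyeMeasurements(ed=right_ed, al=9.0, ld=4.0, pdmax=5.0,
                                  pdmin=4.0) if right_ed else EyeMeasurements(),
        )
        assert specimen_eye_average(rec)["ed"] == pytest.approx(expected)

    def test_full_two_eye_record_matches_per_trait_means(self, rng):
        left_vals = dict(zip(core_data.EYE_TRAITS,
                             sorted(rng.uniform(4, 10, 5))[::-1]))
        right_vals = {t: v * 1.04 for t, v in left_vals.items()}
        # keep pupil ordering valid
        for vals in (left_vals, right_vals):
            vals["pdmin"] = min(vals["pdmin"], vals["pdmax"])
        rec = make_specimen(left=EyeMeasurements(**left_vals),
                            right=EyeMeasurements(**right_vals))
        avg = specimen_eye_average(rec)
        for t in core_data.EYE_TRAITS:
            assert avg[t] == pytest.approx(
                (left_vals[t] + right_vals[t]) / 2.0
            )

    def test_trait_absent_on_both_sides_raises(self):
        rec = make_specimen(
            left=EyeMeasurements(ed=10.0),
            right=EyeMeasurements(ed=11.0),
        )
        with pytest.raises(ValidationError, match="al"):
            specimen_eye_average(rec)


class TestSpeciesMeans:
    def test_two_specimens_average(self):
        recs = []
        for i, ed in enumerate((10.0, 14.0)):
            recs.append(make_specimen(
                specimen_id=f"s{i}",
                left=EyeMeasurements(ed=ed, al=9.0, ld=4.0, pdmax=5.0,
                                     pdmin=4.0),
                right=EyeMeasurements(),
            ))
        out = species_means(recs)
        assert len(out) == 1
        assert out.loc[0, "ed"] == pytest.approx(12.0)
        assert out.loc[0, "n_specimens"] == 2

    def test_single_specimen_is_identity(self):
        rec = make_specimen()
        out = species_means([rec])
        assert out.loc[0, "ed"] == pytest.approx(
            specimen_eye_average(rec)["ed"]
        )

    def test_mean_matches_accumulation_oracle_and_permutation(self, rng):
        recs = []
        for i in range(30):
            base = rng.uniform(5, 12)
            recs.append(make_specimen(
                specimen_id=f"s{i}",
                body_mass=float(rng.uniform(10, 50)),
                left=EyeMeasurements(ed=base, al=base * 0.95, ld=base * 0.45,
                                     pdmax=base * 0.5, pdmin=base * 0.45),
                right=EyeMeasurements(ed=base * 1.02, al=base * 0.97,
                                      ld=base * 0.46, pdmax=base * 0.51,
                                      pdmin=base * 0.46),
            ))
        out = species_means(recs)
        # independent accumulation oracle
        total = 0.0
        for r in recs:
            total += (r.left.ed + r.right.ed) / 2.0
        assert out.loc[0, "ed"] == pytest.approx(total / 30, rel=1e-12)
        # permutation invariance
        shuffled = species_means(recs[::-1])
        assert shuffled.loc[0, "ed"] == pytest.approx(out.loc[0, "ed"],
                                                      rel=1e-14)

    def test_conflicting_diel_class_raises(self):
        recs = [make_specimen(specimen_id="a", diel_class="diurnal"),
                make_specimen(specimen_id="b", diel_class="nocturnal")]
        with pytest.raises(ValidationError, match="diel_class"):
            species_means(recs)


class TestRoundSig:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (math.log10(2.5), 0.3979),
            (math.log10(1000.0), 3.000),
            # significant figures of the signed value: -1.154901... -> -1.155
            (math.log10(0.07), -1.155),
            (1.0, 1.0),
            (0.0, 0.0),
        ],
    )
    def test_known_values(self, value, expected):
        assert round_sig(value, 4) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_g_formatter(self, x):
        """%.4g is the independent significant-figure oracle."""
        val = math.log10(x)
        assert round_sig(val, 4) == pytest.approx(float(f"{val:.4g}"),
                                                  rel=1e-12, abs=1e-12)


class TestLogTransform:
    def test_values_and_anguilliform_flag(self):
        species = species_means([
            make_specimen(specimen_id="a", species_id="m", family="Muraenidae",
                          diel_class="nocturnal"),
            make_specimen(specimen_id="b", species_id="w", family="Labridae"),
        ])
        logs = log_transform(species)
        assert logs.set_index("species_id")["anguilliform_flag"].to_dict() == \
            {"m": True, "w": False}
        row = logs.set_index("species_id").loc["w"]
        expected = round_sig(math.log10(
            species.set_index("species_id").loc["w", "ed"]), 4)
        assert row["log_ed"] == expected

    def test_scaling_traits_by_ten_shifts_logs_by_one(self):
        species = species_means([make_specimen()])
        scaled = species.copy()
        for t in ("body_mass",) + core_data.EYE_TRAITS:
            scaled[t] = scaled[t] * 10.0
        a = log_transform(species)
        b = log_transform(scaled)
        for t in ("body_mass",) + core_data.EYE_TRAITS:
            base = math.log10(species.loc[0, t])
            assert b.loc[0, f"log_{t}"] == pytest.approx(
                round_sig(base + 1.0, 4), abs=1e-12
            )
            assert a.loc[0, f"log_{t}"] == pytest.approx(
                round_sig(base, 4), abs=1e-12
            )

    def test_non_positive_trait_raises(self):
        species = species_means([make_specimen()])
        species.loc[0, "ld"] = 0.0
        with pytest.raises(ValidationError, match="ld"):
            log_transform(species)


class TestSubset:
    def test_anguilliform_exclusion_removes_eel_families(self, tmp_path):
        species = species_means([
            make_specimen(specimen_id="a", species_id="m",
                          family="Muraenidae", diel_class="nocturnal"),
            make_specimen(specimen_id="b", species_id="c",
                          family="Congridae", diel_class="nocturnal"),
            make_specimen(specimen_id="c", species_id="w", family="Labridae"),
        ])
        logs = log_transform(species)
        kept = subset(logs, ~logs["anguilliform_flag"])
        assert kept["species_id"].tolist() == ["w"]

    def test_true_predicate_is_identity(self, preset_tables):
        _, species, _ = preset_tables
        out = subset(species, lambda row: True)
        pd.testing.assert_frame_equal(out, species)

    def test_diel_filter_matches_manual_tally(self, preset_tables):
        _, species, _ = preset_tables
        noct = subset(species, (species["diel_class"] == "nocturnal"))
        assert len(noct) == (species["diel_class"] == "nocturnal").sum()
        # order preserved
        assert noct.index.is_monotonic_increasing

    def test_empty_result_warns(self, preset_tables):
        _, species, _ = preset_tables
        with pytest.warns(UserWarning, match="empty"):
            subset(species, species["diel_class"] == "cathemeral")
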