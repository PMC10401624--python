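"""Muscle-code parsing, CSV round trips and record validation."""

import numpy as np
import pandas as pd
import pytest

from antjump import (
    FiberRecord,
    FiberSet,
    Leg,
    MuscleCodeError,
    MuscleMeasurement,
    SpeciesRecord,
    ValidationError,
    parse_muscle_code,
)
from antjump.io import (
    fibers_by_muscle,
    read_fiber_export,
    read_muscle_table,
    read_species_table,
    total_muscle_volume,
    write_fiber_export,
    write_muscle_table,
    write_species_table,
)

# full segmented-muscle inventory of the study (leg-prefixed shorthand expanded)
MUSCLE_INVENTORY = [
    "Ipcm2", "Iscm4",
    "Iscm1", "IIscm1", "IIIscm1",
    "IIscm2", "IIIscm2",
    "Iscm3", "IIscm3", "IIIscm3",
    "Ipcm8", "IIscm6", "IIIscm6",
    "Ipcm4", "IIpcm3_4", "IIIpcm3_4",
    "Ictm1", "IIctm1", "IIIctm1",
    "Ictm2", "IIctm2", "IIIctm2",
    "Ictm3", "IIctm3", "IIIctm3",
    "Idvm5", "IA1", "IA2",
]


@pytest.mark.parametrize(
    "code, leg, group",
    [
        ("IIscm6", Leg.II, "scm6"),
        ("Ipcm8", Leg.I, "pcm8"),
        ("IIIscm1", Leg.III, "scm1"),
        ("IIpcm3_4", Leg.II, "pcm3_4"),
        ("IA1", Leg.NONE, "IA1"),
        ("Idvm5", Leg.NONE, "Idvm5"),
        ("ftm1", Leg.NONE, "ftm1"),
    ],
)
def test_parse_muscle_code(code, leg, group):
    parsed = parse_muscle_code(code)
    assert parsed.leg is leg
    assert parsed.group == group


def test_parse_is_total_over_study_inventory():
    for code in MUSCLE_INVENTORY:
        parse_muscle_code(code)  # must not raise


@pytest.mark.parametrize("bad", ["", "IV??", "II", "I", "scm?6", "1scm6"])
def test_malformed_codes_rejected(bad):
    with pytest.raises(MuscleCodeError):
        parse_muscle_code(bad)


def test_measurement_leg_derived_and_checked():
    m = MuscleMeasurement("sp", "IIIscm6", 1e-10)
    assert m.leg is Leg.III
    with pytest.raises(ValidationError):
        MuscleMeasurement("sp", "IIIscm6", 1e-10, leg=Leg.I)


def test_muscle_table_round_trip_and_units(tmp_path):
    records = [
        MuscleMeasurement("Gigantiops destructor", "IIscm6", 2.0e-10),
        MuscleMeasurement("Gigantiops destructor", "IIIscm6", 2.1e-10, side="left"),
        MuscleMeasurement("Formica rufa", "IIscm6", 4.0e-11),
    ]
    path = tmp_path / "volumes.csv"
    write_muscle_table(records, path)
    assert read_muscle_table(path) == records

    # declared mm^3 unit converts by exactly 1e-9
    df = pd.DataFrame(
        {"species": ["a", "a", "a"], "muscle_code": ["IIscm6", "IIIscm6", "Ipcm8"],
         "volume": [1.0, 2.0, 3.0]}
    )
    mm_path = tmp_path / "mm.csv"
    df.to_csv(mm_path, index=False)
    got = read_muscle_table(mm_path, unit="mm3")
    assert [r.volume_m3 for r in got] == [1e-9, 2e-9, 3e-9]


def test_muscle_table_rejects_bad_rows(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame(
        {"species": ["a"], "muscle_code": ["IIscm6"], "volume": [0.0]}
    ).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="rows \\[0\\]"):
        read_muscle_table(path)

    pd.DataFrame(
        {"species": ["a", "a"], "muscle_code": ["IIscm6", "IIscm6"],
         "volume": [1.0, 2.0]}
    ).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="duplicate"):
        read_muscle_table(path)

    pd.DataFrame({"species": ["a"], "volume": [1.0]}).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="missing column"):
        read_muscle_table(path)


def test_fiber_export_round_trip_and_counts(tmp_path):
    rng = np.random.default_rng(0)
    records = [
        FiberRecord("Harpegnathos saltator", "IIscm6", i,
                    float(l), float(a))
        for i, (l, a) in enumerate(
            zip(rng.uniform(1e-4, 8e-4, 97), rng.uniform(2.0, 14.0, 97))
        )
    ]
    path = tmp_path / "fibers.csv"
    write_fiber_export(records, path)
    got = read_fiber_export(path)
    assert got == records
    sets = fibers_by_muscle(got)
    assert len(sets[("Harpegnathos saltator", "IIscm6")]) == 97


def test_fiber_export_empty_file_warns(tmp_path, caplog):
    path = tmp_path / "empty.csv"
    path.write_text("species,muscle_code,fiber_id,length,pennation_angle\n")
    with caplog.at_level("WARNING"):
        assert read_fiber_export(path) == []
    assert any("empty" in r.message for r in caplog.records)


def test_fiber_angle_range_enforced(tmp_path):
    path = tmp_path / "fibers.csv"
    pd.DataFrame(
        {"species": ["a"], "muscle_code": ["IIscm6"], "fiber_id": [0],
         "length": [1e-4], "pennation_angle": [90.0]}
    ).to_csv(path, index=False)
    with pytest.raises(ValidationError):
        read_fiber_export(path)


def test_species_record_requires_mass_or_volume():
    with pytest.raises(ValidationError):
        SpeciesRecord("x", jumping=False, body_length_mm=10.0)
    ok = SpeciesRecord("x", jumping=True, body_length_mm=10.0,
                       thorax_volume_m3=3e-9)
    assert ok.thorax_volume_m3 == 3e-9


def test_species_table_round_trip(tmp_path):
    records = [
        SpeciesRecord("Myrmecia nigrocincta", jumping=True, body_length_mm=12.25,
                      specimen_id="CASENT0741302", body_mass_kg=2.66e-5),
        SpeciesRecord("Nothomyrmecia macrops", jumping=False, body_length_mm=8.66,
                      thorax_volume_m3=1.1e-9),
    ]
    path = tmp_path / "species.csv"
    write_species_table(records, path)
    assert read_species_table(path) == records


def test_total_volume_sums_bilateral_sides():
    records = [
        MuscleMeasurement("sp", "IIscm6", 1e-10, side="left"),
        MuscleMeasurement("sp", "IIscm6", 1.2e-10, side="right"),
        MuscleMeasurement("sp", "IIIscm6", 2e-10, side="left"),
        MuscleMeasurement("other", "IIscm6", 9e-10, side="left"),
    ]
    total = total_muscle_volume(records, "sp", ["IIscm6", "IIIscm6"])
    assert total == pytest.approx(4.2e-10, rel=1e-12)
    with pytest.raises(ValidationError):
        total_muscle_volume(records, "absent", ["IIscm6"])


def test_fiber_set_from_records_requires_single_muscle():
    recs = [
        FiberRecord("a", "IIscm6", 0, 1e-4, 5.0),
        FiberRecord("a", "IIIscm6", 1, 1e-4, 5.0),
    ]
    with pytest.raises(ValidationError):
        FiberSet.from_records(recs)


def test_leg_table_round_trip_with_unit_conversion(tmp_path):
    from antjump import LegMeasurement, LegPosition
    from antjump.io import read_leg_table, write_leg_table

    records = [
        LegMeasurement("Gigantiops destructor", LegPosition.HIND, 1, 14.7,
                       femur_length_mm=4.78, tibia_length_mm=4.58),
        LegMeasurement("Gigantiops destructor", LegPosition.FRONT, 2, 8.93),
    ]
    path = tmp_path / "legs.csv"
    write_leg_table(records, path)
    assert read_leg_table(path) == records

    # metres in, millimetres stored
    pd.DataFrame(
        {"species": ["a"], "leg": ["hind"], "replicate": [1],
         "total_length": [0.0147]}
    ).to_csv(path, index=False)
    assert read_leg_table(path, unit="m")[0].total_length_mm == pytest.approx(
        14.7, rel=1e-12
    )
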