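"""CSV readers/writers for all tabular pipeline inputs.

Files are RFC-4180 CSV, UTF-8, ``.`` decimal separator. Each reader takes a
declared unit for its dimensioned columns and converts to SI on ingest;
writers emit SI by default so that a write-then-read round trip is exact.
Validation failures name the offending rows.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .nomenclature import Leg
from .types import (
    FiberRecord,
    FiberSet,
    LegMeasurement,
    LegPosition,
    MuscleMeasurement,
    SpeciesRecord,
    ValidationError,
)
from .units import LENGTH_UNITS, VOLUME_UNITS, convert, from_si, to_si

__all__ = [
    "read_muscle_table",
    "write_muscle_table",
    "read_fiber_export",
    "write_fiber_export",
    "fibers_by_muscle",
    "read_species_table",
    "write_species_table",
    "read_leg_table",
    "write_leg_table",
    "total_muscle_volume",
]

logger = logging.getLogger(__name__)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_muscle_table(path: str | Path, unit: str = "m3") -> list[MuscleMeasurement]:
    """Read a per-muscle volume table.

    Columns: ``species, muscle_code, volume`` plus optional ``leg`` and
    ``side``. ``unit`` declares the unit of the ``volume`` column.
    Duplicate (species, muscle_code, side) rows are an error — the study
    design is one specimen per species, so repeats indicate a corrupt table.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["species", "muscle_code", "volume"], path)
    bad = df.index[~(df["volume"] > 0)].tolist()
    if bad:
        raise ValidationError(f"{path}: non-positive volume in rows {bad}")
    keys = list(
        zip(
            df["species"],
            df["muscle_code"],
            df["side"] if "side" in df.columns else [None] * len(df),
        )
    )
    dupes = [k for k, n in Counter(keys).items() if n > 1]
    if dupes:
        rows = [i for i, k in enumerate(keys) if k in set(dupes)]
        raise ValidationError(f"{path}: duplicate (species, muscle_code) rows {rows}")
    records = []
    for i, row in df.iterrows():
        leg = Leg(str(row["leg"])) if "leg" in df.columns and pd.notna(row.get("leg")) else None
        side = str(row["side"]) if "side" in df.columns and pd.notna(row.get("side")) else None
        try:
            records.append(
                MuscleMeasurement(
                    species_name=str(row["species"]),
                    muscle_code=str(row["muscle_code"]),
                    volume_m3=to_si(float(row["volume"]), unit, VOLUME_UNITS),
                    leg=leg,
                    side=side,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_muscle_table(
    records: Iterable[MuscleMeasurement], path: str | Path, unit: str = "m3"
) -> None:
    rows = [
        {
            "species": r.species_name,
            "muscle_code": r.muscle_code,
            "leg": r.leg.value,
            "side": r.side,
            "volume": from_si(r.volume_m3, unit, VOLUME_UNITS),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fiber_export(path: str | Path, length_unit: str = "m") -> list[FiberRecord]:
    """Read a fiber-tracing export (one row per traced fiber).

    Columns: ``species, muscle_code, fiber_id, length, pennation_angle``;
    lengths in ``length_unit``, angles in degrees. An empty file yields an
    empty list with a warning. Per-muscle fiber counts are logged.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("%s: fiber export is empty", path)
        return []
    _require_columns(
        df, ["species", "muscle_code", "fiber_id", "length", "pennation_angle"], path
    )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                FiberRecord(
                    species_name=str(row["species"]),
                    muscle_code=str(row["muscle_code"]),
                    fiber_id=int(row["fiber_id"]),
                    length_m=to_si(float(row["length"]), length_unit, LENGTH_UNITS),
                    pennation_deg=float(row["pennation_angle"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    counts = Counter((r.species_name, r.muscle_code) for r in records)
    for (species, code), n in sorted(counts.items()):
        logger.info("%s: %s %s: %d fibers", path, species, code, n)
    return records


def write_fiber_export(
    records: Iterable[FiberRecord], path: str | Path, length_unit: str = "m"
) -> None:
    rows = [
        {
            "species": r.species_name,
            "muscle_code": r.muscle_code,
            "fiber_id": r.fiber_id,
            "length": from_si(r.length_m, length_unit, LENGTH_UNITS),
            "pennation_angle": r.pennation_deg,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def fibers_by_muscle(records: Iterable[FiberRecord]) -> dict[tuple[str, str], FiberSet]:
    """Group fiber records into one :class:`FiberSet` per (species, muscle)."""
    groups: dict[tuple[str, str], list[FiberRecord]] = {}
    for r in records:
        groups.setdefault((r.species_name, r.muscle_code), []).append(r)
    return {k: FiberSet.from_records(v) for k, v in groups.items()}


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read species metadata.

    Columns: ``species, jumping, body_length_mm`` plus optional
    ``specimen_id, body_mass_kg, thorax_volume_m3``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["species", "jumping", "body_length_mm"], path)
    records = []
    for i, row in df.iterrows():
        jumping = row["jumping"]
        if isinstance(jumping, str):
            token = jumping.strip().lower()
            if token not in {"true", "false"}:
                raise ValidationError(f"{path}: row {i}: jumping must be true/false")
            jumping = token == "true"
        try:
            records.append(
                SpeciesRecord(
                    species_name=str(row["species"]),
                    jumping=bool(jumping),
                    body_length_mm=float(row["body_length_mm"]),
                    specimen_id=_opt_str(row.get("specimen_id")),
                    body_mass_kg=_opt_float(row.get("body_mass_kg")),
                    thorax_volume_m3=_opt_float(row.get("thorax_volume_m3")),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    rows = [
        {
            "species": r.species_name,
            "specimen_id": r.specimen_id,
            "jumping": r.jumping,
            "body_length_mm": r.body_length_mm,
            "body_mass_kg": r.body_mass_kg,
            "thorax_volume_m3": r.thorax_volume_m3,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_leg_table(path: str | Path, unit: str = "mm") -> list[LegMeasurement]:
    """Read replicate leg-length measurements.

    Columns: ``species, leg, replicate, total_length`` plus optional
    ``femur_length, tibia_length``; lengths in ``unit`` (stored in mm).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["species", "leg", "replicate", "total_length"], path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                LegMeasurement(
                    species_name=str(row["species"]),
                    leg=LegPosition(str(row["leg"])),
                    replicate=int(row["replicate"]),
                    total_length_mm=convert(
                        float(row["total_length"]), unit, "mm", LENGTH_UNITS
                    ),
                    femur_length_mm=_opt_converted(row.get("femur_length"), unit),
                    tibia_length_mm=_opt_converted(row.get("tibia_length"), unit),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_leg_table(records: Iterable[LegMeasurement], path: str | Path) -> None:
    rows = [
        {
            "species": r.species_name,
            "leg": r.leg.value,
            "replicate": r.replicate,
            "total_length": r.total_length_mm,
            "femur_length": r.femur_length_mm,
            "tibia_length": r.tibia_length_mm,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def total_muscle_volume(
    records: Iterable[MuscleMeasurement],
    species: str,
    muscle_codes: Sequence[str],
    sum_sides: bool = True,
) -> float:
    """Sum the volume of a muscle subset for one species.

    Bilateral tables carry left/right rows; by default both sides are summed
    (a jump is powered by the musculature of both body sides).
    """
    selected = [
        r
        for r in records
        if r.species_name == species and r.muscle_code in set(muscle_codes)
    ]
    if not selected:
        raise ValidationError(
            f"no measurements for {species} x {list(muscle_codes)}"
        )
    if not sum_sides:
        selected = [r for r in selected if r.side in (None, "left")]
    return float(sum(r.volume_m3 for r in selected))


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_converted(value, unit: str) -> float | None:
    v = _opt_float(value)
    return None if v is None else convert(v, unit, "mm", LENGTH_UNITS)
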