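"""Core domain records shared across the pipeline.

All numeric fields are SI unless the field name says otherwise
(``body_length_mm`` follows the convention of specimen catalogues;
pennation angles are degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .nomenclature import Leg, parse_muscle_code

__all__ = [
    "ValidationError",
    "SpeciesRecord",
    "MuscleMeasurement",
    "FiberRecord",
    "FiberSet",
    "LegPosition",
    "LegMeasurement",
    "PhysiologicalConstants",
]


class ValidationError(ValueError):
    """A record violated a domain invariant."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValidationError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class SpeciesRecord:
    """One specimen standing in for its species.

    At least one of ``body_mass_kg`` / ``thorax_volume_m3`` must be given:
    where no weighed mass exists, thorax (or whole-body) volume serves as a
    size proxy via a uniform tissue density.
    """

    species_name: str
    jumping: bool
    body_length_mm: float
    specimen_id: str = ""
    body_mass_kg: float | None = None
    thorax_volume_m3: float | None = None

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValidationError("species_name must be non-empty")
        if not isinstance(self.jumping, (bool, np.bool_)):
            raise ValidationError("jumping flag must be an explicit boolean")
        _require_positive("body_length_mm", self.body_length_mm)
        if self.body_mass_kg is None and self.thorax_volume_m3 is None:
            raise ValidationError(
                f"{self.species_name}: provide body_mass_kg or thorax_volume_m3"
            )
        if self.body_mass_kg is not None:
            _require_positive("body_mass_kg", self.body_mass_kg)
        if self.thorax_volume_m3 is not None:
            _require_positive("thorax_volume_m3", self.thorax_volume_m3)


@dataclass(frozen=True)
class MuscleMeasurement:
    """A segmented muscle volume, keyed by nomenclature code and leg."""

    species_name: str
    muscle_code: str
    volume_m3: float
    leg: Leg | None = None
    side: str | None = None  # optional left/right for bilateral tables

    def __post_init__(self) -> None:
        _require_positive("volume_m3", self.volume_m3)
        parsed = parse_muscle_code(self.muscle_code)
        if self.leg is None:
            object.__setattr__(self, "leg", parsed.leg)
        elif self.leg != parsed.leg:
            raise ValidationError(
                f"{self.muscle_code}: declared leg {self.leg.value} conflicts "
                f"with code prefix ({parsed.leg.value})"
            )


@dataclass(frozen=True)
class FiberRecord:
    """One traced muscle fiber (length in m, pennation angle in degrees)."""

    species_name: str
    muscle_code: str
    fiber_id: int
    length_m: float
    pennation_deg: float

    def __post_init__(self) -> None:
        _require_positive("length_m", self.length_m)
        if not (0 <= self.pennation_deg < 90):
            raise ValidationError(
                f"pennation_deg must lie in [0, 90), got {self.pennation_deg!r}"
            )


class FiberSet:
    """The traced fibers belonging to one muscle of one specimen."""

    def __init__(
        self,
        lengths_m: Sequence[float] | np.ndarray,
        pennation_deg: Sequence[float] | np.ndarray,
        species_name: str = "",
        muscle_code: str = "",
    ) -> None:
        lengths = np.asarray(lengths_m, dtype=float)
        angles = np.asarray(pennation_deg, dtype=float)
        if lengths.ndim != 1 or angles.ndim != 1:
            raise ValidationError("fiber lengths and angles must be 1-D")
        if lengths.size != angles.size:
            raise ValidationError("fiber lengths and angles must align")
        if lengths.size == 0:
            raise ValidationError("a FiberSet needs at least one fiber")
        if np.any(lengths <= 0):
            raise ValidationError("all fiber lengths must be > 0")
        if np.any((angles < 0) | (angles >= 90)):
            raise ValidationError("all pennation angles must lie in [0, 90)")
        self.lengths_m = lengths
        self.pennation_deg = angles
        self.species_name = species_name
        self.muscle_code = muscle_code

    @classmethod
    def from_records(cls, records: Iterable[FiberRecord]) -> "FiberSet":
        recs = list(records)
        if not recs:
            raise ValidationError("cannot build a FiberSet from zero records")
        keys = {(r.species_name, r.muscle_code) for r in recs}
        if len(keys) > 1:
            raise ValidationError(f"records span multiple muscles: {sorted(keys)}")
        species, code = keys.pop()
        return cls(
            [r.length_m for r in recs],
            [r.pennation_deg for r in recs],
            species_name=species,
            muscle_code=code,
        )

    def to_records(self) -> list[FiberRecord]:
        return [
            FiberRecord(self.species_name, self.muscle_code, i, l, a)
            for i, (l, a) in enumerate(zip(self.lengths_m, self.pennation_deg))
        ]

    def __len__(self) -> int:
        return int(self.lengths_m.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FiberSet):
            return NotImplemented
        return (
            self.species_name == other.species_name
            and self.muscle_code == other.muscle_code
            and np.array_equal(self.lengths_m, other.lengths_m)
            and np.array_equal(self.pennation_deg, other.pennation_deg)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FiberSet({self.species_name!r}, {self.muscle_code!r}, "
            f"n={len(self)})"
        )


class LegPosition(str, Enum):
    FRONT = "front"
    MIDDLE = "middle"
    HIND = "hind"


@dataclass(frozen=True)
class LegMeasurement:
    """One repeat measurement of a leg's length (mm, as catalogued)."""

    species_name: str
    leg: LegPosition
    replicate: int
    total_length_mm: float
    femur_length_mm: float | None = None
    tibia_length_mm: float | None = None

    def __post_init__(self) -> None:
        _require_positive("total_length_mm", self.total_length_mm)
        if self.replicate < 1:
            raise ValidationError("replicate index starts at 1")
        for name in ("femur_length_mm", "tibia_length_mm"):
            v = getattr(self, name)
            if v is not None:
                _require_positive(name, v)


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Muscle physiology and normalization constants.

    ``work_density_j_per_kg`` and ``power_density_w_per_kg`` are the maximum
    mechanical work (~70 J/kg) and average power (~350 W/kg) a unit muscle
    mass can deliver, conserved across taxa; ``muscle_density_kg_per_m3``
    converts muscle volume to mass. ``elastic_storage_factor`` is the
    conservative bound that at most one third of muscle work density can be
    converted into elastic strain energy, so a recoil-driven jump needs at
    least three times the naive work-based muscle volume. The exponents
    size-normalize muscle volume (~size^1), PCSA (~size^0.66) and fiber
    length (~size^0.33).
    """

    work_density_j_per_kg: float = 70.0
    power_density_w_per_kg: float = 350.0
    muscle_density_kg_per_m3: float = 1040.0
    elastic_storage_factor: float = 3.0
    pcsa_exponent: float = 0.66
    fiber_exponent: float = 0.33
    thorax_exponent: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))
        if self.elastic_storage_factor < 1:
            raise ValidationError("elastic_storage_factor must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PhysiologicalConstants":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown constants: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhysiologicalConstants":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
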