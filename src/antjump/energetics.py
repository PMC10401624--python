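"""Jump energetics: work/power demand vs. available muscle volume.

A jump of take-off speed v by a body of mass m requires kinetic energy
W = 1/2 m v^2 (gravitational potential energy is negligible at ant scale)
delivered within the take-off time t, i.e. average power P = W/t. Muscle
can supply at most ~70 J/kg of work and ~350 W/kg of average power per unit
mass, which converts demand into a minimum actuating muscle volume. For a
spring-driven (elastic recoil) jump, at most one third of the muscle work
density can be banked as strain energy, so the work-based volume demand is
multiplied by three as a conservative lower bound. Comparing both demands
against the measured trochanter-depressor volume classifies how the jump
could be actuated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .scaling import mass_from_volume
from .types import PhysiologicalConstants, SpeciesRecord, ValidationError
from .kinematics import TakeoffMetrics

__all__ = [
    "jump_work",
    "jump_power",
    "required_volume_from_work",
    "required_volume_from_power",
    "ActuationClass",
    "classify_actuation",
    "EnergeticsResult",
    "energetics_pipeline",
]


def _positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValidationError(f"{name} must be > 0, got {value!r}")


def jump_work(mass_kg: float, takeoff_speed_m_s: float, height_m: float = 0.0) -> float:
    """Kinetic energy of take-off, W = 1/2 m v^2 (J).

    Gravitational potential energy is excluded by default (marginal for
    small animals); pass ``height_m`` to add an opt-in m*g*h term.
    """
    _positive(mass_kg=mass_kg, takeoff_speed_m_s=takeoff_speed_m_s)
    if height_m < 0:
        raise ValidationError("height_m must be >= 0")
    return 0.5 * mass_kg * takeoff_speed_m_s**2 + mass_kg * 9.81 * height_m


def jump_power(work_j: float, takeoff_time_s: float) -> float:
    """Average power over the take-off, P = W/t (W)."""
    _positive(work_j=work_j, takeoff_time_s=takeoff_time_s)
    return work_j / takeoff_time_s


def required_volume_from_work(
    work_j: float, constants: PhysiologicalConstants | None = None
) -> float:
    """Minimum muscle volume to bank the jump's work elastically (m^3).

    factor * W / (work density * muscle density); with the elastic-storage
    factor at 1 this reduces to the unbounded direct-work demand.
    """
    constants = constants or PhysiologicalConstants()
    _positive(work_j=work_j)
    return constants.elastic_storage_factor * work_j / (
        constants.work_density_j_per_kg * constants.muscle_density_kg_per_m3
    )


def required_volume_from_power(
    power_w: float, constants: PhysiologicalConstants | None = None
) -> float:
    """Minimum muscle volume to deliver the jump's average power directly (m^3)."""
    constants = constants or PhysiologicalConstants()
    _positive(power_w=power_w)
    return power_w / (
        constants.power_density_w_per_kg * constants.muscle_density_kg_per_m3
    )


class ActuationClass(str, Enum):
    """How the measured musculature could drive the observed jump."""

    DIRECT_AND_ELASTIC_FEASIBLE = "direct_and_elastic_feasible"
    ELASTIC_ONLY = "elastic_only"
    INFEASIBLE = "infeasible"
    UNKNOWN = "unknown"


def classify_actuation(
    measured_m3: float | None, required_work_m3: float, required_power_m3: float
) -> ActuationClass:
    """Compare measured muscle volume against both volume demands.

    Meeting the power demand means direct contraction suffices; meeting only
    the (x3) work demand leaves elastic recoil as the viable route; meeting
    neither makes the observed jump unexplainable by this musculature. A
    missing measurement yields ``UNKNOWN`` rather than an error.
    """
    _positive(required_work_m3=required_work_m3, required_power_m3=required_power_m3)
    if measured_m3 is None:
        return ActuationClass.UNKNOWN
    _positive(measured_m3=measured_m3)
    if measured_m3 >= required_power_m3 and measured_m3 >= required_work_m3:
        return ActuationClass.DIRECT_AND_ELASTIC_FEASIBLE
    if measured_m3 >= required_work_m3:
        return ActuationClass.ELASTIC_ONLY
    return ActuationClass.INFEASIBLE


@dataclass(frozen=True)
class EnergeticsResult:
    """End-to-end energetics for one species' jump."""

    species_name: str
    mass_kg: float
    takeoff_speed_m_s: float
    takeoff_time_s: float
    work_j: float
    power_w: float
    required_volume_work_m3: float
    required_volume_power_m3: float
    measured_volume_m3: float | None
    classification: ActuationClass
    constants: PhysiologicalConstants


def energetics_pipeline(
    species: SpeciesRecord,
    kin: TakeoffMetrics,
    measured_volume_m3: float | None = None,
    constants: PhysiologicalConstants | None = None,
    velocity: str = "takeoff",
) -> EnergeticsResult:
    """Chain work, power, required-volume and feasibility for one species.

    Body mass comes from the species record directly, or from thorax volume
    via the uniform muscle density when no weighed mass exists. ``velocity``
    selects the trial's end-of-contact (``'takeoff'``, default) or
    net-displacement (``'mean'``) velocity estimate.
    """
    constants = constants or PhysiologicalConstants()
    if species.body_mass_kg is not None:
        mass = species.body_mass_kg
    else:
        mass = mass_from_volume(
            species.thorax_volume_m3, constants.muscle_density_kg_per_m3
        )
    if velocity == "takeoff":
        speed = kin.takeoff_velocity_m_s
    elif velocity == "mean":
        speed = kin.mean_velocity_m_s
    else:
        raise ValidationError(f"unknown velocity choice {velocity!r}")
    work = jump_work(mass, speed)
    power = jump_power(work, kin.duration_s)
    req_work = required_volume_from_work(work, constants)
    req_power = required_volume_from_power(power, constants)
    return EnergeticsResult(
        species_name=species.species_name,
        mass_kg=mass,
        takeoff_speed_m_s=speed,
        takeoff_time_s=kin.duration_s,
        work_j=work,
        power_w=power,
        required_volume_work_m3=req_work,
        required_volume_power_m3=req_power,
        measured_volume_m3=measured_volume_m3,
        classification=classify_actuation(measured_volume_m3, req_work, req_power),
        constants=constants,
    )
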