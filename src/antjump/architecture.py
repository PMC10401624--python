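"""Muscle architecture metrics from volume plus traced fibers.

PCSA (physiological cross-sectional area) is defined as muscle volume
divided by mean fiber length; it is proportional to the muscle's maximum
isometric force. Pennate fibers pull at an angle to the line of action, so
only the cosine component of their force reaches the tendon: the effective
PCSA discounts PCSA by that cosine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import FiberSet, ValidationError

__all__ = [
    "compute_pcsa",
    "force_loss_factor",
    "compute_effective_pcsa",
    "summarize_architecture",
    "ArchitectureSummary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchitectureSummary:
    """Per-muscle architecture statistics (lengths m, angles degrees)."""

    species_name: str
    muscle_code: str
    n_fibers: int
    mean_fiber_length_m: float
    sd_fiber_length_m: float
    mean_pennation_deg: float
    sd_pennation_deg: float
    pcsa_m2: float
    effective_pcsa_m2: float


def compute_pcsa(volume_m3: float, fibers: FiberSet) -> float:
    """PCSA = muscle volume / arithmetic-mean fiber length.

    By this definition ``pcsa * mean_fiber_length == volume`` identically.
    """
    if not (volume_m3 > 0):
        raise ValidationError(f"volume must be > 0, got {volume_m3!r}")
    return volume_m3 / float(np.mean(fibers.lengths_m))


def force_loss_factor(pennation_deg: float) -> float:
    """cos(pennation angle): the fraction of fiber force reaching the tendon.

    A pennation of 8 deg costs ~1% of instantaneous force (cos 8 = 0.99);
    even 27 deg costs only ~10% (cos 27 = 0.89).
    """
    if not (0 <= pennation_deg < 90):
        raise ValidationError(
            f"pennation angle must lie in [0, 90) degrees, got {pennation_deg!r}"
        )
    return float(np.cos(np.deg2rad(pennation_deg)))


def compute_effective_pcsa(
    volume_m3: float, fibers: FiberSet, mode: str = "mean_angle"
) -> float:
    """PCSA discounted by pennation.

    ``mean_angle`` (default): (V / mean length) * cos(mean angle).
    ``per_fiber``: each fiber carries an equal share V/n of the volume and
    contributes (V/n) * cos(theta_i) / L_i; for heterogeneous fiber lengths
    this weights short fibers more heavily than the mean-angle form.
    """
    if not (volume_m3 > 0):
        raise ValidationError(f"volume must be > 0, got {volume_m3!r}")
    if mode == "mean_angle":
        return compute_pcsa(volume_m3, fibers) * force_loss_factor(
            float(np.mean(fibers.pennation_deg))
        )
    if mode == "per_fiber":
        cosines = np.cos(np.deg2rad(fibers.pennation_deg))
        return float(volume_m3 / len(fibers) * np.sum(cosines / fibers.lengths_m))
    raise ValidationError(f"unknown effective-PCSA mode {mode!r}")


def summarize_architecture(
    volume_m3: float, fibers: FiberSet, mode: str = "mean_angle"
) -> ArchitectureSummary:
    """Mean +/- sample s.d. of fiber length and pennation, plus (effective) PCSA.

    Standard deviations use the n-1 denominator; a single-fiber set reports
    s.d. 0 with a warning.
    """
    n = len(fibers)
    if n == 1:
        logger.warning(
            "%s %s: single traced fiber, s.d. reported as 0",
            fibers.species_name,
            fibers.muscle_code,
        )
        sd_len, sd_ang = 0.0, 0.0
    else:
        sd_len = float(np.std(fibers.lengths_m, ddof=1))
        sd_ang = float(np.std(fibers.pennation_deg, ddof=1))
    return ArchitectureSummary(
        species_name=fibers.species_name,
        muscle_code=fibers.muscle_code,
        n_fibers=n,
        mean_fiber_length_m=float(np.mean(fibers.lengths_m)),
        sd_fiber_length_m=sd_len,
        mean_pennation_deg=float(np.mean(fibers.pennation_deg)),
        sd_pennation_deg=sd_ang,
        pcsa_m2=compute_pcsa(volume_m3, fibers),
        effective_pcsa_m2=compute_effective_pcsa(volume_m3, fibers, mode=mode),
    )
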