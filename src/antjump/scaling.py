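"""Allometric size-normalization and the isometry regression.

Comparing muscles across ants of different body size requires removing the
expected geometric scaling: volumes grow as size^1, areas as ~size^0.66 and
lengths as ~size^0.33 of a reference volume. Thorax volume stands in for
body mass where no weighed mass exists, justified by thorax volume scaling
isometrically with body volume across ants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .types import PhysiologicalConstants, ValidationError

__all__ = [
    "NormalizationMode",
    "NormalizedMetrics",
    "relative_volume",
    "relative_pcsa",
    "relative_fiber_length",
    "normalize_pcsa_by_thorax_surface",
    "mass_from_volume",
    "isometry_slope",
    "IsometryFit",
]


class NormalizationMode(str, Enum):
    MUSCLE_VOLUME = "muscle_volume"
    THORAX_SURFACE = "thorax_surface"


@dataclass(frozen=True)
class NormalizedMetrics:
    """Size-normalized metrics for one muscle of one species."""

    species_name: str
    muscle_code: str
    relative_volume: float
    relative_pcsa: float
    relative_fiber_length: float
    normalization_mode: NormalizationMode


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValidationError(f"{name} must be > 0, got {value!r}")


def relative_volume(v_muscle_m3: float, v_thorax_m3: float) -> float:
    """Muscle volume as a fraction of thorax volume (size-free, exponent 1)."""
    _check_positive(v_muscle_m3=v_muscle_m3, v_thorax_m3=v_thorax_m3)
    return v_muscle_m3 / v_thorax_m3


def relative_pcsa(
    pcsa_m2: float,
    v_muscle_m3: float,
    constants: PhysiologicalConstants | None = None,
) -> float:
    """PCSA normalized to muscle volume^0.66 (default exponent)."""
    constants = constants or PhysiologicalConstants()
    _check_positive(pcsa_m2=pcsa_m2, v_muscle_m3=v_muscle_m3)
    return pcsa_m2 / v_muscle_m3 ** constants.pcsa_exponent


def relative_fiber_length(
    length_m: float,
    v_muscle_m3: float,
    constants: PhysiologicalConstants | None = None,
) -> float:
    """Fiber length normalized to muscle volume^0.33 (default exponent)."""
    constants = constants or PhysiologicalConstants()
    _check_positive(length_m=length_m, v_muscle_m3=v_muscle_m3)
    return length_m / v_muscle_m3 ** constants.fiber_exponent


def normalize_pcsa_by_thorax_surface(pcsa_m2: float, v_thorax_m3: float) -> float:
    """PCSA divided by a thorax surface-area proxy, V_thorax^(2/3).

    An isometric pair of species maps to identical values.
    """
    _check_positive(pcsa_m2=pcsa_m2, v_thorax_m3=v_thorax_m3)
    return pcsa_m2 / v_thorax_m3 ** (2.0 / 3.0)


def mass_from_volume(volume_m3: float, density_kg_per_m3: float = 1040.0) -> float:
    """Body or muscle mass from volume under a uniform tissue density."""
    if volume_m3 < 0:
        raise ValidationError(f"volume must be >= 0, got {volume_m3!r}")
    _check_positive(density_kg_per_m3=density_kg_per_m3)
    return volume_m3 * density_kg_per_m3


@dataclass(frozen=True)
class IsometryFit:
    """Log-log regression slope with its t-based 95% confidence interval."""

    slope: float
    ci_low: float
    ci_high: float
    intercept: float
    n: int

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def isometry_slope(
    volumes_a, volumes_b, method: str = "ols", confidence: float = 0.95
) -> IsometryFit:
    """Slope of log10(a) on log10(b) with a t-based confidence interval.

    A slope CI covering 1 is consistent with isometry. ``method='ols'``
    (default) is ordinary least squares; ``'rma'`` is reduced major axis
    (slope = sign(r) * sd(log a) / sd(log b)), offered because neither axis
    is error-free in practice.
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired 1-D samples required")
    if a.size < 3:
        raise ValidationError(f"need >= 3 pairs, got {a.size}")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("log-log regression requires strictly positive values")
    x, y = np.log10(b), np.log10(a)
    n = x.size
    fit = stats.linregress(x, y)
    if method == "ols":
        slope, stderr, intercept = fit.slope, fit.stderr, fit.intercept
    elif method == "rma":
        r = fit.rvalue
        slope = float(np.sign(r) if r != 0 else 1.0) * float(
            np.std(y, ddof=1) / np.std(x, ddof=1)
        )
        intercept = float(np.mean(y) - slope * np.mean(x))
        # standard error of the RMA slope equals that of the OLS slope
        stderr = fit.stderr
    else:
        raise ValidationError(f"unknown regression method {method!r}")
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    half = tcrit * stderr
    return IsometryFit(
        slope=float(slope),
        ci_low=float(slope - half),
        ci_high=float(slope + half),
        intercept=float(intercept),
        n=int(n),
    )
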