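"""Unit registries and rounding helpers.

Internal computations are in SI (m, kg, s, m3, J, W); pennation angles are
kept in degrees and converted to radians only at the point where a cosine is
evaluated. Tabular inputs declare their unit, and every conversion is an
exact power of ten applied as a single correctly-rounded multiply or divide,
so write-then-read round trips are bit-exact and decimal inputs land on the
nearest representable value.
"""

from __future__ import annotations

import math

__all__ = [
    "VOLUME_UNITS",
    "LENGTH_UNITS",
    "MASS_UNITS",
    "to_si",
    "from_si",
    "convert",
    "round_half_up",
    "round_sig",
]

#: Volume unit -> decimal exponent relative to m^3.
VOLUME_UNITS: dict[str, int] = {"m3": 0, "mm3": -9, "um3": -18}

#: Length unit -> decimal exponent relative to m.
LENGTH_UNITS: dict[str, int] = {"m": 0, "mm": -3, "um": -6}

#: Mass unit -> decimal exponent relative to kg.
MASS_UNITS: dict[str, int] = {"kg": 0, "g": -3, "mg": -6}


def _exponent(unit: str, registry: dict[str, int]) -> int:
    try:
        return registry[unit]
    except KeyError:
        raise ValueError(
            f"unknown unit {unit!r}; expected one of {sorted(registry)}"
        ) from None


def _scale(value: float, exponent: int) -> float:
    # multiply by 10**n for n >= 0, divide by 10**-n otherwise: both are a
    # single correctly-rounded operation against an exactly representable
    # power of ten
    if exponent >= 0:
        return value * float(10**exponent)
    return value / float(10**-exponent)


def to_si(value: float, unit: str, registry: dict[str, int]) -> float:
    """Convert ``value`` expressed in ``unit`` to the SI base of ``registry``."""
    return _scale(value, _exponent(unit, registry))


def from_si(value: float, unit: str, registry: dict[str, int]) -> float:
    """Convert an SI ``value`` into ``unit`` (inverse of :func:`to_si`)."""
    return _scale(value, -_exponent(unit, registry))


def convert(value: float, from_unit: str, to_unit: str, registry: dict[str, int]) -> float:
    """Convert between two units of the same registry."""
    return _scale(value, _exponent(from_unit, registry) - _exponent(to_unit, registry))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (display convention for ratio tables).

    Python's built-in ``round`` uses banker's rounding; printed morphometric
    ratios follow the ordinary half-up convention instead.
    """
    factor = 10.0 ** decimals
    if x >= 0:
        return math.floor(x * factor + 0.5) / factor
    return -math.floor(-x * factor + 0.5) / factor


def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant digits (half up).

    Used to compare computed energetics against values printed with a
    2-3 significant digit mantissa.
    """
    if x == 0:
        return 0.0
    if n_sig < 1:
        raise ValueError("n_sig must be >= 1")
    decimals = n_sig - 1 - math.floor(math.log10(abs(x)))
    return round_half_up(x, decimals)
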