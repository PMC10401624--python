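"""Myrmecological muscle nomenclature parsing.

Leg muscles carry a Roman-numeral prefix naming the thoracic segment / leg
pair they serve (I = front, II = middle, III = hind) followed by a group
token such as ``scm6`` (sterno-coxal, here the trochanter depressor),
``pcm8`` (pleuro-coxal), ``ctm1`` (coxo-trochanteral) or ``ftm1``/``ftm2``
(femoro-tibial extensor/flexor). Codes that are not leg muscles (the
abdominal levator ``IA1``, rotator ``IA2``, the head's indirect muscle
``Idvm5``) are kept verbatim with no leg assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = ["Leg", "ParsedMuscleCode", "parse_muscle_code", "MuscleCodeError", "KNOWN_LEG_STEMS"]


class MuscleCodeError(ValueError):
    """A muscle nomenclature token could not be parsed."""


class Leg(str, Enum):
    """Leg pair served by a muscle (``NONE`` for non-leg muscles)."""

    I = "I"
    II = "II"
    III = "III"
    NONE = "none"


#: Group stems that denote leg musculature and therefore admit a leg prefix.
KNOWN_LEG_STEMS = ("scm", "pcm", "ctm", "ftm")

_CODE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")
_LEG_RE = re.compile(
    r"^(?P<prefix>I{1,3})(?P<group>(?:%s)\d+(?:_\d+)?)$" % "|".join(KNOWN_LEG_STEMS)
)


@dataclass(frozen=True)
class ParsedMuscleCode:
    """A muscle code split into its leg prefix and group token."""

    leg: Leg
    group: str


def parse_muscle_code(code: str) -> ParsedMuscleCode:
    """Split a nomenclature token into (leg, group).

    Examples
    --------
    >>> parse_muscle_code("IIscm6")
    ParsedMuscleCode(leg=<Leg.II: 'II'>, group='scm6')
    >>> parse_muscle_code("IA1").leg
    <Leg.NONE: 'none'>
    """
    if not code:
        raise MuscleCodeError("empty muscle code")
    if not _CODE_RE.match(code):
        raise MuscleCodeError(
            f"malformed muscle code {code!r}: unexpected characters"
        )
    if re.fullmatch(r"I{1,3}", code):
        raise MuscleCodeError(
            f"malformed muscle code {code!r}: leg prefix without a muscle group"
        )
    m = _LEG_RE.match(code)
    if m:
        return ParsedMuscleCode(leg=Leg(m.group("prefix")), group=m.group("group"))
    # Not a prefixed leg muscle: abdominal/head muscles (IA1, Idvm5) or a
    # bare leg-group token (ftm1) used without a leg prefix.
    return ParsedMuscleCode(leg=Leg.NONE, group=code)
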