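"""Published observations used as pipeline inputs.

These are the printed measurements for the study cast — four jumping
species (Gigantiops destructor, Harpegnathos saltator, Myrmecia
nigrocincta, Odontomachus rixosus) paired with four non-jumping relatives
(Formica rufa, Euponera sikorae, Nothomyrmecia macrops, Odontomachus
kuroiwae). They are inputs to the analysis, not expected outputs: body
masses, take-off speeds and times, measured trochanter-depressor volumes,
and mean leg/body lengths.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "JUMP_OBSERVATIONS",
    "LEG_OBSERVATIONS",
    "jump_observations_frame",
    "leg_observations_frame",
]

#: Jump performance inputs: body mass (kg), take-off speed (m/s), take-off
#: time (s) and the measured total (bilateral, mid+hind) trochanter
#: depressor muscle volume (m^3).
JUMP_OBSERVATIONS: dict[str, dict[str, float]] = {
    "Gigantiops destructor": {
        "body_mass_kg": 1.55e-5,
        "takeoff_speed_m_s": 0.6,
        "takeoff_time_s": 0.0275,
        "measured_muscle_volume_m3": 4.1e-10,
    },
    "Harpegnathos saltator": {
        "body_mass_kg": 3.2e-5,
        "takeoff_speed_m_s": 0.7,
        "takeoff_time_s": 0.02,
        "measured_muscle_volume_m3": 1.29e-9,
    },
    "Myrmecia nigrocincta": {
        "body_mass_kg": 2.66e-5,
        "takeoff_speed_m_s": 0.44,
        "takeoff_time_s": 0.0199,
        "measured_muscle_volume_m3": 4.94e-10,
    },
}

#: Mean leg lengths (mm) and body length (mm) per species; ``jumping``
#: flags the prosalient species.
LEG_OBSERVATIONS: dict[str, dict[str, float | bool]] = {
    "Gigantiops destructor": {
        "front_mm": 8.93, "middle_mm": 10.03, "hind_mm": 14.7,
        "body_length_mm": 9.24, "jumping": True,
    },
    "Formica rufa": {
        "front_mm": 7.08, "middle_mm": 7.24, "hind_mm": 9.03,
        "body_length_mm": 7.79, "jumping": False,
    },
    "Harpegnathos saltator": {
        "front_mm": 8.46, "middle_mm": 7.92, "hind_mm": 10.91,
        "body_length_mm": 11.8, "jumping": True,
    },
    "Euponera sikorae": {
        "front_mm": 7.19, "middle_mm": 7.13, "hind_mm": 9.02,
        "body_length_mm": 10.93, "jumping": False,
    },
    "Odontomachus rixosus": {
        "front_mm": 8.63, "middle_mm": 8.22, "hind_mm": 10.62,
        "body_length_mm": 11.07, "jumping": True,
    },
    "Odontomachus kuroiwae": {
        "front_mm": 7.46, "middle_mm": 6.9, "hind_mm": 9.01,
        "body_length_mm": 8.45, "jumping": False,
    },
    "Myrmecia nigrocincta": {
        "front_mm": 10.15, "middle_mm": 10.94, "hind_mm": 14.93,
        "body_length_mm": 12.25, "jumping": True,
    },
    "Nothomyrmecia macrops": {
        "front_mm": 5.34, "middle_mm": 5.81, "hind_mm": 7.23,
        "body_length_mm": 8.66, "jumping": False,
    },
}


def jump_observations_frame() -> pd.DataFrame:
    """Jump inputs as a DataFrame indexed by species."""
    return pd.DataFrame.from_dict(JUMP_OBSERVATIONS, orient="index")


def leg_observations_frame() -> pd.DataFrame:
    """Leg/body length inputs as a DataFrame indexed by species."""
    return pd.DataFrame.from_dict(LEG_OBSERVATIONS, orient="index")
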