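"""Stimulus bookkeeping: dB SPL, ear-canal gain, equal-force conversion.

Both stimulation pathways are referenced to 60 dB SPL at the ear canal.
The middle ear is not modelled; a fixed pressure gain of 26 dB (24 dB
surface-area ratio of the tympanic membrane to the oval-window membrane
plus 2.5 dB ossicular lever, rounded) maps the ear-canal level to 86 dB
SPL at the oval window.  The round-window level then follows from equal
delivered force: the same force spread over the smaller round-window area
means a higher pressure, level_rw = level_ow + 20*log10(a_ow / a_rw),
which evaluates to ~93 dB SPL for the 5.1 / 2.3 mm^2 areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fixtures import GeometrySpec

__all__ = [
    "P_REF",
    "EC_LEVEL_DB_SPL",
    "EC_GAIN_DB",
    "LEVER_GAIN_DB",
    "spl_to_pressure",
    "pressure_to_spl",
    "equal_force_level",
    "ec_gain",
    "stimulus_force",
    "pressure_ratio_db",
    "stiffness_fold_to_thickness_fold",
    "StimulusCalibration",
    "default_calibration",
]

#: Reference sound pressure (Pa), 20 uPa.
P_REF = 20e-6
#: Ear-canal stimulus level (dB SPL), common to both pathways.
EC_LEVEL_DB_SPL = 60.0
#: Fixed middle-ear pressure gain (dB): the model uses the set constant 26,
#: not the exactly computed surface + lever total.
EC_GAIN_DB = 26.0
#: Assumed ossicular lever contribution (dB).
LEVER_GAIN_DB = 2.5


def spl_to_pressure(level: float) -> float:
    """Pressure amplitude (Pa) of a level in dB SPL re 20 uPa."""
    return P_REF * 10.0 ** (level / 20.0)


def pressure_to_spl(pressure: float) -> float:
    """Level in dB SPL of a pressure amplitude (Pa)."""
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    return 20.0 * math.log10(pressure / P_REF)


def equal_force_level(level_a: float, area_a: float, area_b: float) -> float:
    """Level at area_b delivering the same force as level_a over area_a.

    F = p * A, so level_b = level_a + 20*log10(area_a / area_b).  Its own
    inverse under area swap.
    """
    if area_a <= 0 or area_b <= 0:
        raise ValueError("areas must be positive")
    return level_a + 20.0 * math.log10(area_a / area_b)


def ec_gain(area_tm: float, area_ow: float, lever_db: float = LEVER_GAIN_DB) -> tuple[float, float]:
    """(surface_db, total_db) middle-ear pressure gain from area ratio + lever.

    surface_db = 20*log10(area_tm / area_ow); total adds the lever term.
    Note the model uses the set constant ``EC_GAIN_DB`` = 26 dB, not this
    computed total (which is ~26.4 dB for the default areas).
    """
    if area_tm <= 0 or area_ow <= 0:
        raise ValueError("areas must be positive")
    surface_db = 20.0 * math.log10(area_tm / area_ow)
    return surface_db, surface_db + lever_db


def stimulus_force(level: float, area: float) -> float:
    """Force (N) delivered by a level in dB SPL over an area (m^2)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return spl_to_pressure(level) * area


def pressure_ratio_db(ratio: float) -> float:
    """dB equivalent of a pressure (or force-at-fixed-area) ratio."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return 20.0 * math.log10(ratio)


def stiffness_fold_to_thickness_fold(stiffness_fold: float) -> float:
    """Thickness increase equivalent to a bending-stiffness increase.

    Plate bending stiffness scales with thickness cubed, so a stiffness
    fold maps to fold**(1/3) in thickness (100x stiffness ~ 4.6x thickness).
    """
    if stiffness_fold <= 0:
        raise ValueError("stiffness_fold must be positive")
    return stiffness_fold ** (1.0 / 3.0)


@dataclass(frozen=True)
class StimulusCalibration:
    """Resolved stimulus levels and forces for both pathways."""

    p_ec_level: float
    ec_gain: float
    level_owm: float
    level_rwm: float
    a_ow: float
    a_rw: float

    @property
    def pressure_owm(self) -> float:
        return spl_to_pressure(self.level_owm)

    @property
    def pressure_rwm(self) -> float:
        return spl_to_pressure(self.level_rwm)

    @property
    def force(self) -> float:
        """Delivered force (N); equal across pathways by construction."""
        return stimulus_force(self.level_owm, self.a_ow)


def default_calibration(geometry: GeometrySpec) -> StimulusCalibration:
    """Equal-force stimulus calibration for a geometry.

    Forward: 60 dB SPL + 26 dB gain = 86 dB SPL over the oval-window
    membrane.  Reverse: the exact equal-force level over the round window
    (92.92 dB SPL for the default areas; 93 dB when rounded for reporting).
    """
    level_owm = EC_LEVEL_DB_SPL + EC_GAIN_DB
    level_rwm = equal_force_level(level_owm, geometry.a_ow, geometry.a_rw)
    return StimulusCalibration(
        p_ec_level=EC_LEVEL_DB_SPL,
        ec_gain=EC_GAIN_DB,
        level_owm=level_owm,
        level_rwm=level_rwm,
        a_ow=geometry.a_ow,
        a_rw=geometry.a_rw,
    )
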