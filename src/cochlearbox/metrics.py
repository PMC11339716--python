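"""Verification and comparison metrics.

Covers the transfer quantities used to verify the normal model against
published middle-ear measurements — the middle-ear transfer function
(METF = 20 log10 of footplate displacement in um per Pa of ear-canal
pressure), the cochlear input impedance Z_C = P_SV / U_stapes, the reverse
middle-ear impedance Z_ME_R (the same probes on reverse-stimulation
solutions) and the round-window/oval-window volume-displacement ratio —
plus the place-frequency machinery: characteristic-frequency (CF)
extraction from BM displacement profiles, the Greenwood human
place-frequency map, unwrapped phase re the basal edge in cycles, and
relative amplitude at reference CF locations (the hearing-threshold-change
proxy used to stage pathologies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .solver import SolutionField

__all__ = [
    "TransferMetrics",
    "CFMap",
    "GREENWOOD_A_HZ",
    "GREENWOOD_ALPHA",
    "GREENWOOD_K",
    "METF_PLAUSIBILITY_BAND_DB",
    "IMPEDANCE_PLAUSIBILITY_BAND",
    "metf",
    "cochlear_input_impedance",
    "reverse_middle_ear_impedance",
    "volume_displacement_ratio",
    "extract_cf",
    "greenwood_reference",
    "greenwood_position",
    "phase_re_base",
    "phase_re_base_profile",
    "relative_amplitude_at_cf",
    "max_displacement_db",
]

# Human Greenwood constants f(x) = A * (10**(a * (1 - x)) - k) with x the
# normalized distance from the base; literature defaults, config-overridable.
GREENWOOD_A_HZ = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88

#: Broad plausibility band for the middle-ear transfer function
#: (dB ref um/Pa): covers the spread of published human METF measurements
#: together with the steeper high-frequency roll-off of a reduced-order
#: model.  A logged sanity constant, not a digitized experimental bound.
METF_PLAUSIBILITY_BAND_DB = (-70.0, -10.0)

#: Order-of-magnitude plausibility band for |Z_C| and |Z_ME_R| (Pa*s/m^3),
#: consistent with published ranges; a logged constant.
IMPEDANCE_PLAUSIBILITY_BAND = (1e6, 1e12)


@dataclass(frozen=True)
class TransferMetrics:
    """Transfer quantities of one (scenario, pathway, frequency) run."""

    frequency: float
    metf: float | None  # dB ref um/Pa (forward runs only)
    z_c: complex | None  # cochlear input impedance (forward runs)
    z_me_r: complex | None  # reverse middle-ear impedance (reverse runs)
    vol_ratio: float  # |u_rw| / |u_ow|


@dataclass(frozen=True)
class CFMap:
    """Characteristic place of one run."""

    frequency: float
    cf_location: float  # normalized distance from base in [0, 1]
    peak_displacement: float  # m
    phase_at_cf: float  # cycles re the basal segment


def metf(d_stapes: complex | float, p_ec: float) -> float:
    """Middle-ear transfer function, dB ref um/Pa.

    20 * log10(|stapes footplate displacement| in um / ear-canal pressure
    in Pa).
    """
    if p_ec <= 0:
        raise ValueError("ear-canal pressure must be positive")
    return 20.0 * np.log10(abs(d_stapes) * 1e6 / p_ec)


def cochlear_input_impedance(p_sv: complex, u_stapes: complex) -> complex:
    """Cochlear input impedance Z_C = P_SV / U_stapes (Pa*s/m^3).

    ``u_stapes`` is the footplate piston volume velocity (velocity times
    the 4.2 mm^2 footplate area); ``p_sv`` the vestibule pressure 200 um
    from the oval window, both on a forward-stimulation solution.
    """
    if abs(u_stapes) == 0:
        raise ValueError("stapes volume velocity must be nonzero")
    return p_sv / u_stapes


def reverse_middle_ear_impedance(p_sv_r: complex, u_stapes_r: complex) -> complex:
    """Reverse middle-ear impedance Z_ME_R = P_SV_R / U_stapes_R.

    Same probes as :func:`cochlear_input_impedance`, evaluated on a
    reverse-stimulation solution.
    """
    if abs(u_stapes_r) == 0:
        raise ValueError("stapes volume velocity must be nonzero")
    return p_sv_r / u_stapes_r


def volume_displacement_ratio(solution: "SolutionField") -> float:
    """|U_RW| / |U_OW| of a forward solution.

    At a fixed frequency the displacement ratio equals the velocity ratio;
    incompressibility with rigid walls pins it at 1.
    """
    if abs(solution.u_ow) == 0:
        raise ValueError("oval-window volume velocity is zero")
    return abs(solution.u_rw) / abs(solution.u_ow)


def extract_cf(profile: np.ndarray, x: np.ndarray | None = None) -> tuple[float, float]:
    """Characteristic place of a |d(x)| profile.

    Returns ``(location, peak)`` with the location normalized to [0, 1]
    (by index span, or by ``x`` if given).  The arg-max is refined by a
    parabolic fit through the three samples around it; ties break toward
    the base.  A monotone profile returns the corresponding endpoint with
    a warning; a flat profile is an error.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 2:
        raise ValueError("profile must be a 1-D array with at least 2 samples")
    if np.ptp(profile) == 0:
        raise ValueError("flat profile has no characteristic place")
    if x is None:
        pos = np.linspace(0.0, 1.0, profile.size)
    else:
        x = np.asarray(x, dtype=float)
        pos = (x - x[0]) / (x[-1] - x[0])
    i = int(np.argmax(profile))  # first (most basal) max on ties
    diffs = np.diff(profile)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        warnings.warn("monotone displacement profile; returning the endpoint", stacklevel=2)
        return float(pos[i]), float(profile[i])
    if 0 < i < profile.size - 1:
        y0, y1, y2 = profile[i - 1 : i + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            loc = pos[i] + delta * (pos[min(i + 1, profile.size - 1)] - pos[i])
            peak = y1 - 0.25 * (y0 - y2) * delta
            return float(loc), float(peak)
    return float(pos[i]), float(profile[i])


def greenwood_reference(
    x: float | np.ndarray,
    *,
    A: float = GREENWOOD_A_HZ,
    alpha: float = GREENWOOD_ALPHA,
    k: float = GREENWOOD_K,
) -> float | np.ndarray:
    """Greenwood place-frequency map f(x) = A*(10**(alpha*(1-x)) - k).

    ``x`` is the normalized distance from the base in [0, 1]; apex (x=1)
    maps to ~20 Hz, base (x=0) to ~21 kHz with the human constants.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise ValueError("x must lie in [0, 1]")
    f = A * (10.0 ** (alpha * (1.0 - x_arr)) - k)
    return float(f) if np.isscalar(x) else f


def greenwood_position(
    f: float,
    *,
    A: float = GREENWOOD_A_HZ,
    alpha: float = GREENWOOD_ALPHA,
    k: float = GREENWOOD_K,
) -> float:
    """Inverse Greenwood map: normalized distance from base of frequency f."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    arg = f / A + k
    x = 1.0 - np.log10(arg) / alpha
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"frequency {f} Hz maps outside the basilar membrane")
    return float(x)


def phase_re_base_profile(d: np.ndarray) -> np.ndarray:
    """Unwrapped phase of a complex field along x, in cycles re the base.

    Unwrapping proceeds base->apex; negative values are lags.
    """
    d = np.asarray(d)
    phase = np.unwrap(np.angle(d))
    return (phase - phase[0]) / (2.0 * np.pi)


def phase_re_base(solution: "SolutionField", location: float) -> float:
    """Phase of the BM displacement at a normalized location, cycles re base."""
    prof = phase_re_base_profile(solution.d)
    pos = np.linspace(0.0, 1.0, prof.size)
    if not (0.0 <= location <= 1.0):
        raise ValueError("location must be a normalized position in [0, 1]")
    return float(np.interp(location, pos, prof))


def amplitude_at(solution_d: np.ndarray, location: float) -> float:
    """|d| interpolated at a normalized location."""
    mag = np.abs(np.asarray(solution_d))
    pos = np.linspace(0.0, 1.0, mag.size)
    return float(np.interp(location, pos, mag))


def relative_amplitude_at_cf(
    solution: "SolutionField",
    reference_cf_locations: Sequence[float] | dict[float, float],
    reference_amplitudes: Sequence[float] | dict[float, float],
) -> float:
    """Amplitude change (dB) at the normal-forward CF place of this frequency.

    20*log10(|d(x_cf_ref)| / |d_ref(x_cf_ref)|); 0 dB is the normal model
    under forward stimulation, the baseline for hearing-threshold change.
    References may be dicts keyed by frequency or aligned sequences of one
    entry (this run's frequency).
    """
    f = solution.frequency
    if isinstance(reference_cf_locations, dict):
        if f not in reference_cf_locations:
            raise KeyError(f"no reference CF location for {f} Hz")
        loc = reference_cf_locations[f]
        ref_amp = reference_amplitudes[f]
    else:
        loc = float(np.atleast_1d(reference_cf_locations)[0])
        ref_amp = float(np.atleast_1d(reference_amplitudes)[0])
    amp = amplitude_at(solution.d, loc)
    if ref_amp <= 0:
        raise ValueError("reference amplitude must be positive")
    return 20.0 * float(np.log10(amp / ref_amp))


def max_displacement_db(solution: "SolutionField") -> float:
    """Maximum BM displacement over x, in dB re 1 m (relative use only)."""
    return 20.0 * float(np.log10(np.max(np.abs(solution.d))))
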