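"""Coil-orientation preference via amplitude-weighted circular statistics.

Angle convention (fixed throughout the package): 0 deg = East (toward the
right preauricular point), counterclockwise positive, 90 deg = North
(toward the nasion).  The canonical motor-cortex coil orientation,
"North-East", is 45 deg.

The mean resultant vector sums the per-orientation amplitude vectors and
divides by the number of orientations: with amplitudes a_i at angles
theta_i,

    R = || sum_i a_i (cos theta_i, sin theta_i) || / N.

Equal amplitudes at equally spaced angles give length 0; a single nonzero
amplitude of 1 among 8 orientations gives length 1/8.  Because background
EMG alone produces nonzero resultant lengths, preferences are baseline
corrected by subtracting the resultant length of the matched pre-TMS
window from the post-TMS one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationProfile",
    "OrientationPreference",
    "resultant",
    "baseline_corrected_preference",
    "compass_label",
    "COMPASS_POINTS",
]

COMPASS_POINTS = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")  # 0, 45, ... 315 deg


@dataclass(frozen=True)
class OrientationProfile:
    """Normalised MEP amplitude per coil orientation."""

    angles_deg: tuple[float, ...]
    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.mod(np.asarray(self.angles_deg, dtype=float), 360.0)
        if len(self.angles_deg) != len(self.amplitudes):
            raise ValueError("angles and amplitudes must have equal length")
        if len(np.unique(np.round(a, 9))) != len(a):
            raise ValueError("angles must be distinct modulo 360")
        if np.any(np.asarray(self.amplitudes, dtype=float) < 0):
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class OrientationPreference:
    """Strength and direction of the coil-orientation preference."""

    resultant_length: float
    preferred_angle_deg: float | None  # None when the resultant has length 0
    corrected_length: float
    n_orientations: int


def resultant(profile: OrientationProfile) -> tuple[float, float | None]:
    """Length and direction of the amplitude-weighted mean resultant vector.

    The angle is mapped to [0, 360) and reported as None for a zero-length
    resultant, whose direction is undefined.
    """
    angles = np.asarray(profile.angles_deg, dtype=float)
    amps = np.asarray(profile.amplitudes, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least 2 orientations")
    rad = np.deg2rad(angles)
    vx = float(np.sum(amps * np.cos(rad)))
    vy = float(np.sum(amps * np.sin(rad)))
    n = angles.size
    length = float(np.hypot(vx, vy) / n)
    # numerically zero resultants (e.g. perfectly uniform profiles) have no
    # defined direction
    if length <= 1e-12 * max(1.0, float(amps.max(initial=0.0))):
        return 0.0, None
    angle = float(np.mod(np.rad2deg(np.arctan2(vy, vx)), 360.0))
    return length, angle


def baseline_corrected_preference(
    post_profile: OrientationProfile, pre_profile: OrientationProfile
) -> OrientationPreference:
    """Post-TMS preference with the pre-TMS resultant length subtracted.

    The preferred angle is taken from the post-TMS profile; the corrected
    length is post length minus pre length and may be negative when
    background activity is more orientation-structured than the MEPs.
    """
    post_a = np.mod(np.asarray(post_profile.angles_deg, float), 360.0)
    pre_a = np.mod(np.asarray(pre_profile.angles_deg, float), 360.0)
    if post_a.size != pre_a.size or not np.allclose(np.sort(post_a), np.sort(pre_a)):
        raise ValueError("post and pre profiles must share the same angle set")
    post_len, post_ang = resultant(post_profile)
    pre_len, _ = resultant(pre_profile)
    return OrientationPreference(
        resultant_length=post_len,
        preferred_angle_deg=post_ang,
        corrected_length=post_len - pre_len,
        n_orientations=len(post_profile.angles_deg),
    )


def compass_label(angle_deg: float) -> str:
    """Nearest of the 8 compass points; ties go counterclockwise (up).

    90 -> N (nasion), 45 -> NE, 112.5 (tie) -> NW.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    idx = int(np.floor((np.mod(angle_deg, 360.0) + 22.5) / 45.0)) % 8
    return COMPASS_POINTS[idx]
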