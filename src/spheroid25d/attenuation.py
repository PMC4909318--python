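"""Signal-attenuation quantification and visibility classification.

Fluorescence deep inside spheroid tissue is attenuated by absorption and
scattering, so only an upper portion of each spheroid is measurable.  The
axial intensity profile I(z) of a *stable* whole-cell marker through the
spheroid centre quantifies this: the percentage retained at depth z is

    P_att(z) = 100 * I(z) / I_max,

where I_max is the profile maximum (taken as the unattenuated level near
the spheroid top).  The depth at which P_att falls to a user threshold
P_min bounds the analyzable region, and comparing that depth with the
vertical diameter 2c of the fitted ellipsoid yields a visibility class:

* FULL            — depth >= 2c: the whole spheroid is measurable.
* HALF            — c <= depth < 2c: the upper half (at least) is
                    measurable; counts are extrapolated to the lower half.
* NOT_ANALYZABLE  — depth < c: less than half measurable, no valid
                    extrapolation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "AxialProfile",
    "Visibility",
    "DepthResult",
    "attenuation_percentage",
    "analyzable_depth",
    "classify_visibility",
]


@dataclass
class AxialProfile:
    """Axial intensity profile I(z) through a spheroid centre.

    ``z_values`` are ascending micrometre depths with spacing equal to the
    stack z-step; ``z_top`` (the first z of the spheroid, estimated as the
    profile's upper inflection point) is attached by the ellipsoid stage.
    """

    z_values: np.ndarray  # um, ascending
    intensities: np.ndarray
    z_top: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.z_values.shape != self.intensities.shape:
            raise ValueError("z_values and intensities must have the same length")
        if self.z_values.size and np.any(np.diff(self.z_values) <= 0):
            raise ValueError("z_values must be strictly ascending")

    @property
    def z_step(self) -> float:
        return float(self.z_values[1] - self.z_values[0])

    @property
    def i_max(self) -> float:
        return float(self.intensities.max())

    @property
    def z_at_max(self) -> float:
        return float(self.z_values[int(np.argmax(self.intensities))])


def attenuation_percentage(profile: AxialProfile) -> np.ndarray:
    """Percentage of signal retained at each depth, ``100 * I(z) / I_max``."""
    i_max = profile.i_max
    if i_max <= 0:
        raise ValueError("profile maximum must be positive")
    return 100.0 * profile.intensities / i_max


class DepthResult(NamedTuple):
    depth: float  # um, z_analyzable - z_top
    z_analyzable: float  # um
    capped: bool  # False when P_att never fell below P_min in the window


def analyzable_depth(profile: AxialProfile, p_min: float = 50.0) -> DepthResult:
    """Analyzable depth of a spheroid: from its top to the P_min crossing.

    The profile is smoothed with a Gaussian of one z-step before crossing
    detection so cell-scale texture does not trigger it; the search starts
    strictly after the profile maximum so the rising flank near the top is
    never mistaken for attenuation.  The crossing is interpolated linearly
    between slices.  When P_att never drops to ``p_min`` inside the
    profile window the depth extends to the last sample and the result is
    flagged uncapped.
    """
    if not (0.0 < p_min < 100.0):
        raise ValueError("p_min must lie strictly between 0 and 100")
    if profile.z_top is None:
        raise ValueError("profile.z_top is not set; run the ellipsoid stage first")

    smooth = gaussian_filter1d(profile.intensities, sigma=1.0, mode="nearest")
    i_max = smooth.max()
    if i_max <= 0:
        raise ValueError("profile maximum must be positive")
    p_att = 100.0 * smooth / i_max
    k_max = int(np.argmax(smooth))

    z = profile.z_values
    for k in range(k_max + 1, z.size):
        if p_att[k] <= p_min:
            # linear sub-slice interpolation between k-1 (above) and k
            p0, p1 = p_att[k - 1], p_att[k]
            frac = (p0 - p_min) / (p0 - p1) if p0 != p1 else 1.0
            z_cross = z[k - 1] + frac * (z[k] - z[k - 1])
            return DepthResult(float(z_cross - profile.z_top), float(z_cross), True)
    return DepthResult(float(z[-1] - profile.z_top), float(z[-1]), False)


class Visibility(str, enum.Enum):
    FULL = "full"
    HALF = "half"
    NOT_ANALYZABLE = "not-analyzable"


def classify_visibility(ellipsoid, depth: float) -> Visibility:
    """Classify a spheroid by comparing analyzable depth with 2c.

    Equality cases fall into the more permissive class: ``depth == 2c`` is
    FULL, ``depth == c`` is HALF.
    """
    c = ellipsoid.c
    if c <= 0:
        raise ValueError("ellipsoid vertical semi-axis must be positive")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth >= 2 * c:
        return Visibility.FULL
    if depth >= c:
        return Visibility.HALF
    return Visibility.NOT_ANALYZABLE
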