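"""Feeding field-of-view along a reef cross-section.

A grazing herbivore's ability to spot an approaching predator is proxied by
how much of the upward 90-degree quadrant is unobstructed by terrain. Virtual
observers are placed along the transect at the mean eye height of a feeding
fish (2.5 cm above the benthos) and each looks horizontally toward the
transect midpoint out to a sight range set by typical flight-initiation
distance and water visibility (2.5 m). The maximum angle subtended above the
horizontal by terrain within range is the obstruction angle theta; the
visible fraction is (90 - theta) / 90 and its complement is the blocked
fraction. Both are reported; the visible fraction feeds downstream models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import OutOfBoundsError
from .profiles import ElevationProfile


@dataclass(frozen=True)
class ObserverConfig:
    """Geometry of the virtual feeding-fish observers."""

    eye_height: float = 0.025  # m above the benthos
    spacing: float = 1.0       # m between observers
    first_offset: float = 0.5  # m position of the first observer
    sight_length: float = 2.5  # m horizontal sight range

    def __post_init__(self):
        for name in ("eye_height", "spacing", "first_offset", "sight_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ViewshedResult:
    per_observer: tuple
    """Tuple of ``(x, direction, theta_deg, visible_fraction)`` records."""
    transect_visible: float
    transect_blocked: float


def observer_positions(transect_length: float, config: ObserverConfig | None = None) -> list:
    """Observer x positions and viewing directions for a transect.

    Observers sit at ``first_offset, first_offset + spacing, ...`` and each
    looks toward the transect midpoint; an observer at the exact midpoint
    looks both ways.
    """
    config = config or ObserverConfig()
    if transect_length <= config.first_offset:
        raise ValueError("transect shorter than the first observer offset")
    mid = transect_length / 2.0
    out = []
    xi = config.first_offset
    while xi <= transect_length + 1e-9:
        if abs(xi - mid) < 1e-9:
            out.append((xi, ("left", "right")))
        elif xi < mid:
            out.append((xi, ("right",)))
        else:
            out.append((xi, ("left",)))
        xi += config.spacing
    return out


def obstruction_angle(
    profile: ElevationProfile,
    x_obs: float,
    direction: str,
    config: ObserverConfig | None = None,
) -> float:
    """Maximum terrain angle (degrees above horizontal) seen by one observer.

    The eye sits at ``z(x_obs) + eye_height``; terrain samples within
    ``sight_length`` horizontal distance in ``direction`` are scanned and the
    largest subtended angle is returned, clamped to [0, 90]. Downward angles
    clamp to zero: a fish at a drop-off keeps its full upward view.
    """
    config = config or ObserverConfig()
    if x_obs < profile.x[0] - 1e-9 or x_obs > profile.x[-1] + 1e-9:
        raise OutOfBoundsError("observer outside profile extent")
    z_eye = float(profile.elevation_at(x_obs)) + config.eye_height
    if direction == "right":
        mask = (profile.x > x_obs) & (profile.x <= x_obs + config.sight_length)
    elif direction == "left":
        mask = (profile.x < x_obs) & (profile.x >= x_obs - config.sight_length)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    if not np.any(mask):
        return 0.0
    dz = profile.z[mask] - z_eye
    dist = np.abs(profile.x[mask] - x_obs)
    theta = math.degrees(np.max(np.arctan2(dz, dist)))
    return float(min(90.0, max(0.0, theta)))


def field_of_view(profile: ElevationProfile, config: ObserverConfig | None = None) -> ViewshedResult:
    """Per-observer and transect-mean visible fractions of the feeding field of view.

    Each observer contributes ``(90 - theta) / 90``; the midpoint observer
    contributes the mean of its two directions, so every observer location
    carries equal weight.
    """
    config = config or ObserverConfig()
    records = []
    per_loc = []
    for x_obs, directions in observer_positions(profile.length, config):
        fracs = []
        for d in directions:
            theta = obstruction_angle(profile, profile.x[0] + x_obs, d, config)
            frac = (90.0 - theta) / 90.0
            records.append((x_obs, d, theta, frac))
            fracs.append(frac)
        per_loc.append(float(np.mean(fracs)))
    visible = float(np.mean(per_loc))
    return ViewshedResult(
        per_observer=tuple(records),
        transect_visible=visible,
        transect_blocked=1.0 - visible,
    )
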