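"""Inverting observed shell transparency into exposure space.

A shell collected from the wild integrates the severity of its
low-saturation exposure — the product of intensity (aragonite saturation
state Omega) and duration (days). The forward model

    T = alpha * Omega^b + slope * D + beta

is closed-form invertible in either variable:

    Omega(T, D) = ((T - slope*D - beta) / alpha) ** (1/b)
    D(T, Omega) = (T - alpha * Omega^b - beta) / slope

Since one transparency cannot discriminate intensity from duration, the
useful output is the exposure envelope: the locus of (Omega, D) pairs
consistent with one observed T, restricted to the biologically active
region (Omega <= 1.5 response threshold, durations beyond the ~2-day
emergence of the effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .profiles import TransparencyConstants, get_profile

__all__ = [
    "InversionDomainError",
    "DurationResult",
    "ExposureEnvelope",
    "forward_transparency",
    "invert_omega",
    "invert_duration",
    "emergence_time",
    "exposure_envelope",
]

#: observed biological range of shell transparency
TRANSPARENCY_RANGE = (0.4, 0.9)
#: minimum transparency ever observed in the exposures
TRANSPARENCY_FLOOR_OBSERVED = 0.44
#: saturation-state response threshold bounding the envelope
OMEGA_THRESHOLD = 1.5
#: envelope duration floor: effects emerge only after ~2 days
DURATION_FLOOR_DAYS = 2.0


class InversionDomainError(ValueError):
    """Transparency/duration combination outside the model's domain."""


class DurationResult(NamedTuple):
    """Inverted exposure duration with a below-emergence flag."""

    days: float
    below_emergence: bool

    def __float__(self) -> float:
        return self.days


def forward_transparency(
    omega_ar, duration_days, profile: str | TransparencyConstants = "eq5_verbatim"
):
    """Forward model T = alpha * Omega^b + slope * D + beta."""
    c = get_profile(profile)
    omega_ar = np.asarray(omega_ar, dtype=float)
    out = (
        c.alpha_pristine * omega_ar**c.exponent_b
        + c.duration_slope * np.asarray(duration_days, dtype=float)
        + c.beta
    )
    return float(out) if out.ndim == 0 else out


def invert_omega(
    transparency: float,
    duration_days: float,
    profile: str | TransparencyConstants = "eq5_verbatim",
) -> float:
    """Saturation state consistent with an observed transparency and duration.

    With the verbatim intensity-inversion constants this is
    Omega = 10 ** (log10((T + 0.0238 D + 0.0344) / 0.81) / 0.255).
    """
    c = get_profile(profile)
    numerator = transparency - c.duration_slope * duration_days - c.beta
    if numerator <= 0:
        raise InversionDomainError(
            f"transparency {transparency} at {duration_days} d implies a "
            "non-positive power-law term; outside the model domain"
        )
    return float((numerator / c.alpha_pristine) ** (1.0 / c.exponent_b))


def invert_duration(
    transparency: float,
    omega_ar: float,
    profile: str | TransparencyConstants = "eq6_verbatim",
) -> DurationResult:
    """Exposure duration consistent with an observed transparency and Omega.

    With the verbatim duration-inversion constants this is
    D = (T - 0.82 * Omega^0.0255 - 0.0555) / (-0.0239). Negative
    durations (observed transparency above what any positive exposure
    could leave) are returned flagged, not clamped.
    """
    if omega_ar <= 0:
        raise InversionDomainError(f"omega_ar must be positive, got {omega_ar}")
    c = get_profile(profile)
    days = (
        transparency - c.alpha_pristine * omega_ar**c.exponent_b - c.beta
    ) / c.duration_slope
    return DurationResult(days=float(days), below_emergence=days < 0)


def emergence_time(profile: str | TransparencyConstants = "eq6_verbatim") -> float:
    """Days of exposure before transparency change becomes detectable.

    Obtained by setting the duration-adjusted deficit to zero for a
    pristine shell (observed transparency equal to its Day-4 prediction):
    D = beta / (-slope). ~2.3 days under the verbatim duration-inversion
    constants; infinity (undefined) in the zero-slope limit.
    """
    return get_profile(profile).emergence_days


@dataclass
class ExposureEnvelope:
    """The (Omega, duration) locus consistent with one observed transparency."""

    transparency_observed: float
    curve: pd.DataFrame  # columns omega_ar, duration_days, ascending omega
    omega_range: tuple[float, float]
    duration_floor_days: float
    profile: str
    out_of_observed_range: bool = False
    below_transparency_floor: bool = False

    def __len__(self) -> int:
        return len(self.curve)


def exposure_envelope(
    transparency: float,
    omega_grid: np.ndarray | None = None,
    profile: str | TransparencyConstants = "eq6_verbatim",
    duration_floor_days: float = DURATION_FLOOR_DAYS,
) -> ExposureEnvelope:
    """Exposure envelope for one observed transparency.

    Durations are inverted on an Omega grid (default 0.5 to 1.5 in steps
    of 0.01, covering the treatment range up to the response threshold);
    points earlier than the ~2-day emergence floor are excluded. The
    curve increases monotonically in Omega: milder intensity requires a
    longer duration to leave the same shell state.

    Transparencies outside the observed biological range [0.4, 0.9]
    produce a warning (and a flag on the result) but still a curve.
    """
    c = get_profile(profile)
    if omega_grid is None:
        omega_grid = np.arange(0.5, OMEGA_THRESHOLD + 1e-9, 0.01)
    omega_grid = np.asarray(omega_grid, dtype=float)
    omega_grid = omega_grid[(omega_grid > 0) & (omega_grid <= OMEGA_THRESHOLD)]

    lo, hi = TRANSPARENCY_RANGE
    out_of_range = not lo <= transparency <= hi
    if out_of_range:
        warnings.warn(
            f"transparency {transparency} outside the observed biological "
            f"range [{lo}, {hi}]; envelope extrapolates the calibration",
            stacklevel=2,
        )
    below_floor = transparency < TRANSPARENCY_FLOOR_OBSERVED
    if below_floor:
        warnings.warn(
            f"transparency {transparency} is below the minimum ever observed "
            f"({TRANSPARENCY_FLOOR_OBSERVED}); likely at the biological floor",
            stacklevel=2,
        )

    days = np.array(
        [invert_duration(transparency, w, c).days for w in omega_grid]
    )
    keep = days >= duration_floor_days
    curve = pd.DataFrame(
        {"omega_ar": omega_grid[keep], "duration_days": days[keep]}
    ).sort_values("omega_ar", ignore_index=True)
    return ExposureEnvelope(
        transparency_observed=float(transparency),
        curve=curve,
        omega_range=(float(omega_grid.min()), float(omega_grid.max())),
        duration_floor_days=duration_floor_days,
        profile=c.name,
        out_of_observed_range=out_of_range,
        below_transparency_floor=below_floor,
    )
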