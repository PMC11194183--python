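"""Named constant sets for the transparency dose-response model.

The shell-transparency model is

    T = alpha * Omega^b + slope * D + beta      (medium/high exposure)

with T the observed transparency, Omega the aragonite saturation state,
D the exposure duration in days, alpha the seasonal intercept and beta
the duration-regression intercept. The published account prints slightly
different constants in different places (alpha 0.82 vs 0.81; beta 0.1026
vs -0.0344 vs 0.0555; slope -0.0238 vs -0.0239; exponent 0.255 with one
0.0255 variant). These are not reconciled silently: each printed set is
preserved verbatim as a named profile, and a self-consistent set is
provided for exact forward/inverse round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TransparencyConstants", "PROFILES", "get_profile"]


@dataclass(frozen=True)
class TransparencyConstants:
    """One coherent set of constants for the transparency model.

    Attributes
    ----------
    alpha_pristine : seasonal intercept for a pristine (unexposed) shell.
    exponent_b : power-law exponent on the saturation state.
    duration_slope : transparency change per day of exposure (negative).
    beta : intercept of the deficit-versus-duration regression.
    """

    name: str
    alpha_pristine: float
    exponent_b: float
    duration_slope: float
    beta: float

    @property
    def emergence_days(self) -> float:
        """Duration at which the duration-adjusted deficit reaches zero.

        Infinite (undefined) in the degenerate zero-slope limit.
        """
        if self.duration_slope == 0:
            return float("inf")
        return self.beta / (-self.duration_slope)


PROFILES: dict[str, TransparencyConstants] = {
    # Constants as stated in the results narrative; mutually consistent
    # (alpha 0.82, b 0.255, slope -0.0238, beta 0.1026).
    "results_text": TransparencyConstants(
        "results_text", alpha_pristine=0.82, exponent_b=0.255,
        duration_slope=-0.0238, beta=0.1026,
    ),
    # Verbatim constants of the intensity-inversion equation
    # (alpha 0.81, offset 0.0344 i.e. beta -0.0344).
    "eq5_verbatim": TransparencyConstants(
        "eq5_verbatim", alpha_pristine=0.81, exponent_b=0.255,
        duration_slope=-0.0238, beta=-0.0344,
    ),
    # Verbatim constants of the duration-inversion equation, including its
    # printed exponent 0.0255 (where 0.255 would be expected).
    "eq6_verbatim": TransparencyConstants(
        "eq6_verbatim", alpha_pristine=0.82, exponent_b=0.0255,
        duration_slope=-0.0239, beta=0.0555,
    ),
}
# the self-consistent set coincides with the results narrative
PROFILES["self_consistent"] = TransparencyConstants(
    "self_consistent", alpha_pristine=0.82, exponent_b=0.255,
    duration_slope=-0.0238, beta=0.1026,
)
# aliases matching the calibration-model enum
PROFILES["discussion_eq5"] = PROFILES["eq5_verbatim"]
PROFILES["discussion_eq6"] = PROFILES["eq6_verbatim"]


def get_profile(profile: str | TransparencyConstants) -> TransparencyConstants:
    """Resolve a profile name (or pass a custom constant set through)."""
    if isinstance(profile, TransparencyConstants):
        return profile
    try:
        return PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown constants profile {profile!r}; "
            f"available: {sorted(set(PROFILES))}"
        ) from None
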