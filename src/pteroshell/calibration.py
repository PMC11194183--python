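"""Seasonal power-law calibration of shell transparency to CO2 exposure.

The calibration chain, fitted from individual-level transparency records:

1. Per season, at the 4-day time point, transparency T versus aragonite
   saturation state Omega is fit as a power law T = alpha_s * Omega^b_s
   (ordinary least squares on log T vs log Omega).
2. The cross-season exponent b is the arithmetic mean of the per-season
   exponents, with SE = SD/sqrt(n).
3. The seasonal intercept alpha tracks the field ("Day 0") transparency
   of that season linearly: alpha = 1.0293 * T_day0 - 0.1087, giving
   alpha = 0.82 for a pristine shell (T_day0 ~ 0.90).
4. Each duration-experiment record gets a predicted Day-4 transparency
   D4T = alpha_s * Omega^b; the deficit (observed - D4T) regressed on
   duration for the medium/high treatments yields
   deficit = slope * D + beta, with slope ~ -0.0238 / day.

Ambient records are excluded from step 4: exposure above the Omega ~ 1.5
response threshold shows no duration effect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .profiles import PROFILES, TransparencyConstants, get_profile

__all__ = [
    "CalibrationModel",
    "TransparencyCalibrator",
    "CalibrationError",
    "fit_power_per_season",
    "average_exponent",
    "alpha_from_day0",
    "predict_d4t",
    "fit_duration_effect",
]

# alpha-versus-Day-0-transparency calibration line
ALPHA_LINE_SLOPE = 1.0293
ALPHA_LINE_INTERCEPT = -0.1087
#: Day-0 transparency of a pristine field-caught shell
PRISTINE_DAY0_TRANSPARENCY = 0.90
#: saturation-state threshold above which no duration effect is seen
OMEGA_RESPONSE_THRESHOLD = 1.5


class CalibrationError(ValueError):
    """Degenerate design or out-of-range input in a calibration fit."""


def fit_power_per_season(
    omega_ar: np.ndarray,
    transparency: np.ndarray,
    method: str = "loglog",
) -> tuple[float, float]:
    """Fit T = alpha * Omega^b for one season's 4-day records.

    ``method="loglog"`` (default) fits by OLS in log-log space, i.e. a
    multiplicative-error reading of the power law; ``method="nls"`` fits
    by nonlinear least squares in the original scale.

    Returns
    -------
    (alpha, exponent_b), both back-transformed to the original scale.
    """
    omega_ar = np.asarray(omega_ar, dtype=float)
    transparency = np.asarray(transparency, dtype=float)
    if omega_ar.shape != transparency.shape:
        raise CalibrationError("omega_ar and transparency must align")
    if np.any(omega_ar <= 0) or np.any(transparency <= 0):
        raise CalibrationError("power fit requires positive omega and transparency")
    if np.unique(omega_ar).size < 3:
        raise CalibrationError(
            f"need >= 3 distinct omega_ar values, got {np.unique(omega_ar).size}"
        )
    if np.ptp(np.log(omega_ar)) < 1e-8:
        raise CalibrationError("degenerate omega_ar spread")
    if method == "loglog":
        b, log_alpha = np.polyfit(np.log(omega_ar), np.log(transparency), 1)
        return float(np.exp(log_alpha)), float(b)
    if method == "nls":
        (alpha, b), _ = curve_fit(
            lambda x, a, e: a * x**e, omega_ar, transparency, p0=(0.7, 0.25)
        )
        return float(alpha), float(b)
    raise ValueError(f"unknown fit method {method!r}")


def average_exponent(per_season_exponents) -> tuple[float, float]:
    """Mean and standard error of independent per-season exponents."""
    exps = np.asarray(list(per_season_exponents), dtype=float)
    if exps.size < 2:
        raise CalibrationError("need exponents from >= 2 seasons")
    return float(exps.mean()), float(exps.std(ddof=1) / np.sqrt(exps.size))


def alpha_from_day0(day0_transparency: float) -> float:
    """Seasonal intercept alpha from that season's field (Day 0) transparency."""
    lo = -ALPHA_LINE_INTERCEPT / ALPHA_LINE_SLOPE
    if not lo <= day0_transparency <= 1.0:
        raise CalibrationError(
            f"day0 transparency {day0_transparency} outside ({lo:.4f}, 1]"
        )
    return ALPHA_LINE_SLOPE * day0_transparency + ALPHA_LINE_INTERCEPT


def predict_d4t(
    omega_ar, alpha: float, exponent_b: float = 0.255
) -> np.ndarray | float:
    """Predicted Day-4 transparency D4T = alpha * Omega^b."""
    omega_ar = np.asarray(omega_ar, dtype=float)
    if np.any(omega_ar <= 0):
        raise CalibrationError("omega_ar must be positive")
    out = alpha * omega_ar**exponent_b
    return float(out) if out.ndim == 0 else out


def fit_duration_effect(
    records: pd.DataFrame,
    alpha_by_season: dict[str, float],
    exponent_b: float = 0.255,
    floor: float | None = 0.40,
) -> tuple[float, float]:
    """OLS of the transparency deficit (observed - D4T) on exposure duration.

    Only medium/high-treatment records enter the fit; ambient exposures
    sit above the response threshold and show no duration effect.
    Records at or below the ~0.40 biological transparency floor are
    censored, not linear responses, and are excluded (set
    ``floor=None`` to keep them) — the published duration regression was
    likewise built from the late-year datasets whose shells stayed above
    the floor.

    Returns
    -------
    (duration_slope, beta) of deficit = slope * duration + beta.
    """
    required = {"season", "treatment", "omega_ar", "duration_days", "transparency"}
    missing = required - set(records.columns)
    if missing:
        raise CalibrationError(f"records missing columns {sorted(missing)}")
    sub = records[records["treatment"].isin(["medium", "high"])]
    if floor is not None:
        sub = sub[sub["transparency"] > floor + 1e-12]
    if sub.empty:
        raise CalibrationError(
            "no medium/high records: duration regression excludes ambient"
        )
    if sub["duration_days"].nunique() < 2:
        raise CalibrationError("need >= 2 distinct exposure durations")
    alpha = sub["season"].map(alpha_by_season)
    if alpha.isna().any():
        missing_seasons = sorted(sub.loc[alpha.isna(), "season"].unique())
        raise CalibrationError(f"no fitted alpha for season(s) {missing_seasons}")
    deficit = sub["transparency"] - predict_d4t(
        sub["omega_ar"].to_numpy(), 1.0, exponent_b
    ) * alpha.to_numpy()
    fit = stats.linregress(sub["duration_days"].to_numpy(), deficit.to_numpy())
    return float(fit.slope), float(fit.intercept)


@dataclass
class CalibrationModel:
    """Fitted constants of the transparency calibration chain."""

    exponent_b: float
    exponent_se: float
    alpha_by_season: dict[str, float]
    exponents_by_season: dict[str, float]
    alpha_line: tuple[float, float] | None  # (slope, intercept) vs Day-0 T
    alpha_pristine: float
    duration_slope: float
    beta: float
    constants_profile: str = "results_text"

    def __post_init__(self) -> None:
        if self.exponent_b <= 0:
            raise CalibrationError(f"exponent_b must be positive: {self.exponent_b}")
        if self.duration_slope >= 0:
            raise CalibrationError(
                f"duration_slope must be negative: {self.duration_slope}"
            )

    def to_constants(self) -> TransparencyConstants:
        """Export as a constant set usable by the exposure inversion."""
        return TransparencyConstants(
            name="fitted",
            alpha_pristine=self.alpha_pristine,
            exponent_b=self.exponent_b,
            duration_slope=self.duration_slope,
            beta=self.beta,
        )

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "CalibrationModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        if payload.get("alpha_line") is not None:
            payload["alpha_line"] = tuple(payload["alpha_line"])
        return cls(**payload)


class TransparencyCalibrator(BaseEstimator):
    """Fit the full transparency calibration chain from a record table.

    A scikit-learn style estimator: ``fit`` consumes a DataFrame of
    individual-level records with columns ``season``, ``treatment``
    (ambient/medium/high), ``omega_ar``, ``duration_days``,
    ``transparency`` and optionally ``day0_transparency`` (per-season
    field transparency); ``predict`` returns modelled transparency for
    records with ``season``/``omega_ar``/``duration_days``/``treatment``.

    Parameters
    ----------
    fit_method : "loglog" (OLS on logs, default) or "nls".
    day4_duration : duration (days) defining the power-law time point.
    fit_alpha_line : refit the alpha-versus-Day-0 line when per-season
        Day-0 transparencies are available; otherwise the published line
        (slope 1.0293, intercept -0.1087) is carried over.
    pristine_day0 : Day-0 transparency defining the pristine alpha.

    Attributes
    ----------
    alpha_by_season_, exponents_by_season_ : per-season power-law fits.
    exponent_b_, exponent_se_ : cross-season mean exponent and its SE.
    alpha_line_ : (slope, intercept) of alpha vs Day-0 transparency.
    alpha_pristine_ : alpha at ``pristine_day0``.
    duration_slope_, beta_ : duration-deficit regression constants.
    model_ : the assembled :class:`CalibrationModel`.
    """

    def __init__(
        self,
        fit_method: str = "loglog",
        day4_duration: float = 4.0,
        fit_alpha_line: bool = True,
        pristine_day0: float = PRISTINE_DAY0_TRANSPARENCY,
        constants_profile: str = "results_text",
        transparency_floor: float | None = 0.40,
    ):
        self.fit_method = fit_method
        self.day4_duration = day4_duration
        self.fit_alpha_line = fit_alpha_line
        self.pristine_day0 = pristine_day0
        self.constants_profile = constants_profile
        self.transparency_floor = transparency_floor

    def fit(self, X: pd.DataFrame, y=None) -> "TransparencyCalibrator":
        records = X
        day4 = records[records["duration_days"] == self.day4_duration]
        if day4.empty:
            raise CalibrationError(
                f"no records at the {self.day4_duration}-day time point"
            )
        alphas, exponents = {}, {}
        for season, grp in day4.groupby("season", sort=False):
            a, b = fit_power_per_season(
                grp["omega_ar"].to_numpy(),
                grp["transparency"].to_numpy(),
                method=self.fit_method,
            )
            alphas[str(season)] = a
            exponents[str(season)] = b
        self.alpha_by_season_ = alphas
        self.exponents_by_season_ = exponents
        self.exponent_b_, self.exponent_se_ = average_exponent(exponents.values())

        if self.fit_alpha_line and "day0_transparency" in records.columns:
            per_season_day0 = (
                records.dropna(subset=["day0_transparency"])
                .groupby("season")["day0_transparency"].mean()
            )
            common = [s for s in alphas if s in per_season_day0.index]
            if len(common) >= 2:
                line = stats.linregress(
                    per_season_day0[common].to_numpy(),
                    np.array([alphas[s] for s in common]),
                )
                self.alpha_line_ = (float(line.slope), float(line.intercept))
            else:
                self.alpha_line_ = (ALPHA_LINE_SLOPE, ALPHA_LINE_INTERCEPT)
        else:
            self.alpha_line_ = (ALPHA_LINE_SLOPE, ALPHA_LINE_INTERCEPT)
        slope, intercept = self.alpha_line_
        self.alpha_pristine_ = slope * self.pristine_day0 + intercept

        self.duration_slope_, self.beta_ = fit_duration_effect(
            records, alphas, exponent_b=self.exponent_b_,
            floor=self.transparency_floor,
        )
        self.model_ = CalibrationModel(
            exponent_b=self.exponent_b_,
            exponent_se=self.exponent_se_,
            alpha_by_season=alphas,
            exponents_by_season=exponents,
            alpha_line=self.alpha_line_,
            alpha_pristine=float(self.alpha_pristine_),
            duration_slope=self.duration_slope_,
            beta=self.beta_,
            constants_profile=self.constants_profile,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Modelled transparency: D4T plus the duration deficit.

        Ambient records receive the bare power-law prediction; medium and
        high records additionally carry the fitted linear duration term.
        """
        check_is_fitted(self, "model_")
        alpha = X["season"].map(self.alpha_by_season_)
        if alpha.isna().any():
            raise CalibrationError("unseen season in predict input")
        d4t = alpha.to_numpy() * X["omega_ar"].to_numpy() ** self.exponent_b_
        exposed = X["treatment"].isin(["medium", "high"]).to_numpy()
        deficit = self.duration_slope_ * X["duration_days"].to_numpy() + self.beta_
        return d4t + np.where(exposed, deficit, 0.0)
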