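"""Seawater CO2-system speciation: pH, pCO2 and aragonite saturation state.

Solves the marine carbonate system from a measured pair — (DIC, TA) or
(pH, TA) — at lab (surface) pressure on the total hydrogen-ion pH scale,
the configuration used for carboy-based CO2 exposure experiments: carbonic
acid dissociation constants from the Mehrbach data as refit by Dickson &
Millero (1987), bisulfate from Dickson (1990), borate-to-salinity from
Lee et al. (2010) (Uppström 1974 available), aragonite solubility from
Mucci (1983), CO2 solubility from Weiss (1974).

Alkalinity balance includes carbonate, borate, water, free proton,
bisulfate and fluoride terms; nutrient (phosphate/silicate) alkalinity is
taken as zero, matching datasets where nutrients are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConstantProfile",
    "WaterSample",
    "EquilibriumConstants",
    "evaluate_constants",
    "solve_from_dic_ta",
    "solve_from_ph_ta",
    "omega_aragonite",
]

#: bounds for the bracketed pH search (total scale)
PH_BRACKET = (5.5, 9.5)
#: convergence tolerance on the alkalinity residual, umol/kg
TA_TOLERANCE = 1e-3


class CarbonateValidationError(ValueError):
    """Raised when an input lies outside the supported oceanographic range."""


class CarbonateSolverError(RuntimeError):
    """Raised when the pH root search fails to converge."""


@dataclass(frozen=True)
class ConstantProfile:
    """Selection of dissociation-constant formulations.

    Defaults correspond to CO2SYS run with Mehrbach constants refit by
    Dickson & Millero, the Dickson KHSO4 constant and the Lee et al.
    boron-salinity ratio, at surface pressure on the total pH scale.
    The Lee default reproduces the published seasonal saturation states
    markedly better than the Uppström alternative.
    """

    k1k2_source: Literal["Mehrbach-refit-DicksonMillero"] = (
        "Mehrbach-refit-DicksonMillero"
    )
    khso4_source: Literal["Dickson-1990"] = "Dickson-1990"
    borate_salinity_source: Literal["Uppstrom-1974", "Lee-2010"] = "Lee-2010"
    ksp_aragonite_source: Literal["Mucci-1983"] = "Mucci-1983"
    pressure_dbar: float = 0.0

    def __post_init__(self) -> None:
        if self.pressure_dbar != 0.0:
            raise CarbonateValidationError(
                "only surface pressure (0 dbar) is supported"
            )


@dataclass
class WaterSample:
    """Carbonate-system state of one treatment/time point.

    Concentrations are umol/kg-seawater; ``pco2`` is uatm; ``ph`` is on the
    total scale; ``omega_ar`` is the aragonite saturation state
    [Ca2+][CO3 2-]/Ksp_ar.
    """

    salinity: float
    temperature: float
    dic: float | None = None
    ta: float | None = None
    ph: float | None = None
    pco2: float | None = None
    omega_ar: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.salinity <= 45.0:
            raise CarbonateValidationError(
                f"salinity {self.salinity} outside [0, 45]"
            )
        if not -2.0 <= self.temperature <= 40.0:
            raise CarbonateValidationError(
                f"temperature {self.temperature} C outside [-2, 40]"
            )
        for name in ("dic", "ta"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise CarbonateValidationError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Stoichiometric constants at one (S, T), total pH scale, mol/kg-SW."""

    k0: float  # CO2 solubility, mol kg-1 atm-1
    k1: float
    k2: float
    kb: float
    kw: float
    ks: float  # bisulfate, free scale
    kf: float  # HF, free scale
    ksp_ar: float  # aragonite solubility product, mol2 kg-2
    total_borate: float  # mol kg-1
    total_sulfate: float
    total_fluoride: float
    total_calcium: float
    sws_to_total: float  # multiplicative [H] scale factor


def evaluate_constants(
    salinity: float, temperature: float, profile: ConstantProfile | None = None
) -> EquilibriumConstants:
    """Evaluate all equilibrium constants at (S, T) on the total pH scale."""
    if profile is None:
        profile = ConstantProfile()
    s = float(salinity)
    tk = float(temperature) + 273.15
    ln_tk = np.log(tk)
    sqrt_s = np.sqrt(s)

    # ionic strength of seawater, mol/kg-H2O
    ion_str = 19.924 * s / (1000.0 - 1.005 * s)
    sqrt_i = np.sqrt(ion_str)

    # conservative totals (mol/kg-SW), scaled to chlorinity S/1.80655
    total_sulfate = 0.14 / 96.062 * s / 1.80655
    total_fluoride = 0.000067 / 18.998 * s / 1.80655
    total_calcium = 0.02128 / 40.087 * s / 1.80655
    if profile.borate_salinity_source == "Uppstrom-1974":
        total_borate = 0.000232 / 10.811 * s / 1.80655
    else:  # Lee et al. 2010
        total_borate = 0.0004326 * s / 35.0

    # bisulfate dissociation, Dickson 1990a, free scale, mol/kg-SW
    ln_ks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * ln_tk
        + (-13856.0 / tk + 324.57 - 47.986 * ln_tk) * sqrt_i
        + (35474.0 / tk - 771.54 + 114.723 * ln_tk) * ion_str
        - 2698.0 / tk * ion_str**1.5
        + 1776.0 / tk * ion_str**2
        + np.log(1.0 - 0.001005 * s)
    )
    ks = np.exp(ln_ks)

    # hydrogen fluoride, Dickson & Riley 1979, free scale
    ln_kf = (
        1590.2 / tk - 12.641 + 1.525 * sqrt_i + np.log(1.0 - 0.001005 * s)
    )
    kf = np.exp(ln_kf)

    # pH scale conversions: [H]_total = [H]_free (1 + ST/KS)
    free_to_total = 1.0 + total_sulfate / ks
    sws_to_free = 1.0 / (1.0 + total_sulfate / ks + total_fluoride / kf)
    sws_to_total = sws_to_free * free_to_total

    # CO2 solubility, Weiss 1974, mol/kg-SW/atm
    tk100 = tk / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / tk100
        + 23.3585 * np.log(tk100)
        + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2)
    )
    k0 = np.exp(ln_k0)

    # carbonic acid, Mehrbach refit by Dickson & Millero 1987 (SWS scale)
    pk1 = 3670.7 / tk - 62.008 + 9.7944 * ln_tk - 0.0118 * s + 0.000116 * s**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * s + 0.000118 * s**2
    k1 = 10.0**-pk1 * sws_to_total
    k2 = 10.0**-pk2 * sws_to_total

    # boric acid, Dickson 1990b, total scale
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2)
        / tk
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_tk
        + 0.053105 * sqrt_s * tk
    )
    kb = np.exp(ln_kb)

    # water, Millero 1995 (SWS scale)
    ln_kw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * ln_tk
        + (118.67 / tk - 5.977 + 1.0495 * ln_tk) * sqrt_s
        - 0.01615 * s
    )
    kw = np.exp(ln_kw) * sws_to_total

    # aragonite solubility, Mucci 1983, mol2/kg2
    log_ksp_ar = (
        -171.945
        - 0.077993 * tk
        + 2903.293 / tk
        + 71.595 * np.log10(tk)
        + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqrt_s
        - 0.10018 * s
        + 0.0059415 * s**1.5
    )
    ksp_ar = 10.0**log_ksp_ar

    return EquilibriumConstants(
        k0=k0,
        k1=k1,
        k2=k2,
        kb=kb,
        kw=kw,
        ks=ks,
        kf=kf,
        ksp_ar=ksp_ar,
        total_borate=total_borate,
        total_sulfate=total_sulfate,
        total_fluoride=total_fluoride,
        total_calcium=total_calcium,
        sws_to_total=sws_to_total,
    )


def _alkalinity_umol(h: float, dic_mol: float, k: EquilibriumConstants) -> float:
    """Model total alkalinity (umol/kg) at total-scale [H+] and DIC (mol/kg)."""
    denom = h * h + k.k1 * h + k.k1 * k.k2
    hco3 = dic_mol * k.k1 * h / denom
    co3 = dic_mol * k.k1 * k.k2 / denom
    boh4 = k.total_borate * k.kb / (k.kb + h)
    oh = k.kw / h
    h_free = h / (1.0 + k.total_sulfate / k.ks)
    hso4 = k.total_sulfate / (1.0 + k.ks / h_free)
    hf = k.total_fluoride / (1.0 + k.kf / h_free)
    ta_mol = hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf
    return ta_mol * 1e6


def _speciate_at_ph(
    ph: float, dic_mol: float, k: EquilibriumConstants
) -> tuple[float, float, float]:
    """Return ([CO2*], [HCO3-], [CO3 2-]) in mol/kg at total-scale pH."""
    h = 10.0**-ph
    denom = h * h + k.k1 * h + k.k1 * k.k2
    co2 = dic_mol * h * h / denom
    hco3 = dic_mol * k.k1 * h / denom
    co3 = dic_mol * k.k1 * k.k2 / denom
    return co2, hco3, co3


def omega_aragonite(
    co3: float,
    salinity: float,
    temperature: float,
    constants: ConstantProfile | EquilibriumConstants | None = None,
) -> float:
    """Aragonite saturation state Omega = [Ca2+][CO3 2-] / Ksp_aragonite.

    Parameters
    ----------
    co3 : carbonate-ion concentration, mol/kg-SW (must be positive).
    """
    if co3 <= 0:
        raise CarbonateValidationError(f"co3 must be positive, got {co3}")
    if isinstance(constants, EquilibriumConstants):
        k = constants
    else:
        k = evaluate_constants(salinity, temperature, constants)
    return k.total_calcium * co3 / k.ksp_ar


def solve_from_dic_ta(
    dic: float,
    ta: float,
    salinity: float,
    temperature: float,
    constants: ConstantProfile | None = None,
    sample_id: str | None = None,
) -> WaterSample:
    """Solve the CO2 system from a DIC-TA pair.

    Finds the unique total-scale pH at which the modelled alkalinity matches
    ``ta`` (bracketed Brent search on pH in [5.5, 9.5], residual tolerance
    1e-3 umol/kg), then derives pCO2 and the aragonite saturation state.

    Parameters
    ----------
    dic, ta : umol/kg-SW.
    salinity : practical salinity.
    temperature : deg C.

    Returns
    -------
    WaterSample with ``ph``, ``pco2`` (uatm) and ``omega_ar`` filled.
    """
    sample = WaterSample(
        salinity=salinity, temperature=temperature, dic=dic, ta=ta,
        sample_id=sample_id,
    )
    k = evaluate_constants(salinity, temperature, constants)
    dic_mol = dic * 1e-6

    def residual(ph: float) -> float:
        return _alkalinity_umol(10.0**-ph, dic_mol, k) - ta

    lo, hi = PH_BRACKET
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise CarbonateSolverError(
            f"alkalinity residual does not change sign on pH {PH_BRACKET} "
            f"for sample {sample_id or '(unnamed)'}: "
            f"DIC={dic}, TA={ta}, S={salinity}, T={temperature}"
        )
    # TA is monotone increasing in pH at fixed DIC, so the root is unique
    ph = brentq(residual, lo, hi, xtol=1e-10, maxiter=200)
    if abs(residual(ph)) > TA_TOLERANCE:
        raise CarbonateSolverError(
            f"pH search did not reach |dTA| < {TA_TOLERANCE} umol/kg for "
            f"sample {sample_id or '(unnamed)'}"
        )
    co2, _, co3 = _speciate_at_ph(ph, dic_mol, k)
    sample.ph = float(ph)
    sample.pco2 = float(co2 / k.k0 * 1e6)
    sample.omega_ar = float(omega_aragonite(co3, salinity, temperature, k))
    return sample


def solve_from_ph_ta(
    ph: float,
    ta: float,
    salinity: float,
    temperature: float,
    constants: ConstantProfile | None = None,
    sample_id: str | None = None,
) -> WaterSample:
    """Solve the CO2 system from a pH-TA pair (closed form at fixed pH).

    At known [H+], every alkalinity term except the carbonate terms is
    determined, so DIC follows directly from the carbonate-alkalinity
    remainder; round-trips with :func:`solve_from_dic_ta`.
    """
    if not 6.0 <= ph <= 9.0:
        raise CarbonateValidationError(f"ph {ph} outside [6, 9]")
    sample = WaterSample(
        salinity=salinity, temperature=temperature, ta=ta, ph=ph,
        sample_id=sample_id,
    )
    k = evaluate_constants(salinity, temperature, constants)
    h = 10.0**-ph
    boh4 = k.total_borate * k.kb / (k.kb + h)
    oh = k.kw / h
    h_free = h / (1.0 + k.total_sulfate / k.ks)
    hso4 = k.total_sulfate / (1.0 + k.ks / h_free)
    hf = k.total_fluoride / (1.0 + k.kf / h_free)
    carb_alk = ta * 1e-6 - boh4 - oh + h_free + hso4 + hf
    if carb_alk <= 0:
        raise CarbonateSolverError(
            f"non-positive carbonate alkalinity at pH={ph}, TA={ta}"
        )
    # carb_alk = DIC * K1 (h + 2 K2) / (h^2 + K1 h + K1 K2)
    denom = h * h + k.k1 * h + k.k1 * k.k2
    dic_mol = carb_alk * denom / (k.k1 * (h + 2.0 * k.k2))
    co2, _, co3 = _speciate_at_ph(ph, dic_mol, k)
    sample.dic = float(dic_mol * 1e6)
    sample.pco2 = float(co2 / k.k0 * 1e6)
    sample.omega_ar = float(omega_aragonite(co3, salinity, temperature, k))
    return sample
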