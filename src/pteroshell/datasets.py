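"""Reference experimental conditions for the seasonal CO2 exposures.

Mean water chemistry of the five Gulf of Maine seasonal laboratory
exposures (three CO2 treatments each: ambient bubbling ~380-440 uatm,
medium ~800 ppm, high ~1200 ppm). These means parameterize the synthetic
data generator and serve as solver inputs when reproducing the published
speciation.
"""

from __future__ import annotations

import pandas as pd

SEASONS = ("Jan14", "Apr14", "Aug14", "Nov14", "Apr15")
TREATMENTS = ("ambient", "medium", "high")

_ROWS = [
    # season, treatment, salinity, temp_C, dic, ta, ph, pco2, pco2_sd, omega, omega_sd
    ("Jan14", "ambient", 32, 8.02, 2101.1, 2248.2, 7.95, 421, 14, 1.69, 0.05),
    ("Jan14", "medium", 32, 8.02, 2177.8, 2250.0, 7.73, 728, 13, 1.08, 0.02),
    ("Jan14", "high", 32, 8.02, 2224.6, 2257.2, 7.59, 1016, 32, 0.81, 0.03),
    ("Apr14", "ambient", 34, 8.05, 2084.7, 2219.0, 7.97, 471, 11, 1.54, 0.03),
    ("Apr14", "medium", 34, 8.05, 2167.0, 2223.4, 7.74, 852, 20, 0.95, 0.02),
    ("Apr14", "high", 34, 8.05, 2202.8, 2219.2, 7.60, 1189, 45, 0.71, 0.02),
    ("Aug14", "ambient", 34, 7.77, 2039.8, 2182.5, 8.02, 430, 14, 1.60, 0.04),
    ("Aug14", "medium", 34, 7.77, 2113.4, 2188.3, 7.75, 718, 40, 1.07, 0.06),
    ("Aug14", "high", 34, 7.77, 2154.0, 2189.7, 7.64, 985, 39, 0.80, 0.03),
    ("Nov14", "ambient", 33, 7.57, 2084.6, 2210.7, 8.01, 476, 17, 1.48, 0.03),
    ("Nov14", "medium", 33, 7.57, 2150.8, 2198.8, 7.71, 864, 14, 0.88, 0.01),
    ("Nov14", "high", 33, 7.57, 2199.7, 2202.4, 7.58, 1310, 58, 0.63, 0.02),
    ("Apr15", "ambient", 33, 8.04, 2081.3, 2218.5, 7.99, 449, 3, 1.58, 0.01),
    ("Apr15", "medium", 33, 8.04, 2152.3, 2221.8, 7.78, 750, 35, 1.04, 0.04),
    ("Apr15", "high", 33, 8.04, 2202.0, 2216.8, 7.59, 1183, 61, 0.70, 0.04),
]


def seasonal_treatment_chemistry() -> pd.DataFrame:
    """Mean carbonate chemistry of each season x treatment cell.

    Columns: season, treatment, salinity, temperature_C, dic_umol_kg,
    ta_umol_kg, ph, pco2_uatm, pco2_sd, omega_ar, omega_sd. pH, pCO2 and
    omega_ar are the published time-averaged values; DIC/TA/S/T are the
    experiment means from which the speciation can be recomputed.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "season", "treatment", "salinity", "temperature_C",
            "dic_umol_kg", "ta_umol_kg", "ph", "pco2_uatm", "pco2_sd",
            "omega_ar", "omega_sd",
        ],
    )
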