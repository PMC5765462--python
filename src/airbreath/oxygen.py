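"""Oxygen unit conversions and freshwater O2 solubility.

The package's canonical units are kPa O2 partial pressure for the air
phase and % air saturation for the water phase.  Solubility of oxygen in
air-equilibrated fresh water is computed from the Benson & Krause (1984)
empirical fit, the coefficient set used by USGS/standard limnological
tables.
"""

from __future__ import annotations

import numpy as np

#: Gas constant in L·kPa·mmol⁻¹·K⁻¹ (= 8.31446 J·mol⁻¹·K⁻¹ rescaled).
R_GAS = 8.31446e-3

#: Mole fraction of O2 in dry air.
O2_FRACTION = 0.20946

#: Standard atmosphere in kPa.
ATM_KPA = 101.325

#: Molar mass of O2, g·mmol⁻¹ scale (32 g/mol = 0.032 g/mmol).
O2_MG_PER_MMOL = 32.0


def water_vapour_pressure_kpa(temp_c: float) -> float:
    """Saturation vapour pressure of water (kPa), Magnus formula."""
    return 0.61094 * np.exp(17.625 * temp_c / (temp_c + 243.04))


def o2_solubility(temp_c: float, pressure_kpa: float = ATM_KPA) -> float:
    """Oxygen content of air-saturated fresh water, mmol O2 · L⁻¹.

    Benson–Krause equation for dissolved O2 (mg/L) at standard pressure,
    rescaled to the local barometric pressure (vapour-pressure corrected)
    and converted to mmol/L.

    Parameters
    ----------
    temp_c : water temperature, °C.
    pressure_kpa : barometric pressure, kPa (default one atmosphere).
    """
    if not (0.0 < temp_c < 40.0):
        raise ValueError(f"temperature {temp_c} °C outside supported range (0, 40)")
    t_k = temp_c + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / t_k
        - 6.642308e7 / t_k**2
        + 1.243800e10 / t_k**3
        - 8.621949e11 / t_k**4
    )
    do_mg_l = np.exp(ln_c)  # mg/L at 1 atm moist air
    p_w = water_vapour_pressure_kpa(temp_c)
    pressure_factor = (pressure_kpa - p_w) / (ATM_KPA - p_w)
    return do_mg_l * pressure_factor / O2_MG_PER_MMOL


def po2_air_saturated_kpa(temp_c: float, pressure_kpa: float = ATM_KPA) -> float:
    """PO2 of water-saturated air (kPa) at given temperature/pressure."""
    return O2_FRACTION * (pressure_kpa - water_vapour_pressure_kpa(temp_c))


def kpa_to_percent_sat(po2_kpa, temp_c: float, pressure_kpa: float = ATM_KPA):
    """Convert O2 partial pressure (kPa) to % air saturation."""
    return 100.0 * np.asarray(po2_kpa) / po2_air_saturated_kpa(temp_c, pressure_kpa)


def percent_sat_to_kpa(pct_sat, temp_c: float, pressure_kpa: float = ATM_KPA):
    """Convert % air saturation to O2 partial pressure (kPa)."""
    return np.asarray(pct_sat) / 100.0 * po2_air_saturated_kpa(temp_c, pressure_kpa)
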