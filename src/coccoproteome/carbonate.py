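"""Seawater CO2-system speciation from measured DIC and total alkalinity.

Given dissolved inorganic carbon (DIC) and total alkalinity (TA) at a known
temperature and salinity, the full carbonate system is over-determined and the
remaining parameters (pH, pCO2, the three dissolved carbon species and the
calcite saturation state Omega) follow from the stoichiometric equilibrium
constants.  This module evaluates the CO2SYS-default constant set for the
Mehrbach K1/K2 refit on the total pH scale, solves TA(pH; DIC) = TA_measured
with a safeguarded Newton iteration, and reports the speciated state.

Conventions
-----------
* total pH scale, mol per kg of seawater, pressure 0 dbar (surface cultures);
* DIC/TA inputs and the speciated carbon pools in µmol kg-1;
* pCO2 as an uncorrected partial pressure in µatm (no fugacity correction),
  the unit the source data tables print as p.p.m.v.;
* alkalinity is the minimal carbonate + borate + water form
  TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]free - [HSO4-] - [HF],
  with optional phosphate and silicate terms for nutrient-enriched media.

Constant provenance: K0 Weiss (1974); K1/K2 Mehrbach et al. (1973) as refit
by Dickson & Millero (1987); KB Dickson (1990b); KW Millero (1995);
KS Dickson (1990a); KF Dickson & Riley (1979); borate/salinity Uppström
(1974); calcite solubility Mucci (1983); Ca/salinity Riley & Tongudai.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "ConstantsSet",
    "CarbonateState",
    "equilibrium_constants",
    "speciate",
    "alkalinity_residual",
    "solve_from_dic_ta",
    "omega_calcite",
    "percent_dic_drawdown",
    "solve_table",
]


class DomainError(ValueError):
    """Input outside the physical/parameterised domain; names the field."""


@dataclass(frozen=True)
class ConstantsSet:
    """Stoichiometric equilibrium constants at one (T, S), pressure 0 dbar.

    K1/K2/KB/KW are expressed on the total pH scale, KS and KF on the free
    scale (they define the scale conversions), all in mol kg-SW-1 units.
    """

    temperature: float  # °C
    salinity: float  # practical salinity
    K0: float  # CO2 solubility, mol kg-1 atm-1
    K1: float  # H2CO3 -> HCO3-, total scale
    K2: float  # HCO3- -> CO3--, total scale
    KB: float  # B(OH)3, total scale
    KW: float  # water, total scale, mol2 kg-2
    KS: float  # HSO4-, free scale
    KF: float  # HF, free scale
    Ksp_cal: float  # calcite solubility product, mol2 kg-2
    BT: float  # total borate, mol kg-1
    ST: float  # total sulfate, mol kg-1
    FT: float  # total fluoride, mol kg-1
    CaT: float  # total calcium, mol kg-1
    PT: float = 0.0  # total phosphate, mol kg-1 (optional TA terms)
    SiT: float = 0.0  # total silicate, mol kg-1
    KP1: float = 0.0
    KP2: float = 0.0
    KP3: float = 0.0
    KSi: float = 0.0

    def free_to_total(self) -> float:
        """h_total / h_free = 1 + ST/KS."""
        return 1.0 + self.ST / self.KS


def equilibrium_constants(
    temperature: float,
    salinity: float,
    phosphate: float = 0.0,
    silicate: float = 0.0,
) -> ConstantsSet:
    """Evaluate the full constant set at (T, S), pressure 0.

    Parameters
    ----------
    temperature : float
        In-situ temperature, °C, must lie in (0, 40).
    salinity : float
        Practical salinity, must lie in (1, 45).
    phosphate, silicate : float
        Medium nutrient totals in mol kg-1; only used when the alkalinity
        model is asked to include nutrient terms.

    Constants natively defined on the seawater scale (K1, K2, KW) are
    converted to the total scale via the sulfate/fluoride equilibria.
    """
    if not 0.0 < temperature < 40.0:
        raise DomainError(f"temperature {temperature} °C outside (0, 40)")
    if not 1.0 < salinity < 45.0:
        raise DomainError(f"salinity {salinity} outside (1, 45)")

    T = temperature + 273.15
    S = salinity
    lnT = math.log(T)
    sqS = math.sqrt(S)

    # --- salinity-proportional totals (mol kg-SW-1)
    BT = 0.000232 / 10.811 * S / 1.80655  # Uppström (1974)
    ST = 0.14 / 96.062 * S / 1.80655  # Morris & Riley (1966)
    FT = 0.000067 / 18.998 * S / 1.80655  # Riley (1965)
    CaT = 0.02128 / 40.087 * S / 1.80655  # Riley & Tongudai (1967)

    # --- ionic strength (mol kg-H2O-1)
    ion = 19.924 * S / (1000.0 - 1.005 * S)

    # --- KS, Dickson (1990a), free scale, mol kg-SW-1
    lnKS = (
        -4276.1 / T
        + 141.328
        - 23.093 * lnT
        + (-13856.0 / T + 324.57 - 47.986 * lnT) * math.sqrt(ion)
        + (35474.0 / T - 771.54 + 114.723 * lnT) * ion
        - 2698.0 / T * ion**1.5
        + 1776.0 / T * ion**2
    )
    KS = math.exp(lnKS) * (1.0 - 0.001005 * S)

    # --- KF, Dickson & Riley (1979), free scale, mol kg-SW-1
    lnKF = 1590.2 / T - 12.641 + 1.525 * math.sqrt(ion)
    KF = math.exp(lnKF) * (1.0 - 0.001005 * S)

    # scale conversion factors
    free_to_tot = 1.0 + ST / KS
    sws_to_tot = free_to_tot / (1.0 + ST / KS + FT / KF)

    # --- K0, Weiss (1974), mol kg-1 atm-1
    T100 = T / 100.0
    lnK0 = (
        -60.2409
        + 93.4517 / T100
        + 23.3585 * math.log(T100)
        + S * (0.023517 - 0.023656 * T100 + 0.0047036 * T100**2)
    )
    K0 = math.exp(lnK0)

    # --- K1, K2: Mehrbach et al. (1973) refit by Dickson & Millero (1987),
    # seawater scale, converted to total.
    pK1 = 3670.7 / T - 62.008 + 9.7944 * lnT - 0.0118 * S + 0.000116 * S**2
    pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S**2
    K1 = 10.0**-pK1 * sws_to_tot
    K2 = 10.0**-pK2 * sws_to_tot

    # --- KB, Dickson (1990b), already total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / T
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    KB = math.exp(lnKB)

    # --- KW, Millero (1995), seawater scale -> total
    lnKW = (
        148.9802
        - 13847.26 / T
        - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
        - 0.01615 * S
    )
    KW = math.exp(lnKW) * sws_to_tot

    # --- phosphate (Yao & Millero 1995 / DOE 1994) and silicate, SWS -> total
    lnKP1 = (
        -4576.752 / T
        + 115.525
        - 18.453 * lnT
        + (-106.736 / T + 0.69171) * sqS
        + (-0.65643 / T - 0.01844) * S
    )
    lnKP2 = (
        -8814.715 / T
        + 172.0883
        - 27.927 * lnT
        + (-160.340 / T + 1.3566) * sqS
        + (0.37335 / T - 0.05778) * S
    )
    lnKP3 = (
        -3070.75 / T
        - 18.141
        + (17.27039 / T + 2.81197) * sqS
        + (-44.99486 / T - 0.09984) * S
    )
    lnKSi = (
        -8904.2 / T
        + 117.385
        - 19.334 * lnT
        + (-458.79 / T + 3.5913) * math.sqrt(ion)
        + (188.74 / T - 1.5998) * ion
        + (-12.1652 / T + 0.07871) * ion**2
    )
    KP1 = math.exp(lnKP1) * sws_to_tot
    KP2 = math.exp(lnKP2) * sws_to_tot
    KP3 = math.exp(lnKP3) * sws_to_tot
    KSi = math.exp(lnKSi) * (1.0 - 0.001005 * S) * sws_to_tot

    # --- calcite solubility, Mucci (1983), mol2 kg-2
    log10Ksp = (
        -171.9065
        - 0.077993 * T
        + 2839.319 / T
        + 71.595 * math.log10(T)
        + (-0.77712 + 0.0028426 * T + 178.34 / T) * sqS
        - 0.07711 * S
        + 0.0041249 * S**1.5
    )
    Ksp_cal = 10.0**log10Ksp

    return ConstantsSet(
        temperature=temperature,
        salinity=salinity,
        K0=K0,
        K1=K1,
        K2=K2,
        KB=KB,
        KW=KW,
        KS=KS,
        KF=KF,
        Ksp_cal=Ksp_cal,
        BT=BT,
        ST=ST,
        FT=FT,
        CaT=CaT,
        PT=phosphate,
        SiT=silicate,
        KP1=KP1,
        KP2=KP2,
        KP3=KP3,
        KSi=KSi,
    )


def speciate(dic: float, ph: float, constants: ConstantsSet):
    """Closed-form carbonate speciation at a known total-scale pH.

    Returns ``(co2aq, hco3, co3)`` in the units of ``dic``; the three pools
    sum to DIC by construction.
    """
    if dic < 0:
        raise DomainError("dic must be non-negative")
    h = 10.0**-ph
    K1, K2 = constants.K1, constants.K2
    denom = h * h + K1 * h + K1 * K2
    co2aq = dic * h * h / denom
    hco3 = dic * K1 * h / denom
    co3 = dic * K1 * K2 / denom
    return co2aq, hco3, co3


def alkalinity_residual(
    ph: float,
    dic: float,
    ta: float,
    constants: ConstantsSet,
    include_nutrients: bool = False,
) -> float:
    """TA computed at (pH, DIC) minus the measured TA, µmol kg-1.

    Monotone decreasing in pH is *not* the convention here: raising pH
    raises the computed alkalinity, so the residual is monotone increasing
    in pH; the solver brackets its unique zero on [2, 12].
    """
    c = constants
    h = 10.0**-ph  # total scale
    _, hco3, co3 = speciate(dic, ph, c)
    h_free = h / c.free_to_total()
    boh4 = c.BT * c.KB / (c.KB + h) * 1e6
    oh = c.KW / h * 1e6
    hso4 = c.ST / (1.0 + c.KS / h_free) * 1e6
    hf = c.FT / (1.0 + c.KF / h_free) * 1e6
    ta_calc = hco3 + 2.0 * co3 + boh4 + oh - h_free * 1e6 - hso4 - hf
    if include_nutrients and (c.PT > 0 or c.SiT > 0):
        KP1, KP2, KP3 = c.KP1, c.KP2, c.KP3
        pden = h**3 + KP1 * h**2 + KP1 * KP2 * h + KP1 * KP2 * KP3
        h3po4 = c.PT * h**3 / pden
        hpo4 = c.PT * KP1 * KP2 * h / pden
        po4 = c.PT * KP1 * KP2 * KP3 / pden
        sioh3 = c.SiT * c.KSi / (c.KSi + h)
        ta_calc += (hpo4 + 2.0 * po4 - h3po4 + sioh3) * 1e6
    return ta_calc - ta


@dataclass(frozen=True)
class CarbonateState:
    """One fully solved water sample (µmol kg-1, total-scale pH, µatm)."""

    dic: float
    ta: float
    ph: float
    pco2: float
    co2aq: float
    hco3: float
    co3: float
    omega_cal: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def omega_calcite(co3: float, constants: ConstantsSet) -> float:
    """Calcite saturation state Omega = [Ca++][CO3--]/Ksp (co3 in µmol kg-1)."""
    if co3 < 0:
        raise DomainError("co3 must be non-negative")
    return constants.CaT * (co3 * 1e-6) / constants.Ksp_cal


def solve_from_dic_ta(
    dic: float,
    ta: float,
    temperature: float,
    salinity: float = 35.0,
    include_nutrients: bool = False,
    phosphate: float = 0.0,
    silicate: float = 0.0,
    tol: float = 1e-8,
) -> CarbonateState:
    """Solve the CO2 system from a (DIC, TA) pair.

    Safeguarded Newton iteration on the alkalinity residual, bracketed on
    total-scale pH in [2, 12], falling back to bisection whenever a Newton
    step leaves the bracket.  Converges to ``tol`` pH units (default 1e-8).
    """
    if dic <= 0:
        raise DomainError("dic must be positive")
    if ta <= 0:
        raise DomainError("ta must be positive")
    c = equilibrium_constants(temperature, salinity, phosphate, silicate)

    def f(ph: float) -> float:
        return alkalinity_residual(ph, dic, ta, c, include_nutrients)

    lo, hi = 2.0, 12.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise DomainError(
            f"unsolvable water sample: no TA root for dic={dic}, ta={ta} in pH [2, 12]"
        )

    ph = 8.0
    for _ in range(200):
        val = f(ph)
        if val > 0:  # computed TA too high -> pH too high (residual increases with pH)
            hi = ph
        else:
            lo = ph
        # numerical derivative; residual is smooth in ph
        dph = 1e-6
        deriv = (f(ph + dph) - val) / dph
        step = -val / deriv if deriv != 0 else 0.0
        new = ph + step
        if not (lo < new < hi) or step == 0.0:
            new = 0.5 * (lo + hi)
        if abs(new - ph) < tol:
            ph = new
            break
        ph = new

    co2aq, hco3, co3 = speciate(dic, ph, c)
    pco2 = (co2aq * 1e-6) / c.K0 * 1e6  # µatm
    return CarbonateState(
        dic=dic,
        ta=ta,
        ph=ph,
        pco2=pco2,
        co2aq=co2aq,
        hco3=hco3,
        co3=co3,
        omega_cal=omega_calcite(co3, c),
    )


def percent_dic_drawdown(culture_dic: float, blank_dic: float) -> float:
    """Percent DIC drawn down by the culture relative to the cell-free blank."""
    if blank_dic <= 0:
        raise DomainError("blank_dic must be positive")
    return 100.0 * (blank_dic - culture_dic) / blank_dic


def _sigfig(x: float, n: int = 4) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{n}g}")


def solve_table(
    bottles: pd.DataFrame,
    salinity_default: float = 35.0,
    include_nutrients: bool = False,
) -> pd.DataFrame:
    """Speciate every row of a bottle table.

    Expects columns ``sample_id, dic_umol_kg, ta_umol_kg, temperature_c``
    and optionally ``salinity``; appends the solved parameters rounded to
    4 significant figures.
    """
    out = bottles.copy()
    results = []
    for _, row in out.iterrows():
        sal = float(row["salinity"]) if "salinity" in out.columns and np.isfinite(
            row.get("salinity", np.nan)
        ) else salinity_default
        phos = float(row.get("phosphate_umol_kg", 0.0) or 0.0) * 1e-6
        sil = float(row.get("silicate_umol_kg", 0.0) or 0.0) * 1e-6
        st = solve_from_dic_ta(
            float(row["dic_umol_kg"]),
            float(row["ta_umol_kg"]),
            float(row["temperature_c"]),
            sal,
            include_nutrients=include_nutrients,
            phosphate=phos,
            silicate=sil,
        )
        results.append(
            {
                "ph_total": _sigfig(st.ph),
                "pco2_uatm": _sigfig(st.pco2),
                "co2aq": _sigfig(st.co2aq),
                "hco3": _sigfig(st.hco3),
                "co3": _sigfig(st.co3),
                "omega_cal": _sigfig(st.omega_cal),
            }
        )
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(results)], axis=1)
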