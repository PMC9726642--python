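"""Depth-resolved prokaryotic carbon demand vs sinking POC supply.

Leucine incorporation rates are converted to prokaryotic heterotrophic
production (PHP) with a leucine-to-carbon conversion factor (CF, kg C per
mol leucine; 1.55 and 0.44 bracket the published range for deep-sea
communities), optionally corrected from atmospheric to in-situ pressure
with the depth power law, and divided by the prokaryotic growth efficiency
(PGE; 8% mesopelagic, 3% bathypelagic) to give the prokaryotic carbon
demand PCD = PHP/PGE. The particulate organic carbon potentially available
at depth z from the sinking flux is POC_a = 0.2·NPP^1.66·z^−1.68
(mmol C m⁻³ d⁻¹, NPP in mg C m⁻² d⁻¹). The PCD:POC_a ratio says whether
the demand is met by the particle flux.

Also includes the standing-biomass and depressurization-carbon-demand
arithmetic used to assess whether cell lysis upon depressurization could
explain the activity increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pressure import PowerLawFit, correct_php

CARBON_MOLAR_MASS = 12.011  # g mol⁻¹
CONVERSION_FACTORS = (1.55, 0.44)  # kg C mol⁻¹ leucine
PGE_MESOPELAGIC = 0.08
PGE_BATHYPELAGIC = 0.03
MESO_BATHY_BOUNDARY_M = 1000.0  # boundary depth itself counts as mesopelagic


@dataclass(frozen=True)
class CarbonBudgetRow:
    """One depth × conversion-factor scenario of the budget."""

    depth_m: float
    php_atm: float  # µmol C m⁻³ d⁻¹
    php_insitu: float  # µmol C m⁻³ d⁻¹
    conversion_factor: float  # kg C mol⁻¹ leucine
    pge: float
    pcd: float  # µmol C m⁻³ d⁻¹
    npp: float  # mg C m⁻² d⁻¹
    poc_a: float  # mmol C m⁻³ d⁻¹
    ratio: float  # PCD : POC_a, dimensionless


def php_from_rate(rate: float, cf: float = 1.55) -> float:
    """Leucine rate (pmol l⁻¹ h⁻¹) → PHP (µmol C m⁻³ d⁻¹).

    pmol l⁻¹ h⁻¹ equals nmol m⁻³ h⁻¹; ×24 gives nmol m⁻³ d⁻¹; the CF in
    kg C per mol leucine corresponds to CF×1000/12.011 mol C per mol
    leucine; /1000 converts nmol → µmol.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if cf <= 0:
        raise ValueError("conversion factor must be > 0")
    return rate * 24.0 * (cf * 1000.0 / CARBON_MOLAR_MASS) / 1000.0


def pcd(php: float, pge: float) -> float:
    """Prokaryotic carbon demand PCD = PHP/PGE (µmol C m⁻³ d⁻¹)."""
    if not 0.0 < pge <= 1.0:
        raise ValueError("PGE must be in (0, 1]")
    if php < 0:
        raise ValueError("PHP must be >= 0")
    return php / pge


def pge_for_depth(z: float) -> float:
    """Depth-stratum growth efficiency: 8% meso (≤1000 m), 3% bathypelagic."""
    return PGE_MESOPELAGIC if z <= MESO_BATHY_BOUNDARY_M else PGE_BATHYPELAGIC


def poc_available(npp: float, z: float) -> float:
    """POC potentially available at depth z: 0.2 · NPP^1.66 · z^−1.68.

    NPP in mg C m⁻² d⁻¹ (satellite VGPM native units); result in
    mmol C m⁻³ d⁻¹, the printed constants applied verbatim.
    """
    if npp < 0:
        raise ValueError("NPP must be >= 0")
    if z <= 0:
        raise ValueError("depth must be > 0")
    return 0.2 * npp**1.66 * z**-1.68


def pcd_poc_ratio(pcd_umol: float, poc_a_mmol: float) -> float:
    """PCD:POC_a ratio; PCD µmol → mmol by /1000."""
    if poc_a_mmol <= 0:
        raise ValueError("POC_a must be > 0 to form a ratio")
    return (pcd_umol / 1000.0) / poc_a_mmol


def biomass_from_abundance(cells_per_ml: float, content_fg: float = 10.0) -> float:
    """Standing prokaryotic biomass (µg C l⁻¹) from cell abundance.

    cells ml⁻¹ ×1000 → cells l⁻¹; × carbon content (fg C cell⁻¹) ×1e−9 →
    µg C l⁻¹.
    """
    if cells_per_ml < 0 or content_fg < 0:
        raise ValueError("inputs must be >= 0")
    return cells_per_ml * 1000.0 * content_fg * 1e-9


def depressurization_demand(
    delta_rate: float,
    cf: float = 1.55,
    growth_yield: float = 0.5,
    duration_h: float = 24.0,
) -> float:
    """Extra organic carbon demand (ng C l⁻¹) implied by a rate increase.

    ``delta_rate`` is the atmospheric-minus-in-situ bulk leucine rate
    (pmol l⁻¹ h⁻¹), integrated over ``duration_h`` hours, converted to
    carbon with CF (kg C mol⁻¹ → g C mol⁻¹ ×1000; pmol → mol ×1e−12;
    g → ng ×1e9) and divided by the growth yield.
    """
    if delta_rate < 0:
        raise ValueError("delta_rate must be >= 0")
    if not 0.0 < growth_yield <= 1.0:
        raise ValueError("growth yield must be in (0, 1]")
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    return delta_rate * duration_h * (cf * 1000.0) * 1e-12 * 1e9 / growth_yield


def budget_table(
    inputs: pd.DataFrame,
    fit: PowerLawFit,
    cfs: tuple[float, ...] = CONVERSION_FACTORS,
    correct_to_insitu: bool = True,
    cap_at_100: bool = True,
) -> pd.DataFrame:
    """Compute the full budget, one row per depth per CF scenario.

    ``inputs`` needs columns ``depth_m``, ``php_atm_pmol_l_h`` (an
    atmospheric-pressure leucine rate) and ``npp_mg_c_m2_d``. When
    ``correct_to_insitu`` the PCD uses the pressure-corrected PHP.
    """
    rows: list[CarbonBudgetRow] = []
    for _, rec in inputs.iterrows():
        z = float(rec["depth_m"])
        rate = float(rec["php_atm_pmol_l_h"])
        npp = float(rec["npp_mg_c_m2_d"])
        for cf in cfs:
            php_atm = php_from_rate(rate, cf)
            php_is = correct_php(php_atm, z, fit, cap_at_100=cap_at_100)
            php_used = php_is if correct_to_insitu else php_atm
            pge = pge_for_depth(z)
            demand = pcd(php_used, pge)
            poc = poc_available(npp, z)
            rows.append(
                CarbonBudgetRow(
                    depth_m=z,
                    php_atm=php_atm,
                    php_insitu=php_is,
                    conversion_factor=cf,
                    pge=pge,
                    pcd=demand,
                    npp=npp,
                    poc_a=poc,
                    ratio=pcd_poc_ratio(demand, poc) if poc > 0 else float("nan"),
                )
            )
    return pd.DataFrame(
        {
            "depth_m": [r.depth_m for r in rows],
            "cf_kg_c_per_mol": [r.conversion_factor for r in rows],
            "php_atm_umol_m3_d": [r.php_atm for r in rows],
            "php_insitu_umol_m3_d": [r.php_insitu for r in rows],
            "pge": [r.pge for r in rows],
            "pcd_umol_m3_d": [r.pcd for r in rows],
            "npp_mg_c_m2_d": [r.npp for r in rows],
            "poc_a_mmol_m3_d": [r.poc_a for r in rows],
            "pcd_poc_ratio": [r.ratio for r in rows],
        }
    )
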