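"""Deterministic chronic-daily-intake and carcinogenic-risk engine.

The exposure model follows the standard US-EPA drinking-water equations
for two routes.  With Cw the BaPeq concentration in water (mg/L):

    CDI_ingestion = Cw * IR * EF * ED / (BW * AT)
    CDI_dermal    = Cw * SA * Kp * ET * EF * ED * CF / (BW * AT)
    CR            = CDI * SF

where IR is the water ingestion rate (L/day), EF the exposure frequency
(days/year), ED the exposure duration (years), BW body weight (kg), AT
the lifetime averaging time (days), SA the exposed skin area (cm^2), Kp
the dermal permeability coefficient (cm/h), ET the daily contact time
(h/day) and CF the volume conversion 1 L / 1000 cm^3.  The oral slope
factor SF (7.3 (mg/kg/day)^-1 for BaP) is divided by the 92%
gastrointestinal absorption fraction for the dermal (absorbed-dose)
route, giving 7.9 (mg/kg/day)^-1 after rounding.

Concentrations cross the public interface in ng/L (the unit of the
monitoring tables) and are converted to mg/L internally, exactly once.
All formulas accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

#: ng/L -> mg/L
NG_PER_L_TO_MG_PER_L = 1e-6

#: Lifetime averaging time: 70 years x 365 days/year.
LIFETIME_AT_DAYS = 70 * 365

#: De-minimis and upper-bound lifetime cancer-risk management thresholds.
DE_MINIMIS_RISK = 1e-6
RISK_LIMIT = 1e-4


class RiskCategory(str, Enum):
    BELOW_DE_MINIMIS = "below_de_minimis"
    ACCEPTABLE = "acceptable"
    ABOVE_LIMIT = "above_limit"


@dataclass(frozen=True)
class ExposureParameterSet:
    """All symbols of the exposure model, at their point defaults.

    Defaults are the deterministic lifetime-exposure values for an
    eastern-Chinese rural adult population (62.1 kg body weight, 2.39
    L/day ingestion, 16000 cm^2 skin area, 0.15 h/day contact) with the
    US-EPA BaP toxicity values (Kp 1.2 cm/h, oral SF 7.3).
    """

    cw_ng_l: float = 0.0       # BaPeq concentration in water, ng/L
    ir: float = 2.39           # ingestion rate, L/day
    ef: float = 350.0          # exposure frequency, days/year
    ed: float = 70.0           # exposure duration, years
    bw: float = 62.1           # body weight, kg
    at: float = LIFETIME_AT_DAYS  # averaging time, days
    sa: float = 16000.0        # exposed dermal surface area, cm^2
    kp: float = 1.2            # dermal permeability coefficient, cm/h
    et: float = 0.15           # exposure time, h/day
    cf: float = 0.001          # volume conversion, L/cm^3 (fixed)
    sf_oral: float = 7.3       # oral slope factor, (mg/kg/day)^-1
    aaf: float = 0.92          # gastrointestinal absorption fraction

    def __post_init__(self):
        if self.cw_ng_l < 0:
            raise ValueError("Cw must be non-negative")
        for name in ("ir", "ef", "ed", "bw", "at", "sa", "kp", "et", "sf_oral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.ef > 365:
            raise ValueError("exposure frequency cannot exceed 365 days/year")
        if not (0 < self.aaf <= 1):
            raise ValueError("AAF must lie in (0, 1]")
        if self.cf != 0.001:
            raise ValueError("CF is the fixed conversion 1 L/1000 cm^3 = 0.001")

    def with_cw(self, cw_ng_l: float) -> "ExposureParameterSet":
        return replace(self, cw_ng_l=cw_ng_l)


@dataclass(frozen=True)
class RiskResult:
    """Route-wise chronic daily intakes and lifetime cancer risks."""

    cdi_ingestion: float    # mg/kg/day
    cdi_dermal: float       # mg/kg/day
    cr_ingestion: float
    cr_dermal: float
    cr_total: float
    category: RiskCategory


def cdi_ingestion(p: ExposureParameterSet):
    """Chronic daily BaPeq intake via ingestion (mg/kg/day)."""
    cw_mg_l = p.cw_ng_l * NG_PER_L_TO_MG_PER_L
    return cw_mg_l * p.ir * p.ef * p.ed / (p.bw * p.at)


def cdi_dermal(p: ExposureParameterSet):
    """Chronic daily BaPeq intake via dermal absorption (mg/kg/day)."""
    cw_mg_l = p.cw_ng_l * NG_PER_L_TO_MG_PER_L
    return cw_mg_l * p.sa * p.kp * p.et * p.ef * p.ed * p.cf / (p.bw * p.at)


def dermal_sf(sf_oral: float, aaf: float) -> float:
    """Absorbed-dose slope factor for the dermal route: SF_oral / AAF.

    Returned unrounded; use :func:`present_sf` for the conventional
    1-decimal presentation (7.3 / 0.92 -> 7.9).
    """
    if sf_oral <= 0:
        raise ValueError("oral slope factor must be positive")
    if not (0 < aaf <= 1):
        raise ValueError("AAF must lie in (0, 1]")
    return sf_oral / aaf


def present_sf(sf: float) -> float:
    """Round a slope factor to 1 decimal for presentation."""
    return round(sf, 1)


def carcinogenic_risk(cdi, sf):
    """Lifetime cancer probability CR = CDI * SF (no capping; risks << 1)."""
    if np.any(np.asarray(cdi) < 0):
        raise ValueError("CDI must be non-negative")
    if np.any(np.asarray(sf) <= 0):
        raise ValueError("slope factor must be positive")
    return cdi * sf


def classify_risk(cr_total: float) -> RiskCategory:
    """Risk-management category against the 1e-6 / 1e-4 range.

    Both comparisons are strict: a risk exactly at 1e-6 is still below
    de minimis, exactly at 1e-4 still acceptable.
    """
    if cr_total < 0:
        raise ValueError("risk must be non-negative")
    if cr_total > RISK_LIMIT:
        return RiskCategory.ABOVE_LIMIT
    if cr_total > DE_MINIMIS_RISK:
        return RiskCategory.ACCEPTABLE
    return RiskCategory.BELOW_DE_MINIMIS


def total_risk(p: ExposureParameterSet, use_rounded_dermal_sf: bool = False) -> RiskResult:
    """Full route-wise risk characterization for one parameter set.

    The ingestion route uses the oral slope factor; the dermal route uses
    the AAF-adjusted factor, unrounded by default (set
    ``use_rounded_dermal_sf`` to reproduce published tables that carry
    the 1-decimal value through).
    """
    ci = cdi_ingestion(p)
    cd = cdi_dermal(p)
    sf_d = dermal_sf(p.sf_oral, p.aaf)
    if use_rounded_dermal_sf:
        sf_d = present_sf(sf_d)
    cr_i = carcinogenic_risk(ci, p.sf_oral)
    cr_d = carcinogenic_risk(cd, sf_d)
    cr_t = cr_i + cr_d
    return RiskResult(
        cdi_ingestion=ci,
        cdi_dermal=cd,
        cr_ingestion=cr_i,
        cr_dermal=cr_d,
        cr_total=cr_t,
        category=classify_risk(float(cr_t)),
    )


def total_risk_array(
    cw_ng_l, ir, ed, bw, et, sa, *, ef=350.0, at=LIFETIME_AT_DAYS,
    kp=1.2, cf=0.001, sf_oral=7.3, aaf=0.92,
):
    """Vectorized CR_total over arrays of the uncertain parameters.

    Used by the Monte Carlo engine; algebraically identical to
    :func:`total_risk` applied row by row.
    """
    cw = np.asarray(cw_ng_l, dtype=float) * NG_PER_L_TO_MG_PER_L
    denom = np.asarray(bw, dtype=float) * at
    cdi_i = cw * ir * ef * ed / denom
    cdi_d = cw * sa * kp * et * ef * ed * cf / denom
    return cdi_i * sf_oral + cdi_d * dermal_sf(sf_oral, aaf)
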