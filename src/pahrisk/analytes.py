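"""Analyte vocabulary, potency equivalency factors and drinking-water standards.

The package works with the 16 US-EPA priority polycyclic aromatic
hydrocarbons (PAHs), identified everywhere by their conventional
abbreviations.  Seven of them are treated as carcinogenic and carry a
potency equivalency factor (PEF) expressing their carcinogenic potency
relative to benzo[a]pyrene (BaP = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional

#: The 16 priority PAHs, in conventional (roughly boiling-point) order.
ANALYTES: tuple = (
    "Nap", "Acy", "Ace", "Fl", "Phe", "Ant", "Flu", "Pyr",
    "BaA", "Chy", "BaP", "BbF", "BkF", "DahA", "IcdP", "BghiP",
)

#: The seven PAHs classified as carcinogenic (US EPA, 1993).
CARCINOGENIC_ANALYTES: FrozenSet[str] = frozenset(
    {"BaA", "Chy", "BaP", "BbF", "BkF", "DahA", "IcdP"}
)

#: Default BaP-relative potency equivalency factors (US EPA 1993 /
#: Nisbet & LaGoy scheme).  Overridable via :class:`PEFTable`.
DEFAULT_PEFS: Dict[str, float] = {
    "BaA": 0.1,
    "Chy": 0.001,
    "BaP": 1.0,
    "BbF": 0.1,
    "BkF": 0.01,
    "DahA": 1.0,
    "IcdP": 0.1,
}


@dataclass(frozen=True)
class PEFTable:
    """Potency equivalency factors defining the carcinogenic subset.

    Invariants: PEF(BaP) = 1 exactly and every factor lies in (0, 1].
    """

    pef: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PEFS))

    def __post_init__(self):
        for analyte, factor in self.pef.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte in PEF table: {analyte!r}")
            if not (0.0 < factor <= 1.0):
                raise ValueError(
                    f"PEF for {analyte} must be in (0, 1], got {factor}"
                )
        if self.pef.get("BaP") != 1.0:
            raise ValueError("PEF table must assign BaP a factor of exactly 1")

    @property
    def carcinogenic_set(self) -> FrozenSet[str]:
        return frozenset(self.pef)


@dataclass(frozen=True)
class Standard:
    """A drinking-water standard: per-analyte, total-PAH and BaPeq limits (ng/L)."""

    name: str
    analyte_limits: Dict[str, float] = field(default_factory=dict)
    total_limit: Optional[float] = None
    bapeq_limit: Optional[float] = None

    def __post_init__(self):
        for analyte, limit in self.analyte_limits.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte in standard: {analyte!r}")
            if limit <= 0:
                raise ValueError(f"limit for {analyte} must be positive")
        for label, limit in (("total", self.total_limit), ("bapeq", self.bapeq_limit)):
            if limit is not None and limit <= 0:
                raise ValueError(f"{label} limit must be positive")
        if not self.analyte_limits and self.total_limit is None and self.bapeq_limit is None:
            raise ValueError(f"standard {self.name!r} defines no limit")


# Chinese drinking-water safety standard: BaP below 10 ng/L, total PAHs
# below 2000 ng/L.  The BaPeq limit mirrors the BaP limit, which is how
# BaPeq exceedance rates are conventionally screened.
CHINA_STANDARD = Standard(
    name="china",
    analyte_limits={"BaP": 10.0},
    total_limit=2000.0,
    bapeq_limit=10.0,
)

#: US allowable BaP concentration in drinking water.
US_STANDARD = Standard(name="us", analyte_limits={"BaP": 200.0})

#: Egyptian allowable BaP concentration in drinking water.
EGYPT_STANDARD = Standard(name="egypt", analyte_limits={"BaP": 700.0})

STANDARDS: Dict[str, Standard] = {
    s.name: s for s in (CHINA_STANDARD, US_STANDARD, EGYPT_STANDARD)
}
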