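"""Core records: monitored water samples and village cancer registries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List

import pandas as pd

from .analytes import ANALYTES

WATER_TYPES = ("SW", "SG", "DG")   # surface, shallow ground, deep ground water
SEASONS = ("winter", "summer")
GROUPS = ("risk", "control")


@dataclass
class WaterSample:
    """One monitored water sample.

    ``conc`` holds concentrations (ng/L) for detected analytes only;
    ``nondetect`` flags analytes reported below the detection limit.  An
    analyte absent from both mappings was not measured at all.
    """

    village_id: str
    group: str
    water_type: str
    season: str
    conc: Dict[str, float] = field(default_factory=dict)
    nondetect: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.water_type not in WATER_TYPES:
            raise ValueError(
                f"water_type must be one of {WATER_TYPES}, got {self.water_type!r}"
            )
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        for analyte, value in self.conc.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")
            if value <= 0:
                raise ValueError(
                    f"concentration for {analyte} must be positive, got {value}"
                )
            if self.nondetect.get(analyte):
                raise ValueError(
                    f"{analyte} carries both a concentration and a non-detect flag"
                )
        for analyte in self.nondetect:
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")

    def measured(self, analyte: str) -> bool:
        """True if the analyte was measured (detected or flagged non-detect)."""
        return analyte in self.conc or analyte in self.nondetect


@dataclass
class VillageRecord:
    """A village with its cancer registry summary (rates per 100,000/yr)."""

    village_id: str
    group: str
    population: int
    incidence: float
    mortality: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.population < 1:
            raise ValueError("population must be at least 1")
        if self.incidence < 0 or self.mortality < 0:
            raise ValueError("incidence and mortality rates must be non-negative")


def samples_to_frame(samples: Iterable[WaterSample]) -> pd.DataFrame:
    """Flatten samples into the pipeline's tabular CSV schema.

    One ``<analyte>_ng_l`` and one ``<analyte>_nd`` column per analyte;
    unmeasured analytes get an empty concentration and nd=False.
    """
    rows = []
    for s in samples:
        row: Dict[str, object] = {
            "village_id": s.village_id,
            "group": s.group,
            "water_type": s.water_type,
            "season": s.season,
        }
        for a in ANALYTES:
            row[f"{a}_ng_l"] = s.conc.get(a)
            row[f"{a}_nd"] = bool(s.nondetect.get(a, False))
        rows.append(row)
    columns = ["village_id", "group", "water_type", "season"]
    for a in ANALYTES:
        columns += [f"{a}_ng_l", f"{a}_nd"]
    return pd.DataFrame(rows, columns=columns)


def frame_to_samples(frame: pd.DataFrame) -> List[WaterSample]:
    """Inverse of :func:`samples_to_frame` (validation included)."""
    samples = []
    for _, row in frame.iterrows():
        conc, nd = {}, {}
        for a in ANALYTES:
            value = row.get(f"{a}_ng_l")
            flagged = bool(row.get(f"{a}_nd", False))
            if flagged:
                nd[a] = True
            elif value is not None and pd.notna(value):
                conc[a] = float(value)
        samples.append(
            WaterSample(
                village_id=str(row["village_id"]),
                group=str(row["group"]),
                water_type=str(row["water_type"]),
                season=str(row["season"]),
                conc=conc,
                nondetect=nd,
            )
        )
    return samples


def villages_to_frame(villages: Iterable[VillageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "village_id": v.village_id,
                "group": v.group,
                "population": v.population,
                "incidence_per_100k": v.incidence,
                "mortality_per_100k": v.mortality,
            }
            for v in villages
        ]
    )


def frame_to_villages(frame: pd.DataFrame) -> List[VillageRecord]:
    return [
        VillageRecord(
            village_id=str(row["village_id"]),
            group=str(row["group"]),
            population=int(row["population"]),
            incidence=float(row["incidence_per_100k"]),
            mortality=float(row["mortality_per_100k"]),
        )
        for _, row in frame.iterrows()
    ]
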