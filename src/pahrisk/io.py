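"""CSV interfaces and YAML configuration for the pipeline.

Concentration files carry ng/L at every interface; the exposure
equations convert to mg/L internally.  Sample CSVs have the schema
``village_id, group, water_type, season`` followed by one
``<analyte>_ng_l`` and one ``<analyte>_nd`` column per analyte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .analytes import ANALYTES, DEFAULT_PEFS, PEFTable, Standard
from .samples import (VillageRecord, WaterSample, frame_to_samples,
                      frame_to_villages, samples_to_frame, villages_to_frame)

logger = logging.getLogger("pahrisk")

_META_COLUMNS = ["village_id", "group", "water_type", "season"]


def read_samples(path) -> List[WaterSample]:
    """Read and validate a water-sample CSV.

    Errors carry 1-based data row numbers.  Unknown analyte columns are
    rejected; a value co-occurring with nd=true is rejected.
    """
    frame = pd.read_csv(path)
    for col in _META_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    for col in frame.columns:
        if col in _META_COLUMNS:
            continue
        base, _, suffix = col.rpartition("_")
        if suffix == "l":   # `<analyte>_ng_l`
            base = col[: -len("_ng_l")]
        if base not in ANALYTES:
            raise ValueError(f"unknown analyte column {col!r} in {path}")
    if frame.empty:
        logger.warning("sample file %s has a header but no rows", path)
        return []
    samples = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        for a in ANALYTES:
            value, flag = row.get(f"{a}_ng_l"), row.get(f"{a}_nd")
            if bool(flag) and value is not None and pd.notna(value):
                raise ValueError(
                    f"{path} row {i}: {a} has both a concentration and nd=true")
        try:
            samples.extend(frame_to_samples(row.to_frame().T))
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from exc
    return samples


def write_samples(samples: List[WaterSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def read_villages(path) -> List[VillageRecord]:
    frame = pd.read_csv(path)
    if frame.empty:
        logger.warning("village file %s has a header but no rows", path)
        return []
    return frame_to_villages(frame)


def write_villages(villages: List[VillageRecord], path) -> None:
    villages_to_frame(villages).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Blocks mirror the stages: ``synthetic`` (campaign design),
    ``exposure`` (point parameter values, units in key names), ``mc``
    (draw count and per-parameter distributions), ``standards`` (named
    limit sets, ng/L), ``stats`` (non-detect policy) and ``io``.
    """

    seed: int = 0
    synthetic: Dict = field(default_factory=dict)
    exposure: Dict = field(default_factory=lambda: {
        "ir_l_per_day": 2.39, "ef_days_per_year": 350.0, "ed_years": 70.0,
        "bw_kg": 62.1, "at_days": 25550.0, "sa_cm2": 16000.0,
        "kp_cm_per_h": 1.2, "et_h_per_day": 0.15, "sf_oral_per_mg_kg_day": 7.3,
        "gi_absorption_fraction": 0.92,
    })
    mc: Dict = field(default_factory=lambda: {
        "n": 10_000,
        "lognormal_cv": {"BW": 0.2, "ET": 0.2, "IR": 0.2, "SA": 0.2},
        "ed_uniform_years": [0.0, 70.0],
    })
    standards: Dict = field(default_factory=lambda: {
        "china": {"bap_ng_l": 10.0, "total_ng_l": 2000.0, "bapeq_ng_l": 10.0},
        "us": {"bap_ng_l": 200.0},
        "egypt": {"bap_ng_l": 700.0},
    })
    stats: Dict = field(default_factory=lambda: {"nd_policy": "half_dl"})
    pefs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PEFS))
    out_dir: str = "pahrisk_out"

    def __post_init__(self):
        # partial dict blocks are merged over the defaults, so e.g.
        # mc={"n": 500} keeps the default distribution settings
        for name in ("exposure", "mc", "standards", "stats"):
            defaults = self.__dataclass_fields__[name].default_factory()
            merged = {**defaults, **getattr(self, name)}
            setattr(self, name, merged)
        for key, value in self.exposure.items():
            if not isinstance(value, (int, float)) or value <= 0:
                raise ValueError(f"exposure parameter {key} must be positive")
        if int(self.mc.get("n", 0)) < 1:
            raise ValueError("mc.n must be a positive draw count")
        for name, block in self.standards.items():
            if not block:
                raise ValueError(f"standard {name!r} defines no limit")

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = cls()
        for key, value in data.items():
            if isinstance(value, dict) and isinstance(getattr(merged, key), dict):
                base = dict(getattr(merged, key))
                base.update(value)
                setattr(merged, key, base)
            else:
                setattr(merged, key, value)
        merged.__post_init__()
        return merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> Dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable digest of the full configuration, for provenance."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def pef_table(self) -> PEFTable:
        return PEFTable(pef=dict(self.pefs))

    def standard_objects(self) -> Dict[str, Standard]:
        out = {}
        for name, block in self.standards.items():
            analyte_limits = {}
            if "bap_ng_l" in block:
                analyte_limits["BaP"] = float(block["bap_ng_l"])
            out[name] = Standard(
                name=name,
                analyte_limits=analyte_limits,
                total_limit=float(block["total_ng_l"]) if "total_ng_l" in block else None,
                bapeq_limit=float(block["bapeq_ng_l"]) if "bapeq_ng_l" in block else None,
            )
        return out


def write_manifest(config: PipelineConfig, path, extra: Optional[Dict] = None) -> None:
    """JSON manifest of a run: package version, seed and config hash."""
    from . import __version__
    manifest = {
        "package": "pahrisk",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
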