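"""End-to-end orchestration: synthetic campaign (optional) -> BaPeq ->
screening -> deterministic risk -> Monte Carlo -> campaign statistics.

Every run is a pure function of (input files, configuration): all
randomness flows from ``config.seed``, and every output directory gets a
JSON manifest carrying the package version, the seed and a hash of the
full configuration.
"""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import groupstats, montecarlo, screening, synthetic
from .exposure import ExposureParameterSet, total_risk
from .io import PipelineConfig, write_manifest, write_samples, write_villages
from .samples import VillageRecord, WaterSample

logger = logging.getLogger("pahrisk")


def exposure_from_config(config: PipelineConfig, cw_ng_l: float = 0.0) -> ExposureParameterSet:
    e = config.exposure
    return ExposureParameterSet(
        cw_ng_l=cw_ng_l,
        ir=e["ir_l_per_day"], ef=e["ef_days_per_year"], ed=e["ed_years"],
        bw=e["bw_kg"], at=e["at_days"], sa=e["sa_cm2"], kp=e["kp_cm_per_h"],
        et=e["et_h_per_day"], sf_oral=e["sf_oral_per_mg_kg_day"],
        aaf=e["gi_absorption_fraction"],
    )


def mc_specs_from_config(
    config: PipelineConfig, cw_spec: montecarlo.DistributionSpec,
) -> List[montecarlo.DistributionSpec]:
    """Distribution specs: fitted Cw, uniform ED, lognormal anthropometrics."""
    e = config.exposure
    means = {"BW": e["bw_kg"], "ET": e["et_h_per_day"],
             "IR": e["ir_l_per_day"], "SA": e["sa_cm2"]}
    specs = [cw_spec]
    low, high = config.mc.get("ed_uniform_years", [0.0, 70.0])
    specs.append(montecarlo.DistributionSpec("ED", "uniform",
                                             {"low": float(low), "high": float(high)}))
    for name, cv in config.mc.get("lognormal_cv", {}).items():
        specs.append(montecarlo.DistributionSpec(
            name, "lognormal", {"mean": means[name], "cv": float(cv)}))
    return specs


def _risk_summary(risks: np.ndarray) -> Dict[str, float]:
    n = risks.size
    return {
        "n": int(n),
        "mean": float(risks.mean()),
        "se": float(risks.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        "p5": float(np.quantile(risks, 0.05)),
        "p50": float(np.quantile(risks, 0.50)),
        "p95": float(np.quantile(risks, 0.95)),
    }


def run_pipeline(
    config: PipelineConfig,
    samples: Optional[List[WaterSample]] = None,
    villages: Optional[List[VillageRecord]] = None,
) -> Dict[str, object]:
    """Run every stage and write the report bundle under ``config.out_dir``.

    With ``samples``/``villages`` supplied the synthetic stage is
    skipped and downstream behavior is identical.  Returns a dict of
    in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pefs = config.pef_table()
    standards = config.standard_objects()
    nd_policy = config.stats.get("nd_policy", "half_dl")
    results: Dict[str, object] = {}
    completed: List[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                value = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            results[name] = value
            completed.append(name)
            return value
        return wrap

    # -- synthetic -----------------------------------------------------
    design = synthetic.CampaignDesign(
        seed=config.seed, **{k: v for k, v in config.synthetic.items() if k != "seed"})
    detection_limits = dict(design.detection_limits)
    if samples is None:
        def _synthetic():
            v, s = synthetic.generate_campaign(design)
            write_villages(v, out / "villages.csv")
            write_samples(s, out / "samples.csv")
            return v, s
        villages, samples = stage("synthetic")(_synthetic)
    else:
        write_samples(samples, out / "samples.csv")
        if villages is not None:
            write_villages(villages, out / "villages.csv")

    # -- bapeq ---------------------------------------------------------
    def _bapeq():
        rows = []
        for s in samples:
            rows.append({
                "village_id": s.village_id, "group": s.group,
                "water_type": s.water_type, "season": s.season,
                "bapeq_ng_l": screening.bapeq_concentration(
                    s, pefs, "zero", detection_limits),
                "total_pahs_ng_l": screening.total_pahs(s, "zero", detection_limits),
                "carcinogenic_sum_ng_l": screening.carcinogenic_sum(
                    s, pefs, "zero", detection_limits),
            })
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "bapeq.csv", index=False)
        return frame
    bapeq_frame = stage("bapeq")(_bapeq)

    # -- screening -----------------------------------------------------
    def _screening():
        china = standards["china"]
        flag_rows = []
        for s in samples:
            flags = screening.screen_sample(s, china, pefs, "zero", detection_limits)
            flag_rows.append({"village_id": s.village_id, "water_type": s.water_type,
                              "season": s.season, **flags})
        pd.DataFrame(flag_rows).to_csv(out / "screening_flags.csv", index=False)
        rates = {name: groupstats.exceedance_rates(
                     samples, std, pefs, "zero", detection_limits)
                 for name, std in standards.items()}
        (out / "exceedance.json").write_text(json.dumps(rates, indent=2))
        return rates
    stage("screening")(_screening)

    # -- deterministic risk --------------------------------------------
    def _deterministic():
        rows = []
        for s, bapeq in zip(samples, bapeq_frame["bapeq_ng_l"]):
            rr = total_risk(exposure_from_config(config, cw_ng_l=float(bapeq)))
            rows.append({
                "village_id": s.village_id, "group": s.group,
                "water_type": s.water_type, "season": s.season,
                "bapeq_ng_l": bapeq, "cdi_ingestion": rr.cdi_ingestion,
                "cdi_dermal": rr.cdi_dermal, "cr_ingestion": rr.cr_ingestion,
                "cr_dermal": rr.cr_dermal, "cr_total": rr.cr_total,
                "category": rr.category.value,
            })
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "risk.csv", index=False)
        summary = {"total": _risk_summary(frame["cr_total"].to_numpy())}
        for group, sub in frame.groupby("group"):
            summary[f"group_{group}"] = _risk_summary(sub["cr_total"].to_numpy())
        for wt, sub in frame.groupby("water_type"):
            summary[f"water_{wt}"] = _risk_summary(sub["cr_total"].to_numpy())
        return {"frame": frame, "summary": summary}
    deterministic = stage("deterministic")(_deterministic)

    # -- monte carlo ---------------------------------------------------
    def _mc():
        n = int(config.mc.get("n", 10_000))
        det_frame = deterministic["frame"]
        fixed = exposure_from_config(config)
        strata = {"total": np.ones(len(det_frame), dtype=bool)}
        for group in det_frame["group"].unique():
            strata[f"group_{group}"] = (det_frame["group"] == group).to_numpy()
        for wt in det_frame["water_type"].unique():
            strata[f"water_{wt}"] = (det_frame["water_type"] == wt).to_numpy()
        mc_summary, sens = {}, {}
        for i, (name, mask) in enumerate(strata.items()):
            detected = det_frame.loc[mask, "bapeq_ng_l"]
            detected = detected[detected > 0]
            cw_spec = montecarlo.fit_cw_distribution(detected.to_numpy())
            specs = mc_specs_from_config(config, cw_spec)
            result = montecarlo.simulate_risk(specs, fixed, n=n,
                                              seed=config.seed + 1000 + i)
            mc_summary[name] = {"n": n, **result.summary_row()}
            if name == "total":
                sens = result.sensitivity
        payload = {"summary": mc_summary, "sensitivity": sens}
        (out / "mc_summary.json").write_text(json.dumps(payload, indent=2))
        return payload
    mc = stage("mc")(_mc)

    # -- combined deterministic/probabilistic table --------------------
    def _table():
        rows = []
        for approach, summary in (("deterministic", deterministic["summary"]),
                                  ("probabilistic", mc["summary"])):
            for name, stats_row in summary.items():
                rows.append({"approach": approach, "stratum": name, **stats_row})
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "risk_summary.csv", index=False)
        return frame
    stage("risk_table")(_table)

    # -- campaign statistics -------------------------------------------
    def _stats():
        season_table = groupstats.comparison_table(
            samples, "season", "water_type", pefs, nd_policy, detection_limits)
        season_table.to_csv(out / "comparison_season.csv", index=False)
        group_table = groupstats.comparison_table(
            samples, "group", "water_type", pefs, nd_policy, detection_limits)
        group_table.to_csv(out / "comparison_group.csv", index=False)
        payload: Dict[str, object] = {}
        if villages:
            payload["incidence_mortality"] = groupstats.incidence_mortality_correlation(
                villages)
            by_group = {g: [v.incidence for v in villages if v.group == g]
                        for g in ("risk", "control")}
            payload["incidence_comparison"] = groupstats.compare(
                by_group, "wilcoxon", factor="group").__dict__
        (out / "stats_summary.json").write_text(json.dumps(payload, indent=2, default=str))
        return {"season_table": season_table, "group_table": group_table, **payload}
    stage("stats")(_stats)

    write_manifest(config, out / "manifest.json", extra={"stages": completed})
    results["out_dir"] = str(out)
    return results
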