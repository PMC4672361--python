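"""Monte Carlo uncertainty propagation and rank-correlation sensitivity.

Uncertain exposure parameters are described by named distribution specs
(point, lognormal parameterized by natural-scale mean and CV, or
uniform).  The engine draws all parameters independently, pushes every
draw through the deterministic risk model and summarizes the resulting
lifetime-risk distribution (mean, SE of the mean, 5th/50th/95th
percentiles) together with Spearman rank correlations between each
varied input and the output risk — the conventional sensitivity measure
of spreadsheet risk tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ExposureParameterSet, total_risk_array

#: Parameters that may be drawn stochastically, with the attribute they
#: map to on :class:`ExposureParameterSet`.
UNCERTAIN_PARAMETERS = {"Cw": "cw_ng_l", "IR": "ir", "ED": "ed",
                        "BW": "bw", "ET": "et", "SA": "sa"}

FAMILIES = ("point", "lognormal", "uniform")


@dataclass(frozen=True)
class DistributionSpec:
    """A named parameter with its sampling distribution.

    families:
      * ``point``: params ``{"value": v}``
      * ``lognormal``: params ``{"mean": m, "cv": c}`` on the natural scale
      * ``uniform``: params ``{"low": a, "high": b}``
    """

    name: str
    family: str
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in UNCERTAIN_PARAMETERS:
            raise ValueError(
                f"unknown parameter {self.name!r}; expected one of "
                f"{sorted(UNCERTAIN_PARAMETERS)}"
            )
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "point" and "value" not in p:
            raise ValueError("point spec needs a 'value'")
        if self.family == "lognormal":
            if p.get("mean", 0) <= 0 or p.get("cv", 0) <= 0:
                raise ValueError("lognormal spec needs mean > 0 and cv > 0")
        if self.family == "uniform":
            if not ("low" in p and "high" in p and p["low"] < p["high"]):
                raise ValueError("uniform spec needs low < high")

    @property
    def is_stochastic(self) -> bool:
        return self.family != "point"

    def log_params(self) -> Tuple[float, float]:
        """(mu, sigma) of the underlying normal for a lognormal spec."""
        if self.family != "lognormal":
            raise ValueError("log_params only defined for lognormal specs")
        sigma2 = math.log1p(self.params["cv"] ** 2)
        mu = math.log(self.params["mean"]) - sigma2 / 2
        return mu, math.sqrt(sigma2)

    @property
    def geometric_mean(self) -> float:
        mu, _ = self.log_params()
        return math.exp(mu)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point":
            return np.full(n, float(self.params["value"]))
        if self.family == "lognormal":
            mu, sigma = self.log_params()
            return rng.lognormal(mean=mu, sigma=sigma, size=n)
        return rng.uniform(self.params["low"], self.params["high"], size=n)


@dataclass
class MCResult:
    """Monte Carlo risk distribution with summaries and sensitivities."""

    n: int
    risks: np.ndarray
    mean: float
    se: float
    p5: float
    p50: float
    p95: float
    sensitivity: Dict[str, float]   # Spearman rho; NaN for constant inputs

    def summary_row(self) -> Dict[str, float]:
        return {"mean": self.mean, "se": self.se,
                "p5": self.p5, "p50": self.p50, "p95": self.p95}


def fit_cw_distribution(
    bapeq_values: Sequence[float],
    candidates: Sequence[str] = ("lognormal", "uniform"),
) -> DistributionSpec:
    """Select a best-fit distribution for detected BaPeq concentrations.

    Each candidate family is fitted by maximum likelihood; the winner has
    the lowest AIC (ties broken by the smaller Kolmogorov–Smirnov
    statistic).  At least 10 strictly positive values are required, with
    nonzero spread.
    """
    x = np.asarray(list(bapeq_values), dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("concentration values must be strictly positive")
    if np.allclose(x, x[0]):
        raise ValueError("values are constant; no distribution can be fitted")

    fits: List[Tuple[float, float, DistributionSpec]] = []
    diagnostics: List[str] = []
    for family in candidates:
        try:
            if family == "lognormal":
                logs = np.log(x)
                mu, sigma = logs.mean(), logs.std(ddof=0)
                ll = stats.lognorm.logpdf(x, s=sigma, scale=np.exp(mu)).sum()
                ks = stats.kstest(x, stats.lognorm(s=sigma, scale=np.exp(mu)).cdf).statistic
                mean = math.exp(mu + sigma ** 2 / 2)
                cv = math.sqrt(math.expm1(sigma ** 2))
                spec = DistributionSpec("Cw", "lognormal", {"mean": mean, "cv": cv})
            elif family == "uniform":
                low, high = x.min(), x.max()
                ll = -x.size * math.log(high - low)
                ks = stats.kstest(x, stats.uniform(low, high - low).cdf).statistic
                spec = DistributionSpec("Cw", "uniform", {"low": float(low), "high": float(high)})
            else:
                raise ValueError(f"cannot fit family {family!r}")
            aic = 2 * 2 - 2 * ll
            fits.append((aic, ks, spec))
        except Exception as exc:  # keep per-family diagnostics for the error path
            diagnostics.append(f"{family}: {exc}")
    if not fits:
        raise ValueError("all candidate fits failed: " + "; ".join(diagnostics))
    fits.sort(key=lambda t: (t[0], t[1]))
    return fits[0][2]


def sample_parameters(
    specs: Iterable[DistributionSpec], n: int, seed: int,
    defaults: Optional[ExposureParameterSet] = None,
) -> pd.DataFrame:
    """Independent draw table (n rows, one column per uncertain parameter).

    Parameters without a spec are held at their point defaults.
    Reproducible: the same seed yields the same table.
    """
    if n < 1:
        raise ValueError("draw count must be at least 1")
    defaults = defaults or ExposureParameterSet()
    by_name = {}
    for spec in specs:
        if spec.name in by_name:
            raise ValueError(f"duplicate spec for parameter {spec.name}")
        by_name[spec.name] = spec
    rng = np.random.default_rng(seed)
    columns = {}
    for name, attr in UNCERTAIN_PARAMETERS.items():
        spec = by_name.get(name)
        if spec is None:
            spec = DistributionSpec(name, "point", {"value": getattr(defaults, attr)})
        columns[name] = spec.draw(n, rng)
    return pd.DataFrame(columns)


def sensitivity(draws: pd.DataFrame, risks: np.ndarray) -> Dict[str, float]:
    """Spearman rank correlation of each input column with the output risk.

    Constant columns get NaN (not applicable); if every column is
    constant the analysis is meaningless and raises.
    """
    if len(draws) < 3:
        raise ValueError("need at least 3 draws for rank correlations")
    out: Dict[str, float] = {}
    any_varied = False
    for name in draws.columns:
        col = draws[name].to_numpy()
        if np.ptp(col) == 0:
            out[name] = float("nan")
            continue
        any_varied = True
        rho = stats.spearmanr(col, risks).statistic
        out[name] = float(rho)
    if not any_varied:
        raise ValueError("all parameters are constant; nothing to rank")
    return out


def simulate_risk(
    specs: Iterable[DistributionSpec],
    fixed: Optional[ExposureParameterSet] = None,
    n: int = 10_000,
    seed: int = 0,
) -> MCResult:
    """Propagate parameter uncertainty through the risk model.

    Draws every uncertain parameter, evaluates the total (ingestion +
    dermal) lifetime risk per draw, and returns summaries plus rank
    sensitivities.  With all specs collapsed to points this reproduces
    the deterministic result exactly (SE = 0).
    """
    fixed = fixed or ExposureParameterSet()
    draws = sample_parameters(specs, n, seed, defaults=fixed)
    risks = total_risk_array(
        cw_ng_l=draws["Cw"].to_numpy(),
        ir=draws["IR"].to_numpy(),
        ed=draws["ED"].to_numpy(),
        bw=draws["BW"].to_numpy(),
        et=draws["ET"].to_numpy(),
        sa=draws["SA"].to_numpy(),
        ef=fixed.ef, at=fixed.at, kp=fixed.kp, cf=fixed.cf,
        sf_oral=fixed.sf_oral, aaf=fixed.aaf,
    )
    if n >= 3:
        try:
            sens = sensitivity(draws, risks)
        except ValueError:   # fully degenerate run: all parameters fixed
            sens = {name: float("nan") for name in draws.columns}
    else:
        sens = {name: float("nan") for name in draws.columns}
    return _summarize(risks, sens)


def _summarize(risks: np.ndarray, sens: Dict[str, float]) -> MCResult:
    n = risks.size
    mean = float(risks.mean())
    se = float(risks.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    # type-7 (linear interpolation) empirical quantiles
    p5, p50, p95 = (float(q) for q in np.quantile(risks, [0.05, 0.5, 0.95]))
    return MCResult(n=n, risks=risks, mean=mean, se=se, p5=p5, p50=p50, p95=p95,
                    sensitivity=sens)


def summarize(result: MCResult) -> Dict[str, float]:
    """Flat report row: mean, SE and the three conventional percentiles."""
    return result.summary_row()


def merge_results(a: MCResult, b: MCResult) -> MCResult:
    """Pool the draws of two runs (sensitivities are not preserved)."""
    risks = np.concatenate([a.risks, b.risks])
    sens = {name: float("nan") for name in a.sensitivity}
    return _summarize(risks, sens)
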