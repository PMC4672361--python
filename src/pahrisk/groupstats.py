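"""Campaign statistics: geometric means, normality, group comparisons,
exceedance rates and the incidence–mortality correlation.

Concentration summaries use the geometric mean with a t-interval on the
log scale, the natural summary for lognormal environmental data.  Group
comparisons follow the classical scheme for such campaigns: ANOVA on
Box-Cox-transformed values alongside its nonparametric equivalent
(Kruskal–Wallis for three groups, Wilcoxon rank-sum for two); the rank
test's p-value is the headline in rendered tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from .analytes import ANALYTES, PEFTable, Standard
from .samples import VillageRecord, WaterSample
from .screening import bapeq_concentration, carcinogenic_sum, screen_sample, total_pahs


@dataclass(frozen=True)
class GMSummary:
    gm: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    factor: str
    method: str            # anova | kruskal_wallis | wilcoxon
    statistic: float
    p_value: float
    group_ns: Tuple[int, ...]

    @property
    def marker(self) -> str:
        """Conventional significance marker: ** P<0.01, * P<0.05."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def geometric_mean_ci(values: Sequence[float], level: float = 0.95) -> GMSummary:
    """Geometric mean with a log-scale t confidence interval.

    All values must be strictly positive (resolve non-detects first).
    With a single value the interval degenerates to the point.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("no values given")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    logs = np.log(x)
    gm = math.exp(logs.mean())
    if x.size < 2:
        return GMSummary(gm=gm, ci_low=gm, ci_high=gm, n=1)
    sem = logs.std(ddof=1) / math.sqrt(x.size)
    t = stats.t.ppf(0.5 + level / 2, df=x.size - 1)
    return GMSummary(
        gm=gm,
        ci_low=math.exp(logs.mean() - t * sem),
        ci_high=math.exp(logs.mean() + t * sem),
        n=int(x.size),
    )


def boxcox_lambda(values: Sequence[float]) -> Tuple[float, np.ndarray]:
    """Best-fit Box-Cox lambda on a fixed grid [-3, 3] (step 0.01).

    Maximizes the profile log-likelihood; returns (lambda, transformed
    values), with the lambda = 0 branch equal to the natural log.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 values, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    grid = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 2)
    # profile log-likelihood, vectorized over the whole grid:
    #   ll(lam) = (lam - 1) * sum(log x) - n/2 * log(var(y_lam))
    logx = np.log(x)
    lam_col = grid[:, None]
    with np.errstate(over="ignore"):
        y = np.where(lam_col == 0.0, logx[None, :],
                     np.expm1(lam_col * logx[None, :]) / np.where(lam_col == 0.0, 1.0, lam_col))
    lls = (grid - 1.0) * logx.sum() - x.size / 2.0 * np.log(y.var(axis=1, ddof=0))
    lam = float(grid[int(np.argmax(lls))])
    return lam, stats.boxcox(x, lmbda=lam)


def normality_tests(values: Sequence[float]) -> Dict[str, float]:
    """Anderson–Darling and Lilliefors-corrected KS p-values vs normality.

    Both tests estimate mean and SD from the data.  Constant input has
    no defined test; NaN p-values are returned.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 values, got {x.size}")
    if np.ptp(x) == 0:
        return {"anderson_darling_p": float("nan"),
                "kolmogorov_smirnov_p": float("nan")}
    _, ad_p = normal_ad(x)
    _, ks_p = lilliefors(x, dist="norm")
    return {"anderson_darling_p": float(ad_p), "kolmogorov_smirnov_p": float(ks_p)}


def compare(
    values_by_group: Mapping[str, Sequence[float]],
    method: str,
    factor: str = "",
) -> ComparisonResult:
    """Compare concentration groups by the requested test.

    ``wilcoxon`` (rank-sum) is restricted to exactly 2 groups,
    ``kruskal_wallis`` to 3 or more; ``anova`` accepts either.
    """
    groups = [np.asarray(list(v), dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 observations")
    if method == "wilcoxon":
        if len(groups) != 2:
            raise ValueError(
                f"wilcoxon rank-sum compares exactly 2 groups, got {len(groups)}")
        stat, p = stats.ranksums(groups[0], groups[1])
    elif method == "kruskal_wallis":
        if len(groups) < 3:
            raise ValueError(
                f"kruskal_wallis expects 3 or more groups, got {len(groups)}")
        stat, p = stats.kruskal(*groups)
    elif method == "anova":
        stat, p = stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        factor=factor, method=method, statistic=float(stat),
        p_value=float(p), group_ns=tuple(g.size for g in groups),
    )


def exceedance_rates(
    samples: Iterable[WaterSample],
    standard: Standard,
    pefs: Optional[PEFTable] = None,
    nd_policy: str = "zero",
    detection_limits: Optional[Mapping[str, float]] = None,
) -> Dict[str, Dict[str, float]]:
    """Per-limit exceedance counts and percentages over a sample set.

    Percentages are count/total expressed to 1 decimal (25.9 means
    25.9%).  Cross-module contract: the fraction equals the mean of the
    screening flag column.
    """
    pefs = pefs or PEFTable()
    counts: Dict[str, int] = {}
    total = 0
    for sample in samples:
        flags = screen_sample(sample, standard, pefs, nd_policy, detection_limits)
        total += 1
        for key, flag in flags.items():
            counts[key] = counts.get(key, 0) + int(flag)
    if total == 0:
        raise ValueError("no samples to screen")
    return {
        key: {"count": count, "total": total,
              "percent": round(100.0 * count / total, 1)}
        for key, count in counts.items()
    }


def incidence_mortality_correlation(
    villages: Sequence[VillageRecord],
) -> Dict[str, float]:
    """Pearson correlation between village incidence and mortality rates."""
    if len(villages) < 3:
        raise ValueError("need at least 3 villages")
    inc = np.asarray([v.incidence for v in villages])
    mor = np.asarray([v.mortality for v in villages])
    if np.ptp(inc) == 0 or np.ptp(mor) == 0:
        raise ValueError("zero variance in incidence or mortality rates")
    r, p = stats.pearsonr(inc, mor)
    return {"r": float(r), "p_value": float(p)}


# --------------------------------------------------------------------------
# Campaign tables
# --------------------------------------------------------------------------

AGGREGATE_ROWS = ("sum_PAHs", "sum_PAHs_c", "BaPeq")


def _row_values(
    samples: List[WaterSample],
    row: str,
    pefs: PEFTable,
    nd_policy: str,
    detection_limits: Optional[Mapping[str, float]],
) -> np.ndarray:
    """Positive per-sample values for one table row (analyte or aggregate)."""
    out = []
    for s in samples:
        if row == "sum_PAHs":
            v = total_pahs(s, nd_policy, detection_limits)
        elif row == "sum_PAHs_c":
            v = carcinogenic_sum(s, pefs, nd_policy, detection_limits)
        elif row == "BaPeq":
            v = bapeq_concentration(s, pefs, nd_policy, detection_limits)
        elif row in s.conc:
            v = s.conc[row]
        elif s.nondetect.get(row) and nd_policy != "zero":
            dl = (detection_limits or {}).get(row)
            v = 0.5 * dl if (nd_policy == "half_dl" and dl) else (dl or 0.0)
        else:
            continue
        if v > 0:
            out.append(v)
    return np.asarray(out)


def _anova_boxcox_p(groups: Mapping[str, np.ndarray]) -> float:
    """One-way ANOVA p on Box-Cox-transformed values (pooled lambda)."""
    if len(groups) < 2:
        return float("nan")
    pooled = np.concatenate(list(groups.values()))
    if pooled.size < 10 or np.ptp(pooled) == 0:
        return float("nan")
    lam, _ = boxcox_lambda(pooled)
    transformed = [stats.boxcox(g, lmbda=lam) for g in groups.values()]
    return float(stats.f_oneway(*transformed).pvalue)


def _fmt_gm(summary: Optional[GMSummary]) -> str:
    if summary is None:
        return "nd"
    return f"{summary.gm:.1f} ({summary.ci_low:.1f}, {summary.ci_high:.1f})"


def comparison_table(
    samples: List[WaterSample],
    stratum: str,
    compare_by: str,
    pefs: Optional[PEFTable] = None,
    nd_policy: str = "half_dl",
    detection_limits: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Campaign summary table: GM (95% CI) per stratum cell and p-values.

    ``stratum``/``compare_by`` are sample attributes (``season``,
    ``water_type`` or ``group``).  One row per analyte with any positive
    value plus the three aggregate rows (total PAHs, carcinogenic PAHs,
    BaPeq).  Within each stratum level, cells are split by water type
    and a rank test across water types is reported; across stratum
    levels a two-group rank test is reported per water type and overall.
    Rank-test p-values are the headline; an ANOVA p on Box-Cox
    transformed values is attached where group sizes permit.
    """
    pefs = pefs or PEFTable()
    levels = sorted({getattr(s, stratum) for s in samples})
    if len(levels) != 2:
        raise ValueError(f"stratum {stratum!r} must have exactly 2 levels, got {levels}")
    compare_levels = sorted({getattr(s, compare_by) for s in samples})

    def subset(level=None, cmp_level=None):
        out = samples
        if level is not None:
            out = [s for s in out if getattr(s, stratum) == level]
        if cmp_level is not None:
            out = [s for s in out if getattr(s, compare_by) == cmp_level]
        return out

    rows = []
    # an analyte earns a row only if it was actually detected somewhere
    row_names = [a for a in ANALYTES if any(a in s.conc for s in samples)]
    row_names += list(AGGREGATE_ROWS)
    for row_name in row_names:
        record: Dict[str, object] = {"analyte": row_name}
        for level in levels:
            per_cmp = {}
            for cmp_level in compare_levels:
                vals = _row_values(subset(level, cmp_level), row_name,
                                   pefs, nd_policy, detection_limits)
                per_cmp[cmp_level] = vals
                record[f"{level}_{cmp_level}_gm"] = _fmt_gm(
                    geometric_mean_ci(vals) if vals.size >= 2 else None)
            usable = {k: v for k, v in per_cmp.items() if v.size >= 2}
            if len(usable) >= 3:
                record[f"{level}_P"] = compare(usable, "kruskal_wallis").p_value
            elif len(usable) == 2:
                record[f"{level}_P"] = compare(usable, "wilcoxon").p_value
            else:
                record[f"{level}_P"] = float("nan")
            record[f"{level}_P_anova"] = _anova_boxcox_p(usable)
        for cmp_level in compare_levels + ["all"]:
            a = _row_values(subset(levels[0], None if cmp_level == "all" else cmp_level),
                            row_name, pefs, nd_policy, detection_limits)
            b = _row_values(subset(levels[1], None if cmp_level == "all" else cmp_level),
                            row_name, pefs, nd_policy, detection_limits)
            if a.size >= 2 and b.size >= 2:
                record[f"P_{cmp_level}"] = compare(
                    {"a": a, "b": b}, "wilcoxon").p_value
            else:
                record[f"P_{cmp_level}"] = float("nan")
        rows.append(record)
    return pd.DataFrame(rows)
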