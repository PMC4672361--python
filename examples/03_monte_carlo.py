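"""Probabilistic risk with parameter uncertainty and sensitivity ranking.

The BaPeq concentration gets a lognormal distribution (mean 10 ng/L,
CV 1.5), exposure duration a uniform 0-70 years, and body weight a
narrow lognormal; 10,000 Monte Carlo draws are propagated through the
risk model.
"""

from pahrisk import DistributionSpec, simulate_risk

specs = [
    DistributionSpec("Cw", "lognormal", {"mean": 10.0, "cv": 1.5}),
    DistributionSpec("ED", "uniform", {"low": 0.0, "high": 70.0}),
    DistributionSpec("BW", "lognormal", {"mean": 62.1, "cv": 0.05}),
]
result = simulate_risk(specs, n=10_000, seed=1)

print(f"mean risk : {result.mean:.3e}   (SE {result.se:.1e})")
print(f"P5 / P50 / P95 : {result.p5:.2e} / {result.p50:.2e} / {result.p95:.2e}")
print("rank correlations with risk:")
for name, rho in sorted(result.sensitivity.items(),
                        key=lambda kv: -abs(kv[1]) if kv[1] == kv[1] else 1):
    print(f"  {name:3s} : {rho:+.3f}" if rho == rho else f"  {name:3s} :  n/a (constant)")

# Concentration dominates (rho ~ 0.77), exposure duration comes second
# (~0.58), body weight is weakly negative; parameters held constant get
# no rank correlation.  The skewed Cw pushes the mean above the median.
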