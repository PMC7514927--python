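"""Evaluate the Weibull-gamma law: density, hazard shapes, quantiles, sampling.

The four parameters are c, beta (Weibull generator shape/scale) and
k, s (gamma baseline shape/scale).  Different corners of the parameter
space give decreasing, increasing, unimodal or bathtub hazards, which
is what makes the family useful for lifetime data.
"""

import numpy as np

from wgamma import WgParams, wg_cdf, wg_hazard, wg_pdf, wg_quantile, wg_rvs

params = WgParams(c=0.5, beta=1.0, k=0.5, s=0.4)
print(f"W-g parameters: c={params.c}, beta={params.beta}, k={params.k}, s={params.s}")

grid = np.array([0.05, 0.2, 0.5, 1.0, 2.0])
print("\n x      pdf      cdf      hazard")
for x, f, F, h in zip(grid, wg_pdf(grid, params), wg_cdf(grid, params),
                      wg_hazard(grid, params)):
    print(f"{x:4.2f}  {f:7.4f}  {F:7.4f}  {h:7.4f}")

# quartiles: where 25/50/75% of lifetimes fall
q = wg_quantile(np.array([0.25, 0.5, 0.75]), params)
print(f"\nquartiles: {q.round(4)}  (cdf round-trip errors "
      f"{np.abs(wg_cdf(q, params) - [0.25, 0.5, 0.75]).max():.1e})")

# a reproducible sample and its agreement with the model mean
x = wg_rvs(20_000, params, seed=42)
print(f"sample of n=20000 (seed 42): mean={x.mean():.4f}, "
      f"sd={x.std():.4f}, max={x.max():.2f}")
print("c*k < 1: the density diverges at 0 and the hazard decreases — the\n"
      "early-failure regime this family captures that the gamma alone cannot")
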