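"""The algebraic series machinery: recursions, truncated sums, moments.

The W-g density admits a formal rearrangement into gamma-type kernels.
Where the truncated sums converge they agree with the closed-form
density; moments/mgf can be computed term-by-term, by adaptive
quadrature (the recommended route) or by Monte Carlo.
"""

import math

import numpy as np

from wgamma import WgParams, mgf, moment, p_coefficients, pdf_series, wg_logpdf

p_exp = WgParams(1.0, 1.0, 1.0, 1.0)   # reduces to the unit exponential
p_gen = WgParams(1.3, 1.2, 0.8, 1.0)   # a generic convergent point

print("p-recursion start:", p_coefficients(1, 4).round(4))

res = pdf_series(0.5, p_exp, order=15)
print(f"series pdf at x=0.5 (exponential case): {res.value:.7f} "
      f"vs closed form {math.exp(-0.5):.7f}  converged={res.converged}")

res = pdf_series(0.6, p_gen, order=18)
closed = math.exp(wg_logpdf(0.6, p_gen))
print(f"series pdf at x=0.6 (generic): {res.value:.6f} vs {closed:.6f} "
      f"(last block {res.last_block:.1e})")

m_quad = moment(1, p_gen, method="quadrature")
m_mc = moment(1, p_gen, method="mc", n_mc=200_000, seed=1)
print(f"mean by quadrature {m_quad:.5f}  by Monte Carlo {m_mc:.5f}")

m_series = moment(1, WgParams(1, 1, 2, 1), method="series")
print(f"series mean of nested gamma(k=2): {m_series.value:.6f} (exact 2)")

print(f"mgf at t=0.25 for gamma(k=2,s=1) nested case: "
      f"{mgf(0.25, WgParams(1, 1, 2, 1)):.6f} (exact {0.75 ** -2:.6f})")
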