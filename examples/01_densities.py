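"""Evaluate the zero-inflated bivariate copula density for one cell.

Builds a cell's natural parameters, evaluates the joint pmf on a small
count grid, and verifies it behaves like a probability distribution.
"""

import numpy as np

from zicoex import CellParams, joint_pmf, zi_joint_pmf, zinb_marginal_pmf

params = CellParams(mu1=2.0, mu2=3.0, sigma1=0.5, sigma2=0.8,
                    rho=0.45, p1=0.10, p2=0.05)

grid = np.arange(6)
y1, y2 = np.meshgrid(grid, grid, indexing="ij")
pmf = zi_joint_pmf(y1, y2, params)

print("joint pmf on counts 0..5 x 0..5 (rows = gene 1):")
for row in pmf:
    print("  " + " ".join(f"{v:.4f}" for v in row))
# The (0,0) cell carries both the copula mass and the dropout mass.
print(f"P(0,0) with dropout: {pmf[0, 0]:.4f}  "
      f"without: {float(joint_pmf(0, 0, params)):.4f}")

wide = np.arange(200)
w1, w2 = np.meshgrid(wide, wide, indexing="ij")
print(f"total mass on 0..199 squared: {zi_joint_pmf(w1, w2, params).sum():.8f}"
      "  (should be ~1)")

marg = zi_joint_pmf(np.zeros_like(wide), wide, params).sum()
print(f"sum over y2 at y1=0: {marg:.6f}  equals zero-inflated NB marginal "
      f"{float(zinb_marginal_pmf(0, 2.0, 0.5, 0.10)):.6f}")
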