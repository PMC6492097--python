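"""Pool a shared quadratic exposure-outcome curve from two studies.

Two large studies cover adjacent exposure ranges (20-25 and 25-30) and
share a quadratic log-hazard truth with its minimum at 22.  Both pooling
routes should recover the nadir; the multivariate route should be more
precise, because it borrows each study's whole fitted curve where the
other study has no data.
"""

import numpy as np

from fpmeta import (
    FPSpec, curve_from_mvmeta, fit_cox_fp, make_example, metacurve_pool,
    mvmeta_pool,
)

studies = make_example(1, scale=0.1, seed=1)
print("studies:", [(s.study_id, s.n, s.n_events) for s in studies])

spec = FPSpec((1, 2))  # quadratic: beta1*x + beta2*x^2
fits = [fit_cox_fp(s, spec) for s in studies]

grid = np.round(np.arange(20.0, 30.001, 0.01), 2)
mv = curve_from_mvmeta(mvmeta_pool(fits, model="ce"), grid, x0=25.0)
mc = metacurve_pool(fits, grid, x0=25.0, model="ce")

for name, curve in (("mvmeta", mv), ("metacurve", mc)):
    nadir = curve.grid[np.argmin(curve.estimate)]
    print(f"{name:10s} nadir {nadir:5.2f}   "
          f"log-HR at 30 vs 25: {curve.at(30.0):+.3f}")
off = ~np.isclose(grid, 25.0)
print("mvmeta SE <= metacurve SE at every off-reference point:",
      bool(np.all(mv.se[off] <= mc.se[off] + 1e-12)))
# The nadir estimates should sit near 22; the SE ordering reflects the
# borrowing of strength of the coefficient-level pooling.
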