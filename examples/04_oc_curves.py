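"""Operating-characteristic curves, with fixed and coverage-dependent clustering.

The OC curve traces P(classified acceptable) over true coverage.
Holding rho fixed across coverage levels is a modeling choice; field
estimates suggest clustering often shrinks as coverage rises.  A
ClusteringSpec can carry a (p, rho) grid, and the curve machinery
re-resolves it at every grid point.
"""

import numpy as np

from clusterlqas import ClusteringSpec, oc_curve

design = dict(method="hedt", k=9, m=10, d=75)
grid = np.linspace(0.60, 0.95, 8)

fixed = ClusteringSpec.from_rho(0.10)
varying = ClusteringSpec.from_rho_grid([0.60, 0.95], [0.20, 0.05])

curve_fixed = oc_curve(**design, clustering=fixed, p_grid=grid)
curve_var = oc_curve(**design, clustering=varying, p_grid=grid)

print("P(classified acceptable), 9 x 10 design with d = 75\n")
print(f"{'true p':>7s} {'rho=.10':>9s} {'rho=f(p)':>9s}")
for p, a, b in zip(grid, curve_fixed.prob_accept, curve_var.prob_accept):
    print(f"{p:7.3f} {a:9.4f} {b:9.4f}")

# curve_fixed.plot() draws the curve when matplotlib is installed.
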