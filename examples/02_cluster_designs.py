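"""Compare the three cluster-LQAS design methods on one couplet.

Field surveys sample k clusters of m subjects; within-cluster
correlation inflates the variance of the total, so the binomial design
understates both risks.  Three remedies are implemented:

* ``pezzoli`` — latent cluster coverage Binomial(eta, p)/eta, exact
  finite-mixture pmf (parameterized by sigma, the SD of coverages);
* ``hedt``    — beta-binomial cluster counts (parameterized by rho);
* ``hund``    — design-effect rescaling to an effective binomial.

``compare_designs`` builds the side-by-side table, resolving a
sigma-fixed clustering into per-threshold rho values (and vice versa)
exactly as the cross-parameterization comparison requires.
"""

import pandas as pd

from clusterlqas import ClusteringSpec, DesignTargets, compare_designs

pd.set_option("display.width", 120)

table = compare_designs(
    targets_list=[DesignTargets(0.75, 0.90)],
    m=10,
    clustering_spec_list=[ClusteringSpec.from_sigma(0.1)],
    methods=["srs", "pezzoli", "hund", "hedt"],
)
print("sigma = .1, alpha = beta = .1, m = 10")
print(table.round({"alpha": 3, "beta": 3}).to_string(index=False))
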