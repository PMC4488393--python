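"""Estimate between-cluster variance from survey summaries, then design.

Published cluster-survey reports usually include, per area, the
estimated coverage p_hat and the SD s of estimated cluster coverages
(or a standard error).  The method-of-moments estimator

    sigma2_hat = (m s^2 - p_hat (1 - p_hat)) / (m - 1),  truncated at 0,

removes the within-cluster binomial noise from s^2.  This script
simulates such a report from a known generator, recovers the clustering,
and feeds the estimate into a design search.
"""

import numpy as np

from clusterlqas import (
    ClusteringSpec,
    DesignTargets,
    SurveySummary,
    estimate_table,
    find_cluster_design,
    generate_fixture,
)

TRUE_RHO = 0.10
spec = ClusteringSpec.from_rho(TRUE_RHO)

df = generate_fixture(
    "hedt", true_p=0.8, clustering=spec, n_areas=200, k=10, m=10, seed=20150630
)
summaries = [
    SurveySummary(area_id=r.area_id, p_hat=r.p_hat, s=r.s, k=int(r.k), m=int(r.m))
    for r in df.itertuples()
]
table = estimate_table(summaries)
rho_hat = float(np.nanmedian(table["rho_hat"]))
n_trunc = int(table["truncated"].sum())
print(f"true rho = {TRUE_RHO}: median rho_hat over 200 areas = {rho_hat:.3f} "
      f"({n_trunc} estimates truncated at zero)")

design = find_cluster_design(
    "hedt", DesignTargets(0.75, 0.90), ClusteringSpec.from_rho(rho_hat), 10
)
print(f"design at the estimated clustering: n = {design.n}, d = {design.d}, "
      f"alpha = {design.alpha_hat:.3f}, beta = {design.beta_hat:.3f}")
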