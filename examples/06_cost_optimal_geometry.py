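"""Choose the cluster geometry (k, m) that minimizes field cost.

More subjects per cluster are cheap but inflate the design effect; more
clusters are statistically efficient but each cluster visit costs
travel.  ``cost_optimal_design`` scans a grid of per-cluster sizes,
finds the minimal feasible design for each, and returns the cheapest.
"""

from clusterlqas import ClusteringSpec, DesignTargets, cost_optimal_design

targets = DesignTargets(0.75, 0.90)
spec = ClusteringSpec.from_rho(0.1)

for c_cluster, c_subject in [(10, 1), (100, 1), (500, 1)]:
    best = cost_optimal_design(
        "hedt", targets, spec,
        cost_per_cluster=c_cluster, cost_per_subject=c_subject,
        m_grid=range(2, 31),
    )
    cost = best.k * c_cluster + best.n * c_subject
    print(f"cluster visit = {c_cluster:4d} x subject: "
          f"k = {best.k:3d}, m = {best.m:3d}, n = {best.n:4d}, "
          f"d = {best.d:4d}, total cost = {cost}")
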