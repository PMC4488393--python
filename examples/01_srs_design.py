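"""Find a classical (non-clustered) LQAS design.

An LQAS survey classifies an area as acceptable or not: sample n
subjects, count successes X, classify low when X <= d.  Given a
threshold couplet (p_l, p_u) and risk caps, the design search finds the
smallest n admitting a decision rule d that respects both caps.
"""

from clusterlqas import DesignTargets, find_srs_design

for p_l, p_u in [(0.55, 0.70), (0.75, 0.90), (0.90, 0.95)]:
    targets = DesignTargets(p_l=p_l, p_u=p_u, alpha=0.1, beta=0.1)
    design = find_srs_design(targets)
    print(
        f"couplet {p_l:.2f}-{p_u:.2f}: n = {design.n:4d}, d = {design.d:4d}, "
        f"alpha = {design.alpha_hat:.3f}, beta = {design.beta_hat:.3f}"
    )

# The feasible rules at the minimal n form a contiguous interval:
targets = DesignTargets(0.75, 0.90)
design = find_srs_design(targets)
print(
    f"\nAt n = {design.n} every rule in "
    f"[{design.feasible.d_min}, {design.feasible.d_max}] is feasible."
)
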