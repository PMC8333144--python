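"""Desk-scale power/false-positive comparison of the functional LRT vs
single-day ANOVA.

Runs 50 replicates per cell on a reduced grid (full study uses 200+).
Power = fraction of replicates where the causal marker passes the
Bonferroni threshold; FPR = fraction where at least one null marker does.
"""

from fppfm.simulation_study import SimConfig, estimate_power_fpr

cells = [
    SimConfig(n_individuals=200, n_markers=500, heritability=0.05, correlated=c)
    for c in (False, True)
]
table = estimate_power_fpr(cells, n_replicates=50, seed=42, fm_full_scan=True)
print(table.to_string(index=False))
print(
    "\npower saturates for both methods at these effect sizes; elevated FM "
    "false-positive rates reflect null markers' chance correlation with the "
    "strong causal locus leaking into their likelihood ratios "
    "(see docs/methods.md)"
)
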