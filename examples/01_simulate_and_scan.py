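"""Simulate an introgression-line trial and run a permutation-thresholded
genome scan.

Generates 200 lines x 300 markers with one causal QTL (curve heritability
0.10, SAD(1)-correlated residuals, three 10-day treatment phases), scans
every marker with the functional existence LRT, and calls QTL regions
against a 200-permutation genome-wide threshold.
"""

from fppfm import FitOptions, genome_scan
from fppfm.simulation_study import SimConfig, simulate_dataset

config = SimConfig(n_individuals=200, n_markers=300, heritability=0.10,
                   correlated=True)
phenos, genos, truth = simulate_dataset(config, seed=7)
print(f"simulated {len(phenos.individuals)} lines, {genos.n_markers} markers; "
      f"causal marker: {truth.causal_marker_ids[0]} (phi2={truth.phi2:.3f})")

result, regions = genome_scan(
    phenos, genos, FitOptions(order=4),
    {"method": "permutation", "n_perm": 200, "alpha": 0.05, "seed": 7},
)
print(f"genome-wide threshold LR* = {result.threshold_lr:.2f} "
      f"(chi-square p* = {result.threshold_p:.3g}, df = {result.df})")
for r in regions:
    print(f"QTL region on {r.chromosome}: {r.cM_min:.1f}-{r.cM_max:.1f} cM, "
          f"peak {r.peak_bin}, p = {r.peak_p:.3g}")

# The peak bin should be the planted causal marker: the LR measures how much
# better genotype-specific Legendre mean curves (with shared SAD(1)
# covariance) explain the trajectories than a single common curve.
peak = result.table.loc[result.table["LR"].idxmax()]
print(f"scan peak: {peak['bin_id']} (LR = {peak['LR']:.1f}) — "
      f"{'matches' if peak['bin_id'] in truth.causal_marker_ids else 'misses'} "
      "the causal marker")
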