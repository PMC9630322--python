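"""Infer cell phases from core clock genes on simulated counts.

Simulates a light-dark time course (500 cells at 4 collection phases)
from the Negative Binomial sinusoidal model, then fits the variational
posterior using the 12 clock genes alone and reports accuracy and
uncertainty calibration against the known phases.
"""

import numpy as np

import circaphase as cp

cfg = cp.SimConfig(n_cells=500, n_phase_grid=4, n_flat_genes=100, n_ccgs=0, seed=1)
disp = cp.DispersionModel.constant(0.15)
cm, true_phases, params = cp.simulate_counts(cfg, disp)
print(f"simulated {cm.n_cells} cells x {cm.n_genes} genes, "
      f"median library {np.median(cm.library_size):.0f} UMIs")

# informative-but-imperfect clock priors: acrophase locations jittered by
# 2 h, 95% prior interval 4 h wide — mimicking priors taken from bulk data
prior = cp.jittered_acrophase_priors(cfg.clock_table, seed=2)
clock = list(cfg.clock_table["gene"])

pc = cp.PipelineConfig(fit=cp.FitConfig(seed=3), max_iterations=1)
report, trace, state = cp.run_pipeline(cm, prior, clock, pc, disp=disp)

err = cp.phase_error_hours(true_phases, report.phase_radians)
print(f"median phase error: {np.median(err):.2f} h "
      "(perfect recovery would be 0; random guessing 6)")
print(f"fraction of cells within 3 h of truth: {cp.ecdf_at(err, 3.0):.2f}")

curve = cp.calibration_curve(report.credible_arcs, true_phases)
print("credible-interval calibration (coverage should be >= level):")
for level, cov in curve:
    print(f"  {level:.0%} HDR interval covers truth for {cov:.1%} of cells")

print(f"log10 Bayes factor vs permuted clock: {trace.log10_bayes_factor[0]:.0f} "
      "(values near 0 would mean the fit is no better than random)")
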