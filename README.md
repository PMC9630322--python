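# circaphase

Bayesian inference of single-cell circadian phase from droplet scRNA-seq
UMI counts — with calibrated uncertainty and de novo discovery of
clock-controlled genes.

## The problem

Every cell carries a ~24 h molecular clock whose state ("circadian
phase") is set by the mRNA levels of ~20 core clock genes (*Arntl*,
*Nr1d1*, *Dbp*, ...). Standard time-course designs assume all cells in a
sample share the collection time's phase; studying phase heterogeneity,
or unsynchronized cultures, requires estimating each cell's phase from
its transcriptome alone. Clock transcripts are only moderately expressed,
so a per-cell estimate from sparse UMI counts is uncertain — a useful
estimator must say *how* uncertain.

## The model

Counts are Negative Binomial with the library size as exposure and a
sinusoidal mean on the log scale:

```
X_ij ~ NB(L_i λ_ij, δ_ij)            Var(X) = E[X] + δ E[X]²
log λ_ij = μ_j + Q_j A_j cos(θ_i − φ_j)
δ_ij = g_ζ(λ_ij)                      (fitted mean–dispersion trend)
```

Per gene: mesor `μ_j` (mean log proportion), amplitude `A_j`, acrophase
`φ_j` (peak phase), and an indicator `Q_j ~ Bernoulli(γ_j)` for whether
the gene cycles at all. Per cell: a circular phase `θ_i` (hours =
radians × 12/π; hour 0 is anchored at the reference gene's peak, *Arntl*
by default). Priors: von Mises on acrophases (e.g., centred on bulk
estimates), Normal on mesors (empirical-Bayes location), a transformed
Beta on amplitudes, Beta–Bernoulli on the cycling indicator, and a
circular-uniform (or von Mises) prior on cell phases.

Inference is variational: free-form categorical factors on a circular
grid for every cell phase and gene acrophase (the optimal mean-field
family for these coordinates, updated in closed form by coordinate
ascent), MAP profiles for mesor/amplitude, and analytic marginalization
of `Q_j`. Two steps alternate: **Step 1** fits the posterior using the
current cycling genes; **Step 2** fits every other expressed gene
conditional on the phase posterior and promotes genes with posterior
cycling probability > 0.95 and an amplitude more than 2 SD above the
amplitude–mesor trend (a Pearson residual). The loop keeps de novo
cyclers only while the core-clock evidence — a leave-one-gene-out
predictive score — improves, and a permutation Bayes factor reports how
much better than random the fit explains clock expression. Per-cell
uncertainty is reported as highest-density-region (HDR) credible arcs.

## Worked example

```python
import numpy as np
import circaphase as cp

cfg = cp.SimConfig(n_cells=1000, n_flat_genes=500, n_ccgs=20, seed=11)
disp = cp.DispersionModel.constant(0.15)
cm, true_phases, params = cp.simulate_counts(cfg, disp)

prior = cp.jittered_acrophase_priors(cfg.clock_table, seed=12)
clock = list(cfg.clock_table["gene"])
report, trace, state = cp.run_pipeline(
    cm, prior, clock, cp.PipelineConfig(fit=cp.FitConfig(seed=13)), disp=disp
)

err = cp.phase_error_hours(true_phases, report.phase_radians)
print(np.median(err), len(report.de_novo_genes))
```

Running `python examples/02_de_novo_cyclers.py` (this exact setup)
prints:

```
evidence trace (higher = phases explain clock expression better):
  iteration 1: clock evidence -23227.3, log10 BF 477.0, 12 cycling genes
  iteration 2: clock evidence -21836.4, log10 BF 1081.1, 32 cycling genes
stopping reason: no_new_cyclers

de novo cyclers: 20 called, 20 are true CCGs (precision 1.00, sensitivity 1.00)
median phase error: clock-only 1.07 h -> with de novo cyclers 0.75 h
```

Reading: starting from the 12 clock genes, the fitted phases are within
~1 h of truth for half the cells; Step 2 recovers all 20 hidden
clock-controlled genes with no false calls, and folding them in sharpens
the median error to 0.75 h while the clock evidence improves (so they
are kept). The log10 Bayes factor of ~10³ says the fit explains clock
expression astronomically better than a phase-scrambled null. The other
scripts in `examples/` demonstrate calibration of the HDR intervals,
inference under realistic (non-sinusoidal) waveforms, and the PCA-angle
baseline with the out-of-sample clock-likelihood score.

## Command line

```bash
circaphase simulate --n-cells 1000 --seed 1 --out sim/
circaphase fit --counts sim/counts.tsv --clock-genes clock.txt --seed 2 --out run/
circaphase evaluate --predictions run/cells.tsv --truths sim/true_phases.tsv --out ecdf.tsv
circaphase baseline-pca --counts sim/counts.tsv --genes clock.txt --out pca.tsv
```

`fit` accepts 10x-style MatrixMarket directories or dense TSVs and
writes per-cell phases with HDR arcs, per-gene MAP parameters and
detection statistics, and the evidence trace — all as TSV.

## Layout

- `src/circaphase/model.py` — containers, NB likelihood, priors, dispersion trend
- `src/circaphase/inference.py` — Step-1 variational engine, evidence, Bayes factor, HDR
- `src/circaphase/cyclers.py` — Step-2 gene fits, detection statistics, the outer loop
- `src/circaphase/simulate.py` — both simulators and waveform diagnostics
- `src/circaphase/evaluate.py` — shifting, errors, calibration, stability, holdout, enrichment, PCA baseline
- `src/circaphase/io.py`, `cli.py` — formats, reports, command line
- `docs/methods.md` — the model, algorithm and design choices in detail
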