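# Methods

## Generative model

For cell *i* with library size `L_i` and gene *j*, UMI counts follow a
Negative Binomial in the mean/dispersion parametrization,

```
X_ij ~ NB(L_i λ_ij, δ_ij),   E[X] = L_i λ_ij,   Var(X) = E[X] + δ_ij E[X]²,
log λ_ij = μ_j + Q_j A_j cos(θ_i − φ_j),
δ_ij = g_ζ(λ_ij).
```

`θ_i ∈ [0, 2π)` is the cell's circadian phase (hours = radians × 12/π);
`μ_j` is the mesor (mean log proportion), `A_j ≥ 0` the amplitude in
natural-log units (A = 0.7 means ~2-fold peak-to-mesor), `φ_j` the
acrophase, and `Q_j ∈ {0,1}` gates the sinusoid entirely. The dispersion
is tied to the expected proportion through a polynomial trend `g_ζ`
shared by all genes and cells.

Priors: cell phases circular-uniform by default (von Mises if collection
times are informative); mesors Normal with the empirical log pseudobulk
proportion as location (scale 2.0 — weak); acrophases von Mises per gene
(circular-uniform when nothing is known); amplitudes a transformed Beta
on `[A_min, A_max]` (defaults 0 and 1.5, i.e., at most ~e³ ≈ 20-fold
peak-to-trough, uniform by default); the cycling indicator a
Beta–Bernoulli, `Beta(1,1)` for unknown genes and `Beta(9,1)` for the
trusted clock genes (prior cycling probability 0.9 — the clock list is
an assumption, not a certainty). The reference gene's acrophase is a
point mass at 0 rad, anchoring hour 0 of the cycle at its peak (*Arntl*
by default); it is excluded from the variational parameters.

## Dispersion trend

Per-gene NB dispersions are estimated by maximum likelihood with means
fixed at `L_i` × pseudobulk proportion (phase ignored), restricted to
genes with pseudobulk proportion above 1e-5; a degree-2 polynomial of
log δ on log λ is then fit by least squares. Estimates driven to the
Poisson boundary are floored at 1e-4 before the log fit. Evaluation
clamps λ to the fitted range so the trend cannot explode at extreme
proportions. `degree=0` gives the pooled method-of-moments constant.
Simulations in the tests and acceptance run use a constant δ = 0.15,
a typical UMI overdispersion for moderately expressed genes.

## Variational inference (Step 1)

The posterior `P(θ, β | X)` is approximated by a fully factorized
`q(θ, β) = Π_i q(θ_i) Π_j q(φ_j) q(Q_j)` and optimized by coordinate
ascent on the ELBO:

* **Cell phases and acrophases** are free-form categorical distributions
  on a 64-point uniform circular grid. For these coordinates the
  free-form family contains the optimal mean-field factor, so each
  update is an exact softmax of expected log-joint terms. The required
  inner products are circular convolutions/correlations over the grid
  and are evaluated with FFTs, giving O(n·G log G) per gene per sweep.
* **Mesor and amplitude** are point (MAP) coordinates. The amplitude is
  profiled on a 25-point grid with one parabolic refinement; the mesor
  is tied to the gene's pseudobulk proportion via
  `μ(A) = log p − log I0(A)`, which keeps the marginal expected
  proportion at its empirical value under near-uniform phases (I0 is the
  modified Bessel function). Their prior densities enter the ELBO; their
  entropy does not (a standard MAP-within-VI treatment).
* **The cycling indicator** is marginalized analytically against its
  Beta–Bernoulli prior; its posterior probability `q_γ` weights the
  sinusoidal vs flat branch in every other update. The update collapses
  the acrophase against its prior (a Rao-Blackwellized update), so a
  gene whose apparent rhythm relies on one lucky alignment is discounted
  by the prior mass of that alignment.

The first sweep holds gene parameters at their initialization and only
updates the phase factors: profiling amplitudes against still-diffuse
phases would collapse every gene to `A = 0` (an all-flat saddle point of
the coordinate ascent). Sweeps continue until the ELBO improves by less
than 0.05 nats (max 30 sweeps). Everything is deterministic given the
seed; the seed only perturbs the initial phase log-weights
(SD 0.25), which is how run-to-run stability is probed. On data where
the likelihood is informative the ascent converges to essentially the
same fixed point from any jittered start, so the run-to-run circular SD
is far below the 1 h scale; uncertainty about a *single* run's phases is
carried by the posterior itself, not by run-to-run spread.

Discretization: probabilities on the grid are treated as a density times
the cell width 2π/G, so entropies are differential and the ELBO
approximates its continuous counterpart; on instances small enough for
brute-force quadrature the optimized ELBO sits within 0.1 nat of the
true evidence when the factorization is exact (reference-gene case) and
below it otherwise (verified in the tests).

## Clock evidence and the permutation Bayes factor

The stopping signal of the outer loop is a *predictive* clock-evidence
score. For each clock gene, its own contribution is subtracted from the
cell-phase log weights (leave-one-gene-out) and the gene's counts are
scored under those phases, with the indicator and acrophase collapsed
against their priors and mesor/amplitude at their MAP values. The
leave-one-out step matters: free-form phase factors can soak up a single
gene's noise, and without it the score rewards per-gene overfitting —
equally on real and permuted data, drowning their difference in noise.

The null for the Bayes factor re-fits the model with each clock gene's
observations re-attached to a random cell's phase factor (one
independent permutation per gene). This destroys phase coherence
*across* genes while keeping every count paired with its own cell's
library size; naively permuting the count matrix columns also breaks the
count–exposure pairing and biases the null downward even for completely
flat genes. The log10 difference of the two evidences is reported; on
all-flat data it fluctuates around 0 (|median| < 1 over seeds, verified),
and on rhythmic fixtures it reaches hundreds.

## De novo cycler detection (Step 2)

Every non-cycling gene above the expression floor (pseudobulk proportion
> 1e-5) is fit conditional on the Step-1 phase posterior with `Q = 1`:
three inner iterations alternating the acrophase factor and the
amplitude profile (13-point grid). Two statistics summarize the fit:

* `q_fraction` — the posterior probability of non-zero amplitude, with
  *both* the acrophase and the amplitude collapsed against their priors
  (grid quadrature). The amplitude collapse is an explicit Occam factor:
  a flat gene's small spurious-amplitude likelihood peak occupies little
  prior mass and is discounted accordingly, keeping the flat-gene tail
  below the 0.95 threshold.
* `amplitude_residual` — genes are binned into mesor deciles, amplitude
  mean and SD per bin define a piecewise-linear trend and spread, and
  the residual is `(A − trend(μ)) / spread(μ)` (SD floored at 10% of the
  median bin SD). Large positive values flag genes with larger
  amplitudes than their expression level predicts.

Genes with `q_fraction > 0.95` **and** residual > 2 are promoted;
Step 1 re-runs with the enlarged set (warm-started from the conditional
fits); the iteration's state is kept only if the clock evidence does not
decrease and the Bayes factor stays positive (up to 3 iterations). The
returned state is always the best-evidence one, so de novo cyclers can
only sharpen, never degrade, the clock's own explanation.

## Simulators

**Generative-model simulator.** Cell phases are drawn uniformly from
`n_phase_grid` equally spaced values (4 emulates a light-dark time
course sampled every 6 h; 23 emulates unsynchronized cultures); log
library sizes are Normal (defaults: median 10,000 UMIs, SD 0.5 on the
natural-log scale); clock genes come from a canonical 12-gene table with
staggered acrophases (hours after the *Arntl* peak), mesors spanning
proportions 1e-5–1e-3 and amplitudes 0.3–1.0; CCGs draw amplitudes
uniform on [0.3, 1.0], proportions log-uniform on [1e-5, 1e-3] and
uniform acrophases; flat genes draw proportions log-uniform on
[2e-6, 1e-3]. Counts follow the NB model above. Simulation studies use
informative-but-imperfect clock priors: acrophase prior locations are
the truths plus a Normal shift of SD 2 h, with the von Mises scale set
so the central 95% prior interval spans 4 h; the reference gene keeps
its exact acrophase.

**Waveform simulator.** A bulk time-course table of per-gene proportions
(equally spaced, whole 24 h periods) is turned into cells: flat genes
are pinned to their across-timepoint median, library sizes are
log10-normal (mean log10(5000), SD 0.5), counts are Poisson with mean
proportion × library size, and 200 cells per timepoint over a 2 h × 48 h
course yields 4800 cells. The shipped table is synthetic (cosinor
waveforms with a seeded 12 h harmonic admixture and 5% multiplicative
noise, cyclers carrying a small share of total mass so per-timepoint
normalization does not imprint a compensatory rhythm on flat genes); it
exercises the identical code path as a real bulk table, which can be
supplied as TSV. Waveform diagnostics: the circadian FFT fraction
(24 h Fourier amplitude over the sum of all non-DC amplitudes) and a
Poisson likelihood-ratio statistic of the true waveform against the flat
median. Rhythm calls on waveform tables use a cosinor F-test with
Benjamini–Hochberg correction — a deliberately simple harmonic-regression
caller, not a rank-based detector, and labelled as such.

## Evaluation statistics

* **Optimal shift**: a 1-minute-resolution grid search for the global
  rotation minimizing the summed circular error; the reflected estimates
  (θ → −θ) are scored too, because projection methods cannot identify
  the cycle's direction, and the better orientation is reported with a
  flag. Methods with an absolute origin can be evaluated unshifted; both
  modes are exposed.
* **Error**: `(12/π)·arccos(cos(θ − θ̂))` hours, in [0, 12]; summarized
  as right-continuous eCDFs.
* **Calibration**: fraction of cells whose true phase lies inside the
  HDR arcs at each confidence level. HDR arcs are the smallest set of
  cells of a 512-point circular density grid (periodic interpolation of
  the posterior factor) reaching the requested mass.
* **Stability**: per-cell mean absolute circular deviation of repeated
  runs' estimates from their circular mean, in hours; the antipodal
  degenerate case falls back deterministically to the first run's value.
  Density summaries use Gaussian kernels of bandwidth 0.2 h (0.01 h for
  deterministic methods).
* **Out-of-sample clock likelihood**: per clock gene, a Poisson cosinor
  GLM (statsmodels, library size as exposure) fit on training cells with
  a method's phases; the test cells' Poisson log likelihood under the
  method's test phases is standardized against 50 random-uniform-phase
  null scores.
* **Enrichment**: overlap of the de novo set with a target set versus
  1000 random same-size draws from the universe;
  `p = (1 + #{null ≥ observed}) / (n_null + 1)`.
* **PCA-angle baseline**: z-scored log1p library-size-normalized counts,
  top two principal components (SVD, each component oriented so its
  largest-magnitude loading is positive — fully deterministic), phase =
  atan2(PC2, PC1).

## Numerical choices and degenerate inputs

Grid sizes: 64 phase points for fits (0.56 h resolution, refined by the
continuous circular mean for point estimates), 128+ in the oracle tests,
512 for HDR arcs. Amplitude grids: 25 points in Step 1, 13 in Step 2.
The NB log pmf switches to the Poisson limit below δ = 1e-10; an inlined
fast path reuses the count-only gamma terms across the phase grid when
the dispersion is constant (cross-checked against the reference
implementation in the tests). All-zero genes return a flagged flat
summary; empty gene subsets, invalid confidences, mismatched lengths and
non-finite inputs raise. Ties in the circular mean return 0 by
convention except where a specific rule is documented (stability).

## What the simulations do and do not show

The generative fixtures match the model exactly, so recovery and
calibration results certify the inference machinery, not robustness to
model misspecification; the waveform simulator probes one real
mismatch (non-sinusoidal waveforms, Poisson noise) and shows phase
recovery survives it. Not represented: technical/batch effects on the
mean, cell-subpopulation differences in gene parameters, doublets and
ambient RNA, and gene-gene correlation beyond the shared phase. Problem
sizes (500–1000 cells, ~530 genes, 5-run stability) were chosen as the
smallest at which the detection and calibration behaviors are stable;
the engine handles tens of thousands of cells in minutes since all heavy
operations are vectorized over cells.

## Known limitations

A single phase prior is shared by all cells (per-cell collection-time
priors would be a small extension). Mesor/amplitude uncertainty is not
propagated into the phase posterior (MAP treatment) — HDR calibration on
the fixtures shows this costs little there, but it may understate
uncertainty for very sparse genes. The evidence score is a bound-flavored
predictive quantity, not a marginal likelihood; only its comparisons
(across iterations, against the permutation null) are meaningful. De
novo detection inherits the 24 h pure-sinusoid assumption; strongly
non-sinusoidal cyclers are found less reliably.
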