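"""Variational inference for the circadian phase model (Step 1).

The posterior P(theta, beta | X) over cell phases and gene parameters is
approximated by a fully factorized variational distribution

    q(theta, beta) = prod_i q(theta_i) * prod_j q(phi_j) q(Q_j) ,

optimized by coordinate ascent on the evidence lower bound (ELBO). The
circular factors q(theta_i) and q(phi_j) are free-form categorical
distributions on a uniform grid over [0, 2pi) — the *optimal* mean-field
family for these coordinates, so each update is available in closed form
(a softmax of expected log joint terms). Mesor and amplitude are point
(MAP) coordinates updated by profile maximization, and the cycler
indicator Q_j is marginalized analytically against its Beta-Bernoulli
prior, yielding a posterior probability q_gamma_j = q(Q_j = 1).

Because every factor update is a deterministic function of the others, a
fit is exactly reproducible for a fixed seed; the seed only perturbs the
initialization, which is how run-to-run stability is probed.

The expensive inner products all reduce to circular convolutions or
correlations over the phase grid and are evaluated with FFTs, which keeps
full fits on thousands of cells in the seconds-to-minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from ._circular import TWO_PI, circular_mean, kappa_from_resultant, phase_grid, resultant_length, wrap
from .model import CountMatrix, DispersionModel, PriorSpec, nb_log_pmf

__all__ = [
    "FitConfig",
    "VariationalState",
    "EvidenceTrace",
    "initialize_state",
    "elbo",
    "optimize_step1",
    "phase_point_estimates",
    "hdr_interval",
    "credible_arcs",
    "arc_contains",
    "clock_evidence",
    "bayes_factor_vs_permuted",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Settings for one Step-1 variational optimization.

    grid_size: number of phase grid points for the circular factors.
    max_sweeps/tol: coordinate-ascent stops when the ELBO improves by less
        than ``tol`` nats over a sweep (after ``min_sweeps``).
    amp_grid: resolution of the amplitude profile search per gene.
    init_jitter: SD of the seeded log-weight perturbation applied to the
        initial cell phase factors; the only stochastic ingredient.
    """

    grid_size: int = 64
    max_sweeps: int = 30
    min_sweeps: int = 4
    tol: float = 0.05
    amp_grid: int = 25
    init_jitter: float = 0.25
    seed: int = 0


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------


@dataclass
class VariationalState:
    """Variational parameters of q(theta, beta) for the current cycling genes.

    ``log_q_theta`` has one normalized categorical row per cell on ``grid``;
    gene arrays are aligned with ``cycling_genes``. The reference gene's
    acrophase factor is a frozen point mass at 0 radians.
    """

    grid: np.ndarray
    log_q_theta: np.ndarray  # (n_cells, G)
    cycling_genes: list[str]
    q_phi: np.ndarray  # (k, G) probabilities
    mesor: np.ndarray  # (k,) MAP
    amplitude: np.ndarray  # (k,) MAP
    q_gamma: np.ndarray  # (k,) posterior P(Q_j = 1)
    mesor_prior_locs: dict[str, float]
    clock_genes: list[str]
    seed: int
    pseudobulk: dict[str, float] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.log_q_theta.shape[0]

    @property
    def grid_size(self) -> int:
        return self.grid.size

    # Von Mises summaries of the cell phase factors (moment-matched).
    @property
    def q_theta_loc(self) -> np.ndarray:
        return circular_mean(self.grid, weights=np.exp(self.log_q_theta), axis=1)

    @property
    def q_theta_conc(self) -> np.ndarray:
        rbar = resultant_length(
            np.broadcast_to(self.grid, self.log_q_theta.shape),
            weights=np.exp(self.log_q_theta),
            axis=1,
        )
        return kappa_from_resultant(rbar)

    @property
    def q_phi_loc(self) -> np.ndarray:
        return circular_mean(
            np.broadcast_to(self.grid, self.q_phi.shape), weights=self.q_phi, axis=1
        )

    def gene_pos(self, gene: str) -> int:
        return self.cycling_genes.index(gene)

    def copy(self) -> "VariationalState":
        return replace(
            self,
            log_q_theta=self.log_q_theta.copy(),
            cycling_genes=list(self.cycling_genes),
            q_phi=self.q_phi.copy(),
            mesor=self.mesor.copy(),
            amplitude=self.amplitude.copy(),
            q_gamma=self.q_gamma.copy(),
            mesor_prior_locs=dict(self.mesor_prior_locs),
            pseudobulk=dict(self.pseudobulk),
        )


@dataclass
class EvidenceTrace:
    """Per-iteration clock evidence and permutation Bayes factor."""

    log_evidence: list[float] = field(default_factory=list)
    log10_bayes_factor: list[float] = field(default_factory=list)
    n_cycling: list[int] = field(default_factory=list)
    stopping_reason: str = "max_iterations"


# ---------------------------------------------------------------------------
# FFT helpers on the circle
# ---------------------------------------------------------------------------


def circ_conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular convolution along the last axis: out[k] = sum_l a[l] b[k-l]."""
    n = a.shape[-1]
    return np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=n)


def circ_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation along the last axis: out[l] = sum_k a[k] b[k-l].

    Substituting m = k - l gives sum_m a[m+l] b[m], which is
    irfft(rfft(a) * conj(rfft(b)))[l] for real inputs.
    """
    n = a.shape[-1]
    return np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=n)


_circ_corr = circ_corr


def _log_normalize(logw: np.ndarray, axis=-1) -> np.ndarray:
    return logw - special.logsumexp(logw, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_state(
    prior: PriorSpec,
    clock_genes,
    cm: CountMatrix,
    seed: int = 0,
    config: FitConfig | None = None,
) -> VariationalState:
    """Build the initial variational state with clock genes as cyclers.

    Cell phase factors start near the cell phase prior (uniform by default)
    with a small seeded jitter; acrophase factors start at their priors;
    mesors start at the empirical log pseudobulk proportion (the empirical
    Bayes prior location); amplitudes at a moderate 0.3 log units; cycler
    probabilities at their prior means.
    """
    config = config or FitConfig(seed=seed)
    clock_genes = list(clock_genes)
    missing = [g for g in clock_genes if g not in set(cm.gene_ids)]
    if missing:
        raise KeyError(f"clock genes absent from the count matrix: {missing}")
    if prior.reference_gene not in clock_genes:
        raise ValueError(
            f"reference gene {prior.reference_gene!r} must be in the clock list"
        )

    G = config.grid_size
    grid = phase_grid(G)
    rng = np.random.default_rng(seed)

    log_q_theta = prior.cell_prior.log_density(grid)[None, :] + rng.normal(
        0.0, config.init_jitter, size=(cm.n_cells, G)
    )
    log_q_theta = _log_normalize(log_q_theta)

    props = cm.pseudobulk_proportions()
    prop_by_gene = dict(zip(cm.gene_ids, props))
    k = len(clock_genes)
    q_phi = np.empty((k, G))
    mesor = np.empty(k)
    amplitude = np.full(k, 0.3)
    q_gamma = np.empty(k)
    mesor_locs = {}
    for pos, gene in enumerate(clock_genes):
        if gene == prior.reference_gene:
            q_phi[pos] = 0.0
            q_phi[pos, 0] = 1.0
        else:
            logp = prior.acrophase_log_density(gene, grid)
            q_phi[pos] = np.exp(_log_normalize(logp))
        p = prop_by_gene[gene]
        if p <= 0:
            raise ValueError(f"clock gene {gene!r} has zero counts")
        mesor[pos] = np.log(p)
        mesor_locs[gene] = prior.mesor_locs.get(gene, float(np.log(p)))
        q_gamma[pos] = prior.q_prior_prob(gene, clock_genes)

    return VariationalState(
        grid=grid,
        log_q_theta=log_q_theta,
        cycling_genes=clock_genes,
        q_phi=q_phi,
        mesor=mesor,
        amplitude=amplitude,
        q_gamma=q_gamma,
        mesor_prior_locs=mesor_locs,
        clock_genes=clock_genes,
        seed=seed,
        pseudobulk={g: float(prop_by_gene[g]) for g in cm.gene_ids},
    )


# ---------------------------------------------------------------------------
# likelihood tables
# ---------------------------------------------------------------------------


def _diff_table(
    x: np.ndarray,
    lib: np.ndarray,
    mesor: float,
    amplitude: float,
    disp: DispersionModel,
    grid: np.ndarray,
) -> np.ndarray:
    """(n_cells, G) NB log likelihood at each phase *difference* d = theta - phi.

    Inlines the NB log pmf (same formula as :func:`~circaphase.model.nb_log_pmf`,
    cross-checked in the tests) so the count-only gamma terms are computed
    once per cell rather than once per grid point.
    """
    log_lam = mesor + amplitude * np.cos(grid)
    lam = np.exp(log_lam)
    delta = np.broadcast_to(disp(lam), grid.shape)
    means = lib[:, None] * lam[None, :]
    if delta.max() < 1e-10:  # Poisson limit
        return (
            special.xlogy(x[:, None], means)
            - means
            - special.gammaln(x + 1.0)[:, None]
        )
    r = 1.0 / delta
    gln_x1 = special.gammaln(x + 1.0)
    if np.ptp(r) <= 1e-9 * r[0]:
        r0 = r[0]
        gln_xr = special.gammaln(x + r0)[:, None]
        gln_r = special.gammaln(r0)
    else:
        gln_xr = special.gammaln(x[:, None] + r[None, :])
        gln_r = special.gammaln(r)
    return (
        gln_xr
        - gln_r
        - gln_x1[:, None]
        + r * np.log(r / (r + means))
        + x[:, None] * np.log(means / (r + means))
    )


def _flat_loglik(
    x: np.ndarray, lib: np.ndarray, mesor: float, disp: DispersionModel
) -> float:
    lam = np.exp(mesor)
    return float(nb_log_pmf(x, lib * lam, disp(lam)).sum())


def _mesor_given_amplitude(pseudobulk_prop: float, amplitude: np.ndarray) -> np.ndarray:
    """Profile mesor keeping the marginal expected proportion at its
    pseudobulk value: E[exp(A cos)] = I0(A) under near-uniform phases."""
    return np.log(pseudobulk_prop) - np.log(special.i0(amplitude))


# ---------------------------------------------------------------------------
# coordinate updates
# ---------------------------------------------------------------------------


def _update_gene(
    state: VariationalState,
    pos: int,
    x: np.ndarray,
    lib: np.ndarray,
    prior: PriorSpec,
    disp: DispersionModel,
    q_theta: np.ndarray,
    config: FitConfig,
    update_gamma: bool = True,
    update_amplitude: bool = True,
):
    """Update one gene's (A, mu), q(phi) and q_gamma given the phase factors.

    Returns the (n_cells, G) expected sinusoidal log-likelihood profile over
    the *cell phase* grid (for the subsequent q(theta) update) and the flat
    log likelihood.
    """
    gene = state.cycling_genes[pos]
    grid = state.grid
    pb = state.pseudobulk[gene]

    if update_amplitude:
        # amplitude profile search with the mesor tied to the pseudobulk proportion
        w = _circ_corr(q_theta, state.q_phi[pos][None, :])  # (n, G) weights over d
        w = np.clip(w, 0.0, None)
        amps = np.linspace(prior.amp_min, prior.amp_max, config.amp_grid)
        amps = np.clip(amps, 1e-6, None)
        mus = _mesor_given_amplitude(pb, amps)
        scores = np.empty(amps.size)
        for a_idx in range(amps.size):
            table = _diff_table(x, lib, mus[a_idx], amps[a_idx], disp, grid)
            scores[a_idx] = float((w * table).sum())
        scores += prior.amplitude_log_density(amps)
        scores += prior.mesor_log_density(mus, state.mesor_prior_locs[gene])
        best = int(np.argmax(scores))
        # one parabolic refinement around the best grid point
        if 0 < best < amps.size - 1:
            a0, a1, a2 = amps[best - 1: best + 2]
            s0, s1, s2 = scores[best - 1: best + 2]
            denom = (s0 - 2 * s1 + s2)
            if denom < 0:
                a_hat = a1 - 0.5 * (a2 - a1) * (s2 - s0) / denom
                a_hat = float(np.clip(a_hat, a0, a2))
            else:
                a_hat = float(a1)
        else:
            a_hat = float(amps[best])
        state.amplitude[pos] = a_hat
        state.mesor[pos] = float(_mesor_given_amplitude(pb, np.array(a_hat)))

    mu_hat, a_hat = float(state.mesor[pos]), float(state.amplitude[pos])
    table = _diff_table(x, lib, mu_hat, a_hat, disp, grid)  # (n, G) over d

    # acrophase factor update (skip the frozen reference point mass)
    profile = _circ_corr(q_theta, table).sum(axis=0)  # (G,) over phi
    if gene != prior.reference_gene:
        log_prior_phi = prior.acrophase_log_density(gene, grid)
        state.q_phi[pos] = np.exp(_log_normalize(log_prior_phi + profile))

    # cycler indicator update, with the acrophase collapsed against its prior
    flat_ll = _flat_loglik(x, lib, float(np.log(pb)), disp)
    if update_gamma:
        if gene != prior.reference_gene:
            log_mass = _log_normalize(prior.acrophase_log_density(gene, grid))
            sin_ev = float(special.logsumexp(log_mass + profile))
        else:
            sin_ev = float(profile[0])
        a, b = prior.gamma_params(gene, state.clock_genes)
        log_odds = np.log(a / b) + sin_ev - flat_ll
        state.q_gamma[pos] = float(special.expit(log_odds))

    # expected sinusoidal log likelihood over the cell phase grid
    cell_profile = circ_conv(state.q_phi[pos][None, :], table)  # (n, G) over theta
    return cell_profile, flat_ll


def _update_theta(
    state: VariationalState,
    prior: PriorSpec,
    contribs: np.ndarray,
) -> None:
    log_prior_theta = prior.cell_prior.log_density(state.grid)
    state.log_q_theta = _log_normalize(log_prior_theta[None, :] + contribs)


def optimize_step1(
    state: VariationalState,
    cm: CountMatrix,
    prior: PriorSpec,
    disp: DispersionModel,
    config: FitConfig | None = None,
    cell_perms: np.ndarray | None = None,
) -> VariationalState:
    """Coordinate-ascent optimization of q over the current cycling genes.

    Alternates closed-form cell phase factor updates with per-gene
    amplitude/mesor/acrophase/indicator updates until the ELBO improvement
    over a sweep falls below ``config.tol`` nats. Deterministic given the
    state (whose initialization carries the seed).

    ``cell_perms`` (one permutation of the cells per cycling gene) fits
    the permutation-null model instead: gene ``pos``'s observation for
    cell i informs the phase of cell ``cell_perms[pos][i]``, which
    destroys cross-gene phase coherence while keeping every gene's
    count-exposure pairs intact. Used by the Bayes factor diagnostic.
    """
    config = config or FitConfig(seed=state.seed)
    state = state.copy()
    if not state.cycling_genes:
        raise ValueError("cycling gene set is empty")
    idx = cm.gene_index(state.cycling_genes)
    lib = cm.library_size
    xcols = [cm.counts[:, j].astype(float) for j in idx]

    last_elbo = -np.inf
    for sweep in range(config.max_sweeps):
        q_theta = np.exp(state.log_q_theta)
        contribs = np.zeros_like(state.log_q_theta)
        # the first sweep holds gene parameters at their initialization so
        # the phase factors can concentrate before amplitudes are profiled
        # (profiling against diffuse phases collapses into the all-flat
        # saddle point otherwise)
        update_params = sweep > 0
        for pos in range(len(state.cycling_genes)):
            perm = None if cell_perms is None else cell_perms[pos]
            qg = q_theta if perm is None else q_theta[perm]
            cell_profile, _flat = _update_gene(
                state, pos, xcols[pos], lib, prior, disp, qg, config,
                update_gamma=update_params, update_amplitude=update_params,
            )
            if perm is None:
                contribs += state.q_gamma[pos] * cell_profile
            else:  # perm is a bijection, so fancy-index assignment is safe
                contribs[perm] += state.q_gamma[pos] * cell_profile
        _update_theta(state, prior, contribs)

        current = elbo(state, cm, prior, disp, state.cycling_genes, cell_perms=cell_perms)
        if not np.isfinite(current):
            raise FloatingPointError(
                f"ELBO became non-finite at sweep {sweep} "
                f"(genes={state.cycling_genes[:5]}...)"
            )
        if sweep + 1 >= config.min_sweeps and current - last_elbo < config.tol:
            break
        last_elbo = current
    return state


# ---------------------------------------------------------------------------
# ELBO and evidence
# ---------------------------------------------------------------------------


def elbo(
    state: VariationalState,
    cm: CountMatrix,
    prior: PriorSpec,
    disp: DispersionModel,
    gene_subset=None,
    cell_perms: np.ndarray | None = None,
) -> float:
    """Evidence lower bound of the current q, restricted to ``gene_subset``.

    Continuous (differential) entropies are used for the gridded circular
    factors so the value approximates the continuous-model ELBO and is a
    lower bound on the log evidence of the restricted model (with the MAP
    point coordinates entering through their prior densities).
    """
    genes = list(gene_subset) if gene_subset is not None else list(state.cycling_genes)
    if not genes:
        raise ValueError("gene_subset must be non-empty")
    grid = state.grid
    G = grid.size
    dtheta = TWO_PI / G
    q_theta = np.exp(state.log_q_theta)

    total = 0.0
    # cell phase prior and entropy
    log_prior_theta = prior.cell_prior.log_density(grid)
    total += float((q_theta * log_prior_theta[None, :]).sum())
    total += float(-(q_theta * (state.log_q_theta - np.log(dtheta))).sum())

    lib = cm.library_size
    for gene in genes:
        pos = state.gene_pos(gene)
        x = cm.counts[:, cm.gene_index([gene])[0]].astype(float)
        table = _diff_table(x, lib, state.mesor[pos], state.amplitude[pos], disp, grid)
        qg = q_theta if cell_perms is None else q_theta[cell_perms[pos]]
        w = np.clip(_circ_corr(qg, state.q_phi[pos][None, :]), 0.0, None)
        e_sin = float((w * table).sum())
        e_flat = _flat_loglik(x, lib, state.mesor[pos], disp)
        g = float(np.clip(state.q_gamma[pos], 1e-12, 1 - 1e-12))
        total += g * e_sin + (1 - g) * e_flat

        # Q prior + entropy (Beta-Bernoulli marginal)
        p1 = prior.q_prior_prob(gene, state.clock_genes)
        total += g * np.log(p1 / g) + (1 - g) * np.log((1 - p1) / (1 - g))

        # acrophase prior + entropy (absent for the reference point mass)
        if gene != prior.reference_gene:
            qp = np.clip(state.q_phi[pos], 1e-300, None)
            total += float((qp * prior.acrophase_log_density(gene, grid)).sum())
            total += float(-(qp * np.log(qp / dtheta)).sum())

        # MAP point coordinates enter via their prior densities
        total += float(
            prior.mesor_log_density(state.mesor[pos], state.mesor_prior_locs[gene])
        )
        total += float(prior.amplitude_log_density(np.array([state.amplitude[pos]]))[0])
    return float(total)


def clock_evidence(
    state: VariationalState,
    cm: CountMatrix,
    prior: PriorSpec,
    disp: DispersionModel,
    clock_genes=None,
    cell_perms: np.ndarray | None = None,
) -> float:
    """Predictive log evidence score of core clock expression.

    Scores how well the estimated cell phases explain the clock genes'
    counts: it must *improve* when extra cycling genes sharpen the phase
    estimates in a way consistent with the clock, and worsen when they
    drag the phases away from it — this is the stopping signal of the de
    novo loop and the numerator/denominator of the permutation Bayes
    factor.

    The free-form phase factors can soak up a single gene's noise, so each
    gene is scored under *leave-that-gene-out* phase factors (its own
    contribution is subtracted from the cell phase log weights before
    renormalizing). The cycling indicator and the acrophase are collapsed
    analytically against their priors. This makes the score predictive —
    "how well do phases learned from everything else explain this clock
    gene" — which is what both the stopping rule and the permutation null
    need; without the leave-one-out step the score rewards per-gene
    overfitting equally on real and permuted data and their difference is
    dominated by noise.
    """
    genes = list(clock_genes) if clock_genes is not None else list(state.clock_genes)
    if not genes:
        raise ValueError("clock gene list must be non-empty")
    grid = state.grid
    lib = cm.library_size
    total = 0.0
    for gene in genes:
        pos = state.gene_pos(gene)
        x = cm.counts[:, cm.gene_index([gene])[0]].astype(float)
        table = _diff_table(x, lib, state.mesor[pos], state.amplitude[pos], disp, grid)
        contrib = state.q_gamma[pos] * circ_conv(state.q_phi[pos][None, :], table)
        logq = (
            state.log_q_theta
            if cell_perms is None
            else state.log_q_theta[cell_perms[pos]]
        )
        q_loo = np.exp(_log_normalize(logq - contrib))
        profile = _circ_corr(q_loo, table).sum(axis=0)  # over acrophase
        if gene != prior.reference_gene:
            log_mass = _log_normalize(prior.acrophase_log_density(gene, grid))
            sin_ev = float(special.logsumexp(log_mass + profile))
        else:
            sin_ev = float(profile[0])
        pb = state.pseudobulk[gene]
        flat_ll = _flat_loglik(x, lib, float(np.log(pb)), disp)
        p1 = float(np.clip(prior.q_prior_prob(gene, state.clock_genes), 1e-12, 1 - 1e-12))
        total += float(np.logaddexp(np.log(p1) + sin_ev, np.log1p(-p1) + flat_ll))
        total += float(
            prior.mesor_log_density(state.mesor[pos], state.mesor_prior_locs[gene])
        )
        total += float(prior.amplitude_log_density(np.array([state.amplitude[pos]]))[0])
    return float(total)


def bayes_factor_vs_permuted(
    state: VariationalState,
    cm: CountMatrix,
    prior: PriorSpec,
    disp: DispersionModel,
    clock_genes=None,
    seed: int = 0,
    config: FitConfig | None = None,
) -> float:
    """log10 Bayes factor of the fitted clock model against a permuted null.

    The null re-fits the clock model with the cells permuted independently
    within each clock gene (each gene's observations are re-attached to a
    random cell's phase), which destroys any phase coherence *across*
    genes while keeping every count paired with its own cell's library
    size. The difference of the two clock evidences is returned in log10
    units; values near 0 mean the fit explains clock expression no better
    than random phase assignments.
    """
    genes = list(clock_genes) if clock_genes is not None else list(state.clock_genes)
    rng = np.random.default_rng(seed)
    perms = np.vstack([rng.permutation(cm.n_cells) for _ in genes])
    config = config or FitConfig(seed=seed)
    perm_state = initialize_state(prior, genes, cm, seed=seed, config=config)
    perm_state.clock_genes = list(state.clock_genes)
    perm_state = optimize_step1(perm_state, cm, prior, disp, config, cell_perms=perms)
    ev_real = clock_evidence(state, cm, prior, disp, genes)
    ev_perm = clock_evidence(perm_state, cm, prior, disp, genes, cell_perms=perms)
    return float((ev_real - ev_perm) / np.log(10.0))


# ---------------------------------------------------------------------------
# point estimates and credible regions
# ---------------------------------------------------------------------------


def phase_point_estimates(state: VariationalState) -> np.ndarray:
    """Circular posterior mean phase per cell, in [0, 2pi)."""
    return state.q_theta_loc


def _density_on_fine_grid(state: VariationalState, cell: int, n_points: int = 512):
    """Periodic linear interpolation of the cell's log density onto a fine grid."""
    fine = phase_grid(n_points)
    coarse = np.concatenate([state.grid, [TWO_PI]])
    logq = state.log_q_theta[cell] - np.log(TWO_PI / state.grid_size)  # log density
    logq = np.concatenate([logq, [logq[0]]])
    dens = np.exp(np.interp(fine, coarse, logq))
    mass = dens / dens.sum()
    return fine, mass


def hdr_interval(state: VariationalState, cell: int, confidence: float, n_points: int = 512):
    """Highest-density-region credible arcs for one cell's phase posterior.

    Returns a list of ``(start, end)`` arcs in radians with ``start < end``
    (``end`` may exceed 2pi for arcs that wrap through 0); their total mass
    on a ``n_points`` circular density grid is the smallest set of grid
    cells reaching ``confidence``.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    fine, mass = _density_on_fine_grid(state, cell, n_points)
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    n_take = int(np.searchsorted(cum, confidence) + 1)
    selected = np.zeros(n_points, dtype=bool)
    selected[order[:n_take]] = True
    return _mask_to_arcs(selected, fine, TWO_PI / n_points)


def credible_arcs(state: VariationalState, levels, n_points: int = 512):
    """HDR arcs for every cell at each confidence level.

    Returns ``{level: [arcs_for_cell_0, arcs_for_cell_1, ...]}``.
    """
    out = {float(lv): [] for lv in levels}
    for cell in range(state.n_cells):
        fine, mass = _density_on_fine_grid(state, cell, n_points)
        order = np.argsort(mass)[::-1]
        cum = np.cumsum(mass[order])
        for lv in levels:
            n_take = int(np.searchsorted(cum, lv) + 1)
            selected = np.zeros(n_points, dtype=bool)
            selected[order[:n_take]] = True
            out[float(lv)].append(_mask_to_arcs(selected, fine, TWO_PI / n_points))
    return out


def _mask_to_arcs(mask: np.ndarray, grid: np.ndarray, step: float):
    n = mask.size
    if mask.all():
        return [(0.0, TWO_PI)]
    # rotate so the scan starts at an unselected point, then collect runs
    start0 = int(np.argmin(mask))
    arcs = []
    run_start = None
    for off in range(n + 1):
        k = (start0 + off) % n
        if off < n and mask[k]:
            if run_start is None:
                run_start = k
            run_end = k
        else:
            if run_start is not None:
                lo = grid[run_start] - step / 2
                hi = grid[run_end] + step / 2
                if hi <= lo:
                    hi += TWO_PI
                arcs.append((float(lo), float(hi)))
                run_start = None
    return arcs


def arc_contains(arcs, theta: float) -> bool:
    """Whether angle ``theta`` lies in any of the circular arcs."""
    for lo, hi in arcs:
        if wrap(np.asarray(theta - lo)) <= (hi - lo) + 1e-12:
            return True
    return False
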