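"""De novo cycler detection (Step 2) and the outer inference loop.

After Step 1 produces cell phase posteriors from the current cycling genes,
every other sufficiently expressed gene is fit *conditionally* on those
posteriors with its cycling indicator forced on (Q_j = 1). Two statistics
summarize each fit:

* ``q_fraction`` — the posterior probability that the gene has non-zero
  amplitude (the fraction of posterior indicator samples that are 1);
* ``amplitude_residual`` — a Pearson residual of the gene's MAP amplitude
  against the amplitude expected for its MAP mesor, estimated from the
  mesor-binned amplitude trend across all candidate genes. Large positive
  values flag genes whose amplitude is larger than their expression level
  predicts.

Genes passing both thresholds (defaults: q_fraction > 0.95 and residual > 2)
are added to the cycling set and Step 1 re-runs. The loop stops when the
Bayesian evidence of the core clock genes worsens, when the fit is no better
than a permuted-matrix null (log10 Bayes factor <= 0), or at the iteration
cap; the state from the best-evidence iteration is returned, so de novo
cyclers are only kept when they help explain clock expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ._circular import circular_mean, radians_to_hours
from .inference import (
    EvidenceTrace,
    FitConfig,
    VariationalState,
    _diff_table,
    _flat_loglik,
    _log_normalize,
    _mesor_given_amplitude,
    bayes_factor_vs_permuted,
    circ_conv,
    circ_corr,
    clock_evidence,
    credible_arcs,
    initialize_state,
    optimize_step1,
    phase_point_estimates,
)
from .model import CountMatrix, DispersionModel, PriorSpec, fit_dispersion_model

__all__ = [
    "GeneFitSummary",
    "PipelineConfig",
    "PhaseReport",
    "conditional_gene_fit",
    "amplitude_pearson_residual",
    "select_de_novo",
    "run_pipeline",
]


@dataclass
class GeneFitSummary:
    """MAP parameters and detection statistics for one conditionally fit gene."""

    gene_id: str
    mesor: float
    amplitude: float
    acrophase: float
    q_fraction: float
    amplitude_residual: float = np.nan
    flagged: bool = False  # all-zero/degenerate gene
    q_phi: np.ndarray | None = None  # fitted acrophase factor, for warm starts


@dataclass
class PipelineConfig:
    """End-to-end settings for the two-step inference loop."""

    fit: FitConfig = field(default_factory=FitConfig)
    max_iterations: int = 3
    q_threshold: float = 0.95
    residual_threshold: float = 2.0
    proportion_floor: float = 1e-5
    credible_levels: tuple = (0.5, 0.8, 0.95)
    compute_bayes_factor: bool = True
    step2_inner_iters: int = 3
    step2_amp_grid: int = 13


@dataclass
class PhaseReport:
    """Per-cell phase estimates with credible arcs, plus the cycler list."""

    cell_ids: list[str]
    phase_radians: np.ndarray
    phase_hours: np.ndarray
    credible_arcs: dict  # level -> list of arc lists per cell
    cycling_genes: list[str]
    de_novo_genes: list[str]
    gene_summaries: list[GeneFitSummary]
    stopping_reason: str


# ---------------------------------------------------------------------------
# Step 2: conditional gene fits
# ---------------------------------------------------------------------------


def conditional_gene_fit(
    gene: str,
    state: VariationalState,
    cm: CountMatrix,
    prior: PriorSpec,
    disp: DispersionModel,
    config: PipelineConfig | None = None,
) -> GeneFitSummary:
    """Fit one gene's sinusoidal parameters holding cell phases fixed.

    The cell phase factors of ``state`` are frozen; the gene's acrophase
    factor, amplitude and mesor are optimized with the cycling indicator
    set to 1. ``q_fraction`` is the posterior indicator probability with
    the acrophase collapsed against its prior (so a gene whose apparent
    amplitude relies on one lucky phase alignment is penalized by how
    little prior mass that alignment carries).
    """
    config = config or PipelineConfig()
    j = cm.gene_index([gene])[0]
    x = cm.counts[:, j].astype(float)
    lib = cm.library_size
    total = x.sum()
    if total == 0:
        return GeneFitSummary(gene, -np.inf, 0.0, 0.0, 0.0, flagged=True)
    pb = float(total / lib.sum())
    grid = state.grid
    q_theta = np.exp(state.log_q_theta)
    log_prior_phi = (
        prior.acrophase_log_density(gene, grid)
        if gene != prior.reference_gene
        else None
    )
    if log_prior_phi is None:  # reference gene: point mass at 0
        q_phi = np.zeros(grid.size)
        q_phi[0] = 1.0
    else:
        q_phi = np.exp(_log_normalize(log_prior_phi))

    amp = 0.3
    mu = float(_mesor_given_amplitude(pb, np.array(amp)))
    profile = None
    for it in range(config.step2_inner_iters):
        # acrophase factor given (mu, A)
        table = _diff_table(x, lib, mu, amp, disp, grid)
        profile = circ_corr(q_theta, table).sum(axis=0)
        if log_prior_phi is not None:
            q_phi = np.exp(_log_normalize(log_prior_phi + profile))
        # amplitude profile given q(phi)
        w = np.clip(circ_corr(q_theta, q_phi[None, :]), 0.0, None)
        amps = np.clip(
            np.linspace(prior.amp_min, prior.amp_max, config.step2_amp_grid), 1e-6, None
        )
        mus = _mesor_given_amplitude(pb, amps)
        scores = np.array(
            [
                (w * _diff_table(x, lib, mus[k], amps[k], disp, grid)).sum()
                for k in range(amps.size)
            ]
        )
        scores += prior.amplitude_log_density(amps)
        best = int(np.argmax(scores))
        if 0 < best < amps.size - 1:
            s0, s1, s2 = scores[best - 1: best + 2]
            denom = s0 - 2 * s1 + s2
            if denom < 0:
                step = amps[1] - amps[0]
                amp = float(
                    np.clip(
                        amps[best] - 0.5 * step * (s2 - s0) / denom,
                        amps[best - 1],
                        amps[best + 1],
                    )
                )
            else:
                amp = float(amps[best])
        else:
            amp = float(amps[best])
        mu = float(_mesor_given_amplitude(pb, np.array(amp)))

    # collapsed indicator update: the sinusoidal branch evidence integrates
    # the acrophase AND the amplitude against their priors on the grids, so
    # a flat gene's small spurious-amplitude likelihood peak is discounted
    # by the little prior mass it occupies (an explicit Occam factor)
    amps = np.clip(
        np.linspace(prior.amp_min, prior.amp_max, config.step2_amp_grid), 1e-6, None
    )
    mus = _mesor_given_amplitude(pb, amps)
    log_mass_a = prior.amplitude_log_density(amps) + np.log(amps[1] - amps[0])
    if log_prior_phi is not None:
        log_mass_phi = _log_normalize(log_prior_phi)
    per_amp = np.empty(amps.size)
    for k in range(amps.size):
        prof_k = circ_corr(q_theta, _diff_table(x, lib, mus[k], amps[k], disp, grid)).sum(axis=0)
        if log_prior_phi is not None:
            per_amp[k] = special.logsumexp(log_mass_phi + prof_k)
        else:
            per_amp[k] = prof_k[0]
    sin_ev = float(special.logsumexp(log_mass_a + per_amp))

    # final acrophase factor at the MAP parameters
    table = _diff_table(x, lib, mu, amp, disp, grid)
    profile = circ_corr(q_theta, table).sum(axis=0)
    if log_prior_phi is not None:
        q_phi = np.exp(_log_normalize(log_prior_phi + profile))
    flat_ll = _flat_loglik(x, lib, float(np.log(pb)), disp)
    a, b = prior.gamma_params(gene, state.clock_genes)
    q_frac = float(special.expit(np.log(a / b) + sin_ev - flat_ll))

    acro = float(circular_mean(grid, weights=q_phi))
    return GeneFitSummary(gene, mu, amp, acro, q_frac, q_phi=q_phi)


def amplitude_pearson_residual(summaries, n_bins: int = 10):
    """Pearson residual of each gene's MAP amplitude given its MAP mesor.

    Genes are binned into mesor deciles; the amplitude mean and SD per bin
    define a piecewise-linear trend and spread, and the residual is
    (amplitude - trend(mesor)) / spread(mesor). Residuals are written back
    onto the summaries and also returned as an array.
    """
    summaries = list(summaries)
    if len(summaries) < 50:
        raise ValueError("need at least 50 gene summaries for a stable trend")
    mesors = np.array([s.mesor for s in summaries])
    amps = np.array([s.amplitude for s in summaries])
    usable = np.isfinite(mesors)

    if np.ptp(mesors[usable]) < 1e-9:  # degenerate: constant mesor
        mean, sd = amps[usable].mean(), amps[usable].std()
        sd = max(sd, 1e-6)
        resid = (amps - mean) / sd
    else:
        edges = np.quantile(mesors[usable], np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        nb = len(edges) - 1
        which = np.clip(np.searchsorted(edges, mesors, side="right") - 1, 0, nb - 1)
        centers, means, sds = [], [], []
        for b in range(nb):
            sel = usable & (which == b)
            if sel.sum() < 3:
                continue
            centers.append(mesors[sel].mean())
            means.append(amps[sel].mean())
            sds.append(amps[sel].std(ddof=1))
        centers = np.array(centers)
        order = np.argsort(centers)
        centers, means, sds = centers[order], np.array(means)[order], np.array(sds)[order]
        sd_floor = max(1e-6, 0.1 * float(np.median(sds)))
        trend = np.interp(mesors, centers, means)
        spread = np.maximum(np.interp(mesors, centers, sds), sd_floor)
        resid = (amps - trend) / spread

    resid = np.where(usable, resid, -np.inf)
    for s, r in zip(summaries, resid):
        s.amplitude_residual = float(r)
    return resid


def select_de_novo(
    summaries,
    q_threshold: float = 0.95,
    residual_threshold: float = 2.0,
    exclude=(),
) -> list[str]:
    """Genes passing both detection thresholds, excluding current cyclers."""
    exclude = set(exclude)
    out = []
    for s in summaries:
        if s.gene_id in exclude or s.flagged:
            continue
        if s.q_fraction > q_threshold and s.amplitude_residual > residual_threshold:
            out.append(s.gene_id)
    return out


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------


def _step2(state, cm, prior, disp, config) -> list[GeneFitSummary]:
    props = cm.pseudobulk_proportions()
    cycling = set(state.cycling_genes)
    candidates = [
        g
        for g, p in zip(cm.gene_ids, props)
        if g not in cycling and p > config.proportion_floor
    ]
    summaries = [
        conditional_gene_fit(g, state, cm, prior, disp, config) for g in candidates
    ]
    if len(summaries) >= 50:
        amplitude_pearson_residual(summaries)
    else:
        for s in summaries:
            s.amplitude_residual = -np.inf
    return summaries


def _extend_state(state: VariationalState, summaries, genes, prior) -> VariationalState:
    by_id = {s.gene_id: s for s in summaries}
    state = state.copy()
    for g in genes:
        s = by_id[g]
        state.cycling_genes.append(g)
        state.q_phi = np.vstack([state.q_phi, s.q_phi[None, :]])
        state.mesor = np.append(state.mesor, s.mesor)
        state.amplitude = np.append(state.amplitude, s.amplitude)
        state.q_gamma = np.append(state.q_gamma, s.q_fraction)
        state.mesor_prior_locs.setdefault(g, np.log(state.pseudobulk[g]))
    return state


def run_pipeline(
    cm: CountMatrix,
    prior: PriorSpec,
    clock_genes,
    config: PipelineConfig | None = None,
    disp: DispersionModel | None = None,
):
    """Full two-step inference: phase estimation + de novo cycler detection.

    Returns ``(PhaseReport, EvidenceTrace, VariationalState)`` where the
    state is the one from the best clock-evidence iteration.
    """
    config = config or PipelineConfig()
    clock_genes = list(clock_genes)
    if disp is None:
        try:
            disp = fit_dispersion_model(cm, proportion_floor=config.proportion_floor)
        except ValueError:
            disp = DispersionModel.constant(0.1)

    state = initialize_state(prior, clock_genes, cm, seed=config.fit.seed, config=config.fit)
    state = optimize_step1(state, cm, prior, disp, config.fit)
    trace = EvidenceTrace()
    ev = clock_evidence(state, cm, prior, disp, clock_genes)
    bf = (
        bayes_factor_vs_permuted(
            state, cm, prior, disp, clock_genes, seed=config.fit.seed, config=config.fit
        )
        if config.compute_bayes_factor
        else np.nan
    )
    trace.log_evidence.append(ev)
    trace.log10_bayes_factor.append(bf)
    trace.n_cycling.append(len(state.cycling_genes))

    best_state, best_ev = state, ev
    all_summaries: list[GeneFitSummary] = []
    de_novo: list[str] = []

    if config.compute_bayes_factor and bf <= 0:
        trace.stopping_reason = "worse_than_random"
    else:
        for _ in range(1, config.max_iterations):
            summaries = _step2(best_state, cm, prior, disp, config)
            all_summaries = summaries
            new = select_de_novo(
                summaries,
                config.q_threshold,
                config.residual_threshold,
                exclude=best_state.cycling_genes,
            )
            new = [g for g in new if g not in set(de_novo)]
            if not new:
                trace.stopping_reason = "no_new_cyclers"
                break
            cand_state = _extend_state(best_state, summaries, new, prior)
            cand_state = optimize_step1(cand_state, cm, prior, disp, config.fit)
            ev = clock_evidence(cand_state, cm, prior, disp, clock_genes)
            bf = (
                bayes_factor_vs_permuted(
                    cand_state, cm, prior, disp, clock_genes,
                    seed=config.fit.seed, config=config.fit,
                )
                if config.compute_bayes_factor
                else np.nan
            )
            trace.log_evidence.append(ev)
            trace.log10_bayes_factor.append(bf)
            trace.n_cycling.append(len(cand_state.cycling_genes))
            if ev < best_ev:
                trace.stopping_reason = "evidence_worsened"
                break
            if config.compute_bayes_factor and bf <= 0:
                trace.stopping_reason = "worse_than_random"
                break
            best_state, best_ev = cand_state, ev
            de_novo.extend(new)

    phases = phase_point_estimates(best_state)
    arcs = credible_arcs(best_state, config.credible_levels)
    report = PhaseReport(
        cell_ids=list(cm.cell_ids),
        phase_radians=phases,
        phase_hours=radians_to_hours(phases),
        credible_arcs=arcs,
        cycling_genes=list(best_state.cycling_genes),
        de_novo_genes=de_novo,
        gene_summaries=all_summaries,
        stopping_reason=trace.stopping_reason,
    )
    return report, trace, best_state
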