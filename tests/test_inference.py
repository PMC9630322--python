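"""Variational engine: initialization, ELBO bounds, recovery, HDR intervals."""

import numpy as np
import pytest
from scipy import special, stats

import circaphase as cp
from circaphase._circular import phase_grid
from circaphase.inference import _log_normalize, circ_conv, circ_corr
from circaphase.model import nb_log_pmf


def _circular_correlation(a, b):
    """Fisher-Lee circular correlation coefficient."""
    abar = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    bbar = np.arctan2(np.sin(b).mean(), np.cos(b).mean())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    return (sa * sb).sum() / np.sqrt((sa**2).sum() * (sb**2).sum())


class TestFFTHelpers:
    def test_match_brute_force(self, rng):
        G = 16
        a, b = rng.normal(size=G), rng.normal(size=G)
        conv = np.array([sum(a[l] * b[(k - l) % G] for l in range(G)) for k in range(G)])
        corr = np.array([sum(a[k] * b[(k - l) % G] for k in range(G)) for l in range(G)])
        np.testing.assert_allclose(circ_conv(a, b), conv, atol=1e-10)
        np.testing.assert_allclose(circ_corr(a, b), corr, atol=1e-10)


class TestInitializeState:
    def test_clock_genes_become_cyclers(self, small_sim, clock_genes):
        st = cp.initialize_state(small_sim["prior"], clock_genes, small_sim["cm"], seed=0)
        assert st.cycling_genes == clock_genes
        assert len(st.cycling_genes) == 12

    def test_mesor_is_log_pseudobulk_proportion(self, small_sim, clock_genes):
        st = cp.initialize_state(small_sim["prior"], clock_genes, small_sim["cm"], seed=0)
        props = small_sim["cm"].pseudobulk_proportions()
        j = small_sim["cm"].gene_index([clock_genes[3]])[0]
        assert np.isclose(st.mesor[3], np.log(props[j]))

    def test_same_seed_bit_identical(self, small_sim, clock_genes):
        a = cp.initialize_state(small_sim["prior"], clock_genes, small_sim["cm"], seed=9)
        b = cp.initialize_state(small_sim["prior"], clock_genes, small_sim["cm"], seed=9)
        np.testing.assert_array_equal(a.log_q_theta, b.log_q_theta)
        np.testing.assert_array_equal(a.q_phi, b.q_phi)

    def test_missing_clock_gene_named_in_error(self, small_sim, clock_genes):
        with pytest.raises(KeyError, match="Nonexistent1"):
            cp.initialize_state(
                small_sim["prior"], clock_genes + ["Nonexistent1"], small_sim["cm"], seed=0
            )


def _one_gene_instance(reference: bool, n_cells=2, seed=0, grid_size=128):
    """Tiny instance: one gene, two cells, known data; returns the pieces."""
    rng = np.random.default_rng(seed)
    lib = np.array([5000.0, 8000.0][:n_cells])
    x = np.array([3.0, 1.0][:n_cells])
    cm = cp.CountMatrix(
        counts=x[:, None].astype(int),
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=["g"],
        library_size=lib,
    )
    ref = "g" if reference else "OTHER"
    prior = cp.PriorSpec(reference_gene=ref, clock_gamma_alpha=9.0, clock_gamma_beta=1.0)
    disp = cp.DispersionModel.constant(0.2)
    fc = cp.FitConfig(grid_size=grid_size, seed=seed, tol=1e-4, max_sweeps=80)
    st = cp.initialize_state(prior, ["g"] if reference else ["g", "OTHER"][:1], cm,
                             seed=seed, config=fc) if reference else None
    if not reference:
        # build by hand: "g" is an ordinary (non-reference) cycling gene
        grid = phase_grid(grid_size)
        logu = np.full((n_cells, grid_size), -np.log(grid_size))
        props = cm.pseudobulk_proportions()
        st = cp.VariationalState(
            grid=grid,
            log_q_theta=_log_normalize(logu + rng.normal(0, 0.1, (n_cells, grid_size))),
            cycling_genes=["g"],
            q_phi=np.full((1, grid_size), 1.0 / grid_size),
            mesor=np.array([np.log(props[0])]),
            amplitude=np.array([0.3]),
            q_gamma=np.array([0.9]),
            mesor_prior_locs={"g": float(np.log(props[0]))},
            clock_genes=["g"],
            seed=seed,
            pseudobulk={"g": float(props[0])},
        )
    return cm, prior, disp, fc, st


def _quadrature_evidence(cm, prior, disp, state, reference: bool, n_theta=1024, n_phi=256):
    """Brute-force log evidence at the state's MAP (mesor, amplitude).

    Integrates the cell phases (and, for a non-reference gene, the
    acrophase) over fine grids and sums the cycling indicator against its
    Beta-Bernoulli marginal prior. Includes the same point-parameter prior
    densities the ELBO carries.
    """
    mu, amp = float(state.mesor[0]), float(state.amplitude[0])
    x = cm.counts[:, 0].astype(float)
    lib = cm.library_size
    thetas = phase_grid(n_theta)

    def per_cell_loglik(phi):
        lam = np.exp(mu + amp * np.cos(thetas[None, :] - phi))
        delta = disp(lam)
        return nb_log_pmf(x[:, None], lib[:, None] * lam, delta)  # (n, n_theta)

    def integrate_cells(phi):
        ll = per_cell_loglik(phi)
        # uniform cell prior: evidence_i = log mean_theta p(x_i | theta)
        return special.logsumexp(ll, axis=1) - np.log(n_theta)

    p1 = prior.q_prior_prob("g", state.clock_genes)
    flat = nb_log_pmf(x, lib * np.exp(mu), float(disp(np.exp(mu)))).sum()
    if reference:
        sin_branch = integrate_cells(0.0).sum()
    else:
        phis = phase_grid(n_phi)
        per_phi = np.array([integrate_cells(p).sum() for p in phis])
        sin_branch = float(special.logsumexp(per_phi) - np.log(n_phi))
    evidence = float(np.logaddexp(np.log(p1) + sin_branch, np.log1p(-p1) + flat))
    evidence += float(prior.mesor_log_density(mu, state.mesor_prior_locs["g"]))
    evidence += float(prior.amplitude_log_density(np.array([amp]))[0])
    return evidence


class TestElboBounds:
    def test_elbo_tight_for_conditionally_independent_instance(self):
        # reference gene: acrophase fixed, cells independent given the MAP
        # parameters -> the free-form mean field is exact and the ELBO must
        # match the quadrature evidence to within grid error
        cm, prior, disp, fc, st = _one_gene_instance(reference=True)
        st = cp.optimize_step1(st, cm, prior, disp, fc)
        bound = cp.elbo(st, cm, prior, disp)
        evidence = _quadrature_evidence(cm, prior, disp, st, reference=True)
        assert bound <= evidence + 1e-6
        assert evidence - bound < 0.1

    def test_elbo_below_quadrature_with_free_acrophase(self):
        cm, prior, disp, fc, st = _one_gene_instance(reference=False)
        st = cp.optimize_step1(st, cm, prior, disp, fc)
        bound = cp.elbo(st, cm, prior, disp)
        evidence = _quadrature_evidence(cm, prior, disp, st, reference=False)
        assert bound <= evidence + 1e-6

    def test_grid_refinement_changes_elbo_little(self):
        vals = []
        for G in (64, 128, 256):
            cm, prior, disp, fc, st = _one_gene_instance(reference=True, grid_size=G)
            st = cp.optimize_step1(st, cm, prior, disp, fc)
            vals.append(cp.elbo(st, cm, prior, disp))
        assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0]) + 0.05
        assert abs(vals[2] - vals[0]) < 0.1


class TestOptimizeStep1:
    def test_phase_recovery_on_generative_simulation(
        self, small_sim, fitted_state
    ):
        est = cp.phase_point_estimates(fitted_state)
        shift = cp.optimal_shift(est, small_sim["phases"])
        aligned = cp.apply_shift(est, shift)
        rho = abs(_circular_correlation(aligned, small_sim["phases"]))
        assert rho > 0.8
        assert np.median(cp.phase_error_hours(small_sim["phases"], est)) < 2.5

    def test_flat_genes_do_not_induce_spurious_certainty(
        self, flat_sim, fitted_state, clock_genes, disp
    ):
        fc = cp.FitConfig(seed=3)
        st = cp.initialize_state(flat_sim["prior"], clock_genes, flat_sim["cm"],
                                 seed=3, config=fc)
        st = cp.optimize_step1(st, flat_sim["cm"], flat_sim["prior"], disp, fc)
        flat_conc = np.median(st.q_theta_conc)
        informative_conc = np.median(fitted_state.q_theta_conc)
        assert flat_conc < informative_conc / 3

    def test_single_gene_single_cell_runs(self):
        cm = cp.CountMatrix(
            counts=np.array([[4]]), cell_ids=["c"], gene_ids=["g"],
            library_size=np.array([1000.0]),
        )
        prior = cp.PriorSpec(reference_gene="g")
        fc = cp.FitConfig(grid_size=32, seed=0)
        st = cp.initialize_state(prior, ["g"], cm, seed=0, config=fc)
        st = cp.optimize_step1(st, cm, prior, cp.DispersionModel.constant(0.1), fc)
        val = cp.elbo(st, cm, prior, cp.DispersionModel.constant(0.1))
        assert np.isfinite(val)

    def test_deterministic_given_seed(self, small_sim, clock_genes, disp):
        fc = cp.FitConfig(seed=17, max_sweeps=6)
        runs = []
        for _ in range(2):
            st = cp.initialize_state(small_sim["prior"], clock_genes,
                                     small_sim["cm"], seed=17, config=fc)
            st = cp.optimize_step1(st, small_sim["cm"], small_sim["prior"], disp, fc)
            runs.append(cp.phase_point_estimates(st))
        np.testing.assert_array_equal(runs[0], runs[1])


class TestPointEstimatesAndHDR:
    def _von_mises_state(self, loc=1.0, conc=5.0, grid_size=256):
        grid = phase_grid(grid_size)
        logq = _log_normalize(conc * np.cos(grid - loc)[None, :])
        return cp.VariationalState(
            grid=grid, log_q_theta=logq, cycling_genes=["g"],
            q_phi=np.full((1, grid_size), 1.0 / grid_size),
            mesor=np.array([-8.0]), amplitude=np.array([0.5]),
            q_gamma=np.array([0.9]), mesor_prior_locs={"g": -8.0},
            clock_genes=["g"], seed=0, pseudobulk={"g": 1e-4},
        )

    def test_point_estimate_is_symmetric_mode(self):
        st = self._von_mises_state(loc=1.0, conc=5.0)
        assert abs(cp.phase_point_estimates(st)[0] - 1.0) < 1e-6

    def test_point_estimate_wraps(self):
        st = self._von_mises_state(loc=0.1)
        val = cp.phase_point_estimates(st)[0]
        assert 0 <= val < 2 * np.pi and abs(val - 0.1) < 1e-6

    def test_point_estimate_matches_sampling_oracle(self, rng):
        st = self._von_mises_state(loc=2.3, conc=3.0)
        probs = np.exp(st.log_q_theta[0])
        draws = rng.choice(st.grid, size=10**5, p=probs / probs.sum())
        oracle = np.arctan2(np.sin(draws).mean(), np.cos(draws).mean()) % (2 * np.pi)
        assert abs(cp.phase_point_estimates(st)[0] - oracle) < 0.01

    def test_hdr_symmetric_single_arc(self):
        st = self._von_mises_state(loc=np.pi, conc=8.0)
        arcs = cp.hdr_interval(st, 0, 0.95)
        assert len(arcs) == 1
        lo, hi = arcs[0]
        cell = 2 * np.pi / 512
        assert abs((lo + hi) / 2 - np.pi) < 2 * cell

    def test_hdr_approaches_full_circle(self):
        st = self._von_mises_state(conc=1.0)
        arcs = cp.hdr_interval(st, 0, 0.9999)
        total = sum(hi - lo for lo, hi in arcs)
        assert total > 2 * np.pi * 0.99

    def test_hdr_mass_bracketed_by_quadrature(self):
        st = self._von_mises_state(loc=1.7, conc=4.0)
        for conf in (0.5, 0.8, 0.95):
            arcs = cp.hdr_interval(st, 0, conf)
            mass, _ = _vm_mass_in_arcs(arcs, loc=1.7, conc=4.0)
            two_cells = 2 * (2 * np.pi / 512) * stats.vonmises(4.0).pdf(0.0)
            assert conf - 0.01 <= mass <= conf + two_cells + 0.01

    def test_invalid_confidence(self):
        st = self._von_mises_state()
        with pytest.raises(ValueError):
            cp.hdr_interval(st, 0, 1.5)


def _vm_mass_in_arcs(arcs, loc, conc):
    from scipy import integrate

    total = 0.0
    for lo, hi in arcs:
        val, err = integrate.quad(
            lambda t: stats.vonmises(conc, loc=loc).pdf(((t - loc + np.pi) % (2 * np.pi)) - np.pi + loc),
            lo, hi, limit=400,
        )
        total += val
    return total, err


class TestEvidenceAndBayesFactor:
    def test_evidence_deterministic(self, fitted_state, small_sim, disp):
        a = cp.clock_evidence(fitted_state, small_sim["cm"], small_sim["prior"], disp)
        b = cp.clock_evidence(fitted_state, small_sim["cm"], small_sim["prior"], disp)
        assert a == b

    def test_optimized_fit_beats_unoptimized(self, small_sim, clock_genes,
                                             fitted_state, disp):
        raw = cp.initialize_state(small_sim["prior"], clock_genes, small_sim["cm"], seed=3)
        ev_raw = cp.clock_evidence(raw, small_sim["cm"], small_sim["prior"], disp)
        ev_fit = cp.clock_evidence(fitted_state, small_sim["cm"], small_sim["prior"], disp)
        assert ev_fit > ev_raw

    def test_bayes_factor_reproducible_and_positive_on_rhythms(
        self, fitted_state, small_sim, disp
    ):
        fc = cp.FitConfig(seed=3)
        a = cp.bayes_factor_vs_permuted(fitted_state, small_sim["cm"],
                                        small_sim["prior"], disp, seed=11, config=fc)
        b = cp.bayes_factor_vs_permuted(fitted_state, small_sim["cm"],
                                        small_sim["prior"], disp, seed=11, config=fc)
        assert a == b
        assert a > 2  # strongly rhythmic positive control
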