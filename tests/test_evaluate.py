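"""Evaluation statistics: shifting, errors, calibration, stability, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import circaphase as cp
from circaphase._circular import TWO_PI, wrap


class TestOptimalShift:
    def test_identity_when_estimates_equal_truths(self, rng):
        t = rng.uniform(0, TWO_PI, 50)
        res = cp.optimal_shift(t, t, allow_reflection=False)
        assert min(res.shift, TWO_PI - res.shift) < TWO_PI / (24 * 60) + 1e-9

    def test_constant_offset_recovered(self, rng):
        t = rng.uniform(0, TWO_PI, 50)
        res = cp.optimal_shift(wrap(t + 1.3), t, allow_reflection=False)
        assert abs(res.shift - 1.3) < TWO_PI / (24 * 60) + 1e-9

    def test_reflection_detected(self, rng):
        t = rng.uniform(0, TWO_PI, 200)
        res = cp.optimal_shift(wrap(-t + 0.7), t)
        assert res.reflected
        aligned = cp.apply_shift(wrap(-t + 0.7), res)
        assert np.median(cp.phase_error_hours(t, aligned)) < 0.05

    def test_matches_fine_grid_brute_force(self, rng):
        for _ in range(20):
            t = rng.uniform(0, TWO_PI, 30)
            est = wrap(t + rng.uniform(0, TWO_PI) + rng.normal(0, 0.3, 30))
            coarse = cp.optimal_shift(est, t, allow_reflection=False)
            fine = cp.optimal_shift(est, t, n_grid=24 * 60 * 60, allow_reflection=False)
            # the objective is piecewise linear with per-term slope +-1, so
            # its minimum is generally a flat interval (location inside it is
            # arbitrary) and a 1-minute grid can overshoot the continuum
            # optimum by at most n * step/2 in objective value
            step = TWO_PI / (24 * 60)
            assert coarse.total_error <= fine.total_error + len(t) * step / 2

    @given(c=st.floats(0, 2 * np.pi))
    @settings(deadline=None, max_examples=25)
    def test_shift_equivariance(self, c):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, TWO_PI, 40)
        est = wrap(t + rng.normal(0, 0.2, 40))
        base = cp.optimal_shift(est, t, allow_reflection=False).shift
        moved = cp.optimal_shift(wrap(est + c), t, allow_reflection=False).shift
        d = abs(wrap(np.array(moved - base - c)))
        assert min(float(d), TWO_PI - float(d)) < 2 * TWO_PI / (24 * 60) + 1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cp.optimal_shift([0.0, 1.0], [0.0])


class TestPhaseError:
    def test_hand_examples(self):
        assert cp.phase_error_hours(0.0, 0.0) == 0.0
        assert np.isclose(cp.phase_error_hours(0.0, np.pi), 12.0)
        assert np.isclose(cp.phase_error_hours(0.0, np.pi / 6), 2.0)

    @given(a=st.floats(-20, 20), b=st.floats(-20, 20), k=st.integers(-3, 3))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_periodic(self, a, b, k):
        e = float(cp.phase_error_hours(a, b))
        assert 0.0 <= e <= 12.0
        e2 = float(cp.phase_error_hours(a + TWO_PI * k, b))
        assert abs(e - e2) < 1e-6


class TestErrorEcdf:
    def test_all_zero_errors(self):
        xs, fr = cp.error_ecdf([0.0, 0.0, 0.0])
        assert fr[-1] == 1.0 and xs[-1] == 0.0

    def test_uniform_errors_median(self, rng):
        errors = rng.uniform(0, 12, 10**5)
        assert abs(cp.ecdf_at(errors, 6.0) - 0.5) < 0.01

    def test_single_value_step(self):
        assert cp.ecdf_at([3.0], 2.9) == 0.0
        assert cp.ecdf_at([3.0], 3.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cp.error_ecdf([])


class TestCalibration:
    def test_point_mass_at_truth_covers_everything(self):
        truths = np.array([1.0, 2.0, 3.0])
        arcs = {0.5: [[(t - 0.01, t + 0.01)] for t in truths]}
        assert cp.calibration_curve(arcs, truths) == [(0.5, 1.0)]

    def test_zero_width_intervals_cover_nothing(self):
        truths = np.array([1.0, 2.0])
        arcs = {0.0: [[(5.0, 5.0)] for _ in truths]}
        assert cp.calibration_curve(arcs, truths) == [(0.0, 0.0)]

    def test_exact_posterior_coverage(self, rng):
        # truths drawn from the very distribution whose HDR arcs we report:
        # coverage must match the nominal level
        n = 2000
        conc, loc = 4.0, 2.0
        truths = wrap(stats.vonmises(conc, loc=loc).rvs(n, random_state=7))
        dist = stats.vonmises(conc, loc=loc)
        for level in (0.5, 0.8):
            half = np.pi / 2
            lo, hi = -np.pi, np.pi
            # central interval of the von Mises = HDR by symmetry
            half = dist.ppf(0.5 + level / 2) - loc
            arcs = {level: [[(loc - half, loc + half)] for _ in range(n)]}
            (lvl, cov), = cp.calibration_curve(arcs, truths)
            assert abs(cov - level) < 0.03


class TestStability:
    def test_identical_runs_zero(self):
        runs = np.tile(np.array([[0.3], [1.0]]), (1, 5))
        np.testing.assert_allclose(cp.stability(runs), 0.0, atol=1e-12)

    def test_two_run_hand_example(self):
        # runs {0, pi/6}: circular mean pi/12, deviations pi/12 each = 1 h
        runs = np.array([[0.0, np.pi / 6]])
        assert np.isclose(cp.stability(runs)[0], 1.0)

    def test_antipodal_tie_uses_first_run(self):
        runs = np.array([[0.0, np.pi]])
        # tie-break: center = first run -> deviations {0, pi} -> mean 6 h
        assert np.isclose(cp.stability(runs)[0], 6.0)


@pytest.fixture(scope="module")
def split(disp):
    cfg = cp.SimConfig(n_cells=600, n_flat_genes=10, n_ccgs=0, seed=3)
    cm, phases, params = cp.simulate_counts(cfg, disp)
    half = 300
    train = cp.CountMatrix(cm.counts[:half], cm.cell_ids[:half], cm.gene_ids,
                           cm.library_size[:half])
    test = cp.CountMatrix(cm.counts[half:], cm.cell_ids[half:], cm.gene_ids,
                          cm.library_size[half:])
    clock = list(cp.default_clock_table()["gene"])
    return train, test, clock, phases[:half], phases[half:]


class TestHoldoutLikelihood:
    def test_truth_scores_high(self, split):
        train, test, clock, ptr, pte = split
        res = cp.holdout_clock_likelihood(train, test, clock, ptr, pte,
                                          n_null=50, seed=0)
        assert res.score > 3

    def test_random_phases_within_null(self, split, rng):
        train, test, clock, ptr, pte = split
        res = cp.holdout_clock_likelihood(
            train, test, clock,
            rng.uniform(0, TWO_PI, train.n_cells),
            rng.uniform(0, TWO_PI, test.n_cells),
            n_null=50, seed=1,
        )
        assert abs(res.score) < 2

    def test_glm_recovers_poisson_cosinor_parameters(self, rng):
        n = 5000
        theta = rng.uniform(0, TWO_PI, n)
        lib = np.full(n, 10_000.0)
        mu, A, phi = np.log(3e-4), 0.6, 1.2
        x = rng.poisson(lib * np.exp(mu + A * np.cos(theta - phi)))
        mu_hat, A_hat, phi_hat = cp.fit_cosinor_glm(x, lib, theta)
        assert abs(mu_hat - mu) < abs(mu) * 0.05
        assert abs(A_hat - A) < 0.05 * max(1.0, A) + 0.02
        assert cp.phase_error_hours(phi, phi_hat) < 0.25

    def test_overlapping_cells_rejected(self, split):
        train, test, clock, ptr, pte = split
        with pytest.raises(ValueError):
            cp.holdout_clock_likelihood(train, train, clock, ptr, ptr)


class TestEnrichment:
    def test_matches_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(1000)]
        target = universe[:100]
        de_novo = universe[:5] + universe[500:515]  # 5 hits of 20
        p = cp.enrichment_test(de_novo, target, universe, n_null=10**5, seed=0)
        exact = stats.hypergeom.sf(4, 1000, 100, 20)  # P(overlap >= 5)
        assert abs(p - exact) / exact < 0.15

    def test_nested_set_is_significant(self):
        universe = [f"g{i}" for i in range(1000)]
        target = universe[:50]
        de_novo = universe[:10]
        assert cp.enrichment_test(de_novo, target, universe, n_null=1000, seed=0) <= 0.01

    def test_target_equals_universe(self):
        universe = [f"g{i}" for i in range(100)]
        assert cp.enrichment_test(universe[:5], universe, universe, n_null=200, seed=0) == 1.0

    def test_seeded_reproducibility_and_range(self):
        universe = [f"g{i}" for i in range(200)]
        a = cp.enrichment_test(universe[:10], universe[5:60], universe, seed=3)
        b = cp.enrichment_test(universe[:10], universe[5:60], universe, seed=3)
        assert a == b and 0 < a <= 1


class TestPCABaseline:
    def test_exact_circle_recovered(self):
        n = 256
        angles = np.arange(n) * TWO_PI / n
        # two genes whose (log1p-normalized, z-scored) values trace a circle
        y1 = np.cos(angles)
        y2 = np.sin(angles)
        lib = np.full(n, 1_000_000.0)
        counts = np.round(
            np.column_stack([np.expm1(3 + y1), np.expm1(3 + y2)])
        ).astype(int)
        cm = cp.CountMatrix(counts=counts, cell_ids=[f"c{i}" for i in range(n)],
                            gene_ids=["g1", "g2"], library_size=lib)
        est = cp.pca_angle_baseline(cm, ["g1", "g2"])
        shift = cp.optimal_shift(est, angles)
        aligned = cp.apply_shift(est, shift)
        assert np.median(cp.phase_error_hours(angles, aligned)) < 0.25

    def test_deterministic(self, small_sim, clock_genes):
        a = cp.pca_angle_baseline(small_sim["cm"], clock_genes)
        b = cp.pca_angle_baseline(small_sim["cm"], clock_genes)
        np.testing.assert_array_equal(a, b)

    def test_pure_noise_gives_random_errors(self, rng):
        n = 2000
        lib = np.full(n, 10_000.0)
        counts = rng.poisson(1.0, size=(n, 20))
        cm = cp.CountMatrix(counts=counts, cell_ids=[f"c{i}" for i in range(n)],
                            gene_ids=[f"g{j}" for j in range(20)], library_size=lib)
        truths = rng.uniform(0, TWO_PI, n)
        est = cp.pca_angle_baseline(cm, cm.gene_ids)
        shift = cp.optimal_shift(est, truths)
        med = np.median(cp.phase_error_hours(truths, cp.apply_shift(est, shift)))
        assert abs(med - 6.0) < 0.5

    def test_rank_deficient_rejected(self):
        cm = cp.CountMatrix(counts=np.ones((10, 2), dtype=int),
                            cell_ids=[f"c{i}" for i in range(10)],
                            gene_ids=["g1", "g2"],
                            library_size=np.full(10, 100.0))
        with pytest.raises(ValueError):
            cp.pca_angle_baseline(cm, ["g1", "g2"])
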