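"""Evaluation statistics for phase inference methods.

Everything needed to benchmark a phase estimator against ground truth:
optimal global shifting (methods without an absolute phase origin are
rotated, and optionally reflected, to best align with truth before errors
are computed), circular error in hours, error eCDFs, credible-interval
calibration, run-to-run stability, an out-of-sample core-clock likelihood
score standardized against a random-phase null, a gene-set enrichment test
with an empirical null, and a PCA-angle baseline estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._circular import HOURS_PER_RADIAN, TWO_PI, wrap
from .inference import arc_contains
from .model import CountMatrix

__all__ = [
    "ShiftResult",
    "optimal_shift",
    "apply_shift",
    "phase_error_hours",
    "error_ecdf",
    "calibration_curve",
    "stability",
    "HoldoutResult",
    "holdout_clock_likelihood",
    "fit_cosinor_glm",
    "enrichment_test",
    "pca_angle_baseline",
]


# ---------------------------------------------------------------------------
# optimal shift and errors
# ---------------------------------------------------------------------------


@dataclass
class ShiftResult:
    """Best global rotation (and optional reflection) aligning estimates to truth."""

    shift: float  # radians; aligned estimate = (+-estimate) - shift
    reflected: bool
    total_error: float  # sum of arccos(cos(.)) at the optimum, radians


def _total_error_by_shift(diffs: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    return np.arccos(np.cos(diffs[:, None] - shifts[None, :])).sum(axis=0)


def optimal_shift(
    estimates, truths, n_grid: int = 24 * 60, allow_reflection: bool = True
) -> ShiftResult:
    """Grid-search the rotation minimizing total circular error vs truth.

    The search runs at 1-minute resolution by default. Because projection
    methods (PCA and friends) cannot identify the direction of the cycle,
    the reflected estimates (theta -> -theta) are scored too and the better
    orientation is returned, flagged in the result.
    """
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape or estimates.size == 0:
        raise ValueError("estimates and truths must be equal-length, non-empty")
    shifts = np.arange(n_grid) * (TWO_PI / n_grid)
    totals = _total_error_by_shift(estimates - truths, shifts)
    best = int(np.argmin(totals))
    result = ShiftResult(float(shifts[best]), False, float(totals[best]))
    if allow_reflection:
        totals_r = _total_error_by_shift(-estimates - truths, shifts)
        best_r = int(np.argmin(totals_r))
        if totals_r[best_r] < result.total_error:
            result = ShiftResult(float(shifts[best_r]), True, float(totals_r[best_r]))
    return result


def apply_shift(estimates, shift: ShiftResult) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    if shift.reflected:
        est = -est
    return wrap(est - shift.shift)


def phase_error_hours(truth, estimate) -> np.ndarray:
    """Circular error in hours on [0, 12]: (12/pi) arccos(cos(theta - theta_hat))."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    return HOURS_PER_RADIAN * np.arccos(np.clip(np.cos(truth - estimate), -1.0, 1.0))


def error_ecdf(errors):
    """Right-continuous eCDF of phase errors; returns (sorted hours, fractions)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("no errors supplied")
    xs = np.sort(errors)
    fracs = np.arange(1, xs.size + 1) / xs.size
    return xs, fracs


def ecdf_at(errors, hour: float) -> float:
    errors = np.asarray(errors, dtype=float)
    return float((errors <= hour).mean())


# ---------------------------------------------------------------------------
# calibration and stability
# ---------------------------------------------------------------------------


def calibration_curve(arcs_by_level: dict, truths):
    """Empirical coverage of HDR credible arcs at each confidence level.

    ``arcs_by_level`` maps level -> list (per cell) of arc lists, as
    produced by :func:`circaphase.inference.credible_arcs`. Returns a list
    of (level, coverage) pairs sorted by level.
    """
    truths = np.asarray(truths, dtype=float)
    out = []
    for level in sorted(arcs_by_level):
        arcs_per_cell = arcs_by_level[level]
        if len(arcs_per_cell) != truths.size:
            raise ValueError("one arc set per cell is required")
        hits = sum(
            arc_contains(arcs, float(t)) for arcs, t in zip(arcs_per_cell, truths)
        )
        out.append((float(level), hits / truths.size))
    return out


def stability(run_matrix) -> np.ndarray:
    """Per-cell run-to-run circular standard deviation, in hours.

    ``run_matrix`` is (n_cells, n_runs). For each cell the circular mean of
    its estimates across runs is computed and the mean absolute circular
    deviation from it is returned in hours. In the degenerate antipodal
    case (zero resultant, circular mean undefined) the first run's estimate
    is used as the center — a documented deterministic tie-break.
    """
    runs = np.asarray(run_matrix, dtype=float)
    if runs.ndim != 2 or runs.shape[1] < 2:
        raise ValueError("need at least 2 runs per cell")
    c = np.cos(runs).mean(axis=1)
    s = np.sin(runs).mean(axis=1)
    center = np.arctan2(s, c)
    degenerate = np.hypot(c, s) < 1e-9
    center[degenerate] = runs[degenerate, 0]
    dev = np.arccos(np.clip(np.cos(runs - center[:, None]), -1.0, 1.0))
    return HOURS_PER_RADIAN * dev.mean(axis=1)


# ---------------------------------------------------------------------------
# out-of-sample clock likelihood
# ---------------------------------------------------------------------------


def fit_cosinor_glm(x, lib, theta):
    """Poisson GLM fit of one gene's counts on a cosinor basis.

    log E[X_i] = log L_i + mu + a cos(theta_i) + b sin(theta_i); returns
    (mu, A, phi) with A = hypot(a, b) and phi = atan2(b, a).
    """
    X = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    model = sm.GLM(np.asarray(x, dtype=float), X, family=sm.families.Poisson(),
                   exposure=np.asarray(lib, dtype=float))
    res = model.fit()
    mu, a, b = res.params
    return float(mu), float(np.hypot(a, b)), float(wrap(np.arctan2(b, a)))


def _poisson_clock_loglik(cm: CountMatrix, clock_genes, params, theta) -> float:
    total = 0.0
    theta = np.asarray(theta, dtype=float)
    for gene, (mu, A, phi) in zip(clock_genes, params):
        j = cm.gene_index([gene])[0]
        lam = np.exp(mu + A * np.cos(theta - phi))
        mean = np.clip(cm.library_size * lam, 1e-300, None)
        total += float(stats.poisson.logpmf(cm.counts[:, j], mean).sum())
    return total


@dataclass
class HoldoutResult:
    score: float  # (loglik - null median) / null SD
    loglik: float
    null_logliks: np.ndarray


def holdout_clock_likelihood(
    train_cm: CountMatrix,
    test_cm: CountMatrix,
    clock_genes,
    train_phases,
    test_phases,
    n_null: int = 50,
    seed: int = 0,
) -> HoldoutResult:
    """Out-of-sample core-clock likelihood score for one method's phases.

    A Poisson cosinor GLM is fit per clock gene on the training cells using
    the method's training phases; the Poisson log likelihood of the test
    cells' clock counts under the method's test phases is then standardized
    against a null of ``n_null`` scores computed with uniform-random train
    and test phases.
    """
    clock_genes = list(clock_genes)
    for g in clock_genes:  # raises KeyError if missing from either split
        train_cm.gene_index([g])
        test_cm.gene_index([g])
    if set(train_cm.cell_ids) & set(test_cm.cell_ids):
        raise ValueError("train and test cells must be disjoint")

    def score_phases(tr_phases, te_phases):
        params = [
            fit_cosinor_glm(
                train_cm.counts[:, train_cm.gene_index([g])[0]],
                train_cm.library_size,
                np.asarray(tr_phases, dtype=float),
            )
            for g in clock_genes
        ]
        return _poisson_clock_loglik(test_cm, clock_genes, params, te_phases)

    ll = score_phases(train_phases, test_phases)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            score_phases(
                rng.uniform(0, TWO_PI, train_cm.n_cells),
                rng.uniform(0, TWO_PI, test_cm.n_cells),
            )
            for _ in range(n_null)
        ]
    )
    sd = null.std(ddof=1)
    return HoldoutResult(float((ll - np.median(null)) / sd), float(ll), null)


# ---------------------------------------------------------------------------
# enrichment and the PCA baseline
# ---------------------------------------------------------------------------


def enrichment_test(de_novo, target, universe, n_null: int = 1000, seed: int = 0) -> float:
    """Empirical enrichment p of the de novo set in a target gene set.

    Null overlaps come from ``n_null`` random same-size gene sets drawn
    from the universe; p = (1 + #{null >= observed}) / (n_null + 1).
    """
    de_novo, target, universe = set(de_novo), set(target), list(universe)
    if not de_novo or not target:
        raise ValueError("gene sets must be non-empty")
    if not de_novo <= set(universe) or not target <= set(universe):
        raise ValueError("gene sets must be subsets of the universe")
    observed = len(de_novo & target)
    rng = np.random.default_rng(seed)
    k = len(de_novo)
    universe_arr = np.array(universe)
    hits = 0
    for _ in range(n_null):
        draw = set(rng.choice(universe_arr, size=k, replace=False))
        if len(draw & target) >= observed:
            hits += 1
    return (1 + hits) / (n_null + 1)


def pca_angle_baseline(cm: CountMatrix, gene_subset) -> np.ndarray:
    """Phase estimates from the angle of the top-2 principal components.

    Counts of the gene subset are library-size normalized, log1p
    transformed and z-scored per gene; the per-cell angle atan2(PC2, PC1)
    of the top two principal components is returned, wrapped to [0, 2pi).
    Deterministic: each component is oriented so its largest-magnitude
    loading is positive.
    """
    genes = list(gene_subset)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    idx = cm.gene_index(genes)
    norm = cm.counts[:, idx] / cm.library_size[:, None] * np.median(cm.library_size)
    Y = np.log1p(norm)
    sd = Y.std(axis=0)
    if (sd == 0).all():
        raise ValueError("rank-deficient input: no gene varies")
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("rank-deficient input: fewer than 2 varying genes")
    Z = (Y[:, keep] - Y[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    if S.size < 2 or S[1] <= 1e-12 * S[0]:
        raise ValueError("rank-deficient input: fewer than 2 principal components")
    pcs = U[:, :2] * S[:2]
    for k in range(2):  # deterministic sign convention
        lead = np.argmax(np.abs(Vt[k]))
        if Vt[k, lead] < 0:
            pcs[:, k] = -pcs[:, k]
    return wrap(np.arctan2(pcs[:, 1], pcs[:, 0]))
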