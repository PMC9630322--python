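"""Core probabilistic model for circadian phase inference from UMI counts.

Transcript counts X_ij for gene j in cell i are modelled as Negative Binomial
with mean L_i * lambda_ij and dispersion delta_ij, where L_i is the cell
library size and the expected log proportion follows a 24 h sinusoid

    log(lambda_ij) = mu_j + Q_j * A_j * cos(theta_i - phi_j)

with mesor mu_j (mean log proportion), amplitude A_j (maximum log deviation
from the mesor), acrophase phi_j (peak phase) and a binary indicator Q_j for
whether the gene cycles at all. theta_i is the latent circadian phase of cell
i, a circular quantity (hours = radians * 12/pi). The dispersion is tied to
the proportion through a fitted polynomial trend delta = g_zeta(lambda),
shared by all genes and cells.

This module owns the domain containers (CountMatrix, GeneParams, PriorSpec,
DispersionModel) and the likelihood/prior/joint density computations that the
inference engine builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

from ._circular import TWO_PI, vonmises_logpdf, wrap

__all__ = [
    "CountMatrix",
    "GeneParams",
    "DispersionModel",
    "CellPhasePrior",
    "PriorSpec",
    "nb_log_pmf",
    "expected_log_proportion",
    "fit_dispersion_model",
    "log_prior",
    "log_joint",
]

_POISSON_DISPERSION_EPS = 1e-10


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer UMI counts (cells x genes) with identifiers and library sizes.

    ``library_size`` defaults to the row sums of ``counts``; it may be
    overridden (e.g., when a gene subset of a larger matrix is analysed but
    exposures should reflect the full transcriptome).
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    library_size: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        n, p = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lengths do not match the count matrix")
        if len(set(self.gene_ids)) != p:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=1).astype(float)
        else:
            self.library_size = np.asarray(self.library_size, dtype=float)
            if self.library_size.shape != (n,):
                raise ValueError("library_size must have one entry per cell")
        if (self.library_size <= 0).any():
            raise ValueError("every retained cell must have positive library size")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: k for k, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from the count matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def pseudobulk_proportions(self) -> np.ndarray:
        """Per-gene summed counts over the summed library size."""
        return self.counts.sum(axis=0) / self.library_size.sum()

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            counts=self.counts[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=[self.gene_ids[k] for k in idx],
            library_size=self.library_size.copy(),
        )


@dataclass
class GeneParams:
    """Sinusoidal parameters for a set of genes (vectorized over genes)."""

    mesor: np.ndarray  # mu_j, natural-log proportion
    amplitude: np.ndarray  # A_j >= 0, log units
    acrophase: np.ndarray  # phi_j, radians in [0, 2pi)
    q: np.ndarray  # Q_j in {0, 1}
    gamma: np.ndarray | None = None  # gamma_j in [0, 1]

    def __post_init__(self):
        self.mesor = np.atleast_1d(np.asarray(self.mesor, dtype=float))
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        self.acrophase = wrap(np.atleast_1d(self.acrophase))
        self.q = np.atleast_1d(np.asarray(self.q))
        if self.gamma is None:
            self.gamma = np.full(self.mesor.shape, 0.5)
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if (self.amplitude < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if ((self.gamma < 0) | (self.gamma > 1)).any():
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.mesor.size


@dataclass
class DispersionModel:
    """Polynomial trend delta = g_zeta(lambda) mapping proportion to dispersion.

    ``coeffs`` are numpy polynomial coefficients (highest degree first) of
    log(delta) as a function of log(lambda). Evaluation clamps lambda to the
    fitted range so the trend cannot be extrapolated into nonsense.
    """

    coeffs: np.ndarray
    lam_range: tuple[float, float]
    lam_floor: float = 1e-5

    def __post_init__(self):
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        lo, hi = self.lam_range
        if not (0 < lo <= hi):
            raise ValueError("invalid lambda range")

    @classmethod
    def constant(cls, delta: float, lam_floor: float = 1e-5) -> "DispersionModel":
        if delta < 0:
            raise ValueError("dispersion must be non-negative")
        return cls(
            coeffs=np.array([np.log(max(delta, _POISSON_DISPERSION_EPS))]),
            lam_range=(1e-12, 1.0),
            lam_floor=lam_floor,
        )

    def __call__(self, lam) -> np.ndarray:
        lam = np.clip(np.asarray(lam, dtype=float), *self.lam_range)
        return np.exp(np.polyval(self.coeffs, np.log(lam)))


@dataclass
class CellPhasePrior:
    """Prior over a cell's circadian phase: von Mises or circular uniform."""

    loc: float = 0.0
    kappa: float = 0.0  # kappa == 0 -> circular uniform

    def log_density(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self.kappa <= 0:
            return np.full(theta.shape, -np.log(TWO_PI))
        return vonmises_logpdf(theta, self.loc, self.kappa)


@dataclass
class PriorSpec:
    """All prior hyperparameters of the model.

    Acrophase priors are von Mises per gene (``acrophase_priors[gene] =
    (loc, kappa)``); genes without an entry get a circular-uniform prior.
    The ``reference_gene``'s acrophase prior is a point mass at 0 radians,
    which anchors hour 0 of the cycle at that gene's peak. Amplitudes live
    on the shared interval [amp_min, amp_max] under a transformed Beta
    prior; the cycler probability gamma_j has a Beta prior whose parameters
    differ between the trusted clock genes and everything else.
    """

    acrophase_priors: dict[str, tuple[float, float]] = field(default_factory=dict)
    reference_gene: str = "Arntl"
    mesor_locs: dict[str, float] = field(default_factory=dict)  # empirical by default
    mesor_scale: float = 2.0
    amp_min: float = 0.0
    amp_max: float = 1.5
    amp_alpha: float = 1.0
    amp_beta: float = 1.0
    gamma_alpha: float = 1.0
    gamma_beta: float = 1.0
    clock_gamma_alpha: float = 9.0
    clock_gamma_beta: float = 1.0
    cell_prior: CellPhasePrior = field(default_factory=CellPhasePrior)

    def __post_init__(self):
        if self.amp_min >= self.amp_max:
            raise ValueError("amp_min must be < amp_max")
        for name in ("mesor_scale", "amp_alpha", "amp_beta", "gamma_alpha",
                     "gamma_beta", "clock_gamma_alpha", "clock_gamma_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- per-component log densities -------------------------------------
    def acrophase_log_density(self, gene: str, phi) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        if gene == self.reference_gene:
            raise ValueError("reference gene acrophase is a point mass at 0")
        if gene in self.acrophase_priors:
            loc, kappa = self.acrophase_priors[gene]
            return vonmises_logpdf(phi, loc, kappa)
        return np.full(phi.shape, -np.log(TWO_PI))

    def mesor_log_density(self, mu, loc) -> np.ndarray:
        return stats.norm.logpdf(mu, loc=loc, scale=self.mesor_scale)

    def amplitude_log_density(self, amp) -> np.ndarray:
        """Transformed-Beta log density on [amp_min, amp_max]; -inf outside."""
        amp = np.asarray(amp, dtype=float)
        width = self.amp_max - self.amp_min
        u = (amp - self.amp_min) / width
        out = np.full(amp.shape, -np.inf)
        inside = (u >= 0) & (u <= 1)
        out[inside] = stats.beta.logpdf(
            np.clip(u[inside], 1e-12, 1 - 1e-12), self.amp_alpha, self.amp_beta
        ) - np.log(width)
        return out

    def gamma_params(self, gene: str, clock_genes=()) -> tuple[float, float]:
        if gene in set(clock_genes):
            return self.clock_gamma_alpha, self.clock_gamma_beta
        return self.gamma_alpha, self.gamma_beta

    def q_prior_prob(self, gene: str, clock_genes=()) -> float:
        """Marginal prior P(Q_j = 1) under the Beta-Bernoulli hierarchy."""
        a, b = self.gamma_params(gene, clock_genes)
        return a / (a + b)

    def with_reference(self, gene: str) -> "PriorSpec":
        return replace(self, reference_gene=gene)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def nb_log_pmf(x, mean, dispersion):
    """Negative Binomial log pmf in mean/dispersion parametrization.

    ``Var = mean + dispersion * mean**2``. At ``dispersion -> 0`` the
    distribution converges to Poisson, which is used directly below a tiny
    threshold for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    dispersion = np.asarray(dispersion, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(mean).all() and np.isfinite(dispersion).all()):
        raise ValueError("non-finite inputs to nb_log_pmf")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (mean <= 0).any():
        raise ValueError("mean must be positive")
    if (dispersion < 0).any():
        raise ValueError("dispersion must be non-negative")

    x, mean, dispersion = np.broadcast_arrays(x, mean, dispersion)
    out = np.empty(x.shape, dtype=float)
    pois = dispersion < _POISSON_DISPERSION_EPS
    if pois.any():
        out[pois] = special.xlogy(x[pois], mean[pois]) - mean[pois] - special.gammaln(x[pois] + 1)
    nb = ~pois
    if nb.any():
        r = 1.0 / dispersion[nb]
        m = mean[nb]
        xx = x[nb]
        out[nb] = (
            special.gammaln(xx + r)
            - special.gammaln(r)
            - special.gammaln(xx + 1)
            + r * np.log(r / (r + m))
            + xx * np.log(m / (r + m))
        )
    return out if out.ndim else float(out)


def expected_log_proportion(theta, params: GeneParams):
    """log(lambda_ij) = mu_j + Q_j A_j cos(theta_i - phi_j).

    ``theta`` broadcasts against the gene axis: pass shape (n, 1) to obtain
    an (n_cells, n_genes) matrix. The gene's expected count in cell i is
    ``L_i * exp(result)``.
    """
    theta = np.asarray(theta, dtype=float)
    return params.mesor + params.q * params.amplitude * np.cos(theta - params.acrophase)


# ---------------------------------------------------------------------------
# dispersion trend
# ---------------------------------------------------------------------------


def _gene_ml_dispersion(x: np.ndarray, mean: np.ndarray) -> float:
    """Maximum-likelihood NB dispersion for one gene at fixed means."""

    def nll(log_delta):
        return -nb_log_pmf(x, mean, np.exp(log_delta)).sum()

    res = optimize.minimize_scalar(nll, bounds=(-9.0, 3.0), method="bounded")
    return float(np.exp(res.x))


def _pooled_mom_dispersion(counts: np.ndarray, means: np.ndarray) -> float:
    """Pooled method-of-moments dispersion from the estimating equation
    E[(X - m)^2 - m] = delta * m^2 summed over all observations."""
    num = ((counts - means) ** 2 - means).sum()
    den = (means**2).sum()
    return float(max(num / den, 0.0))


def fit_dispersion_model(
    cm: CountMatrix,
    degree: int = 2,
    proportion_floor: float = 1e-5,
    min_genes: int = 50,
) -> DispersionModel:
    """Fit the mean-dispersion trend g_zeta from counts, ignoring phase.

    Per-gene NB dispersions are estimated by maximum likelihood with means
    fixed at L_i times the gene's pseudobulk proportion; a polynomial of
    log(delta) on log(lambda) is then fit by least squares over genes above
    the expression floor. ``degree=0`` returns the pooled method-of-moments
    constant instead.
    """
    props = cm.pseudobulk_proportions()
    keep = np.flatnonzero(props > proportion_floor)
    if keep.size < max(min_genes, degree + 2):
        raise ValueError(
            f"only {keep.size} genes pass the proportion floor {proportion_floor}; "
            f"need at least {max(min_genes, degree + 2)}"
        )
    lam = props[keep]
    lam_range = (float(lam.min()), float(lam.max()))

    if degree == 0:
        means = cm.library_size[:, None] * lam[None, :]
        delta = _pooled_mom_dispersion(cm.counts[:, keep].astype(float), means)
        return DispersionModel(
            coeffs=np.array([np.log(max(delta, _POISSON_DISPERSION_EPS))]),
            lam_range=lam_range,
            lam_floor=proportion_floor,
        )

    deltas = np.empty(keep.size)
    for out_k, j in enumerate(keep):
        means = cm.library_size * props[j]
        deltas[out_k] = _gene_ml_dispersion(cm.counts[:, j].astype(float), means)
    # genes driven to the Poisson boundary contribute a small positive floor
    deltas = np.maximum(deltas, 1e-4)
    coeffs = np.polyfit(np.log(lam), np.log(deltas), degree)

    model = DispersionModel(coeffs=coeffs, lam_range=lam_range, lam_floor=proportion_floor)
    if (model(np.geomspace(*lam_range, 64)) <= 0).any():  # pragma: no cover
        raise RuntimeError("fitted dispersion trend is not positive")
    return model


# ---------------------------------------------------------------------------
# priors and joint
# ---------------------------------------------------------------------------


def log_prior(
    params: GeneParams,
    theta,
    prior: PriorSpec,
    gene_ids,
    clock_genes=(),
    mesor_locs=None,
) -> float:
    """Unnormalized-model log prior: sum of all component log densities.

    Amplitudes outside [amp_min, amp_max] yield -inf rather than raising.
    ``mesor_locs`` supplies the (typically empirical) Normal prior locations
    per gene; ``prior.mesor_locs`` and then 0.0 are the fallbacks.
    """
    gene_ids = list(gene_ids)
    if len(gene_ids) != params.n_genes:
        raise ValueError("gene_ids must match params")
    total = 0.0
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    total += prior.cell_prior.log_density(theta).sum()
    for k, gene in enumerate(gene_ids):
        if mesor_locs is not None and gene in mesor_locs:
            loc = mesor_locs[gene]
        else:
            loc = prior.mesor_locs.get(gene, 0.0)
        total += float(prior.mesor_log_density(params.mesor[k], loc))
        total += float(prior.amplitude_log_density(params.amplitude[k:k + 1])[0])
        if gene != prior.reference_gene:
            total += float(prior.acrophase_log_density(gene, params.acrophase[k:k + 1])[0])
        elif abs(np.cos(params.acrophase[k]) - 1.0) > 1e-9:
            return -np.inf  # reference acrophase must sit at its point mass
        a, b = prior.gamma_params(gene, clock_genes)
        g = float(np.clip(params.gamma[k], 1e-12, 1 - 1e-12))
        total += float(stats.beta.logpdf(g, a, b))
        qk = float(params.q[k])
        total += qk * np.log(g) + (1 - qk) * np.log1p(-g)
    return float(total)


def log_joint(
    cm: CountMatrix,
    thetas,
    params: GeneParams,
    prior: PriorSpec,
    disp: DispersionModel,
    gene_subset,
    clock_genes=(),
    mesor_locs=None,
) -> float:
    """Unnormalized log posterior log P(X, theta, beta) over a gene subset."""
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ValueError("gene_subset must be non-empty")
    idx = cm.gene_index(gene_subset)
    order = np.argsort(idx)  # evaluation order must not matter
    idx = idx[order]
    gene_subset = [gene_subset[k] for k in order]
    thetas = np.asarray(thetas, dtype=float).reshape(-1, 1)
    sub = GeneParams(
        mesor=params.mesor[order],
        amplitude=params.amplitude[order],
        acrophase=params.acrophase[order],
        q=params.q[order],
        gamma=params.gamma[order],
    )
    log_lam = expected_log_proportion(thetas, sub)  # (n, k)
    lam = np.exp(log_lam)
    means = cm.library_size[:, None] * lam
    delta = disp(lam)
    ll = nb_log_pmf(cm.counts[:, idx].astype(float), means, delta).sum()
    lp = log_prior(sub, thetas.ravel(), prior, gene_subset, clock_genes, mesor_locs)
    return float(ll + lp)
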