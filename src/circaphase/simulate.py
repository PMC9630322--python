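"""Simulators and waveform diagnostics.

Two generators are provided:

* :func:`simulate_counts` draws UMI counts from the package's own Negative
  Binomial sinusoidal generative model — clock genes from a canonical
  parameter table, clock-controlled genes (CCGs) and flat genes from
  configurable parameter pools, cell phases from a small set of equally
  spaced values (4 for a light-dark time-course design, 23 for
  "unsynchronized" cultures), and log-normal library sizes.

* :func:`simulate_from_waveforms` turns a bulk time-course expression table
  into single cells: each cell is assigned a timepoint, flat genes are
  pinned to their across-timepoint median proportion, and counts are
  Poisson with mean proportion x library size. This exercises inference
  under realistic (non-sinusoidal) waveforms.

The waveform diagnostics (circadian FFT fraction, likelihood-ratio
statistic of the true waveform against flat, and a cosinor F-test cycler
caller with Benjamini-Hochberg correction) quantify how sinusoidal and how
strong each gene's temporal signal is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._circular import TWO_PI, hours_to_radians, wrap
from .model import CountMatrix, DispersionModel, GeneParams, PriorSpec
from ._circular import vonmises_kappa_for_interval

__all__ = [
    "SimConfig",
    "WaveformTable",
    "default_clock_table",
    "simulate_counts",
    "simulate_from_waveforms",
    "jittered_acrophase_priors",
    "circadian_fft_fraction",
    "waveform_lrt",
    "harmonic_cycler_call",
    "synthetic_waveform_table",
]


# ---------------------------------------------------------------------------
# clock parameter table
# ---------------------------------------------------------------------------


def default_clock_table() -> pd.DataFrame:
    """Canonical core-clock parameter table for simulations.

    Twelve murine clock genes with staggered acrophases (hours after the
    Arntl peak, which anchors hour 0), mesors spanning the moderate
    expression range typical of clock transcripts (proportions 1e-5 to
    1e-3) and amplitudes of 0.3-1.0 natural-log units.
    """
    rows = [
        # gene, peak hours after Arntl peak, proportion, amplitude (ln units)
        ("Arntl", 0.0, 2e-4, 0.8),
        ("Npas2", 1.0, 4e-5, 0.7),
        ("Nr1d1", 6.0, 5e-4, 1.0),
        ("Nr1d2", 8.0, 2e-4, 0.8),
        ("Ciart", 10.0, 1e-4, 0.8),
        ("Per1", 12.0, 3e-4, 0.6),
        ("Per3", 12.0, 6e-5, 0.7),
        ("Dbp", 12.0, 1e-3, 1.0),
        ("Tef", 13.0, 3e-4, 0.5),
        ("Per2", 16.0, 2e-4, 0.6),
        ("Cry2", 16.0, 1e-4, 0.4),
        ("Cry1", 20.0, 1e-4, 0.5),
    ]
    df = pd.DataFrame(rows, columns=["gene", "peak_hours", "proportion", "amplitude"])
    df["acrophase"] = hours_to_radians(df["peak_hours"].to_numpy())
    df["mesor"] = np.log(df["proportion"].to_numpy())
    return df[["gene", "mesor", "amplitude", "acrophase"]]


@dataclass
class SimConfig:
    """Study conditions for the Negative Binomial generative simulator."""

    n_cells: int = 1000
    lib_log_mean: float = float(np.log(10_000.0))  # natural-log library size
    lib_log_sd: float = 0.5
    n_phase_grid: int = 4  # 4 = light-dark time course; 23 = unsynchronized
    n_flat_genes: int = 500
    n_ccgs: int = 20
    clock_table: pd.DataFrame = field(default_factory=default_clock_table)
    ccg_amp_range: tuple = (0.3, 1.0)
    ccg_prop_range: tuple = (1e-5, 1e-3)
    flat_prop_range: tuple = (2e-6, 1e-3)
    seed: int = 0

    def __post_init__(self):
        if self.n_phase_grid < 1:
            raise ValueError("n_phase_grid must be >= 1")
        if self.lib_log_sd <= 0:
            raise ValueError("lib_log_sd must be positive")


def _draw_nb(rng, mean, delta):
    """Draw NB (mean/dispersion parametrization); Poisson at delta ~ 0."""
    out = np.empty(np.shape(mean), dtype=np.int64)
    delta = np.broadcast_to(delta, np.shape(mean))
    pois = delta < 1e-10
    out[pois] = rng.poisson(np.asarray(mean)[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / delta[nb]
        m = np.asarray(mean)[nb]
        out[nb] = rng.negative_binomial(r, r / (r + m))
    return out


def simulate_counts(cfg: SimConfig, disp: DispersionModel):
    """Draw (CountMatrix, true phases, true GeneParams) from the NB model.

    Cell phases are uniform over ``n_phase_grid`` equally spaced values;
    CCG and flat-gene parameters are drawn from their pools (amplitudes
    uniform, proportions log-uniform, acrophases uniform on the circle).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    lib = np.maximum(np.round(np.exp(rng.normal(cfg.lib_log_mean, cfg.lib_log_sd, n))), 1.0)

    phase_choices = np.arange(cfg.n_phase_grid) * (TWO_PI / cfg.n_phase_grid)
    phases = phase_choices[rng.integers(0, cfg.n_phase_grid, n)]

    ct = cfg.clock_table
    gene_ids = list(ct["gene"])
    mesor = list(ct["mesor"].to_numpy(dtype=float))
    amplitude = list(ct["amplitude"].to_numpy(dtype=float))
    acrophase = list(ct["acrophase"].to_numpy(dtype=float))
    q = [1] * len(gene_ids)

    lo, hi = cfg.ccg_prop_range
    for k in range(cfg.n_ccgs):
        gene_ids.append(f"CCG{k + 1:04d}")
        mesor.append(float(np.log(np.exp(rng.uniform(np.log(lo), np.log(hi))))))
        amplitude.append(float(rng.uniform(*cfg.ccg_amp_range)))
        acrophase.append(float(rng.uniform(0, TWO_PI)))
        q.append(1)
    lo, hi = cfg.flat_prop_range
    for k in range(cfg.n_flat_genes):
        gene_ids.append(f"FLAT{k + 1:04d}")
        mesor.append(float(rng.uniform(np.log(lo), np.log(hi))))
        amplitude.append(0.0)
        acrophase.append(0.0)
        q.append(0)

    params = GeneParams(
        mesor=np.array(mesor),
        amplitude=np.array(amplitude),
        acrophase=np.array(acrophase),
        q=np.array(q),
        gamma=np.array(q, dtype=float),
    )
    log_lam = params.mesor[None, :] + params.q[None, :] * params.amplitude[None, :] * np.cos(
        phases[:, None] - params.acrophase[None, :]
    )
    lam = np.exp(log_lam)
    means = lib[:, None] * lam
    delta = disp(lam)
    counts = _draw_nb(rng, means, delta)

    cm = CountMatrix(
        counts=counts,
        cell_ids=[f"cell{i + 1:05d}" for i in range(n)],
        gene_ids=gene_ids,
        library_size=lib,
    )
    return cm, phases, params


def jittered_acrophase_priors(
    clock_table: pd.DataFrame,
    seed: int = 0,
    shift_sd_hours: float = 2.0,
    interval_width_hours: float = 4.0,
    reference_gene: str = "Arntl",
) -> PriorSpec:
    """Informative-but-imperfect clock priors for simulation studies.

    Prior acrophase locations are the true acrophases plus a seeded Normal
    shift with SD ``shift_sd_hours`` (2 h by default); the von Mises
    concentration is set so the central 95% prior interval spans
    ``interval_width_hours``. The reference gene keeps its exact (point
    mass) acrophase, anchoring hour 0.
    """
    rng = np.random.default_rng(seed)
    kappa = vonmises_kappa_for_interval(
        hours_to_radians(interval_width_hours / 2.0), mass=0.95
    )
    priors = {}
    for _, row in clock_table.iterrows():
        gene = row["gene"]
        if gene == reference_gene:
            continue
        shift = rng.normal(0.0, shift_sd_hours) * np.pi / 12.0
        priors[gene] = (float(wrap(row["acrophase"] + shift)), float(kappa))
    return PriorSpec(acrophase_priors=priors, reference_gene=reference_gene)


# ---------------------------------------------------------------------------
# realistic-waveform simulator
# ---------------------------------------------------------------------------


@dataclass
class WaveformTable:
    """Per-gene proportions over an equally spaced circadian time course."""

    gene_ids: list[str]
    timepoints: np.ndarray  # hours, strictly increasing, equally spaced
    proportions: np.ndarray  # (n_genes, n_timepoints), >= 0
    cycler: np.ndarray | None = None  # boolean flags

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if (np.diff(self.timepoints) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        steps = np.diff(self.timepoints)
        if not np.allclose(steps, steps[0]):
            raise ValueError("timepoints must be equally spaced")
        if (self.proportions < 0).any():
            raise ValueError("proportions must be non-negative")
        if self.proportions.shape != (len(self.gene_ids), self.timepoints.size):
            raise ValueError("proportions shape must be (n_genes, n_timepoints)")
        if self.cycler is not None:
            self.cycler = np.asarray(self.cycler, dtype=bool)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.proportions, index=self.gene_ids, columns=self.timepoints
        )
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "WaveformTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=list(df.index),
            timepoints=np.array([float(c) for c in df.columns]),
            proportions=df.to_numpy(dtype=float),
        )


def simulate_from_waveforms(
    wt: WaveformTable,
    cells_per_timepoint: int = 200,
    lib_log10_mean: float = float(np.log10(5000.0)),
    lib_log10_sd: float = 0.5,
    seed: int = 0,
):
    """Poisson single-cell counts from bulk waveforms; returns (CountMatrix, phases).

    Flat genes (``wt.cycler`` false) have their proportions replaced by the
    across-timepoint median; the true phase of a cell sampled at hour t is
    t * pi/12 (mod 2pi). Returns ``(CountMatrix, phases, tp_index)`` where
    ``tp_index`` maps each cell to its row in ``wt.timepoints`` (needed by
    the waveform likelihood-ratio statistic, since a time course longer
    than 24 h maps two timepoints onto each circadian phase).
    """
    rng = np.random.default_rng(seed)
    props = wt.proportions.copy()
    if wt.cycler is not None:
        flat = ~wt.cycler
        props[flat] = np.median(props[flat], axis=1, keepdims=True)

    T = wt.timepoints.size
    n = cells_per_timepoint * T
    tp_index = np.repeat(np.arange(T), cells_per_timepoint)
    lib = np.maximum(
        np.round(10.0 ** rng.normal(lib_log10_mean, lib_log10_sd, n)), 1.0
    )
    means = lib[:, None] * props[:, tp_index].T  # (cells, genes)
    counts = rng.poisson(means)
    phases = wrap(hours_to_radians(wt.timepoints[tp_index]))
    cm = CountMatrix(
        counts=counts,
        cell_ids=[f"cell{i + 1:05d}" for i in range(n)],
        gene_ids=list(wt.gene_ids),
        library_size=lib,
    )
    return cm, phases, tp_index


# ---------------------------------------------------------------------------
# waveform diagnostics
# ---------------------------------------------------------------------------


def circadian_fft_fraction(values, timepoints) -> float:
    """Share of the 24 h Fourier component among all non-DC components.

    ``timepoints`` must be equally spaced and span a whole number of 24 h
    periods. A constant signal (all non-DC amplitudes zero) returns 0.
    """
    values = np.asarray(values, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    steps = np.diff(timepoints)
    if steps.size == 0 or not np.allclose(steps, steps[0]):
        raise ValueError("timepoints must be equally spaced")
    duration = steps[0] * values.size
    n_periods = duration / 24.0
    if abs(n_periods - round(n_periods)) > 1e-9 or round(n_periods) < 1:
        raise ValueError("time course must span a whole number of 24 h periods")
    k24 = int(round(n_periods))
    amps = np.abs(np.fft.rfft(values))
    amps[0] = 0.0  # exclude DC
    total = amps[1:].sum()
    if total == 0:
        return 0.0
    return float(amps[k24] / total)


def waveform_lrt(counts, tp_index, waveform, lib_sizes) -> float:
    """2 x (Poisson loglik under the true waveform - under the flat median).

    ``counts``: one gene's counts across cells; ``tp_index``: each cell's
    timepoint index into ``waveform`` (per-timepoint proportions).
    """
    counts = np.asarray(counts, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    mean_true = np.clip(waveform[np.asarray(tp_index)] * lib, 1e-300, None)
    mean_flat = np.clip(np.median(waveform) * lib, 1e-300, None)
    ll_true = stats.poisson.logpmf(counts, mean_true).sum()
    ll_flat = stats.poisson.logpmf(counts, mean_flat).sum()
    return float(2.0 * (ll_true - ll_flat))


def harmonic_cycler_call(wt: WaveformTable, q_threshold: float = 0.05) -> np.ndarray:
    """Cosinor rhythm calls per gene with Benjamini-Hochberg correction.

    For each gene an ordinary least-squares fit of the proportions on a
    24 h cosinor basis (intercept + cos + sin) is compared to an
    intercept-only fit with an F-test; genes with BH-adjusted q below the
    threshold are flagged as cyclers. This is a deliberately simple
    harmonic-regression caller, not a reimplementation of rank-based
    rhythm detectors.
    """
    t = wt.timepoints
    if t.size < 8:
        raise ValueError("need at least 8 timepoints for the cosinor F-test")
    omega = TWO_PI / 24.0
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    pvals = np.empty(len(wt.gene_ids))
    for g in range(len(wt.gene_ids)):
        y = wt.proportions[g]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(((y - X @ beta) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        df1, df2 = 2, t.size - 3
        if rss1 <= 0:
            pvals[g] = 0.0 if rss0 > rss1 else 1.0
            continue
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        pvals[g] = float(stats.f.sf(F, df1, df2))
    if q_threshold <= 0:
        return np.zeros(len(wt.gene_ids), dtype=bool)
    reject, _, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    return reject


def synthetic_waveform_table(
    n_cyclers: int = 60,
    n_flat: int = 300,
    timepoints=None,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> WaveformTable:
    """Synthetic stand-in for a bulk circadian time-course expression table.

    Built entirely in silico (no external dataset): cycling genes are 24 h
    cosinor waveforms with a seeded admixture of a 12 h harmonic, flat
    genes are constants, and both carry multiplicative noise. Proportions
    are normalized per timepoint. Intended to exercise the
    realistic-waveform simulation code path on data of the same shape as a
    2 h-resolution, 48 h bulk time course.
    """
    rng = np.random.default_rng(seed)
    if timepoints is None:
        timepoints = np.arange(0, 48, 2.0)
    timepoints = np.asarray(timepoints, dtype=float)
    genes, rows, flags = [], [], []
    for k in range(n_cyclers):
        # cyclers carry little total mass so the per-timepoint proportion
        # normalization does not imprint a compensatory rhythm on flat genes
        base = 10 ** rng.uniform(-6, -4)
        amp = rng.uniform(0.3, 1.0)
        phase = rng.uniform(0, 24)
        harm = rng.uniform(0.0, 0.4)  # relative 12 h harmonic content
        w = base * np.exp(
            amp * np.cos(TWO_PI * (timepoints - phase) / 24.0)
            + harm * amp * np.cos(TWO_PI * timepoints / 12.0)
        )
        rows.append(w * np.exp(rng.normal(0, noise_sd, timepoints.size)))
        genes.append(f"CYC{k + 1:04d}")
        flags.append(True)
    for k in range(n_flat):
        base = 10 ** rng.uniform(-6, -3)
        rows.append(base * np.exp(rng.normal(0, noise_sd, timepoints.size)))
        genes.append(f"FLAT{k + 1:04d}")
        flags.append(False)
    props = np.vstack(rows)
    props = props / props.sum(axis=0, keepdims=True)
    return WaveformTable(
        gene_ids=genes,
        timepoints=timepoints,
        proportions=props,
        cycler=np.array(flags),
    )
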