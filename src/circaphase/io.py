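"""File formats, run configuration and report writing.

Count matrices are read either from a 10x-style MatrixMarket triplet
directory (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``; features
may be 1-column plain symbols or the 10x 3-column layout whose second
column holds the gene symbol) or from a dense TSV (cells x genes, header
row of gene ids, first column of cell ids). Cells below a library-size
floor (default 1000 UMIs) are dropped with a logged count.

Reports are written as plain TSVs: per-cell phases with credible arcs,
per-gene MAP parameters and detection statistics, the per-iteration
evidence trace, and a YAML run-metadata file carrying the seed, a config
hash and the stopping reason.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from ._circular import radians_to_hours
from .cyclers import PhaseReport, PipelineConfig
from .inference import EvidenceTrace, FitConfig, VariationalState
from .model import CountMatrix

__all__ = ["RunConfig", "read_counts", "write_counts", "write_phase_report", "read_phase_report"]

logger = logging.getLogger("circaphase")


@dataclass
class RunConfig:
    """Everything a ``fit`` run needs, loadable from YAML."""

    counts_path: str = ""
    clock_genes_path: str = ""
    output_dir: str = "circaphase_out"
    seed: int = 0
    min_library: int = 1000
    proportion_floor: float = 1e-5
    q_threshold: float = 0.95
    residual_threshold: float = 2.0
    max_iterations: int = 3
    credible_levels: tuple = (0.5, 0.8, 0.95)
    grid_size: int = 64
    max_sweeps: int = 30
    tol: float = 0.05
    reference_gene: str = "Arntl"
    acrophase_priors: dict = field(default_factory=dict)  # gene -> [loc_rad, kappa]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            fit=FitConfig(
                grid_size=self.grid_size,
                max_sweeps=self.max_sweeps,
                tol=self.tol,
                seed=self.seed,
            ),
            max_iterations=self.max_iterations,
            q_threshold=self.q_threshold,
            residual_threshold=self.residual_threshold,
            proportion_floor=self.proportion_floor,
            credible_levels=tuple(self.credible_levels),
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def _read_features(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    col = 1 if df.shape[1] >= 2 else 0  # 10x layout: id, symbol, type
    return [str(v) for v in df[col]]


def read_counts(path, fmt: str = "auto", min_library: int = 1000) -> CountMatrix:
    """Read a count matrix from a MatrixMarket directory or a dense TSV.

    Cells whose library size falls below ``min_library`` are dropped (the
    number dropped is logged). Duplicate gene symbols raise, naming the
    offenders.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "mtx" if path.is_dir() else "tsv"
    if fmt == "mtx":
        mat = mmread(path / "matrix.mtx")
        genes = _read_features(path / "features.tsv")
        barcodes = [
            str(v) for v in pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
        ]
        dense = np.asarray(mat.todense())
        if dense.shape == (len(genes), len(barcodes)):
            dense = dense.T  # 10x convention: genes x cells
        elif dense.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(barcodes)} barcodes, {len(genes)} features)"
            )
        counts, cell_ids, gene_ids = dense, barcodes, genes
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        cell_ids = [str(v) for v in df.index]
        gene_ids = [str(v) for v in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if not np.allclose(counts, np.round(counts)):
        raise ValueError("count matrix contains non-integer entries")
    counts = np.asarray(np.round(counts), dtype=np.int64)
    seen, dupes = set(), []
    for g in gene_ids:
        if g.lower() in seen:
            dupes.append(g)
        seen.add(g.lower())
    if dupes:
        raise ValueError(f"duplicate gene ids (case-insensitive): {sorted(set(dupes))}")

    # the library size is an exposure: when the matrix is a gene subset of
    # the transcriptome a sidecar carries the full per-cell totals
    sidecar = (
        path / "library_sizes.tsv" if fmt == "mtx"
        else path.with_suffix(path.suffix + ".libsize.tsv")
    )
    if sidecar.exists():
        ls = pd.read_csv(sidecar, sep="\t", index_col=0)
        lib = ls.iloc[:, 0].reindex(cell_ids).to_numpy(dtype=float)
        if np.isnan(lib).any():
            raise ValueError("library-size sidecar does not cover all cells")
    else:
        lib = counts.sum(axis=1).astype(float)
    keep = lib >= min_library
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d cells with library size < %d", dropped, min_library)
    if not keep.any():
        raise ValueError("no cells pass the library-size floor")
    return CountMatrix(
        counts=counts[keep],
        cell_ids=[c for c, k in zip(cell_ids, keep) if k],
        gene_ids=gene_ids,
        library_size=lib[keep],
    )


def write_counts(cm: CountMatrix, path, fmt: str = "tsv") -> None:
    """Write a count matrix as dense TSV or a MatrixMarket triplet directory."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids)
        df.index.name = "cell"
        df.to_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".libsize.tsv")
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(path / "matrix.mtx", coo_matrix(cm.counts.T))
        pd.Series(cm.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({0: cm.gene_ids, 1: cm.gene_ids, 2: "Gene Expression"}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        sidecar = path / "library_sizes.tsv"
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not np.allclose(cm.library_size, cm.counts.sum(axis=1)):
        pd.DataFrame(
            {"cell_id": cm.cell_ids, "library_size": cm.library_size}
        ).set_index("cell_id").to_csv(sidecar, sep="\t")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _arcs_to_str(arcs) -> str:
    # hi may exceed 2pi for arcs wrapping through 0; keep the raw span so
    # containment can be reconstructed, converting both ends to hours
    return ";".join(
        f"{float(radians_to_hours(lo)):.3f}-{float(hi * 12.0 / np.pi):.3f}"
        for lo, hi in arcs
    )


def write_phase_report(
    report: PhaseReport,
    trace: EvidenceTrace,
    state: VariationalState,
    outdir,
    run_config: RunConfig | None = None,
) -> dict:
    """Write cells.tsv, genes.tsv, evidence.tsv and run_metadata.yaml.

    Returns the paths written. Phase hours always lie in [0, 24), with
    hour 0 anchored at the reference gene's acrophase.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cells = pd.DataFrame(
        {
            "cell_id": report.cell_ids,
            "phase_radians": report.phase_radians,
            "phase_hours": report.phase_hours,
        }
    )
    for level in sorted(report.credible_arcs):
        cells[f"hdr_{level:g}"] = [
            _arcs_to_str(arcs) for arcs in report.credible_arcs[level]
        ]
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False, float_format="%.6f")

    clock = set(state.clock_genes)
    de_novo = set(report.de_novo_genes)
    rows = []
    for pos, gene in enumerate(state.cycling_genes):
        rows.append(
            {
                "gene_id": gene,
                "mesor": state.mesor[pos],
                "amplitude": state.amplitude[pos],
                "acrophase": float(state.q_phi_loc[pos]),
                "q_fraction": state.q_gamma[pos],
                "amplitude_residual": np.nan,
                "is_clock": gene in clock,
                "is_de_novo": gene in de_novo,
            }
        )
    for s in report.gene_summaries:
        if s.gene_id in set(state.cycling_genes):
            continue
        rows.append(
            {
                "gene_id": s.gene_id,
                "mesor": s.mesor,
                "amplitude": s.amplitude,
                "acrophase": s.acrophase,
                "q_fraction": s.q_fraction,
                "amplitude_residual": s.amplitude_residual,
                "is_clock": False,
                "is_de_novo": False,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "genes.tsv", sep="\t", index=False, float_format="%.6f")

    pd.DataFrame(
        {
            "iteration": np.arange(1, len(trace.log_evidence) + 1),
            "log_evidence": trace.log_evidence,
            "log10_bayes_factor": trace.log10_bayes_factor,
            "n_cycling_genes": trace.n_cycling,
        }
    ).to_csv(outdir / "evidence.tsv", sep="\t", index=False, float_format="%.6f")

    meta = {
        "seed": int(state.seed),
        "stopping_reason": report.stopping_reason,
        "n_cells": len(report.cell_ids),
        "n_cycling_genes": len(report.cycling_genes),
        "n_de_novo": len(report.de_novo_genes),
    }
    if run_config is not None:
        meta["config_hash"] = run_config.config_hash()
    with open(outdir / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    return {
        "cells": outdir / "cells.tsv",
        "genes": outdir / "genes.tsv",
        "evidence": outdir / "evidence.tsv",
        "metadata": outdir / "run_metadata.yaml",
    }


def read_phase_report(outdir) -> pd.DataFrame:
    """Reread the per-cell table of a written report."""
    return pd.read_csv(Path(outdir) / "cells.tsv", sep="\t")
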