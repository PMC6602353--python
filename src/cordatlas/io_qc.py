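"""Count-matrix container, 10x-style triplet IO, quality filtering and depth equalization.

The in-memory count matrix is an :class:`anndata.AnnData` with

* ``X`` — sparse CSR matrix of non-negative integer UMI counts, cells x genes,
* ``obs`` — per-cell metadata with optional ``stage`` and ``replicate`` columns,
* ``var`` — per-gene metadata with a boolean ``mito`` column (mitochondrial flag).

On disk the matrix is the 10x sparse-triplet layout: ``matrix.mtx`` (genes x
cells, integer MatrixMarket), ``genes.tsv`` (id, symbol), ``barcodes.tsv`` and an
optional ``cells.tsv`` metadata table (barcode, stage, replicate).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

#: Gene-name prefix that marks mitochondrial genes (mouse nomenclature).
DEFAULT_MITO_PREFIX = "mt-"
#: Cells with a larger fraction of mitochondrial UMIs are discarded.
DEFAULT_MAX_MITO = 0.06
#: Cells detecting fewer genes than this are discarded.
DEFAULT_MIN_GENES = 500


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

def make_count_matrix(
    counts,
    gene_names,
    barcodes,
    stage=None,
    replicate=None,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
) -> AnnData:
    """Build a validated AnnData count matrix (cells x genes).

    ``counts`` may be dense or sparse; it is stored as CSR with an integer
    dtype. ``stage``/``replicate`` are optional per-cell vectors.
    """
    x = sp.csr_matrix(counts)
    _check_counts(x)
    gene_names = pd.Index(np.asarray(gene_names, dtype=object), name="gene")
    barcodes = pd.Index(np.asarray(barcodes, dtype=object), name="barcode")
    if len(gene_names) != x.shape[1]:
        raise CountMatrixError(
            f"{len(gene_names)} gene names for a matrix with {x.shape[1]} columns"
        )
    if len(barcodes) != x.shape[0]:
        raise CountMatrixError(
            f"{len(barcodes)} barcodes for a matrix with {x.shape[0]} rows"
        )
    if gene_names.has_duplicates:
        raise CountMatrixError("gene names are not unique")
    if barcodes.has_duplicates:
        raise CountMatrixError("cell barcodes are not unique")
    obs = pd.DataFrame(index=barcodes)
    if stage is not None:
        obs["stage"] = np.asarray(stage, dtype=object)
    if replicate is not None:
        obs["replicate"] = np.asarray(replicate, dtype=object)
    var = pd.DataFrame(index=gene_names)
    var["mito"] = gene_names.str.startswith(mito_prefix)
    return AnnData(X=x.astype(np.int64), obs=obs, var=var)


def _check_counts(x: sp.spmatrix) -> None:
    data = x.data if sp.issparse(x) else np.asarray(x).ravel()
    if data.size and data.min() < 0:
        raise CountMatrixError("count matrix contains negative entries")
    if data.size and not np.allclose(data, np.round(data)):
        raise CountMatrixError("count matrix contains non-integer entries")


# ---------------------------------------------------------------------------
# 10x triplet IO
# ---------------------------------------------------------------------------

def read_10x(path, mito_prefix: str = DEFAULT_MITO_PREFIX) -> AnnData:
    """Read a 10x-style triplet directory into an AnnData (cells x genes).

    Expects ``matrix.mtx`` (genes x cells), ``genes.tsv``, ``barcodes.tsv`` and,
    if present, ``cells.tsv`` with barcode/stage/replicate columns.
    """
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    genes_file = path / "genes.tsv"
    barcodes_file = path / "barcodes.tsv"
    for f in (mtx_file, genes_file, barcodes_file):
        if not f.exists():
            raise FileNotFoundError(f"missing 10x triplet file: {f}")
    m = scipy.io.mmread(mtx_file)  # genes x cells
    genes = pd.read_csv(genes_file, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str)
    if genes.shape[0] != m.shape[0]:
        raise CountMatrixError(
            f"{genes_file} lists {genes.shape[0]} genes but matrix.mtx has "
            f"{m.shape[0]} rows"
        )
    if barcodes.shape[0] != m.shape[1]:
        raise CountMatrixError(
            f"{barcodes_file} lists {barcodes.shape[0]} barcodes but matrix.mtx "
            f"has {m.shape[1]} columns"
        )
    symbols = genes.iloc[:, 1] if genes.shape[1] > 1 else genes.iloc[:, 0]
    adata = make_count_matrix(
        sp.csr_matrix(m.T), symbols.astype(str).to_numpy(),
        barcodes.to_numpy(), mito_prefix=mito_prefix,
    )
    adata.var["gene_id"] = genes.iloc[:, 0].astype(str).to_numpy()
    cells_file = path / "cells.tsv"
    if cells_file.exists():
        meta = pd.read_csv(cells_file, sep="\t").set_index("barcode")
        meta.index = meta.index.astype(str)
        if not meta.index.equals(pd.Index(adata.obs_names)):
            raise CountMatrixError(
                f"{cells_file} barcodes do not match barcodes.tsv"
            )
        for col in meta.columns:
            adata.obs[col] = meta[col].to_numpy()
    return adata


def write_10x(adata: AnnData, path) -> None:
    """Write an AnnData to the 10x triplet layout with sorted triplet order.

    Triplets are written column-major over the genes x cells orientation, so a
    write/read/write cycle is byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = sp.csc_matrix(adata.X.T)  # genes x cells, column-major order
    m.sum_duplicates()
    scipy.io.mmwrite(path / "matrix.mtx", m, field="integer")
    gene_ids = (
        adata.var["gene_id"]
        if "gene_id" in adata.var
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    pd.DataFrame({"id": np.asarray(gene_ids), "symbol": adata.var_names}).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta_cols = [c for c in ("stage", "replicate") if c in adata.obs]
    if meta_cols:
        meta = adata.obs[meta_cols].copy()
        meta.insert(0, "barcode", adata.obs_names)
        meta.to_csv(path / "cells.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Per-cell QC statistics and the thresholds that were applied."""

    n_input_cells: int
    n_retained_cells: int
    max_mito: float
    min_genes: int
    mito_fraction: pd.Series
    genes_detected: pd.Series
    retained: pd.Series
    warnings: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "n_input_cells": int(self.n_input_cells),
            "n_retained_cells": int(self.n_retained_cells),
            "thresholds": {"max_mito": self.max_mito, "min_genes": self.min_genes},
            "warnings": list(self.warnings),
            "cells": {
                bc: {
                    "mito_fraction": float(self.mito_fraction[bc]),
                    "genes_detected": int(self.genes_detected[bc]),
                    "retained": bool(self.retained[bc]),
                }
                for bc in self.mito_fraction.index
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def cell_qc_stats(adata: AnnData) -> pd.DataFrame:
    """Per-cell mitochondrial UMI fraction and detected-gene count."""
    x = sp.csr_matrix(adata.X)
    total = np.asarray(x.sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    mito = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    detected = np.asarray((x > 0).sum(axis=1)).ravel()
    return pd.DataFrame(
        {"mito_fraction": frac, "genes_detected": detected},
        index=adata.obs_names,
    )


def filter_cells(
    adata: AnnData,
    max_mito: float = DEFAULT_MAX_MITO,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[AnnData, QcReport]:
    """Discard cells with a high mitochondrial fraction or few detected genes.

    A cell is retained when its mitochondrial UMI fraction is at most
    ``max_mito`` *and* it detects at least ``min_genes`` genes (a gene counts as
    detected when its UMI count is > 0). Boundary cells — exactly at either
    threshold — are retained.
    """
    stats = cell_qc_stats(adata)
    notes: list[str] = []
    if not adata.var["mito"].any():
        notes.append(
            "no genes flagged mitochondrial; filtering on detected genes only"
        )
        warnings.warn(notes[-1])
        mito_ok = np.ones(adata.n_obs, dtype=bool)
    else:
        mito_ok = stats["mito_fraction"].to_numpy() <= max_mito
    genes_ok = stats["genes_detected"].to_numpy() >= min_genes
    keep = mito_ok & genes_ok
    report = QcReport(
        n_input_cells=adata.n_obs,
        n_retained_cells=int(keep.sum()),
        max_mito=max_mito,
        min_genes=min_genes,
        mito_fraction=stats["mito_fraction"],
        genes_detected=stats["genes_detected"],
        retained=pd.Series(keep, index=adata.obs_names),
        warnings=notes,
    )
    return adata[keep].copy(), report


# ---------------------------------------------------------------------------
# depth equalization
# ---------------------------------------------------------------------------

def equalize_depth(samples: list[AnnData], seed: int) -> list[AnnData]:
    """Downsample per-cell UMI totals so all samples share the lowest mean depth.

    Mirrors read-level depth normalisation on the UMI matrix: within each
    higher-depth sample every cell's total is thinned by hypergeometric sampling
    without replacement to the common fraction ``min_mean / sample_mean``.
    Deterministic given ``seed``; zero entries stay zero and no total increases.
    """
    if len(samples) < 2:
        raise ValueError("equalize_depth needs at least two samples")
    universe = set(samples[0].var_names)
    for s in samples[1:]:
        if universe.isdisjoint(s.var_names):
            raise ValueError("samples have disjoint gene sets")
        if set(s.var_names) != universe:
            raise ValueError("samples must share an identical gene universe")
    rng = np.random.default_rng(seed)
    means = [float(np.asarray(s.X.sum(axis=1)).mean()) for s in samples]
    target = min(means)
    out = []
    for s, mean in zip(samples, means):
        if mean <= target:
            out.append(s.copy())
            continue
        frac = target / mean
        x = sp.csr_matrix(s.X).astype(np.int64)
        new = x.copy()
        for i in range(x.shape[0]):
            row = x.getrow(i)
            total = int(row.sum())
            keep = int(round(total * frac))
            if keep >= total:
                continue
            colors = row.data.astype(np.int64)
            thinned = rng.multivariate_hypergeometric(colors, keep)
            new.data[new.indptr[i]: new.indptr[i + 1]] = thinned
        new.eliminate_zeros()
        res = s.copy()
        res.X = new
        out.append(res)
    return out
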