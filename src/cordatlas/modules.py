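"""Iterative discovery of concertedly expressed gene modules.

Relevant transcriptomic features are groups of genes with concerted expression
across cells. Genes correlating (Spearman) with at least ``min_partners``
other genes are pre-selected, lowering the correlation cutoff until roughly a
target number of genes is retained. The retained genes are then grouped and
filtered iteratively:

1. hierarchical clustering of genes on the Spearman dissimilarity (1 - rho)
   with Ward's agglomeration criterion, cut into a fixed number of modules;
2. per-cell module scores (mean z-scored log level over module genes) are
   binarized with a parameter-free adaptive threshold; modules expressed in
   fewer than ``min_cells_expressing`` cells are excluded;
3. among module-expressing cells, the fraction of true gene-level Boolean
   calls must reach ``min_true_ratio``, otherwise the module is excluded.

Genes of excluded modules are dropped and the loop repeats until no module is
excluded. The module count never increases, so the loop always terminates.
This module contains no randomness: identical inputs give identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


@dataclass
class ModuleConfig:
    """Tuning knobs of the module-identification loop.

    ``n_modules`` is a heuristic granularity choice for the initial clustering
    (200 for a ~2000-gene selection on real data); after filtering it is scaled
    down proportionally to the surviving gene count.
    """

    target_n_correlated_genes: int = 2000
    min_partners: int = 3
    n_modules: int = 200
    min_cells_expressing: int = 5
    min_true_ratio: float = 0.40
    correlation_cutoff_schedule: tuple = tuple(np.round(np.arange(0.5, 0.04, -0.05), 2))

    def __post_init__(self) -> None:
        for name in ("target_n_correlated_genes", "min_partners", "n_modules",
                     "min_cells_expressing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_true_ratio < 1:
            raise ValueError("min_true_ratio must be in (0, 1)")


@dataclass
class GeneModuleSet:
    """Disjoint gene modules with per-cell scores, calls and loop history."""

    modules: dict
    cell_scores: pd.DataFrame
    cell_calls: pd.DataFrame
    history: list = field(default_factory=list)
    converged: bool = False

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.modules.values() for g in genes]

    def module_of(self, gene: str):
        for mid, genes in self.modules.items():
            if gene in genes:
                return mid
        return None


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

def _dense(adata_or_matrix, genes=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(adata_or_matrix, AnnData):
        sub = adata_or_matrix if genes is None else adata_or_matrix[:, list(genes)]
        x = sub.X
        names = list(sub.var_names)
    else:
        x = adata_or_matrix
        names = list(genes) if genes is not None else [
            f"g{i}" for i in range(x.shape[1])
        ]
    x = x.toarray() if sp.issparse(x) else np.asarray(x)
    return x.astype(float), names


def spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Gene-gene Spearman correlation; constant genes get rho 0 and a warning."""
    ranks = rankdata(x, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes; Spearman rho set to 0")
    safe = ranks.copy()
    safe[:, constant] = np.arange(x.shape[0])[:, None]  # placeholder, zeroed below
    rho = np.corrcoef(safe, rowvar=False)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def select_correlated_genes(adata_or_matrix, cfg: ModuleConfig | None = None,
                            genes=None) -> list[str]:
    """Genes with high positive Spearman correlation to >= min_partners others.

    Lowers the cutoff along the schedule until the retained count first reaches
    the target; if the schedule is exhausted, returns whatever qualifies at the
    final cutoff with a warning.
    """
    cfg = cfg or ModuleConfig()
    x, names = _dense(adata_or_matrix, genes)
    if x.shape[1] < cfg.min_partners + 1:
        raise ValueError("need more genes than min_partners")
    rho = spearman_matrix(x)
    np.fill_diagonal(rho, -np.inf)  # partners exclude self
    selected: list[str] = []
    for cutoff in cfg.correlation_cutoff_schedule:
        partners = (rho >= cutoff).sum(axis=1)
        keep = partners >= cfg.min_partners
        selected = [names[i] for i in np.flatnonzero(keep)]
        if len(selected) >= cfg.target_n_correlated_genes:
            return selected
    warnings.warn(
        f"correlation schedule exhausted with {len(selected)} genes "
        f"(target {cfg.target_n_correlated_genes})"
    )
    return selected


def cluster_gene_modules(adata_or_matrix, genes, n_modules: int) -> dict:
    """Ward clustering of genes on the Spearman dissimilarity 1 - rho.

    Cuts the tree into exactly ``n_modules`` groups; module ids follow the
    order of first appearance along the input gene list, so the partition is
    invariant to gene order up to ids.
    """
    genes = list(genes)
    if len(genes) < n_modules:
        raise ValueError(f"{len(genes)} genes cannot form {n_modules} modules")
    x, names = _dense(adata_or_matrix, genes)
    if n_modules == len(genes):
        return {i: (g,) for i, g in enumerate(names)}
    rho = spearman_matrix(x)
    d = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="ward")
    flat = cut_tree(z, n_clusters=n_modules).ravel()
    modules: dict[int, list[str]] = {}
    remap: dict[int, int] = {}
    for g, c in zip(names, flat):
        mid = remap.setdefault(c, len(remap))
        modules.setdefault(mid, []).append(g)
    return {mid: tuple(gs) for mid, gs in modules.items()}


# ---------------------------------------------------------------------------
# scoring, binarization and filtering
# ---------------------------------------------------------------------------

def zscored_log(x: np.ndarray) -> np.ndarray:
    """Per-gene z-score of log(count + 1); zero-variance genes map to 0."""
    logged = np.log1p(x)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mu) / sd
    z[:, sd == 0] = 0.0
    return z


def module_cell_scores(adata_or_matrix, modules: dict, genes=None) -> pd.DataFrame:
    """Per-cell module score: mean z-scored log level over module genes."""
    if not modules:
        raise ValueError("no modules given")
    all_genes = [g for gs in modules.values() for g in gs]
    x, names = _dense(adata_or_matrix, all_genes if genes is None else genes)
    pos = {g: i for i, g in enumerate(names)}
    z = zscored_log(x)
    cols = {
        mid: z[:, [pos[g] for g in gs]].mean(axis=1) for mid, gs in modules.items()
    }
    index = (
        adata_or_matrix.obs_names
        if isinstance(adata_or_matrix, AnnData)
        else pd.RangeIndex(x.shape[0])
    )
    return pd.DataFrame(cols, index=index)


def adaptive_binarize(values) -> np.ndarray:
    """Parameter-free two-class split of a 1-D vector.

    The threshold minimizes the total within-group sum of squared deviations
    over all splits of the sorted values; entries above the threshold are True.
    A constant vector yields all False. Ties in the objective resolve to the
    lowest threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("adaptive_binarize needs at least two values")
    s = np.sort(v)
    if s[0] == s[-1]:
        return np.zeros(v.size, dtype=bool)
    n = v.size
    c1 = np.cumsum(s)
    c2 = np.cumsum(s ** 2)
    k = np.arange(1, n)  # low group size
    sse_low = c2[k - 1] - c1[k - 1] ** 2 / k
    sse_high = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    sse = sse_low + sse_high
    valid = s[k] > s[k - 1]  # a threshold must separate distinct values
    sse[~valid] = np.inf
    best = int(np.argmin(sse))
    threshold = 0.5 * (s[best] + s[best + 1])
    return v > threshold


def gene_level_calls(adata_or_matrix, genes) -> pd.DataFrame:
    """Adaptive binarization of each gene's z-scored log levels across cells."""
    x, names = _dense(adata_or_matrix, genes)
    z = zscored_log(x)
    calls = np.column_stack([adaptive_binarize(z[:, j]) for j in range(z.shape[1])])
    index = (
        adata_or_matrix.obs_names
        if isinstance(adata_or_matrix, AnnData)
        else pd.RangeIndex(x.shape[0])
    )
    return pd.DataFrame(calls, index=index, columns=names)


def filter_modules(
    modules: dict,
    cell_scores: pd.DataFrame,
    gene_calls: pd.DataFrame,
    cfg: ModuleConfig | None = None,
):
    """Apply the expressing-cell and Boolean-consistency module filters.

    A module survives iff (a) its binarized score is True in at least
    ``min_cells_expressing`` cells and (b) among those module-expressing
    cells, at least ``min_true_ratio`` of the gene-level Boolean values over
    its genes are True. Returns ``(survivors, removed_ids, cell_calls)``.
    """
    cfg = cfg or ModuleConfig()
    calls = pd.DataFrame(
        {mid: adaptive_binarize(cell_scores[mid].to_numpy()) for mid in modules},
        index=cell_scores.index,
    )
    survivors, removed = {}, []
    for mid, genes in modules.items():
        expressing = calls[mid].to_numpy()
        if expressing.sum() < cfg.min_cells_expressing:
            removed.append(mid)
            continue
        ratio = gene_calls.loc[expressing, list(genes)].to_numpy().mean()
        if ratio < cfg.min_true_ratio:
            removed.append(mid)
            continue
        survivors[mid] = genes
    return survivors, removed, calls


def identify_modules(
    adata_or_matrix, cfg: ModuleConfig | None = None, genes=None
) -> GeneModuleSet:
    """Full iterative module-identification loop.

    Pre-selects correlated genes, then repeats cluster -> score -> binarize ->
    filter, dropping the genes of excluded modules and re-clustering the
    survivors with a proportionally smaller module count, until no module is
    excluded. Deterministic and guaranteed to terminate.
    """
    cfg = cfg or ModuleConfig()
    if not isinstance(adata_or_matrix, AnnData):
        x = np.asarray(adata_or_matrix, dtype=float)
        names = list(genes) if genes is not None else [
            f"g{i}" for i in range(x.shape[1])
        ]
        adata_or_matrix = AnnData(
            X=x, var=pd.DataFrame(index=pd.Index(names, name="gene"))
        )
        genes = None
    current = select_correlated_genes(adata_or_matrix, cfg, genes)
    initial = max(len(current), 1)
    history: list[int] = []
    index = adata_or_matrix.obs_names
    empty = GeneModuleSet(
        {}, pd.DataFrame(index=index), pd.DataFrame(index=index), history, True
    )
    while True:
        if len(current) < 2:
            warnings.warn("all modules excluded; empty module set")
            return empty
        n_mod = max(2, min(len(current),
                           round(cfg.n_modules * len(current) / initial)))
        modules = cluster_gene_modules(adata_or_matrix, current, n_mod)
        scores = module_cell_scores(adata_or_matrix, modules)
        calls_by_gene = gene_level_calls(adata_or_matrix, current)
        survivors, removed, cell_calls = filter_modules(
            modules, scores, calls_by_gene, cfg
        )
        history.append(len(modules))
        if not removed:
            return GeneModuleSet(
                survivors, scores[list(survivors)], cell_calls[list(survivors)],
                history, True,
            )
        if not survivors:
            warnings.warn("all modules excluded; empty module set")
            empty.history = history
            return empty
        current = [g for gs in survivors.values() for g in gs]
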