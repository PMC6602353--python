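"""Neurogenesis pseudotime by PCA on a curated trajectory gene space.

The differentiation axis from progenitor to neuron is reconstructed linearly:
a dataset balanced over (stage, dorsoventral domain) strata defines a
PC1-PC2 plane over a curated gene space (the modules containing the
pan-progenitor, pan-neuronal, early- and late-progenitor anchors, purged of
dorsoventrally biased genes); the whole dataset is then projected onto that
plane with the fitted eigenvectors, and pseudotime is the PC1 coordinate
oriented so the pan-neuronal anchor increases along it. Per-domain expression
profiles along pseudotime are smoothed with natural cubic splines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.decomposition import PCA

from .modules import GeneModuleSet, _dense
from .patterns import nb_lrt_multigroup

#: Strata smaller than this are used whole instead of subsampled.
DEFAULT_STRATUM_FLOOR = 25
#: Genes more dorsoventrally biased than this are excluded from the gene space.
DEFAULT_DV_P_CUTOFF = 5e-15


# ---------------------------------------------------------------------------
# balanced resampling
# ---------------------------------------------------------------------------

def balanced_resample(
    adata: AnnData,
    stage_labels,
    domain_labels,
    seed: int,
    floor: int = DEFAULT_STRATUM_FLOOR,
) -> AnnData:
    """Sample approximately equal cell numbers per (stage, domain) stratum.

    Each stratum of at least ``floor`` cells is subsampled without replacement
    to the size of the smallest such stratum; smaller strata are taken whole.
    Deterministic given ``seed``.
    """
    stages = np.asarray(stage_labels)
    domains = np.asarray(domain_labels)
    if adata.n_obs == 0:
        raise ValueError("no cells to resample")
    strata = pd.MultiIndex.from_arrays([stages, domains])
    sizes = pd.Series(1, index=strata).groupby(level=[0, 1]).count()
    eligible = sizes[sizes >= floor]
    target = int(eligible.min()) if len(eligible) else None
    rng = np.random.default_rng(seed)
    keep = np.zeros(adata.n_obs, dtype=bool)
    for key in sizes.index:
        mask = np.flatnonzero((stages == key[0]) & (domains == key[1]))
        if target is None or len(mask) < floor or len(mask) <= target:
            keep[mask] = True
        else:
            keep[rng.choice(mask, size=target, replace=False)] = True
    return adata[keep].copy()


# ---------------------------------------------------------------------------
# trajectory gene selection
# ---------------------------------------------------------------------------

class TrajectoryGenes(NamedTuple):
    retained: list
    excluded: list


def select_trajectory_genes(
    adata: AnnData,
    modules: GeneModuleSet | dict,
    anchors,
    dv_labels,
    p_cutoff: float = DEFAULT_DV_P_CUTOFF,
) -> TrajectoryGenes:
    """Union of the anchor-containing modules, purged of DV-biased genes.

    Each anchor (e.g. Sox2, Tubb3, Lin28a, Fabp7) must belong to exactly one
    module; the union of those modules' genes is tested for differential
    expression against the dorsoventral domain label with an omnibus NB LRT
    (chi-square, ``n_domains - 1`` degrees of freedom), and genes with
    ``p < p_cutoff`` are excluded.
    """
    module_map = modules.modules if isinstance(modules, GeneModuleSet) else modules
    chosen: dict = {}
    for anchor in anchors:
        owners = [mid for mid, genes in module_map.items() if anchor in genes]
        if not owners:
            raise ValueError(f"anchor gene '{anchor}' is in no module")
        if len(owners) > 1:
            raise ValueError(f"anchor gene '{anchor}' is in several modules: {owners}")
        chosen[owners[0]] = module_map[owners[0]]
    genes = list(dict.fromkeys(g for gs in chosen.values() for g in gs))
    labels = np.asarray(dv_labels)
    x, names = _dense(adata, genes)
    retained, excluded = [], []
    for j, g in enumerate(names):
        _, p = nb_lrt_multigroup(x[:, j], labels)
        (excluded if p < p_cutoff else retained).append(g)
    return TrajectoryGenes(retained, excluded)


# ---------------------------------------------------------------------------
# median-ratio normalization
# ---------------------------------------------------------------------------

def median_ratio_size_factors(
    x: np.ndarray, reference: np.ndarray | None = None, min_ref_genes: int = 10
):
    """Per-cell median-ratio size factors.

    The reference is the per-gene geometric mean over the fit cells, using the
    genes detected in every fit cell; with fewer than ``min_ref_genes`` such
    genes the size factors fall back to total-count scaling. Returns
    ``(size_factors, reference)`` where ``reference`` is ``None`` for the
    fallback; pass the returned reference to normalize further matrices
    consistently.
    """
    x = np.asarray(x, dtype=float)
    if reference is None:
        everywhere = (x > 0).all(axis=0)
        if everywhere.sum() < min_ref_genes:
            totals = x.sum(axis=1)
            sf = totals / max(totals.mean(), 1e-12)
            return np.where(sf > 0, sf, 1.0), None
        ref = np.full(x.shape[1], np.nan)
        ref[everywhere] = np.exp(np.log(x[:, everywhere]).mean(axis=0))
        reference = ref
    used = np.isfinite(reference) & (reference > 0)
    if not used.any():
        totals = x.sum(axis=1)
        sf = totals / max(totals.mean(), 1e-12)
        return np.where(sf > 0, sf, 1.0), None
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = x[:, used] / reference[used]
    sf = np.median(ratios, axis=1)
    bad = ~(sf > 0)
    if bad.any():  # cells empty on reference genes: total-count fallback
        totals = x.sum(axis=1)
        sf[bad] = np.maximum(totals[bad] / max(totals.mean(), 1e-12), 1e-12)
    return sf, reference


def log_normalize(x: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """log(1 + count / size factor)."""
    return np.log1p(np.asarray(x, dtype=float) / size_factors[:, None])


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

@dataclass
class PseudotimeProjection:
    """Fitted PC plane, per-cell coordinates and the oriented pseudotime."""

    eigenvectors: pd.DataFrame  # genes x [PC1, PC2], orthonormal columns
    pc1: pd.Series
    pc2: pd.Series
    pseudotime: pd.Series       # oriented PC1
    genes: list
    excluded_genes: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"PC1": self.pc1, "PC2": self.pc2, "pseudotime": self.pseudotime}
        )


def project_pca(
    m_fit: AnnData,
    m_apply: AnnData,
    genes,
    neuron_anchor: str = "Tubb3",
    excluded_genes=(),
) -> PseudotimeProjection:
    """Fit PCA on the balanced matrix, project the full dataset, orient PC1.

    Counts are median-ratio normalized (reference genes and geometric means
    from the fit matrix) and log-transformed; a two-component PCA is fitted on
    the fit matrix and both matrices share its eigenvectors. PC1's sign is
    fixed so the pan-neuronal anchor gene increases with pseudotime.
    """
    genes = list(genes)
    if m_fit.n_obs < 3:
        raise ValueError("need at least three cells to fit the PC plane")
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    # size factors come from the full transcriptome, not the curated subset
    full_fit, fit_names = _dense(m_fit)
    full_apply, _ = _dense(m_apply)
    sf_fit, reference = median_ratio_size_factors(full_fit)
    if reference is not None and m_apply.n_vars == m_fit.n_vars:
        sf_apply, _ = median_ratio_size_factors(full_apply, reference=reference)
    else:
        sf_apply, _ = median_ratio_size_factors(full_apply)
    x_fit, _ = _dense(m_fit, genes)
    x_apply, _ = _dense(m_apply, genes)
    l_fit = log_normalize(x_fit, sf_fit)
    l_apply = log_normalize(x_apply, sf_apply)
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(l_fit)
    scores = (l_apply - pca.mean_) @ pca.components_.T
    vecs = pca.components_.T.copy()  # genes x 2
    pc1, pc2 = scores[:, 0], scores[:, 1]
    if neuron_anchor in genes:
        anchor_level = l_apply[:, genes.index(neuron_anchor)]
        if np.std(anchor_level) > 0 and np.corrcoef(pc1, anchor_level)[0, 1] < 0:
            pc1 = -pc1
            vecs[:, 0] = -vecs[:, 0]
    index = m_apply.obs_names
    return PseudotimeProjection(
        eigenvectors=pd.DataFrame(vecs, index=genes, columns=["PC1", "PC2"]),
        pc1=pd.Series(pc1, index=index),
        pc2=pd.Series(pc2, index=index),
        pseudotime=pd.Series(pc1, index=index),
        genes=genes,
        excluded_genes=list(excluded_genes),
    )


# ---------------------------------------------------------------------------
# smoothed per-domain expression profiles
# ---------------------------------------------------------------------------

@dataclass
class SmoothedProfile:
    domain: str
    gene: str
    coefficients: np.ndarray
    grid: np.ndarray
    values: np.ndarray
    n_expressing_cells: int
    flagged: bool = False


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (intercept included) with the given knots.

    With K knots the basis has K columns: 1, x, and K-2 truncated-cubic
    combinations that are linear beyond the boundary knots. K = 4 knots give a
    fit with three effective degrees of freedom beyond the intercept.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)

    def d(k):
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - last)
    return np.column_stack(cols)


def smooth_profiles(
    adata: AnnData,
    pseudotime,
    domain_labels,
    genes,
    df: int = 3,
    min_cells: int = 20,
    n_grid: int = 100,
) -> list[SmoothedProfile]:
    """Per-(domain, gene) spline fits of log-normalized expression vs pseudotime.

    A natural cubic spline with ``df`` degrees of freedom (knots at pseudotime
    quantiles of the domain's cells) is fitted by least squares. Profiles with
    fewer than ``min_cells`` expressing cells — or domains with too few cells
    to constrain the fit — are set identically to zero and flagged. Each
    profile is evaluated on a grid spanning its own domain's pseudotime range;
    outside that range the fit would be unsupported extrapolation.
    """
    pt = np.asarray(pseudotime, dtype=float)
    labels = np.asarray(domain_labels)
    genes = list(genes)
    if len(pt) != adata.n_obs or len(labels) != adata.n_obs:
        raise ValueError("pseudotime and domain labels must align with cells")
    full, _ = _dense(adata)
    sf, _ = median_ratio_size_factors(full)
    x, _ = _dense(adata, genes)
    lx = log_normalize(x, sf)
    out = []
    for domain in dict.fromkeys(labels):
        mask = labels == domain
        t = pt[mask]
        grid = (
            np.linspace(t.min(), t.max(), n_grid)
            if mask.any()
            else np.linspace(pt.min(), pt.max(), n_grid)
        )
        n_params = df + 1
        degenerate_domain = mask.sum() < n_params or np.ptp(t) == 0
        if not degenerate_domain:
            knots = np.quantile(t, np.linspace(0, 1, df + 1))
            knots = np.unique(knots)
            if len(knots) < df + 1:
                degenerate_domain = True
        for j, gene in enumerate(genes):
            n_expr = int((x[mask, j] > 0).sum())
            if degenerate_domain or n_expr < min_cells:
                out.append(
                    SmoothedProfile(
                        domain, gene, np.zeros(n_params), grid,
                        np.zeros(n_grid), n_expr, flagged=True,
                    )
                )
                continue
            basis = natural_spline_basis(t, knots)
            coef, *_ = np.linalg.lstsq(basis, lx[mask, j], rcond=None)
            values = natural_spline_basis(grid, knots) @ coef
            out.append(SmoothedProfile(domain, gene, coef, grid, values, n_expr))
    return out


def profiles_to_frame(profiles: list[SmoothedProfile]) -> pd.DataFrame:
    """Long-format table (domain, gene, grid point, value)."""
    rows = []
    for p in profiles:
        for g, v in zip(p.grid, p.values):
            rows.append(
                {"domain": p.domain, "gene": p.gene, "pseudotime": g, "value": v}
            )
    return pd.DataFrame(rows)
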