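"""Neuronal subtype discovery within one cardinal class.

Cells of a single neuronal class are clustered hierarchically (Ward linkage on
Euclidean distances between z-scored log-transformed levels of curated-module
genes) and the tree is cut at a user-chosen clade count — clade counts are a
curation decision made per class by inspecting the dendrogram, not an
automatic model selection. Clades violating marker expectations (e.g. high
progenitor markers inside a neuronal class) can be flagged for exclusion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree

from .modules import _dense, zscored_log

#: Expected-sign convention for marker rules.
EXPECTED_PRESENT = 1
EXPECTED_ABSENT = -1


@dataclass
class SubtypeResult:
    """Clade labels, the dendrogram and per-clade summaries."""

    labels: pd.Series          # contiguous integers starting at 0
    linkage_matrix: np.ndarray
    modules_used: list
    mean_stage: pd.Series      # mean numeric stage per clade (NaN if unparsable)

    @property
    def n_subtypes(self) -> int:
        return int(self.labels.max()) + 1

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with barcodes as leaf names."""
        root = to_tree(self.linkage_matrix)
        names = list(self.labels.index)

        def fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(root, root.dist) + ";"


def _stage_to_number(stage) -> float:
    m = re.search(r"(\d+(?:\.\d+)?)", str(stage))
    return float(m.group(1)) if m else np.nan


def cluster_cells(
    adata: AnnData,
    curated_modules,
    k: int,
    linkage_method: str = "ward",
) -> SubtypeResult:
    """Hierarchical clustering of cells in curated-module gene space.

    ``curated_modules`` is a mapping of module id to gene list (or a flat gene
    list); features are z-scored log(count + 1) levels of the union of those
    genes. The tree is cut into ``k`` clades, labelled contiguously in order
    of first appearance along the cell list.
    """
    if isinstance(curated_modules, dict):
        genes = [g for gs in curated_modules.values() for g in gs]
        modules_used = list(curated_modules)
    else:
        genes = list(curated_modules)
        modules_used = ["curated"]
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"curated module genes absent from matrix: {missing}")
    if adata.n_obs < 2:
        raise ValueError("need at least two cells to cluster")
    if k > adata.n_obs:
        raise ValueError(f"k={k} exceeds the number of cells ({adata.n_obs})")
    x, _ = _dense(adata, genes)
    z = zscored_log(x)
    zmat = linkage(z, method=linkage_method)
    flat = cut_tree(zmat, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap)) for c in flat])
    labels = pd.Series(labels, index=adata.obs_names, name="subtype")
    if "stage" in adata.obs:
        stage_num = adata.obs["stage"].map(_stage_to_number)
        mean_stage = stage_num.groupby(labels).mean()
    else:
        mean_stage = pd.Series(np.nan, index=sorted(set(labels)))
    return SubtypeResult(labels, zmat, modules_used, mean_stage)


def flag_misassigned_clades(
    result: SubtypeResult,
    adata: AnnData,
    marker_rules: dict,
    z_threshold: float = 0.5,
) -> dict:
    """Flag clades whose mean marker expression violates expectations.

    ``marker_rules`` maps a gene to an expected sign: ``EXPECTED_ABSENT`` (-1)
    flags clades where the gene's mean z-scored log level exceeds
    ``z_threshold`` (e.g. progenitor markers inside a neuronal class);
    ``EXPECTED_PRESENT`` (+1) flags clades where it falls below
    ``-z_threshold``. Returns ``{clade: [violated genes]}`` for flagged clades.
    """
    missing = [g for g in marker_rules if g not in adata.var_names]
    if missing:
        raise KeyError(f"rule genes absent from matrix: {missing}")
    if not marker_rules:
        return {}
    genes = list(marker_rules)
    x, _ = _dense(adata, genes)
    z = zscored_log(x)
    flags: dict[int, list[str]] = {}
    for clade in range(result.n_subtypes):
        mask = result.labels.to_numpy() == clade
        means = z[mask].mean(axis=0)
        violated = [
            g
            for g, m in zip(genes, means)
            if (marker_rules[g] == EXPECTED_ABSENT and m > z_threshold)
            or (marker_rules[g] == EXPECTED_PRESENT and m < -z_threshold)
        ]
        if violated:
            flags[clade] = violated
    return flags
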