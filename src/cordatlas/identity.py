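"""Cell-identity assignment from a binary marker knowledge matrix.

Each cell's marker profile is binarized (UMI count >= threshold) and compared
with the rows of a knowledge matrix — a binary identities x markers table in
which each progenitor domain, neuronal class or coarse tissue is defined by a
characteristic marker combination. The cell inherits the identity of the row at
minimal Euclidean distance. Assignment is two-step: coarse tissue first, then
dorsoventral domain within progenitors and class within neurons.

An identity may own several alternative rows (e.g. early neurons that still
carry progenitor markers); the cell-to-identity distance is the minimum over
that identity's rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

#: Binarization threshold in UMI counts; a count of exactly 2 switches a marker on.
DEFAULT_BINARIZE_THRESHOLD = 2

TISSUE_LEVEL = "tissue"
PROGENITOR_LEVEL = "progenitor-domain"
NEURON_LEVEL = "neuronal-class"
UNCLASSIFIED = "unclassified"

#: Tissue labels whose cells receive a second, domain-level assignment.
NEURAL_TISSUES = {"progenitor": PROGENITOR_LEVEL, "neuron": NEURON_LEVEL}


class KnowledgeMatrixError(ValueError):
    pass


@dataclass
class KnowledgeMatrix:
    """Binary identities x markers table, possibly spanning several levels.

    ``table`` holds one row per marker combination with columns ``identity``,
    ``level`` and one 0/1 column per marker gene. Several rows may share an
    identity (alternative marker combinations); two rows with identical vectors
    but different identities at the same level are rejected as non-identifiable.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "identity" not in self.table or "level" not in self.table:
            raise KnowledgeMatrixError("table needs 'identity' and 'level' columns")
        if not self.marker_names:
            raise KnowledgeMatrixError("knowledge matrix has no marker columns")
        values = self.table[self.marker_names].to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise KnowledgeMatrixError("marker entries must be 0 or 1")
        for level in self.levels:
            sub = self.table[self.table["level"] == level]
            vecs = sub[self.marker_names].to_numpy()
            seen: dict[bytes, str] = {}
            for ident, vec in zip(sub["identity"], vecs):
                key = vec.tobytes()
                if seen.get(key, ident) != ident:
                    raise KnowledgeMatrixError(
                        f"rows for '{seen[key]}' and '{ident}' at level '{level}' "
                        "are identical and make the matrix non-identifiable"
                    )
                seen[key] = ident

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("identity", "level")]

    @property
    def levels(self) -> list[str]:
        return list(dict.fromkeys(self.table["level"]))

    def identities(self, level: str) -> list[str]:
        sub = self.table[self.table["level"] == level]
        return list(dict.fromkeys(sub["identity"]))

    def at_level(self, level: str) -> "KnowledgeMatrix":
        """Restrict to one level, dropping markers unused at that level."""
        sub = self.table[self.table["level"] == level].reset_index(drop=True)
        if sub.empty:
            raise KnowledgeMatrixError(f"no rows at level '{level}'")
        markers = [m for m in self.marker_names if sub[m].any()]
        return KnowledgeMatrix(sub[["identity", "level", *markers]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, level: str | None = None) -> "KnowledgeMatrix":
        """Read a TSV whose first column is the identity label.

        A ``level`` column is optional in the file; when absent, ``level``
        (default "tissue") is assigned to every row.
        """
        table = pd.read_csv(path, sep="\t")
        first = table.columns[0]
        if first != "identity":
            table = table.rename(columns={first: "identity"})
        if "level" not in table:
            table.insert(1, "level", level or TISSUE_LEVEL)
        return cls(table)


# ---------------------------------------------------------------------------
# binarization and nearest-row assignment
# ---------------------------------------------------------------------------

def binarize_markers(
    adata: AnnData,
    markers: list[str],
    threshold: int = DEFAULT_BINARIZE_THRESHOLD,
) -> np.ndarray:
    """Binary cells x markers matrix: 1 iff the UMI count is >= threshold."""
    missing = [m for m in markers if m not in adata.var_names]
    if missing:
        raise KeyError(f"markers absent from the count matrix: {missing}")
    idx = [adata.var_names.get_loc(m) for m in markers]
    x = sp.csr_matrix(adata.X)[:, idx].toarray()
    return x >= threshold


def _nearest_rows(profiles: np.ndarray, km: KnowledgeMatrix):
    """Squared Euclidean distances of binary profiles to every knowledge row.

    Returns (labels, distance, ambiguous, unclassified_mask) applying the
    maximum-distance rule: a cell whose best row is no closer than the all-zero
    profile is left unclassified rather than force-assigned.
    """
    rows = km.table[km.marker_names].to_numpy(dtype=float)
    idents = km.table["identity"].to_numpy()
    p = profiles.astype(float)
    # squared distance via ||p||^2 + ||r||^2 - 2 p.r ; binary so exact integers
    d2 = (
        (p ** 2).sum(axis=1, keepdims=True)
        + (rows ** 2).sum(axis=1)[None, :]
        - 2.0 * p @ rows.T
    )
    d2 = np.round(d2).astype(np.int64)
    best = d2.min(axis=1)
    first = d2.argmin(axis=1)
    labels = idents[first]
    ambiguous = np.zeros(len(p), dtype=bool)
    for i in range(len(p)):
        tied = np.flatnonzero(d2[i] == best[i])
        if len(set(idents[tied])) > 1:
            ambiguous[i] = True
    n_on = p.sum(axis=1).astype(np.int64)  # squared distance to all-zero profile
    unclassified = best >= n_on
    return labels, np.sqrt(best.astype(float)), ambiguous, unclassified


def assign_identities(
    adata: AnnData,
    km: KnowledgeMatrix,
    threshold: int = DEFAULT_BINARIZE_THRESHOLD,
) -> pd.DataFrame:
    """Two-step nearest-row identity assignment.

    Step one assigns a coarse tissue from the tissue-level rows. Step two
    re-assigns cells labelled ``progenitor``/``neuron`` to a dorsoventral
    domain or neuronal class using the corresponding level of the knowledge
    matrix. Ties are flagged ``ambiguous`` and resolved to the first row in
    knowledge-matrix order; cells matching nothing better than the empty
    profile are ``unclassified``.

    Returns a per-cell table with ``tissue``, ``domain``, ``distance``,
    ``ambiguous`` columns (plus ``stage`` when present in ``adata.obs``).
    """
    if km.table.empty:
        raise KnowledgeMatrixError("empty knowledge matrix")
    tissue_km = km.at_level(TISSUE_LEVEL) if TISSUE_LEVEL in km.levels else km
    labels, dist, amb, uncl = _nearest_rows(
        binarize_markers(adata, tissue_km.marker_names, threshold), tissue_km
    )
    tissue = np.where(uncl, UNCLASSIFIED, labels)
    domain = np.full(adata.n_obs, "", dtype=object)
    distance = dist.copy()
    ambiguous = amb.copy()
    for tissue_label, level in NEURAL_TISSUES.items():
        if level not in km.levels:
            continue
        mask = tissue == tissue_label
        if not mask.any():
            continue
        sub_km = km.at_level(level)
        l2, d2, a2, u2 = _nearest_rows(
            binarize_markers(adata[mask], sub_km.marker_names, threshold), sub_km
        )
        domain[mask] = np.where(u2, UNCLASSIFIED, l2)
        distance[mask] = d2
        ambiguous[mask] |= a2
    out = pd.DataFrame(
        {
            "tissue": tissue,
            "domain": domain,
            "distance": distance,
            "ambiguous": ambiguous,
        },
        index=adata.obs_names,
    )
    for col in ("stage", "replicate"):
        if col in adata.obs:
            out[col] = adata.obs[col].to_numpy()
    return out


def final_labels(ann: pd.DataFrame) -> pd.Series:
    """Most specific label per cell: domain where assigned, else tissue."""
    dom = ann["domain"].astype(str)
    return pd.Series(
        np.where(dom != "", dom, ann["tissue"].astype(str)), index=ann.index
    )


# ---------------------------------------------------------------------------
# doublet-rate estimation
# ---------------------------------------------------------------------------

def estimate_doublet_rate(
    adata: AnnData,
    sig_a: list[str],
    sig_b: list[str],
    threshold: int = DEFAULT_BINARIZE_THRESHOLD,
) -> float:
    """Fraction of cells positive for two disjoint lineage signatures.

    A cell is positive for a signature when at least half of its markers are on
    after binarization. Cells positive for both (e.g. a neural and a mesodermal
    signature) are mixtures of two transcriptomes.
    """
    if set(sig_a) & set(sig_b):
        raise ValueError("signature gene sets overlap")
    pos_a = binarize_markers(adata, list(sig_a), threshold).mean(axis=1) >= 0.5
    pos_b = binarize_markers(adata, list(sig_b), threshold).mean(axis=1) >= 0.5
    return float((pos_a & pos_b).mean())


# ---------------------------------------------------------------------------
# population dynamics
# ---------------------------------------------------------------------------

def population_fractions(ann: pd.DataFrame, stage_col: str = "stage") -> pd.DataFrame:
    """Per-stage population fractions of progenitor domains and neuronal classes.

    Three normalizations per stage, each summing to one:

    * ``combined`` — every domain relative to progenitors + neurons together,
    * ``within_progenitors`` — progenitor domains among progenitors,
    * ``within_neurons`` — neuronal classes among neurons.

    Stages without neural cells yield NaN fractions flagged ``undefined``.
    """
    if stage_col not in ann:
        raise KeyError(f"annotation lacks a '{stage_col}' column")
    rows = []
    neural = ann[
        ann["tissue"].isin(NEURAL_TISSUES) & (ann["domain"] != UNCLASSIFIED)
    ]
    for stage, grp in ann.groupby(stage_col, sort=True, observed=True):
        sub = neural[neural[stage_col] == stage]
        if sub.empty:
            rows.append(
                {
                    "stage": stage, "normalization": "combined", "domain": None,
                    "fraction": np.nan, "n_cells": 0, "undefined": True,
                }
            )
            continue
        total = len(sub)
        for tissue_label, norm in (
            ("progenitor", "within_progenitors"),
            ("neuron", "within_neurons"),
        ):
            part = sub[sub["tissue"] == tissue_label]
            counts = part["domain"].value_counts()
            for dom, n in counts.items():
                rows.append(
                    {
                        "stage": stage, "normalization": norm, "domain": dom,
                        "fraction": n / len(part), "n_cells": int(n),
                        "undefined": False,
                    }
                )
                rows.append(
                    {
                        "stage": stage, "normalization": "combined", "domain": dom,
                        "fraction": n / total, "n_cells": int(n),
                        "undefined": False,
                    }
                )
    return pd.DataFrame(rows)
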