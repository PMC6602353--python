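"""Exhaustive combinatorial spatial-pattern differential expression.

For each gene, every bipartition of the N dorsoventral domains into a
"positive" combination and its complementary "negative" combination is scored
with an approximate chi-square likelihood-ratio test: the null models the gene
with a single negative-binomial mean, the alternative with one mean per side,
both sharing a fixed per-gene dispersion. The gene is associated with the
combination of maximal alternative-model likelihood, then trimmed by
significance, fold-change, mean-expression and expressed-cell-ratio filters.

All 2^N - 2 ordered bipartitions are scored from per-domain sufficient
statistics (count sums, cell counts, log-gamma sums), so the cost per gene is
one pass over cells plus a (2^N - 2) x N matrix product rather than 2^N - 2
separate model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.special import gammaln
from scipy.stats import chi2


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class DomainPartition:
    """A non-empty proper subset of domain labels and its complement."""

    positive: tuple
    negative: tuple

    def __post_init__(self) -> None:
        pos, neg = set(self.positive), set(self.negative)
        if not pos or not neg:
            raise PartitionError("both sides of a partition must be non-empty")
        if pos & neg:
            raise PartitionError("positive and negative sides overlap")

    @property
    def domains(self) -> tuple:
        return tuple(sorted(set(self.positive) | set(self.negative)))


def enumerate_partitions(domains) -> list[DomainPartition]:
    """All 2^N - 2 ordered bipartitions of the domain label set.

    Each subset and its complement appear as two distinct partitions. The order
    is deterministic: subsets are enumerated as bitmasks 1 .. 2^N - 2 over the
    sorted label list.
    """
    labels = sorted(set(domains))
    n = len(labels)
    if n < 2:
        raise PartitionError("need at least two domains to form partitions")
    out = []
    for mask in range(1, 2 ** n - 1):
        pos = tuple(labels[i] for i in range(n) if mask >> i & 1)
        neg = tuple(labels[i] for i in range(n) if not mask >> i & 1)
        out.append(DomainPartition(pos, neg))
    return out


def model_universe_size(n_domains: int) -> int:
    """Number of combinatorial models including the empty and full combinations."""
    return 2 ** int(n_domains)


# ---------------------------------------------------------------------------
# negative-binomial likelihood machinery
# ---------------------------------------------------------------------------

def estimate_dispersion(counts) -> float:
    """Method-of-moments NB dispersion alpha with Var = mu + alpha * mu^2.

    Estimated once per gene across all cells and shared by the null and
    alternative fits (a fixed-variance NB). Falls back to Poisson (alpha = 0)
    when the moment estimate is non-positive.
    """
    x = np.asarray(counts, dtype=float).ravel()
    m = x.mean()
    if m <= 0 or x.size < 2:
        return 0.0
    v = x.var(ddof=1)
    alpha = (v - m) / m ** 2
    return float(max(alpha, 0.0))


def _group_loglik(S, n, T, alpha):
    """NB/Poisson log-likelihood of groups from sufficient statistics.

    ``S`` sum of counts, ``n`` number of cells, ``T`` sum of lgamma(x + r) for
    NB size r = 1/alpha (ignored for alpha = 0). The lgamma(x + 1) observation
    constant is omitted; it cancels in likelihood ratios and is constant across
    partitions of the same cells. The group MLE mean is S / n.
    """
    S = np.asarray(S, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(n > 0, S / np.maximum(n, 1), 0.0)
        if alpha > 0:
            r = 1.0 / alpha
            ll = (
                np.asarray(T, dtype=float)
                - n * gammaln(r)
                + n * r * np.log(r / (r + mu))
                + np.where(S > 0, S * np.log(mu / (r + mu)), 0.0)
            )
        else:
            ll = np.where(S > 0, S * np.log(mu), 0.0) - S
    return np.where(n > 0, ll, 0.0)


@dataclass
class LrtResult:
    lrt_stat: float
    p_value: float
    log2_fc: float


def nb_lrt(counts, positive_mask, dispersion: float | None = None) -> LrtResult:
    """Two-sample NB likelihood-ratio test with shared fixed dispersion.

    Null: one mean for all cells. Alternative: one mean per side. The statistic
    2*(ll_alt - ll_null) is clamped at zero and referred to chi-square with one
    degree of freedom. ``log2_fc`` compares the positive and negative means
    with a pseudo-mean of 1/(cells in group) on each side.
    """
    x = np.asarray(counts, dtype=float).ravel()
    mask = np.asarray(positive_mask, dtype=bool).ravel()
    if mask.all() or not mask.any():
        raise ValueError("both groups of the partition must be non-empty")
    if x.sum() == 0:
        return LrtResult(0.0, 1.0, 0.0)
    alpha = estimate_dispersion(x) if dispersion is None else float(dispersion)
    T = gammaln(x + 1.0 / alpha) if alpha > 0 else np.zeros_like(x)
    S = np.array([x[mask].sum(), x[~mask].sum()])
    n = np.array([mask.sum(), (~mask).sum()], dtype=float)
    Tg = np.array([T[mask].sum(), T[~mask].sum()])
    ll_alt = _group_loglik(S, n, Tg, alpha).sum()
    ll_null = _group_loglik(x.sum(), x.size, T.sum(), alpha).item()
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    mu_pos, mu_neg = S[0] / n[0], S[1] / n[1]
    fc = math.log2((mu_pos + 1.0 / n[0]) / (mu_neg + 1.0 / n[1]))
    return LrtResult(float(stat), float(chi2.sf(stat, df=1)), float(fc))


def nb_lrt_multigroup(counts, group_labels, dispersion: float | None = None):
    """Omnibus NB LRT of expression against a multi-level predictor.

    Null: single mean. Alternative: one mean per level. The statistic is
    referred to chi-square with (number of levels - 1) degrees of freedom.
    Returns ``(stat, p_value)``.
    """
    x = np.asarray(counts, dtype=float).ravel()
    labels = np.asarray(group_labels)
    levels, inv = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if x.sum() == 0:
        return 0.0, 1.0
    alpha = estimate_dispersion(x) if dispersion is None else float(dispersion)
    T = gammaln(x + 1.0 / alpha) if alpha > 0 else np.zeros_like(x)
    S = np.bincount(inv, weights=x, minlength=len(levels))
    n = np.bincount(inv, minlength=len(levels)).astype(float)
    Tg = np.bincount(inv, weights=T, minlength=len(levels))
    ll_alt = _group_loglik(S, n, Tg, alpha).sum()
    ll_null = _group_loglik(x.sum(), x.size, T.sum(), alpha).item()
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(stat), float(chi2.sf(stat, df=len(levels) - 1))


# ---------------------------------------------------------------------------
# best-pattern search over all bipartitions
# ---------------------------------------------------------------------------

@dataclass
class PatternResult:
    """Best-fitting domain combination for one gene, with filter inputs."""

    gene: str
    best_partition: DomainPartition
    lrt_stat: float
    p_value: float
    log2_fc: float
    mean_positive: float
    expressed_ratio_positive: float
    n_positive_cells: int
    passes: dict = field(default_factory=dict)

    @property
    def passes_all(self) -> bool:
        return bool(self.passes) and all(self.passes.values())


@dataclass
class FilterConfig:
    """Trimming cutoffs applied to best-pattern results.

    Significance and fold-change are strict inequalities (P < p_cutoff,
    log2 fold-change > log2fc_cutoff); the minimal mean expression and the
    expressed-cell ratio, both evaluated on the positive sample, are inclusive.
    """

    p_cutoff: float = 1e-9
    log2fc_cutoff: float = 2.0
    min_mean_umi: float = 0.2
    min_expressed_ratio: float = 0.10

    def __post_init__(self) -> None:
        for name in ("p_cutoff", "log2fc_cutoff", "min_mean_umi", "min_expressed_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def progenitor(cls) -> "FilterConfig":
        return cls(min_expressed_ratio=0.10)

    @classmethod
    def neuron(cls) -> "FilterConfig":
        return cls(min_expressed_ratio=0.08)


class _PartitionIndex:
    """Precomputed membership matrix and complement lookup for a partition list."""

    def __init__(self, partitions: list[DomainPartition], domains: list):
        self.partitions = partitions
        self.domains = list(domains)
        pos_index = {p: i for i, p in enumerate(self.domains)}
        self.members = np.zeros((len(partitions), len(self.domains)))
        for i, part in enumerate(partitions):
            for d in part.positive:
                self.members[i, pos_index[d]] = 1.0
        by_set = {frozenset(p.positive): i for i, p in enumerate(partitions)}
        self.complement = np.array(
            [by_set.get(frozenset(p.negative), -1) for p in partitions]
        )
        # precedence for likelihood ties: smaller positive side, then lexicographic
        order = sorted(
            range(len(partitions)),
            key=lambda i: (len(partitions[i].positive), partitions[i].positive),
        )
        self.tie_rank = np.empty(len(partitions), dtype=int)
        self.tie_rank[order] = np.arange(len(partitions))


def _domain_aggregates(x, domain_inv, n_domains, alpha):
    S = np.bincount(domain_inv, weights=x, minlength=n_domains)
    n = np.bincount(domain_inv, minlength=n_domains).astype(float)
    T = (
        np.bincount(domain_inv, weights=gammaln(x + 1.0 / alpha), minlength=n_domains)
        if alpha > 0
        else np.zeros(n_domains)
    )
    E = np.bincount(domain_inv, weights=(x > 0).astype(float), minlength=n_domains)
    return S, n, T, E


def _best_for_gene(gene, x, domain_inv, index: _PartitionIndex,
                   dispersion: float | None) -> PatternResult:
    alpha = estimate_dispersion(x) if dispersion is None else float(dispersion)
    S, n, T, E = _domain_aggregates(x, domain_inv, len(index.domains), alpha)
    side = _group_loglik(index.members @ S, index.members @ n,
                         index.members @ T, alpha)
    # group log-likelihood of each partition's negative side: exactly the
    # positive-side value of its complement, so complementary orderings tie
    # bit-for-bit and the tie-break below is decided by structure, not rounding
    other = np.where(
        index.complement >= 0,
        side[index.complement],
        _group_loglik(S.sum() - index.members @ S, n.sum() - index.members @ n,
                      T.sum() - index.members @ T, alpha),
    )
    ll_alt = side + other
    ll_null = _group_loglik(S.sum(), n.sum(), T.sum(), alpha).item()
    cand = np.flatnonzero(ll_alt == ll_alt.max())
    best = cand[np.argmin(index.tie_rank[cand])]
    part = index.partitions[best]
    stat = max(2.0 * (ll_alt[best] - ll_null), 0.0)
    n_pos = float(index.members[best] @ n)
    n_neg = n.sum() - n_pos
    mu_pos = float(index.members[best] @ S) / n_pos
    mu_neg = (S.sum() - index.members[best] @ S) / n_neg
    if x.sum() == 0:
        return PatternResult(gene, part, 0.0, 1.0, 0.0, 0.0, 0.0, int(n_pos))
    fc = math.log2((mu_pos + 1.0 / n_pos) / (mu_neg + 1.0 / n_neg))
    ratio = float(index.members[best] @ E) / n_pos
    return PatternResult(
        gene, part, float(stat), float(chi2.sf(stat, df=1)), float(fc),
        float(mu_pos), ratio, int(n_pos),
    )


def best_pattern(
    gene_counts,
    domain_labels,
    partitions: list[DomainPartition] | None = None,
    dispersion: float | None = None,
    gene: str = "gene",
) -> PatternResult:
    """Select the domain combination with the highest alternative likelihood.

    Scores every bipartition with the shared-dispersion NB LRT and returns the
    best one. Exact likelihood ties (every unordered bipartition ties with its
    reversed orientation) resolve to the smaller positive side, then to the
    lexicographically smallest one.
    """
    x = np.asarray(gene_counts, dtype=float).ravel()
    labels = np.asarray(domain_labels)
    if len(x) != len(labels):
        raise ValueError("counts and domain labels differ in length")
    domains = sorted(np.unique(labels).tolist())
    if partitions is None:
        partitions = enumerate_partitions(domains)
    universe = set(partitions[0].domains)
    if set(domains) - universe:
        raise PartitionError(
            f"cells carry domain labels outside the partition universe: "
            f"{sorted(set(domains) - universe)}"
        )
    index = _PartitionIndex(partitions, sorted(universe))
    inv = np.searchsorted(np.array(index.domains, dtype=object), labels)
    return _best_for_gene(gene, x, inv, index, dispersion)


def fit_patterns(
    adata: AnnData,
    domain_labels,
    genes: list[str] | None = None,
    partitions: list[DomainPartition] | None = None,
    dispersion: float | None = None,
) -> list[PatternResult]:
    """Run the best-pattern search for every gene of a count matrix."""
    labels = np.asarray(domain_labels)
    if len(labels) != adata.n_obs:
        raise ValueError("domain labels must align with cells")
    domains = sorted(np.unique(labels).tolist())
    if partitions is None:
        partitions = enumerate_partitions(domains)
    universe = set(partitions[0].domains)
    if set(domains) - universe:
        raise PartitionError(
            f"cells carry domain labels outside the partition universe: "
            f"{sorted(set(domains) - universe)}"
        )
    index = _PartitionIndex(partitions, sorted(universe))
    inv = np.searchsorted(np.array(index.domains, dtype=object), labels)
    gene_list = list(genes) if genes is not None else list(adata.var_names)
    x = sp.csc_matrix(adata[:, gene_list].X)
    out = []
    for j, g in enumerate(gene_list):
        col = np.asarray(x[:, j].todense(), dtype=float).ravel()
        out.append(_best_for_gene(g, col, inv, index, dispersion))
    return out


def filter_patterns(
    results: list[PatternResult], cfg: FilterConfig | None = None
) -> list[PatternResult]:
    """Apply the significance/fold-change/mean/ratio trimming filters.

    Sets the per-filter ``passes`` flags on every result and returns those
    passing all four.
    """
    cfg = cfg or FilterConfig()
    for r in results:
        r.passes = {
            "significance": r.p_value < cfg.p_cutoff,
            "fold_change": r.log2_fc > cfg.log2fc_cutoff,
            "mean": r.mean_positive >= cfg.min_mean_umi,
            "ratio": r.expressed_ratio_positive >= cfg.min_expressed_ratio,
        }
    return [r for r in results if r.passes_all]


def intersect_gene_sets(
    results: list[PatternResult], annotation_sets: dict
) -> dict:
    """Intersect pattern results with named, user-supplied gene lists."""
    return {
        name: [r for r in results if r.gene in set(genes)]
        for name, genes in annotation_sets.items()
    }


def results_to_frame(results: list[PatternResult]) -> pd.DataFrame:
    """Tabulate pattern results (positive set semicolon-joined)."""
    rows = []
    for r in results:
        row = {
            "gene": r.gene,
            "positive": ";".join(r.best_partition.positive),
            "lrt_stat": r.lrt_stat,
            "p_value": r.p_value,
            "log2_fc": r.log2_fc,
            "mean_positive": r.mean_positive,
            "expressed_ratio_positive": r.expressed_ratio_positive,
        }
        for k, v in r.passes.items():
            row[f"pass_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
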