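"""Tests of gene-module discovery: correlation selection, Ward clustering,
adaptive binarization and the iterative filter loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cordatlas.modules import (
    ModuleConfig,
    adaptive_binarize,
    cluster_gene_modules,
    filter_modules,
    gene_level_calls,
    identify_modules,
    module_cell_scores,
    select_correlated_genes,
    zscored_log,
)
from cordatlas.simulate import preset_module_benchmark, simulate_counts


def brute_force_threshold(v):
    """Exhaustive minimum within-group SSE split of a 1-D vector."""
    s = np.sort(v)
    best, best_sse = None, np.inf
    for k in range(1, len(s)):
        if s[k] == s[k - 1]:
            continue
        sse = s[:k].var() * k + s[k:].var() * (len(s) - k)
        if sse < best_sse:
            best_sse, best = sse, 0.5 * (s[k - 1] + s[k])
    return best


class TestAdaptiveBinarize:
    def test_separated_modes_split_cleanly(self):
        v = np.array([0, 0, 0, 10, 10, 10], dtype=float)
        assert adaptive_binarize(v).tolist() == [False] * 3 + [True] * 3

    def test_constant_vector_all_false(self):
        assert not adaptive_binarize(np.ones(5)).any()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            v = rng.uniform(size=int(rng.integers(5, 60)))
            want = brute_force_threshold(v)
            got = adaptive_binarize(v)
            assert (got == (v > want)).all()

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=40)
    )
    def test_split_minimizes_sse(self, values):
        v = np.asarray(values)
        calls = adaptive_binarize(v)
        if np.ptp(v) == 0:
            assert not calls.any()
            return
        want = brute_force_threshold(v)
        assert (calls == (v > want)).all()


class TestCorrelationSelection:
    def test_perfectly_correlated_block_retained(self, rng):
        driver = rng.normal(size=100)
        x = np.column_stack([driver + 0.01 * rng.normal(size=100) for _ in range(10)])
        cfg = ModuleConfig(target_n_correlated_genes=10, min_partners=3)
        names = [f"g{i}" for i in range(10)]
        assert set(select_correlated_genes(x, cfg, genes=names)) == set(names)

    def test_independent_noise_exhausts_schedule_with_warning(self, rng):
        x = rng.normal(size=(50, 12))
        cfg = ModuleConfig(
            target_n_correlated_genes=12, min_partners=3,
            correlation_cutoff_schedule=(0.9, 0.8),
        )
        with pytest.warns(UserWarning, match="schedule exhausted"):
            out = select_correlated_genes(x, cfg)
        assert len(out) < 12

    def test_planted_module_genes_survive_selection(self):
        cfg = preset_module_benchmark(3)
        adata, truth = simulate_counts(cfg)
        mcfg = ModuleConfig(target_n_correlated_genes=200, n_modules=6)
        selected = set(select_correlated_genes(adata, mcfg))
        planted = set(truth.gene_modules)
        assert len(planted & selected) / len(planted) >= 0.95


class TestClustering:
    def _blocks(self, rng, n_cells=80):
        a = rng.normal(size=n_cells)
        x = np.column_stack(
            [a + 0.05 * rng.normal(size=n_cells) for _ in range(6)]
            + [-a + 0.05 * rng.normal(size=n_cells) for _ in range(6)]
        )
        names = [f"up{i}" for i in range(6)] + [f"dn{i}" for i in range(6)]
        return x, names

    def test_anticorrelated_blocks_recovered(self, rng):
        x, names = self._blocks(rng)
        modules = cluster_gene_modules(x, names, n_modules=2)
        parts = {frozenset(v) for v in modules.values()}
        assert parts == {frozenset(names[:6]), frozenset(names[6:])}

    def test_one_module_per_gene(self, rng):
        x, names = self._blocks(rng)
        modules = cluster_gene_modules(x, names, n_modules=12)
        assert all(len(v) == 1 for v in modules.values())

    def test_gene_order_invariance(self, rng):
        x, names = self._blocks(rng)
        perm = rng.permutation(len(names))
        m1 = cluster_gene_modules(x, names, 2)
        m2 = cluster_gene_modules(x[:, perm], [names[i] for i in perm], 2)
        assert {frozenset(v) for v in m1.values()} == {
            frozenset(v) for v in m2.values()
        }


class TestScores:
    def test_single_gene_module_score_is_its_z_level(self, rng):
        x = rng.poisson(3.0, size=(50, 3)).astype(float)
        scores = module_cell_scores(x, {0: ("g1",)}, genes=["g0", "g1", "g2"])
        assert np.allclose(scores[0].to_numpy(), zscored_log(x)[:, 1])

    def test_score_columns_are_centred(self, rng):
        x = rng.poisson(2.0, size=(60, 8)).astype(float)
        names = [f"g{i}" for i in range(8)]
        scores = module_cell_scores(x, {0: tuple(names[:4]), 1: tuple(names[4:])},
                                    genes=names)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_module_cells_score_higher(self):
        cfg = preset_module_benchmark(5)
        adata, truth = simulate_counts(cfg)
        planted = {}
        for g, name in truth.gene_modules.items():
            planted.setdefault(name, []).append(g)
        scores = module_cell_scores(adata, {n: tuple(g) for n, g in planted.items()})
        for name, members in truth.module_cells.items():
            s = scores[name].to_numpy()
            in_mod = np.zeros(adata.n_obs, bool)
            in_mod[np.asarray(members)] = True
            # AUC via rank-sum
            ranks = pd.Series(s).rank().to_numpy()
            auc = (ranks[in_mod].mean() - (in_mod.sum() + 1) / 2) / (~in_mod).sum()
            assert auc >= 0.9


class TestFilterAndLoop:
    def test_module_expressed_in_too_few_cells_removed(self):
        scores = pd.DataFrame({0: [0, 0, 0, 0, 0, 0, 10, 10, 10, 10]},
                              index=range(10)).astype(float)
        calls = pd.DataFrame(True, index=range(10), columns=["g1", "g2"])
        survivors, removed, _ = filter_modules(
            {0: ("g1", "g2")}, scores, calls,
            ModuleConfig(min_cells_expressing=5),
        )
        assert removed == [0]
        survivors, removed, _ = filter_modules(
            {0: ("g1", "g2")}, scores, calls,
            ModuleConfig(min_cells_expressing=4),
        )
        assert not removed

    def test_incoherent_module_removed_by_true_ratio(self, rng):
        # bimodal scores but random gene-level calls far below 40% true
        scores = pd.DataFrame(
            {0: np.r_[np.zeros(20), np.ones(20) * 5]}, index=range(40)
        )
        calls = pd.DataFrame(
            rng.uniform(size=(40, 5)) < 0.1, index=range(40),
            columns=[f"g{i}" for i in range(5)],
        )
        _, removed, _ = filter_modules(
            {0: tuple(f"g{i}" for i in range(5))}, scores, calls, ModuleConfig()
        )
        assert removed == [0]

    def test_iterative_loop_removes_noise_and_converges(self, rng):
        # two coherent blocks plus independent noise genes forced into the
        # clustering: the noise module is filtered, the loop re-clusters and
        # converges on the second pass
        n = 120
        block1 = np.zeros(n)
        block1[:40] = 1
        block2 = np.zeros(n)
        block2[60:] = 1
        cols, names = [], []
        for i in range(8):
            cols.append(rng.poisson(5.0 * block1 + 0.05))
            names.append(f"a{i}")
        for i in range(8):
            cols.append(rng.poisson(5.0 * block2 + 0.05))
            names.append(f"b{i}")
        for i in range(8):
            # sparse independent noise: gene-level calls are mostly false, so
            # the 40% consistency filter removes the noise module
            cols.append(rng.poisson(0.2, size=n))
            names.append(f"n{i}")
        x = np.column_stack(cols).astype(float)
        cfg = ModuleConfig(
            target_n_correlated_genes=24, min_partners=3, n_modules=3,
            correlation_cutoff_schedule=(0.5, 0.3, 0.1, 0.0),
        )
        result = identify_modules(x, cfg, genes=names)
        assert result.converged
        assert len(result.history) >= 2
        assert result.history == sorted(result.history, reverse=True)
        kept = {frozenset(v) for v in result.modules.values()}
        assert frozenset(f"a{i}" for i in range(8)) in kept
        assert frozenset(f"b{i}" for i in range(8)) in kept

    def test_identify_modules_is_deterministic(self):
        cfg = preset_module_benchmark(7, n_cells=300, n_noise_genes=100)
        adata, _ = simulate_counts(cfg)
        mcfg = ModuleConfig(target_n_correlated_genes=200, n_modules=6)
        r1 = identify_modules(adata, mcfg)
        r2 = identify_modules(adata, mcfg)
        assert r1.modules == r2.modules
        assert r1.history == r2.history
        assert r1.cell_scores.equals(r2.cell_scores)
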