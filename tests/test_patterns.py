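"""Tests of the combinatorial NB likelihood-ratio pattern search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import nbinom, poisson

from cordatlas.patterns import (
    DomainPartition,
    FilterConfig,
    PartitionError,
    best_pattern,
    enumerate_partitions,
    estimate_dispersion,
    filter_patterns,
    fit_patterns,
    intersect_gene_sets,
    model_universe_size,
    nb_lrt,
    nb_lrt_multigroup,
)
from cordatlas.simulate import SimConfig, simulate_counts


# ---------------------------------------------------------------------------
# independent oracle: grid maximization of the NB/Poisson log-likelihood
# ---------------------------------------------------------------------------

def brute_force_lrt(x, mask, n_grid=4001):
    alpha = estimate_dispersion(x)

    def loglik(data, mu):
        if alpha > 0:
            r = 1.0 / alpha
            return nbinom.logpmf(data, r, r / (r + mu)).sum()
        return poisson.logpmf(data, mu).sum()

    def best(data):
        m = data.mean()
        if m == 0:
            return loglik(data, 1e-12)
        return max(loglik(data, mu) for mu in np.geomspace(m / 10, m * 10, n_grid))

    stat = 2 * (best(x[mask]) + best(x[~mask]) - best(x))
    return max(stat, 0.0)


class TestEnumeration:
    def test_two_domains_give_two_ordered_partitions(self):
        parts = enumerate_partitions(["a", "b"])
        assert parts == [
            DomainPartition(("a",), ("b",)),
            DomainPartition(("b",), ("a",)),
        ]

    @pytest.mark.parametrize("n,expected_models", [(12, 4096), (13, 8192)])
    def test_model_universe_counts(self, n, expected_models):
        labels = [f"d{i:02d}" for i in range(n)]
        parts = enumerate_partitions(labels)
        assert len(parts) == expected_models - 2
        assert model_universe_size(n) == expected_models

    def test_order_is_deterministic(self):
        assert enumerate_partitions(["b", "a", "c"]) == enumerate_partitions(
            ["c", "a", "b"]
        )

    def test_fewer_than_two_domains_rejected(self):
        with pytest.raises(PartitionError):
            enumerate_partitions(["a"])

    @given(st.integers(min_value=2, max_value=8))
    def test_every_partition_proper_and_complementary(self, n):
        labels = [f"d{i}" for i in range(n)]
        parts = enumerate_partitions(labels)
        assert len(parts) == 2 ** n - 2
        for p in parts:
            assert set(p.positive) | set(p.negative) == set(labels)
            assert not set(p.positive) & set(p.negative)
            assert 1 <= len(p.positive) <= n - 1


class TestNbLrt:
    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            x = rng.negative_binomial(2, 2 / 5, size=120).astype(float)
            mask = np.zeros(120, bool)
            mask[:60] = True
            if x.sum() == 0:
                continue
            ps.append(nb_lrt(x, mask).p_value)
        assert 0.35 < np.median(ps) < 0.65

    def test_strong_effect_is_detected(self, rng):
        # 8-fold mean difference, 200 cells per group, base mean 2 UMI
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            a = rng.negative_binomial(3, 3 / 5, size=200)       # mean 2
            b = rng.negative_binomial(3, 3 / 19, size=200)      # mean 16
            x = np.concatenate([a, b]).astype(float)
            mask = np.arange(400) < 200
            hits += nb_lrt(x, mask).p_value < 1e-9
        assert hits >= 0.95 * n_sim

    def test_matches_brute_force_oracle(self, rng):
        worst = 0.0
        for _ in range(20):
            n = int(rng.integers(10, 51))
            mu, r = rng.uniform(0.5, 5), rng.uniform(1, 5)
            x = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
            if x.sum() == 0:
                continue
            k = int(rng.integers(2, n - 1))
            mask = np.zeros(n, bool)
            mask[:k] = True
            worst = max(worst, abs(nb_lrt(x, mask).lrt_stat - brute_force_lrt(x, mask)))
        assert worst < 1e-4

    def test_symmetric_under_group_swap(self, rng):
        x = rng.poisson(3.0, size=80).astype(float)
        mask = np.arange(80) < 30
        r1, r2 = nb_lrt(x, mask), nb_lrt(x, ~mask)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-9)
        assert r1.log2_fc == pytest.approx(-r2.log2_fc, abs=1e-9)

    def test_all_zero_gene_is_null(self):
        res = nb_lrt(np.zeros(40), np.arange(40) < 20)
        assert (res.lrt_stat, res.p_value, res.log2_fc) == (0.0, 1.0, 0.0)

    def test_multigroup_detects_level_effect(self, rng):
        labels = np.repeat(["a", "b", "c"], 100)
        x = np.concatenate(
            [rng.poisson(1.0, 100), rng.poisson(1.0, 100), rng.poisson(8.0, 100)]
        ).astype(float)
        stat, p = nb_lrt_multigroup(x, labels)
        assert p < 1e-9
        _, p_null = nb_lrt_multigroup(rng.poisson(2.0, 300).astype(float), labels)
        assert p_null > 1e-6


class TestBestPattern:
    def _simulate(self, positive, domains, n_per_domain=150, effect=8.0, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat(domains, n_per_domain)
        mu = np.where(np.isin(labels, positive), 0.5 * effect, 0.5)
        x = rng.poisson(mu).astype(float)
        return x, labels

    def test_recovers_planted_pair(self):
        domains = ["d1", "d2", "d3", "d4", "d5"]
        x, labels = self._simulate(("d2", "d4"), domains)
        res = best_pattern(x, labels)
        assert res.best_partition.positive == ("d2", "d4")

    def test_recovers_planted_singleton(self):
        domains = ["d1", "d2", "d3", "d4", "d5"]
        x, labels = self._simulate(("d3",), domains)
        res = best_pattern(x, labels)
        assert res.best_partition.positive == ("d3",)

    def test_flat_gene_fails_significance(self, rng):
        labels = np.repeat(["d1", "d2", "d3"], 100)
        x = rng.poisson(1.0, 300).astype(float)
        res = best_pattern(x, labels)
        filter_patterns([res])
        assert not res.passes["significance"]

    def test_likelihood_tie_broken_to_smaller_then_lexicographic_side(self):
        # complementary orderings tie exactly; with two domains the lexico-
        # graphically smaller singleton wins regardless of which side is high
        x, labels = self._simulate(("b",), ["a", "b"])
        res = best_pattern(x, labels)
        assert res.best_partition.positive == ("a",)
        assert res.log2_fc < 0

    def test_labels_outside_partition_universe_rejected(self):
        parts = enumerate_partitions(["a", "b"])
        with pytest.raises(PartitionError):
            best_pattern(np.ones(3), np.array(["a", "b", "zz"]), partitions=parts)


class TestFilters:
    def _result(self, **kw):
        base = dict(
            gene="g", best_partition=DomainPartition(("a",), ("b",)),
            lrt_stat=100.0, p_value=1e-12, log2_fc=3.0, mean_positive=1.0,
            expressed_ratio_positive=0.5, n_positive_cells=100,
        )
        base.update(kw)
        from cordatlas.patterns import PatternResult
        return PatternResult(**base)

    def test_p_value_boundary_is_strict(self):
        assert not filter_patterns([self._result(p_value=1e-8)])
        assert filter_patterns([self._result(p_value=1e-10)])

    def test_log2fc_boundary_is_strict(self):
        assert not filter_patterns([self._result(log2_fc=2.0)])
        assert filter_patterns([self._result(log2_fc=2.0001)])

    def test_mean_and_ratio_are_inclusive(self):
        cfg = FilterConfig()
        assert filter_patterns([self._result(mean_positive=0.2)], cfg)
        assert filter_patterns(
            [self._result(expressed_ratio_positive=0.10)], cfg
        )
        assert not filter_patterns([self._result(mean_positive=0.19)], cfg)

    def test_neuron_config_uses_eight_percent_ratio(self):
        cfg = FilterConfig.neuron()
        assert filter_patterns([self._result(expressed_ratio_positive=0.09)], cfg)

    def test_type_one_error_controlled_under_global_null(self):
        # no planted patterns: despite best-of-8190 selection, the filter
        # stack should pass (essentially) nothing
        cfg = SimConfig(
            stages=("e10.5",), n_cells_per_stage=1300, n_genes=300,
            domain_proportions={
                "e10.5": {d: 1 / 13 for d in
                          ("FP", "p3", "pMN", "p2", "p1", "p0", "dp6", "dp5",
                           "dp4", "dp3", "dp2", "dp1", "RP")}},
            seed=8,
        )
        adata, truth = simulate_counts(cfg)
        genes = [g for g in adata.var_names if g.startswith("Gm")]
        res = fit_patterns(adata, truth.primary_identity, genes=genes)
        hits = filter_patterns(res, FilterConfig.progenitor())
        assert len(hits) / len(genes) < 1e-3


def test_intersect_gene_sets_is_plain_set_semantics():
    from cordatlas.patterns import PatternResult
    results = [
        PatternResult(g, DomainPartition(("a",), ("b",)), 1.0, 1.0, 0.0, 0.0, 0.0, 1)
        for g in ("g1", "g2", "g3")
    ]
    out = intersect_gene_sets(
        results,
        {"empty": [], "all": ["g1", "g2", "g3"], "s1": ["g1", "g2"],
         "s2": ["g2", "g3"]},
    )
    assert out["empty"] == []
    assert [r.gene for r in out["all"]] == ["g1", "g2", "g3"]
    assert {r.gene for r in out["s1"]} & {r.gene for r in out["s2"]} == {"g2"}
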