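"""Network construction: adjacency and TOM arithmetic against brute-force
oracles, module detection on planted structure, eigengene properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amynet import network as net


def _vectors_with_correlation(rho, n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e -= (e @ x) / (x @ x) * x  # orthogonalize
    e /= e.std()
    return x, rho * x + np.sqrt(1 - rho**2) * e


class TestAdjacency:
    def test_perfect_correlation_power_one(self):
        x, y = _vectors_with_correlation(1.0)
        a = net.adjacency(np.vstack([x, x * 2 + 1]),
                          net.AdjacencyConfig(power=1))
        assert a[0, 1] == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        x, y = _vectors_with_correlation(0.0)
        a = net.adjacency(np.vstack([x, y]), net.AdjacencyConfig(power=1))
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_power_two_squares_correlation(self):
        x, y = _vectors_with_correlation(0.5)
        rows = np.vstack([x, y])
        a = net.adjacency(rows, net.AdjacencyConfig(power=2))
        assert a[0, 1] == pytest.approx(0.25, abs=1e-10)

    def test_zero_variance_gene_is_hard_error(self):
        m = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            net.adjacency(m, net.AdjacencyConfig(power=2))

    def test_signed_hybrid_zeroes_negative_correlations(self):
        x, y = _vectors_with_correlation(-0.7)
        a = net.adjacency(np.vstack([x, y]),
                          net.AdjacencyConfig(power=3,
                                              network_type="signed-hybrid"))
        assert a[0, 1] == 0.0


class TestTom:
    def test_no_off_diagonal_adjacency_gives_no_overlap(self):
        t = net.tom(np.eye(5))
        assert np.allclose(t, np.eye(5))

    def test_three_node_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        t = net.tom(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert np.allclose(t[np.triu_indices(3, 1)], 0.5)

    @pytest.mark.parametrize("n,seed", [(3, 0), (5, 1), (6, 2), (8, 3),
                                        (8, 4), (7, 5)])
    def test_matches_triple_loop_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = net.tom(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert t[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                           if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                want = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(want, abs=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, (20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = net.tom(a)
        assert np.allclose(t, t.T)
        assert t.min() >= 0 and t.max() <= 1

    def test_rejects_out_of_range(self):
        a = np.eye(3) * 2
        with pytest.raises(ValueError):
            net.tom(a)


def _planted_tom(n1=40, n2=40, inner=0.8, outer=0.05, seed=0):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    t = np.full((n, n), outer) + rng.uniform(-0.02, 0.02, (n, n))
    t = (t + t.T) / 2
    t[:n1, :n1] = inner + rng.uniform(-0.05, 0.05, (n1, n1))
    t[n1:, n1:] = inner + rng.uniform(-0.05, 0.05, (n2, n2))
    t = np.clip((t + t.T) / 2, 0, 1)
    np.fill_diagonal(t, 1.0)
    return t


class TestModules:
    def test_two_planted_blocks_recovered(self):
        t = _planted_tom()
        genes = [f"g{i}" for i in range(80)]
        rng = np.random.default_rng(0)
        expr = rng.standard_normal((80, 30))
        asn = net.detect_modules(t, genes, expr, min_module_size=10,
                                 cut_height=0.5)
        assert len(asn.modules) == 2
        first = {asn.labels[g] for g in genes[:40]}
        second = {asn.labels[g] for g in genes[40:]}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_all_equal_tom_single_module(self):
        t = np.full((30, 30), 0.6)
        np.fill_diagonal(t, 1.0)
        genes = [f"g{i}" for i in range(30)]
        expr = np.random.default_rng(1).standard_normal((30, 20))
        asn = net.detect_modules(t, genes, expr, min_module_size=5,
                                 cut_height=0.5)
        assert len(asn.modules) == 1
        assert (asn.labels != 0).all()

    def test_gene_permutation_invariance(self):
        t = _planted_tom(seed=3)
        genes = [f"g{i}" for i in range(80)]
        expr = np.random.default_rng(2).standard_normal((80, 25))
        asn1 = net.detect_modules(t, genes, expr, min_module_size=10,
                                  cut_height=0.5)
        perm = np.random.default_rng(5).permutation(80)
        asn2 = net.detect_modules(t[np.ix_(perm, perm)],
                                  [genes[i] for i in perm], expr[perm],
                                  min_module_size=10, cut_height=0.5)
        from itertools import combinations
        for a, b in list(combinations(range(80), 2))[:500]:
            same1 = asn1.labels[genes[a]] == asn1.labels[genes[b]]
            same2 = asn2.labels[genes[a]] == asn2.labels[genes[b]]
            assert same1 == same2

    def test_cut_height_validated(self):
        t = np.eye(10)
        with pytest.raises(ValueError):
            net.detect_modules(t, list("abcdefghij"),
                               np.random.default_rng(0).standard_normal((10, 12)),
                               cut_height=1.5)


class TestEigengene:
    def test_identical_genes_reproduce_profile(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(25)
        m = np.tile(profile, (6, 1))
        eig, ve = net.module_eigengene(m)
        r = np.corrcoef(eig, profile)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # orientation: positive mean member correlation
        assert ve == pytest.approx(1.0)

    def test_sign_flip_of_members_flips_eigengene(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((8, 30))
        m[0] = m[1] + 0.1 * rng.standard_normal(30)  # give it a direction
        e1, _ = net.module_eigengene(m)
        e2, _ = net.module_eigengene(-m)
        assert np.allclose(e1, -e2, atol=1e-10)

    def test_variance_explained_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((10, 20))
        _, ve = net.module_eigengene(m)
        z = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
        c = z @ z.T
        v = rng.standard_normal(10)
        for _ in range(2000):
            v = c @ v
            v /= np.linalg.norm(v)
        lam1 = v @ c @ v
        assert ve == pytest.approx(lam1 / np.trace(c), abs=1e-8)

    def test_single_gene_module_rejected(self):
        with pytest.raises(ValueError):
            net.module_eigengene(np.random.default_rng(0).standard_normal((1, 10)))


class TestModuleTrait:
    def test_perfect_correlation_smallest_p(self):
        x = np.linspace(0, 1, 12)
        res = net.module_trait_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p < 1e-300

    def test_orthogonal_gives_r_zero_p_one(self):
        x, y = _vectors_with_correlation(0.0, n=10)
        res = net.module_trait_correlation(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_r_half_n20_matches_t_distribution_oracle(self):
        x, y = _vectors_with_correlation(0.5, n=20, seed=3)
        res = net.module_trait_correlation(x, y)
        t = 0.5 * np.sqrt(18) / np.sqrt(1 - 0.25)
        want = 2 * stats.t.sf(t, 18)
        assert res.p == pytest.approx(want, rel=1e-6)
        assert want == pytest.approx(0.0248, abs=3e-4)

    def test_zero_variance_trait_rejected(self):
        with pytest.raises(ValueError):
            net.module_trait_correlation(np.arange(5.0), np.ones(5))


class TestTopSubnetwork:
    def _assignment(self, genes, module_genes):
        labels = pd.Series(
            [1 if g in module_genes else 0 for g in genes],
            index=pd.Index(genes, name="gene"))
        return net.ModuleAssignment(labels, 3, 0.75)

    def test_full_module_returned(self):
        t = _planted_tom(10, 10, seed=6)
        genes = [f"g{i}" for i in range(20)]
        asn = self._assignment(genes, set(genes[:10]))
        sub = net.top_subnetwork(t, genes, asn, 1, 10)
        assert set(sub.genes["gene"]) == set(genes[:10])

    def test_star_topology_hub_is_centre(self):
        n = 10
        t = np.zeros((n, n))
        t[0, :] = t[:, 0] = 0.9
        np.fill_diagonal(t, 1.0)
        genes = [f"g{i}" for i in range(n)]
        asn = self._assignment(genes, set(genes))
        sub = net.top_subnetwork(t, genes, asn, 1, n)
        assert sub.genes.iloc[0]["gene"] == "g0"
        assert sub.genes.iloc[0]["hub"]

    def test_ranking_matches_row_sum_oracle(self):
        t = _planted_tom(15, 5, seed=8)
        genes = [f"g{i}" for i in range(20)]
        module = set(genes[:15])
        asn = self._assignment(genes, module)
        sub = net.top_subnetwork(t, genes, asn, 1, 15)
        oracle = {}
        for i in range(15):
            oracle[genes[i]] = sum(t[i, j] for j in range(15) if j != i)
        ranked = sorted(oracle, key=oracle.get, reverse=True)
        assert list(sub.genes["gene"]) == ranked

    def test_n_top_exceeding_module_rejected(self):
        t = np.eye(5)
        genes = list("abcde")
        asn = self._assignment(genes, {"a", "b"})
        with pytest.raises(ValueError):
            net.top_subnetwork(t, genes, asn, 1, 3)


class TestSoftThreshold:
    def test_noise_matrix_falls_back_with_flag(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((150, 30))
        with pytest.warns(UserWarning, match="scale-free"):
            res = net.pick_soft_threshold(m, net.AdjacencyConfig(
                scale_free_r2_target=0.995))
        assert not res.reached_target
        assert res.power in net.AdjacencyConfig().candidate_powers

    def test_duplicating_every_gene_keeps_choice(self, small_expression):
        ds, _ = small_expression
        m = np.log1p(ds.values.to_numpy()[:150])
        cfg = net.AdjacencyConfig()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = net.pick_soft_threshold(m, cfg).power
            p2 = net.pick_soft_threshold(np.vstack([m, m]), cfg).power
        assert p1 == p2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            net.pick_soft_threshold(np.random.default_rng(0)
                                    .standard_normal((20, 5)),
                                    net.AdjacencyConfig())


class TestFilter:
    def test_zero_thresholds_identity(self, small_expression):
        ds, _ = small_expression
        out = net.filter_expression(ds, min_mean=0.0, top_variance=None)
        assert out.values.equals(ds.values)

    def test_impossible_mean_threshold_rejected(self, small_expression):
        ds, _ = small_expression
        with pytest.raises(ValueError):
            net.filter_expression(ds, min_mean=float(ds.values.to_numpy().max())
                                  * 10)

    def test_planted_module_survives_default_filter(self, small_expression):
        ds, truth = small_expression
        out = net.filter_expression(ds, min_mean=1.0, top_variance=200)
        kept = set(out.genes) & truth.module_genes()
        assert len(kept) >= 0.99 * len(truth.module_genes())
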