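import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ganwgcna import wgcna
from ganwgcna.data_io import ExpressionMatrix, TraitTable
from ganwgcna.wgcna import (
    ModuleAssignment,
    NetworkConfig,
    adjacency,
    detect_modules,
    eigengene,
    module_trait_alignment,
    pick_soft_threshold,
    tom,
)


def _brute_force_corr(X):
    n = X.shape[1]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = X[:, i], X[:, j]
            xi = xi - xi.mean()
            xj = xj - xj.mean()
            out[i, j] = out[j, i] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return out


class TestAdjacency:
    def test_matches_two_pass_correlation_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 15))
        r = _brute_force_corr(X)
        for nt, transform in [("unsigned", lambda r: np.abs(r) ** 6),
                              ("signed", lambda r: ((1 + r) / 2) ** 6)]:
            A = adjacency(X, 6, nt)
            expected = transform(r)
            np.fill_diagonal(expected, 1.0)
            assert np.allclose(A, expected, atol=1e-12)

    def test_unsigned_network_merges_anticorrelated_pair(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, -t])
        A = adjacency(X, 6, "unsigned")
        assert A[0, 1] == pytest.approx(1.0)
        # the signed network separates them instead
        assert adjacency(X, 6, "signed")[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_vanishes_at_large_beta(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 10))
        A = adjacency(X, 12, "unsigned")
        np.fill_diagonal(A, 0.0)
        assert A.max() < 0.01

    def test_zero_variance_gene_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(X, 6)


class TestTom:
    def test_isolated_nodes_have_zero_overlap(self):
        A = np.eye(4)
        w = tom(A)
        assert np.allclose(w, np.eye(4))

    def test_fully_connected_triangle(self):
        # 3 nodes, all a = 1: l_12 = 1, k = 2 -> w = (1+1)/(2+1-1) = 1
        A = np.ones((3, 3))
        w = tom(A)
        assert np.allclose(w, 1.0)

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(2)
        n = 20
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        w = tom(A)
        expected = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                ki = sum(A[i, u] for u in range(n) if u != i)
                kj = sum(A[j, u] for u in range(n) if u != j)
                expected[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
        assert np.abs(w - expected).max() < 1e-10

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom(A)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_tom_stays_in_unit_interval_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        w = tom(A)
        assert np.allclose(w, w.T)
        assert (w >= 0).all() and (w <= 1 + 1e-12).all()
        assert np.allclose(np.diag(w), 1.0)


class TestSoftThreshold:
    def test_mean_connectivity_nonincreasing_in_beta(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 40)) + 0.5 * rng.normal(size=(30, 1))
        _, table = pick_soft_threshold(pd.DataFrame(X), NetworkConfig())
        assert (np.diff(table.mean_k) <= 1e-9).all()

    def test_degenerate_perfect_correlation_falls_back(self):
        t = np.linspace(0, 1, 30)
        X = pd.DataFrame(np.outer(t, np.linspace(1, 2, 12)))
        cfg = NetworkConfig()
        beta, table = pick_soft_threshold(X, cfg)
        assert beta >= cfg.min_beta_fallback

    def test_constant_genes_are_dropped_not_fatal(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 12)))
        X[12] = 1.0  # constant gene
        beta, _ = pick_soft_threshold(X, NetworkConfig())
        assert beta >= 1

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            pick_soft_threshold(pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4))))


def _block_tom(sizes, within=0.9, between=0.05):
    n = sum(sizes)
    w = np.full((n, n), between)
    start = 0
    for s in sizes:
        w[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(w, 1.0)
    return w


class TestDetectModules:
    def test_two_perfect_blocks_are_recovered(self):
        w = _block_tom([15, 12])
        asg = detect_modules(w, [f"G{i}" for i in range(27)], NetworkConfig())
        assert asg.module_ids == [1, 2]
        labels = asg.labels.to_numpy()
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]
        # bigger block gets the smaller id
        assert labels[0] == 1

    def test_min_module_size_dominance_unassigns_everything(self):
        w = _block_tom([8, 8])
        asg = detect_modules(w, [f"G{i}" for i in range(16)],
                             NetworkConfig(min_module_size=50))
        assert (asg.labels == 0).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        w = _block_tom([12, 10, 11], within=0.8, between=0.1)
        genes = [f"G{i}" for i in range(33)]
        asg = detect_modules(w, genes, NetworkConfig())
        perm = rng.permutation(33)
        asg_p = detect_modules(w[np.ix_(perm, perm)], [genes[i] for i in perm],
                               NetworkConfig())
        # same partition of gene ids, labels possibly renamed
        a = asg.labels
        b = asg_p.labels[a.index]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a, b) == pytest.approx(1.0)


class TestEigengene:
    def test_rank_one_block_recovers_the_driver(self):
        rng = np.random.default_rng(6)
        u = rng.normal(size=40)
        v = rng.uniform(0.5, 1.5, size=6)
        X = pd.DataFrame(np.outer(u, v), columns=[f"G{i}" for i in range(6)])
        asg = ModuleAssignment(labels=pd.Series([1] * 6, index=X.columns))
        prof = eigengene(X, asg)
        assert prof.explained_variance[1] == pytest.approx(1.0)
        eg = prof.eigengenes[1].to_numpy()
        uc = (u - u.mean()) / u.std()
        assert np.allclose(np.abs(np.corrcoef(eg, uc)[0, 1]), 1.0)
        # orientation: positively correlated with the module mean profile
        assert np.corrcoef(eg, X.mean(axis=1))[0, 1] > 0

    def test_negating_a_module_negates_its_eigengene(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 5)) + rng.normal(size=(30, 1)),
                         columns=[f"G{i}" for i in range(5)])
        asg = ModuleAssignment(labels=pd.Series([1] * 5, index=X.columns))
        e1 = eigengene(X, asg).eigengenes[1]
        e2 = eigengene(-X, asg).eigengenes[1]
        assert np.allclose(e1, -e2, atol=1e-10)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(25, 8)), columns=[f"G{i}" for i in range(8)])
        asg = ModuleAssignment(labels=pd.Series([1] * 8, index=X.columns))
        prof = eigengene(X, asg)
        Z = (X - X.mean()) / X.std(ddof=0)
        C = Z.T @ Z
        v = np.ones(8)
        for _ in range(5000):
            v = C @ v
            v /= np.linalg.norm(v)
        scores = Z.to_numpy() @ v
        scores /= scores.std()
        eg = prof.eigengenes[1].to_numpy()
        assert min(np.abs(eg - scores).max(), np.abs(eg + scores).max()) < 1e-8

    def test_single_gene_module_is_the_standardized_gene(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"G0": rng.normal(size=20)})
        asg = ModuleAssignment(labels=pd.Series([1], index=["G0"]))
        eg = eigengene(X, asg).eigengenes[1].to_numpy()
        g = X["G0"].to_numpy()
        g = (g - g.mean()) / g.std()
        assert np.allclose(np.abs(eg), np.abs(g), atol=1e-10)


class TestModuleTraitAlignment:
    def _real(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"SN{i}" for i in range(n // 2)] + [f"CN{i}" for i in range(n // 2)]
        vals = rng.normal(size=(6, n))
        X = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"G{i}" for i in range(6)], columns=ids),
            sample_group=pd.Series(["SN"] * (n // 2) + ["CN"] * (n // 2), index=ids),
        )
        asg = ModuleAssignment(labels=pd.Series([1] * 6, index=X.gene_ids))
        return X, asg

    def test_zero_variance_trait_is_an_error(self):
        X, asg = self._real()
        traits = TraitTable(trait=pd.Series(0.0, index=X.sample_ids))
        with pytest.raises(ValueError, match="zero variance"):
            module_trait_alignment(asg, X, traits)

    def test_too_few_samples_rejected(self):
        X, asg = self._real()
        keep = X.sample_ids[:3]
        X3 = ExpressionMatrix(values=X.values[keep], sample_group=X.sample_group[keep])
        traits = TraitTable(trait=pd.Series(1.0, index=keep))
        with pytest.raises(ValueError, match="4"):
            module_trait_alignment(asg, X3, traits)

    def test_missing_genes_listed(self):
        X, asg = self._real()
        asg2 = ModuleAssignment(labels=pd.Series([1] * 6, index=[f"H{i}" for i in range(6)]))
        traits = TraitTable(trait=pd.Series(np.arange(12.0), index=X.sample_ids))
        with pytest.raises(ValueError, match="H0"):
            module_trait_alignment(asg2, X, traits)

    def test_null_correlation_gives_p_one(self):
        from ganwgcna._utils import corr_pvalue

        assert corr_pvalue(0.0, 20) == pytest.approx(1.0)

    def test_planted_trait_module_passes_flat_module_fails(self, default_fixture):
        X, traits, truth = default_fixture
        asg = ModuleAssignment(labels=truth.module_of_gene)
        results = module_trait_alignment(asg, X, traits)
        by_mod = {r.module: r for r in results}
        assert by_mod[truth.trait_module].passes
        flat = [m for m, a in truth.archetype_of_module.items() if a == "flat"]
        assert all(not by_mod[m].passes for m in flat)
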