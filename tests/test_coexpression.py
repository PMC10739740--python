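"""Network construction: adjacency, TOM, modules, eigengenes, MM/GS."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from comodmr.coexpression import (
    ModuleSet,
    NetworkParams,
    build_network,
    detect_modules,
    gene_correlation,
    gene_significance,
    merge_modules,
    module_eigengene,
    module_membership,
    pick_soft_threshold,
    signed_hybrid_adjacency,
    tom_similarity,
)
from comodmr.matrix import ExpressionMatrix
from comodmr.preprocess import normalise_transform
from comodmr.simulate import SimConfig, module_labels, simulate_expression


def tom_bruteforce(a):
    """Independent triple-loop evaluation of the TOM formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_signed_hybrid_values(self):
        c = np.array(
            [
                [1.0, 1.0, -0.5, 0.5],
                [1.0, 1.0, 0.2, 0.3],
                [-0.5, 0.2, 1.0, 0.0],
                [0.5, 0.3, 0.0, 1.0],
            ]
        )
        a = signed_hybrid_adjacency(c, 6)
        assert a[0, 1] == 1.0
        assert a[0, 2] == 0.0  # negative correlation zeroed
        assert a[0, 3] == pytest.approx(0.5**6)  # 1/64
        assert (np.diag(a) == 0).all()

    def test_asymmetric_input_rejected(self):
        c = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            signed_hybrid_adjacency(c, 6)


class TestTOM:
    def test_zero_adjacency_gives_identity(self):
        assert np.array_equal(tom_similarity(np.zeros((5, 5))), np.eye(5))

    def test_three_node_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        # l_12 = 0.25; (0.25 + 0.5) / (1 + 1 − 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 25)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, tom_bruteforce(a), atol=1e-12)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        np.testing.assert_allclose(tom, tom.T)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(np.array([[0, 0.2], [0.4, 0]]))


class TestEigengene:
    def test_single_gene_module_correlates_perfectly(self, random_expression):
        x = random_expression(n_genes=1, n_samples=15)
        labels = pd.Series([1], index=x.gene_ids)
        me = module_eigengene(x, labels)
        r = np.corrcoef(me["ME1"], x.values.iloc[0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_identical_genes_reproduce_profile(self, random_expression):
        base = random_expression(n_genes=1, n_samples=12)
        vals = np.tile(base.values.to_numpy(), (6, 1))
        x = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(6)], columns=base.sample_ids),
            layer="transformed",
        )
        me = module_eigengene(x, pd.Series(1, index=x.gene_ids))
        r = np.corrcoef(me["ME1"], vals[0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_first_pc_from_independent_eigendecomposition(self, seed, random_expression):
        x = random_expression(n_genes=30, n_samples=18, seed=seed)
        me = module_eigengene(x, pd.Series(1, index=x.gene_ids))
        z = x.values.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        # oracle: eigendecomposition of the sample covariance of standardised genes
        evals, evecs = np.linalg.eigh(z.T @ z)
        pc1 = evecs[:, -1]
        r = abs(np.corrcoef(me["ME1"], pc1)[0, 1])
        assert r > 1 - 1e-10

    def test_unit_norm_and_positive_orientation(self, random_expression):
        x = random_expression(n_genes=20, n_samples=10, seed=3)
        me = module_eigengene(x, pd.Series(1, index=x.gene_ids))
        assert np.linalg.norm(me["ME1"]) == pytest.approx(1.0)
        z = x.values.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        assert np.corrcoef(me["ME1"], z.mean(axis=0))[0, 1] > 0


class TestMMGS:
    def test_gene_equal_to_eigengene_has_mm_one(self, random_expression):
        x = random_expression(n_genes=10, n_samples=12, seed=1)
        me = module_eigengene(x, pd.Series(1, index=x.gene_ids))
        x2 = ExpressionMatrix(
            pd.concat([x.values, me["ME1"].rename("Gme").to_frame().T]), layer="transformed"
        )
        mm = module_membership(x2, me)
        assert mm.loc["Gme", "ME1"] == pytest.approx(1.0, abs=1e-10)

    def test_gene_equal_to_phenotype_has_gs_one(self):
        pheno = pd.Series([0, 0, 0, 1, 1, 1, 1], index=[f"S{i}" for i in range(7)])
        x = ExpressionMatrix(
            pd.DataFrame([pheno.to_numpy(dtype=float)], index=["G0"], columns=pheno.index),
            layer="transformed",
        )
        gs = gene_significance(x, pheno)
        assert gs["G0"] == pytest.approx(1.0)

    def test_null_gs_stays_small_at_n43(self):
        """|GS| < 0.5 for phenotype-independent genes in ≥99% of null draws."""
        rng = np.random.default_rng(0)
        pheno = pd.Series(np.r_[np.ones(32), np.zeros(11)], index=[f"S{i}" for i in range(43)])
        vals = rng.normal(size=(2000, 43))
        x = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(2000)], columns=pheno.index),
            layer="transformed",
        )
        gs = gene_significance(x, pheno)
        assert (gs.abs() < 0.5).mean() >= 0.99


class TestDetectMerge:
    def _block_expression(self, seed):
        cfg = SimConfig(
            seed=seed, n_genes=400, module_sizes=(50, 50), n_assoc_modules=1,
            within_module_cor=0.9, n_celltypes=2, dirichlet_alpha=(6.0, 3.0),
            marker_genes_per_type=10,
        )
        expr, table, _ = simulate_expression(cfg)
        return normalise_transform(expr), module_labels(cfg), table

    def test_recovers_planted_blocks(self):
        x, truth, _ = self._block_expression(0)
        adj = signed_hybrid_adjacency(gene_correlation(x).to_numpy(), 6)
        labels = detect_modules(tom_similarity(adj), NetworkParams(), x=x)
        ari = adjusted_rand_score(truth, labels)
        assert ari >= 0.9

    def test_noise_matrix_mostly_unassigned(self):
        """≥90% of pure-noise genes stay unassigned, over 20 seeds."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = ExpressionMatrix(
                pd.DataFrame(
                    rng.normal(size=(150, 40)),
                    index=[f"G{i:03d}" for i in range(150)],
                    columns=[f"S{i}" for i in range(40)],
                ),
                layer="transformed",
            )
            adj = signed_hybrid_adjacency(gene_correlation(x).to_numpy(), 6)
            labels = detect_modules(tom_similarity(adj), NetworkParams(), x=x)
            fracs.append((labels == 0).mean())
        assert np.mean(fracs) >= 0.9

    def test_min_module_size_above_all_clusters_gives_all_zero(self):
        x, _, _ = self._block_expression(1)
        adj = signed_hybrid_adjacency(gene_correlation(x).to_numpy(), 6)
        labels = detect_modules(
            tom_similarity(adj), NetworkParams(min_module_size=1000), x=None, gene_ids=x.gene_ids
        )
        assert (labels == 0).all()

    def test_merge_cor_one_is_noop_and_duplicates_merge(self, random_expression):
        x = random_expression(n_genes=40, n_samples=20, seed=5)
        labels = pd.Series([1] * 20 + [2] * 20, index=x.gene_ids)
        assert merge_modules(x, labels, merge_cor=1.0).equals(labels)
        # duplicated module: second block copies the first
        vals = x.values.to_numpy().copy()
        vals[20:] = vals[:20]
        xdup = ExpressionMatrix(
            pd.DataFrame(vals, index=x.gene_ids, columns=x.sample_ids), layer="transformed"
        )
        merged = merge_modules(xdup, labels, merge_cor=0.95)
        assert merged.nunique() == 1

    def test_merge_idempotent(self):
        x, truth, _ = self._block_expression(2)
        labels = pd.Series(truth, index=x.gene_ids)
        once = merge_modules(x, labels, merge_cor=0.5)
        twice = merge_modules(x, once, merge_cor=0.5)
        assert once.equals(twice)


class TestSoftThreshold:
    def test_report_structure_and_default_beta_honoured(self, random_expression):
        x = random_expression(n_genes=60, n_samples=25, seed=2)
        rep = pick_soft_threshold(x, candidates=(2, 4, 6), target_r2=0.8)
        assert len(rep.r_squared) == 3
        assert all(0.0 <= r <= 1.0 for r in rep.r_squared)
        assert rep.chosen_beta in (2, 4, 6)
        # mean connectivity decreases with beta
        assert rep.mean_connectivity == sorted(rep.mean_connectivity, reverse=True)
        # the conventional default is honoured when selection is disabled
        assert NetworkParams().beta == 6

    def test_block_structure_picks_smallest_candidate(self):
        x, _, _ = TestDetectMerge()._block_expression(3)
        rep = pick_soft_threshold(x, candidates=(1, 2, 3), target_r2=0.0)
        assert rep.chosen_beta == 1


class TestEndToEndNetwork:
    def test_build_network_on_planted_fixture(self):
        x, truth, table = TestDetectMerge()._block_expression(4)
        ms = build_network(x, table["phenotype"], NetworkParams())
        assert isinstance(ms, ModuleSet)
        assert len(ms.module_ids) >= 2
        assert adjusted_rand_score(truth, ms.labels) >= 0.8
        # eigengene columns align with labels, MM high for own module
        for m in ms.module_ids[:2]:
            own = ms.membership.loc[ms.genes_in(m), f"ME{m}"]
            assert own.median() > 0.6
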