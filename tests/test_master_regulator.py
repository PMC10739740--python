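"""Top-gene set, channel recombination, hub statistic and permutation p."""

import numpy as np
import pandas as pd
import pytest

from comodmr.coexpression import ModuleSet
from comodmr.master_regulator import (
    STRING_PRIOR,
    TopGeneConfig,
    build_top_gene_set,
    combine_channel_scores,
    hub_statistic,
    identify_master_regulator,
    permutation_test,
    recombine_scores,
)
from comodmr.simulate import PPI_CHANNELS, SimConfig, simulate_ppi


def _edges(pairs, **channel):
    rows = []
    for p1, p2 in pairs:
        row = {"protein1": p1, "protein2": p2, **{c: 0.0 for c in PPI_CHANNELS}}
        row.update(channel)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["protein1", "protein2", *PPI_CHANNELS])
    df["combined"] = combine_channel_scores(df[list(PPI_CHANNELS)].to_numpy())
    return df


def _module_set(n=100, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:03d}" for i in range(n)], name="gene")
    lab = pd.Series(labels if labels is not None else 1, index=genes)
    mm = pd.DataFrame({"ME1": rng.uniform(-1, 1, n)}, index=genes)
    gs = pd.Series(rng.uniform(-1, 1, n), index=genes, name="GS")
    return ModuleSet(labels=lab, membership=mm, gene_significance=gs)


class TestTopGeneSet:
    def test_tiny_quantiles_include_every_module_gene(self):
        ms = _module_set(50)
        cfg = TopGeneConfig(mm_quantile=1e-9, gs_quantile=1e-9)
        top = build_top_gene_set(None, ms, [1], cfg)
        assert len(top) == 50

    def test_expected_size_matches_bruteforce_rank_intersection(self):
        """Independent MM and GS ranks: the joint top-decile set equals a
        direct rank computation and is near 100·0.1·0.1 in expectation."""
        sizes = []
        for seed in range(40):
            ms = _module_set(100, seed=seed)
            cfg = TopGeneConfig(mm_quantile=0.90, gs_quantile=0.90)
            top = build_top_gene_set(None, ms, [1], cfg)
            mm = ms.membership["ME1"]
            gs = ms.gene_significance.abs()
            manual = set(mm.index[mm >= mm.quantile(0.9, interpolation="lower")]) & set(
                gs.index[gs >= gs.quantile(0.9, interpolation="lower")]
            )
            assert set(top["gene"]) == manual
            sizes.append(len(top))
        assert 0.5 <= np.mean(sizes) <= 2.5  # ≈ 1 under independence

    def test_union_semantics_with_coloc_only_gene(self):
        ms = _module_set(100, seed=1)
        coloc = pd.DataFrame({"gene": ["G000"], "PP4": [0.51]})
        # G000 forced below both quantiles
        ms.membership.loc["G000", "ME1"] = -1.0
        ms.gene_significance.loc["G000"] = 0.0
        top = build_top_gene_set(coloc, ms, [1], TopGeneConfig())
        row = top[top["gene"] == "G000"]
        assert len(row) == 1 and row["coloc"].iloc[0] and not row["mm_gs"].iloc[0]

    def test_no_assoc_modules_rejected(self):
        with pytest.raises(ValueError, match="associated"):
            build_top_gene_set(None, _module_set(10), [], TopGeneConfig())


class TestRecombine:
    def test_single_channel_roundtrip_identity(self):
        for s in (0.15, 0.4, 0.73, 0.95):
            e = _edges([("a", "b")], experiments=s)
            out = recombine_scores(e, exclusions=(), combined_score_min=0.0)
            assert out["combined"].iloc[0] == pytest.approx(s, abs=1e-12)

    def test_all_channels_excluded_leaves_prior_and_drops_edge(self):
        e = _edges([("a", "b")], experiments=0.9, textmining=0.8)
        out = recombine_scores(e, exclusions=PPI_CHANNELS, combined_score_min=0.4)
        assert out.empty
        kept = recombine_scores(e, exclusions=PPI_CHANNELS, combined_score_min=0.0)
        assert kept["combined"].iloc[0] == pytest.approx(STRING_PRIOR)

    def test_two_channel_formula_oracle(self):
        s1, s2, p = 0.9, 0.9, STRING_PRIOR
        e = _edges([("a", "b")], experiments=s1, database=s2)
        out = recombine_scores(e, exclusions=(), combined_score_min=0.0)
        sp1 = (s1 - p) / (1 - p)
        sp2 = (s2 - p) / (1 - p)
        expected = (1 - (1 - sp1) * (1 - sp2)) * (1 - p) + p
        assert out["combined"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_excluding_channels_removes_coexpression_only_edges(self):
        e = _edges([("a", "b")], coexpression=0.95)
        assert recombine_scores(e).empty

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            recombine_scores(_edges([("a", "b")]), exclusions=("nonsense",))


class TestHubStatistic:
    def test_edgeless_set_max_degree_zero(self):
        res = hub_statistic(_edges([], experiments=0.9), ["a", "b", "c"])
        assert res.observed_max_degree == 0

    def test_star_centre_is_hub(self):
        pairs = [("hub", f"n{i}") for i in range(6)]
        res = hub_statistic(_edges(pairs, experiments=0.9), ["hub"] + [f"n{i}" for i in range(6)])
        assert res.hub == "hub"
        assert res.observed_max_degree == 6

    def test_degrees_match_bruteforce_incidence_count(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(20)]
        pairs = [
            (nodes[i], nodes[j])
            for i in range(20)
            for j in range(i + 1, 20)
            if rng.random() < 0.2
        ]
        res = hub_statistic(_edges(pairs, experiments=0.9), nodes)
        for v in nodes:
            expected = sum(1 for a, b in pairs if v in (a, b))
            assert res.degrees[v] == expected

    def test_ties_broken_lexicographically_and_reported(self):
        pairs = [("b", "c"), ("a", "c")]
        res = hub_statistic(_edges(pairs, experiments=0.9), ["a", "b", "c"])
        assert res.hub == "a" or res.hub == "c"
        assert res.observed_max_degree == 2
        assert res.hub == min(res.tied_hubs)


class TestPermutation:
    @staticmethod
    def _er_network(seed, n=120, p=0.1):
        nodes = [f"g{i:03d}" for i in range(n)]
        cfg = SimConfig(seed=seed, n_ppi_nodes=n, ppi_edge_prob=p, hub_extra_degree=0)
        edges, _ = simulate_ppi(cfg, nodes)
        return edges, nodes

    def test_add_one_formula_observed_above_all_permutations(self):
        edges, nodes = self._er_network(0)
        obs = hub_statistic(edges, nodes[:30])
        obs.observed_max_degree = 10_000  # larger than any permutation max
        cfg = TopGeneConfig(n_permutations=100, seed=1)
        res = permutation_test(edges, nodes, 30, cfg, observed=obs)
        assert res.p == pytest.approx(1 / 101)

    def test_p_positive_and_monotone_in_observed(self):
        edges, nodes = self._er_network(1)
        cfg = TopGeneConfig(n_permutations=200, seed=2)
        ps = []
        for degree in (0, 3, 6, 10):
            obs = hub_statistic(edges, nodes[:30])
            obs.observed_max_degree = degree
            ps.append(permutation_test(edges, nodes, 30, cfg, observed=obs).p)
        assert all(p > 0 for p in ps)
        assert ps == sorted(ps, reverse=True)

    def test_statistic_invariant_to_node_relabelling(self):
        edges, nodes = self._er_network(3)
        mapping = {n: f"x{n}" for n in nodes}
        renamed = edges.assign(
            protein1=edges["protein1"].map(mapping), protein2=edges["protein2"].map(mapping)
        )
        cfg = TopGeneConfig(n_permutations=300, seed=4)
        obs1 = hub_statistic(edges, nodes[:40])
        obs2 = hub_statistic(renamed, [mapping[n] for n in nodes[:40]])
        assert obs1.observed_max_degree == obs2.observed_max_degree
        p1 = permutation_test(edges, nodes, 40, cfg, observed=obs1).p
        p2 = permutation_test(renamed, [mapping[n] for n in nodes], 40, cfg, observed=obs2).p
        assert p1 == pytest.approx(p2)

    def test_null_p_is_conservatively_valid(self):
        """With no planted hub the add-one p is super-uniform:
        P(p ≤ a) ≤ a (+ Monte-Carlo slack) at every level."""
        ps = []
        for seed in range(60):
            edges, nodes = self._er_network(seed)
            rng = np.random.default_rng(1000 + seed)
            chosen = list(rng.choice(nodes, 30, replace=False))
            obs = hub_statistic(edges, chosen)
            cfg = TopGeneConfig(n_permutations=199, seed=seed)
            ps.append(permutation_test(edges, nodes, 30, cfg, observed=obs).p)
        ps = np.array(ps)
        for a in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= a).mean() <= a + 2.5 * np.sqrt(a * (1 - a) / len(ps))

    def test_set_size_exceeding_universe_rejected(self):
        edges, nodes = self._er_network(5)
        with pytest.raises(ValueError, match="universe"):
            permutation_test(edges, nodes, len(nodes) + 1, TopGeneConfig(), observed=hub_statistic(edges, nodes))

    def test_planted_hub_detected_with_small_p(self):
        """A hub wired to the prospective top set dominates random sets."""
        n = 150
        nodes = [f"g{i:03d}" for i in range(n)]
        top = nodes[:40]
        cfg = SimConfig(seed=7, n_ppi_nodes=n, ppi_edge_prob=0.05, hub_extra_degree=30)
        edges, truth = simulate_ppi(cfg, nodes, hub_node="g000", hub_targets=top)
        pruned = recombine_scores(edges)
        obs = hub_statistic(pruned, top)
        assert obs.hub == truth.planted_hub_node
        res = permutation_test(pruned, nodes, 40, TopGeneConfig(n_permutations=999, seed=8), observed=obs)
        assert res.p <= 0.01
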