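"""Adjacency, TOM, module detection/merging, kME, enrichment and hub selection."""

import math

import numpy as np
import pandas as pd
import pytest

from lncforge.coexpression_network import (
    AdjacencyMatrix,
    UNASSIGNED,
    adjacency_from_expression,
    detect_modules,
    hub_selection,
    hypergeometric_enrichment,
    kme_and_trait_correlation,
    module_eigengene_and_merge,
    tom_matrix,
)
from lncforge.synthetic_data import simulate_block_expression


def oracle_hypergeom_tail(k, n_universe, term_size, module_size):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    denom = math.comb(n_universe, module_size)
    for j in range(k, min(term_size, module_size) + 1):
        total += math.comb(term_size, j) * math.comb(n_universe - term_size,
                                                     module_size - j) / denom
    return total


class TestAdjacency:
    def test_powers_of_correlation(self, rng):
        n = 30
        base = rng.normal(size=n)
        expr = pd.DataFrame({
            "a": base, "b": base,                      # cor 1
            "c": -base,                                # cor -1 with a
            "d": rng.normal(size=n),
        }).T
        adj = adjacency_from_expression(expr, beta=9)
        a = pd.DataFrame(adj.values, index=adj.ids, columns=adj.ids)
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "c"] == pytest.approx(1.0)  # unsigned network
        assert 0 <= a.loc["a", "d"] < 0.5**9 * 50

    def test_explicit_power_values(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        z = -0.8 * x + 0.3 * rng.normal(size=50)
        expr = pd.DataFrame([x, y, z], index=list("abc"))
        adj = adjacency_from_expression(expr, beta=9)
        c = np.corrcoef(expr.to_numpy())
        assert adj.values[0, 1] == pytest.approx(abs(c[0, 1]) ** 9, rel=1e-12)
        assert adj.values[0, 2] == pytest.approx(abs(c[0, 2]) ** 9, rel=1e-12)

    def test_zero_variance_removed_with_warning(self, rng):
        expr = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10),
                             "b": rng.normal(size=10)}).T
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = adjacency_from_expression(expr)
        assert adj.ids == ["a", "b"]

    def test_too_few_samples_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            adjacency_from_expression(expr)


class TestTom:
    def test_two_node_closed_form(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        tom = tom_matrix(a)
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_pair(self):
        a = np.eye(2)
        assert tom_matrix(a)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_three_node_clique_closed_form(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_matrix(a)
        assert tom[0, 1] == pytest.approx(0.5, abs=1e-12)  # (0.25+0.5)/(1+1-0.5)

    def test_equals_adjacency_without_shared_neighbors(self):
        # path graph a-b: no third node, l = 0 and k = a
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert tom_matrix(a)[0, 1] == pytest.approx(0.3 / (0.3 + 1 - 0.3), abs=1e-12)

    def test_bounds_and_symmetry_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 25))
            a = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_matrix(a)
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


class TestModules:
    def test_two_perfect_blocks_recovered(self, rng):
        base1, base2 = rng.normal(size=10), rng.normal(size=10)
        rows = [base1] * 3 + [base2] * 3
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)])
        adj = adjacency_from_expression(expr)
        assign = detect_modules(tom_matrix(adj), adj.ids, min_module_size=3)
        groups = assign.groupby(assign).groups
        assert sorted(len(v) for v in groups.values()) == [3, 3]
        assert UNASSIGNED not in groups

    def test_independent_noise_all_grey(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(200, 40)),
                            index=[f"g{i}" for i in range(200)])
        adj = adjacency_from_expression(expr, beta=9)
        assign = detect_modules(tom_matrix(adj), adj.ids,
                                min_module_size=30, cut_height=0.995)
        assert (assign == UNASSIGNED).all()

    def test_deterministic_labels(self):
        expr, labels, _ = simulate_block_expression(seed=3)
        adj = adjacency_from_expression(expr)
        t = tom_matrix(adj)
        a1 = detect_modules(t, adj.ids)
        a2 = detect_modules(t, adj.ids)
        assert a1.equals(a2)


class TestEigengenes:
    def test_identical_profiles_give_kme_one(self, rng):
        base = rng.normal(size=12)
        expr = pd.DataFrame([base, base, base], index=list("abc"))
        assign = pd.Series(["blue"] * 3, index=list("abc"))
        assign, mes = module_eigengene_and_merge(expr, assign)
        kme, _ = kme_and_trait_correlation(
            expr, mes, pd.DataFrame({"t": rng.integers(0, 2, 12)}, index=mes.index))
        assert np.allclose(kme["blue"], 1.0)

    def test_shared_factor_modules_merge(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=20)
        g = rng.normal(size=20)  # orthogonal factor
        expr = pd.DataFrame(
            [f + rng.normal(0, 0.2, 20) for _ in range(5)]
            + [f + rng.normal(0, 0.25, 20) for _ in range(5)]
            + [g + rng.normal(0, 0.2, 20) for _ in range(5)],
            index=[f"g{i}" for i in range(15)])
        assign = pd.Series(["m1"] * 5 + ["m2"] * 5 + ["m3"] * 5, index=expr.index)
        merged, mes = module_eigengene_and_merge(expr, assign, merge_cor=0.70)
        assert merged[:10].nunique() == 1          # same-factor modules merged
        assert merged.nunique() == 2               # orthogonal module survives

    def test_eigengene_explains_most_variance(self):
        expr, labels, _ = simulate_block_expression(seed=2)
        members = labels.index[labels == "block1"]
        assign = pd.Series(["m"] * len(members), index=members)
        _, mes = module_eigengene_and_merge(expr.loc[members], assign)
        z = ((expr.loc[members].T - expr.loc[members].T.mean())
             / expr.loc[members].T.std(ddof=0)).T
        me = mes["m"].to_numpy()
        var_me = np.mean([np.corrcoef(z.loc[g], me)[0, 1] ** 2 for g in members])
        best_member = max(
            np.mean([np.corrcoef(z.loc[g], z.loc[h])[0, 1] ** 2 for g in members])
            for h in members)
        assert var_me >= best_member - 1e-9

    def test_trait_correlation_extremes(self, rng):
        n = 16
        me = rng.normal(size=n)
        expr = pd.DataFrame([me], index=["g1"])
        samples = [f"s{i}" for i in range(n)]
        expr.columns = samples
        mes = pd.DataFrame({"m": me}, index=samples)
        traits = pd.DataFrame({"same": me, "ortho": rng.normal(size=n)}, index=samples)
        _, mt = kme_and_trait_correlation(expr, mes, traits)
        mt = mt.set_index("trait")
        assert mt.loc["same", "r"] == pytest.approx(1.0)
        assert mt.loc["same", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_rejected(self, rng):
        me = rng.normal(size=8)
        expr = pd.DataFrame([me], index=["g"])
        expr.columns = [f"s{i}" for i in range(8)]
        mes = pd.DataFrame({"m": me}, index=expr.columns)
        with pytest.raises(ValueError, match="constant"):
            kme_and_trait_correlation(expr, mes,
                                      pd.DataFrame({"t": np.ones(8)}, index=expr.columns))


class TestEnrichment:
    def test_matches_direct_tail_summation_small_universes(self, rng):
        for _ in range(40):
            n_universe = int(rng.integers(5, 31))
            universe = [f"g{i}" for i in range(n_universe)]
            module_size = int(rng.integers(1, n_universe + 1))
            module = list(rng.choice(universe, size=module_size, replace=False))
            term_size = int(rng.integers(1, n_universe + 1))
            term = list(rng.choice(universe, size=term_size, replace=False))
            out = hypergeometric_enrichment(module, {"T": term}, universe)
            k = len(set(term) & set(module))
            assert out.loc[0, "p"] == pytest.approx(
                oracle_hypergeom_tail(k, n_universe, term_size, module_size),
                rel=1e-9, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        out = hypergeometric_enrichment(["a"], {"T": ["b"]}, ["a", "b", "c"])
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_term_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="absent from universe"):
            hypergeometric_enrichment(["a"], {"T": ["zz"]}, ["a", "b"])

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(40)]
        term = universe[:15]
        pvals = []
        for _ in range(500):
            module = list(rng.choice(universe, size=10, replace=False))
            out = hypergeometric_enrichment(module, {"T": term}, universe)
            # randomized p-value to de-discretize the null for the KS check
            k = out.loc[0, "k"]
            p_ge = oracle_hypergeom_tail(k, 40, 15, 10)
            p_gt = oracle_hypergeom_tail(k + 1, 40, 15, 10)
            pvals.append(p_gt + rng.uniform() * (p_ge - p_gt))
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestHubSelection:
    def _weights(self, edges, nodes):
        w = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for a, b in edges:
            w.loc[a, b] = w.loc[b, a] = 1.0
        np.fill_diagonal(w.values, 1.0)
        return w

    def test_star_lncrna_ranks_first(self):
        proteins = [f"p{i}" for i in range(10)]
        nodes = proteins + ["hub", "minor"]
        edges = [("hub", p) for p in proteins] + [("minor", "p0")]
        w = self._weights(edges, nodes)
        hubs = hub_selection(w, 0.5, ["hub", "minor"], {"net": proteins}, top_k=1)
        assert [h.lncrna_id for h in hubs] == ["hub"]
        assert hubs[0].degree == 10 and hubs[0].hub_class == "intra"

    def test_inter_network_classification(self):
        nodes = ["pa", "pb", "l1", "l2"]
        edges = [("l1", "pa"), ("l1", "pb"), ("l2", "pa")]
        w = self._weights(edges, nodes)
        hubs = hub_selection(w, 0.5, ["l1", "l2"],
                             {"A": ["pa"], "B": ["pb"]}, top_k=5)
        classes = {h.lncrna_id: h.hub_class for h in hubs}
        assert classes["l1"] == "inter" and classes["l2"] == "intra"

    def test_threshold_above_all_weights_warns_and_is_empty(self):
        w = self._weights([("l1", "p1")], ["p1", "l1"])
        with pytest.warns(UserWarning, match="no neighboring"):
            assert hub_selection(w, 2.0, ["l1"], {"net": ["p1"]}) == []

    def test_empty_subnetwork_rejected(self):
        w = self._weights([], ["p1", "l1"])
        with pytest.raises(ValueError, match="no proteins"):
            hub_selection(w, 0.5, ["l1"], {"net": ["absent"]})
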