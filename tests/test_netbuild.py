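"""Graph construction, similarity matrices and thresholding."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from middennet import (
    AssemblageMatrix,
    abundance_similarity,
    build_two_mode,
    jaccard_similarity,
    max_connected_threshold,
    percent_mni,
    project_subgroup_ties,
    threshold_graph,
)
from middennet.netbuild import check_similarity

from conftest import random_count_matrix


def brute_jaccard(matrix: AssemblageMatrix, axis: str) -> pd.DataFrame:
    """Set-algebra oracle for the Jaccard coefficient."""
    if axis == "contexts":
        sets = {
            c: {t for t in matrix.taxa if matrix.counts.loc[t, c] >= 1}
            for c in matrix.contexts
        }
        items = matrix.contexts
    else:
        sets = {
            t: {c for c in matrix.contexts if matrix.counts.loc[t, c] >= 1}
            for t in matrix.taxa
        }
        items = matrix.taxa
    out = pd.DataFrame(1.0, index=items, columns=items)
    for a, b in itertools.combinations(items, 2):
        union = sets[a] | sets[b]
        v = 1.0 if not union else len(sets[a] & sets[b]) / len(union)
        out.loc[a, b] = out.loc[b, a] = v
    return out


class TestBuildTwoMode:
    def test_presence_ties(self):
        m = AssemblageMatrix(
            pd.DataFrame([[1, 0], [0, 3]], index=["t1", "t2"], columns=["c1", "c2"])
        )
        g = build_two_mode(m, "presence")
        assert g.number_of_edges() == 2
        assert {frozenset(e) for e in g.edges} == {
            frozenset({"t1", "c1"}),
            frozenset({"t2", "c2"}),
        }

    def test_all_zero_matrix_keeps_isolates(self):
        m = AssemblageMatrix(
            pd.DataFrame([[0, 0]], index=["t1"], columns=["c1", "c2"])
        )
        g = build_two_mode(m, "presence")
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_bipartite_purity(self, pineland):
        g = build_two_mode(pineland, "presence")
        for u, v in g.edges:
            assert g.nodes[u]["node_class"] != g.nodes[v]["node_class"]

    def test_weight_rule_uses_percent_mni(self, toy_matrix):
        g = build_two_mode(toy_matrix, "weight")
        assert g.edges["ta", "c1"]["weight"] == pytest.approx(0.2)

    def test_operation_p_species_side_count(self, pineland, pineland_taxa, pineland_contexts):
        op = [c.context_id for c in pineland_contexts if c.site_area == "operation_p"]
        inv = {t.taxon_id for t in pineland_taxa if t.kingdom_class == "invertebrate"}
        sub = pineland.select_contexts(op)
        present_inv = [
            t for t in sub.taxa if t in inv and sub.counts.loc[t].sum() >= 1
        ]
        g = build_two_mode(sub.select_taxa(present_inv), "presence")
        species_nodes = [n for n, d in g.nodes(data=True) if d["node_class"] == "species"]
        assert len(species_nodes) == len(present_inv)


class TestJaccard:
    def test_identical_sets(self):
        m = AssemblageMatrix(
            pd.DataFrame([[1, 1], [2, 5]], index=["t1", "t2"], columns=["c1", "c2"])
        )
        assert jaccard_similarity(m, "contexts").loc["c1", "c2"] == 1.0

    def test_disjoint_sets(self):
        m = AssemblageMatrix(
            pd.DataFrame([[1, 0], [0, 1]], index=["t1", "t2"], columns=["c1", "c2"])
        )
        assert jaccard_similarity(m, "contexts").loc["c1", "c2"] == 0.0

    def test_partial_overlap(self):
        # {a,b,c} vs {b,c,d}: 2 shared over 4 in the union
        df = pd.DataFrame(
            [[1, 0], [1, 1], [1, 1], [0, 1]],
            index=list("abcd"),
            columns=["c1", "c2"],
        )
        sim = jaccard_similarity(AssemblageMatrix(df), "contexts")
        assert sim.loc["c1", "c2"] == 0.5

    def test_empty_sets_similarity_one_with_warning(self):
        df = pd.DataFrame([[0, 0]], index=["t"], columns=["c1", "c2"])
        with pytest.warns(UserWarning, match="empty presence"):
            sim = jaccard_similarity(AssemblageMatrix(df), "contexts")
        assert sim.loc["c1", "c2"] == 1.0

    @pytest.mark.parametrize("axis", ["contexts", "taxa"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_algebra_oracle(self, axis, seed):
        import warnings

        rng = np.random.default_rng(seed)
        m = random_count_matrix(rng, rng.integers(3, 21), rng.integers(3, 21))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty presence sets are expected
            sim = jaccard_similarity(m, axis)
        oracle = brute_jaccard(m, axis)
        assert np.allclose(sim.to_numpy(), oracle.to_numpy())
        check_similarity(sim)


class TestAbundanceSimilarity:
    def _sim(self, rows, index, columns):
        m = AssemblageMatrix(pd.DataFrame(rows, index=index, columns=columns))
        return abundance_similarity(percent_mni(m))

    def test_identical_profiles(self):
        sim = self._sim([[2, 4], [1, 2]], ["t1", "t2"], ["c1", "c2"])
        assert sim.loc["t1", "t2"] == pytest.approx(1.0)

    def test_disjoint_support(self):
        sim = self._sim([[3, 0], [0, 7]], ["t1", "t2"], ["c1", "c2"])
        assert sim.loc["t1", "t2"] == pytest.approx(0.0)

    def test_known_overlap(self):
        # normalized profiles (.5,.5,0) and (.25,.5,.25): summed minima 0.75
        from middennet.metrics import ProportionMatrix

        prop = ProportionMatrix(
            proportions=pd.DataFrame(
                [[0.5, 0.5, 0.0], [0.25, 0.5, 0.25]],
                index=["t1", "t2"],
                columns=["c1", "c2", "c3"],
            ),
            flagged=[],
        )
        sim = abundance_similarity(prop)
        assert sim.loc["t1", "t2"] == pytest.approx(0.75)

    def test_zero_total_taxon_excluded_with_warning(self):
        df = pd.DataFrame(
            [[1, 1], [0, 0], [2, 0]], index=["t1", "t2", "t3"], columns=["c1", "c2"]
        )
        with pytest.warns(UserWarning, match="zero scoped"):
            sim = abundance_similarity(percent_mni(AssemblageMatrix(df)))
        assert list(sim.index) == ["t1", "t3"]

    @pytest.mark.parametrize("seed", range(8))
    def test_symmetric_bounded_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_count_matrix(rng, 8, 6, density=0.8)
        keep = [t for t in m.taxa if m.counts.loc[t].sum() > 0]
        sim = abundance_similarity(percent_mni(m.select_taxa(keep)))
        check_similarity(sim)
        a = sim.to_numpy()
        assert (a <= 1 + 1e-12).all()
        # S = 1 exactly when normalized profiles coincide
        props = percent_mni(m.select_taxa(keep)).proportions
        norm = props.div(props.sum(axis=1), axis=0)
        for i, ti in enumerate(sim.index):
            for j, tj in enumerate(sim.index):
                if i < j and a[i, j] == pytest.approx(1.0, abs=1e-12):
                    assert np.allclose(norm.loc[ti], norm.loc[tj])


class TestThresholdGraph:
    def _sim(self, n, vals):
        items = [f"i{k}" for k in range(n)]
        df = pd.DataFrame(np.eye(n), index=items, columns=items)
        for (i, j), v in vals.items():
            df.iloc[i, j] = df.iloc[j, i] = v
        return df

    def test_strict_cutoff(self):
        sim = self._sim(3, {(0, 1): 0.9, (1, 2): 0.2, (0, 2): 0.0})
        g = threshold_graph(sim, 0.5)
        assert g.number_of_edges() == 1
        assert g.number_of_nodes() == 3  # isolates kept

    def test_t_one_strict_is_edgeless(self):
        sim = self._sim(2, {(0, 1): 1.0})
        assert threshold_graph(sim, 1.0, strict=True).number_of_edges() == 0

    def test_exact_boundary_excluded_when_strict(self):
        sim = self._sim(2, {(0, 1): 0.33})
        assert threshold_graph(sim, 0.33, strict=True).number_of_edges() == 0
        assert threshold_graph(sim, 0.33, strict=False).number_of_edges() == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        sim = pd.DataFrame(a, index=range(n), columns=range(n))
        counts = [
            threshold_graph(sim, t).number_of_edges() for t in np.linspace(0, 1, 21)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMaxConnectedThreshold:
    def test_chain_breaks_at_weakest_needed_edge(self):
        sim = pd.DataFrame(
            [[1.0, 0.8, 0.1], [0.8, 1.0, 0.6], [0.1, 0.6, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        sweep = max_connected_threshold(sim)
        assert sweep.t_star == 0.6

    def test_uniform_complete_graph(self):
        a = np.full((4, 4), 0.4)
        np.fill_diagonal(a, 1.0)
        sim = pd.DataFrame(a, index=list("ABCD"), columns=list("ABCD"))
        assert max_connected_threshold(sim).t_star == 0.4

    def test_disconnected_pairs_error_or_largest(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.9
        a[2, 3] = a[3, 2] = 0.8
        sim = pd.DataFrame(a, index=list("ABCD"), columns=list("ABCD"))
        with pytest.raises(ValueError, match="disconnected"):
            max_connected_threshold(sim)
        sweep = max_connected_threshold(sim, on_disconnected="largest")
        assert sweep.t_star == 0.9
        assert set(sweep.scope) == {"A", "B"}

    @pytest.mark.parametrize("seed", range(10))
    def test_connected_at_t_star_disconnected_above(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        sim = pd.DataFrame(a, index=range(n), columns=range(n))
        sweep = max_connected_threshold(sim)
        g_at = nx.Graph(
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if a[i, j] >= sweep.t_star
        )
        g_at.add_nodes_from(range(n))
        assert nx.is_connected(g_at)
        larger = [v for v in sweep.candidate_values if v > sweep.t_star]
        if larger:
            t2 = min(larger)
            g_above = nx.Graph(
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if a[i, j] >= t2
            )
            g_above.add_nodes_from(range(n))
            assert not nx.is_connected(g_above)


class TestProjectSubgroupTies:
    def _matrix(self):
        # context c: t1+t2 = 7% of 100, t3 = 3%, t4 = 90%
        df = pd.DataFrame({"c": [4, 3, 3, 90]}, index=["t1", "t2", "t3", "t4"])
        return AssemblageMatrix(df)

    def test_inclusive_five_percent_rule(self):
        m = self._matrix()
        part = {"t1": 1, "t2": 1, "t3": 2, "t4": 3}
        g = project_subgroup_ties(m, part, cutoff=0.05)
        assert g.has_edge("context:c", "group:1")
        assert g.edges["context:c", "group:1"]["weight"] == pytest.approx(0.07)
        assert not g.has_edge("context:c", "group:2")  # 3% misses the cutoff
        # exactly 5%: "at least" means inclusive
        df = pd.DataFrame({"c": [5, 95]}, index=["t1", "t2"])
        g2 = project_subgroup_ties(
            AssemblageMatrix(df), {"t1": 1, "t2": 2}, cutoff=0.05
        )
        assert g2.has_edge("context:c", "group:1")

    def test_zero_cutoff_conserves_mass(self, pineland):
        part = {t: i % 4 for i, t in enumerate(pineland.taxa)}
        g = project_subgroup_ties(pineland, part, cutoff=0.0)
        for c in pineland.contexts:
            w = sum(
                g.edges[e]["weight"] for e in g.edges(f"context:{c}")
            )
            assert w == pytest.approx(1.0, abs=1e-9)

    def test_bipartite_purity(self):
        g = project_subgroup_ties(self._matrix(), {"t1": 1, "t2": 1, "t3": 2, "t4": 3})
        for u, v in g.edges:
            assert g.nodes[u]["node_class"] != g.nodes[v]["node_class"]
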