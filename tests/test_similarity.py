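import math

import networkx as nx
import numpy as np
import pytest

from cfsaemda.data_io import DiseaseOntology, SimilarityMatrix
from cfsaemda.similarity import (
    SemanticParams,
    ancestor_closure,
    combined_semantic_similarity,
    disease_gip_similarity,
    gip_bandwidth,
    gip_kernel,
    integrate_similarity,
    mirna_gip_similarity,
    semantic_contribution_wang,
    semantic_contribution_xuan,
    semantic_similarity,
    semantic_value,
)
from cfsaemda.synthetic_data import generate_ontology

CHAIN = DiseaseOntology({"d", "p", "g"}, {("d", "p"), ("p", "g")})
DIAMOND = DiseaseOntology({"d", "p1", "p2", "g"}, {("d", "p1"), ("d", "p2"), ("p1", "g"), ("p2", "g")})


class TestAncestorClosure:
    def test_chain_closure(self):
        dag = ancestor_closure(CHAIN, "d")
        assert dag.nodes == {"d", "p", "g"} and len(dag.edges) == 2

    def test_diamond_closure(self):
        dag = ancestor_closure(DIAMOND, "d")
        assert dag.nodes == {"d", "p1", "p2", "g"} and len(dag.edges) == 4

    def test_uncovered_disease_yields_none(self, worked_example):
        _, onto, _ = worked_example
        assert ancestor_closure(onto, "d3") is None
        assert ancestor_closure(onto, "d1").nodes == {"d1", "p"}


class TestWangContribution:
    def test_chain_values(self):
        c1 = semantic_contribution_wang(ancestor_closure(CHAIN, "d"))
        assert c1 == {"d": 1.0, "p": 0.5, "g": 0.25}

    def test_singleton(self):
        onto = DiseaseOntology({"solo"}, set())
        c1 = semantic_contribution_wang(ancestor_closure(onto, "solo"))
        assert c1 == {"solo": 1.0}

    def test_diamond_grandparent_takes_max_over_children(self):
        c1 = semantic_contribution_wang(ancestor_closure(DIAMOND, "d"))
        assert c1["g"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_mu_power_shortest_path_on_random_dags(self, seed):
        """Independent oracle: C1(k) = mu^(shortest ancestor-path d -> k)."""
        onto = generate_ontology(12, max_parents=3, seed=seed)
        g = onto.graph()
        for d in sorted(onto.terms):
            dag = ancestor_closure(onto, d)
            c1 = semantic_contribution_wang(dag)
            lengths = nx.single_source_shortest_path_length(g, d)
            for k in dag.nodes:
                assert c1[k] == pytest.approx(0.5 ** lengths[k]), (d, k)


class TestSemanticValues:
    def test_chain_semantic_value(self):
        c1 = semantic_contribution_wang(ancestor_closure(CHAIN, "d"))
        assert semantic_value(c1) == pytest.approx(1.75)

    def test_worked_example_d1(self, worked_example):
        _, onto, _ = worked_example
        c1 = semantic_contribution_wang(ancestor_closure(onto, "d1"))
        assert semantic_value(c1) == pytest.approx(1.5)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            semantic_value({})


class TestXuanContribution:
    def test_term_in_all_dags_contributes_zero(self):
        onto = DiseaseOntology({"a", "b", "r"}, {("a", "r"), ("b", "r")})
        c2 = semantic_contribution_xuan(onto, ["a", "b"])
        assert c2["r"] == pytest.approx(0.0)

    def test_rare_term_contribution_natural_log(self):
        onto = DiseaseOntology({"a", "b", "c", "e"}, set())
        c2 = semantic_contribution_xuan(onto, ["a", "b", "c", "e"])
        assert c2["a"] == pytest.approx(math.log(4))

    def test_every_disease_counts_itself(self, worked_example):
        _, onto, _ = worked_example
        c2 = semantic_contribution_xuan(onto, ["d1", "d2", "d3"])
        assert c2["d1"] > 0 and c2["p"] == pytest.approx(-math.log(2 / 3))


class TestSemanticSimilarity:
    def test_worked_example_wang_value(self, worked_example):
        _, onto, _ = worked_example
        dss1 = semantic_similarity(onto, ["d1", "d2", "d3"], scheme="wang")
        assert dss1.values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_disjoint_ancestors_give_zero(self):
        onto = DiseaseOntology({"a", "b", "pa", "pb"}, {("a", "pa"), ("b", "pb")})
        dss = semantic_similarity(onto, ["a", "b"], scheme="wang")
        assert dss.values[0, 1] == 0.0 and not dss.missing[0, 1]

    def test_self_similarity_is_one(self, worked_example):
        _, onto, _ = worked_example
        for scheme in ("wang", "xuan"):
            dss = semantic_similarity(onto, ["d1", "d2", "d3"], scheme=scheme)
            assert dss.values[0, 0] == 1.0 and dss.values[1, 1] == 1.0

    def test_uncovered_disease_rows_are_missing(self, worked_example):
        _, onto, _ = worked_example
        dss = semantic_similarity(onto, ["d1", "d2", "d3"], scheme="wang")
        assert dss.missing[2].all() and dss.missing[:, 2].all()

    def test_permutation_equivariance(self):
        onto = generate_ontology(10, max_parents=2, seed=3)
        ids = sorted(onto.terms)
        perm = [ids[i] for i in [3, 0, 7, 1, 9, 2, 8, 4, 6, 5]]
        a = semantic_similarity(onto, ids, scheme="wang")
        b = semantic_similarity(onto, perm, scheme="wang")
        pi = [ids.index(p) for p in perm]
        assert np.allclose(b.values, a.values[np.ix_(pi, pi)])

    def test_combined_is_elementwise_mean_with_missing_propagation(self, worked_example):
        _, onto, _ = worked_example
        dss1 = semantic_similarity(onto, ["d1", "d2", "d3"], scheme="wang")
        dss2 = semantic_similarity(onto, ["d1", "d2", "d3"], scheme="xuan")
        dss = combined_semantic_similarity(dss1, dss2)
        assert dss.values[0, 1] == pytest.approx((dss1.values[0, 1] + dss2.values[0, 1]) / 2)
        assert dss.values[0, 0] == 1.0
        assert dss.missing[0, 2]

    def test_combined_rejects_id_mismatch(self):
        a = SimilarityMatrix(["x", "y"], np.eye(2))
        b = SimilarityMatrix(["y", "x"], np.eye(2))
        with pytest.raises(ValueError):
            combined_semantic_similarity(a, b)


class TestGIP:
    def test_bandwidth_of_unit_profiles(self):
        profiles = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert gip_bandwidth(profiles, 1.0) == pytest.approx(1.0)

    def test_bandwidth_halves_when_norms_double(self, rng):
        profiles = rng.random((8, 5))
        a1 = gip_bandwidth(profiles)
        a2 = gip_bandwidth(np.sqrt(2) * profiles)
        assert a2 == pytest.approx(a1 / 2)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gip_bandwidth(np.zeros((3, 4)))

    def test_orthogonal_unit_profiles_give_exp_minus_two(self):
        sim = gip_kernel(np.array([[1.0, 0.0], [0.0, 1.0]]), alpha=1.0)
        assert sim.values[0, 1] == pytest.approx(math.exp(-2), rel=1e-12)
        assert sim.values[0, 0] == 1.0

    def test_matches_brute_force_double_loop(self, rng):
        """Oracle: explicit exp(-alpha * ||IP_i - IP_j||^2) pairwise loop."""
        A = (rng.random((10, 6)) < 0.4).astype(float)
        alpha = gip_bandwidth(A)
        sim = gip_kernel(A, alpha)
        for i in range(10):
            for j in range(10):
                expected = math.exp(-alpha * float(((A[i] - A[j]) ** 2).sum()))
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_values_in_unit_interval_with_unit_diagonal(self, rng):
        A = (rng.random((15, 9)) < 0.3).astype(float)
        A[0] = 1  # ensure no degenerate all-zero matrix
        sim = gip_kernel(A, gip_bandwidth(A))
        assert np.all(sim.values > 0) and np.all(sim.values <= 1)
        assert np.all(np.diag(sim.values) == 1.0)

    def test_removing_association_only_touches_affected_rows(self, worked_example):
        assoc, _, _ = worked_example
        base = mirna_gip_similarity(assoc)
        mod = assoc.copy()
        mod.A[1, 1] = 0
        pert = mirna_gip_similarity(mod)
        assert np.all(np.diag(pert.values) == 1.0)
        # miRNA 1's row changed; rows not involving miRNA 1 keep their distances
        # (bandwidth changes globally, so compare which raw distances moved)
        d_base = -np.log(np.clip(base.values, 1e-300, 1.0))
        d_pert = -np.log(np.clip(pert.values, 1e-300, 1.0))
        ratio_base = d_base[0, 2] / d_base[0, 3]
        ratio_pert = d_pert[0, 2] / d_pert[0, 3]
        assert ratio_base == pytest.approx(ratio_pert)


class TestIntegration:
    @pytest.mark.parametrize(
        "primary,missing,gip,expected",
        [(0.4, False, 0.6, 0.5), (0.0, True, 0.6, 0.6), (0.8, False, 0.8, 0.8)],
    )
    def test_elementwise_rule(self, primary, missing, gip, expected):
        ids = ["a", "b"]
        pvals = np.array([[1.0, primary], [primary, 1.0]])
        pmiss = np.zeros((2, 2), dtype=bool)
        pmiss[0, 1] = pmiss[1, 0] = missing
        if missing:
            pvals[0, 1] = pvals[1, 0] = 0.0
        gvals = np.array([[1.0, gip], [gip, 1.0]])
        out = integrate_similarity(SimilarityMatrix(ids, pvals, pmiss), SimilarityMatrix(ids, gvals))
        assert out.values[0, 1] == pytest.approx(expected)
        assert not out.missing.any()

    def test_worked_example_ds_falls_back_to_gip_for_d3(self, worked_example):
        assoc, onto, _ = worked_example
        dss1 = semantic_similarity(onto, list(assoc.disease_ids), scheme="wang")
        dss2 = semantic_similarity(onto, list(assoc.disease_ids), scheme="xuan")
        dss = combined_semantic_similarity(dss1, dss2)
        ksd = disease_gip_similarity(assoc)
        ds = integrate_similarity(dss, ksd)
        assert ds.values[0, 2] == pytest.approx(ksd.values[0, 2])
        assert ds.values[0, 1] == pytest.approx((dss.values[0, 1] + ksd.values[0, 1]) / 2)
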