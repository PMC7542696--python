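import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anatonet import (AnnotationProfiles, GeneNetwork, compare_networks,
                      evaluate_network, filter_network, fully_randomize,
                      hishigaki_score, loocv_entity, make_world,
                      predict_candidates)
from anatonet.evaluate import pr_auc, roc_auc

from oracles import roc_auc_pairs


def _star_net(n_neighbors=4, n_total=10):
    """Gene u connected to n_neighbors genes, the rest isolated nodes."""
    net = GeneNetwork()
    net.graph.add_nodes_from([f"n{i}" for i in range(n_total - 1)] + ["u"])
    for i in range(n_neighbors):
        net.graph.add_edge("u", f"n{i}", score=1.0)
    return net


class TestHishigaki:
    def test_enriched_neighborhood(self):
        # tot_N=10, tot_f=5, n(u)=4, n_f=3: e_f=2, score=+0.5
        net = _star_net()
        score = hishigaki_score(net, "u", {"n0", "n1", "n2"}, tot_f=5, tot_n=10)
        assert score == pytest.approx(0.5)

    def test_null_case_scores_zero(self):
        net = _star_net()
        score = hishigaki_score(net, "u", {"n0", "n1"}, tot_f=5, tot_n=10)
        assert score == 0.0  # n_f = 2 = e_f

    def test_depleted_neighborhood_signed(self):
        net = _star_net()
        assert hishigaki_score(net, "u", set(), tot_f=5, tot_n=10) == pytest.approx(-2.0)

    def test_unsigned_mode_is_symmetric_chi_square(self):
        net = _star_net()
        up = hishigaki_score(net, "u", {"n0", "n1", "n2", "n3"}, tot_f=5, tot_n=10,
                             signed=False)
        down = hishigaki_score(net, "u", set(), tot_f=5, tot_n=10, signed=False)
        assert up == pytest.approx(2.0) and down == pytest.approx(2.0)

    def test_isolated_gene_scores_zero(self):
        net = _star_net()
        assert hishigaki_score(net, "n8", {"n0"}, tot_f=5, tot_n=10) == 0.0

    def test_entity_absent_from_network_scores_zero(self):
        net = _star_net()
        assert hishigaki_score(net, "u", set(), tot_f=0, tot_n=10) == 0.0

    def test_antisymmetric_around_expectation(self):
        net = _star_net()
        for delta in (1, 2):
            up = hishigaki_score(net, "u", set(list(f"n{i}" for i in range(2 + delta))),
                                 tot_f=5, tot_n=10)
            down = hishigaki_score(net, "u", set(f"n{i}" for i in range(2 - delta)),
                                   tot_f=5, tot_n=10)
            assert up == pytest.approx(-down)


class TestAUC:
    def test_separable_scores(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_mann_whitney_pair_count(self):
        # positives {0.9, 0.3}, negatives {0.5, 0.1}: 3 of 4 pairs concordant
        assert roc_auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_ties_get_half_credit(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_concordant_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        scores = rng.integers(0, 15, size=n) / 14.0  # ties likely
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_pairs(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_random_null_mean_is_half(self):
        rng = np.random.default_rng(99)
        aucs = []
        for _ in range(1000):
            scores = rng.random(550)
            labels = np.zeros(550, dtype=bool)
            labels[:50] = True
            aucs.append(roc_auc(scores, labels))
        assert abs(np.mean(aucs) - 0.5) < 0.02

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 8), st.booleans()), min_size=2, max_size=80)
           .filter(lambda xs: any(l for _, l in xs) and any(not l for _, l in xs)))
    def test_midrank_auc_equals_pair_counting_for_any_scores(self, pairs):
        """Property: the rank formulation agrees with explicit concordant-pair
        counting for arbitrary tied integer scores."""
        scores = [s / 8 for s, _ in pairs]
        labels = [l for _, l in pairs]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_pairs(scores, labels), abs=1e-12)

    def test_pr_auc_ordering(self):
        perfect = pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        poor = pr_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert perfect == pytest.approx(1.0)
        assert poor < perfect


@pytest.fixture(scope="module")
def clean_world():
    return make_world(seed=5, p_out=0.0, q=0.0)


class TestLOOCV:
    def test_entity_below_min_genes_rejected(self, clean_world):
        net = filter_network(clean_world.ppi, 0.7)
        with pytest.raises(ValueError):
            loocv_entity(net, clean_world.profiles, "T:0000001", min_genes=10 ** 6)

    def test_masking_excludes_held_out_annotation(self):
        """A positive's score must not use its own held-out annotation: with
        two annotated genes that are mutual neighbors, each held-out gene sees
        only the other as annotated (n_f = 1, tot_f = 1)."""
        net = GeneNetwork.from_edges(
            [("p1", "p2", 1.0), ("p1", "n1", 1.0), ("p2", "n2", 1.0), ("n1", "n2", 1.0)])
        profiles = AnnotationProfiles(
            {"p1": {"E"}, "p2": {"E"}, "n1": {"X"}, "n2": {"X"}})
        roc, _, n_pos = loocv_entity(net, profiles, "E", min_genes=2)
        assert n_pos == 2
        # p1: neighbors {p2, n1}, masked annotated = {p2}: n_f=1, e_f=1*2/4=0.5 -> +0.5
        # negatives n1: neighbors {p1, n2}, annotated {p1,p2}: n_f=1, e_f=2*2/4=1 -> 0
        assert roc == 1.0

    def test_noiseless_planted_modules_near_separable(self, clean_world):
        net = filter_network(clean_world.ppi, 0.0)
        result = evaluate_network(net, clean_world.profiles, min_genes=10)
        assert len(result.per_entity) >= 20
        assert result.mean_roc_auc > 0.9

    def test_fully_randomized_network_is_null(self, clean_world):
        net = filter_network(clean_world.ppi, 0.0)
        rand = fully_randomize(net, seed=123)
        result = evaluate_network(rand, clean_world.profiles, min_genes=10)
        assert len(result.per_entity) >= 30
        assert 0.45 <= result.mean_roc_auc <= 0.55

    def test_single_entity_profile_set(self):
        net = GeneNetwork.from_edges(
            [(f"g{i}", f"g{j}", 1.0) for i in range(12) for j in range(i + 1, 12)])
        mapping = {f"g{i}": {"E"} for i in range(10)}
        mapping.update({"g10": {"X"}, "g11": {"X"}})
        profiles = AnnotationProfiles(mapping)
        result = evaluate_network(net, profiles, min_genes=10)
        assert list(result.per_entity["entity"]) == ["E"]

    def test_all_identical_scores_warn_and_give_half(self):
        # every gene isolated -> all neighborhood scores are 0
        net = GeneNetwork()
        net.graph.add_nodes_from([f"g{i}" for i in range(12)])
        mapping = {f"g{i}": {"E"} for i in range(10)}
        mapping.update({"g10": {"X"}, "g11": {"X"}})
        with pytest.warns(UserWarning, match="identical"):
            roc, _, _ = loocv_entity(net, AnnotationProfiles(mapping), "E", min_genes=10)
        assert roc == 0.5


class TestPredictAndCompare:
    def test_predict_ranks_module_members_first(self, clean_world):
        net = filter_network(clean_world.ppi, 0.0)
        entity = clean_world.module_terms[0][0]  # subtree root of module 0
        annotated = clean_world.profiles.genes_annotated_to(entity)
        ranked = predict_candidates(net, clean_world.profiles, entity, top=5)
        assert all(clean_world.modules[g] == 0 for g in ranked["gene"])
        assert not set(ranked["gene"]) & annotated

    def test_compare_identical_results_zero_difference(self, clean_world):
        net = filter_network(clean_world.ppi, 0.0)
        res = evaluate_network(net, clean_world.profiles, min_genes=10, name="a")
        res2 = evaluate_network(net, clean_world.profiles, min_genes=10, name="b")
        table = compare_networks([res, res2])
        diff = table[("a", "roc_auc")] - table[("b", "roc_auc")]
        assert (diff == 0).all()
        summary = table.attrs["summary"]
        assert summary.loc["a", "mean_roc_auc"] == summary.loc["b", "mean_roc_auc"]

    def test_compare_restricts_to_common_entities(self, clean_world):
        net = filter_network(clean_world.ppi, 0.0)
        res_full = evaluate_network(net, clean_world.profiles, min_genes=10, name="full")
        res_strict = evaluate_network(net, clean_world.profiles, min_genes=18, name="strict")
        table = compare_networks([res_full, res_strict])
        assert 0 < len(res_strict.per_entity) < len(res_full.per_entity)
        assert len(table) == len(res_strict.per_entity)

    def test_dominating_network_has_all_positive_differences(self, clean_world):
        good = filter_network(clean_world.ppi, 0.0)
        null = fully_randomize(good, seed=7)
        res_good = evaluate_network(good, clean_world.profiles, min_genes=10, name="good")
        res_null = evaluate_network(null, clean_world.profiles, min_genes=10, name="null")
        table = compare_networks([res_good, res_null])
        diff = table[("good", "roc_auc")] - table[("null", "roc_auc")]
        assert (diff > 0).all()
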