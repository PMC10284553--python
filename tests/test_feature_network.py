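"""Bipartite construction, projection, connectance and the ERGM."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.special import logit

from conftest import make_relfreq
from ecoweave.feature_network import (
    ErgmModel,
    binarize_article_graph,
    build_bipartite,
    ergm_fit,
    network_summary,
    project,
)


@pytest.fixture()
def small_rf():
    # 4 articles x 3 features, 7 nonzero entries
    return make_relfreq(
        [
            [0.10, 0.30, 0.00],
            [0.20, 0.20, 0.00],
            [0.00, 0.05, 0.40],
            [0.15, 0.00, 0.00],
        ],
        ["complexity", "complexity", "control", "control"],
        columns=["A", "B", "C"],
    )


class TestBipartite:
    def test_one_edge_per_nonzero_entry_with_exact_weights(self, small_rf):
        b = build_bipartite(small_rf)
        assert b.graph.number_of_edges() == 7
        assert b.graph["a0"]["B"]["weight"] == pytest.approx(0.30)
        assert b.group_of("a2") == "control"

    def test_zero_row_rejected(self):
        rf_bad = make_relfreq([[0.0, 0.0], [0.1, 0.1]], ["complexity", "control"])
        with pytest.raises(ValueError):
            build_bipartite(rf_bad)


class TestProjection:
    def test_count_mode_equals_brute_force_cooccurrence(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 6)) * (rng.random((10, 6)) < 0.5)
        X[X.sum(axis=1) == 0, 0] = 0.1
        rf = make_relfreq(X, ["complexity"] * 5 + ["control"] * 5)
        proj = project(build_bipartite(rf), side="feature", weight_mode="count")
        occ = X > 0
        for i, j in itertools.combinations(range(6), 2):
            expected = int((occ[:, i] & occ[:, j]).sum())
            u, v = rf.feature_names[i], rf.feature_names[j]
            if expected == 0:
                assert not proj.graph.has_edge(u, v)
            else:
                assert proj.graph[u][v]["weight"] == expected

    def test_min_sum_weight(self):
        rf = make_relfreq(
            [[0.1, 0.3], [0.2, 0.2]], ["complexity", "control"], columns=["A", "B"]
        )
        proj = project(build_bipartite(rf), side="feature", weight_mode="min_sum")
        assert proj.graph["A"]["B"]["weight"] == pytest.approx(0.1 + 0.2)

    def test_lonely_feature_is_isolated(self, small_rf):
        proj = project(build_bipartite(small_rf), side="feature")
        # C co-occurs with B (article a2) but never with A
        assert proj.graph.has_edge("B", "C")
        assert not proj.graph.has_edge("A", "C")

    def test_article_side_projection(self, small_rf):
        proj = project(build_bipartite(small_rf), side="article")
        assert proj.graph["a0"]["a1"]["weight"] == 2  # share A and B
        assert proj.graph["a0"]["a3"]["weight"] == 1  # share A


class TestNetworkSummary:
    def test_complete_graph_connectance_one(self):
        s = network_summary(nx.complete_graph(5))
        assert s["connectance"] == pytest.approx(1.0)

    def test_formula_23_nodes_250_links(self):
        g = nx.gnm_random_graph(23, 250, seed=1)
        s = network_summary(g)
        assert s["connectance"] == pytest.approx(250 / 253)

    def test_star_strength_and_degree_distribution(self):
        g = nx.star_graph(4)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        s = network_summary(g)
        assert s["strength"][0] == pytest.approx(4.0)
        assert s["degree_distribution"][1] == pytest.approx(4 / 5)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node(0)
        with pytest.raises(ValueError):
            network_summary(g)


def test_binarize_threshold():
    rf = make_relfreq(
        [[0.1, 0.1, 0.0], [0.1, 0.1, 0.1], [0.0, 0.0, 0.1], [0.2, 0.0, 0.0]],
        ["complexity", "complexity", "control", "control"],
    )
    g1 = binarize_article_graph(rf, tau=1)
    g2 = binarize_article_graph(rf, tau=2)
    assert g1.has_edge("a0", "a3") and g1.has_edge("a1", "a2")
    assert g2.has_edge("a0", "a1") and not g2.has_edge("a0", "a3")


def graph_from_probs(rng, n, p_within, p_between, focal_frac=0.5):
    groups = {
        i: ("complexity" if i < int(n * focal_frac) else "control")
        for i in range(n)
    }
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    same = np.array([groups[i] == groups[j] for i, j in zip(iu, ju)])
    p = np.where(same, p_within, p_between)
    ties = rng.random(iu.size) < p
    g.add_edges_from(zip(iu[ties], ju[ties]))
    return g, groups


class TestErgm:
    def test_intercept_only_equals_logit_density(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edges_from([(0, 1), (0, 2), (0, 3)])  # 3 of 6 dyads
        res = ergm_fit(g, groups={i: "a" for i in range(4)}, terms=("edges",))
        assert res.converged
        assert res.params["edges"] == pytest.approx(0.0, abs=1e-8)

    def test_six_node_mle_matches_likelihood_grid_oracle(self):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        # mixed ties within every covariate pattern (no separation)
        g.add_edges_from([(0, 1), (0, 2), (3, 4), (0, 3), (1, 4), (2, 5), (2, 3)])
        groups = {i: ("complexity" if i < 3 else "control") for i in range(6)}
        model = ErgmModel(g, groups=groups)
        res = model.fit()
        assert res.converged

        # brute-force oracle: dyad covariates re-derived independently,
        # coarse-to-fine grid search of the Bernoulli likelihood
        nodes = list(g.nodes)
        rows, y = [], []
        for i, j in itertools.combinations(nodes, 2):
            same = float(groups[i] == groups[j])
            nf = float(groups[i] == "complexity") + float(groups[j] == "complexity")
            rows.append((1.0, same, nf))
            y.append(float(g.has_edge(i, j)))
        X = np.array(rows)
        y = np.array(y)

        def ll(theta):
            eta = X @ theta
            return (y * eta).sum() - np.logaddexp(0, eta).sum()

        center = np.zeros(3)
        width = 8.0
        for _ in range(8):
            axes = [np.linspace(c - width, c + width, 11) for c in center]
            grid = np.array(list(itertools.product(*axes)))
            vals = (grid @ X.T * y).sum(axis=1) - np.logaddexp(
                0, grid @ X.T
            ).sum(axis=1)
            center = grid[np.argmax(vals)]
            width *= 0.2
        assert np.abs(res.params.to_numpy() - center).max() < 1e-4
        # oracle dominance: the Newton optimum beats every grid point
        assert model.loglike(res.params.to_numpy()) >= vals.max() - 1e-12

    def test_planted_homophily_recovered(self):
        rng = np.random.default_rng(123)
        true = logit(0.8) - logit(0.2)
        est, se = [], []
        for _ in range(5):
            g, groups = graph_from_probs(rng, 100, 0.8, 0.2)
            res = ergm_fit(g, groups=groups)
            assert res.converged
            est.append(res.params["nodematch.group"])
            se.append(res.bse["nodematch.group"])
        est = np.array(est)
        assert np.all(np.abs(est - true) < 4 * np.array(se))

    def test_cross_check_against_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        g, groups = graph_from_probs(rng, 30, 0.6, 0.3)
        model = ErgmModel(g, groups=groups)
        res = model.fit()
        glm = sm.GLM(model.y, model.X, family=sm.families.Binomial()).fit()
        assert np.abs(res.params.to_numpy() - glm.params).max() < 1e-6
        assert np.abs(res.bse.to_numpy() - glm.bse).max() < 1e-6

    def test_empty_and_complete_graphs_flagged(self):
        groups = {i: ("a" if i < 3 else "b") for i in range(6)}
        empty = nx.Graph()
        empty.add_nodes_from(range(6))
        r = ergm_fit(empty, groups=groups, terms=("edges",))
        assert not r.converged and "empty or complete" in r.message
        r = ergm_fit(nx.complete_graph(6), groups=groups, terms=("edges",))
        assert not r.converged

    def test_perfect_separation_flagged(self):
        # all within-group ties present, no between-group ties
        g = nx.Graph()
        g.add_nodes_from(range(8))
        for i, j in itertools.combinations(range(4), 2):
            g.add_edge(i, j)
        for i, j in itertools.combinations(range(4, 8), 2):
            g.add_edge(i, j)
        groups = {i: ("a" if i < 4 else "b") for i in range(8)}
        r = ergm_fit(g, groups=groups, focal_group="a",
                     terms=("edges", "nodematch"))
        assert not r.converged
        assert "separation" in r.message or "degenerate" in r.message

    def test_summary_mentions_terms(self):
        rng = np.random.default_rng(2)
        g, groups = graph_from_probs(rng, 20, 0.5, 0.5)
        res = ergm_fit(g, groups=groups, focal_group="complexity")
        text = res.summary()
        assert "nodematch.group" in text and "nodefactor.group.complexity" in text
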