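import numpy as np
import pandas as pd
import pytest

import meegconnet as m
from meegconnet import graph_metrics as gm
from meegconnet.errors import AlignmentError, ParameterError, ValidationError
import _oracles as oracle


def random_er_graph(rng, n=None, weighted=True):
    n = n or int(rng.integers(2, 8))
    p = rng.uniform(0.15, 0.9)
    w = rng.uniform(0.1, 1.0, size=(n, n)) if weighted else np.ones((n, n))
    mask = rng.uniform(size=(n, n)) < p
    adj = np.triu(w * mask, k=1)
    adj = adj + adj.T
    return m.BrainGraph(adj)


class TestThreshold:
    def test_proportional_one_keeps_complete_graph(self, rng):
        w = rng.uniform(0.1, 1, size=(6, 6))
        w = np.triu(w, 1) + np.triu(w, 1).T
        conn = m.ConnectivityMatrix(w, method="mi")
        g = m.threshold_adjacency(conn, "proportional", 1.0)
        assert g.n_edges == 15

    def test_absolute_above_max_empties_graph(self, rng):
        g = random_er_graph(rng, n=6)
        out = m.threshold_adjacency(g.adjacency, "absolute",
                                    g.adjacency.max() + 1)
        assert out.n_edges == 0

    def test_proportional_keeps_exactly_largest(self, rng):
        w = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        vals = rng.permutation(np.linspace(0.1, 1.0, 15))
        w[iu] = vals
        w = w + w.T
        g = m.threshold_adjacency(w, "proportional", 0.2)
        assert g.n_edges == 3
        kept = g.adjacency[iu]
        assert set(kept[kept > 0]) == set(np.sort(vals)[-3:])

    def test_bad_fraction_rejected(self, rng):
        g = random_er_graph(rng)
        for v in (0.0, 1.5, -0.1):
            with pytest.raises(ParameterError):
                m.threshold_adjacency(g.adjacency, "proportional", v)


class TestFixtureValues:
    def test_complete_graph_global_metrics(self, graphs):
        g4 = m.global_metrics(graphs["K4"])
        assert g4.density == 1.0
        assert g4.char_path_length == 1.0
        assert g4.global_efficiency == 1.0
        assert g4.radius == 1.0 and g4.diameter == 1.0

    def test_path_graph_global_metrics(self, graphs):
        p4 = m.global_metrics(graphs["path4"])
        assert p4.density == pytest.approx(0.5)
        assert p4.char_path_length == pytest.approx(10 / 6)
        assert p4.global_efficiency == pytest.approx(13 / 18)
        assert p4.radius == 2 and p4.diameter == 3

    def test_disconnected_graph_infinite_radius(self, graphs):
        gmx = m.global_metrics(graphs["disjoint_edges"])
        assert np.isinf(gmx.radius) and np.isinf(gmx.diameter)
        # disconnected pairs are excluded from the CPL mean
        assert gmx.char_path_length == 1.0

    def test_k4_node_metrics(self, graphs):
        nm = m.node_metrics(graphs["K4"])
        assert (nm["degree"] == 3).all()
        assert (nm["clustering"] == 1.0).all()
        assert (nm["coreness"] == 3).all()
        assert (nm["betweenness"] == 0.0).all()

    def test_path4_betweenness_and_coreness(self, graphs):
        nm = m.node_metrics(graphs["path4"])
        assert list(nm["betweenness"]) == [0, 2, 2, 0]
        assert (nm["coreness"] == 1).all()

    def test_k3_edge_metrics(self, graphs):
        em = m.edge_metrics(graphs["K3"])
        assert (em["edge_betweenness"] == 1.0).all()
        assert (em["neighborhood_overlap"] == 1).all()

    def test_path_edge_overlap_zero(self, graphs):
        em = m.edge_metrics(graphs["path4"])
        mid = em[(em["u"] == "n1") & (em["v"] == "n2")].iloc[0]
        assert mid["neighborhood_overlap"] == 0

    def test_chord_is_a_shortcut(self, graphs):
        em = m.edge_metrics(graphs["cycle5_chord"])
        chord = em[(em["u"] == "n0") & (em["v"] == "n2")].iloc[0]
        assert chord["is_shortcut"] and chord["delta_cpl"] > 0


class TestOracleEquivalence:
    """Every metric equals brute-force enumeration on random small graphs."""

    N_GRAPHS = 60  # the full 200-graph sweep runs in the acceptance suite

    def test_against_brute_force(self, rng):
        for _ in range(self.N_GRAPHS):
            g = random_er_graph(rng)
            check_graph_against_oracle(g)

    def test_permutation_equivariance(self, rng):
        g = random_er_graph(rng, n=7)
        perm = rng.permutation(7)
        gp = m.BrainGraph(g.adjacency[np.ix_(perm, perm)])
        a, b = m.global_metrics(g), m.global_metrics(gp)
        assert vars(a) == vars(b)
        nm = m.node_metrics(g, m.ModulePartition(np.zeros(7, int), 0.0))
        nmp = m.node_metrics(gp, m.ModulePartition(np.zeros(7, int), 0.0))
        for col in ("degree", "clustering", "coreness", "betweenness"):
            np.testing.assert_allclose(
                nm[col].to_numpy()[perm], nmp[col].to_numpy(), atol=1e-9
            )

    def test_edge_addition_monotonicity(self, rng):
        for _ in range(20):
            g = random_er_graph(rng, n=6)
            iu = np.triu_indices(6, 1)
            empty = np.flatnonzero(g.adjacency[iu] == 0)
            if empty.size == 0:
                continue
            pick = empty[int(rng.integers(empty.size))]
            adj = g.adjacency.copy()
            i, j = iu[0][pick], iu[1][pick]
            adj[i, j] = adj[j, i] = 0.5
            g2 = m.BrainGraph(adj)
            a, b = m.global_metrics(g), m.global_metrics(g2)
            assert b.density > a.density
            assert b.global_efficiency >= a.global_efficiency - 1e-12
            if np.isfinite(a.diameter):
                # on an already-connected graph a new edge can only
                # shorten paths; on disconnected graphs newly connected
                # (distant) pairs may legitimately raise the mean
                assert b.char_path_length <= a.char_path_length + 1e-12


def check_graph_against_oracle(g):
    adj = g.adjacency
    gmx = m.global_metrics(g)
    assert gmx.density == pytest.approx(oracle.bf_density(adj))
    cpl, eff = oracle.bf_cpl_efficiency(adj)
    rad, dia = oracle.bf_radius_diameter(adj)
    assert gmx.char_path_length == pytest.approx(cpl)
    assert gmx.global_efficiency == pytest.approx(eff)
    assert gmx.radius == pytest.approx(rad)
    assert gmx.diameter == pytest.approx(dia)

    part = m.detect_modules(g, seed=0)
    nm = m.node_metrics(g, part)
    np.testing.assert_allclose(nm["degree"], (adj > 0).sum(axis=1))
    np.testing.assert_allclose(nm["strength"], adj.sum(axis=1), atol=1e-12)
    np.testing.assert_allclose(nm["clustering"], oracle.bf_clustering(adj),
                               atol=1e-12)
    np.testing.assert_array_equal(nm["coreness"], oracle.bf_coreness(adj))
    np.testing.assert_allclose(nm["betweenness"],
                               oracle.bf_node_betweenness(adj), atol=1e-9)
    np.testing.assert_allclose(
        nm["participation"],
        oracle.bf_participation(adj, part.community_id), atol=1e-12,
    )

    if g.n_edges:
        em = m.edge_metrics(g)
        ebc = oracle.bf_edge_betweenness(adj)
        labels = g.node_labels
        for _, row in em.iterrows():
            i, j = labels.index(row["u"]), labels.index(row["v"])
            e = (min(i, j), max(i, j))
            assert row["edge_betweenness"] == pytest.approx(ebc[e], abs=1e-9)
            assert row["neighborhood_overlap"] == oracle.bf_overlap(adj, i, j)
            d = oracle.bf_delta_cpl(adj, i, j)
            assert row["delta_cpl"] == pytest.approx(d, abs=1e-9)
            assert row["is_shortcut"] == (d > 1e-12)


class TestModules:
    def test_two_cliques_split(self, graphs):
        part = m.detect_modules(graphs["two_cliques"], seed=3)
        assert part.n_communities == 2
        assert len(set(part.community_id[:5])) == 1
        assert len(set(part.community_id[5:])) == 1
        assert part.community_id[0] != part.community_id[5]

    def test_single_clique_one_module(self, graphs):
        assert m.detect_modules(graphs["K4"], seed=0).n_communities == 1

    def test_deterministic_given_seed(self, rng):
        g = random_er_graph(rng, n=7)
        a = m.detect_modules(g, seed=5)
        b = m.detect_modules(g, seed=5)
        np.testing.assert_array_equal(a.community_id, b.community_id)
        assert a.modularity_q == b.modularity_q

    def test_empty_graph_singletons(self):
        g = m.BrainGraph(np.zeros((4, 4)))
        part = m.detect_modules(g, seed=0)
        assert part.n_communities == 4
        assert part.modularity_q == 0.0


class TestRegionalAggregation:
    @pytest.fixture
    def atlas(self):
        return m.ScoutAtlas(
            ["o_l", "o_r", "f_l", "f_r"],
            [[0], [1], [2], [3]],
            np.array([[-1, -3, 0], [1, -3, 0], [-1, 3, 0], [1, 3, 0]], float),
            ["occipital", "occipital", "frontal", "frontal"],
        )

    def test_lobe_level_means(self, atlas):
        nm = pd.DataFrame(
            {"strength": [4.0, 6.0, 1.0, 3.0]},
            index=pd.Index(atlas.roi_labels, name="label"),
        )
        out = m.aggregate_by_region(nm, atlas, level="lobe")
        assert out.loc[("occipital", "L"), "strength"] == 4.0
        assert out.loc[("occipital", "R"), "strength"] == 6.0
        # pooling both hemispheres of a lobe is the mean of its ROIs
        occ = out.xs("occipital", level="lobe")["strength"].mean()
        assert occ == 5.0

    def test_roi_level_is_identity(self, atlas):
        nm = pd.DataFrame({"degree": [1.0, 2, 3, 4]},
                          index=pd.Index(atlas.roi_labels, name="label"))
        out = m.aggregate_by_region(nm, atlas, level="roi")
        pd.testing.assert_frame_equal(out, nm)

    def test_unknown_label_rejected(self, atlas):
        nm = pd.DataFrame({"degree": [1.0]},
                          index=pd.Index(["nope"], name="label"))
        with pytest.raises(AlignmentError, match="nope"):
            m.aggregate_by_region(nm, atlas, level="lobe")


class TestBrainGraphValidation:
    def test_negative_weights_and_loops_rejected(self):
        with pytest.raises(ValidationError):
            m.BrainGraph(np.array([[0, -1], [-1, 0]], float))
        with pytest.raises(ValidationError):
            m.BrainGraph(np.array([[1, 0], [0, 0]], float))

    def test_fixture_counts(self, graphs):
        assert (graphs["K4"].n_nodes, graphs["K4"].n_edges) == (4, 6)
        assert (graphs["two_cliques"].n_nodes,
                graphs["two_cliques"].n_edges) == (10, 21)
        assert np.isinf(m.global_metrics(graphs["disjoint_edges"]).radius)
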