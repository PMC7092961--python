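import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnaet.seqio import InputError, StructResidue, StructureModel, parse_wuss
from rnaet.structmetrics import (
    ContactGraph,
    clustering_z,
    contact_graph_1d,
    contact_graph_2d,
    contact_graph_3d,
    scw,
    scw_moments,
    smoothness,
    z_profile,
)


def _model(points, extra_atoms=None):
    """Structure with one atom per residue at the given coordinates."""
    residues = []
    for i, p in enumerate(points):
        coords = np.atleast_2d(np.asarray(p, dtype=float))
        if extra_atoms and i in extra_atoms:
            coords = np.vstack([coords, extra_atoms[i]])
        residues.append(StructResidue("A", i + 1, "A", coords))
    return StructureModel(residues)


def _graph_from_edges(L, edges):
    A = np.zeros((L, L), dtype=bool)
    for i, j in edges:
        A[i - 1, j - 1] = A[j - 1, i - 1] = True
    return ContactGraph(A, "tertiary")


def path_graph(L):
    return _graph_from_edges(L, [(i, i + 1) for i in range(1, L)])


class TestContactGraphs:
    def test_cutoff_rule(self):
        g = contact_graph_3d(_model([(0, 0, 0), (10, 0, 0), (3.9, 0, 0)]))
        assert g.A[0, 2] and not g.A[0, 1]

    def test_just_over_cutoff_is_no_contact(self):
        g = contact_graph_3d(_model([(0, 0, 0), (10, 0, 0), (4.1, 0, 0)]))
        assert not g.A[0, 2]

    def test_backbone_neighbors_excluded_by_default(self):
        g = contact_graph_3d(_model([(0, 0, 0), (1, 0, 0), (2, 0, 0)]))
        assert not g.A[0, 1] and g.A[0, 2]
        g0 = contact_graph_3d(_model([(0, 0, 0), (1, 0, 0), (2, 0, 0)]),
                              exclude_neighbors=0)
        assert g0.A[0, 1]

    def test_min_heavy_atom_distance_vs_c1p(self):
        # residue 3's second atom reaches residue 1; its first atom does not
        m = _model([(0, 0, 0), (50, 0, 0), (9, 0, 0)],
                   extra_atoms={2: np.array([[3.5, 0.0, 0.0]])})
        assert contact_graph_3d(m, atoms="heavy").A[0, 2]
        assert not contact_graph_3d(m, atoms="c1p").A[0, 2]

    def test_1d_graph_edge_count(self):
        assert contact_graph_1d(4).n_edges == 3
        assert contact_graph_1d(1).n_edges == 0

    def test_2d_graph_pairs_plus_backbone(self):
        g = contact_graph_2d(parse_wuss("((..))"), 6)
        assert g.n_edges == 5 + 2
        assert g.A[0, 5] and g.A[1, 4]

    def test_2d_pair_out_of_range_rejected(self):
        with pytest.raises(InputError):
            contact_graph_2d(parse_wuss("((..))"), 4)


class TestScw:
    def test_path_examples(self):
        g = path_graph(4)
        assert scw({1, 2}, g) == 1
        assert scw(set(), g) == 0
        assert scw({3}, g) == 0
        assert scw({1, 2, 3, 4}, g) == g.n_edges

    def test_counts_only_internal_edges(self):
        g = _graph_from_edges(5, [(1, 2), (2, 3), (1, 4), (4, 5)])
        assert scw({1, 2, 4}, g) == 2


def enumerate_scw_moments(g, k):
    """Exhaustive mean/variance of w over all C(L, k) selections."""
    ws = [scw(set(sel), g)
          for sel in itertools.combinations(range(1, g.L + 1), k)]
    return float(np.mean(ws)), float(np.var(ws))


class TestAnalyticMoments:
    def test_path4_closed_form(self):
        g = path_graph(4)
        mean, var = scw_moments(g, 2)
        assert mean == pytest.approx(0.5)
        assert math.sqrt(var) == pytest.approx(0.5)
        assert clustering_z({1, 2}, g) == pytest.approx(1.0)

    @pytest.mark.parametrize("name,g", [
        ("path6", path_graph(6)),
        ("cycle7", _graph_from_edges(7, [(i, i % 7 + 1) for i in range(1, 8)])),
        ("star5", _graph_from_edges(5, [(1, j) for j in range(2, 6)])),
        ("two_triangles", _graph_from_edges(
            6, [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])),
    ])
    def test_matches_enumeration_on_small_graphs(self, name, g):
        for k in range(2, g.L):
            mean, var = scw_moments(g, k)
            e_mean, e_var = enumerate_scw_moments(g, k)
            assert mean == pytest.approx(e_mean, abs=1e-9), (name, k)
            assert var == pytest.approx(e_var, abs=1e-9), (name, k)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=10, deadline=None)
    def test_matches_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 11))
        A = np.triu(rng.random((L, L)) < 0.35, k=1)
        g = ContactGraph(A | A.T, "tertiary")
        k = int(rng.integers(2, L))
        mean, var = scw_moments(g, k)
        e_mean, e_var = enumerate_scw_moments(g, k)
        assert mean == pytest.approx(e_mean, abs=1e-9)
        assert var == pytest.approx(e_var, abs=1e-9)


class TestClusteringZ:
    def test_degenerate_selections_flagged(self):
        g = path_graph(5)
        assert math.isnan(clustering_z({2}, g))
        assert math.isnan(clustering_z(set(), g))
        assert clustering_z({1, 2, 3, 4, 5}, g) == 0.0  # full universe: no excess

    def test_edgeless_graph_flagged(self):
        g = ContactGraph(np.zeros((4, 4), dtype=bool), "tertiary")
        assert math.isnan(clustering_z({1, 2}, g))

    def test_complete_graph_has_no_variance(self):
        A = ~np.eye(5, dtype=bool)
        g = ContactGraph(A, "tertiary")
        # every k-selection has exactly C(k,2) internal edges: zero excess
        assert clustering_z({1, 2, 3}, g) == 0.0

    def test_permutation_mode_agrees_with_analytic(self):
        rng = np.random.default_rng(42)
        L = 25
        A = np.triu(rng.random((L, L)) < 0.2, k=1)
        g = ContactGraph(A | A.T, "tertiary")
        sel = set(rng.choice(np.arange(1, L + 1), size=8, replace=False).tolist())
        za = clustering_z(sel, g, mode="analytic")
        zp = clustering_z(sel, g, mode="permutation", n_perm=100_000, seed=7)
        assert zp == pytest.approx(za, abs=0.05)

    def test_permutation_mode_requires_seed(self):
        with pytest.raises(InputError):
            clustering_z({1, 2}, path_graph(4), mode="permutation")


class TestZProfile:
    def test_all_tied_ranks_single_valid_bin(self):
        g = path_graph(6)
        prof = z_profile(np.ones(6), g)
        assert prof.bins["valid"].sum() == 1
        assert prof.bins.loc[prof.bins["valid"], "coverage"].iloc[0] == 100.0
        assert prof.mean_0_35 == 0.0  # inherits the full-universe bin

    def test_cumulative_selection_sizes_monotone(self, default_bundle, default_graph):
        from rnaet.optimize import score_alignment
        s = score_alignment(default_bundle.alignment, default_graph)
        prof = z_profile(s.trace.ranks, default_graph)
        assert np.all(np.diff(prof.bins["size"]) >= 0)
        assert prof.bins["size"].iloc[-1] == default_graph.L

    def test_planted_cluster_scores_high(self, default_bundle, default_graph):
        from rnaet.trace import build_upgma, rvet
        aln = default_bundle.alignment
        ranks = rvet(aln, build_upgma(aln)).ranks
        prof = z_profile(ranks, default_graph)
        assert prof.mean_0_35 >= 2.0

    def test_random_ranks_are_calibrated(self, default_graph):
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            ranks = rng.permutation(default_graph.L).astype(float) + 1
            if abs(z_profile(ranks, default_graph).mean_0_35) <= 2.0:
                hits += 1
        assert hits >= 95

    def test_scw_monotone_over_cumulative_bins(self, default_graph):
        rng = np.random.default_rng(5)
        ranks = rng.permutation(default_graph.L).astype(float)
        prof = z_profile(ranks, default_graph)
        w = prof.bins["w"].dropna()
        assert np.all(np.diff(w) >= 0)


class TestSmoothness:
    def test_path_examples(self):
        g = path_graph(3)
        assert smoothness(np.array([1.0, 1.0, 2.0]), g) == 1.0
        assert smoothness(np.array([1.0, 2.0, 1.0]), g) == 2.0
        assert smoothness(np.array([7.0, 7.0, 7.0]), g) == 0.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance_and_quadratic_scaling(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 12))
        A = np.triu(rng.random((L, L)) < 0.4, k=1)
        g = ContactGraph(A | A.T, "tertiary")
        x = rng.random(L) * 10
        base = smoothness(x, g)
        assert smoothness(x + 37.0, g) == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert smoothness(3.0 * x, g) == pytest.approx(9.0 * base, rel=1e-9)
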