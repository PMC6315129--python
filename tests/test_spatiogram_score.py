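import numpy as np
import pytest

import faceasym as fa
from faceasym.asymmetry_features import FeatureHeatMap, build_normal_model
from faceasym.correspondence import AverageMesh
from faceasym.spatiogram_score import augment_histogram, vertex_adjacency

from _bruteforce import bf_adjacency, bf_components, bf_histogram, bf_score


def path_graph_adjacency(n):
    """Adjacency of a 1D chain 0-1-2-...-(n-1) as a sparse matrix."""
    import scipy.sparse as sp
    i = np.arange(n - 1)
    a = sp.coo_matrix((np.ones(n - 1), (i, i + 1)), shape=(n, n))
    return (a + a.T).tocsr()


class TestBuildHistogram:
    def test_equal_bins_on_known_values(self):
        counts, members = fa.build_histogram(np.array([0, 45, 90, 135.0]),
                                             np.linspace(0, 180, 5))
        np.testing.assert_array_equal(counts, [1, 1, 1, 1])
        assert [list(m) for m in members] == [[0], [1], [2], [3]]

    def test_all_zero_map_in_first_bin(self):
        counts, _ = fa.build_histogram(np.zeros(17), np.linspace(0, 180, 26))
        assert counts[0] == 17 and counts.sum() == 17

    def test_last_bin_closed(self):
        counts, _ = fa.build_histogram(np.array([180.0]), np.linspace(0, 180, 26))
        assert counts[-1] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fa.build_histogram(np.array([181.0]), np.linspace(0, 180, 26))

    def test_matches_bruteforce_binning(self, rng):
        values = rng.uniform(0, 180, 500)
        edges = np.linspace(0, 180, 26)
        counts, members = fa.build_histogram(values, edges)
        bcounts, bmembers = bf_histogram(values.tolist(), edges.tolist())
        np.testing.assert_array_equal(counts, bcounts)
        for m, bm in zip(members, bmembers):
            np.testing.assert_array_equal(m, bm)


class TestCoherentRegions:
    def test_sizes_split_by_tau(self):
        adj = path_graph_adjacency(100)
        # points 0..24 form a 25-chain; 40..44 a 5-chain
        pts = np.r_[np.arange(25), np.arange(40, 45)]
        regions, incoherent = fa.coherent_regions(pts, adj, tau=20)
        assert len(regions) == 1 and len(regions[0]) == 25
        np.testing.assert_array_equal(incoherent, np.arange(40, 45))

    def test_single_component_above_tau(self):
        regions, inc = fa.coherent_regions(np.arange(30), path_graph_adjacency(30), tau=20)
        assert len(regions) == 1 and len(regions[0]) == 30 and len(inc) == 0

    def test_isolated_vertices_all_incoherent(self):
        import scipy.sparse as sp
        adj = sp.csr_matrix((30, 30))
        regions, inc = fa.coherent_regions(np.arange(30), adj, tau=20)
        assert regions == [] and len(inc) == 30

    def test_empty_set_is_empty_output(self):
        regions, inc = fa.coherent_regions(np.array([], dtype=int),
                                           path_graph_adjacency(10), tau=5)
        assert regions == [] and len(inc) == 0

    def test_matches_bfs_oracle_on_mesh(self, template30, rng):
        mesh, _ = template30
        adj = vertex_adjacency(mesh)
        pts = rng.choice(mesh.n_vertices, size=400, replace=False)
        regions, incoherent = fa.coherent_regions(pts, adj, tau=5)
        bf = bf_components(pts, bf_adjacency(mesh.faces.tolist()))
        expected_regions = sorted([c for c in bf if len(c) >= 5])
        got = sorted([r.tolist() for r in regions])
        assert got == expected_regions
        expected_inc = sorted(x for c in bf if len(c) < 5 for x in c)
        assert incoherent.tolist() == expected_inc


class TestAugmentedHistogram:
    def test_constant_map_single_whole_mesh_region(self, plane_mesh):
        h = augment_histogram(np.zeros(plane_mesh.n_vertices), plane_mesh,
                              np.linspace(0, 1, 5), tau=20)
        assert h.counts[0] == plane_mesh.n_vertices
        assert len(h.regions[0]) == 1 and len(h.regions[0][0]) == plane_mesh.n_vertices

    def test_two_disjoint_patches_give_two_regions(self, template30):
        mesh, lm = template30
        values = np.zeros(mesh.n_vertices)
        for name in ("cheilion_l", "cheilion_r"):
            near = np.linalg.norm(mesh.vertices - lm.points[name], axis=1) < 10
            values[near] = 0.9
        h = augment_histogram(values, mesh, np.array([0, 0.5, 1.0]), tau=20)
        assert len(h.regions[1]) == 2

    def test_invariants_on_random_maps(self, template30, rng):
        mesh, _ = template30
        values = rng.uniform(0, 180, mesh.n_vertices)
        h = augment_histogram(values, mesh, np.linspace(0, 180, 26), tau=10)
        assert h.counts.sum() == mesh.n_vertices
        for b in range(h.n_bins):
            sizes = [len(r) for r in h.regions[b]]
            assert all(s >= 10 for s in sizes)
            union = np.concatenate([*h.regions[b], h.incoherent[b]]) if \
                (h.regions[b] or len(h.incoherent[b])) else np.array([])
            assert len(union) == h.counts[b]
            assert len(np.unique(union)) == len(union)  # disjoint


class TestDistances:
    def test_psi_zero_for_identical_maps(self, rng):
        m = rng.uniform(0, 10, 50)
        regions = [np.arange(0, 25), np.arange(30, 50)]
        assert fa.spatial_weight(regions, m, m, np.ones(50)) == 0.0

    def test_psi_two_point_region_mean(self):
        m_subj = np.array([1.0, 3.0])
        m_ref = np.zeros(2)
        sigma = np.ones(2)
        assert fa.spatial_weight([np.array([0, 1])], m_subj, m_ref, sigma) == pytest.approx(2.0)

    def test_directed_zero_for_identical_maps(self, plane_mesh, rng):
        vals = rng.uniform(0, 1, plane_mesh.n_vertices)
        edges = np.linspace(0, 1, 11)
        h = augment_histogram(vals, plane_mesh, edges, tau=3)
        d, psi = fa.directed_distance(h, h, vals, vals, np.ones(len(vals)))
        assert d == 0.0 and np.all(psi == 0)

    def test_disjoint_supports_sum_psi(self, plane_mesh):
        # all mass in different bins: Bhattacharyya factor is 1 per bin
        n = plane_mesh.n_vertices
        lo, hi = np.full(n, 0.1), np.full(n, 0.9)
        edges = np.array([0, 0.5, 1.0])
        h_lo = augment_histogram(lo, plane_mesh, edges, tau=3)
        h_hi = augment_histogram(hi, plane_mesh, edges, tau=3)
        sigma = np.ones(n)
        d, psi = fa.directed_distance(h_lo, h_hi, lo, hi, sigma)
        assert d == pytest.approx(psi.sum())
        assert d == pytest.approx(0.8)  # one coherent region, error 0.8 sigma

    def test_symmetric_distance_is_symmetric(self, template30, rng):
        mesh, _ = template30
        a = rng.uniform(0, 180, mesh.n_vertices)
        b = rng.uniform(0, 180, mesh.n_vertices)
        sigma = rng.uniform(0.5, 2, mesh.n_vertices)
        edges = np.linspace(0, 180, 26)
        adj = vertex_adjacency(mesh)
        ha = augment_histogram(a, adj, edges, tau=10)
        hb = augment_histogram(b, adj, edges, tau=10)
        r1, _, _ = fa.symmetric_distance(ha, hb, a, b, sigma)
        r2, _, _ = fa.symmetric_distance(hb, ha, b, a, sigma)
        assert abs(r1 - r2) < 1e-12
        d_ab, _ = fa.directed_distance(ha, hb, a, b, sigma)
        d_ba, _ = fa.directed_distance(hb, ha, b, a, sigma)
        assert r1 == pytest.approx(0.5 * (d_ab + d_ba), abs=1e-12)

    def test_sigma_scaling_divides_score(self, plane_mesh, rng):
        n = plane_mesh.n_vertices
        a, b = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        sigma = rng.uniform(0.5, 2, n)
        edges = np.linspace(0, 1, 11)
        ha = augment_histogram(a, plane_mesh, edges, tau=3)
        hb = augment_histogram(b, plane_mesh, edges, tau=3)
        r1, _, _ = fa.symmetric_distance(ha, hb, a, b, sigma)
        r3, _, _ = fa.symmetric_distance(ha, hb, a, b, 3.0 * sigma)
        assert r3 == pytest.approx(r1 / 3.0, rel=1e-12)

    def test_mismatched_edges_rejected(self, plane_mesh, rng):
        n = plane_mesh.n_vertices
        a = rng.uniform(0, 1, n)
        h1 = augment_histogram(a, plane_mesh, np.linspace(0, 1, 11), tau=3)
        h2 = augment_histogram(a, plane_mesh, np.linspace(0, 1, 6), tau=3)
        with pytest.raises(ValueError, match="bin edges"):
            fa.directed_distance(h1, h2, a, a, np.ones(n))

    def test_minmax_variant_available(self, plane_mesh, rng):
        n = plane_mesh.n_vertices
        a, b = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        edges = np.linspace(0, 1, 11)
        ha = augment_histogram(a, plane_mesh, edges, tau=3)
        hb = augment_histogram(b, plane_mesh, edges, tau=3)
        d_b, _ = fa.directed_distance(ha, hb, a, b, np.ones(n), variant="bhattacharyya")
        d_m, _ = fa.directed_distance(ha, hb, a, b, np.ones(n), variant="minmax")
        assert d_b >= 0 and d_m >= 0 and d_m != d_b
        with pytest.raises(ValueError, match="variant"):
            fa.directed_distance(ha, hb, a, b, np.ones(n), variant="nope")


class TestScoreSubject:
    def _model(self, mesh, data):
        maps = [FeatureHeatMap("deformation_magnitude", row, str(i))
                for i, row in enumerate(data)]
        return build_normal_model(maps, AverageMesh(mesh, []))

    def test_subject_equal_to_model_mean_scores_zero(self, plane_mesh, rng):
        data = rng.uniform(0, 2, size=(10, plane_mesh.n_vertices))
        model = self._model(plane_mesh, data)
        hm = FeatureHeatMap("deformation_magnitude",
                            model.mean["deformation_magnitude"], "avg")
        assert fa.score_subject(hm, model, tau=3).score == 0.0

    def test_score_matches_bruteforce_composition(self, plane_mesh, rng):
        # whole pipeline of the similarity metric vs an independent oracle
        data = rng.uniform(0, 2, size=(8, plane_mesh.n_vertices))
        model = self._model(plane_mesh, data)
        subject = FeatureHeatMap("deformation_magnitude", data[0], "s0")
        got = fa.score_subject(subject, model, tau=4).score
        expected = bf_score(data[0].tolist(),
                            model.mean["deformation_magnitude"].tolist(),
                            model.sd["deformation_magnitude"].tolist(),
                            plane_mesh.faces.tolist(),
                            model.bin_edges["deformation_magnitude"].tolist(), 4)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_point_count_mismatch_rejected(self, plane_mesh, rng):
        data = rng.uniform(0, 2, size=(4, plane_mesh.n_vertices))
        model = self._model(plane_mesh, data)
        bad = FeatureHeatMap("deformation_magnitude", np.zeros(7), "s")
        with pytest.raises(ValueError, match="points"):
            fa.score_subject(bad, model)
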