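"""Covariate-constrained manifold learning: geometry and contracts."""

import numpy as np
import pytest

from netkappa import CCML, centroid_distance_test, geodesic_distances, loo_centroid_stability
from netkappa.embedding import _classical_mds, check_feature_matrix, stress_of


@pytest.fixture
def two_groups(rng):
    """Two feature clouds whose covariate separates along group identity."""
    n = 12
    a = rng.normal(0, 0.5, (n, 6)) + np.array([0.8, 0, 0, 0, 0, 0])
    b = rng.normal(0, 0.5, (n, 6)) - np.array([0.8, 0, 0, 0, 0, 0])
    x = np.vstack([a, b])
    cov = np.concatenate([rng.normal(-0.6, 0.08, n), rng.normal(-0.2, 0.08, n)])
    labels = np.array(["TSD"] * n + ["CSR"] * n)
    return x, cov, labels


class TestGeodesicDistances:
    def test_collinear_points_equal_euclidean(self):
        x = np.linspace(0, 5, 12)[:, None]
        d, k = geodesic_distances(np.hstack([x, np.zeros_like(x)]), k=2)
        expected = np.abs(x - x.T)
        np.testing.assert_allclose(d, expected, atol=1e-10)

    def test_complete_graph_equals_euclidean(self, rng):
        x = rng.normal(0, 1, (10, 4))
        d, k = geodesic_distances(x, k=9)
        eu = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        np.testing.assert_allclose(d, eu, atol=1e-10)

    def test_circle_geodesic_tracks_arc_length(self):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        x = np.column_stack([np.cos(theta), np.sin(theta)])
        d, _ = geodesic_distances(x, k=2)
        arc = np.minimum(np.abs(theta - theta[25]), 2 * np.pi - np.abs(theta - theta[25]))
        chord = np.linalg.norm(x - x[25], axis=1)
        far = arc > np.pi / 2
        assert np.all(d[25, far] > chord[far])
        np.testing.assert_allclose(d[25], arc, rtol=0.05)

    def test_metric_properties(self, rng):
        x = rng.normal(0, 1, (15, 5))
        d, _ = geodesic_distances(x, k=4)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        # triangle inequality on a sample of triples
        for i, j, l in [(0, 3, 7), (2, 9, 14), (1, 5, 10)]:
            assert d[i, j] <= d[i, l] + d[l, j] + 1e-10

    def test_disconnection_escalates_k(self):
        x = np.vstack([np.zeros((5, 2)), 100 + np.zeros((5, 2))])
        x += np.arange(10)[:, None] * 0.01
        with pytest.warns(UserWarning, match="escalating"):
            _, k = geodesic_distances(x, k=1)
        assert k > 1


class TestCCMLFit:
    def test_first_coordinate_exactly_alpha_kappa(self, two_groups):
        x, cov, _ = two_groups
        m = CCML(n_neighbors=5).fit(x, cov)
        np.testing.assert_array_equal(m.embedding_[:, 0], m.alpha_ * cov)

    def test_stress_monotone_over_iterations(self, two_groups):
        x, cov, _ = two_groups
        m = CCML(n_neighbors=5).fit(x, cov)
        trace = np.array(m._trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_matches_classical_isomap_when_covariate_is_first_coordinate(self, rng):
        t = rng.uniform(0, 3, 40)
        h = rng.uniform(0, 1, 40)
        x = np.column_stack([np.cos(t) * t, np.sin(t) * t, h]) @ rng.normal(0, 1, (3, 8))
        d_geo, _ = geodesic_distances(x, 6)
        iso = _classical_mds(d_geo, 2)
        m = CCML(n_neighbors=6).fit(x, iso[:, 0] * 2.7)
        assert m.stress_ <= 1.05 * stress_of(iso, d_geo)
        assert m.alpha_ == pytest.approx(1 / 2.7, rel=0.1)

    def test_group_ordering_follows_covariate(self, two_groups):
        x, cov, labels = two_groups
        m = CCML(n_neighbors=5).fit(x, cov)
        c0 = m.embedding_[:, 0] * np.sign(m.alpha_)  # orient along kappa
        assert np.mean(c0[labels == "TSD"]) < np.mean(c0[labels == "CSR"])

    def test_constant_covariate_falls_back_unconstrained(self, two_groups):
        x, _, _ = two_groups
        with pytest.warns(UserWarning, match="constant"):
            m = CCML(n_neighbors=5).fit(x, np.full(len(x), -0.4))
        assert np.isnan(m.alpha_)
        assert m.embedding_.shape == (len(x), 2)

    def test_degenerate_feature_columns_refused(self, rng):
        x = rng.normal(0, 1, (10, 5))
        x[:, 2] = 0.0
        with pytest.raises(ValueError, match="constant zero"):
            check_feature_matrix(x)
        assert check_feature_matrix(x, allow_degenerate=True).shape == x.shape


class TestCentroidDistance:
    def test_separated_clouds_minimum_p(self, rng):
        emb = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(8, 0.3, (10, 2))])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        r = centroid_distance_test(emb, labels, n_perm=999, seed=0)
        # only a relabelling equal to the true partition (or its mirror)
        # can tie the observed distance, so p sits at the attainable floor
        assert r.p_two_tailed <= 0.005

    def test_single_cloud_uniform_ish_p(self, rng):
        ps = []
        for s in range(40):
            local = np.random.default_rng(s)
            emb = local.normal(0, 1, (20, 2))
            labels = np.array(["a"] * 10 + ["b"] * 10)
            ps.append(centroid_distance_test(emb, labels, n_perm=199, seed=s).p_two_tailed)
        assert 0.25 < np.mean(ps) < 0.75

    def test_group_requirements(self, rng):
        emb = rng.normal(0, 1, (6, 2))
        with pytest.raises(ValueError, match="exactly 2"):
            centroid_distance_test(emb, np.array(["a", "b", "c"] * 2), n_perm=100, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            centroid_distance_test(emb, np.array(["a"] * 5 + ["b"]), n_perm=100, seed=0)


class TestLeaveOneOut:
    def test_stable_groups_fixed_embedding(self, two_groups):
        x, cov, labels = two_groups
        m = CCML(n_neighbors=5).fit(x, cov)
        full = centroid_distance_test(m.embedding_, labels, n_perm=199, seed=0).observed
        loo = loo_centroid_stability(
            x, cov, labels, mode="fixed_embedding", ccml_kwargs={"n_neighbors": 5}
        )
        assert len(loo) == len(x)
        assert np.all(np.abs(loo["centroid_distance"] - full) / full < 0.15)

    def test_outlier_removal_shifts_most(self, two_groups):
        x, cov, labels = two_groups
        x = x.copy()
        x[0] = 40.0  # gross outlier in group TSD
        cov = cov.copy()
        cov[0] = -3.0
        loo = loo_centroid_stability(
            x, cov, labels, mode="fixed_embedding", ccml_kwargs={"n_neighbors": 5}
        )
        full_like = np.median(loo["centroid_distance"])
        shifts = np.abs(loo["centroid_distance"] - full_like)
        assert shifts.idxmax() == 0

    def test_refit_mode_runs_per_record(self, two_groups):
        x, cov, labels = two_groups
        loo = loo_centroid_stability(
            x, cov, labels, mode="refit", ccml_kwargs={"n_neighbors": 5, "maxiter": 50}
        )
        assert len(loo) == len(x)
        assert (loo["centroid_distance"] > 0).all()
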