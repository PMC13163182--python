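"""Synthetic cohort generation and disruption implanting."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netkappa import (
    CohortSpec,
    ParameterizationError,
    RegionalTimeSeriesSet,
    generate_cohort,
    generate_graph_cohort,
    implant_disruption,
    kappa_within,
    wavelet_correlation_matrix,
)
from netkappa.cohort import _subject_correlation


class TestCohortSpec:
    def test_defaults_mirror_study_design(self):
        spec = CohortSpec()
        assert spec.n_subjects == 28
        assert spec.conditions == ("RW", "TSD", "CSR")
        assert spec.n_regions == 89
        assert spec.n_volumes == 384
        assert spec.tr_seconds == 1.25
        assert spec.kappa_targets["RW"] == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            CohortSpec(n_regions=3)
        with pytest.raises(ValueError):
            CohortSpec(temporal_ar=1.0)
        with pytest.raises(ValueError, match="reference"):
            CohortSpec(kappa_targets={"RW": -0.2})

    def test_non_positive_definite_levels_rejected(self):
        with pytest.raises(ParameterizationError):
            CohortSpec(base_connectivity=(0.2, 0.9, 0.2))


class TestGenerateCohort:
    def test_cardinality_84_scans_default_shape(self):
        # full design: 28 subjects x 3 conditions = 84 scan records; use a
        # reduced spec here and assert the product rule
        spec = CohortSpec(n_subjects=4, n_regions=20, n_volumes=96, edge_budget=40, seed=0)
        out = generate_cohort(spec)
        assert len(out) == 4 * 3
        assert all(ts.values.shape == (20, 96) for ts in out)

    def test_seed_determinism_bitwise(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        for x, y in zip(a, b):
            assert x.subject_id == y.subject_id and x.condition == y.condition
            np.testing.assert_array_equal(x.values, y.values)

    def test_null_targets_reuse_reference_covariance(self):
        # kappa targets all zero: each condition simulates from the identical
        # covariance, so wavelet correlations of different conditions agree
        # up to sampling noise
        spec = CohortSpec(
            n_subjects=2, n_regions=20, n_volumes=384, edge_budget=40,
            kappa_targets={"RW": 0, "TSD": 0, "CSR": 0}, seed=3,
        )
        out = {(t.subject_id, t.condition): t for t in generate_cohort(spec)}
        r1 = wavelet_correlation_matrix(out[("sub-01", "RW")], 3).values
        r2 = wavelet_correlation_matrix(out[("sub-01", "TSD")], 3).values
        assert np.corrcoef(r1.ravel(), r2.ravel())[0, 1] > 0.8

    def test_hubs_have_elevated_degree(self, small_spec):
        from netkappa.graphs import build_graph

        out = [t for t in generate_cohort(small_spec) if t.condition == "RW"]
        n_hubs = small_spec.n_hubs
        for ts in out:
            cm = wavelet_correlation_matrix(ts, 3)
            g = build_graph(cm, small_spec.edge_budget)
            deg = np.array([g.graph.degree[r] for r in ts.region_ids])
            assert deg[:n_hubs].mean() > 1.5 * deg[n_hubs:].mean()

    def test_spectral_sanity_converges_with_length(self):
        # temporal_ar = 0: scale-3 wavelet correlation approaches the
        # generating correlation as the series lengthens
        errs = {}
        for t in (128, 512):
            spec = CohortSpec(
                n_subjects=2, n_regions=15, n_volumes=t, edge_budget=30,
                temporal_ar=0.0, seed=11,
            )
            from netkappa.cohort import (
                _as_cm, _graph_based_correlation, _simulate_series, _subject_streams,
            )
            from netkappa.graphs import build_graph as bg

            ss = _subject_streams(spec)[0].spawn(3)
            r_raw = _subject_correlation(spec, np.random.default_rng(ss[0]))
            a = nx.to_numpy_array(
                bg(_as_cm(r_raw, spec.region_ids), spec.edge_budget).graph,
                nodelist=spec.region_ids,
            )
            r_true = _graph_based_correlation(a, np.sqrt(np.abs(r_raw).sum(1)))
            x = _simulate_series(r_true, spec, np.random.default_rng(ss[1]))
            ts = RegionalTimeSeriesSet("s", "c", x, spec.region_ids, spec.tr_seconds)
            cm = wavelet_correlation_matrix(ts, 3)
            errs[t] = np.linalg.norm(cm.values - r_true)
        assert errs[512] < errs[128]


class TestImplantDisruption:
    @pytest.fixture
    def hub_degrees(self, rng):
        deg = np.concatenate([rng.integers(18, 30, 13), rng.integers(2, 10, 76)])
        excess = deg.sum() - 800
        deg[-1] -= excess % 2  # make the sum even and = 2E realizable
        return pd.Series(deg.astype(float), index=[f"R{i:03d}" for i in range(89)])

    def test_zero_target_identity(self, hub_degrees):
        total = int(hub_degrees.sum() // 2)
        dp, g = implant_disruption(hub_degrees, 0.0, total, seed=0)
        fit = kappa_within(hub_degrees, pd.Series(np.asarray(dp, float), index=hub_degrees.index))
        assert abs(fit.kappa) <= 0.02
        assert g.number_of_edges() == total

    def test_realized_graph_matches_degree_sequence(self, hub_degrees):
        dp, g = implant_disruption(hub_degrees, -0.4, 400, seed=1)
        realized = np.array([g.degree[i] for i in hub_degrees.index])
        np.testing.assert_array_equal(realized, np.asarray(dp))
        assert g.number_of_edges() == 400

    @pytest.mark.parametrize("target", [-0.8, -0.5, -0.2])
    def test_slope_recovery_over_seeds(self, hub_degrees, target):
        ks = []
        for seed in range(20):
            dp, _ = implant_disruption(hub_degrees, target, 400, seed=seed)
            ks.append(
                kappa_within(
                    hub_degrees, pd.Series(np.asarray(dp, float), index=hub_degrees.index)
                ).kappa
            )
        assert np.mean(ks) == pytest.approx(target, abs=0.1)

    def test_out_of_range_target_rejected(self, hub_degrees):
        with pytest.raises(ValueError, match="kappa_target"):
            implant_disruption(hub_degrees, 0.9, 400)


class TestGenerateGraphCohort:
    def test_cardinality_and_determinism(self, small_spec):
        a = generate_graph_cohort(small_spec, realize=False)
        b = generate_graph_cohort(small_spec, realize=False)
        assert len(a) == small_spec.n_subjects * 3
        for key in a:
            pd.testing.assert_series_equal(a[key], b[key])

    def test_realized_graphs_have_budgeted_edges(self, small_spec):
        gc = generate_graph_cohort(small_spec)
        for g in gc.values():
            assert g.number_of_edges() == small_spec.edge_budget

    def test_degree_sum_preserved_under_jitter(self, small_spec):
        gc = generate_graph_cohort(small_spec, realize=False)
        for s in gc.values():
            assert int(s.sum()) == 2 * small_spec.edge_budget
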