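"""Freedman-Diaconis binning and histogram distance metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segscore import (
    PerturbationSpec,
    SceneSpec,
    build_histogram_pair,
    evaluate_feature_level,
    fd_bin_edges,
    generate_scene,
    histogram_distance,
    perturb,
)
from segscore.feature_eval import (
    DISTRIBUTION_METRIC_NAMES,
    DIVERGENCE_METRIC_NAMES,
    HistogramPair,
)

CDF_METRICS = ("kolmogorov_smirnov", "match_distance", "cramer_von_mises", "wasserstein")

#: metrics defined as sums over bins (or over the CDF), hence invariant to
#: padding both histograms with empty bins; per-bin *mean/median* error
#: metrics are bin-count dependent by definition and excluded
SUM_BASED_METRICS = (
    "l1", "l2", "l_inf", "histogram_intersection", "chi_square", "bhattacharyya",
    "canberra", "kl_divergence", "js_distance", "psi", "hellinger",
    "total_variation",
) + CDF_METRICS


def pair(p, q, edges=None):
    p, q = np.asarray(p, float), np.asarray(q, float)
    if edges is None:
        edges = np.arange(len(p) + 1, dtype=float)
    return HistogramPair(np.asarray(edges, float), p, q)


class TestFdBinEdges:
    def test_all_equal_values_give_single_unit_bin(self):
        assert fd_bin_edges([4.0, 4.0], [4.0]).tolist() == [3.5, 4.5]

    def test_uniform_hundred_integers_give_five_bins(self):
        # pooled IQR = 49.5 -> h = 99 * 100^(-1/3) ~ 21.3 -> ceil(99/21.3) = 5
        edges = fd_bin_edges(np.arange(100.0), [])
        assert len(edges) - 1 == 5

    def test_zero_iqr_with_range_falls_back_to_sturges(self):
        values = [1.0] * 14 + [9.0]  # IQR 0, range 8, n=15 -> ceil(log2 15)+1 = 5
        edges = fd_bin_edges(values, [])
        assert len(edges) - 1 == 5

    def test_both_samples_empty_is_undefined(self):
        assert fd_bin_edges([], []) is None


class TestBuildHistogramPair:
    def test_identical_samples_give_identical_histograms(self):
        h = build_histogram_pair([1, 2, 2, 5], [1, 2, 2, 5])
        assert np.array_equal(h.p, h.q)

    def test_counting_on_given_edges(self):
        h = build_histogram_pair([1, 1, 1], [2, 2, 2], edges=[0.5, 1.5, 2.5])
        assert h.p.tolist() == [1.0, 0.0]
        assert h.q.tolist() == [0.0, 1.0]

    def test_rightmost_edge_inclusive(self):
        h = build_histogram_pair([1, 2, 2, 3], [1, 3], edges=[1.0, 2.0, 3.0])
        assert h.p.tolist() == [0.25, 0.75]  # 3.0 falls in the last bin

    def test_empty_side_is_undefined(self):
        assert build_histogram_pair([], [1.0, 2.0]) is None


class TestDistances:
    def test_identical_histograms_score_perfect(self):
        h = build_histogram_pair([1, 2, 2, 5, 8], [1, 2, 2, 5, 8])
        assert histogram_distance(h, "histogram_intersection") == 1.0
        for name in DIVERGENCE_METRIC_NAMES:
            assert histogram_distance(h, name) == 0.0, name

    def test_disjoint_point_masses_closed_forms(self):
        h = pair([1, 0], [0, 1])
        assert histogram_distance(h, "histogram_intersection") == 0.0
        assert histogram_distance(h, "l1") == 2.0
        assert histogram_distance(h, "l_inf") == 1.0
        assert histogram_distance(h, "js_distance") == pytest.approx(math.sqrt(math.log(2)))

    def test_wasserstein_one_bin_shift_of_split_mass(self):
        h = pair([0.5, 0.5, 0.0], [0.0, 0.5, 0.5])
        assert histogram_distance(h, "wasserstein") == pytest.approx(1.0)

    def test_wasserstein_equals_match_distance_on_unit_bins(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            h = pair(p, q)
            assert histogram_distance(h, "wasserstein") == pytest.approx(
                histogram_distance(h, "match_distance"), abs=1e-12
            )

    def test_js_symmetric_kl_asymmetric(self):
        p, q = [0.8, 0.15, 0.05], [0.2, 0.3, 0.5]
        kl_pq = histogram_distance(pair(p, q), "kl_divergence")
        kl_qp = histogram_distance(pair(q, p), "kl_divergence")
        assert kl_pq != pytest.approx(kl_qp)
        assert histogram_distance(pair(p, q), "js_distance") == pytest.approx(
            histogram_distance(pair(q, p), "js_distance")
        )

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            histogram_distance(pair([1, 0], [0, 1]), "nope")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_cdf_metrics_match_cumulative_sum_oracle(self, seed):
        """Each CDF-based distance equals an explicit running-sum oracle on
        random 10-bin pairs with non-uniform edges."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(10))
        q = rng.dirichlet(np.ones(10))
        edges = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 2.0, 10))])
        h = pair(p, q, edges)
        # oracle: python-loop running sums
        cp = cq = 0.0
        ks = match = cvm = wass = 0.0
        for i in range(10):
            cp += p[i]
            cq += q[i]
            d = abs(cp - cq)
            ks = max(ks, d)
            match += d
            cvm += (cp - cq) ** 2
            wass += d * (edges[i + 1] - edges[i])
        assert histogram_distance(h, "kolmogorov_smirnov") == pytest.approx(ks, abs=1e-9)
        assert histogram_distance(h, "match_distance") == pytest.approx(match, abs=1e-9)
        assert histogram_distance(h, "cramer_von_mises") == pytest.approx(cvm, abs=1e-9)
        assert histogram_distance(h, "wasserstein") == pytest.approx(wass, abs=1e-9)

    @pytest.mark.parametrize("name", SUM_BASED_METRICS)
    def test_sum_based_metrics_ignore_padding_bins(self, name):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        h = pair(p, q, edges=[0, 1, 2, 3, 4])
        padded = pair(
            np.concatenate([[0.0], p, [0.0]]),
            np.concatenate([[0.0], q, [0.0]]),
            edges=[-1, 0, 1, 2, 3, 4, 5],
        )
        assert histogram_distance(h, name) == pytest.approx(
            histogram_distance(padded, name), abs=1e-12
        )

    def test_intersection_bounded_and_registry_complete(self):
        assert len(DISTRIBUTION_METRIC_NAMES) == 38
        rng = np.random.default_rng(9)
        for _ in range(50):
            h = pair(rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5)))
            v = histogram_distance(h, "histogram_intersection")
            assert 0.0 <= v <= 1.0


class TestEvaluateFeatureLevel:
    def test_identical_pair_perfect_across_all_features(self, scene):
        labels, intensity = scene
        rows = evaluate_feature_level(labels, labels, intensity)
        for rec in rows:
            if rec["metric"] == "histogram_intersection":
                assert rec["value"] == 1.0
            if rec["metric"] in DIVERGENCE_METRIC_NAMES:
                assert rec["value"] == 0.0

    def test_dilated_prediction_shifts_area_distribution(self):
        labels, _ = generate_scene(SceneSpec(seed=13, n_regions=10))
        dilated = perturb(labels, PerturbationSpec("dilate", 1))
        rows = evaluate_feature_level(
            labels, dilated, feature_names=("area",), metric_names=("histogram_intersection",)
        )
        assert rows[0]["value"] < 1.0

    def test_empty_prediction_flags_everything_undefined(self, scene):
        labels, _ = scene
        rows = evaluate_feature_level(
            labels, np.zeros_like(labels), feature_names=("area", "solidity")
        )
        assert rows and all(math.isnan(rec["value"]) for rec in rows)

    def test_unknown_feature_rejected(self, scene):
        labels, _ = scene
        with pytest.raises(KeyError):
            evaluate_feature_level(labels, labels, feature_names=("volume",))
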