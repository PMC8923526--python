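import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from anthemet.canet import (CAError, aggregate_by_characteristic,
                            correspondence_analysis, cross_distances,
                            day_night_labels, diurnal_stability,
                            metabolite_network, nonneg_shift,
                            pairwise_distances, percentile_threshold)
from anthemet.preprocess import preprocess_peak_table, standardize
from conftest import make_matrix


class TestNonnegShift:
    def test_global_minimum_subtracted(self, rng):
        values = rng.normal(size=(6, 4))
        values[2, 1] = -2.3
        values[values < -2.3] = 0.0
        shifted = nonneg_shift(make_matrix(values, state="standardized"))
        assert shifted.values.to_numpy().min() == pytest.approx(0.0)
        assert np.allclose(shifted.values.to_numpy(),
                           values - values.min(), atol=1e-12)

    def test_nonnegative_input_unchanged_and_idempotent(self, rng):
        values = np.abs(rng.normal(size=(5, 3)))
        values[0, 0] = 0.0
        m = make_matrix(values, state="standardized")
        once = nonneg_shift(m)
        twice = nonneg_shift(once)
        assert np.allclose(once.values, values, atol=1e-12)
        assert np.allclose(once.values, twice.values, atol=1e-12)


class TestCorrespondenceAnalysis:
    def test_identical_rows_have_zero_inertia(self):
        values = np.tile([1.0, 2.0, 3.0], (4, 1))
        with pytest.warns(RuntimeWarning, match="independent"):
            ca = correspondence_analysis(values)
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ca.row_coords.to_numpy(), 0.0, atol=1e-7)

    def test_inertia_times_total_is_chi_square(self, rng):
        N = rng.integers(1, 60, size=(6, 5)).astype(float)
        ca = correspondence_analysis(N)
        chi2 = chi2_contingency(N, correction=False).statistic
        assert ca.total_inertia * N.sum() == pytest.approx(chi2, rel=1e-10)
        assert np.sum(ca.principal_inertias) == pytest.approx(ca.total_inertia,
                                                              abs=1e-10)

    def test_row_distances_equal_chi_square_profile_distances(self, rng):
        from oracles import chi_square_row_distances
        N = rng.integers(1, 40, size=(3, 3)).astype(float)
        ca = correspondence_analysis(N)
        d = pairwise_distances(ca.row_coords).to_numpy()
        assert np.allclose(d, chi_square_row_distances(N), atol=1e-10)

    def test_mass_weighted_centroids_at_origin(self, rng):
        N = rng.integers(1, 30, size=(5, 4)).astype(float)
        ca = correspondence_analysis(N)
        assert np.allclose(ca.row_masses @ ca.row_coords.to_numpy(), 0.0, atol=1e-10)
        assert np.allclose(ca.col_masses @ ca.col_coords.to_numpy(), 0.0, atol=1e-10)

    def test_dimension_count_is_min_shape_minus_one(self, rng):
        N = rng.integers(1, 30, size=(7, 4)).astype(float)
        assert correspondence_analysis(N).d == 3

    def test_zero_sum_row_rejected(self):
        N = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(CAError, match="zero-sum"):
            correspondence_analysis(N)

    def test_negative_entries_rejected(self):
        with pytest.raises(CAError, match="nonnegative"):
            correspondence_analysis(np.array([[1.0, -0.5], [2.0, 1.0]]))


class TestDistances:
    def test_point_against_itself_is_zero(self, rng):
        N = rng.integers(1, 30, size=(5, 4)).astype(float)
        ca = correspondence_analysis(N)
        d = pairwise_distances(ca.col_coords)
        assert np.allclose(np.diag(d), 0.0)

    def test_cross_distance_shape_and_hand_value(self):
        N = np.array([[10.0, 2.0], [3.0, 9.0], [5.0, 5.0]])
        ca = correspondence_analysis(N)
        d = cross_distances(ca)
        assert d.shape == (2, 3)
        expected = np.linalg.norm(ca.col_coords.to_numpy()[0]
                                  - ca.row_coords.to_numpy()[0])
        assert d.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_distances_invariant_under_joint_rotation(self, rng):
        N = rng.integers(1, 30, size=(6, 5)).astype(float)
        ca = correspondence_analysis(N)
        rows = ca.row_coords.to_numpy()
        cols = ca.col_coords.to_numpy()
        q, _ = np.linalg.qr(rng.normal(size=(rows.shape[1],) * 2))
        from scipy.spatial.distance import cdist
        assert np.allclose(cdist(cols, rows), cdist(cols @ q, rows @ q), atol=1e-10)


class TestPercentileThreshold:
    def test_linear_interpolation_on_1_to_20(self):
        threshold, edges = percentile_threshold(np.arange(1.0, 21.0), 0.15)
        assert threshold == pytest.approx(3.85)
        assert sorted(edges.passed["distance"]) == [1.0, 2.0, 3.0]

    def test_full_percentile_excludes_maximum_only(self, rng):
        values = rng.random(50)
        threshold, edges = percentile_threshold(values, 1.0)
        assert threshold == pytest.approx(values.max())
        assert len(edges.passed) == np.sum(values < values.max())

    def test_all_equal_distances_pass_nothing(self):
        _, edges = percentile_threshold(np.full(30, 2.0), 0.15)
        assert len(edges.passed) == 0

    def test_passed_count_bounded_by_percentile(self, rng):
        values = rng.random(400)
        _, edges = percentile_threshold(values, 0.15)
        assert len(edges.passed) <= 0.15 * len(values) + 1

    def test_empty_input_rejected(self):
        with pytest.raises(CAError):
            percentile_threshold(np.array([]))


def edge_list_from(distances: pd.DataFrame, percentile=0.5):
    return percentile_threshold(distances, percentile)[1]


class TestAggregation:
    def meta(self, levels):
        idx = [f"s{i}" for i in range(len(levels))]
        return pd.DataFrame({
            "experiment": levels,
            "datetime": "2016-08-16T10:00:00",
        }, index=idx)

    def dist(self, rows):
        return pd.DataFrame(rows, index=["metA", "metB"][:len(rows)],
                            columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_mean_of_passed_distances(self):
        d = self.dist([[1.0, 3.0, 9.0, 9.0]])
        edges = edge_list_from(d, 0.6)  # threshold between 3 and 9
        net = aggregate_by_characteristic(edges, self.meta(["A", "A", "A", "B"]),
                                          "experiment")
        assert len(net) == 1
        row = net.iloc[0]
        assert (row["metabolite"], row["level"]) == ("metA", "A")
        assert row["mean_distance"] == pytest.approx(2.0)

    def test_levels_without_passed_pairs_get_no_edge(self):
        d = self.dist([[1.0, 9.0], [9.0, 9.0]])
        edges = edge_list_from(d, 0.4)
        net = aggregate_by_characteristic(edges, self.meta(["A", "B"]), "experiment")
        assert set(net["level"]) == {"A"}

    def test_empty_network_is_valid(self):
        d = self.dist([[2.0, 2.0]])
        edges = edge_list_from(d, 0.15)  # all equal -> nothing passes
        net = aggregate_by_characteristic(edges, self.meta(["A", "B"]), "experiment")
        assert net.empty

    def test_sample_order_invariance(self, rng):
        d = pd.DataFrame(rng.random((2, 8)), index=["metA", "metB"],
                         columns=[f"s{i}" for i in range(8)])
        levels = ["A", "B", "A", "B", "A", "B", "A", "B"]
        edges = edge_list_from(d, 0.5)
        net = aggregate_by_characteristic(edges, self.meta(levels), "experiment")
        perm = rng.permutation(8)
        d2 = d.iloc[:, perm]
        edges2 = edge_list_from(d2, 0.5)
        net2 = aggregate_by_characteristic(
            edges2, self.meta(list(np.array(levels)[perm])).set_index(d2.columns),
            "experiment")
        merged = net.merge(net2, on=["metabolite", "level"], suffixes=("", "_p"))
        assert np.allclose(merged["mean_distance"], merged["mean_distance_p"])

    def test_unlabeled_characteristic_rejected(self):
        d = self.dist([[1.0, 2.0]])
        edges = edge_list_from(d, 0.9)
        with pytest.raises(CAError, match="cultivar"):
            aggregate_by_characteristic(edges, self.meta(["A", "B"]), "cultivar")

    def test_aggregate_first_mode(self):
        d = self.dist([[1.0, 3.0, 9.0, 9.0], [8.0, 8.0, 8.0, 8.0]])
        edges = edge_list_from(d, 0.5)
        net = aggregate_by_characteristic(edges, self.meta(["A", "A", "B", "B"]),
                                          "experiment", mode="aggregate-first")
        # metA/A mean 2.0 is below the 50th percentile of the four means
        assert ("metA", "A") in set(zip(net["metabolite"], net["level"]))


class TestDayNight:
    def meta_at(self, times):
        idx = [f"s{i}" for i in range(len(times))]
        return pd.DataFrame({"datetime": [f"2016-08-16T{t}:00" for t in times]},
                            index=idx)

    def test_window_boundaries(self):
        labels = day_night_labels(self.meta_at(["06:00", "18:00", "20:00", "04:00"]))
        assert list(labels) == ["day", "day", "night", "night"]

    def test_night_core_hours(self):
        assert day_night_labels(self.meta_at(["02:00"])).iloc[0] == "night"

    def test_outside_windows_rejected(self):
        with pytest.raises(CAError, match="05"):
            day_night_labels(self.meta_at(["05:00"]))


class TestDiurnalStability:
    def test_single_outlier_closed_form(self):
        values = np.zeros((11, 1))
        values[-1, 0] = 1.0
        records = diurnal_stability(make_matrix(values), ["met_001"])
        p = 1 / 11
        assert records[0].sd_scaled == pytest.approx(np.sqrt(p * (1 - p)), abs=1e-9)

    def test_square_wave_attains_maximum(self):
        values = np.array([[0.0]] * 6 + [[1.0]] * 6)
        records = diurnal_stability(make_matrix(values), ["met_001"])
        assert records[0].sd_scaled == pytest.approx(0.5)

    def test_sd_bounded_by_half(self, rng):
        values = rng.normal(size=(50, 8))
        records = diurnal_stability(make_matrix(values),
                                    [f"met_{j + 1:03d}" for j in range(8)])
        assert all(0 <= r.sd_scaled <= 0.5 for r in records)
        assert [r.sd_scaled for r in records] == sorted(r.sd_scaled for r in records)

    def test_flat_metabolite_ranks_before_rhythmic(self, small_dataset, small_spec):
        table, _, truth, _ = small_dataset
        matrix = preprocess_peak_table(table)
        amps = truth["diurnal_amplitudes"]
        flat = truth["marker_id"]
        wavy = max(amps, key=amps.get)
        records = diurnal_stability(matrix, [flat, wavy])
        assert records[0].metabolite_id == flat

    def test_day_night_flags_from_network(self):
        values = np.random.default_rng(0).normal(size=(12, 2))
        net = pd.DataFrame({"metabolite": ["met_001"], "level": ["night"],
                            "mean_distance": [0.1], "n_pairs": [3]})
        records = diurnal_stability(make_matrix(values), ["met_001", "met_002"], net)
        by_id = {r.metabolite_id: r for r in records}
        assert by_id["met_001"].night_association and not by_id["met_001"].day_association
        assert not by_id["met_002"].night_association


class TestOnSyntheticProfiles:
    def test_within_block_metabolites_are_closer_in_ca_space(self, small_dataset):
        table, _, _, _ = small_dataset
        matrix = standardize(preprocess_peak_table(table))
        shifted = nonneg_shift(matrix)
        ca = correspondence_analysis(shifted.values)
        d = pairwise_distances(ca.col_coords)
        ids = list(d.columns)
        blocks = {m: (int(m.split("_")[1]) - 1) % 4 for m in ids}
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                (within if blocks[a] == blocks[b] else between).append(d.loc[a, b])
        assert np.median(within) < np.median(between)

    def test_metabolite_network_edges_respect_threshold(self, small_dataset):
        table, _, _, _ = small_dataset
        matrix = standardize(preprocess_peak_table(table))
        ca = correspondence_analysis(nonneg_shift(matrix).values)
        threshold, net = metabolite_network(ca.col_coords, 0.15)
        assert (net.passed["distance"] < threshold).all()
        assert len(net.passed) <= 0.15 * len(net.edges) + 1
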