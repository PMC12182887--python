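import numpy as np
import pytest
from scipy import stats

from paintnnd.io import RegionOfInterest
from paintnnd.spatial import (Histogram, NNDistribution, aggregate_conditions,
                              compare_conditions, cross_nnd, delta_area,
                              estimate_density, first_nnd,
                              normalized_histogram, significance_stars,
                              simulate_csr)


def brute_force_first_nnd(pts):
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_cross_nnd(q, r):
    return np.linalg.norm(q[:, None, :] - r[None, :, :], axis=-1).min(axis=1)


class TestFirstNND:
    def test_two_points(self):
        nnd = first_nnd(np.array([[0.0, 0.0], [50.0, 0.0]]))
        np.testing.assert_allclose(nnd.distances, [50.0, 50.0])

    def test_collinear_triplet(self):
        nnd = first_nnd(np.array([[0.0, 0.0], [3.0, 0.0], [7.0, 0.0]]))
        np.testing.assert_allclose(nnd.distances, [3.0, 3.0, 4.0])

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1000, size=(500, 2))
        got = first_nnd(pts).distances
        np.testing.assert_allclose(got, brute_force_first_nnd(pts), rtol=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            first_nnd(np.array([[0.0, 0.0]]))


class TestCrossNND:
    def test_identical_sets_give_zeros(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        np.testing.assert_allclose(cross_nnd(pts, pts).distances, 0.0)

    def test_three_four_five_triangle(self):
        q = np.array([[0.0, 0.0]])
        r = np.array([[3.0, 4.0], [10.0, 0.0]])
        np.testing.assert_allclose(cross_nnd(q, r).distances, [5.0])

    def test_asymmetric_in_arguments(self):
        q = np.array([[0.0, 0.0]])
        r = np.array([[3.0, 4.0], [10.0, 0.0]])
        np.testing.assert_allclose(cross_nnd(r, q).distances, [5.0, 10.0])

    def test_matches_brute_force(self, rng):
        q = rng.uniform(0, 500, size=(200, 2))
        r = rng.uniform(0, 500, size=(300, 2))
        np.testing.assert_allclose(cross_nnd(q, r).distances,
                                   brute_force_cross_nnd(q, r), rtol=1e-12)

    def test_permutation_invariant(self, rng):
        q = rng.uniform(0, 100, size=(50, 2))
        r = rng.uniform(0, 100, size=(60, 2))
        perm_q, perm_r = rng.permutation(50), rng.permutation(60)
        base = cross_nnd(q, r).distances
        permuted = cross_nnd(q[perm_q], r[perm_r]).distances
        np.testing.assert_allclose(permuted, base[perm_q], rtol=1e-12)

    def test_empty_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_nnd(rng.uniform(0, 1, (3, 2)), np.empty((0, 2)))


class TestEstimateDensity:
    def test_unit_density(self, rng):
        pts = rng.uniform(0, 10_000, size=(100, 2))
        roi = RegionOfInterest.rectangle(10_000, 10_000)
        assert estimate_density(pts, roi) == pytest.approx(1.0)

    def test_empty_warns_zero(self):
        roi = RegionOfInterest.rectangle(1000, 1000)
        with pytest.warns(UserWarning):
            assert estimate_density(np.empty((0, 2)), roi) == 0.0

    def test_non_square_roi_arithmetic(self, rng):
        pts = rng.uniform(0, [7300, 4100], size=(357, 2))
        roi = RegionOfInterest.rectangle(7300, 4100)
        assert estimate_density(pts, roi) == pytest.approx(357 / 29.93, rel=1e-4)

    def test_counts_only_inside(self):
        pts = np.array([[5.0, 5.0], [2000.0, 5.0]])
        roi = RegionOfInterest.rectangle(1000, 1000)
        assert estimate_density(pts, roi) == pytest.approx(1.0)


class TestSimulateCSR:
    def test_region_side_from_density(self):
        ens = simulate_csr(1.0, n_molecules=100, seed=0)
        assert ens.side_nm == pytest.approx(10_000.0)  # 10 um x 10 um
        assert ens.n_simulated == 100
        assert ens.positions.shape == (100, 2)
        assert ens.positions.min() >= 0 and ens.positions.max() <= ens.side_nm

    def test_reproducible_from_seed(self):
        a = simulate_csr(5.0, 1000, seed=42)
        b = simulate_csr(5.0, 1000, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_uniformity_chi_square(self):
        """Counts in a 10x10 grid of sub-squares are multinomial-uniform."""
        ens = simulate_csr(10.0, 100_000, seed=7)
        ix = np.floor(ens.positions / (ens.side_nm / 10)).clip(0, 9).astype(int)
        counts = np.bincount(ix[:, 0] * 10 + ix[:, 1], minlength=100)
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=99)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_csr(0.0, 100)
        with pytest.raises(ValueError):
            simulate_csr(1.0, 1)


class TestNormalizedHistogram:
    def test_single_bin_density(self):
        h = normalized_histogram(np.array([1.0, 2.0, 3.0]), bin_size=5.0)
        assert h.densities[0] == pytest.approx(1 / 5.0)
        assert h.densities[1:].sum() == 0

    def test_three_spread_distances(self):
        h = normalized_histogram(np.array([2.0, 7.0, 12.0]), bin_size=5.0,
                                 norm_range=(0.0, 200.0))
        np.testing.assert_allclose(h.densities[:3], 1 / 15.0)
        assert len(h.densities) == 40

    def test_unit_integral(self, rng):
        h = normalized_histogram(rng.uniform(0, 150, 1000), bin_size=5.0)
        assert np.sum(h.densities * h.bin_size) == pytest.approx(1.0)

    def test_out_of_range_distances_excluded(self):
        h = normalized_histogram(np.array([10.0, 500.0]), bin_size=5.0)
        assert np.sum(h.densities * h.bin_size) == pytest.approx(1.0)
        assert h.modal_bin_center == 12.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalized_histogram(np.array([]))
        with pytest.raises(ValueError):
            normalized_histogram(np.array([500.0]))  # nothing in range

    def test_misaligned_range_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            normalized_histogram(np.array([1.0]), bin_size=5.0,
                                 norm_range=(0.0, 203.0))


def _hist_from_densities(densities, bin_size=5.0):
    densities = np.asarray(densities, dtype=float)
    edges = bin_size * np.arange(len(densities) + 1)
    return Histogram(bin_edges=edges, densities=densities, bin_size=bin_size,
                     norm_range=(0.0, edges[-1]))


class TestDeltaArea:
    def test_identical_histograms_give_zero(self, rng):
        h = normalized_histogram(rng.uniform(0, 150, 500), bin_size=5.0)
        assert delta_area(h, h).delta_area == 0.0

    def test_single_excess_bin_arithmetic(self):
        # one 5-nm bin exceeds CSR by 0.008 per nm -> 0.008 * 5 = 0.04
        base = np.full(40, 1 / 200.0)
        exp = base.copy()
        exp[2] += 0.008
        exp[10] -= 0.008  # keep unit integral; negative part ignored
        res = delta_area(_hist_from_densities(exp), _hist_from_densities(base))
        assert res.delta_area == pytest.approx(0.04)

    def test_mismatched_binning_rejected(self):
        a = _hist_from_densities(np.full(40, 1 / 200.0), bin_size=5.0)
        b = _hist_from_densities(np.full(20, 1 / 200.0), bin_size=10.0)
        with pytest.raises(ValueError, match="binning"):
            delta_area(a, b)

    def test_bounded_between_zero_and_one(self, rng):
        """Positive part of a difference of unit densities stays in [0, 1]."""
        for _ in range(20):
            a = normalized_histogram(rng.uniform(0, 200, 50), bin_size=5.0)
            b = normalized_histogram(rng.uniform(0, 200, 50), bin_size=5.0)
            v = delta_area(a, b).delta_area
            assert 0.0 <= v <= 1.0

    def test_null_calibration_small(self):
        """Two CSR samples of equal density: delta area is near zero."""
        a = simulate_csr(10.0, 30_000, seed=1)
        b = simulate_csr(10.0, 30_000, seed=2)
        ha = normalized_histogram(first_nnd(a.positions))
        hb = normalized_histogram(first_nnd(b.positions))
        assert delta_area(ha, hb).delta_area < 0.03


class TestAggregateConditions:
    def test_single_cell(self, rng):
        h = normalized_histogram(rng.uniform(0, 150, 200))
        mean, std = aggregate_conditions([h])
        np.testing.assert_array_equal(mean, h.densities)
        np.testing.assert_array_equal(std, 0.0)

    def test_identical_cells_zero_std(self, rng):
        h = normalized_histogram(rng.uniform(0, 150, 200))
        _, std = aggregate_conditions([h, h])
        np.testing.assert_array_equal(std, 0.0)

    def test_two_cell_arithmetic(self):
        a = _hist_from_densities([0.1])
        b = _hist_from_densities([0.3])
        mean, std = aggregate_conditions([a, b])
        assert mean[0] == pytest.approx(0.2)
        assert std[0] == pytest.approx(0.1)  # population std

    def test_mixed_binning_rejected(self, rng):
        a = normalized_histogram(rng.uniform(0, 150, 100), bin_size=5.0)
        b = normalized_histogram(rng.uniform(0, 150, 100), bin_size=10.0)
        with pytest.raises(ValueError, match="binning"):
            aggregate_conditions([a, b])


class TestCompareConditions:
    def test_identical_groups(self):
        res = compare_conditions({"a": [0.1, 0.2], "b": [0.1, 0.2]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert res.stars == "n.s."

    def test_hand_computed_f(self):
        res = compare_conditions({"a": [0.0, 1.0], "b": [2.0, 3.0]})
        assert res.f_statistic == pytest.approx(8.0)
        assert res.p_value == pytest.approx(0.10557, abs=1e-4)

    def test_group_summaries_use_population_std(self):
        res = compare_conditions({"a": [0.0, 1.0], "b": [2.0, 3.0]})
        assert res.group_means == {"a": 0.5, "b": 2.5}
        assert res.group_stds["a"] == pytest.approx(0.5)
        assert res.group_sizes == {"a": 2, "b": 2}

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_conditions({"a": [0.1], "b": [0.1, 0.2]})
        with pytest.raises(ValueError, match="2 condition"):
            compare_conditions({"a": [0.1, 0.2]})

    @pytest.mark.parametrize(
        "p,stars",
        [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "n.s.")])
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars


def test_nndistribution_tracks_length(rng):
    nnd = NNDistribution(distances=rng.uniform(0, 10, 17))
    assert nnd.n_query == 17
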