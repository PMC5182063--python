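import numpy as np
import pytest

from strobopalm import (
    ClusterSpec,
    close_binary,
    density_cluster,
    measure_cluster_area,
    moods_median_test,
    rasterize_cluster,
    shape_metrics,
    simulate_cluster,
    zero_area_baseline,
)
from strobopalm.clustermorph import BinaryImage
from strobopalm.loc_data import NOISE_LABEL

from conftest import table_from_points


# ---------------------------------------------------------------------------
# independent brute-force DBSCAN oracle (density connectivity by definition)
# ---------------------------------------------------------------------------

def brute_force_dbscan(xy, eps, min_pts):
    n = len(xy)
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    neighbours = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbours]  # neighbourhood includes self
    labels = np.full(n, NOISE_LABEL)
    current = 0
    for i in range(n):
        if labels[i] != NOISE_LABEL or not core[i]:
            continue
        # expand the density-connected component from this core point
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbours[j]:
                if labels[k] == NOISE_LABEL:
                    labels[k] = current
                    stack.append(k)
        current += 1
    return labels


def same_partition(a, b):
    """Label vectors agree up to renaming, with identical noise sets."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == NOISE_LABEL, b == NOISE_LABEL):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == NOISE_LABEL:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestDensityClustering:
    def test_matches_brute_force_on_random_instances(self, rng):
        """DBSCAN labelling equals the from-definition density-connectivity
        oracle on 100 random instances of <= 40 points."""
        for _ in range(100):
            n = int(rng.integers(5, 41))
            xy = rng.uniform(0, 300, size=(n, 2))
            eps = float(rng.uniform(20, 120))
            min_pts = int(rng.integers(2, 8))
            t = table_from_points(np.zeros(n, dtype=int), xy)
            got = density_cluster(t, eps, min_pts).df["cluster_label"].to_numpy()
            want = brute_force_dbscan(xy, eps, min_pts)
            assert same_partition(got, want)

    def test_two_gaussian_clouds(self, rng):
        xy = np.vstack(
            [
                rng.normal((0, 0), 15, size=(200, 2)),
                rng.normal((2000, 0), 15, size=(200, 2)),
            ]
        )
        t = table_from_points(np.zeros(400, dtype=int), xy)
        labels = density_cluster(t, 50.0, 10).df["cluster_label"].to_numpy()
        clusters = set(labels) - {NOISE_LABEL}
        assert len(clusters) == 2
        assert np.mean(labels != NOISE_LABEL) >= 0.95
        # the two clouds never share a label
        assert len(set(labels[:200]) & set(labels[200:]) - {NOISE_LABEL}) == 0

    def test_sparse_scatter_is_all_noise(self, rng):
        xy = rng.uniform(0, 100_000, size=(200, 2))
        t = table_from_points(np.zeros(200, dtype=int), xy)
        labels = density_cluster(t, 50.0, 10).df["cluster_label"].to_numpy()
        assert (labels == NOISE_LABEL).all()

    def test_empty_table(self):
        from strobopalm.loc_data import LocalizationTable

        assert len(density_cluster(LocalizationTable(), 50.0, 10)) == 0


class TestRasterize:
    def test_single_localization_single_pixel(self):
        img = rasterize_cluster(table_from_points([0], [(7.0, 3.0)]), 15.0)
        assert img.pixels.sum() == 1

    def test_square_corners_hand_binned(self):
        t = table_from_points(range(4), [(0, 0), (100, 0), (0, 100), (100, 100)])
        assert rasterize_cluster(t, 100.0).pixels.sum() == 4
        assert rasterize_cluster(t, 200.0).pixels.sum() == 1

    def test_half_open_edge_convention(self):
        """A coordinate exactly on a pixel edge lands in the higher pixel."""
        t = table_from_points([0, 1], [(15.0, 0.0), (14.999, 0.0)])
        img = rasterize_cluster(t, 15.0)
        cols = np.flatnonzero(img.pixels.any(axis=0))
        assert len(cols) == 2  # edge point in pixel 1, the other in pixel 0


class TestClosing:
    def test_morphology_axioms(self, rng):
        base = BinaryImage(rng.random((40, 40)) < 0.25, 15.0)
        closed = close_binary(base, 2)
        again = close_binary(closed, 2)
        assert np.all(closed.pixels | base.pixels == closed.pixels)  # extensive
        assert np.array_equal(closed.pixels, again.pixels)           # idempotent

    def test_radius_zero_is_identity(self, rng):
        base = BinaryImage(rng.random((20, 20)) < 0.3, 15.0)
        assert np.array_equal(close_binary(base, 0).pixels, base.pixels)

    def test_single_pixel_gap_is_bridged(self):
        img = BinaryImage(np.array([[0, 0, 0, 0, 0], [0, 1, 0, 1, 0], [0, 0, 0, 0, 0]], bool), 15.0)
        assert close_binary(img, 1).pixels[1, 2]

    def test_solid_disk_unchanged(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2
        closed = close_binary(BinaryImage(disk, 15.0), 2)
        assert np.array_equal(closed.pixels, disk)


class TestShapeMetrics:
    def _disk(self, r=20):
        yy, xx = np.mgrid[0 : 2 * r + 21, 0 : 2 * r + 21]
        c = r + 10
        return BinaryImage((xx - c) ** 2 + (yy - c) ** 2 <= r**2, 1.0)

    def test_disk_near_unity(self):
        s = shape_metrics(self._disk(20))
        assert s.circularity >= 0.9
        assert s.solidity >= 0.95
        assert s.eccentricity >= 0.95

    def test_square_circularity_closed_form(self):
        img = np.zeros((50, 50), bool)
        img[5:45, 5:45] = True
        s = shape_metrics(BinaryImage(img, 1.0))
        assert s.circularity == pytest.approx(np.pi / 4, abs=0.05)
        assert s.solidity == pytest.approx(1.0, abs=0.01)
        assert s.eccentricity == pytest.approx(1.0, abs=0.01)

    def test_plus_sign_solidity_closed_form(self):
        """Five k x k squares in a plus: hull area 7k^2, so S = 5/7."""
        k = 12
        img = np.zeros((3 * k + 2, 3 * k + 2), bool)
        img[k : 2 * k, :3 * k] = True
        img[: 3 * k, k : 2 * k] = True
        s = shape_metrics(BinaryImage(img, 1.0))
        assert s.solidity == pytest.approx(5 / 7, abs=0.05)

    def test_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[0:61, 0:61]
        ell = ((xx - 30) / 28.0) ** 2 + ((yy - 30) / 14.0) ** 2 <= 1
        s = shape_metrics(BinaryImage(ell, 1.0))
        assert s.eccentricity == pytest.approx(0.5, abs=0.05)

    def test_bounds_on_random_blobs(self, rng):
        """S, E in (0, 1] and A <= H for arbitrary closed foregrounds."""
        for _ in range(25):
            px = rng.random((30, 30)) < rng.uniform(0.05, 0.5)
            if not px.any():
                continue
            s = shape_metrics(close_binary(BinaryImage(px, 10.0), 1))
            assert 0 < s.solidity <= 1 + 1e-9
            assert 0 < s.eccentricity <= 1 + 1e-9
            assert s.area_nm2 <= s.hull_area_nm2 + 1e-9

    def test_physical_units_scale(self):
        img = np.zeros((10, 10), bool)
        img[2:8, 2:8] = True
        s = shape_metrics(BinaryImage(img, 15.0))
        assert s.area_nm2 == pytest.approx(36 * 15.0**2)


class TestZeroAreaBaseline:
    def test_point_source_area_strictly_positive(self):
        """Localization noise makes even a zero-area cluster measure > 0."""
        areas = zero_area_baseline(ClusterSpec("point", 300, sigma_nm=15.0), 100, seed=1)
        assert (areas > 0).all()

    def test_doubling_precision_noise_grows_the_baseline(self):
        a15 = zero_area_baseline(ClusterSpec("point", 300, sigma_nm=15.0), 200, seed=2)
        a30 = zero_area_baseline(ClusterSpec("point", 300, sigma_nm=30.0), 200, seed=2)
        assert np.median(a30) > np.median(a15)

    def test_seed_determinism(self):
        spec = ClusterSpec("point", 200, sigma_nm=15.0)
        a = zero_area_baseline(spec, 60, seed=3)
        b = zero_area_baseline(spec, 60, seed=3)
        assert np.array_equal(a, b)

    def test_extended_clusters_exceed_baseline(self):
        """A 150-nm disk with matched localization count and precision is
        cleanly separated from the zero-area baseline."""
        baseline = zero_area_baseline(ClusterSpec("point", 300, sigma_nm=15.0), 100, seed=4)
        disks = np.array(
            [
                measure_cluster_area(
                    simulate_cluster(
                        ClusterSpec("disk", 300, radius_nm=150.0, sigma_nm=15.0), seed=100 + i
                    )
                ).area_nm2
                for i in range(100)
            ]
        )
        _, p, _ = moods_median_test(disks, baseline)
        assert p < 0.001
        assert np.median(disks) > np.median(baseline)

    def test_point_clusters_match_their_baseline(self, rng):
        """Point-source ensembles vs the matched baseline: no significant
        difference in >= 90% of repeated draws."""
        not_significant = 0
        n_runs = 10
        for run in range(n_runs):
            a = zero_area_baseline(
                ClusterSpec("point", 300, sigma_nm=15.0), 60, seed=1000 + 2 * run
            )
            b = zero_area_baseline(
                ClusterSpec("point", 300, sigma_nm=15.0), 60, seed=1001 + 2 * run
            )
            _, p, _ = moods_median_test(a, b)
            not_significant += p > 0.05
        assert not_significant >= 0.9 * n_runs

    def test_arc_vs_cap_shape_discrimination(self):
        """A long thin arc and a compact cap of equal localization budget
        differ in both area and circularity under Mood's test."""
        arc_spec = ClusterSpec(
            "annular-arc", 300, radius_nm=250.0, width_nm=60.0,
            arc_start_deg=0.0, arc_end_deg=200.0, sigma_nm=15.0,
        )
        cap_spec = ClusterSpec("disk", 300, radius_nm=120.0, sigma_nm=15.0)
        arcs = [measure_cluster_area(simulate_cluster(arc_spec, seed=i)) for i in range(100)]
        caps = [measure_cluster_area(simulate_cluster(cap_spec, seed=500 + i)) for i in range(100)]
        _, p_area, _ = moods_median_test(
            [a.area_nm2 for a in arcs], [c.area_nm2 for c in caps]
        )
        _, p_circ, _ = moods_median_test(
            [a.circularity for a in arcs], [c.circularity for c in caps]
        )
        assert p_area < 0.001
        assert p_circ < 0.001
        assert np.median([a.circularity for a in arcs]) < np.median(
            [c.circularity for c in caps]
        )


class TestMoodsMedianTest:
    def test_hand_computed_separated_samples(self):
        """{1,2,3,4} vs {6,7,8,9}: grand median 5, table [[0,4],[4,0]],
        chi-square = 8 without continuity correction."""
        stat, p, table = moods_median_test([1, 2, 3, 4], [6, 7, 8, 9])
        assert stat == pytest.approx(8.0)
        assert np.array_equal(table, [[0, 4], [4, 0]])
        assert p < 0.01

    def test_identical_samples_null(self):
        stat, p, _ = moods_median_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_median_ties_count_as_not_above(self):
        # pooled median is 2; both 2s are "not above"
        _, _, table = moods_median_test([1, 2, 2], [3, 4, 1])
        assert table[0].sum() + table[1].sum() == 6
        assert table[1][0] == 3  # all of sample A at or below the median

    def test_degenerate_pooled_sample(self):
        with pytest.raises(ValueError):
            moods_median_test([5, 5, 5], [5, 5, 5])

    def test_type_one_error_rate(self, rng):
        """Null rejection rate at alpha = 0.05 stays within [0.03, 0.07]
        over 1,000 same-distribution draws (n = 200 each)."""
        rejections = 0
        n_sim = 1_000
        for _ in range(n_sim):
            a = rng.standard_normal(200)
            b = rng.standard_normal(200)
            _, p, _ = moods_median_test(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07
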