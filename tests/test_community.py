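import numpy as np
import pytest
from scipy.spatial import ConvexHull, QhullError

from isoshift.community import (
    METRIC_NAMES,
    AssemblageSnapshot,
    community_posterior,
    layman_metrics,
)
from isoshift.compare import probability_greater
from isoshift.simulate import SyntheticSpec, generate_group


def brute_force_metrics(pts):
    """Independent oracle: pairwise scans and scipy's hull for the area."""
    pts = np.asarray(pts, float)
    S = len(pts)
    centroid = pts.mean(axis=0)
    cd = np.mean([np.hypot(*(p - centroid)) for p in pts])
    nnd = []
    for i in range(S):
        nnd.append(min(np.hypot(*(pts[i] - pts[j])) for j in range(S) if j != i))
    nnd = np.asarray(nnd)
    try:
        ta = ConvexHull(pts).volume  # 2-D "volume" is the area
    except QhullError:
        ta = 0.0
    return {
        "d13c_range": pts[:, 0].max() - pts[:, 0].min(),
        "d15n_range": pts[:, 1].max() - pts[:, 1].min(),
        "mean_dist_centroid": cd,
        "mean_nnd": float(nnd.mean()),
        "sd_nnd": float(nnd.std(ddof=1)),
        "total_area": ta,
    }


class TestLaymanMetrics:
    def test_unit_square(self):
        m = layman_metrics([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert m["d13c_range"] == 1.0
        assert m["d15n_range"] == 1.0
        assert m["mean_dist_centroid"] == pytest.approx(np.sqrt(2) / 2)
        assert m["mean_nnd"] == pytest.approx(1.0)
        assert m["sd_nnd"] == pytest.approx(0.0)
        assert m["total_area"] == pytest.approx(1.0)

    def test_collinear_points_have_zero_area(self):
        m = layman_metrics([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert m["total_area"] == 0.0

    def test_duplicate_points_give_zero_nnd(self):
        m = layman_metrics([(0, 0), (0, 0), (1, 2)])
        assert m["mean_nnd"] < 1.0  # two coincident points pull it down
        assert min(m["mean_nnd"], 0.0) == 0.0

    def test_two_points_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="2 points"):
            m = layman_metrics([(0, 0), (2, 1)])
        assert m["total_area"] == 0.0
        assert m["d13c_range"] == 2.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            layman_metrics([(0, 0)])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_quadruples(self, seed):
        pts = np.random.default_rng(seed).uniform(-5, 5, size=(4, 2))
        got = layman_metrics(pts)
        want = brute_force_metrics(pts)
        for k in METRIC_NAMES:
            assert got[k] == pytest.approx(want[k], abs=1e-10), k

    def test_rigid_motion_invariance_and_contraction_scaling(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-3, 3, size=(5, 2))
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ rot.T + np.array([4.0, -2.0])
        base, rigid = layman_metrics(pts), layman_metrics(moved)
        # distance-based metrics are rigid-motion invariant; the axis-aligned
        # ranges are only translation invariant
        for k in ("mean_dist_centroid", "mean_nnd", "sd_nnd", "total_area"):
            assert rigid[k] == pytest.approx(base[k]), k
        shifted = layman_metrics(pts + np.array([4.0, -2.0]))
        for k in METRIC_NAMES:
            assert shifted[k] == pytest.approx(base[k]), k
        c = 0.6
        contracted = pts.mean(axis=0) + c * (pts - pts.mean(axis=0))
        small = layman_metrics(contracted)
        assert small["mean_dist_centroid"] == pytest.approx(c * base["mean_dist_centroid"])
        assert small["mean_nnd"] == pytest.approx(c * base["mean_nnd"])
        assert small["total_area"] == pytest.approx(c**2 * base["total_area"])

    def test_mean_based_area_bounded_by_individual_hull(self):
        """TA over species means never exceeds the all-individuals hull area."""
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 0.5, size=(30, 2)) for m in
                  ([0, 0], [3, 1], [1, 3], [4, 4])]
        means = np.array([g.mean(axis=0) for g in groups])
        ta_means = layman_metrics(means)["total_area"]
        ta_all = ConvexHull(np.vstack(groups)).volume
        assert ta_means <= ta_all


def _snapshot(mean_list, n, sd, period="P", seed=0):
    groups = []
    for i, m in enumerate(mean_list):
        g = generate_group(
            SyntheticSpec(f"sp{i}", period, n, tuple(m), (sd, sd), seed=seed + i)
        )
        groups.append(g)
    return AssemblageSnapshot(period, tuple(groups))


class TestCommunityPosterior:
    MEANS = [(-19.4, 13.6), (-17.4, 12.8), (-18.0, 14.4), (-18.3, 16.7)]

    def test_determinism(self):
        snap = _snapshot(self.MEANS, n=20, sd=0.5)
        a = community_posterior(snap, n_draws=300, seed=4).draws
        b = community_posterior(snap, n_draws=300, seed=4).draws
        assert a.equals(b)

    def test_concentrates_on_sample_means_in_degenerate_limit(self):
        snap = _snapshot(self.MEANS, n=4000, sd=0.05, seed=31)
        post = community_posterior(snap, n_draws=500, seed=1)
        target = layman_metrics([g.xy.mean(axis=0) for g in snap.groups])
        for k in METRIC_NAMES:
            if k == "sd_nnd":  # near-zero denominator-free scale, skip ratio
                continue
            med = float(np.median(post.metric(k)))
            assert med == pytest.approx(target[k], rel=0.01), k

    def test_contracted_assemblage_detected(self):
        """Contracting species means toward the centroid by 40% lowers the
        spacing metrics with near-certainty."""
        means = np.asarray(self.MEANS)
        centroid = means.mean(axis=0)
        contracted = centroid + 0.6 * (means - centroid)
        snap_a = _snapshot(means, n=200, sd=0.4, period="A", seed=11)
        snap_b = _snapshot(contracted, n=200, sd=0.4, period="B", seed=17)
        post_a = community_posterior(snap_a, n_draws=2000, seed=2)
        post_b = community_posterior(snap_b, n_draws=2000, seed=3)
        lowered = 0
        for k in ("d13c_range", "d15n_range", "mean_dist_centroid", "mean_nnd", "total_area"):
            dp = probability_greater(post_a.metric(k), post_b.metric(k), quantity=k)
            if dp.probability > 0.99:
                lowered += 1
        assert lowered == 5

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            _snapshot(self.MEANS[:2], n=10, sd=0.3)

    def test_period_mismatch_rejected(self):
        g1 = generate_group(SyntheticSpec("a", "P", 10, (0, 0), (1, 1), seed=0))
        g2 = generate_group(SyntheticSpec("b", "Q", 10, (1, 1), (1, 1), seed=1))
        g3 = generate_group(SyntheticSpec("c", "P", 10, (2, 0), (1, 1), seed=2))
        with pytest.raises(ValueError, match="period"):
            AssemblageSnapshot("P", (g1, g2, g3))
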