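import numpy as np
import pytest

from isoshift.data import SourceDistribution
from isoshift.mixing import MixingProblem
from isoshift.polygon import (
    PolygonScreenError,
    PolygonScreenResult,
    filter_outliers,
    simulate_polygons,
)

from conftest import NO_DTDF, make_group


def _triangle_problem(consumer_xy, sd=0.05):
    sources = (
        SourceDistribution("a", (-21.0, 12.0), (sd, sd), 5),
        SourceDistribution("b", (-17.0, 12.0), (sd, sd), 5),
        SourceDistribution("c", (-19.0, 16.0), (sd, sd), 5),
    )
    return MixingProblem(make_group(consumer_xy), sources, NO_DTDF)


class TestSimulatePolygons:
    def test_centroid_consumer_is_kept(self):
        problem = _triangle_problem([(-19.0, 13.3)] * 3)
        res = simulate_polygons(problem, iterations=500, seed=1)
        assert np.all(res.probabilities >= 0.95)

    def test_distant_consumer_is_excluded(self):
        problem = _triangle_problem([(-29.0, 13.3)] * 3)  # 10 permil beyond
        res = simulate_polygons(problem, iterations=500, seed=1)
        assert np.all(res.probabilities == 0.0)

    def test_zero_variance_matches_point_in_triangle_oracle(self):
        """With point sources the screen is the deterministic hull test."""
        rng = np.random.default_rng(4)
        pts = np.column_stack(
            [rng.uniform(-22, -16, 40), rng.uniform(11, 17, 40)]
        )
        problem = _triangle_problem([tuple(p) for p in pts], sd=0.0)
        res = simulate_polygons(problem, iterations=200, seed=0)

        tri = np.array([[-21.0, 12.0], [-17.0, 12.0], [-19.0, 16.0]])

        def sign(p, a, b):
            return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])

        expected = []
        for p in pts:
            s = [sign(p, tri[i], tri[(i + 1) % 3]) for i in range(3)]
            inside = all(x >= 0 for x in s) or all(x <= 0 for x in s)
            expected.append(1.0 if inside else 0.0)
        np.testing.assert_array_equal(res.probabilities, expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        pts = [tuple(p) for p in rng.normal([-19.0, 13.5], 1.0, size=(10, 2))]
        res = simulate_polygons(_triangle_problem(pts, sd=0.4), 300, seed=5)
        shift = np.array([3.0, -2.0])
        shifted = [tuple(np.array(p) + shift) for p in pts]
        sources = tuple(
            SourceDistribution(s.name, tuple(s.mean_arr + shift), s.sd, s.n)
            for s in _triangle_problem(pts, sd=0.4).sources
        )
        problem2 = MixingProblem(make_group(shifted), sources, NO_DTDF)
        res2 = simulate_polygons(problem2, 300, seed=5)
        np.testing.assert_allclose(res2.probabilities, res.probabilities)

    def test_source_relabelling_invariance(self):
        pts = [(-19.0, 13.0), (-20.5, 12.2), (-18.0, 15.0)]
        p1 = _triangle_problem(pts, sd=0.3)
        p2 = MixingProblem(p1.consumers, p1.sources[::-1], p1.dtdf)
        r1 = simulate_polygons(p1, 300, seed=2)
        r2 = simulate_polygons(p2, 300, seed=2)
        # same seed and symmetric vertex sampling: distributions agree; check
        # the estimates are statistically indistinguishable
        np.testing.assert_allclose(
            r1.probabilities, r2.probabilities, atol=0.1
        )

    def test_inflated_sds_help_exterior_consumers(self):
        """Wider source uncertainty makes unreachable consumers reachable.

        (The same is not true of interior consumers: as vertex noise grows,
        the hull wobbles off a central point, so inclusion probability is
        not monotone in the source SDs there.)
        """
        outside = [(-22.5, 12.0), (-16.0, 15.5), (-19.0, 17.0)]
        for seed in (0, 1, 2):
            r1 = simulate_polygons(_triangle_problem(outside, sd=0.1), 400, seed=seed)
            r2 = simulate_polygons(_triangle_problem(outside, sd=1.2), 400, seed=seed)
            assert np.all(r2.probabilities >= r1.probabilities)
            assert r2.probabilities.sum() > r1.probabilities.sum()

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="100"):
            simulate_polygons(_triangle_problem([(-19.0, 13.3)]), iterations=50)

    def test_two_source_degenerate_band(self):
        sources = (
            SourceDistribution("a", (-21.0, 12.0), (0.0, 0.0), 5),
            SourceDistribution("b", (-17.0, 16.0), (0.0, 0.0), 5),
        )
        on_segment = (-19.0, 14.0)
        off_segment = (-19.0, 15.0)
        problem = MixingProblem(make_group([on_segment, off_segment]), sources, NO_DTDF)
        res = simulate_polygons(problem, 200, seed=0)
        assert res.probabilities[0] == 1.0
        assert res.probabilities[1] == 0.0


class TestFilterOutliers:
    def _result(self, probs):
        group = make_group([(-19.0, 13.0)] * len(probs))
        return PolygonScreenResult(group, np.asarray(probs), 500, 0)

    def test_no_removals_when_all_inside(self):
        kept, report = filter_outliers(self._result([1.0, 1.0, 1.0]))
        assert len(kept) == 3
        assert report["kept"].all()

    def test_threshold_logic(self):
        kept, report = filter_outliers(self._result([1.0, 0.6, 0.01]), threshold=0.05)
        assert len(kept) == 2
        assert list(report["kept"]) == [True, True, False]
        assert report.loc[2, "probability"] == pytest.approx(0.01)

    def test_all_removed_is_hard_error(self):
        with pytest.raises(PolygonScreenError):
            filter_outliers(self._result([0.0, 0.01]), threshold=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_outlier_recovered(self, seed):
        """One consumer displaced 8 permil must be the unique removal."""
        rng = np.random.default_rng(100 + seed)
        xy = [tuple(p) for p in rng.normal([-19.0, 13.3], 0.4, size=(12, 2))]
        xy.append((-19.0 - 8.0, 13.3))
        problem = _triangle_problem(xy, sd=0.4)
        res = simulate_polygons(problem, 1000, seed=seed)
        kept, report = filter_outliers(res, threshold=0.05)
        assert list(report["kept"]) == [True] * 12 + [False]
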