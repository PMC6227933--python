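import numpy as np
import pytest
from hypothesis import given, strategies as st

from isoshift.data import (
    DiscriminationFactor,
    InsufficientDataError,
    IsotopeSample,
    SourceDistribution,
)
from isoshift.mixing import (
    McmcSettings,
    MixingPosterior,
    MixingProblem,
    combine_sources,
    fit_mixing_model,
    posterior_summary,
)

from conftest import NO_DTDF, make_group


def _samples(xy, name="prey"):
    return [IsotopeSample(name, "p", float(x), float(y)) for x, y in xy]


class TestCombineSources:
    def test_identical_moments_unchanged(self):
        a = SourceDistribution("a", (-20.0, 13.0), (0.5, 0.8), 600)
        b = SourceDistribution("b", (-20.0, 13.0), (0.5, 0.8), 600)
        pooled = combine_sources(a, b, "ab")
        assert pooled.mean == a.mean
        # concatenation semantics: the n-1 denominator shifts the pooled SD
        # by O(1/n), vanishing for large groups
        assert pooled.sd == pytest.approx(a.sd, abs=1e-3)
        assert pooled.n == 1200

    @given(
        st.lists(st.tuples(st.floats(-25, -15), st.floats(8, 18)), min_size=2, max_size=10),
        st.lists(st.tuples(st.floats(-25, -15), st.floats(8, 18)), min_size=2, max_size=10),
    )
    def test_summary_pooling_equals_concatenation(self, xy_a, xy_b):
        """Pooling (n, mean, sd) summaries must agree with pooling raw samples."""
        from isoshift.data import source_from_samples
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate zero-SD draws are fine here
            sa = source_from_samples(_samples(xy_a), "a")
            sb = source_from_samples(_samples(xy_b), "b")
            by_summary = combine_sources(sa, sb, "pool")
            by_concat = combine_sources(_samples(xy_a), _samples(xy_b), "pool")
        assert by_summary.mean == pytest.approx(by_concat.mean, abs=1e-9)
        assert by_summary.sd == pytest.approx(by_concat.sd, abs=1e-9)
        assert by_summary.n == by_concat.n

    def test_pooled_sample_size_adds(self):
        # the published pooled forage-fish group records the summed n
        cod = SourceDistribution("Arctic cod", (-20.4, 13.7), (0.5, 1.1), 8)
        capelin = SourceDistribution("capelin", (-19.5, 13.8), (0.3, 0.5), 14)
        pooled = combine_sources(cod, capelin, "Arctic cod/capelin")
        assert pooled.n == 22

    def test_empty_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            combine_sources([], [], "x")


class TestMcmcSettings:
    @pytest.mark.parametrize(
        "it, burn, thin, retained",
        [(500_000, 300_000, 100, 2000), (12_000, 2_000, 100, 100), (40_000, 15_000, 25, 1000)],
    )
    def test_retained_contract(self, it, burn, thin, retained):
        assert McmcSettings(it, burn, thin).retained == retained

    @pytest.mark.parametrize(
        "it, burn, thin", [(100, 200, 1), (1000, 500, 0), (1000, 990, 1)]
    )
    def test_invalid_settings_rejected(self, it, burn, thin):
        with pytest.raises(ValueError):
            McmcSettings(it, burn, thin)


class TestFitMixingModel:
    def test_draw_count_and_simplex(self, toy_triangle_problem, fast_settings):
        post = fit_mixing_model(toy_triangle_problem, fast_settings)
        assert post.draws.shape == (fast_settings.retained, 3)
        np.testing.assert_allclose(post.draws.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(post.draws >= 0) and np.all(post.draws <= 1)
        assert np.all(post.residual_sd_draws > 0)

    def test_single_source_requires_flag(self, fast_settings):
        g = make_group([(-19.0, 14.0)] * 5)
        problem = MixingProblem(
            g, (SourceDistribution("only", (-19.0, 14.0), (0.5, 0.5), 5),), NO_DTDF
        )
        with pytest.raises(ValueError, match="at least 2 sources"):
            fit_mixing_model(problem, fast_settings)
        post = fit_mixing_model(problem, fast_settings, allow_single_source=True)
        np.testing.assert_array_equal(post.draws, 1.0)

    def test_too_few_consumers_rejected(self, fast_settings):
        problem = MixingProblem(
            make_group([(-19.0, 14.0), (-19.1, 14.2)]),
            (
                SourceDistribution("a", (-21.0, 12.0), (0.3, 0.3), 5),
                SourceDistribution("b", (-17.0, 16.0), (0.3, 0.3), 5),
            ),
            NO_DTDF,
        )
        with pytest.raises(InsufficientDataError):
            fit_mixing_model(problem, fast_settings)

    def test_midpoint_consumer_recovers_half_half(self, mid_settings):
        """Mass-balance oracle: consumer midway between near-point sources.

        With negligible variances, p = (mu2' - x) / (mu2' - mu1') = 0.5 on
        both isotopes.
        """
        rng = np.random.default_rng(2)
        xy = rng.normal([-19.0, 14.0], [0.02, 0.02], size=(40, 2))
        problem = MixingProblem(
            make_group(xy),
            (
                SourceDistribution("lo", (-21.0, 12.0), (0.01, 0.01), 5),
                SourceDistribution("hi", (-17.0, 16.0), (0.01, 0.01), 5),
            ),
            NO_DTDF,
        )
        post = fit_mixing_model(problem, mid_settings)
        med = np.median(post.draws, axis=0)
        assert med == pytest.approx([0.5, 0.5], abs=0.02)

    def test_label_equivariance(self, toy_triangle_problem, fast_settings):
        """Permuting source order permutes posterior columns exactly."""
        post = fit_mixing_model(toy_triangle_problem, fast_settings)
        perm = [2, 0, 1]
        permuted_problem = MixingProblem(
            toy_triangle_problem.consumers,
            tuple(toy_triangle_problem.sources[i] for i in perm),
            toy_triangle_problem.dtdf,
        )
        post_p = fit_mixing_model(permuted_problem, fast_settings)
        np.testing.assert_array_equal(post_p.draws, post.draws[:, perm])

    def test_dtdf_shifts_are_applied(self, mid_settings):
        """A consumer at source+DTDF must be attributed to that source."""
        dtdf = DiscriminationFactor("fish", (1.2, 2.1), (0.05, 0.05))
        rng = np.random.default_rng(9)
        xy = rng.normal([-21.0 + 1.2, 12.0 + 2.1], [0.05, 0.05], size=(30, 2))
        problem = MixingProblem(
            make_group(xy),
            (
                SourceDistribution("right", (-21.0, 12.0), (0.05, 0.05), 5),
                SourceDistribution("wrong", (-16.0, 17.0), (0.05, 0.05), 5),
            ),
            dtdf,
        )
        post = fit_mixing_model(problem, mid_settings)
        assert np.median(post.proportion("right")) > 0.95

    def test_wider_residual_prior_never_narrows_intervals(
        self, toy_triangle_problem, mid_settings
    ):
        widths = []
        for scale in (0.5, 10.0):
            post = fit_mixing_model(
                toy_triangle_problem, mid_settings, sigma_prior_scale=scale
            )
            s = posterior_summary(post)
            widths.append(float((s.hi_pct - s.lo_pct).mean()))
        assert widths[1] >= widths[0] - 1.0  # small slack for Monte-Carlo noise


class TestPosteriorSummary:
    def test_constant_draws_zero_width(self, fast_settings):
        draws = np.full((fast_settings.retained, 4), 0.25)
        post = MixingPosterior(
            draws=draws,
            residual_sd_draws=np.full((fast_settings.retained, 2), 0.1),
            source_names=("a", "b", "c", "d"),
            settings=fast_settings,
            ess=np.full(4, float(fast_settings.retained)),
        )
        s = posterior_summary(post)
        assert (s.median_pct == 25.0).all()
        assert (s.hi_pct - s.lo_pct == 0.0).all()

    def test_interval_matches_sort_and_interpolate_oracle(self, toy_triangle_problem, fast_settings):
        post = fit_mixing_model(toy_triangle_problem, fast_settings)
        s = posterior_summary(post, level=0.9)
        d = np.sort(post.draws[:, 0] * 100.0)
        n = len(d)

        def naive_quantile(q):  # linear interpolation between order statistics
            h = (n - 1) * q
            lo = int(np.floor(h))
            return d[lo] + (h - lo) * (d[min(lo + 1, n - 1)] - d[lo])

        assert s.lo_pct[0] == pytest.approx(naive_quantile(0.05), abs=1e-9)
        assert s.hi_pct[0] == pytest.approx(naive_quantile(0.95), abs=1e-9)

    def test_invalid_level_rejected(self, toy_triangle_problem, fast_settings):
        post = fit_mixing_model(toy_triangle_problem, fast_settings)
        with pytest.raises(ValueError):
            posterior_summary(post, level=1.5)
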