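import math

import numpy as np
import pytest
from scipy.stats import norm

from nichespace.datamodel import (
    AxisDescriptor,
    EstimateTable,
    IndividualObservations,
    MetricCI,
    MetricCISet,
)
from nichespace.errors import UndefinedCIError, ValidationError
from nichespace.resampling import (
    ResamplingConfig,
    compare_communities,
    nonparametric_bootstrap,
    nonparametric_replicates,
    parametric_replicates,
    parametric_resample,
    percentile_ci,
    truncated_normal_draws,
)
from nichespace.simulate import generate_individuals

from conftest import make_community

AXES_XY = (AxisDescriptor("x"), AxisDescriptor("y"))


def _obs(seed=0, s=4, k=5, sd=0.3):
    rng = np.random.default_rng(seed)
    records = {
        f"t{i}": np.array([3.0 * i, 3.0 * (i % 2)]) + rng.normal(0, sd, (k, 2))
        for i in range(s)
    }
    return IndividualObservations(AXES_XY, records)


class TestResamplingConfig:
    def test_defaults(self):
        cfg = ResamplingConfig()
        assert cfg.replicates == 10000 and cfg.level == 0.95

    @pytest.mark.parametrize("kw", [
        {"replicates": 0},
        {"level": 0.0},
        {"level": 1.5},
        {"scheme": "bayesian"},
        {"seed": -1},
    ])
    def test_rejects(self, kw):
        with pytest.raises(ValidationError):
            ResamplingConfig(**kw)


class TestPercentileCI:
    def test_1_to_100(self):
        lo, hi = percentile_ci(np.arange(1.0, 101.0), 0.95)
        assert lo == pytest.approx(3.475, abs=1e-12)
        assert hi == pytest.approx(97.525, abs=1e-12)

    def test_constant_samples(self):
        lo, hi = percentile_ci(np.full(50, 2.5), 0.95)
        assert lo == hi == 2.5

    def test_level_zero_rejected(self):
        with pytest.raises(ValidationError):
            percentile_ci(np.arange(10.0), 0.0)

    def test_all_nan(self):
        with pytest.raises(UndefinedCIError):
            percentile_ci(np.full(10, np.nan), 0.95)


class TestNonparametricBootstrap:
    def test_zero_variance_zero_width(self):
        # identical individuals within each taxon -> no sampling variation
        records = {
            "a": np.tile([0.0, 0.0], (4, 1)),
            "b": np.tile([3.0, 0.0], (4, 1)),
            "c": np.tile([0.0, 3.0], (4, 1)),
        }
        obs = IndividualObservations(AXES_XY, records)
        cis = nonparametric_bootstrap(obs, ResamplingConfig(replicates=200, seed=1))
        for name in cis.metric_names:
            ci = cis[name]
            assert ci.lower == ci.upper == pytest.approx(ci.point, abs=1e-12)

    def test_same_seed_identical(self):
        obs = _obs()
        cfg = ResamplingConfig(replicates=300, seed=42)
        a = nonparametric_bootstrap(obs, cfg)
        b = nonparametric_bootstrap(obs, cfg)
        for name in a.metric_names:
            assert a[name] == b[name]

    def test_seed_stability_across_seeds(self):
        # endpoints from two seeds agree within Monte-Carlo tolerance:
        # 3x the asymptotic standard error of the empirical quantile
        cm = make_community(
            [[2.0 * i, 2.0 * (i % 2)] for i in range(8)], axis_names=["x", "y"]
        )
        obs = generate_individuals(cm, k=10, sd=0.1, seed=99)
        b = 1000
        a = nonparametric_bootstrap(obs, ResamplingConfig(replicates=b, seed=1))
        c = nonparametric_bootstrap(obs, ResamplingConfig(replicates=b, seed=2))
        z = norm.ppf(0.025)
        for name in ("CD", "NND", "SDNND", "CHV"):
            sd_dist = a[name].dist_sd
            se = sd_dist * math.sqrt(0.025 * 0.975 / b) / norm.pdf(z)
            assert abs(a[name].lower - c[name].lower) < 3 * se + 1e-12
            assert abs(a[name].upper - c[name].upper) < 3 * se + 1e-12

    def test_adding_taxon_does_not_perturb_streams(self):
        obs = _obs(s=3)
        cfg = ResamplingConfig(replicates=50, seed=7)
        stack3 = nonparametric_replicates(obs, cfg)
        obs4 = _obs(s=4)  # same first three taxa, same per-taxon records
        for t in ("t0", "t1", "t2"):
            np.testing.assert_array_equal(obs.records[t], obs4.records[t])
        stack4 = nonparametric_replicates(obs4, cfg)
        np.testing.assert_array_equal(stack3, stack4[:, :3, :])

    def test_degenerate_chv_reported_undefined(self):
        # all taxa collinear with zero within-taxon variance: every
        # replicate is degenerate in 2-D
        records = {f"t{i}": np.tile([float(i), float(i)], (3, 1)) for i in range(4)}
        obs = IndividualObservations(AXES_XY, records)
        with pytest.warns(UserWarning, match="undefined"):
            cis = nonparametric_bootstrap(obs, ResamplingConfig(replicates=50, seed=0))
        assert not cis["CHV"].defined
        assert cis["CD"].defined

    def test_ci_width_shrinks_with_k(self):
        cm = make_community(
            [[2.0 * i, 2.0 * (i % 2)] for i in range(6)], axis_names=["x", "y"]
        )
        widths = {}
        for k in (5, 40):
            tot = 0.0
            for rep in range(10):
                obs = generate_individuals(cm, k=k, sd=0.5, seed=100 + rep)
                cis = nonparametric_bootstrap(
                    obs, ResamplingConfig(replicates=300, seed=rep)
                )
                tot += cis["CD"].width
            widths[k] = tot / 10
        assert widths[40] < widths[5]

    def test_width_vanishes_as_noise_vanishes(self):
        cm = make_community(
            [[2.0 * i, 2.0 * (i % 2)] for i in range(6)], axis_names=["x", "y"]
        )
        prev = None
        for sd in (1.0, 0.1, 0.01):
            obs = generate_individuals(cm, k=8, sd=sd, seed=5)
            cis = nonparametric_bootstrap(obs, ResamplingConfig(replicates=300, seed=3))
            w = cis["CD"].width
            if prev is not None:
                assert w < prev
            prev = w
        assert prev < 0.01


class TestTruncatedNormal:
    def test_half_normal_mean(self):
        rng = np.random.default_rng(0)
        draws = truncated_normal_draws(0.0, 1.0, 0.0, math.inf, 100_000, rng)
        assert np.all(draws >= 0.0)
        expected = math.sqrt(2.0 / math.pi)
        se = math.sqrt((1.0 - 2.0 / math.pi) / 100_000)
        assert abs(draws.mean() - expected) < 4 * se

    def test_moments_match_closed_form(self):
        from scipy.stats import truncnorm

        mean, sd, lo, hi = 1.0, 2.0, 0.0, 3.0
        a, b = (lo - mean) / sd, (hi - mean) / sd
        rng = np.random.default_rng(1)
        draws = truncated_normal_draws(mean, sd, lo, hi, 200_000, rng)
        dist = truncnorm(a, b, loc=mean, scale=sd)
        assert draws.mean() == pytest.approx(dist.mean(), abs=4 * dist.std() / math.sqrt(200_000))
        assert draws.var() == pytest.approx(dist.var(), rel=0.02)

    def test_negative_sd(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            truncated_normal_draws(0.0, -1.0, 0.0, 1.0, 10, rng)

    def test_empty_interval(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            truncated_normal_draws(0.0, 1.0, 2.0, 1.0, 10, rng)

    def test_zero_mass_interval(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            truncated_normal_draws(0.0, 1e-12, 5.0, 6.0, 10, rng)


class TestParametricResample:
    def _est(self, sds, bounds=None):
        lo, hi = bounds if bounds else (-math.inf, math.inf)
        axes = (
            AxisDescriptor("x", lower=lo, upper=hi),
            AxisDescriptor("y", lower=lo, upper=hi),
        )
        means = np.array([[0.1, 0.2], [0.5, 0.4], [0.9, 0.6], [0.3, 0.8]])
        return EstimateTable(
            tuple(f"t{i}" for i in range(4)), axes, means,
            np.full((4, 2), float(sds)),
        )

    def test_zero_sd_zero_width(self):
        est = self._est(0.0)
        cfg = ResamplingConfig(replicates=100, seed=0, scheme="parametric")
        cis = parametric_resample(est, cfg)
        for name in cis.metric_names:
            ci = cis[name]
            assert ci.lower == ci.upper == pytest.approx(ci.point, abs=1e-12)

    def test_bounds_respected(self):
        est = self._est(0.5, bounds=(0.0, 1.0))
        cfg = ResamplingConfig(replicates=500, seed=3, scheme="parametric")
        stack = parametric_replicates(est, cfg)
        assert np.all(stack >= 0.0) and np.all(stack <= 1.0)

    def test_determinism(self):
        est = self._est(0.2, bounds=(0.0, 1.0))
        cfg = ResamplingConfig(replicates=200, seed=11, scheme="parametric")
        a = parametric_resample(est, cfg)
        b = parametric_resample(est, cfg)
        for name in a.metric_names:
            assert a[name] == b[name]

    def test_scheme_mismatch(self):
        est = self._est(0.1)
        with pytest.raises(ValidationError):
            parametric_resample(est, ResamplingConfig(scheme="nonparametric"))


class TestCompareCommunities:
    def _ciset(self, intervals):
        metrics = {
            name: MetricCI(point=(lo + hi) / 2 if lo is not None else 1.0,
                           lower=lo, upper=hi, n_used=100)
            for name, (lo, hi) in intervals.items()
        }
        return MetricCISet(metrics, replicates=100, level=0.95, seed=0,
                           scheme="nonparametric")

    def test_disjoint_flagged(self):
        a = self._ciset({"CD": (0.0, 1.0)})
        b = self._ciset({"CD": (2.0, 3.0)})
        report = compare_communities(a, b)
        assert report["CD"].flagged_different
        assert report.flagged == ("CD",)

    def test_overlapping_not_flagged(self):
        a = self._ciset({"CD": (0.0, 2.0)})
        b = self._ciset({"CD": (1.0, 3.0)})
        assert not compare_communities(a, b)["CD"].flagged_different

    def test_touching_endpoints_overlap(self):
        a = self._ciset({"CD": (0.0, 1.0)})
        b = self._ciset({"CD": (1.0, 2.0)})
        entry = compare_communities(a, b)["CD"]
        assert entry.overlap and not entry.flagged_different

    def test_mismatched_metrics(self):
        a = self._ciset({"CD": (0.0, 1.0)})
        b = self._ciset({"NND": (0.0, 1.0)})
        with pytest.raises(ValidationError):
            compare_communities(a, b)

    def test_undefined_ci_not_comparable(self):
        a = self._ciset({"CHV": (None, None)})
        b = self._ciset({"CHV": (0.0, 1.0)})
        entry = compare_communities(a, b)["CHV"]
        assert not entry.comparable and not entry.flagged_different
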