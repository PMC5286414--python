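"""Resampling schemes and confidence intervals for community metrics.

Two schemes are provided:

* non-parametric — when individual-level measurements exist, each taxon's
  k_t individuals are redrawn with replacement (independently per taxon),
  taxon means recomputed, and all metrics recalculated per replicate;
* parametric — when only per-(taxon, axis) means and SDs exist (the shape
  of mixing-model output), each value is redrawn from a normal
  distribution truncated to the axis' declared bounds, independently
  across taxa and measurements.

Intervals are equal-tailed percentile intervals: empirical quantiles at
(1-level)/2 and 1-(1-level)/2 using linear interpolation between order
statistics (numpy's default quantile rule). Replicates with an undefined
hull are dropped from the CHV distribution only; if more than half the
replicates are undefined the CHV interval itself is reported undefined.

Reproducibility: a single root seed is split into per-taxon substreams
(keyed by a CRC-32 of the taxon name), so runs are bit-identical for a
given seed and adding a taxon does not perturb the draws of the others.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr
from scipy.stats import truncnorm

from .datamodel import (
    CommunityMatrix,
    EstimateTable,
    IndividualObservations,
    MetricCI,
    MetricCISet,
    MetricSet,
)
from .errors import UndefinedCIError, ValidationError
from .io import taxon_means
from .metrics import _metrics_batch, compute_all_metrics

__all__ = [
    "ResamplingConfig",
    "ComparisonReport",
    "MetricComparison",
    "nonparametric_bootstrap",
    "parametric_resample",
    "percentile_ci",
    "compare_communities",
    "truncated_normal_draws",
    "nonparametric_replicates",
    "parametric_replicates",
]

SCHEMES = ("nonparametric", "parametric")


@dataclass(frozen=True)
class ResamplingConfig:
    """Knobs of a resampling run; defaults follow the method description
    (10,000 replicates, 95% intervals)."""

    replicates: int = 10000
    level: float = 0.95
    seed: int = 0
    scheme: str = "nonparametric"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must be in (0, 1), got {self.level}")
        if self.scheme not in SCHEMES:
            raise ValidationError(
                f"scheme must be one of {SCHEMES}, got {self.scheme!r}"
            )
        if int(self.seed) != self.seed or self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")


def _taxon_rng(seed: int, taxon: str) -> np.random.Generator:
    """Deterministic per-taxon substream of the root seed."""
    key = zlib.crc32(taxon.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def percentile_ci(samples, level: float) -> tuple[float, float]:
    """Equal-tailed empirical quantile interval at the given level.

    Quantile rule: linear interpolation between order statistics
    (``numpy.quantile`` with ``method='linear'``), so for samples 1..100 at
    level 0.95 the interval is (3.475, 97.525).
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise UndefinedCIError("no finite samples to form an interval")
    if x.size < 2:
        raise ValidationError("need at least 2 finite samples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def truncated_normal_draws(
    mean: float,
    sd: float,
    lower: float,
    upper: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from normal(mean, sd) truncated to [lower, upper] by the
    inverse-CDF transform — a deterministic draw count per call, so streams
    stay aligned across runs."""
    if sd < 0:
        raise ValidationError(f"sd must be >= 0, got {sd}")
    if not lower < upper:
        raise ValidationError(f"empty truncation interval [{lower}, {upper}]")
    u = rng.random(size)
    if sd == 0:
        if not lower <= mean <= upper:
            raise ValidationError(
                f"degenerate distribution at {mean} outside [{lower}, {upper}]"
            )
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    if ndtr(b) - ndtr(a) <= 0.0:
        raise ValidationError(
            f"truncation interval [{lower}, {upper}] has zero probability "
            f"mass under normal({mean}, {sd})"
        )
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def nonparametric_replicates(
    obs: IndividualObservations, cfg: ResamplingConfig
) -> np.ndarray:
    """The (B, S, n) stack of bootstrap taxon-mean communities.

    For each replicate and each taxon independently, k_t individuals are
    drawn with replacement from that taxon's k_t records and averaged.
    """
    b = cfg.replicates
    cols = []
    for taxon in obs.taxa:
        data = obs.records[taxon]
        k = data.shape[0]
        rng = _taxon_rng(cfg.seed, taxon)
        idx = rng.integers(0, k, size=(b, k))
        cols.append(data[idx].mean(axis=1))  # (B, n)
    return np.stack(cols, axis=1)


def parametric_replicates(est: EstimateTable, cfg: ResamplingConfig) -> np.ndarray:
    """The (B, S, n) stack of parametric redraws: one truncated-normal draw
    per (taxon, axis) per replicate, independent across cells."""
    b = cfg.replicates
    cols = []
    for i, taxon in enumerate(est.taxa):
        rng = _taxon_rng(cfg.seed, taxon)
        u = rng.random((b, len(est.axes)))
        vals = np.empty_like(u)
        for j, ax in enumerate(est.axes):
            mean, sd = float(est.means[i, j]), float(est.sds[i, j])
            if sd == 0:
                vals[:, j] = mean
                continue
            a = (ax.lower - mean) / sd
            hi = (ax.upper - mean) / sd
            if ndtr(hi) - ndtr(a) <= 0.0:
                raise ValidationError(
                    f"axis {ax.name!r}, taxon {taxon!r}: truncation interval "
                    f"has zero probability mass"
                )
            vals[:, j] = truncnorm.ppf(u[:, j], a, hi, loc=mean, scale=sd)
        cols.append(vals)
    return np.stack(cols, axis=1)


def _summarize(
    point: MetricSet,
    dists: Mapping[str, np.ndarray],
    cfg: ResamplingConfig,
) -> MetricCISet:
    metrics: dict[str, MetricCI] = {}
    dropped: dict[str, int] = {}
    for name, pt in point.items():
        samples = np.asarray(dists[name], dtype=float)
        finite = samples[np.isfinite(samples)]
        n_drop = samples.size - finite.size
        if n_drop:
            dropped[name] = n_drop
        if finite.size == 0 or n_drop > samples.size / 2:
            warnings.warn(
                f"{name}: undefined in {n_drop}/{samples.size} replicates; "
                "interval reported undefined",
                stacklevel=3,
            )
            metrics[name] = MetricCI(
                point=pt, lower=None, upper=None, n_used=int(finite.size)
            )
            continue
        lo, hi = percentile_ci(finite, cfg.level) if finite.size > 1 else (
            float(finite[0]),
            float(finite[0]),
        )
        metrics[name] = MetricCI(
            point=pt,
            lower=lo,
            upper=hi,
            n_used=int(finite.size),
            dist_mean=float(finite.mean()),
            dist_sd=float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        )
    return MetricCISet(
        metrics=metrics,
        replicates=cfg.replicates,
        level=cfg.level,
        seed=cfg.seed,
        scheme=cfg.scheme,
        dropped=dropped,
    )


def nonparametric_bootstrap(
    obs: IndividualObservations, cfg: ResamplingConfig | None = None
) -> MetricCISet:
    """Bootstrap metric confidence intervals from individual-level data.

    The point estimate comes from the original taxon means; each replicate
    redraws individuals with replacement independently per taxon and
    recomputes every metric. Identical seeds give bit-identical output.
    """
    cfg = cfg or ResamplingConfig()
    if cfg.scheme != "nonparametric":
        raise ValidationError(f"expected scheme 'nonparametric', got {cfg.scheme!r}")
    cm0 = taxon_means(obs)
    if cm0.n_taxa < 2:
        raise ValidationError("bootstrap needs at least 2 taxa")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = compute_all_metrics(cm0)
    stack = nonparametric_replicates(obs, cfg)
    dists = _metrics_batch(stack, cm0.axis_names)
    return _summarize(point, dists, cfg)


def parametric_resample(
    est: EstimateTable, cfg: ResamplingConfig | None = None
) -> MetricCISet:
    """Parametric metric confidence intervals from (mean, SD) estimates.

    Each replicate draws one value per (taxon, axis) from a truncated
    normal with that cell's mean and SD and the axis' declared bounds,
    then recomputes every metric.
    """
    cfg = cfg or ResamplingConfig(scheme="parametric")
    if cfg.scheme != "parametric":
        raise ValidationError(f"expected scheme 'parametric', got {cfg.scheme!r}")
    cm0 = est.community
    if cm0.n_taxa < 2:
        raise ValidationError("parametric resampling needs at least 2 taxa")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = compute_all_metrics(cm0)
    stack = parametric_replicates(est, cfg)
    dists = _metrics_batch(stack, cm0.axis_names)
    return _summarize(point, dists, cfg)


@dataclass(frozen=True)
class MetricComparison:
    """Interval overlap verdict for one metric across two communities."""

    a_lower: float | None
    a_upper: float | None
    b_lower: float | None
    b_upper: float | None
    comparable: bool
    overlap: bool | None
    flagged_different: bool

    def __post_init__(self) -> None:
        if self.comparable and self.flagged_different != (not self.overlap):
            raise ValidationError("flagged_different must equal (not overlap)")


@dataclass(frozen=True)
class ComparisonReport:
    """Per-metric CI overlap between two communities. Non-overlap of the
    intervals is the (sole) inferential flag for a difference."""

    entries: Mapping[str, MetricComparison] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(
            name for name, e in self.entries.items() if e.flagged_different
        )

    def __getitem__(self, name: str) -> MetricComparison:
        return self.entries[name]


def compare_communities(a: MetricCISet, b: MetricCISet) -> ComparisonReport:
    """Compare two communities metric-by-metric via CI overlap.

    Intervals are closed: a shared endpoint counts as overlap. Metrics
    whose interval is undefined in either set are marked non-comparable.
    """
    if set(a.metric_names) != set(b.metric_names):
        raise ValidationError(
            f"metric sets differ: {sorted(a.metric_names)} vs "
            f"{sorted(b.metric_names)}"
        )
    entries: dict[str, MetricComparison] = {}
    for name in a.metric_names:
        ca, cb = a[name], b[name]
        if not (ca.defined and cb.defined):
            entries[name] = MetricComparison(
                ca.lower, ca.upper, cb.lower, cb.upper,
                comparable=False, overlap=None, flagged_different=False,
            )
            continue
        overlap = ca.lower <= cb.upper and cb.lower <= ca.upper
        entries[name] = MetricComparison(
            ca.lower, ca.upper, cb.lower, cb.upper,
            comparable=True, overlap=overlap, flagged_different=not overlap,
        )
    return ComparisonReport(entries)
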