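"""Core data types: community matrices, individual observations, estimate
tables, metric sets and their confidence-interval counterparts.

A community is a set of S taxa, each described by an n-vector of niche
coordinates (isotope ratios, trophic position, diet fractions, traits...).
All downstream computation consumes these types.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DimensionError,
    DuplicateTaxonError,
    EmptyTaxonError,
    MissingValueError,
    ValidationError,
)

__all__ = [
    "AxisDescriptor",
    "CommunityMatrix",
    "IndividualObservations",
    "EstimateTable",
    "MetricSet",
    "MetricCI",
    "MetricCISet",
]


@dataclass(frozen=True)
class AxisDescriptor:
    """One niche axis: a name, a unit label, and optional hard bounds.

    Bounds are used by the parametric resampler to truncate normal draws
    to mathematically admissible ranges (e.g. diet fractions in [0, 1]).
    """

    name: str
    unit: str = ""
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("axis name must be non-empty")
        if not self.lower < self.upper:
            raise ValidationError(
                f"axis {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )

    @property
    def bounded(self) -> bool:
        return math.isfinite(self.lower) or math.isfinite(self.upper)


def _check_axes(axes: Sequence[AxisDescriptor]) -> tuple[AxisDescriptor, ...]:
    axes = tuple(axes)
    names = [a.name for a in axes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate axis names: {dupes}")
    return axes


def _check_taxa(taxa: Sequence[str]) -> tuple[str, ...]:
    taxa = tuple(str(t) for t in taxa)
    if any(not t for t in taxa):
        raise ValidationError("taxon identifiers must be non-empty")
    seen: set[str] = set()
    for t in taxa:
        if t in seen:
            raise DuplicateTaxonError(f"duplicate taxon identifier: {t!r}")
        seen.add(t)
    return taxa


@dataclass(frozen=True)
class CommunityMatrix:
    """S taxa x n axes of taxon-mean niche coordinates.

    Parameters
    ----------
    taxa
        Unique, non-empty taxon identifiers (length S).
    axes
        Axis descriptors (length n), unique names.
    values
        Real S x n matrix; row i is the coordinate vector of taxon i.
        Missing values are rejected: ingest must fail or drop rows with a
        report, never impute.
    """

    taxa: tuple[str, ...]
    axes: tuple[AxisDescriptor, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", _check_taxa(self.taxa))
        object.__setattr__(self, "axes", _check_axes(self.axes))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise DimensionError("values must be a 2-D matrix")
        if vals.shape != (len(self.taxa), len(self.axes)):
            raise DimensionError(
                f"values shape {vals.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.axes)} axes"
            )
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise MissingValueError(
                f"non-finite value for taxon {self.taxa[i]!r}, "
                f"axis {self.axes[j].name!r}"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_axes(self) -> int:
        return len(self.axes)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    def axis_index(self, name: str) -> int:
        from .errors import AxisNotFoundError

        try:
            return self.axis_names.index(name)
        except ValueError:
            raise AxisNotFoundError(
                f"unknown axis {name!r}; available: {list(self.axis_names)}"
            ) from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.axis_index(name)]

    def with_values(self, values: np.ndarray) -> "CommunityMatrix":
        return replace(self, values=np.array(values, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.axes == other.axes
            and np.array_equal(self.values, other.values)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class IndividualObservations:
    """Replicate measurements per taxon: input to non-parametric resampling.

    ``records`` maps each taxon to a (k_t x n) array of individual
    measurements, axis-aligned with ``axes``.
    """

    axes: tuple[AxisDescriptor, ...]
    records: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", _check_axes(self.axes))
        n = len(self.axes)
        clean: dict[str, np.ndarray] = {}
        if not self.records:
            raise EmptyTaxonError("no individual records present")
        for taxon, arr in self.records.items():
            if not taxon:
                raise ValidationError("taxon identifiers must be non-empty")
            a = np.atleast_2d(np.asarray(arr, dtype=float))
            if a.shape[0] < 1:
                raise EmptyTaxonError(f"taxon {taxon!r} has no records")
            if a.shape[1] != n:
                raise DimensionError(
                    f"taxon {taxon!r}: records have {a.shape[1]} values, "
                    f"expected {n}"
                )
            if not np.all(np.isfinite(a)):
                raise MissingValueError(
                    f"non-finite measurement for taxon {taxon!r}"
                )
            if a.shape[0] == 1:
                warnings.warn(
                    f"taxon {taxon!r} has a single individual; "
                    "bootstrap resampling degenerates to the point value",
                    stacklevel=2,
                )
            a.setflags(write=False)
            clean[str(taxon)] = a
        object.__setattr__(self, "records", clean)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.records)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    @property
    def counts(self) -> dict[str, int]:
        """Individuals per taxon, k_t."""
        return {t: arr.shape[0] for t, arr in self.records.items()}


@dataclass(frozen=True)
class EstimateTable:
    """Per (taxon, axis) mean and standard deviation — the shape of
    mixing-model output — used by the parametric resampler.

    Truncation bounds are carried by the axis descriptors.
    """

    taxa: tuple[str, ...]
    axes: tuple[AxisDescriptor, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", _check_taxa(self.taxa))
        object.__setattr__(self, "axes", _check_axes(self.axes))
        shape = (len(self.taxa), len(self.axes))
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != shape or sds.shape != shape:
            raise DimensionError(
                f"means/sds must both have shape {shape}; got "
                f"{means.shape} and {sds.shape}"
            )
        if not (np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
            raise MissingValueError("estimate table contains non-finite cells")
        if np.any(sds < 0):
            i, j = np.argwhere(sds < 0)[0]
            raise ValidationError(
                f"negative SD for taxon {self.taxa[i]!r}, "
                f"axis {self.axes[j].name!r}"
            )
        for j, ax in enumerate(self.axes):
            col = means[:, j]
            if np.any(col < ax.lower) or np.any(col > ax.upper):
                raise ValidationError(
                    f"mean outside declared bounds on axis {ax.name!r}"
                )
        means.setflags(write=False)
        sds.setflags(write=False)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def community(self) -> CommunityMatrix:
        """The point-estimate community implied by the means."""
        return CommunityMatrix(self.taxa, self.axes, np.array(self.means))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EstimateTable):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.axes == other.axes
            and np.array_equal(self.means, other.means)
            and np.array_equal(self.sds, other.sds)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class MetricSet:
    """Named point values of the community metrics.

    ``ranges`` holds one per-axis range keyed by axis name; ``chv`` is
    ``None`` when the hull volume is undefined (S <= n or degenerate
    geometry).
    """

    ranges: Mapping[str, float]
    cd: float
    nnd: float
    sdnnd: float
    chv: float | None
    dimension: int
    taxon_count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", dict(self.ranges))
        for name, v in self.items():
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"metric {name!r} is not finite non-negative: {v}")

    def items(self) -> list[tuple[str, float | None]]:
        """Ordered (name, value) pairs: per-axis ranges first, then CD,
        NND, SDNND, CHV."""
        out: list[tuple[str, float | None]] = [
            (f"R_{ax}", float(v)) for ax, v in self.ranges.items()
        ]
        out += [
            ("CD", float(self.cd)),
            ("NND", float(self.nnd)),
            ("SDNND", float(self.sdnnd)),
            ("CHV", None if self.chv is None else float(self.chv)),
        ]
        return out

    def as_dict(self) -> dict[str, float | None]:
        return dict(self.items())

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.items())


@dataclass(frozen=True)
class MetricCI:
    """Point estimate plus interval and distribution summary for one metric.

    ``lower``/``upper`` are ``None`` when the interval is undefined (e.g.
    CHV degenerate in most replicates). ``n_used`` counts the replicates
    that contributed to the interval.
    """

    point: float | None
    lower: float | None
    upper: float | None
    n_used: int
    dist_mean: float | None = None
    dist_sd: float | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if self.lower > self.upper:
                raise ValidationError(
                    f"CI lower {self.lower} exceeds upper {self.upper}"
                )

    @property
    def defined(self) -> bool:
        return self.lower is not None and self.upper is not None

    @property
    def width(self) -> float:
        if not self.defined:
            return math.nan
        return self.upper - self.lower  # type: ignore[operator]


@dataclass(frozen=True)
class MetricCISet:
    """Confidence intervals for every metric from one resampling run."""

    metrics: Mapping[str, MetricCI]
    replicates: int
    level: float
    seed: int
    scheme: str
    dropped: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValidationError("level must be in (0, 1)")
        object.__setattr__(self, "metrics", dict(self.metrics))
        object.__setattr__(self, "dropped", dict(self.dropped))

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(self.metrics)

    def __getitem__(self, name: str) -> MetricCI:
        return self.metrics[name]
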