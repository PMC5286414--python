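"""Synthetic communities reproducing the conceptual scenario archetypes.

Each archetype yields a pair of communities sharing identical first-two-
axis coordinates — a 2-D view and a 3-D view whose third axis is
constructed per archetype — so the qualitative metric signatures of
"adding a dimension" and "adding invading taxa" can be asserted:

* ``third_axis_narrow`` / ``third_axis_wide`` — third axis varies little /
  widely (range-driven signature);
* ``single_outlier`` — one taxon displaced on the third axis;
* ``all_spread`` — every taxon varies widely and unevenly;
* ``correlated_axis`` — third axis an affine function of the first plus
  tiny jitter: distance metrics barely move, CHV changes dimension;
* ``uncorrelated_axis`` — independent third-axis draws;
* ``invasion_*`` — three invading taxa added to a fixed baseline
  community, placed to move specific metrics (vertically/horizontally in
  2-D, or hidden in / clustered on / dispersed along the third axis, or
  placed to change nothing).

Coordinates are parameterized equivalents of the published schematics,
not replicas; defaults are chosen so the documented inequalities hold
with margin.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    AxisDescriptor,
    CommunityMatrix,
    EstimateTable,
    IndividualObservations,
)
from .errors import ValidationError

__all__ = [
    "ARCHETYPES",
    "INVASION_ARCHETYPES",
    "ScenarioSpec",
    "generate_scenario",
    "pre_invasion_community",
    "generate_individuals",
    "generate_estimate_table",
]

ARCHETYPES = (
    "third_axis_narrow",
    "third_axis_wide",
    "single_outlier",
    "all_spread",
    "correlated_axis",
    "uncorrelated_axis",
    "invasion_vertical",
    "invasion_horizontal",
    "invasion_hidden_third_axis",
    "invasion_clustered_third",
    "invasion_dispersed_third",
    "invasion_no_change",
)

INVASION_ARCHETYPES = tuple(a for a in ARCHETYPES if a.startswith("invasion_"))

_AXIS_1 = AxisDescriptor("d13C", unit="permil")
_AXIS_2 = AxisDescriptor("d15N", unit="permil")
_AXIS_3 = AxisDescriptor("dI", unit="permil")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    ``narrow_spread``/``wide_spread`` are half-widths of the third-axis
    jitter; ``ring_radius``/``zigzag`` shape the deterministic baseline of
    the invasion family (taxa on a circle with an alternating third-axis
    offset, which keeps nearest-neighbor structure stable when taxa are
    added or removed).
    """

    archetype: str
    s: int = 12
    base_n: int = 2
    seed: int = 0
    narrow_spread: float = 0.1
    wide_spread: float = 10.0
    outlier_offset: float = 10.0
    correlation_slope: float = 0.4
    correlation_jitter: float = 0.15
    ring_radius: float = 5.0
    zigzag: float = 1.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(
                f"unknown archetype {self.archetype!r}; "
                f"valid: {list(ARCHETYPES)}"
            )
        if self.base_n != 2:
            raise ValidationError("base dimensionality is fixed at 2")
        min_s = 6 if self.archetype in INVASION_ARCHETYPES else 4
        if self.s < min_s:
            raise ValidationError(
                f"{self.archetype} needs at least {min_s} taxa, got {self.s}"
            )
        for name in (
            "narrow_spread", "wide_spread", "outlier_offset",
            "correlation_jitter", "ring_radius", "zigzag",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def _rng(spec: ScenarioSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def _taxon_rng(seed: int, taxon: str) -> np.random.Generator:
    key = zlib.crc32(taxon.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, 0xA5]))


def _names(count: int, prefix: str = "sp") -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1:02d}" for i in range(count))


def _base_cloud(spec: ScenarioSpec) -> np.ndarray:
    """Random 2-D base community for the added-dimension archetypes:
    uniform in a plausible isotope box."""
    rng = _rng(spec, 101)
    x = rng.uniform(-30.0, -20.0, spec.s)
    y = rng.uniform(5.0, 15.0, spec.s)
    return np.column_stack([x, y])


_I_CENTER = -17.5  # nominal center of the arbitrary third isotope axis


def _third_axis(spec: ScenarioSpec, xy: np.ndarray) -> np.ndarray:
    rng = _rng(spec, 202)
    s = spec.s
    if spec.archetype == "third_axis_narrow":
        return _I_CENTER + rng.uniform(-spec.narrow_spread, spec.narrow_spread, s)
    if spec.archetype == "third_axis_wide":
        # evenly spread plus tiny jitter: range-driven, packing even
        base = np.linspace(-spec.wide_spread, spec.wide_spread, s)
        return _I_CENTER + base + rng.uniform(-spec.narrow_spread, spec.narrow_spread, s)
    if spec.archetype == "single_outlier":
        t = _I_CENTER + rng.uniform(-spec.narrow_spread, spec.narrow_spread, s)
        t[s // 2] += spec.outlier_offset
        return t
    if spec.archetype == "all_spread":
        return _I_CENTER + rng.uniform(-spec.wide_spread, spec.wide_spread, s)
    if spec.archetype == "correlated_axis":
        x = xy[:, 0]
        jit = rng.uniform(-spec.correlation_jitter, spec.correlation_jitter, s)
        return _I_CENTER + spec.correlation_slope * (x - x.mean()) + jit
    if spec.archetype == "uncorrelated_axis":
        return _I_CENTER + rng.uniform(-5.0, 5.0, s)
    raise AssertionError(spec.archetype)  # pragma: no cover


_RING_CENTER = (-25.0, 10.0)


def _ring_points(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """All S+3 baseline slots of the invasion family: points on a circle
    with an alternating third-axis offset (last slot at 0). Returns
    (xy, third) for the full slot set."""
    m = spec.s + 3
    theta = 2.0 * np.pi * np.arange(m) / m
    cx, cy = _RING_CENTER
    xy = np.column_stack(
        [cx + spec.ring_radius * np.cos(theta), cy + spec.ring_radius * np.sin(theta)]
    )
    t = 0.5 * spec.zigzag * np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
    t[m - 1] = 0.0
    return xy, t


def _removed_slots(spec: ScenarioSpec) -> tuple[int, int, int]:
    # pairwise non-adjacent slots, one of them in the low-NND wrap region,
    # none extreme on either 2-D axis: keeps the pre-community metrics
    # representative of the full ring
    m = spec.s + 3
    return (2, 5, m - 2)


def _invasion_points(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(native_xy, native_t, invader_xy, invader_t) per invasion archetype."""
    xy, t = _ring_points(spec)
    removed = list(_removed_slots(spec))
    keep = [j for j in range(len(t)) if j not in removed]
    nat_xy, nat_t = xy[keep], t[keep]
    cx, cy = _RING_CENTER
    r = spec.ring_radius
    arch = spec.archetype
    if arch == "invasion_no_change":
        # invaders sit at the vacant ring slots but pulled toward the
        # center (factor tuned so every metric stays within a few percent
        # of the baseline: far enough in to barely grow the hull, far
        # enough out to preserve centroid distances and packing)
        rho = 0.78
        inv_xy = np.column_stack(
            [cx + (xy[removed, 0] - cx) * rho, cy + (xy[removed, 1] - cy) * rho]
        )
        inv_t = t[removed] * rho
    elif arch == "invasion_vertical":
        inv_xy = np.array([[cx - 2.0, cy + r + 6.0], [cx, cy + r + 7.0], [cx + 2.0, cy + r + 6.0]])
        inv_t = np.zeros(3)
    elif arch == "invasion_horizontal":
        inv_xy = np.array([[cx + r + 6.0, cy - 2.0], [cx + r + 7.0, cy], [cx + r + 6.0, cy + 2.0]])
        inv_t = np.zeros(3)
    elif arch == "invasion_hidden_third_axis":
        ang = np.array([0.3, 2.4, 4.5])
        inv_xy = np.column_stack([cx + 2.0 * np.cos(ang), cy + 2.0 * np.sin(ang)])
        inv_t = np.array([8.0, 8.7, 9.4]) * spec.zigzag
    elif arch == "invasion_clustered_third":
        ang = np.array([0.5, 2.6, 4.7])
        inv_xy = np.column_stack([cx + 1.5 * np.cos(ang), cy + 1.5 * np.sin(ang)])
        inv_t = (15.0 + np.array([0.0, 0.3, 0.6])) * spec.zigzag
    elif arch == "invasion_dispersed_third":
        ang = np.array([1.0, 3.1, 5.2])
        inv_xy = np.column_stack([cx + 2.0 * np.cos(ang), cy + 2.0 * np.sin(ang)])
        inv_t = np.array([6.0, 13.0, 20.0]) * spec.zigzag
    else:  # pragma: no cover
        raise AssertionError(arch)
    return nat_xy, nat_t, inv_xy, inv_t


def _pair(
    taxa: tuple[str, ...], xy: np.ndarray, third: np.ndarray
) -> tuple[CommunityMatrix, CommunityMatrix]:
    cm2 = CommunityMatrix(taxa, (_AXIS_1, _AXIS_2), xy)
    cm3 = CommunityMatrix(
        taxa, (_AXIS_1, _AXIS_2, _AXIS_3), np.column_stack([xy, third])
    )
    return cm2, cm3


def generate_scenario(spec: ScenarioSpec) -> tuple[CommunityMatrix, CommunityMatrix]:
    """Build the (2-D, 3-D) community pair for a scenario.

    Both communities share their first two axes exactly; invasion
    archetypes include the three invading taxa (compare against
    :func:`pre_invasion_community` for the before/after contrast).
    Deterministic given the spec (including its seed).
    """
    if spec.archetype in INVASION_ARCHETYPES:
        nat_xy, nat_t, inv_xy, inv_t = _invasion_points(spec)
        taxa = _names(len(nat_t)) + _names(3, "inv")
        xy = np.vstack([nat_xy, inv_xy])
        third = np.concatenate([nat_t, inv_t])
        return _pair(taxa, xy, third)
    xy = _base_cloud(spec)
    third = _third_axis(spec, xy)
    return _pair(_names(spec.s), xy, third)


def pre_invasion_community(spec: ScenarioSpec) -> tuple[CommunityMatrix, CommunityMatrix]:
    """The baseline community of the invasion family (no invaders), shared
    by every invasion archetype at a given spec."""
    if spec.archetype not in INVASION_ARCHETYPES:
        raise ValidationError(
            f"{spec.archetype!r} is not an invasion archetype"
        )
    nat_xy, nat_t, _, _ = _invasion_points(spec)
    return _pair(_names(len(nat_t)), nat_xy, nat_t)


def generate_individuals(
    cm: CommunityMatrix, k: int, sd: float, seed: int
) -> IndividualObservations:
    """k individuals per taxon: independent normal(taxon mean, sd) draws
    per axis, from per-taxon substreams of the root seed."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    records = {}
    for i, taxon in enumerate(cm.taxa):
        rng = _taxon_rng(seed, taxon)
        records[taxon] = cm.values[i] + rng.normal(0.0, sd, (k, cm.n_axes)) if sd > 0 \
            else np.tile(cm.values[i], (k, 1))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k = 1 warning is expected here
        return IndividualObservations(cm.axes, records)


def generate_estimate_table(
    cm: CommunityMatrix,
    sd_map: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> EstimateTable:
    """Pair a community's means with per-axis SDs (and optional bounds) in
    the shape of mixing-model output. Fraction-unit axes default to
    bounds [0, 1] when none are given."""
    bounds = bounds or {}
    axes = []
    for ax in cm.axes:
        if ax.name in bounds:
            lo, hi = bounds[ax.name]
            axes.append(AxisDescriptor(ax.name, unit=ax.unit, lower=lo, upper=hi))
        elif ax.unit == "fraction" and not ax.bounded:
            axes.append(AxisDescriptor(ax.name, unit=ax.unit, lower=0.0, upper=1.0))
        else:
            axes.append(ax)
    missing = [a.name for a in axes if a.name not in sd_map]
    if missing:
        raise ValidationError(f"sd_map missing axes: {missing}")
    sds = np.tile([float(sd_map[a.name]) for a in axes], (cm.n_taxa, 1))
    return EstimateTable(cm.taxa, tuple(axes), np.array(cm.values), sds)
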