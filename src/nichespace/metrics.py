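"""Generalized Layman community metrics in n-dimensional niche space.

For a community of S taxa with coordinate vectors x_1..x_S in R^n:

* per-axis range       — max minus min along each axis
* CD                   — mean Euclidean distance of taxa to the centroid
                         (species spread)
* NND                  — mean distance of each taxon to its nearest
                         neighbor (density of species packing)
* SDNND                — sample standard deviation of nearest-neighbor
                         distances (evenness of packing)
* CHV                  — convex hull area (n = 2) / volume (n > 2); the
                         total occupied niche space. Requires S > n.

Axes are used on their raw scales by default, mixing units exactly as
supplied (permil, trophic-position units, diet fractions...); pass the
community through :func:`standardize` first if z-scored axes are wanted.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .datamodel import CommunityMatrix, MetricSet
from .errors import (
    DegenerateGeometryError,
    DimensionError,
    InsufficientTaxaError,
)

__all__ = [
    "euclidean_distance",
    "axis_range",
    "centroid",
    "mean_distance_to_centroid",
    "nearest_neighbor_distances",
    "mean_nnd",
    "sd_nnd",
    "convex_hull_volume",
    "compute_all_metrics",
    "standardize",
]

#: relative SVD tolerance below which the point cloud is declared flat
_RANK_RTOL = 1e-10


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two equal-length real vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DimensionError(
            f"vectors have different lengths: {a.shape[0]} vs {b.shape[0]}"
        )
    return float(np.sqrt(np.sum((a - b) ** 2)))


def axis_range(cm: CommunityMatrix, axis: str) -> float:
    """Range (max minus min) of one axis across all taxa."""
    col = cm.column(axis)
    return float(col.max() - col.min())


def centroid(cm: CommunityMatrix) -> np.ndarray:
    """Per-axis arithmetic mean over taxa."""
    return cm.values.mean(axis=0)


def mean_distance_to_centroid(cm: CommunityMatrix) -> float:
    """CD: average Euclidean distance of each taxon to the centroid."""
    if cm.n_taxa < 2:
        warnings.warn(
            "mean distance to centroid of a single taxon is trivially 0",
            stacklevel=2,
        )
        return 0.0
    c = centroid(cm)
    return float(np.sqrt(((cm.values - c) ** 2).sum(axis=1)).mean())


def nearest_neighbor_distances(cm: CommunityMatrix) -> np.ndarray:
    """Distance from each taxon to its nearest other taxon (self excluded)."""
    if cm.n_taxa < 2:
        raise InsufficientTaxaError(
            "nearest-neighbor distances need at least 2 taxa"
        )
    d = cdist(cm.values, cm.values)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def mean_nnd(cm: CommunityMatrix) -> float:
    """NND: mean nearest-neighbor distance."""
    return float(nearest_neighbor_distances(cm).mean())


def sd_nnd(cm: CommunityMatrix) -> float:
    """SDNND: sample standard deviation (divisor S-1) of nearest-neighbor
    distances. For S = 2 both distances coincide and the value is 0."""
    nnd = nearest_neighbor_distances(cm)
    return float(np.std(nnd, ddof=1))


def _hull_measure(points: np.ndarray) -> float:
    """Lebesgue measure of the convex hull of an (S, n) point set.

    Raises if S <= n or the points span fewer than n dimensions.
    """
    s, n = points.shape
    if s <= n:
        raise InsufficientTaxaError(
            f"convex hull volume needs more taxa than axes (S={s}, n={n})"
        )
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0 or sv[-1] <= _RANK_RTOL * sv[0]:
        raise DegenerateGeometryError(
            f"points span fewer than {n} dimensions (singular values {sv})"
        )
    if n == 1:
        return float(points.max() - points.min())
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateGeometryError(str(exc)) from exc


def convex_hull_volume(cm: CommunityMatrix) -> float:
    """CHV: area (n = 2) or volume (n > 2) of the convex hull of the taxa;
    for n = 1 the consistent limit is the range.

    Requires strictly more taxa than axes and full-dimensional geometry;
    violations raise rather than returning 0, so flat data is never
    mistaken for a tiny hull.
    """
    return _hull_measure(cm.values)


def compute_all_metrics(cm: CommunityMatrix) -> MetricSet:
    """All metrics in one pass: per-axis ranges, CD, NND, SDNND, CHV.

    Unlike :func:`convex_hull_volume`, an undefined hull (S <= n or
    degenerate geometry) is reported as ``chv=None`` with a warning so the
    remaining metrics still flow.
    """
    if cm.n_taxa < 2:
        raise InsufficientTaxaError("community metrics need at least 2 taxa")
    ranges = {ax: axis_range(cm, ax) for ax in cm.axis_names}
    cd = mean_distance_to_centroid(cm)
    nnd_vals = nearest_neighbor_distances(cm)
    chv: float | None
    try:
        chv = _hull_measure(cm.values)
    except (InsufficientTaxaError, DegenerateGeometryError) as exc:
        warnings.warn(f"CHV undefined: {exc}", stacklevel=2)
        chv = None
    return MetricSet(
        ranges=ranges,
        cd=cd,
        nnd=float(nnd_vals.mean()),
        sdnnd=float(np.std(nnd_vals, ddof=1)),
        chv=chv,
        dimension=cm.n_axes,
        taxon_count=cm.n_taxa,
    )


def standardize(cm: CommunityMatrix) -> CommunityMatrix:
    """Optional z-score preprocessing: center each axis and scale to unit
    sample SD. Constant axes are centered but left unscaled."""
    sd = cm.values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return cm.with_values((cm.values - cm.values.mean(axis=0)) / sd)


def _metrics_batch(points: np.ndarray, axis_names: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Vectorized metrics over a (B, S, n) stack of resampled communities.

    Returns one length-B array per metric name; CHV entries are NaN where
    the hull is undefined for that replicate. Must agree with
    :func:`compute_all_metrics` applied per slice (asserted in tests).
    """
    b, s, n = points.shape
    out: dict[str, np.ndarray] = {}
    for j, ax in enumerate(axis_names):
        col = points[:, :, j]
        out[f"R_{ax}"] = col.max(axis=1) - col.min(axis=1)
    cent = points.mean(axis=1, keepdims=True)
    out["CD"] = np.sqrt(((points - cent) ** 2).sum(axis=2)).mean(axis=1)
    diff = points[:, :, None, :] - points[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=3))
    idx = np.arange(s)
    d[:, idx, idx] = np.inf
    nnd = d.min(axis=2)
    out["NND"] = nnd.mean(axis=1)
    out["SDNND"] = nnd.std(axis=1, ddof=1)
    chv = np.full(b, np.nan)
    if s > n:
        for i in range(b):
            try:
                chv[i] = _hull_measure(points[i])
            except (InsufficientTaxaError, DegenerateGeometryError):
                pass
    out["CHV"] = chv
    return out
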