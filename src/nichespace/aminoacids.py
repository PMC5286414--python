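"""Derived niche axes from compound-specific amino-acid isotope data.

Provides the trophic-position calculator (from the δ15N offset between a
trophic amino acid, Glutamic Acid, and a source amino acid,
Phenylalanine), sample-mean normalization of per-amino-acid δ13C
signatures, the δ-notation conversion, and assembly of a
:class:`~nichespace.datamodel.CommunityMatrix` whose axes are derived
quantities (trophic position + diet fractions, etc.).

Mixing-model estimation itself is out of scope: diet fractions arrive as
precomputed columns (means, optionally SDs) and are passed through.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AxisDescriptor, CommunityMatrix, EstimateTable
from .errors import ValidationError

__all__ = [
    "TrophicParams",
    "DerivedAxis",
    "trophic_position",
    "normalize_aa_carbon",
    "delta_value",
    "build_derived_community",
]

GLUTAMIC_ACID = "Glutamic Acid"
PHENYLALANINE = "Phenylalanine"


@dataclass(frozen=True)
class TrophicParams:
    """Trophic-position equation parameters.

    ``beta`` is the producer-level Glu-Phe offset and ``tdf`` the
    per-trophic-step enrichment. The shipped defaults (3.4 and 7.6 permil)
    are the commonly used literature values, but both vary across systems
    and are deliberately configurable.
    """

    beta: float = 3.4
    tdf: float = 7.6

    def __post_init__(self) -> None:
        if self.tdf == 0:
            raise ValidationError("tdf must be non-zero")
        if not (math.isfinite(self.beta) and math.isfinite(self.tdf)):
            raise ValidationError("trophic parameters must be finite")


def trophic_position(
    glu_n15: float, phe_n15: float, params: TrophicParams | None = None
) -> float:
    """Trophic position from Glutamic Acid and Phenylalanine δ15N values:

    TP = ((glu - phe) - beta) / tdf + 1

    A Glu-Phe difference of exactly ``beta`` gives TP = 1 (a producer).
    """
    params = params or TrophicParams()
    if not (math.isfinite(glu_n15) and math.isfinite(phe_n15)):
        raise ValidationError("delta values must be finite")
    return ((glu_n15 - phe_n15) - params.beta) / params.tdf + 1.0


def normalize_aa_carbon(profile: Mapping[str, float]) -> dict[str, float]:
    """Center a per-amino-acid δ13C profile on its sample mean.

    Each present value has the mean of the present values subtracted, so
    the output sums to zero; absent amino acids (e.g. an excluded
    Tyrosine) simply do not participate.
    """
    if len(profile) < 2:
        raise ValidationError(
            "normalization needs at least 2 amino-acid values"
        )
    vals = {k: float(v) for k, v in profile.items()}
    if not all(math.isfinite(v) for v in vals.values()):
        raise ValidationError("profile contains non-finite values")
    mean = sum(vals.values()) / len(vals)
    return {k: v - mean for k, v in vals.items()}


def delta_value(r_sample: float, r_standard: float) -> float:
    """Per-mil δ notation: ((R_sample / R_standard) - 1) x 1000."""
    if not (r_sample > 0 and r_standard > 0):
        raise ValidationError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass(frozen=True)
class DerivedAxis:
    """One derived axis of the output community.

    kind 'trophic_position' consumes the Glu/Phe δ15N rows; kind
    'passthrough' copies the variable named by ``source``. Diet-fraction
    units get bounds automatically: 'fraction' -> [0, 1],
    'percent' -> [0, 100].
    """

    name: str
    kind: str
    source: str | None = None
    beta: float = 3.4
    tdf: float = 7.6
    unit: str = ""
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in ("trophic_position", "passthrough"):
            raise ValidationError(
                f"unknown derived-axis kind {self.kind!r} for {self.name!r}"
            )
        if self.kind == "passthrough" and not self.source:
            raise ValidationError(
                f"passthrough axis {self.name!r} needs a 'source' variable"
            )

    def descriptor(self) -> AxisDescriptor:
        lower, upper = self.lower, self.upper
        if not (math.isfinite(lower) or math.isfinite(upper)):
            if self.unit == "fraction":
                lower, upper = 0.0, 1.0
            elif self.unit == "percent":
                lower, upper = 0.0, 100.0
        return AxisDescriptor(self.name, unit=self.unit, lower=lower, upper=upper)


def _lookup(
    df: pd.DataFrame, taxon: str, variable: str, element: str | None
) -> tuple[float, float]:
    mask = (df["taxon"] == taxon) & (df["amino_acid"] == variable)
    if element is not None and "element" in df.columns:
        mask &= df["element"].fillna("") == element
    rows = df[mask]
    if rows.empty:
        where = f" ({element})" if element else ""
        raise ValidationError(
            f"missing input: no {variable!r}{where} row for taxon {taxon!r}"
        )
    row = rows.iloc[0]
    sd = float(row["sd"]) if "sd" in rows.columns and pd.notna(row.get("sd")) else 0.0
    return float(row["delta"]), sd


def build_derived_community(
    raw: pd.DataFrame,
    axes: Sequence[DerivedAxis],
    *,
    with_sds: bool = False,
) -> CommunityMatrix | EstimateTable:
    """Assemble a community of derived axes from a long-format raw table.

    ``raw`` has columns ``taxon, amino_acid, element, delta`` (and
    optionally ``sd``); passthrough variables (e.g. diet fractions) use
    the ``amino_acid`` column as a generic variable name. With
    ``with_sds=True`` an :class:`EstimateTable` is returned instead,
    pairing each derived value with its input SD (trophic-position SDs are
    combined from the Glu and Phe SDs in quadrature, scaled by 1/tdf).
    """
    required = {"taxon", "amino_acid", "delta"}
    if not required.issubset(raw.columns):
        raise ValidationError(
            f"raw table needs columns {sorted(required)}, got {list(raw.columns)}"
        )
    raw = raw.copy()
    raw["taxon"] = raw["taxon"].astype(str)
    raw["amino_acid"] = raw["amino_acid"].astype(str)
    taxa = tuple(dict.fromkeys(raw["taxon"]))
    if not taxa:
        raise ValidationError("raw table has no rows")
    axes = list(axes)
    means = np.empty((len(taxa), len(axes)))
    sds = np.zeros_like(means)
    for j, ax in enumerate(axes):
        for i, taxon in enumerate(taxa):
            if ax.kind == "trophic_position":
                glu, glu_sd = _lookup(raw, taxon, GLUTAMIC_ACID, "N")
                phe, phe_sd = _lookup(raw, taxon, PHENYLALANINE, "N")
                params = TrophicParams(beta=ax.beta, tdf=ax.tdf)
                means[i, j] = trophic_position(glu, phe, params)
                sds[i, j] = math.hypot(glu_sd, phe_sd) / abs(ax.tdf)
            else:
                assert ax.source is not None
                means[i, j] = _lookup(raw, taxon, ax.source, None)[0]
                sds[i, j] = _lookup(raw, taxon, ax.source, None)[1]
    descriptors = tuple(ax.descriptor() for ax in axes)
    if with_sds:
        return EstimateTable(taxa, descriptors, means, sds)
    return CommunityMatrix(taxa, descriptors, means)
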