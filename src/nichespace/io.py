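"""CSV readers/writers for the three table dialects plus metric output.

Dialect is deliberately rigid: comma-separated, UTF-8, ``.`` decimal,
mandatory header, first column the taxon identifier. No locale inference.

* community CSV:    ``taxon,axis1,axis2,...`` — one row per taxon
* individuals CSV:  ``taxon,axis1,...``       — repeated taxon rows
* estimate CSV:     ``taxon,axis,mean,sd``    — long format
* metrics CSV:      ``metric,point,lower,upper`` with ``#`` comment header
"""
from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AxisDescriptor,
    CommunityMatrix,
    EstimateTable,
    IndividualObservations,
    MetricCI,
    MetricCISet,
    MetricSet,
)
from .errors import (
    EmptyTaxonError,
    MissingValueError,
    ParseError,
    ValidationError,
)

__all__ = [
    "read_community",
    "write_community",
    "read_individuals",
    "write_individuals",
    "read_estimates",
    "write_estimates",
    "taxon_means",
    "write_metrics",
    "read_metrics",
    "read_axes_config",
]

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptyTaxonError(f"{path}: file is empty") from None
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a taxon column plus >= 1 axis column")
    return df


def _numeric_columns(df: pd.DataFrame, path: Path, *, drop_incomplete: bool) -> pd.DataFrame:
    """Convert all non-taxon columns to float, locating bad cells precisely."""
    taxon_col = df.columns[0]
    out = df.copy()
    missing_rows: set[int] = set()
    for col in df.columns[1:]:
        raw = df[col]
        blank = raw.isna() | (raw.str.strip() == "")
        converted = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {raw.iloc[i]!r} at row {i + 2}, "
                f"column {col!r}"
            )
        if blank.any():
            if not drop_incomplete:
                i = int(np.flatnonzero(blank.to_numpy())[0])
                raise MissingValueError(
                    f"{path}: missing value at row {i + 2}, column {col!r} "
                    f"(taxon {df[taxon_col].iloc[i]!r}); pass "
                    f"drop_incomplete=True to drop such rows"
                )
            missing_rows.update(np.flatnonzero(blank.to_numpy()).tolist())
        # re-parse with Python's correctly-rounded float(): pandas' fast
        # parser can be off by 1 ulp, which breaks full-precision round-trips
        out[col] = [
            np.nan if b else float(v) for v, b in zip(raw, blank)
        ]
    if missing_rows:
        dropped = df[taxon_col].iloc[sorted(missing_rows)].tolist()
        warnings.warn(
            f"{path}: dropped {len(missing_rows)} incomplete row(s) "
            f"(taxa: {dropped})",
            stacklevel=3,
        )
        out = out.drop(index=sorted(missing_rows)).reset_index(drop=True)
    return out


def _make_axes(
    names: Sequence[str], axes_config: Sequence[AxisDescriptor] | None
) -> tuple[AxisDescriptor, ...]:
    if axes_config is None:
        return tuple(AxisDescriptor(name=str(n)) for n in names)
    by_name = {a.name: a for a in axes_config}
    return tuple(by_name.get(str(n), AxisDescriptor(name=str(n))) for n in names)


def read_community(
    path: str | Path,
    axes_config: Sequence[AxisDescriptor] | None = None,
    *,
    drop_incomplete: bool = False,
) -> CommunityMatrix:
    """Read a community CSV (one row per taxon, first column the taxon id).

    Axis bounds/units come from ``axes_config`` (sidecar, not the data
    file). Missing cells raise :class:`MissingValueError` unless
    ``drop_incomplete`` is set, in which case offending rows are dropped
    with a warning — never imputed.
    """
    path = Path(path)
    df = _numeric_columns(_read_table(path), path, drop_incomplete=drop_incomplete)
    taxa = df.iloc[:, 0].astype(str).tolist()
    axes = _make_axes(df.columns[1:], axes_config)
    return CommunityMatrix(tuple(taxa), axes, df.iloc[:, 1:].to_numpy(dtype=float))


def write_community(cm: CommunityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.values, columns=list(cm.axis_names))
    df.insert(0, "taxon", list(cm.taxa))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_individuals(
    path: str | Path,
    axes_config: Sequence[AxisDescriptor] | None = None,
    *,
    drop_incomplete: bool = False,
) -> IndividualObservations:
    """Read a long-format individuals CSV: taxon column + n numeric columns,
    one row per individual measurement."""
    path = Path(path)
    df = _numeric_columns(_read_table(path), path, drop_incomplete=drop_incomplete)
    if df.shape[0] == 0:
        raise EmptyTaxonError(f"{path}: no data rows")
    axes = _make_axes(df.columns[1:], axes_config)
    records: dict[str, np.ndarray] = {}
    taxon_col = df.columns[0]
    for taxon, grp in df.groupby(taxon_col, sort=False):
        records[str(taxon)] = grp.iloc[:, 1:].to_numpy(dtype=float)
    return IndividualObservations(axes, records)


def write_individuals(obs: IndividualObservations, path: str | Path) -> None:
    frames = []
    for taxon, arr in obs.records.items():
        df = pd.DataFrame(arr, columns=list(obs.axis_names))
        df.insert(0, "taxon", taxon)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_estimates(
    path: str | Path,
    axes_config: Sequence[AxisDescriptor] | None = None,
) -> EstimateTable:
    """Read a long-format estimate CSV: ``taxon,axis,mean,sd``."""
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"taxon": str, "axis": str}, skipinitialspace=True,
        float_precision="round_trip",
    )
    required = {"taxon", "axis", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: estimate CSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.shape[0] == 0:
        raise EmptyTaxonError(f"{path}: no data rows")
    taxa = list(dict.fromkeys(df["taxon"].astype(str)))
    axis_names = list(dict.fromkeys(df["axis"].astype(str)))
    axes = _make_axes(axis_names, axes_config)
    means = np.full((len(taxa), len(axes)), np.nan)
    sds = np.full_like(means, np.nan)
    ti = {t: i for i, t in enumerate(taxa)}
    aj = {a: j for j, a in enumerate(axis_names)}
    for row in df.itertuples(index=False):
        means[ti[str(row.taxon)], aj[str(row.axis)]] = float(row.mean)
        sds[ti[str(row.taxon)], aj[str(row.axis)]] = float(row.sd)
    if np.isnan(means).any() or np.isnan(sds).any():
        i, j = np.argwhere(np.isnan(means) | np.isnan(sds))[0]
        raise MissingValueError(
            f"{path}: no (mean, sd) pair for taxon {taxa[i]!r}, "
            f"axis {axis_names[j]!r}"
        )
    return EstimateTable(tuple(taxa), axes, means, sds)


def write_estimates(est: EstimateTable, path: str | Path) -> None:
    rows = []
    for i, taxon in enumerate(est.taxa):
        for j, ax in enumerate(est.axes):
            rows.append((taxon, ax.name, est.means[i, j], est.sds[i, j]))
    pd.DataFrame(rows, columns=["taxon", "axis", "mean", "sd"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def taxon_means(obs: IndividualObservations) -> CommunityMatrix:
    """Collapse individual observations to per-taxon arithmetic means."""
    taxa = obs.taxa
    values = np.vstack([obs.records[t].mean(axis=0) for t in taxa])
    return CommunityMatrix(taxa, obs.axes, values)


def write_metrics(ms: MetricSet | MetricCISet, path: str | Path) -> None:
    """Write a metrics CSV: ``metric,point,lower,upper`` (lower/upper blank
    for plain :class:`MetricSet`). CI files carry level/replicates/seed/
    scheme as ``#`` comment header lines."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(ms, MetricCISet):
        lines.append(f"# level={_fmt(ms.level)}")
        lines.append(f"# replicates={ms.replicates}")
        lines.append(f"# seed={ms.seed}")
        lines.append(f"# scheme={ms.scheme}")
        for name, count in ms.dropped.items():
            lines.append(f"# dropped_{name}={count}")
        lines.append("metric,point,lower,upper")
        for name, ci in ms.metrics.items():
            cells = [
                "" if v is None else _fmt(v)
                for v in (ci.point, ci.lower, ci.upper)
            ]
            lines.append(f"{name},{cells[0]},{cells[1]},{cells[2]}")
    elif isinstance(ms, MetricSet):
        lines.append("metric,point,lower,upper")
        for name, v in ms.items():
            lines.append(f"{name},{'' if v is None else _fmt(v)},,")
    else:
        raise ValidationError(f"cannot write object of type {type(ms).__name__}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metrics(path: str | Path) -> MetricCISet:
    """Read a metrics CSV written by :func:`write_metrics` back into a
    :class:`MetricCISet` (plain metric files get zero-width metadata
    defaults)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, float | None, float | None, float | None]] = []
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ParseError(f"{path}: malformed metrics row {line!r}")
        name = parts[0]
        vals = [None if p == "" else float(p) for p in parts[1:]]
        rows.append((name, vals[0], vals[1], vals[2]))
    if not rows:
        raise ParseError(f"{path}: no metric rows")
    metrics = {
        name: MetricCI(point=p, lower=lo, upper=hi, n_used=0)
        for name, p, lo, hi in rows
    }
    return MetricCISet(
        metrics=metrics,
        replicates=int(meta.get("replicates", 1)),
        level=float(meta.get("level", 0.95)),
        seed=int(meta.get("seed", 0)),
        scheme=meta.get("scheme", "unknown"),
        dropped={
            k.removeprefix("dropped_"): int(v)
            for k, v in meta.items()
            if k.startswith("dropped_")
        },
    )


def read_axes_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML/JSON sidecar config.

    Recognized keys: ``axes`` (list of {name, unit, lower, upper}),
    ``ci_level``, ``replicates``, ``seed``. Returns a dict with ``axes``
    materialized as :class:`AxisDescriptor` objects.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    out: dict[str, Any] = dict(raw)
    axes = []
    for entry in raw.get("axes", []) or []:
        if not isinstance(entry, dict) or "name" not in entry:
            raise ParseError(f"{path}: each axes entry needs a 'name'")
        axes.append(
            AxisDescriptor(
                name=str(entry["name"]),
                unit=str(entry.get("unit", "")),
                lower=float(entry.get("lower", -math.inf)),
                upper=float(entry.get("upper", math.inf)),
            )
        )
    out["axes"] = axes
    return out
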