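"""CSV schemas, validated loaders and writers for the pipeline.

Exact column contracts:

* counts:            route_id, site_class, point_id, year, species, count
* covariates-point:  route_id, point_id, year, grass250
* covariates-route:  route_id, year, grass2500

Covariate files may additionally carry a ``source`` column
(observed / extrapolated / carried) written by the extrapolation stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CovariateTable, POINT_COLUMNS, ROUTE_COLUMNS
from .simulate import COUNT_COLUMNS

SITE_CLASSES = {"focal", "paired"}


class SchemaError(ValueError):
    """Input file violates the CSV schema contract."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _require_int(df: pd.DataFrame, col: str, path, non_negative: bool = False) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals != vals.round())
    if non_negative:
        bad |= vals < 0
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # 1-based with header line
        kind = "non-negative integer" if non_negative else "integer"
        raise SchemaError(f"{path}: column '{col}' must be {kind}; bad file row(s) {rows}")
    return vals.astype(int)


def load_counts(path) -> pd.DataFrame:
    """Read and validate a long-format count table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    df["year"] = _require_int(df, "year", path)
    df["count"] = _require_int(df, "count", path, non_negative=True)
    bad_cls = ~df["site_class"].isin(SITE_CLASSES)
    if bad_cls.any():
        rows = (df.index[bad_cls] + 2).tolist()[:10]
        raise SchemaError(f"{path}: site_class must be focal or paired; bad file row(s) {rows}")
    return df[COUNT_COLUMNS]


def load_covariates(point_path, route_path) -> CovariateTable:
    """Read and validate point- and route-level covariate tables."""
    point = pd.read_csv(point_path)
    route = pd.read_csv(route_path)
    _require_columns(point, POINT_COLUMNS, point_path)
    _require_columns(route, ROUTE_COLUMNS, route_path)
    point["year"] = _require_int(point, "year", point_path)
    route["year"] = _require_int(route, "year", route_path)
    for df, col, path in ((point, "grass250", point_path), (route, "grass2500", route_path)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 1)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]
            raise SchemaError(f"{path}: {col} must be a proportion in [0, 1]; "
                              f"bad file row(s) {rows}")
        df[col] = vals.astype(float)
    try:
        return CovariateTable(point=point, route=route)
    except ValueError as e:  # pragma: no cover - double guard
        raise SchemaError(str(e)) from e


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_covariates(cov: CovariateTable, point_path, route_path) -> None:
    cov.point.to_csv(point_path, index=False)
    cov.route.to_csv(route_path, index=False)
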