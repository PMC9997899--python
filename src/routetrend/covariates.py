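"""Grassland-cover covariates: storage, missing-year extrapolation, joining.

Land-cover proportions exist at two scales — a 250-m buffer around each
survey point (``grass250``) and a 2,500-m buffer around each route
(``grass2500``) — and are typically unavailable for the earliest survey
years.  Missing years are filled by an ordinary least-squares regression of
cover on calendar year, fit independently per location and per scale, with
predictions clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

POINT_COLUMNS = ["route_id", "point_id", "year", "grass250"]
ROUTE_COLUMNS = ["route_id", "year", "grass2500"]


@dataclass
class CovariateTable:
    """Point-level and route-level grassland cover, long format.

    ``point`` has columns route_id, point_id, year, grass250 and ``route``
    has route_id, year, grass2500; both may carry a ``source`` column with
    values observed / extrapolated / carried.  Proportions lie in [0, 1].
    """

    point: pd.DataFrame
    route: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols, name in ((self.point, POINT_COLUMNS, "point"),
                               (self.route, ROUTE_COLUMNS, "route")):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} covariates missing columns {missing}")
        for df, col in ((self.point, "grass250"), (self.route, "grass2500")):
            vals = df[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or vals.min(initial=0) < 0 or vals.max(initial=0) > 1:
                raise ValueError(f"{col} must be finite proportions in [0, 1]")

    def years(self) -> list[int]:
        ys = set(self.point["year"].astype(int)) | set(self.route["year"].astype(int))
        return sorted(ys)


def _extrapolate_frame(df: pd.DataFrame, value_col: str, key_cols: list[str],
                       target_years: list[int]) -> pd.DataFrame:
    """OLS of cover on year per location; predict missing years, clamp [0,1]."""
    out_parts = []
    targets = np.asarray(sorted(set(int(y) for y in target_years)))
    for key, grp in df.groupby(key_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        obs_years = grp["year"].to_numpy(dtype=float)
        obs_vals = grp[value_col].to_numpy(dtype=float)
        missing = [y for y in targets if y not in set(int(v) for v in obs_years)]
        obs = grp[key_cols + ["year", value_col]].copy()
        obs["source"] = grp["source"].to_numpy() if "source" in grp.columns else "observed"
        out_parts.append(obs)
        if not missing:
            continue
        if len(obs_years) >= 2 and np.ptp(obs_years) > 0:
            slope, intercept = np.polyfit(obs_years, obs_vals, 1)
            pred = np.clip(intercept + slope * np.asarray(missing, dtype=float), 0.0, 1.0)
            source = "extrapolated"
        else:
            # too few observed years for a line: carry the nearest observed value
            log.warning("location %s has <2 observed years; carrying nearest value", key)
            nearest = np.array([obs_vals[np.argmin(np.abs(obs_years - y))] for y in missing])
            pred = np.clip(nearest, 0.0, 1.0)
            source = "carried"
        filled = pd.DataFrame({c: [k] * len(missing) for c, k in zip(key_cols, key)})
        filled["year"] = missing
        filled[value_col] = pred
        filled["source"] = source
        out_parts.append(filled)
    out = pd.concat(out_parts, ignore_index=True)
    out["year"] = out["year"].astype(int)
    return out.sort_values(key_cols + ["year"], ignore_index=True)


def extrapolate_grass(table: CovariateTable, target_years) -> CovariateTable:
    """Fill missing years at both scales by per-location linear regression.

    Observed values are never altered; predictions are clamped to [0, 1];
    the output covers observed plus target years and carries a ``source``
    column (observed / extrapolated / carried).  Locations with fewer than
    two observed years fall back to carrying the nearest observed value,
    with a warning in the run log.  The operation is idempotent: rows
    already present pass through unchanged.
    """
    target_years = [int(y) for y in target_years]
    point = _extrapolate_frame(table.point, "grass250", ["route_id", "point_id"], target_years)
    route = _extrapolate_frame(table.route, "grass2500", ["route_id"], target_years)
    return CovariateTable(point=point, route=route)


def build_design_table(counts: pd.DataFrame, covariates: CovariateTable) -> pd.DataFrame:
    """Join counts with covariates into the model's analysis table.

    Returns one row per (route, point, year) with the response ``y``, the
    covariates ``x_focal``/``grass250``/``grass2500``, and dense integer
    indices ``route_idx`` (0..K-1, design order) and ``route_year_idx``
    (0..K*T-1, route-major) addressing the random-effect layers.  Raises if
    any count row lacks a covariate cell.
    """
    df = counts.merge(covariates.point[POINT_COLUMNS], on=["route_id", "point_id", "year"],
                      how="left")
    df = df.merge(covariates.route[ROUTE_COLUMNS], on=["route_id", "year"], how="left")
    bad = df["grass250"].isna() | df["grass2500"].isna()
    if bad.any():
        cells = df.loc[bad, ["route_id", "point_id", "year"]].drop_duplicates()
        raise ValueError(
            "missing covariate cells for: "
            + "; ".join(f"({r.route_id}, {r.point_id}, {r.year})"
                        for r in cells.head(20).itertuples())
        )

    cls = df.groupby("route_id")["site_class"].nunique()
    if (cls > 1).any():
        raise ValueError(f"site_class varies within route(s): {list(cls[cls > 1].index)}")

    route_ids = sorted(df["route_id"].unique())
    years = sorted(int(y) for y in df["year"].unique())
    k_map = {r: i for i, r in enumerate(route_ids)}
    t_map = {y: i for i, y in enumerate(years)}
    df = df.sort_values(["route_id", "point_id", "year"], ignore_index=True)
    df["x_focal"] = (df["site_class"] == "focal").astype(float)
    df["route_idx"] = df["route_id"].map(k_map).astype(int)
    df["year_idx"] = df["year"].astype(int).map(t_map).astype(int)
    df["route_year_idx"] = df["route_idx"] * len(years) + df["year_idx"]
    df = df.rename(columns={"count": "y"})
    df.attrs["route_ids"] = route_ids
    df.attrs["years"] = years
    return df[["route_id", "site_class", "point_id", "year", "species", "y",
               "x_focal", "grass250", "grass2500",
               "route_idx", "year_idx", "route_year_idx"]]
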