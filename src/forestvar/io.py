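"""Readers, writers and filtering for the inventory-style CSV artifacts.

Column dictionary
-----------------
``plots.csv`` — one row per plot x census period:

========================  =====================================================
column                    meaning
========================  =====================================================
plot_id                   integer plot identifier
region                    forest region label
mat                       mean annual temperature, degC
map                       mean annual precipitation, mm/yr
period                    "earlier" (first measurement year < 2003) or "recent"
meas_year                 first measurement year of the census interval
interval_yr               census interval length, years (3-8)
forestland                1 if the plot is on forestland
harvested                 1 if harvested between measurements
cond_boundary             1 if the plot straddles a forest-type condition
                          boundary
========================  =====================================================

``trees.csv`` — one row per tree x census interval:

========================  =====================================================
plot_id, period           foreign key into the plot table
subplot_id                subplot number 1-4
size_class                "small" (< 12.7 cm DBH) or "large"
pft                       plant functional type label
dbh_t0                    DBH at the first measurement, cm
dbh_t1                    DBH at remeasurement, cm; empty for dead trees or
                          missing remeasurements
status_t1                 "live" or "dead" at remeasurement
shading_cai               crown-area index of taller neighbours, m2/m2
========================  =====================================================

Values are UTF-8 comma-separated with a header row, "." decimal and empty
cells for missing values; lines starting with ``#`` are metadata comments
(config hash and seed of the producing run).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "InventoryTables",
    "SchemaError",
    "read_inventory",
    "write_inventory",
    "apply_plot_filters",
]

PLOT_COLUMNS = [
    "plot_id",
    "region",
    "mat",
    "map",
    "period",
    "meas_year",
    "interval_yr",
    "forestland",
    "harvested",
    "cond_boundary",
]
TREE_COLUMNS = [
    "plot_id",
    "subplot_id",
    "size_class",
    "pft",
    "dbh_t0",
    "dbh_t1",
    "status_t1",
    "period",
    "shading_cai",
]


class SchemaError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


@dataclass
class InventoryTables:
    """Paired tree and plot tables plus a validation/filter report."""

    trees: pd.DataFrame
    plots: pd.DataFrame
    report: dict = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return int(self.plots["plot_id"].nunique())


def _require(df: pd.DataFrame, cols, table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{table} table is missing required column {c!r}")


def read_inventory(tree_path, plot_path) -> InventoryTables:
    """Read and validate the two CSV files.

    Rows with malformed or impossible numeric values (non-numeric or
    non-positive DBH, interval outside (0, 50]) are rejected; the counts of
    kept and dropped rows per rule are returned in ``report``.
    """
    trees = pd.read_csv(tree_path, comment="#")
    plots = pd.read_csv(plot_path, comment="#")
    _require(trees, TREE_COLUMNS, "tree")
    _require(plots, PLOT_COLUMNS, "plot")

    report: dict = {"tree_rows_read": len(trees), "plot_rows_read": len(plots)}

    for col in ("dbh_t0", "dbh_t1", "shading_cai"):
        trees[col] = pd.to_numeric(trees[col], errors="coerce")
    bad = trees["dbh_t0"].isna() | (trees["dbh_t0"] <= 0) | trees["shading_cai"].isna()
    bad |= ~trees["status_t1"].isin(["live", "dead"])
    bad |= ~trees["size_class"].isin(["small", "large"])
    report["tree_rows_dropped_malformed"] = int(bad.sum())
    trees = trees[~bad].reset_index(drop=True)

    for col in ("mat", "map", "interval_yr"):
        plots[col] = pd.to_numeric(plots[col], errors="coerce")
    badp = plots[["mat", "map", "interval_yr"]].isna().any(axis=1)
    badp |= (plots["interval_yr"] <= 0) | (plots["interval_yr"] > 50)
    report["plot_rows_dropped_malformed"] = int(badp.sum())
    plots = plots[~badp].reset_index(drop=True)
    for col in ("forestland", "harvested", "cond_boundary"):
        plots[col] = plots[col].astype(int).astype(bool)

    # orphan trees (no surviving plot/period row)
    key = pd.MultiIndex.from_frame(plots[["plot_id", "period"]])
    tkey = pd.MultiIndex.from_frame(trees[["plot_id", "period"]])
    orphan = ~tkey.isin(key)
    report["tree_rows_dropped_orphaned"] = int(orphan.sum())
    trees = trees[~orphan].reset_index(drop=True)

    report["tree_rows_kept"] = len(trees)
    report["plot_rows_kept"] = len(plots)
    return InventoryTables(trees=trees, plots=plots, report=report)


def write_inventory(
    tables: InventoryTables, tree_path, plot_path, meta: "dict | None" = None
) -> None:
    """Write the two CSVs, embedding run metadata as ``#`` comment lines."""
    header = ""
    if meta:
        header = "".join(f"# {k}={v}\n" for k, v in sorted(meta.items()))
    for df, path, cols in (
        (tables.trees, tree_path, TREE_COLUMNS),
        (tables.plots, plot_path, PLOT_COLUMNS),
    ):
        out = df[cols] if all(c in df.columns for c in cols) else df
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            out.to_csv(fh, index=False)


def apply_plot_filters(tables: InventoryTables) -> InventoryTables:
    """Drop non-forestland, harvested and condition-boundary plot records.

    Mirrors the inventory pre-processing: a plot x period record is retained
    only if it is on forestland, was not harvested between measurements, and
    does not straddle a condition boundary.  Tree rows of dropped records
    are dropped with them.  Idempotent; per-rule counts go in ``report``.
    """
    plots = tables.plots
    nonforest = ~plots["forestland"].astype(bool)
    harvested = plots["harvested"].astype(bool)
    boundary = plots["cond_boundary"].astype(bool)
    keep = ~(nonforest | harvested | boundary)
    report = dict(tables.report)
    report.update(
        {
            "plots_dropped_nonforest": int(nonforest.sum()),
            "plots_dropped_harvested": int((harvested & ~nonforest).sum()),
            "plots_dropped_boundary": int((boundary & ~nonforest & ~harvested).sum()),
            "plot_rows_after_filters": int(keep.sum()),
        }
    )
    plots = plots[keep].reset_index(drop=True)
    key = pd.MultiIndex.from_frame(plots[["plot_id", "period"]])
    tkey = pd.MultiIndex.from_frame(tables.trees[["plot_id", "period"]])
    trees = tables.trees[tkey.isin(key)].reset_index(drop=True)
    report["tree_rows_after_filters"] = len(trees)
    return InventoryTables(trees=trees, plots=plots, report=report)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
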