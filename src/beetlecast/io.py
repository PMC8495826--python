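"""Survey-table CSV reading/writing with schema and range validation.

CSV is the single canonical tabular format; grid geometry travels in the
``row``/``col`` columns rather than a raster format.  The same schema is
produced by the simulator and accepted for real survey exports.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from beetlecast.features import COVARIATES, OUTCOME, compute_neighbor_index

SCHEMA = ["pixel_id", "row", "col", "year"] + COVARIATES
#: Columns that may be absent and will be reconstructed when possible.
OPTIONAL = ["IN_missed", "IN_managed", OUTCOME]


class SchemaError(ValueError):
    """The survey CSV violates the expected schema or value ranges."""


def _fail_rows(mask: np.ndarray, column: str, reason: str) -> None:
    if mask.any():
        rows = np.nonzero(mask)[0][:5] + 2  # 1-based with header line
        raise SchemaError(
            f"column {column!r} {reason} at CSV line(s) {list(map(int, rows))}"
            + ("..." if mask.sum() > 5 else "")
        )


def validate_survey_table(table: pd.DataFrame) -> None:
    """Range and uniqueness checks; raises :class:`SchemaError` with rows."""
    dup = table.duplicated(subset=["pixel_id", "year"]).to_numpy()
    _fail_rows(dup, "pixel_id/year", "is duplicated")
    checks = [
        ("N", lambda x: (x < -1) | (x > 1), "outside [-1, 1]"),
        ("E", lambda x: (x < -1) | (x > 1), "outside [-1, 1]"),
        ("B", lambda x: x < 0, "negative"),
        ("D", lambda x: x < 0, "negative"),
        ("W", lambda x: x < 0, "negative"),
        ("R", lambda x: (x < 0) | (x > 100), "outside [0, 100]"),
        ("C", lambda x: (x < 0) | (x > 1), "outside [0, 1]"),
        ("O", lambda x: ~np.isin(x, (1, 2, 3)), "not an outbreak phase in {1,2,3}"),
        ("IN_missed", lambda x: (x < 0) | (x > 6), "outside [0, 6]"),
        ("IN_managed", lambda x: (x < 0) | (x > 6), "outside [0, 6]"),
        ("I_missed", lambda x: ~np.isin(x, (0, 1)), "not binary"),
        ("I_managed", lambda x: ~np.isin(x, (0, 1)), "not binary"),
    ]
    if OUTCOME in table.columns:
        checks.append((OUTCOME, lambda x: ~np.isin(x, (0, 1)), "not binary"))
    for col, bad, reason in checks:
        if col in table.columns:
            _fail_rows(bad(table[col].to_numpy()), col, reason)
    na = table.isna().any(axis=1).to_numpy()
    _fail_rows(na, "any", "has missing values")


def _recompute_neighbor_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Rebuild IN columns from the indicator columns and grid coordinates.

    Both the indicator and its neighbor index refer to the same survey
    year's "last year" events, so the ring sum of the same-year indicator
    map reproduces the index exactly.
    """
    n_rows = int(table["row"].max()) + 1
    n_cols = int(table["col"].max()) + 1
    park = np.zeros((n_rows, n_cols), dtype=bool)
    park[table["row"], table["col"]] = True
    out = table.copy()
    for src, dst in (("I_missed", "IN_missed"), ("I_managed", "IN_managed")):
        vals = np.empty(len(table))
        for year, grp in table.groupby("year"):
            grid = np.zeros((n_rows, n_cols))
            grid[grp["row"], grp["col"]] = grp[src]
            idx = compute_neighbor_index(grid.astype(int), park_mask=park)
            vals[grp.index.to_numpy()] = idx[grp["row"], grp["col"]]
        out[dst] = vals
    return out


def _derive_outcome(table: pd.DataFrame) -> pd.DataFrame:
    """Outcome at year t = missed-or-managed indicator of the year t+1 rows.

    The final survey year has no successor, so its rows are dropped with a
    warning.
    """
    nxt = table[["pixel_id", "year", "I_missed", "I_managed"]].copy()
    nxt["year"] = nxt["year"] - 1
    nxt[OUTCOME] = ((nxt["I_missed"] + nxt["I_managed"]) > 0).astype(int)
    out = table.merge(
        nxt[["pixel_id", "year", OUTCOME]], on=["pixel_id", "year"], how="left"
    )
    dropped = int(out[OUTCOME].isna().sum())
    warnings.warn(
        f"outcome column derived by shifting indicators; {dropped} final-year "
        "rows dropped"
    )
    out = out.dropna(subset=[OUTCOME]).reset_index(drop=True)
    out[OUTCOME] = out[OUTCOME].astype(int)
    return out


def read_survey_csv(path) -> pd.DataFrame:
    """Read and validate a long-format survey table.

    Missing IN columns are recomputed from the indicator maps when grid
    coordinates are present; a missing outcome column is derived by
    shifting the next year's indicators (losing the final year).
    """
    table = pd.read_csv(path)
    required = [c for c in SCHEMA if c not in OPTIONAL]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"survey CSV lacks required columns: {missing}")
    if "IN_missed" not in table.columns or "IN_managed" not in table.columns:
        table = _recompute_neighbor_indices(table)
    if OUTCOME not in table.columns:
        table = _derive_outcome(table)
    table = table[SCHEMA + [OUTCOME]]
    validate_survey_table(table)
    return table.sort_values(["year", "pixel_id"], kind="stable").reset_index(drop=True)


def write_survey_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in SCHEMA + [OUTCOME] if c in table.columns]
    table[cols].to_csv(path, index=False)
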