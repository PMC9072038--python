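"""Delimited-text I/O for panels, proximity structures, and results.

All files are comma-separated UTF-8 with a mandatory header and "." decimal
separator.  Output files carry comment header lines (prefixed ``#``) with
package version, seed, model tag, and fitted covariance parameters; a
``# created=`` timestamp line is excluded from determinism comparisons.
"""

from __future__ import annotations

import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import BalanceError, ValidationError
from .panel import AreaPanel, ProximityMatrix

__all__ = [
    "read_panel",
    "write_panel",
    "read_proximity",
    "write_proximity",
    "write_results",
    "output_header",
]

_PANEL_FIXED_COLS = ("area_id", "time", "y", "var_y")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        comment="#",
        dtype={"area_id": str, "time": str},
        float_precision="round_trip",
    )


def read_panel(path: str | Path) -> AreaPanel:
    """Read a balanced panel file (columns area_id, time, y, var_y, x1..xp).

    Rows may appear in any order; the panel is stored area-major,
    time-minor with areas in first-appearance order and times sorted.
    """
    df = _read_csv(path)
    missing = [c for c in _PANEL_FIXED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"panel file missing columns {missing}")
    xcols = [c for c in df.columns if c not in _PANEL_FIXED_COLS]
    if not xcols:
        raise ValidationError("panel file has no covariate columns")

    dup = df.duplicated(subset=["area_id", "time"])
    if dup.any():
        pairs = df.loc[dup, ["area_id", "time"]].values.tolist()
        raise ValidationError(f"duplicate (area, time) rows: {pairs[:5]}")

    bad_var = df.index[~(df["var_y"] > 0)].tolist()
    if bad_var:
        raise ValidationError(
            f"var_y must be > 0; offending data rows (0-based): {bad_var}"
        )

    area_ids = list(dict.fromkeys(df["area_id"]))
    time_ids = sorted(set(df["time"]))
    m, T = len(area_ids), len(time_ids)

    expected = {(a, t) for a in area_ids for t in time_ids}
    present = set(zip(df["area_id"], df["time"]))
    absent = sorted(expected - present)
    if absent:
        raise BalanceError(f"panel not balanced; missing cells: {absent[:10]}")

    df = df.set_index(["area_id", "time"])
    order = pd.MultiIndex.from_product([area_ids, time_ids])
    df = df.loc[order]
    y = df["y"].to_numpy().reshape(m, T)
    D = df["var_y"].to_numpy().reshape(m, T)
    X = df[xcols].to_numpy(dtype=float)
    return AreaPanel(area_ids=area_ids, time_ids=time_ids, y=y, D=D, X=X)


def output_header(
    version: str,
    seed: int | None = None,
    model_tag: str | None = None,
    tau: np.ndarray | None = None,
    timestamp: bool = True,
) -> str:
    lines = [f"# stfh version={version}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if model_tag is not None:
        lines.append(f"# model={model_tag}")
    if tau is not None:
        vals = ",".join(f"{v:.10g}" for v in np.asarray(tau).ravel())
        lines.append(f"# tau_hat={vals}")
    if timestamp:
        lines.append(f"# created={datetime.now(timezone.utc).isoformat()}")
    return "\n".join(lines) + "\n"


def _write_with_header(df: pd.DataFrame, path: str | Path, header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_panel(panel: AreaPanel, path: str | Path, header: str = "") -> None:
    m, T, p = panel.m, panel.T, panel.p
    df = pd.DataFrame(
        {
            "area_id": np.repeat(panel.area_ids, T),
            "time": np.tile(panel.time_ids, m),
            "y": panel.y_stacked,
            "var_y": panel.D_stacked,
        }
    )
    for j in range(p):
        df[f"x{j+1}"] = panel.X[:, j]
    _write_with_header(df, path, header)


def read_proximity(path: str | Path, area_ids: list[str]) -> ProximityMatrix:
    """Read a proximity file and align it to the panel's area order.

    Two dialects, auto-detected from the header: a dense matrix file whose
    first column is ``area_id`` and remaining columns are area ids, or a
    two-column neighbor list (``area_id,neighbor_id``).  Neighbor lists are
    symmetrized with a warning if a pair is listed one-way.  The adjacency
    is row-standardized after alignment.
    """
    df = _read_csv(path)
    area_ids = [str(a) for a in area_ids]
    cols = list(df.columns)
    if cols[:2] == ["area_id", "neighbor_id"] and len(cols) == 2:
        A = _adjacency_from_pairs(df, area_ids)
    elif cols[0] == "area_id":
        A = _adjacency_from_dense(df, area_ids)
    else:
        raise ValidationError(
            "proximity file must be a dense matrix (first column 'area_id') "
            "or a neighbor list with columns area_id,neighbor_id"
        )
    if np.any(A.sum(axis=1) == 0):
        iso = [area_ids[i] for i in np.where(A.sum(axis=1) == 0)[0]]
        raise ValidationError(f"isolated areas with no neighbors: {iso}")
    return ProximityMatrix.from_adjacency(A, area_ids)


def _adjacency_from_pairs(df: pd.DataFrame, area_ids: list[str]) -> np.ndarray:
    index = {a: i for i, a in enumerate(area_ids)}
    m = len(area_ids)
    A = np.zeros((m, m))
    for a, b in zip(df["area_id"].astype(str), df["neighbor_id"].astype(str)):
        if a not in index or b not in index:
            unknown = a if a not in index else b
            raise ValidationError(f"proximity references unknown area id {unknown!r}")
        if a == b:
            raise ValidationError(f"self-neighbor listed for area {a!r}")
        A[index[a], index[b]] = 1.0
    if not np.array_equal(A, A.T):
        warnings.warn(
            "neighbor list is not symmetric; symmetrizing", stacklevel=2
        )
        A = np.maximum(A, A.T)
    return A


def _adjacency_from_dense(df: pd.DataFrame, area_ids: list[str]) -> np.ndarray:
    file_ids = [str(a) for a in df["area_id"]]
    col_ids = [c for c in df.columns if c != "area_id"]
    if set(file_ids) != set(col_ids):
        raise ValidationError("dense proximity file: row and column ids differ")
    unknown = set(area_ids) - set(file_ids)
    if unknown:
        raise ValidationError(f"panel areas missing from proximity file: {sorted(unknown)}")
    extra = set(file_ids) - set(area_ids)
    if extra:
        raise ValidationError(f"proximity file areas absent from panel: {sorted(extra)}")
    df = df.set_index("area_id")
    A = df.loc[area_ids, area_ids].to_numpy(dtype=float)
    np.fill_diagonal(A, 0.0)
    if not np.allclose(A, A.T):
        raise ValidationError("dense proximity matrix must be symmetric")
    return A


def write_proximity(W: ProximityMatrix, path: str | Path, header: str = "") -> None:
    """Write the raw (un-standardized) adjacency as a dense matrix file."""
    df = pd.DataFrame(W.adjacency, columns=W.area_ids)
    df.insert(0, "area_id", W.area_ids)
    _write_with_header(df, path, header)


def write_results(table: pd.DataFrame, path: str | Path, header: str = "") -> None:
    _write_with_header(table, path, header)
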