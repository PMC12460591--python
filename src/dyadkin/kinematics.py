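"""Finite-difference kinematics: velocity, acceleration, jerk.

Derivatives are first-order backward differences on the frame grid with
Δt = 1/fps, so velocity is in pixels/second, acceleration in
pixels/second², jerk in pixels/second³.  Two modes are supported per the
usual convention in pose kinematics:

``axis_wise``
    Each axis differenced separately: ``v[i] = (p[i] - p[i-1]) / Δt``
    giving signed ``v_x{k}`` / ``v_y{k}`` columns (likewise ``a_``, ``j_``).

``euclidean``
    The magnitude of the two-axis difference vector:
    ``v[i] = sqrt((x[i]-x[i-1])² + (y[i]-y[i-1])²) / Δt`` in a ``v_{k}``
    column.  Higher derivatives difference the retained *axis components*
    (``a[i] = sqrt((vx[i]-vx[i-1])² + (vy[i]-vy[i-1])²) / Δt``), which is
    not the same as differencing the speed magnitude itself — the axis
    components are therefore kept alongside the magnitudes.

The first frame of each (person, region) group has no predecessor, so
derivative columns start as missing there; any missing operand yields a
missing derivative rather than a guess.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DyadTable

__all__ = [
    "compute_velocity",
    "compute_acceleration",
    "compute_jerk",
    "trim_undefined_rows",
]

MODES = ("axis_wise", "euclidean")


def _diff(values: np.ndarray, dt: float) -> np.ndarray:
    """Backward difference / dt with NaN at index 0."""
    out = np.full_like(values, np.nan, dtype=float)
    out[1:] = (values[1:] - values[:-1]) / dt
    return out


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _derive(
    table: DyadTable,
    mode: str,
    src_x_fmt: str,
    src_y_fmt: str,
    out_prefix: str,
    fps: float | None,
) -> DyadTable:
    """Shared difference step: read axis sources, write `out_prefix` columns."""
    fps = table.fps if fps is None else float(fps)
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    dt = 1.0 / fps
    out = table.copy()
    df = out.df
    new_cols: dict[str, np.ndarray] = {}
    for col in _output_columns(table, mode, out_prefix):
        new_cols[col] = np.full(len(df), np.nan)

    for (_, _), sub in table.group_iter():
        order = sub.index
        for k in table.keypoint_indices():
            sx, sy = src_x_fmt.format(k=k), src_y_fmt.format(k=k)
            if sx not in sub.columns or sub[sx].isna().all():
                continue
            dx = _diff(sub[sx].to_numpy(dtype=float), dt)
            dy = _diff(sub[sy].to_numpy(dtype=float), dt)
            new_cols[f"{out_prefix}_x{k}"][df.index.get_indexer(order)] = dx
            new_cols[f"{out_prefix}_y{k}"][df.index.get_indexer(order)] = dy
            if mode == "euclidean":
                new_cols[f"{out_prefix}_{k}"][df.index.get_indexer(order)] = np.hypot(dx, dy)

    for col, vals in new_cols.items():
        df[col] = vals
    return out


def _output_columns(table: DyadTable, mode: str, prefix: str) -> list[str]:
    cols = []
    for k in table.keypoint_indices():
        cols.append(f"{prefix}_x{k}")
        cols.append(f"{prefix}_y{k}")
        if mode == "euclidean":
            cols.append(f"{prefix}_{k}")
    return cols


def compute_velocity(
    table: DyadTable, fps: float | None = None, mode: str = "euclidean"
) -> DyadTable:
    """Add per-keypoint velocity columns (``v_`` prefix) to the table.

    ``fps`` defaults to the table's own frame rate.  In euclidean mode the
    magnitude ``v_{k}`` is emitted together with the signed components
    ``v_x{k}`` / ``v_y{k}``, which the euclidean acceleration needs.
    """
    _check_mode(mode)
    out = _derive(table, mode, "x{k}", "y{k}", "v", fps)
    out.events.append(f"velocity ({mode})")
    return out


def compute_acceleration(
    table: DyadTable, fps: float | None = None, mode: str = "euclidean"
) -> DyadTable:
    """Add acceleration columns (``a_`` prefix); requires velocity columns."""
    _check_mode(mode)
    _require_prefix(table, "v", mode, "compute_velocity")
    out = _derive(table, mode, "v_x{k}", "v_y{k}", "a", fps)
    out.events.append(f"acceleration ({mode})")
    return out


def compute_jerk(
    table: DyadTable, fps: float | None = None, mode: str = "euclidean"
) -> DyadTable:
    """Add jerk columns (``j_`` prefix); requires acceleration columns."""
    _check_mode(mode)
    _require_prefix(table, "a", mode, "compute_acceleration")
    out = _derive(table, mode, "a_x{k}", "a_y{k}", "j", fps)
    out.events.append(f"jerk ({mode})")
    return out


def _require_prefix(table: DyadTable, prefix: str, mode: str, producer: str) -> None:
    needed = [f"{prefix}_x{k}" for k in table.keypoint_indices()]
    if not any(c in table.df.columns for c in needed):
        raise ValueError(
            f"no {prefix}_ axis columns present; run {producer} first "
            "(euclidean higher derivatives difference the axis components)"
        )


def trim_undefined_rows(table: DyadTable, prefix: str = "v") -> DyadTable:
    """Drop leading rows whose derivative columns are all missing.

    Each group's first frame has no defined derivative; exports of
    kinematic tables conventionally start at the second frame.
    """
    out = table.copy()
    df = out.df
    deriv_cols = [c for c in df.columns if c.startswith(f"{prefix}_")]
    if not deriv_cols:
        return out
    keep = ~df[deriv_cols].isna().all(axis=1)
    # only drop the *leading* undefined row(s) of each group, not interior gaps
    first_frames = df.groupby(["person", "region"])["frame"].transform("min")
    out.df = df[keep | (df["frame"] != first_frames)].reset_index(drop=True)
    return out
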