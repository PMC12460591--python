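"""OpenPose JSON ingestion and CSV / rMEA export.

OpenPose writes one JSON file per video frame, each with a ``people``
array whose entries hold flat ``[x, y, c, x, y, c, ...]`` keypoint arrays
per region.  This module parses those files, assembles whole recordings
into :class:`~dyadkin.core.DyadTable` objects with stable left/right
identities, and writes the long-format CSVs (and rMEA-style motion-energy
text files) used downstream.

At ingestion the ``(0, 0, 0)`` missed-detection sentinel becomes NaN
coordinates with confidence 0, so later stages can treat missingness
uniformly.  Zero-confidence triplets with non-zero coordinates are kept
but counted in the table's event log.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DyadTable,
    FrameRecord,
    GapReport,
    PersonDetection,
    metadata_columns,
    split_triplet_column,
)
from .identity import IdentityPolicy, assign
from .keypoints import (
    BODY_25_NAMES,
    DEFAULT_FPS,
    DEFAULT_FRAME_WIDTH,
    METADATA_COLUMNS,
    REGION_JSON_KEYS,
    REGION_MODELS,
    triplet_columns,
)

__all__ = [
    "parse_frame_file",
    "scan_recording",
    "build_dyad_table",
    "write_dyad_csv",
    "read_dyad_csv",
    "batch_convert",
    "apply_keypoint_labels",
    "strip_keypoint_labels",
    "export_rmea",
]

_FRAME_INDEX_RE = re.compile(r"(\d+)_keypoints\.json$")

ALL_REGIONS = frozenset(REGION_MODELS)


class OpenPoseParseError(ValueError):
    """Raised when a frame file is not valid OpenPose JSON."""


class OpenPoseSchemaError(ValueError):
    """Raised when keypoint arrays do not match a known region model."""


def frame_index_from_filename(name: str) -> int | None:
    """Zero-padded frame counter before ``_keypoints.json``, or None."""
    m = _FRAME_INDEX_RE.search(name)
    return int(m.group(1)) if m else None


def parse_frame_file(
    path: str | Path, regions: set[str] | frozenset[str] = frozenset({"body"})
) -> FrameRecord:
    """Parse one per-frame OpenPose JSON file.

    Parameters
    ----------
    path
        File whose name ends in the zero-padded frame counter plus
        ``_keypoints.json``.
    regions
        Regions to extract (subset of body / face / hand_left /
        hand_right).  Regions absent from the file are simply absent from
        the detection's payloads.

    Raises
    ------
    OpenPoseParseError
        Malformed JSON.
    OpenPoseSchemaError
        A keypoint array whose length is not 3 x the region's model size.
    """
    path = Path(path)
    unknown = set(regions) - ALL_REGIONS
    if unknown:
        raise ValueError(f"unknown regions {sorted(unknown)}; known: {sorted(ALL_REGIONS)}")
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise OpenPoseParseError(f"{path.name}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "people" not in payload:
        raise OpenPoseParseError(f"{path.name}: missing 'people' array")

    detections: list[PersonDetection] = []
    for i, person in enumerate(payload["people"]):
        region_payloads: dict[str, np.ndarray] = {}
        for region in sorted(regions):
            raw = person.get(REGION_JSON_KEYS[region])
            if raw is None or len(raw) == 0:
                continue
            if len(raw) % 3 != 0:
                raise OpenPoseSchemaError(
                    f"{path.name}: person {i} region {region!r} has {len(raw)} "
                    "values, not divisible by 3"
                )
            n = len(raw) // 3
            if n != REGION_MODELS[region]:
                raise OpenPoseSchemaError(
                    f"{path.name}: person {i} region {region!r} has {n} keypoints; "
                    f"expected {REGION_MODELS[region]}"
                )
            region_payloads[region] = np.asarray(raw, dtype=float).reshape(n, 3)
        pid = person.get("person_id")
        if isinstance(pid, list):
            pid = pid[0] if pid else None
        if pid == -1:
            pid = None
        detections.append(
            PersonDetection(detector_index=i, region_payloads=region_payloads, person_id=pid)
        )

    frame_index = frame_index_from_filename(path.name)
    return FrameRecord(
        frame_index=-1 if frame_index is None else frame_index,
        source_filename=path.name,
        detections=detections,
    )


def scan_recording(
    directory: str | Path, regions: set[str] | frozenset[str] = frozenset({"body"})
) -> tuple[list[FrameRecord], GapReport]:
    """Parse every ``*_keypoints.json`` in a directory, sorted by frame index.

    The result is a pure function of directory contents: files are ordered
    by their parsed frame counter (falling back to lexicographic rank,
    with a warning, for files without one), never by filesystem
    enumeration order.  The gap report lists frame indices missing between
    the minimum and maximum observed.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*_keypoints.json"))
    if not files:
        raise FileNotFoundError(f"no frames found: no *_keypoints.json files in {directory}")

    report = GapReport()
    records: list[FrameRecord] = []
    for rank, f in enumerate(files):
        rec = parse_frame_file(f, regions)
        if rec.frame_index < 0:
            warnings.warn(
                f"{f.name}: no zero-padded frame counter; using lexicographic rank {rank}",
                stacklevel=2,
            )
            rec.frame_index = rank
            report.unindexed_files.append(f.name)
        records.append(rec)
    records.sort(key=lambda r: r.frame_index)

    present = {r.frame_index for r in records}
    lo, hi = min(present), max(present)
    report.missing_frames = [i for i in range(lo, hi + 1) if i not in present]
    return records, report


def _select_dyad(
    detections: list[PersonDetection], frame: int, report: GapReport | None
) -> list[PersonDetection]:
    """Keep at most the two detections with highest mean body confidence."""
    if len(detections) <= 2:
        return detections
    if report is not None:
        report.extra_detection_events.append((frame, len(detections)))
    ranked = sorted(
        detections, key=lambda d: (-d.mean_confidence("body"), d.detector_index)
    )
    return sorted(ranked[:2], key=lambda d: d.detector_index)


def build_dyad_table(
    frames: list[FrameRecord],
    policy: IdentityPolicy | str = "midline",
    frame_width: int | None = None,
    fps: float | None = None,
    report: GapReport | None = None,
) -> DyadTable:
    """Assemble parsed frames into a long-format dyad table.

    Each frame contributes at most one left and one right row per region;
    frames between the recording's first and last index that are missing
    or empty contribute sentinel rows (NaN coordinates, confidence 0) so
    every (person, region) series shares a complete, strictly increasing
    frame base.

    ``frame_width`` defaults to 1,920 px and ``fps`` to 30 (both with a
    warning), matching common full-HD recordings; fps in particular must
    be supplied by the user because OpenPose JSON does not store it.
    """
    if not frames:
        raise ValueError("no frames to assemble")
    if frame_width is None:
        frame_width = DEFAULT_FRAME_WIDTH
        if isinstance(policy, str) and policy == "midline" or (
            isinstance(policy, IdentityPolicy) and policy.mode == "midline"
        ):
            warnings.warn(
                f"frame_width not supplied; defaulting to {DEFAULT_FRAME_WIDTH} px",
                stacklevel=2,
            )
    if fps is None:
        fps = DEFAULT_FPS
        warnings.warn(f"fps not supplied; defaulting to {DEFAULT_FPS}", stacklevel=2)
    if isinstance(policy, str):
        policy = IdentityPolicy(mode=policy, frame_width=frame_width)

    regions = sorted(
        {r for rec in frames for det in rec.detections for r in det.region_payloads}
    ) or ["body"]
    max_k = max(REGION_MODELS[r] for r in regions)
    value_cols = triplet_columns(max_k)

    events: list[str] = []
    by_index = {rec.frame_index: rec for rec in frames}
    lo = min(by_index)
    hi = max(by_index)

    rows: list[dict] = []
    n_flagged_zero_conf = 0
    for frame in range(lo, hi + 1):
        rec = by_index.get(frame)
        base = rec.source_filename if rec is not None else ""
        detections = _select_dyad(rec.detections, frame, report) if rec is not None else []
        labels = assign(detections, policy)
        by_side = {side: det for det in detections if (side := labels.get(det.detector_index))}
        for region in regions:
            n_k = REGION_MODELS[region]
            for person in ("left", "right"):
                det = by_side.get(person)
                payload = det.region_payloads.get(region) if det is not None else None
                row: dict = {
                    "base_filename": base,
                    "frame": frame,
                    "region": region,
                    "person": person,
                }
                if payload is None:
                    for col in value_cols:
                        kind, k = split_triplet_column(col)  # type: ignore[misc]
                        row[col] = 0.0 if kind == "c" and k < n_k else np.nan
                else:
                    for k in range(n_k):
                        x, y, c = payload[k]
                        if c == 0.0 and x == 0.0 and y == 0.0:
                            row[f"x{k}"], row[f"y{k}"], row[f"c{k}"] = np.nan, np.nan, 0.0
                        else:
                            if c == 0.0:
                                n_flagged_zero_conf += 1
                            row[f"x{k}"], row[f"y{k}"], row[f"c{k}"] = x, y, c
                    for k in range(n_k, max_k):
                        row[f"x{k}"] = row[f"y{k}"] = row[f"c{k}"] = np.nan
                rows.append(row)

    if n_flagged_zero_conf:
        events.append(
            f"{n_flagged_zero_conf} zero-confidence triplets with non-zero "
            "coordinates kept"
        )
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + value_cols)
    df = df.sort_values(["region", "person", "frame"]).reset_index(drop=True)
    return DyadTable(df=df, fps=float(fps), frame_width=int(frame_width), events=events)


def _maybe_label(df: pd.DataFrame) -> pd.DataFrame:
    renames = _body_label_map(df.columns)
    return df.rename(columns=renames)


def write_dyad_csv(
    table: DyadTable,
    path: str | Path,
    export_type: str = "dyad",
    include_filename: bool = True,
    include_labels: bool = False,
) -> list[Path]:
    """Write the table as CSV.

    ``export_type='dyad'`` writes a single file with both persons;
    ``'individual'`` writes one file per person with ``_left`` / ``_right``
    suffixes.  Column order is metadata followed by triplets in ascending
    keypoint index.  Numbers are written at full repr precision so the
    file round-trips losslessly through :func:`read_dyad_csv`.
    """
    if table.df.empty:
        raise ValueError("refusing to write an empty dyad table")
    if export_type not in ("dyad", "individual"):
        raise ValueError(f"export_type must be 'dyad' or 'individual', got {export_type!r}")
    path = Path(path)
    df = table.df
    if not include_filename:
        df = df.drop(columns=["base_filename"])
    if include_labels:
        df = _maybe_label(df)

    written: list[Path] = []
    if export_type == "dyad":
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    else:
        for person in ("left", "right"):
            sub = df[df["person"] == person]
            if sub.empty:
                continue
            out = path.with_name(f"{path.stem}_{person}{path.suffix or '.csv'}")
            out.parent.mkdir(parents=True, exist_ok=True)
            sub.to_csv(out, index=False, float_format="%.17g")
            written.append(out)
    return written


def read_dyad_csv(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    frame_width: int = DEFAULT_FRAME_WIDTH,
) -> DyadTable:
    """Read a CSV written by :func:`write_dyad_csv` back into a DyadTable."""
    df = pd.read_csv(path, float_precision="round_trip")
    df = strip_keypoint_labels_df(df)
    if "base_filename" not in df.columns:
        df.insert(0, "base_filename", "")
    value_cols = [c for c in df.columns if split_triplet_column(c) or c.split("_")[0] in "vaj"]
    df[value_cols] = df[value_cols].astype(float)
    return DyadTable(df=df, fps=fps, frame_width=frame_width)


def batch_convert(
    input_base: str | Path,
    output_base: str | Path,
    regions: set[str] | frozenset[str] = frozenset({"body"}),
    policy: str = "midline",
    frame_width: int | None = None,
    fps: float | None = None,
    export_type: str = "dyad",
    include_filename: bool = True,
    include_labels: bool = False,
) -> dict:
    """Convert every sub-folder of JSON frames under ``input_base`` to CSV.

    Each sub-folder is treated as one dyad recording and processed
    independently; a failure in one is logged in the returned manifest and
    does not abort the rest.  The manifest is also written to
    ``output_base/manifest.json``.
    """
    input_base = Path(input_base)
    output_base = Path(output_base)
    subdirs = sorted(p for p in input_base.iterdir() if p.is_dir())
    if not subdirs:
        raise FileNotFoundError(f"no dyad sub-folders under {input_base}")
    output_base.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"dyads": {}, "n_ok": 0, "n_failed": 0}
    for sub in subdirs:
        entry: dict = {"status": "ok"}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                records, report = scan_recording(sub, regions)
                table = build_dyad_table(
                    records, policy=policy, frame_width=frame_width, fps=fps, report=report
                )
            files = write_dyad_csv(
                table,
                output_base / f"{sub.name}.csv",
                export_type=export_type,
                include_filename=include_filename,
                include_labels=include_labels,
            )
            entry["n_frames"] = len(records)
            entry["missing_frames"] = report.missing_frames
            entry["outputs"] = [f.name for f in files]
            manifest["n_ok"] += 1
        except Exception as exc:  # isolation contract: log and continue
            entry = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            manifest["n_failed"] += 1
        manifest["dyads"][sub.name] = entry

    (output_base / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _body_label_map(columns) -> dict[str, str]:
    """Map ``x0 -> nose_x`` etc. for indexed columns within BODY_25 range."""
    renames: dict[str, str] = {}
    for col in columns:
        parsed = split_triplet_column(col)
        if parsed is None:
            continue
        kind, k = parsed
        if k < len(BODY_25_NAMES):
            renames[col] = f"{BODY_25_NAMES[k]}_{kind}"
    return renames


def apply_keypoint_labels(table: DyadTable) -> DyadTable:
    """Rename indexed triplet columns to descriptive BODY_25 names.

    ``x0, y0, c0`` become ``nose_x, nose_y, nose_c`` and so on.  The
    rename is bijective and reversible via :func:`strip_keypoint_labels`,
    and applying it twice is a no-op.  Indexed columns beyond the BODY_25
    range (face or hand tables) have no descriptive names and raise.
    """
    df = table.df
    label_set = {f"{n}_{kind}" for n in BODY_25_NAMES for kind in "xyc"}
    offending = []
    renames: dict[str, str] = {}
    for col in df.columns:
        if col in METADATA_COLUMNS or col in label_set:
            continue
        parsed = split_triplet_column(col)
        if parsed is None:
            offending.append(col)
            continue
        kind, k = parsed
        if k >= len(BODY_25_NAMES):
            offending.append(col)
            continue
        renames[col] = f"{BODY_25_NAMES[k]}_{kind}"
    if offending:
        raise ValueError(
            "columns without a BODY_25 descriptive name: " + ", ".join(offending)
        )
    out = table.copy()
    out.df = df.rename(columns=renames)
    return out


def strip_keypoint_labels_df(df: pd.DataFrame) -> pd.DataFrame:
    inverse = {
        f"{name}_{kind}": f"{kind}{k}"
        for k, name in enumerate(BODY_25_NAMES)
        for kind in "xyc"
    }
    return df.rename(columns=inverse)


def strip_keypoint_labels(table: DyadTable) -> DyadTable:
    """Inverse of :func:`apply_keypoint_labels`; restores ``x0..c24``."""
    out = table.copy()
    out.df = strip_keypoint_labels_df(table.df)
    return out


def export_rmea(
    energy_left,
    energy_right,
    out_dir: str | Path,
    dyad_id: str,
    group: str = "all",
    sampling_rate: float = DEFAULT_FPS,
) -> Path:
    """Write a motion-energy pair as rMEA-style plain text.

    rMEA (an R toolkit for motion-energy synchrony) imports per-dyad,
    headerless delimited text with one column per person.  The file is
    named ``<dyadID>_<group>.txt`` (left column first) and a JSON sidecar
    ``<dyadID>_<group>.manifest.json`` records the sampling rate.
    """
    left = np.asarray(energy_left, dtype=float)
    right = np.asarray(energy_right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError(
            f"energy series must be equal-length 1-D, got {left.shape} and {right.shape}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{dyad_id}_{group}.txt"
    np.savetxt(path, np.column_stack((left, right)), delimiter=",", fmt="%.17g")
    sidecar = out_dir / f"{dyad_id}_{group}.manifest.json"
    sidecar.write_text(
        json.dumps(
            {"dyad_id": dyad_id, "group": group, "sampling_rate_hz": sampling_rate,
             "n_samples": int(left.size), "columns": ["left", "right"]},
            indent=2,
        )
    )
    return path


def read_rmea(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an rMEA-style file back into (left, right) arrays."""
    df = pd.read_csv(path, header=None, float_precision="round_trip")
    return df[0].to_numpy(dtype=float), df[1].to_numpy(dtype=float)
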