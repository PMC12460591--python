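"""Core containers shared across the pipeline.

The central exchange type is :class:`DyadTable`: a long-format
:class:`pandas.DataFrame` keyed by (base_filename, frame, region, person)
whose remaining columns are the per-keypoint ``x{k}, y{k}, c{k}`` triplets,
plus the recording metadata (frames per second and frame width) needed to
turn pixel displacements into rates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .keypoints import METADATA_COLUMNS, REGION_MODELS


@dataclass(frozen=True)
class KeypointTriplet:
    """One detected landmark: pixel coordinates and detector confidence.

    ``(0, 0, 0)`` is OpenPose's sentinel for a missed detection.
    """

    x: float
    y: float
    c: float

    @property
    def is_missing(self) -> bool:
        return self.c == 0.0 and self.x == 0.0 and self.y == 0.0


@dataclass
class PersonDetection:
    """All keypoint payloads for one entry of a frame's ``people`` array.

    ``region_payloads`` maps a region name to an ``(K, 3)`` float array of
    (x, y, c) rows, with K fixed by the region's model (body 25, face 70,
    hands 21 each).
    """

    detector_index: int
    region_payloads: dict[str, np.ndarray]
    person_id: int | None = None

    def mean_confidence(self, region: str = "body") -> float:
        payload = self.region_payloads.get(region)
        if payload is None or payload.size == 0:
            return 0.0
        return float(np.mean(payload[:, 2]))

    def mean_x(self, region: str = "body") -> float:
        """Mean x over confident (c > 0) keypoints; NaN when none are."""
        payload = self.region_payloads.get(region)
        if payload is None or payload.size == 0:
            return float("nan")
        mask = payload[:, 2] > 0
        if not mask.any():
            return float("nan")
        return float(np.mean(payload[mask, 0]))


@dataclass
class FrameRecord:
    """Every detection parsed from one per-frame JSON file."""

    frame_index: int
    source_filename: str
    detections: list[PersonDetection] = field(default_factory=list)


@dataclass
class GapReport:
    """Diagnostics accumulated while assembling a recording."""

    missing_frames: list[int] = field(default_factory=list)
    unindexed_files: list[str] = field(default_factory=list)
    extra_detection_events: list[tuple[int, int]] = field(default_factory=list)
    #: (frame, n_detections) for frames that had more than two people

    @property
    def has_gaps(self) -> bool:
        return bool(self.missing_frames)


_TRIPLET_COL = re.compile(r"^([xyc])(\d+)$")


@dataclass
class DyadTable:
    """Long-format dyad keypoint table plus recording metadata.

    One row per (frame, person, region); triplet columns ``x0, y0, c0, ...``
    up to the largest keypoint count among the regions present.  Regions
    with fewer keypoints leave the surplus columns as NaN.  Missing
    detections are NaN coordinates with confidence 0.
    """

    df: pd.DataFrame
    fps: float
    frame_width: int
    events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.frame_width <= 0:
            raise ValueError(f"frame_width must be positive, got {self.frame_width}")

    @property
    def dt(self) -> float:
        """Seconds between consecutive frames."""
        return 1.0 / self.fps

    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    @property
    def persons(self) -> list[str]:
        return sorted(self.df["person"].unique())

    def triplet_columns(self) -> list[str]:
        """Value columns in (x, y, c) * keypoint order, metadata excluded."""
        return [c for c in self.df.columns if _TRIPLET_COL.match(c)]

    def keypoint_indices(self) -> list[int]:
        """Sorted keypoint indices present as columns."""
        idx = {int(m.group(2)) for c in self.df.columns if (m := _TRIPLET_COL.match(c))}
        return sorted(idx)

    def n_keypoints(self, region: str) -> int:
        return REGION_MODELS[region]

    def copy(self) -> "DyadTable":
        return DyadTable(self.df.copy(), self.fps, self.frame_width, list(self.events))

    def group_iter(self):
        """Yield ((person, region), sub-frame sorted by frame) pairs."""
        for key, sub in self.df.groupby(["person", "region"], sort=True):
            yield key, sub.sort_values("frame")


def split_triplet_column(name: str) -> tuple[str, int] | None:
    """``'x12' -> ('x', 12)``; None when the name is not a triplet column."""
    m = _TRIPLET_COL.match(name)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def metadata_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in METADATA_COLUMNS if c in df.columns]
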