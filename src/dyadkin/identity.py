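"""Left/right dyad identity assignment.

Two per-frame policies are supported:

``midline``
    Each detection is labelled by its mean x-coordinate (over confident
    body keypoints) relative to half the frame width.  This suits
    split-screen recordings where the two people keep to their own side
    of the frame.  It is a pure per-frame rule: no temporal smoothing is
    applied, so side swaps show up in the consistency report rather than
    being silently corrected.

``openpose_order``
    The detector's own ``people``-array ordering is trusted: index 0 is
    left, index 1 is right, regardless of where the people actually are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DyadTable, PersonDetection
from .keypoints import DEFAULT_FRAME_WIDTH


@dataclass(frozen=True)
class IdentityPolicy:
    """User-selectable dyad labelling rule."""

    mode: str = "midline"
    frame_width: int = DEFAULT_FRAME_WIDTH

    def __post_init__(self) -> None:
        if self.mode not in ("midline", "openpose_order"):
            raise ValueError(
                f"identity policy must be 'midline' or 'openpose_order', got {self.mode!r}"
            )
        if self.mode == "midline" and self.frame_width <= 0:
            raise ValueError("frame_width must be positive under the midline policy")


def assign_midline(
    detections: list[PersonDetection], frame_width: int = DEFAULT_FRAME_WIDTH
) -> dict[int, str]:
    """Label each detection left/right by mean x relative to the screen centre.

    The mean is taken over body keypoints with confidence > 0 only.
    Detections with no confident body keypoint are unassignable and are
    omitted from the returned map (with a warning).  When both detections
    fall on the same side of the midline — or tie exactly on it — they are
    ranked by mean x (smaller x becomes left) and a warning is issued,
    since the split-screen assumption is then violated.

    Returns a map from ``detector_index`` to ``"left"`` / ``"right"``.
    """
    scored: list[tuple[float, int]] = []
    for det in detections:
        mx = det.mean_x("body")
        if np.isnan(mx):
            warnings.warn(
                f"detection {det.detector_index} has no confident body keypoint; "
                "cannot assign a side",
                stacklevel=2,
            )
            continue
        scored.append((mx, det.detector_index))

    if not scored:
        return {}
    midline = frame_width / 2.0
    if len(scored) == 1:
        mx, idx = scored[0]
        return {idx: "left" if mx < midline else "right"}

    scored.sort()
    (mx0, i0), (mx1, i1) = scored[:2]
    same_side = (mx0 < midline) == (mx1 < midline) or mx0 == midline or mx1 == midline
    if same_side:
        warnings.warn(
            "both detections fall on the same side of the midline "
            f"(mean x {mx0:.1f}, {mx1:.1f}; midline {midline:.1f}); "
            "labelling by x rank",
            stacklevel=2,
        )
    return {i0: "left", i1: "right"}


def assign_openpose_order(detections: list[PersonDetection]) -> dict[int, str]:
    """Label by the detector's array order: index 0 left, index 1 right."""
    out: dict[int, str] = {}
    for det in sorted(detections, key=lambda d: d.detector_index)[:2]:
        out[det.detector_index] = "left" if len(out) == 0 else "right"
    return out


def assign(
    detections: list[PersonDetection], policy: IdentityPolicy
) -> dict[int, str]:
    if policy.mode == "midline":
        return assign_midline(detections, policy.frame_width)
    return assign_openpose_order(detections)


def identity_consistency_report(table: DyadTable) -> pd.DataFrame:
    """Flag frames where a person's mean x crosses the recording midline.

    Intended for tables built under the midline policy: a crossing means
    the per-frame rule may have swapped the two people.  Returns one row
    per flagged (person, frame) with the mean x before and after, plus
    run-length bookkeeping so sustained swaps are distinguishable from
    single-frame jitter.
    """
    midline = table.frame_width / 2.0
    rows = []
    body = table.df[table.df["region"] == "body"]
    x_cols = [c for c in table.triplet_columns() if c.startswith("x")]
    c_cols = [c for c in table.triplet_columns() if c.startswith("c")]
    for person, sub in body.groupby("person"):
        sub = sub.sort_values("frame")
        xs = sub[x_cols].to_numpy(dtype=float)
        cs = sub[c_cols].to_numpy(dtype=float)
        conf = np.nan_to_num(cs) > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_x = np.nanmean(np.where(conf, xs, np.nan), axis=1)
        frames = sub["frame"].to_numpy()
        side = np.where(np.isnan(mean_x), -1, (mean_x >= midline).astype(int))
        prev_side = None
        prev_x = np.nan
        for f, s, mx in zip(frames, side, mean_x):
            if s != -1 and prev_side is not None and prev_side != -1 and s != prev_side:
                rows.append(
                    {
                        "person": person,
                        "frame": int(f),
                        "mean_x_before": float(prev_x),
                        "mean_x_after": float(mx),
                    }
                )
            if s != -1:
                prev_side, prev_x = s, mx
    report = pd.DataFrame(rows, columns=["person", "frame", "mean_x_before", "mean_x_after"])
    if not report.empty:
        report = report.sort_values(["person", "frame"]).reset_index(drop=True)
    return report
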