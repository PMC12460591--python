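"""Keypoint-model constants for OpenPose 2D output.

OpenPose emits fixed-length keypoint arrays per region: 25 body points
(the BODY_25 model), 70 face points, and 21 points per hand.  Each point
is an (x, y, confidence) triplet in image coordinates (origin top-left,
y increasing downward).  The triplet (0, 0, 0) marks a missed detection.
"""

from __future__ import annotations

# region name -> keypoint count
REGION_MODELS: dict[str, int] = {
    "body": 25,
    "face": 70,
    "hand_left": 21,
    "hand_right": 21,
}

# region name -> key in the OpenPose JSON "people" entries
REGION_JSON_KEYS: dict[str, str] = {
    "body": "pose_keypoints_2d",
    "face": "face_keypoints_2d",
    "hand_left": "hand_left_keypoints_2d",
    "hand_right": "hand_right_keypoints_2d",
}

DEFAULT_FRAME_WIDTH = 1920  # pixels; the common full-HD recording width
DEFAULT_FPS = 30.0

# BODY_25 landmark names, index order as documented by OpenPose.
BODY_25_NAMES: tuple[str, ...] = (
    "nose",
    "neck",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "mid_hip",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
    "left_big_toe",
    "left_small_toe",
    "left_heel",
    "right_big_toe",
    "right_small_toe",
    "right_heel",
)

# Limb connections of the BODY_25 skeleton (pairs of keypoint indices).
BODY_25_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1),
    (1, 2), (2, 3), (3, 4),
    (1, 5), (5, 6), (6, 7),
    (1, 8),
    (8, 9), (9, 10), (10, 11),
    (8, 12), (12, 13), (13, 14),
    (0, 15), (15, 17),
    (0, 16), (16, 18),
    (14, 19), (19, 20), (14, 21),
    (11, 22), (22, 23), (11, 24),
)

#: Columns identifying a row of a dyad table; everything after them is triplets.
METADATA_COLUMNS: tuple[str, ...] = ("base_filename", "frame", "region", "person")

PERSONS: tuple[str, str] = ("left", "right")


def triplet_columns(n_keypoints: int) -> list[str]:
    """Column names ``x0, y0, c0, ..., x{K}, y{K}, c{K}`` for a region model."""
    cols: list[str] = []
    for k in range(n_keypoints):
        cols.extend((f"x{k}", f"y{k}", f"c{k}"))
    return cols
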