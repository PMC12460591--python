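import json

import numpy as np
import pandas as pd
import pytest

from dyadkin.core import DyadTable
from dyadkin.keypoints import METADATA_COLUMNS, triplet_columns


def make_table(
    data: dict[str, dict[int, tuple]],
    fps: float = 30.0,
    frame_width: int = 1920,
    region: str = "body",
    confidence: float = 1.0,
) -> DyadTable:
    """Build a DyadTable directly from per-person keypoint trajectories.

    ``data`` maps person -> {keypoint index -> (x_array, y_array)}.
    All series must share one length; frames are 0..n-1.
    """
    n = len(next(iter(next(iter(data.values())).values()))[0])
    max_k = max(k for kp in data.values() for k in kp) + 1
    rows = []
    for person, kps in data.items():
        for t in range(n):
            row = {"base_filename": "", "frame": t, "region": region, "person": person}
            for k in range(max_k):
                if k in kps:
                    x, y = kps[k]
                    row[f"x{k}"], row[f"y{k}"], row[f"c{k}"] = (
                        float(x[t]), float(y[t]), confidence,
                    )
                else:
                    row[f"x{k}"], row[f"y{k}"], row[f"c{k}"] = np.nan, np.nan, 0.0
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + triplet_columns(max_k))
    return DyadTable(df=df, fps=fps, frame_width=frame_width)


def write_body_frame(path, people_triplets):
    """Write one OpenPose body-model JSON file; ``people_triplets`` is a
    list of flat [x, y, c, ...] arrays (75 numbers each)."""
    payload = {
        "version": 1.3,
        "people": [{"person_id": [-1], "pose_keypoints_2d": list(map(float, p))}
                   for p in people_triplets],
    }
    path.write_text(json.dumps(payload))


def flat_person(x_offset: float, y_offset: float = 400.0, c: float = 0.9) -> list[float]:
    """A 25-keypoint person: points on a small grid around (x_offset, y_offset)."""
    out = []
    for k in range(25):
        out.extend((x_offset + 2.0 * k, y_offset + 3.0 * k, c))
    return out


@pytest.fixture
def two_person_dir(tmp_path):
    """Five-frame body recording: one person left (~400), one right (~1400)."""
    d = tmp_path / "dyad01"
    d.mkdir()
    for t in range(5):
        write_body_frame(
            d / f"dyad01_{t:012d}_keypoints.json",
            [flat_person(400.0 + t), flat_person(1400.0 + t)],
        )
    return d
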