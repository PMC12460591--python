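"""Synthetic dyad recordings in the OpenPose on-disk format.

Real two-person recordings cannot ship with the package, so every stage
is exercised against generated ones with known ground truth: two BODY_25
skeletons seated on opposite sides of the frame, moving as a sum of
sinusoidal components plus white Gaussian positional noise, optionally
coupled (a shared oscillation frequency with a fixed time lag between
the two people — the classic leader/follower structure synchrony
analyses should recover).  The writer then degrades the tracks the way a
detector would — per-sample Bernoulli dropout written as the (0, 0, 0)
sentinel, noisy confidence scores — and emits one zero-padded
``*_keypoints.json`` per frame, exactly the dialect the ingestion module
parses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .keypoints import BODY_25_NAMES, DEFAULT_FRAME_WIDTH, REGION_JSON_KEYS, REGION_MODELS


def _region_n(region: str) -> int:
    return REGION_MODELS[region]

__all__ = [
    "MotionComponent",
    "Coupling",
    "DyadSimSpec",
    "SimTracks",
    "simulate_tracks",
    "degrade_and_write",
    "scripted_crossover",
    "generate_recording",
]

# Seated BODY_25 template: (dx, dy) offsets in pixels from the person's
# anchor (roughly the nose).  y grows downward, as in image coordinates.
_TEMPLATE = np.array(
    [
        (0, 0),       # nose
        (0, 40),      # neck
        (-35, 45), (-45, 100), (-50, 150),   # right arm
        (35, 45), (45, 100), (50, 150),      # left arm
        (0, 160),     # mid hip
        (-20, 160), (-25, 230), (-25, 300),  # right leg
        (20, 160), (25, 230), (25, 300),     # left leg
        (-8, -8), (8, -8),                   # eyes
        (-18, -5), (18, -5),                 # ears
        (30, 315), (38, 313), (22, 305),     # left foot
        (-30, 315), (-38, 313), (-22, 305),  # right foot
    ],
    dtype=float,
)
assert _TEMPLATE.shape[0] == len(BODY_25_NAMES)


@dataclass(frozen=True)
class MotionComponent:
    """One sinusoidal movement: ``amplitude·sin(2π·f·t + phase)`` on x."""

    keypoints: tuple[int, ...]
    freq_hz: float
    amplitude_px: float
    phase_rad: float = 0.0
    person: str = "both"  # 'left', 'right', or 'both'
    axis: str = "x"


def _ring_template(n: int, radius: float, seed: int = 12345) -> np.ndarray:
    """n points on a jittered ring — schematic face/hand landmark layouts."""
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n) / n
    r = radius * (1.0 + 0.15 * rng.standard_normal(n))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta)))


# Schematic landmark layouts for the non-body regions, anchored on body
# keypoints (face on the nose, each hand on its wrist).  Geometry is not
# anatomical — only the keypoint counts and the JSON layout matter.
_FACE_TEMPLATE = _ring_template(70, 25.0, seed=7)
_HAND_TEMPLATE = _ring_template(21, 12.0, seed=8)
_HAND_ANCHOR = {"hand_left": 7, "hand_right": 4}  # wrist body keypoints


@dataclass(frozen=True)
class Coupling:
    """A shared oscillation with the right person lagging the left."""

    freq_hz: float = 0.25
    lag_s: float = 0.5
    amplitude_px: float = 40.0
    keypoints: tuple[int, ...] = (0, 1, 4, 7)  # nose, neck, wrists
    axis: str = "x"


@dataclass(frozen=True)
class DyadSimSpec:
    """Everything needed to generate one synthetic dyad recording.

    Defaults describe a short, clean split-screen recording at the
    common 30 FPS / full-HD geometry: mild idiosyncratic sway per person,
    1 px positional noise, no dropout, high confidence.
    """

    n_frames: int = 300
    fps: float = 30.0
    frame_width: int = DEFAULT_FRAME_WIDTH
    frame_height: int = 1080
    motion: tuple[MotionComponent, ...] = (
        MotionComponent(keypoints=(0, 1), freq_hz=0.15, amplitude_px=20.0, person="left"),
        MotionComponent(
            keypoints=(0, 1), freq_hz=0.2, amplitude_px=20.0, phase_rad=1.0, person="right"
        ),
    )
    coupling: Coupling | None = None
    noise_sd: float = 1.0
    dropout_rate: float = 0.0
    dropout_burst_length: int = 1
    confidence_mean: float = 0.85
    confidence_sd: float = 0.05
    confidence_floor: float = 0.3
    regions: tuple[str, ...] = ("body",)
    seed: int = 0
    crossover_frame: int | None = None
    crossover_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0.0 <= self.confidence_floor <= 1.0):
            raise ValueError("confidence_floor must be in [0, 1]")
        if self.crossover_frame is not None and not (
            0 <= self.crossover_frame < self.n_frames
        ):
            raise ValueError("crossover_frame outside the recording")
        known = {"body", "face", "hand_left", "hand_right"}
        if "body" not in self.regions or not set(self.regions) <= known:
            raise ValueError(f"regions must include 'body' and lie in {sorted(known)}")
        # deterministic part of every trajectory must stay inside the frame
        total_amp = sum(m.amplitude_px for m in self.motion) + (
            self.coupling.amplitude_px if self.coupling else 0.0
        )
        margin = np.abs(_TEMPLATE).max() + total_amp
        if margin >= self.frame_width / 4.0 or margin >= self.frame_height * 0.7:
            raise ValueError(
                f"motion amplitude {total_amp:.0f}px would push keypoints out of frame"
            )


@dataclass
class SimTracks:
    """Ground truth from the generator.

    ``positions[t, p, k]`` is the (x, y) of keypoint k of person p
    (p = 0 starts on the left) at frame t, noise included;
    ``true_side[t, p]`` is the person's actual side of the midline.
    """

    spec: DyadSimSpec
    positions: np.ndarray  # (n_frames, 2, 25, 2)
    true_side: np.ndarray  # (n_frames, 2) of 'left'/'right'
    clean_positions: np.ndarray  # noise-free trajectories


def _anchor_x(spec: DyadSimSpec, t: np.ndarray) -> np.ndarray:
    """Per-frame anchor x of both persons, shape (n_frames, 2)."""
    left_x = spec.frame_width * 0.25
    right_x = spec.frame_width * 0.75
    anchors = np.empty((t.size, 2))
    anchors[:, 0] = left_x
    anchors[:, 1] = right_x
    if spec.crossover_frame is not None:
        tau = max(spec.crossover_duration_s * spec.fps / 4.0, 1.0)
        blend = 1.0 / (1.0 + np.exp(-(t - spec.crossover_frame) / tau))
        anchors[:, 0] = left_x + blend * (right_x - left_x)
        anchors[:, 1] = right_x + blend * (left_x - right_x)
    return anchors


def simulate_tracks(spec: DyadSimSpec) -> SimTracks:
    """Generate ground-truth trajectories (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)
    n, fps = spec.n_frames, spec.fps
    t_idx = np.arange(n)
    t_s = t_idx / fps

    anchor_y = spec.frame_height * 0.25
    anchors_x = _anchor_x(spec, t_idx)

    pos = np.empty((n, 2, len(BODY_25_NAMES), 2))
    for p in range(2):
        pos[:, p, :, 0] = anchors_x[:, p, None] + _TEMPLATE[None, :, 0]
        pos[:, p, :, 1] = anchor_y + _TEMPLATE[None, :, 1]

    components = list(spec.motion)
    if spec.coupling is not None:
        c = spec.coupling
        components.append(
            MotionComponent(c.keypoints, c.freq_hz, c.amplitude_px, 0.0, "left", c.axis)
        )
        components.append(
            MotionComponent(
                c.keypoints,
                c.freq_hz,
                c.amplitude_px,
                -2.0 * np.pi * c.freq_hz * c.lag_s,
                "right",
                c.axis,
            )
        )
    for comp in components:
        wave = comp.amplitude_px * np.sin(2 * np.pi * comp.freq_hz * t_s + comp.phase_rad)
        targets = {"left": [0], "right": [1], "both": [0, 1]}[comp.person]
        ax = {"x": 0, "y": 1}[comp.axis]
        for p in targets:
            for k in comp.keypoints:
                pos[:, p, k, ax] += wave

    clean = pos.copy()
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
    np.clip(pos[..., 0], 0.0, spec.frame_width - 1.0, out=pos[..., 0])
    np.clip(pos[..., 1], 0.0, spec.frame_height - 1.0, out=pos[..., 1])

    midline = spec.frame_width / 2.0
    mean_x = clean[:, :, :, 0].mean(axis=2)
    true_side = np.where(mean_x < midline, "left", "right")
    return SimTracks(spec=spec, positions=pos, true_side=true_side, clean_positions=clean)


def _dropout_mask(spec: DyadSimSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_frames, 2, 25) boolean: True where the detection is dropped."""
    shape = (spec.n_frames, 2, len(BODY_25_NAMES))
    if spec.dropout_rate == 0.0:
        return np.zeros(shape, dtype=bool)
    if spec.dropout_burst_length <= 1:
        return rng.random(shape) < spec.dropout_rate
    # burst dropout: Bernoulli starts, each erasing a run of frames
    L = spec.dropout_burst_length
    starts = rng.random(shape) < spec.dropout_rate / L
    mask = np.zeros(shape, dtype=bool)
    for off in range(L):
        mask[off:] |= starts[: shape[0] - off]
    return mask


def degrade_and_write(
    tracks: SimTracks, out_dir: str | Path, prefix: str = "dyad"
) -> list[Path]:
    """Write tracks as one OpenPose-format JSON per frame.

    Dropped detections become ``(0, 0, 0)`` triplets; surviving ones get
    confidence drawn from the spec's Normal(mean, sd) clipped to
    [floor, 1].  Filenames carry the standard zero-padded 12-digit frame
    counter.  Deterministic given the spec's seed.
    """
    spec = tracks.spec
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 1])
    dropped = _dropout_mask(spec, rng)
    conf = np.clip(
        rng.normal(spec.confidence_mean, spec.confidence_sd, size=dropped.shape),
        spec.confidence_floor,
        1.0,
    )
    extra_regions = [r for r in spec.regions if r != "body"]
    extra_conf = {
        r: np.clip(
            rng.normal(spec.confidence_mean, spec.confidence_sd,
                       size=(spec.n_frames, 2, _region_n(r))),
            spec.confidence_floor, 1.0,
        )
        for r in extra_regions
    }

    paths: list[Path] = []
    for t in range(spec.n_frames):
        people = []
        for p in range(2):
            flat: list[float] = []
            for k in range(len(BODY_25_NAMES)):
                if dropped[t, p, k]:
                    flat.extend((0.0, 0.0, 0.0))
                else:
                    x, y = tracks.positions[t, p, k]
                    flat.extend((float(x), float(y), float(conf[t, p, k])))
            person = {"person_id": [-1], "pose_keypoints_2d": flat}
            for r in extra_regions:
                anchor = tracks.positions[t, p, 0 if r == "face" else _HAND_ANCHOR[r]]
                template = _FACE_TEMPLATE if r == "face" else _HAND_TEMPLATE
                payload_r: list[float] = []
                for k in range(template.shape[0]):
                    payload_r.extend(
                        (
                            float(anchor[0] + template[k, 0]),
                            float(anchor[1] + template[k, 1]),
                            float(extra_conf[r][t, p, k]),
                        )
                    )
                person[REGION_JSON_KEYS[r]] = payload_r
            people.append(person)
        payload = {"version": 1.3, "people": people}
        path = out_dir / f"{prefix}_{t:012d}_keypoints.json"
        path.write_text(json.dumps(payload))
        paths.append(path)
    return paths


def scripted_crossover(spec: DyadSimSpec, crossover_frame: int) -> DyadSimSpec:
    """A copy of the spec whose two people smoothly swap sides.

    The anchors exchange along a logistic ramp centred on
    ``crossover_frame``, producing a known violation of the split-screen
    assumption behind the midline identity policy.
    """
    return replace(spec, crossover_frame=crossover_frame)


def generate_recording(
    spec: DyadSimSpec, out_dir: str | Path, prefix: str = "dyad"
) -> SimTracks:
    """Simulate and write a full recording; returns the ground truth."""
    tracks = simulate_tracks(spec)
    degrade_and_write(tracks, out_dir, prefix=prefix)
    return tracks
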