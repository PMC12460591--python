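"""Rendering: skeleton frames, point-light displays, diagnostic plots.

All rendering targets image coordinates, so the y-axis is flipped before
plotting (OpenPose's y grows downward); skeletons therefore appear
upright.  Point-light sequences omit face landmarks by default so the
output stays anonymised, and video encoding is handed off to an external
``ffmpeg`` if one is on PATH — frames are always kept either way.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import DyadTable
from .keypoints import BODY_25_EDGES
from .synchrony import CoherenceResult, MotionEnergySeries

__all__ = [
    "RenderStyle",
    "render_skeleton_frame",
    "render_pld_sequence",
    "plot_diagnostics",
]

_PERSON_COLORS = {"left": "#4fc3f7", "right": "#ffb74d"}


@dataclass
class RenderStyle:
    """Appearance of rendered skeleton / point-light frames."""

    colors: dict[str, str] = field(default_factory=lambda: dict(_PERSON_COLORS))
    point_radius: float = 6.0
    connect: bool = True
    edges: tuple[tuple[int, int], ...] = BODY_25_EDGES
    background: str = "black"
    include_face: bool = False  # anonymity: face landmarks off by default
    keypoints: tuple[int, ...] | None = None  # None = all available
    dpi: int = 100


def _frame_points(table: DyadTable, frame: int, person: str, region: str, style: RenderStyle):
    sub = table.df[
        (table.df["frame"] == frame)
        & (table.df["person"] == person)
        & (table.df["region"] == region)
    ]
    if sub.empty:
        return {}
    row = sub.iloc[0]
    pts = {}
    for k in table.keypoint_indices():
        if style.keypoints is not None and k not in style.keypoints:
            continue
        x, y = row.get(f"x{k}"), row.get(f"y{k}")
        if x is not None and y is not None and np.isfinite(x) and np.isfinite(y):
            pts[k] = (float(x), float(y))
    return pts


def _setup_canvas(table: DyadTable, style: RenderStyle):
    height = table.frame_width * 9 / 16  # assume 16:9 when height unknown
    fig, ax = plt.subplots(
        figsize=(table.frame_width / style.dpi, height / style.dpi), dpi=style.dpi
    )
    fig.subplots_adjust(0, 0, 1, 1)
    ax.set_facecolor(style.background)
    fig.patch.set_facecolor(style.background)
    ax.set_xlim(0, table.frame_width)
    ax.set_ylim(height, 0)  # flipped: image y grows downward
    ax.axis("off")
    return fig, ax


def _draw_frame(ax, table: DyadTable, frame: int, style: RenderStyle) -> int:
    n_drawn = 0
    regions = [r for r in table.regions if style.include_face or r != "face"]
    for person in table.persons:
        color = style.colors.get(person, "white")
        for region in regions:
            pts = _frame_points(table, frame, person, region, style)
            if not pts:
                continue
            xs = [p[0] for p in pts.values()]
            ys = [p[1] for p in pts.values()]
            ax.scatter(xs, ys, s=style.point_radius**2, c=color, zorder=3)
            n_drawn += len(pts)
            if style.connect and region == "body":
                for a, b in style.edges:
                    if a in pts and b in pts:
                        ax.plot(
                            [pts[a][0], pts[b][0]],
                            [pts[a][1], pts[b][1]],
                            color=color,
                            linewidth=1.5,
                            zorder=2,
                        )
    return n_drawn


def render_skeleton_frame(
    table: DyadTable, frame: int, path: str | Path, style: RenderStyle | None = None
) -> Path:
    """Render one frame's detected keypoints (and skeleton edges) to PNG.

    Missing keypoints are simply omitted; a frame with nothing detected
    still produces an (empty) canvas with a warning.  Raises when the
    frame index is absent from the table.
    """
    style = style or RenderStyle()
    if frame not in set(table.df["frame"]):
        raise ValueError(f"frame {frame} not present in the table")
    fig, ax = _setup_canvas(table, style)
    try:
        if _draw_frame(ax, table, frame, style) == 0:
            warnings.warn(f"frame {frame}: no detected keypoints; blank canvas", stacklevel=2)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=style.dpi, facecolor=style.background)
    finally:
        plt.close(fig)
    return path


def render_pld_sequence(
    table: DyadTable,
    out_dir: str | Path,
    start: int | None = None,
    end: int | None = None,
    style: RenderStyle | None = None,
    playback_fps: float | None = None,
    encode: bool = True,
    video_name: str = "pld.mp4",
) -> list[Path]:
    """Render a numbered point-light frame sequence, optionally encoding video.

    One PNG per frame in ``[start, end]`` (inclusive; defaults to the full
    recording).  If ``encode`` and an ``ffmpeg`` binary is on PATH, the
    frames are compiled into ``video_name`` at ``playback_fps`` (defaults
    to the table's fps — raising it speeds the motion up, lowering it
    slows the motion down, without changing the frames).  Without an
    encoder the frames are kept and a warning issued.
    """
    style = style or RenderStyle()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = np.sort(table.df["frame"].unique())
    start = int(frames[0]) if start is None else start
    end = int(frames[-1]) if end is None else end
    selected = [int(f) for f in frames if start <= f <= end]
    if not selected:
        raise ValueError(f"no frames in range [{start}, {end}]")

    written: list[Path] = []
    fig, ax = _setup_canvas(table, style)
    try:
        for i, frame in enumerate(selected):
            for artist in list(ax.lines) + list(ax.collections):
                artist.remove()
            _draw_frame(ax, table, frame, style)
            path = out_dir / f"frame_{i:06d}.png"
            fig.savefig(path, dpi=style.dpi, facecolor=style.background)
            written.append(path)
    finally:
        plt.close(fig)

    if encode:
        fps = playback_fps if playback_fps is not None else table.fps
        encoder = shutil.which("ffmpeg")
        if encoder is None:
            warnings.warn(
                "no ffmpeg on PATH; frames kept, video encoding skipped", stacklevel=2
            )
        else:
            cmd = [
                encoder, "-y", "-framerate", str(fps),
                "-i", str(out_dir / "frame_%06d.png"),
                "-pix_fmt", "yuv420p", str(out_dir / video_name),
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                warnings.warn(
                    f"ffmpeg failed (frames retained): {proc.stderr[-500:]}", stacklevel=2
                )
    return written


# ---------------------------------------------------------------------------
# diagnostic plots


def _plot_timeseries(table: DyadTable, path: Path, keypoints=None) -> None:
    """Per-keypoint x (black) and y (yellow) trajectories, one panel per
    (person, keypoint); tracking losses show as drops to zero/missing."""
    kps = list(keypoints) if keypoints else table.keypoint_indices()[:3]
    persons = table.persons
    fig, axes = plt.subplots(
        len(kps), len(persons), figsize=(5 * len(persons), 2.2 * len(kps)),
        squeeze=False, sharex=True,
    )
    body = table.df[table.df["region"] == "body"]
    for i, k in enumerate(kps):
        for j, person in enumerate(persons):
            sub = body[body["person"] == person].sort_values("frame")
            ax = axes[i][j]
            ax.plot(sub["frame"], sub[f"x{k}"], color="black", lw=0.8, label="x")
            ax.plot(sub["frame"], sub[f"y{k}"], color="gold", lw=0.8, label="y")
            ax.set_ylabel(f"kp {k}")
            if i == 0:
                ax.set_title(person)
    axes[-1][0].set_xlabel("frame")
    axes[0][0].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_quality(profile, path: Path, confidence_threshold=0.5, completeness_threshold=0.8):
    """Mean confidence and completeness (%) per keypoint with threshold lines."""
    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    for (person, region), sub in profile.groupby(["person", "region"]):
        axes[0].plot(sub["keypoint"], 100 * sub["mean_confidence"], "o-",
                     label=f"{person}/{region}", ms=4)
        axes[1].plot(sub["keypoint"], 100 * sub["completeness"], "o-",
                     label=f"{person}/{region}", ms=4)
    axes[0].axhline(100 * confidence_threshold, ls="--", color="grey")
    axes[0].set_ylabel("mean confidence (%)")
    axes[1].axhline(100 * completeness_threshold, ls="--", color="grey")
    axes[1].set_ylabel("completeness (%)")
    axes[1].set_xlabel("keypoint")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_energy(energies: dict[str, MotionEnergySeries], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(10, 3.5))
    for person, series in energies.items():
        ax.plot(series.frames, series.values, lw=0.8,
                color=_PERSON_COLORS.get(person), label=person)
    ax.set_xlabel("frame")
    ax.set_ylabel(f"motion energy ({energies[next(iter(energies))].method})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_coherence(
    result: CoherenceResult, path: Path, significance: np.ndarray | None = None
) -> None:
    """Coherence heat map with COI, phase arrows, and significance contour."""
    fig, ax = plt.subplots(figsize=(10, 5))
    t = result.frames
    periods = result.period_frames
    mesh = ax.pcolormesh(t, periods, result.coherence, cmap="jet", vmin=0, vmax=1,
                         shading="nearest")
    fig.colorbar(mesh, ax=ax, label="coherence")
    ax.plot(t, result.coi_period_s * result.fps, color="white", lw=2)
    if significance is not None and significance.any():
        ax.contour(t, periods, significance.astype(float), levels=[0.5],
                   colors="black", linewidths=1.5)
    # sub-sampled phase arrows
    st = max(1, len(t) // 40)
    ss = max(1, len(periods) // 20)
    ax.quiver(
        t[::st], periods[::ss],
        np.cos(result.phase[::ss, ::st]), -np.sin(result.phase[::ss, ::st]),
        scale=50, width=0.002, color="black",
    )
    ax.set_yscale("log", base=2)
    ax.set_ylim(periods.max(), periods.min())
    ax.set_xlabel("frame")
    ax.set_ylabel("period (frames)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_smoothing(raw: DyadTable, smoothed: DyadTable, path: Path, keypoint=None):
    k = keypoint if keypoint is not None else raw.keypoint_indices()[0]
    persons = raw.persons
    fig, axes = plt.subplots(1, len(persons), figsize=(6 * len(persons), 3), squeeze=False)
    for j, person in enumerate(persons):
        a = raw.df[(raw.df["person"] == person) & (raw.df["region"] == "body")]
        b = smoothed.df[(smoothed.df["person"] == person) & (smoothed.df["region"] == "body")]
        ax = axes[0][j]
        ax.plot(a["frame"], a[f"x{k}"], color="red", lw=0.8, label="raw")
        ax.plot(b["frame"], b[f"x{k}"], color="blue", ls="--", lw=0.8, label="smoothed")
        ax.set_title(f"{person}, keypoint {k} (x)")
        ax.set_xlabel("frame")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_diagnostics(kind: str, inputs, path: str | Path, **kwargs) -> Path:
    """Dispatch to one diagnostic plot.

    ``kind`` is one of ``timeseries`` (DyadTable), ``quality`` (profile
    DataFrame), ``energy`` (dict of MotionEnergySeries), ``coherence``
    (CoherenceResult), or ``smoothing_comparison`` ((raw, smoothed)
    DyadTable pair).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "timeseries":
        _plot_timeseries(inputs, path, **kwargs)
    elif kind == "quality":
        if inputs is None or len(inputs) == 0:
            raise ValueError("empty quality profile")
        _plot_quality(inputs, path, **kwargs)
    elif kind == "energy":
        if not inputs:
            raise ValueError("no energy series to plot")
        _plot_energy(inputs, path)
    elif kind == "coherence":
        _plot_coherence(inputs, path, **kwargs)
    elif kind == "smoothing_comparison":
        _plot_smoothing(inputs[0], inputs[1], path, **kwargs)
    else:
        raise ValueError(f"unknown diagnostic kind {kind!r}")
    return path
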