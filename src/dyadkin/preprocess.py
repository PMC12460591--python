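"""Quality profiling, keypoint removal, interpolation, and smoothing.

Pose detectors lose track of joints — occlusion, motion blur, a hand
leaving the frame — which shows up as zero-confidence samples and gaps.
The functions here quantify that (per-keypoint mean confidence and
completeness), prune keypoints that are unreliable for a whole
recording, repair brief gaps with natural cubic splines, and optionally
smooth the retained trajectories before kinematic analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import CubicSpline

from .core import DyadTable

__all__ = [
    "QualityProfile",
    "RemovalSpec",
    "SummaryStats",
    "quality_profile",
    "summarise_series",
    "remove_keypoints",
    "interpolate",
    "smooth",
    "smooth_series",
]

#: Confidence below which a sample is considered unreliable and re-estimated.
DEFAULT_INTERPOLATION_CONFIDENCE = 0.3

SMOOTHING_DEFAULTS: dict[str, dict] = {
    "moving_average": {"window": 5},
    "savitzky_golay": {"window": 11, "polyorder": 3},
    "butterworth": {"order": 2, "cutoff_fraction": 0.1},  # fraction of Nyquist
    "kza": {"window": 5, "iterations": 3},
}


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of one time series."""

    mean: float
    median: float
    iqr: float
    variance: float
    skewness: float
    kurtosis: float  # excess kurtosis (normal -> 0)
    n: int


@dataclass
class RemovalSpec:
    """Which keypoints to drop and on what evidence.

    Rules are applied in order: user-specified keypoints, never-detected
    keypoints, mean confidence below ``total_confidence_threshold``, then
    missing-data fraction above ``missing_data_threshold``.  With
    ``apply_equally`` the union of both persons' removal sets is applied
    to both, keeping the dyad's column sets identical.
    """

    remove_undetected: bool = True
    total_confidence_threshold: float | None = None
    missing_data_threshold: float | None = None
    specific_keypoints: list[int] = field(default_factory=list)
    apply_equally: bool = True

    def __post_init__(self) -> None:
        for name in ("total_confidence_threshold", "missing_data_threshold"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def quality_profile(table: DyadTable) -> pd.DataFrame:
    """Per-keypoint detection quality, one row per (person, region, keypoint).

    ``mean_confidence`` averages the confidence over all frames with a
    missed detection counted as 0; ``completeness`` is the fraction of
    frames in which the keypoint was detected (confidence > 0).  The two
    are the quantities thresholded by :func:`remove_keypoints`, and
    ``completeness + missing_fraction == 1`` by construction.
    """
    if table.df.empty:
        raise ValueError("empty dyad table")
    rows = []
    for (person, region), sub in table.group_iter():
        n_frames = len(sub)
        for k in table.keypoint_indices():
            c_col = f"c{k}"
            if c_col not in sub.columns:
                continue
            c = sub[c_col].to_numpy(dtype=float)
            if np.isnan(c).all():
                continue  # keypoint not part of this region's model
            c_filled = np.nan_to_num(c, nan=0.0)
            detected = c_filled > 0
            rows.append(
                {
                    "person": person,
                    "region": region,
                    "keypoint": k,
                    "mean_confidence": float(c_filled.mean()),
                    "completeness": float(detected.mean()),
                    "n_frames": n_frames,
                }
            )
    return pd.DataFrame(rows)


def summarise_series(series) -> SummaryStats:
    """Descriptive statistics (missing values excluded).

    Variance is the unbiased sample variance; skewness and kurtosis are
    plain moment estimators (no small-sample bias correction), kurtosis
    reported as excess.  IQR uses linear-interpolation quantiles.
    """
    x = np.asarray(pd.Series(series).dropna(), dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 non-missing values, got {x.size}")
    with warnings.catch_warnings():
        # constant series: higher moments degenerate, reported as NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        return _summary_stats(x)


def _summary_stats(x: np.ndarray) -> SummaryStats:
    return SummaryStats(
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        iqr=float(np.percentile(x, 75) - np.percentile(x, 25)),
        variance=float(np.var(x, ddof=1)),
        skewness=float(stats.skew(x, bias=True)),
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=True)),
        n=int(x.size),
    )


def _group_removals(sub: pd.DataFrame, keypoints: list[int], spec: RemovalSpec) -> dict[int, str]:
    """Removal reasons for one (person, region) group, first rule wins."""
    reasons: dict[int, str] = {}
    for k in spec.specific_keypoints:
        if k in keypoints:
            reasons.setdefault(k, "specific")
    for k in keypoints:
        c = np.nan_to_num(sub[f"c{k}"].to_numpy(dtype=float), nan=0.0)
        if spec.remove_undetected and not (c > 0).any():
            reasons.setdefault(k, "undetected")
            continue
        if (
            spec.total_confidence_threshold is not None
            and c.mean() < spec.total_confidence_threshold
        ):
            reasons.setdefault(k, "low_confidence")
            continue
        missing_fraction = float((c <= 0).mean())
        if (
            spec.missing_data_threshold is not None
            and missing_fraction > spec.missing_data_threshold
        ):
            reasons.setdefault(k, "missing_data")
    return reasons


def remove_keypoints(table: DyadTable, spec: RemovalSpec) -> tuple[DyadTable, pd.DataFrame]:
    """Drop unreliable keypoints; returns the pruned table and a removal log.

    A keypoint removed for every (person, region) group loses its x/y/c
    columns outright; one removed for only some groups (possible when
    ``apply_equally`` is False) has those groups' values masked to NaN
    while the columns survive for the others.  Removing everything is an
    error — the caller almost certainly mis-set a threshold.
    """
    df = table.df
    groups = list(table.group_iter())
    present: dict[tuple[str, str], list[int]] = {}
    for (person, region), sub in groups:
        ks = [
            k
            for k in table.keypoint_indices()
            if f"c{k}" in sub.columns and not sub[f"c{k}"].isna().all()
        ]
        present[(person, region)] = ks

    removal: dict[tuple[str, str], dict[int, str]] = {}
    for (person, region), sub in groups:
        removal[(person, region)] = _group_removals(sub, present[(person, region)], spec)

    if spec.apply_equally:
        by_region: dict[str, dict[int, str]] = {}
        for (person, region), reasons in removal.items():
            merged = by_region.setdefault(region, {})
            for k, why in reasons.items():
                merged.setdefault(k, why)
        removal = {key: dict(by_region[key[1]]) for key in removal}

    log_rows = [
        {"person": p, "region": r, "keypoint": k, "reason": why}
        for (p, r), reasons in sorted(removal.items())
        for k, why in sorted(reasons.items())
    ]
    log = pd.DataFrame(log_rows, columns=["person", "region", "keypoint", "reason"])

    surviving = {
        k for key, ks in present.items() for k in ks if k not in removal[key]
    }
    if not surviving:
        raise ValueError("removal spec would drop every keypoint; loosen the thresholds")

    out_df = df.copy()
    # mask group-local removals
    for (person, region), reasons in removal.items():
        if not reasons:
            continue
        mask = (out_df["person"] == person) & (out_df["region"] == region)
        for k in reasons:
            for kind in "xyc":
                col = f"{kind}{k}"
                if col in out_df.columns:
                    out_df.loc[mask, col] = np.nan
    # drop globally removed columns
    globally_removed = {
        k
        for k in table.keypoint_indices()
        if all(k in removal[key] or k not in present[key] for key in present)
    }
    drop_cols = [
        f"{kind}{k}" for k in sorted(globally_removed) for kind in "xyc"
        if f"{kind}{k}" in out_df.columns
    ]
    out_df = out_df.drop(columns=drop_cols)

    out = table.copy()
    out.df = out_df
    if len(log):
        out.events.append(f"removed {len(log)} (person, region, keypoint) entries")
    return out, log


def interpolate(
    table: DyadTable,
    confidence_threshold: float = DEFAULT_INTERPOLATION_CONFIDENCE,
    include_missing: bool = True,
) -> DyadTable:
    """Re-estimate low-confidence samples with natural cubic splines.

    Within each (person, region) group and for each keypoint, samples
    with confidence below ``confidence_threshold`` (plus missing samples
    when ``include_missing``) are replaced by a natural cubic spline
    fitted to the valid samples against frame index.  Valid samples are
    never touched; no extrapolation happens beyond the first/last valid
    frame (leading/trailing gaps stay missing); keypoints with fewer than
    two valid samples are skipped with a warning.
    """
    if not (0.0 <= confidence_threshold <= 1.0):
        raise ValueError(f"confidence_threshold must be in [0, 1], got {confidence_threshold}")
    out = table.copy()
    df = out.df
    for (person, region), sub in table.group_iter():
        frames = sub["frame"].to_numpy(dtype=float)
        for k in table.keypoint_indices():
            c_col, x_col, y_col = f"c{k}", f"x{k}", f"y{k}"
            if c_col not in sub.columns or sub[c_col].isna().all():
                continue
            c = np.nan_to_num(sub[c_col].to_numpy(dtype=float), nan=0.0)
            x = sub[x_col].to_numpy(dtype=float)
            y = sub[y_col].to_numpy(dtype=float)
            observed = ~np.isnan(x) & ~np.isnan(y)
            valid = observed & (c >= confidence_threshold)
            target = observed & (c < confidence_threshold)
            if include_missing:
                target |= ~observed
            if not target.any():
                continue
            if valid.sum() < 2:
                warnings.warn(
                    f"{person}/{region} keypoint {k}: fewer than 2 valid samples; "
                    "interpolation skipped",
                    stacklevel=2,
                )
                continue
            vf = frames[valid]
            # interior targets only: no extrapolation past the valid support
            target &= (frames >= vf[0]) & (frames <= vf[-1])
            if not target.any():
                continue
            new_x = x.copy()
            new_y = y.copy()
            new_x[target] = CubicSpline(vf, x[valid], bc_type="natural")(frames[target])
            new_y[target] = CubicSpline(vf, y[valid], bc_type="natural")(frames[target])
            df.loc[sub.index, x_col] = new_x
            df.loc[sub.index, y_col] = new_y
    return out


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _kz(x: np.ndarray, window: int, iterations: int) -> np.ndarray:
    """Kolmogorov–Zurbenko filter: iterated centred moving average."""
    z = x.copy()
    for _ in range(iterations):
        z = _moving_average(z, window)
    return z


def _kza(x: np.ndarray, window: int, iterations: int) -> np.ndarray:
    """Kolmogorov–Zurbenko adaptive filter.

    The KZ-smoothed series provides a break detector D(t) = |z(t+q) - z(t-q)|
    (q the half-window); the local window then shrinks in proportion to
    D(t)/max D, so sharp level shifts are tracked with a short window while
    smooth stretches keep the full one.
    """
    n = x.size
    q = max(1, (window - 1) // 2)
    z = _kz(x, window, iterations)
    hi = np.clip(np.arange(n) + q, 0, n - 1)
    lo = np.clip(np.arange(n) - q, 0, n - 1)
    d = np.abs(z[hi] - z[lo])
    d_max = np.nanmax(d) if np.isfinite(d).any() else 0.0
    if d_max <= 0:
        return _moving_average(x, window)
    f = 1.0 - d / d_max
    dprime = np.gradient(d)
    out = np.empty(n)
    for t in range(n):
        qf = max(1, int(round(q * f[t]))) if np.isfinite(f[t]) else q
        q_head = q if dprime[t] < 0 else qf
        q_tail = q if dprime[t] > 0 else qf
        seg = x[max(0, t - q_tail): min(n, t + q_head + 1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[t] = np.nanmean(seg)
    return out


def _apply_to_runs(x: np.ndarray, min_len: int, fn) -> np.ndarray:
    """Apply ``fn`` to each contiguous non-NaN run of at least ``min_len``."""
    out = x.copy()
    isnan = np.isnan(x)
    n = x.size
    start = 0
    while start < n:
        if isnan[start]:
            start += 1
            continue
        end = start
        while end < n and not isnan[end]:
            end += 1
        if end - start >= min_len:
            out[start:end] = fn(x[start:end])
        start = end
    return out


def smooth_series(series, method: str = "moving_average", **params) -> np.ndarray:
    """Smooth one 1-D series; missing samples stay missing.

    Methods: ``moving_average`` (centred window), ``kza``
    (Kolmogorov–Zurbenko adaptive), ``savitzky_golay`` (local polynomial),
    ``butterworth`` (low-pass, applied forward–backward for zero phase;
    cutoff given as a fraction of the Nyquist frequency).  Output length
    equals input length, and positions missing on input are missing on
    output — gaps are never invented by the smoother.
    """
    if method not in SMOOTHING_DEFAULTS:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(SMOOTHING_DEFAULTS)}"
        )
    opts = {**SMOOTHING_DEFAULTS[method], **params}
    x = np.asarray(pd.Series(series), dtype=float)
    n = x.size
    nan_mask = np.isnan(x)

    if method == "moving_average":
        window = int(opts["window"])
        if window > n:
            raise ValueError(f"window {window} longer than series ({n})")
        out = _moving_average(x, window)
    elif method == "kza":
        window = int(opts["window"])
        if window > n:
            raise ValueError(f"window {window} longer than series ({n})")
        out = _kza(x, window, int(opts["iterations"]))
    elif method == "savitzky_golay":
        window = int(opts["window"])
        if window % 2 == 0:
            raise ValueError(f"savitzky_golay window must be odd, got {window}")
        if window > n:
            raise ValueError(f"window {window} longer than series ({n})")
        poly = int(opts["polyorder"])
        out = _apply_to_runs(x, window, lambda seg: signal.savgol_filter(seg, window, poly))
    else:  # butterworth
        cutoff = float(opts["cutoff_fraction"])
        if not (0.0 < cutoff < 1.0):
            raise ValueError(
                f"butterworth cutoff must be a fraction of Nyquist in (0, 1), got {cutoff}"
            )
        order = int(opts["order"])
        b, a = signal.butter(order, cutoff)
        padlen = 3 * (max(len(a), len(b)) - 1)
        if n <= padlen:
            raise ValueError(f"series too short ({n}) for butterworth order {order}")
        out = _apply_to_runs(x, padlen + 1, lambda seg: signal.filtfilt(b, a, seg))

    out[nan_mask] = np.nan
    return out


def smooth(table: DyadTable, method: str = "moving_average", **params) -> DyadTable:
    """Smooth every x/y trajectory of a dyad table, per (person, region)."""
    out = table.copy()
    df = out.df
    for (_, _), sub in table.group_iter():
        for k in table.keypoint_indices():
            for kind in "xy":
                col = f"{kind}{k}"
                if col in sub.columns and not sub[col].isna().all():
                    df.loc[sub.index, col] = smooth_series(
                        sub[col].to_numpy(dtype=float), method, **params
                    )
    out.events.append(f"smoothed with {method}")
    return out
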