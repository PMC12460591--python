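"""Motion energy and wavelet-coherence synchrony for dyads.

Motion energy collapses a person's keypoint trajectories into one value
per frame — the aggregate frame-to-frame displacement — giving a single
movement time series per person.  Interpersonal synchrony is then
quantified by the magnitude-squared wavelet coherence of the two series:
a time- and frequency-resolved correlation in [0, 1] built from
continuous Morlet wavelet transforms, smoothed in time and scale, with a
cone of influence marking edge-affected cells and an AR(1) surrogate
test for pointwise significance.

The wavelet machinery follows the standard Torrence–Compo
parameterisation (Morlet with ω0 = 6, dyadic scales s_j = s0·2^{j·dj})
and the Grinsted-style smoothing operator (scale-dependent Gaussian in
time, boxcar over 0.6 octave in scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DyadTable

__all__ = [
    "MotionEnergySeries",
    "BandSpec",
    "CoherenceResult",
    "compute_motion_energy",
    "morlet_cwt",
    "wavelet_coherence",
    "band_coherence",
    "coherence_significance",
    "DEFAULT_BANDS",
]

OMEGA0 = 6.0
#: Conversion from Morlet scale to equivalent Fourier period.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))


@dataclass
class MotionEnergySeries:
    """Aggregate movement per frame for one person.

    ``values[t]`` is the energy of the step into ``frames[t]`` (the first
    recording frame has no predecessor, so the series starts at the
    second frame).  ``coverage`` is the fraction of keypoints that
    contributed a defined displacement at each step; missing keypoints
    contribute zero energy.
    """

    person: str
    frames: np.ndarray
    values: np.ndarray
    method: str
    fps: float
    coverage: np.ndarray
    per_keypoint: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )


#: Slow interpersonal movement rhythms, the conventional band of interest.
DEFAULT_BANDS = (
    BandSpec("slow", 0.1, 0.5),
    BandSpec("medium", 0.5, 2.0),
    BandSpec("fast", 2.0, 8.0),
)


@dataclass
class CoherenceResult:
    """Wavelet coherence of two equal-length series.

    ``coherence[j, t]`` is R² at scale j and frame t; ``phase`` the
    cross-spectrum angle (positive = left leads right); ``period_s`` the
    equivalent Fourier period per scale in seconds; ``coi_period_s[t]``
    the longest period free of edge effects at frame t.
    """

    coherence: np.ndarray
    phase: np.ndarray
    scales: np.ndarray
    period_s: np.ndarray
    coi_period_s: np.ndarray
    fps: float
    frames: np.ndarray

    @property
    def freq_hz(self) -> np.ndarray:
        return 1.0 / self.period_s

    @property
    def period_frames(self) -> np.ndarray:
        return self.period_s * self.fps

    def valid_mask(self) -> np.ndarray:
        """True for cells unaffected by edges (inside the cone of influence)."""
        return self.period_s[:, None] <= self.coi_period_s[None, :]


# ---------------------------------------------------------------------------
# motion energy


def compute_motion_energy(
    table: DyadTable,
    method: str = "absolute",
    aggregate_coordinates: bool = True,
    aggregate_keypoints: bool = True,
) -> dict[str, MotionEnergySeries]:
    """Frame-differencing motion energy per person.

    Per keypoint, Δx = x_t − x_{t−1} and Δy = y_t − y_{t−1}; with
    ``aggregate_coordinates`` the two combine into the Euclidean step
    magnitude per keypoint, otherwise |Δx| and |Δy| contribute as
    separate channels.  ``method='absolute'`` sums the (linear)
    magnitudes across keypoints; ``'squared'`` sums squared magnitudes,
    weighting energetic motions more heavily.  Missing keypoints
    contribute 0, tracked by the coverage fraction.  With
    ``aggregate_keypoints=False`` the per-keypoint series are retained in
    ``per_keypoint``.
    """
    if method not in ("absolute", "squared"):
        raise ValueError(f"method must be 'absolute' or 'squared', got {method!r}")
    out: dict[str, MotionEnergySeries] = {}
    for person in table.persons:
        sub = table.df[(table.df["person"] == person)]
        # merge regions on the common frame base
        frames = np.sort(sub["frame"].unique())
        if frames.size < 2:
            raise ValueError("need at least 2 frames for frame differencing")
        channels: dict[str, np.ndarray] = {}
        for region in sorted(sub["region"].unique()):
            rsub = sub[sub["region"] == region].sort_values("frame")
            for k in table.keypoint_indices():
                x_col, y_col = f"x{k}", f"y{k}"
                if x_col not in rsub.columns or rsub[x_col].isna().all():
                    continue
                x = rsub[x_col].to_numpy(dtype=float)
                y = rsub[y_col].to_numpy(dtype=float)
                dx = np.diff(x)
                dy = np.diff(y)
                if aggregate_coordinates:
                    channels[f"{region}_{k}"] = np.hypot(dx, dy)
                else:
                    channels[f"{region}_{k}_x"] = np.abs(dx)
                    channels[f"{region}_{k}_y"] = np.abs(dy)
        if not channels:
            raise ValueError(f"person {person!r}: no keypoint trajectories present")
        mat = np.vstack(list(channels.values()))  # channels x (frames-1)
        defined = ~np.isnan(mat)
        coverage = defined.mean(axis=0)
        contrib = np.where(defined, mat, 0.0)
        if method == "squared":
            contrib = contrib**2
        values = contrib.sum(axis=0)
        per_kp = None
        if not aggregate_keypoints:
            per_kp = pd.DataFrame(
                {name: np.where(defined[i], contrib[i], np.nan)
                 for i, name in enumerate(channels)},
                index=pd.Index(frames[1:], name="frame"),
            )
        out[person] = MotionEnergySeries(
            person=person,
            frames=frames[1:],
            values=values,
            method=method,
            fps=table.fps,
            coverage=coverage,
            per_keypoint=per_kp,
        )
    return out


# ---------------------------------------------------------------------------
# Morlet continuous wavelet transform


def _dyadic_scales(n: int, dt: float, dj: float, s0: float, J: int | None):
    if J is None:
        J = int(np.floor(np.log2(n * dt / s0) / dj))
    return s0 * 2.0 ** (dj * np.arange(J + 1))


def morlet_cwt(
    series,
    fps: float,
    omega0: float = OMEGA0,
    dj: float = 1.0 / 12.0,
    s0: float | None = None,
    J: int | None = None,
):
    """Continuous Morlet wavelet transform on dyadic scales.

    The input is demeaned and zero-padded to the next power of two; the
    transform is evaluated in the Fourier domain with the unit-energy
    normalisation, on scales s_j = s0·2^{j·dj} (s0 defaulting to 2·dt).

    Returns ``(W, scales, period_s, coi_period_s)`` where ``W`` is the
    complex transform of shape (n_scales, n), ``period_s`` the equivalent
    Fourier period of each scale in seconds, and ``coi_period_s`` the
    e-folding cone-of-influence boundary per sample, as a period.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if n < 16:
        raise ValueError(f"series too short for a wavelet transform: {n} < 16")
    if np.isnan(x).any():
        raise ValueError("series contains missing values; fill gaps first")
    dt = 1.0 / fps
    if s0 is None:
        s0 = 2.0 * dt
    scales = _dyadic_scales(n, dt, dj, s0, J)

    n_pad = int(2 ** np.ceil(np.log2(n)))
    xp = np.zeros(n_pad)
    xp[:n] = x - x.mean()
    xhat = np.fft.fft(xp)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    fourier_factor = 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))
    W = np.empty((scales.size, n), dtype=complex)
    pos = omega > 0
    norm_const = np.pi**-0.25 * np.sqrt(2.0 * np.pi / dt)
    for j, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = norm_const * np.sqrt(s) * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        W[j] = np.fft.ifft(xhat * psi_hat)[:n]

    period_s = fourier_factor * scales
    edge = np.minimum(np.arange(n), n - 1 - np.arange(n)).astype(float)
    coi_period_s = fourier_factor * np.maximum(edge, 1e-9) * dt / np.sqrt(2.0)
    return W, scales, period_s, coi_period_s


# ---------------------------------------------------------------------------
# smoothing operator and coherence


def _smooth_time(field2d: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Scale-dependent Gaussian smoothing along the time axis.

    Implemented as multiplication in the Fourier domain (zero-padded), so
    the effective kernel is a wrapped Gaussian — non-negative, hence the
    Cauchy–Schwarz bound R² <= 1 is preserved.
    """
    n = field2d.shape[1]
    n_pad = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    fhat = np.fft.fft(field2d, n=n_pad, axis=1)
    gain = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    out = np.fft.ifft(fhat * gain, axis=1)[:, :n]
    if np.isrealobj(field2d):
        return out.real
    return out


def _smooth_scale(field2d: np.ndarray, dj: float) -> np.ndarray:
    """Boxcar smoothing over ~0.6 octave along the scale axis."""
    from scipy.ndimage import uniform_filter1d

    width = max(1, int(round(0.6 / dj)))
    if np.iscomplexobj(field2d):
        return uniform_filter1d(field2d.real, width, axis=0, mode="nearest") + 1j * (
            uniform_filter1d(field2d.imag, width, axis=0, mode="nearest")
        )
    return uniform_filter1d(field2d, width, axis=0, mode="nearest")


def _fill_gaps(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Linearly interpolate interior NaNs; returns (filled, fraction filled)."""
    x = np.asarray(x, dtype=float).copy()
    bad = np.isnan(x)
    if not bad.any():
        return x, 0.0
    good = ~bad
    if good.sum() < 2:
        raise ValueError("series has fewer than 2 defined samples")
    idx = np.arange(x.size)
    x[bad] = np.interp(idx[bad], idx[good], x[good])
    return x, float(bad.mean())


def wavelet_coherence(
    e_left,
    e_right,
    fps: float,
    omega0: float = OMEGA0,
    dj: float = 1.0 / 12.0,
    s0: float | None = None,
    J: int | None = None,
    frames: np.ndarray | None = None,
) -> CoherenceResult:
    """Magnitude-squared wavelet coherence of two motion-energy series.

    R²(t, s) = |S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s)) with S the
    time-and-scale smoothing operator; values lie in [0, 1] up to ~1e-9
    numerical tolerance.  Phase is the angle of the smoothed cross
    spectrum W_x·conj(W_y): positive when the left person leads.

    Interior missing samples are linearly interpolated first (fraction
    reported via a warning above 10%).  The two series must already be
    aligned and of equal length.
    """
    x = np.asarray(e_left, dtype=float)
    y = np.asarray(e_right, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be equal-length 1-D, got {x.shape} vs {y.shape}")
    x, fx = _fill_gaps(x)
    y, fy = _fill_gaps(y)
    if max(fx, fy) > 0.10:
        warnings.warn(
            f"interpolated {max(fx, fy):.0%} of samples before the transform",
            stacklevel=2,
        )
    dt = 1.0 / fps
    Wx, scales, period_s, coi = morlet_cwt(x, fps, omega0, dj, s0, J)
    Wy, _, _, _ = morlet_cwt(y, fps, omega0, dj, s0, J)

    inv_s = 1.0 / scales[:, None]
    Sxx = _smooth_scale(_smooth_time(np.abs(Wx) ** 2 * inv_s, scales, dt), dj)
    Syy = _smooth_scale(_smooth_time(np.abs(Wy) ** 2 * inv_s, scales, dt), dj)
    Wxy = Wx * np.conj(Wy) * inv_s
    Sxy = _smooth_scale(
        _smooth_time(Wxy.real, scales, dt) + 1j * _smooth_time(Wxy.imag, scales, dt), dj
    )
    denom = Sxx * Syy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.abs(Sxy) ** 2 / denom
    r2 = np.where(denom > 0, r2, 0.0)
    phase = np.angle(Sxy)

    if frames is None:
        frames = np.arange(x.size)
    return CoherenceResult(
        coherence=r2,
        phase=phase,
        scales=scales,
        period_s=period_s,
        coi_period_s=coi,
        fps=fps,
        frames=np.asarray(frames),
    )


def band_coherence(
    result: CoherenceResult,
    bands=DEFAULT_BANDS,
    exclude_coi: bool = True,
) -> pd.DataFrame:
    """Mean coherence per frequency band.

    Scales map to Hz through the equivalent Fourier period; each band's
    mean is taken over all (time, scale) cells whose frequency falls in
    [f_lo, f_hi), excluding edge-affected cells outside the cone of
    influence when ``exclude_coi``.  A band that no resolvable scale
    falls into is an error naming the band.
    """
    nyquist = result.fps / 2.0
    freq = result.freq_hz
    valid = result.valid_mask() if exclude_coi else np.ones_like(result.coherence, bool)
    rows = []
    for band in bands:
        if band.f_hi > nyquist * (1 + 1e-12):
            raise ValueError(
                f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) exceeds the "
                f"Nyquist frequency {nyquist} Hz"
            )
        in_band = (freq >= band.f_lo) & (freq < band.f_hi)
        if not in_band.any():
            raise ValueError(
                f"band {band.name!r} ({band.f_lo}-{band.f_hi} Hz) contains no "
                "resolvable wavelet scale"
            )
        cells = valid[in_band, :]
        coh = result.coherence[in_band, :]
        n_cells = int(cells.sum())
        mean = float(coh[cells].mean()) if n_cells else float("nan")
        # circular mean of phase over the same cells
        ph = result.phase[in_band, :][cells]
        mean_phase = float(np.angle(np.exp(1j * ph).mean())) if n_cells else float("nan")
        rows.append(
            {
                "band": band.name,
                "f_lo_hz": band.f_lo,
                "f_hi_hz": band.f_hi,
                "mean_coherence": mean,
                "mean_phase_rad": mean_phase,
                "n_cells": n_cells,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AR(1) surrogate significance


def _fit_ar1(x: np.ndarray) -> tuple[float, float]:
    """Lag-1 autoregression fit: returns (phi, innovation sd)."""
    x = x - x.mean()
    var = float(np.var(x))
    if var <= 0:
        raise ValueError("zero-variance series: significance test undefined")
    phi = float(np.clip(np.dot(x[:-1], x[1:]) / np.dot(x[:-1], x[:-1]), -0.999, 0.999))
    sd = float(np.sqrt(var * (1 - phi**2)))
    return phi, sd


def _ar1_surrogate(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    eps = rng.normal(0.0, sd, n + 64)  # burn-in to forget the zero start
    sim = lfilter([1.0], [1.0, -phi], eps)
    return sim[64:]


def coherence_significance(
    e_left,
    e_right,
    fps: float,
    n_surrogates: int = 300,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    **cwt_kwargs,
) -> tuple[np.ndarray, CoherenceResult]:
    """Pointwise Monte-Carlo significance of the observed coherence.

    The null model is a pair of independent AR(1) processes fitted to
    each series.  For each scale, surrogate coherence values are pooled
    over time and surrogates; a cell is significant when the observed R²
    exceeds the pooled (1 − alpha) quantile at its scale.  Deterministic
    for a fixed seed.

    Returns ``(mask, observed_result)``.
    """
    if n_surrogates < 100:
        raise ValueError(f"need at least 100 surrogates, got {n_surrogates}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, _ = _fill_gaps(np.asarray(e_left, dtype=float))
    y, _ = _fill_gaps(np.asarray(e_right, dtype=float))
    phi_x, sd_x = _fit_ar1(x)
    phi_y, sd_y = _fit_ar1(y)

    observed = wavelet_coherence(x, y, fps, **cwt_kwargs)
    n_scales, n = observed.coherence.shape

    # pooled null distribution per scale, accumulated as histograms in [0, 1]
    n_bins = 4096
    counts = np.zeros((n_scales, n_bins), dtype=np.int64)
    for _ in range(n_surrogates):
        sx = _ar1_surrogate(n, phi_x, sd_x, rng)
        sy = _ar1_surrogate(n, phi_y, sd_y, rng)
        r2 = wavelet_coherence(sx, sy, fps, **cwt_kwargs).coherence
        clipped = np.clip(r2, 0.0, 1.0 - 1e-12)
        bins = (clipped * n_bins).astype(np.int64)
        for j in range(n_scales):
            counts[j] += np.bincount(bins[j], minlength=n_bins)

    cdf = np.cumsum(counts, axis=1) / counts.sum(axis=1, keepdims=True)
    q = np.argmax(cdf >= 1.0 - alpha, axis=1)  # first bin reaching the quantile
    threshold = (q + 1) / n_bins  # upper edge: conservative within one bin
    mask = observed.coherence > threshold[:, None]
    return mask, observed
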