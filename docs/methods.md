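# Methods

This note documents the models, conventions, and numerical choices
behind `dyadkin`, and what the synthetic-data tests do and do not show
about real recordings.

## Data model

OpenPose writes one JSON file per video frame; each entry of the
`people` array holds flat `[x, y, c, …]` arrays per region, with fixed
lengths (body 25, face 70, each hand 21) and `(0, 0, 0)` marking a
missed detection. Coordinates are image pixels (origin top-left, y
downward); `c ∈ [0, 1]` is detector confidence. At ingestion the zero
sentinel becomes NaN coordinates with confidence 0 so all later stages
treat missingness uniformly; a zero-confidence triplet with non-zero
coordinates is kept but counted in the table's event log, since it is
ambiguous rather than definitively absent.

The central container is the **dyad table**: a long-format DataFrame
keyed by `(base_filename, frame, region, person)` with `x{k}, y{k},
c{k}` triplet columns, carrying the recording metadata `fps` and
`frame_width`. Frame rate is *not* stored in OpenPose output, so it is
a user parameter (default 30, warned when defaulted); every kinematic
quantity depends on `Δt = 1/fps`. Frames missing between the first and
last observed index get sentinel rows so every `(person, region)` series
lives on one complete, strictly increasing frame base — interpolation,
differencing, and alignment all rely on that.

Frame indices come from the trailing zero-padded counter of the
standard `*_keypoints.json` filenames, falling back to lexicographic
rank with a warning. When a frame holds more than two detections, the
two with the highest mean body confidence are kept (ties broken by
lower detector index) and the event is recorded in the gap report.

## Dyad identity

Two per-frame policies, chosen by the user:

- **midline** — each detection's mean x over *confident* (c > 0) body
  keypoints is compared with `frame_width / 2` (default 1,920 px).
  The body region drives the assignment and face/hand rows inherit it,
  because body is the most complete region. When both detections land
  on one side, or tie exactly on the midline, they are ranked by mean x
  (smaller → left) with a warning — the split-screen assumption is then
  violated and the result is a best effort. The rule is deliberately
  memoryless: no temporal smoothing is applied, so violations surface in
  the consistency report (frames where a person's mean x crosses the
  midline) instead of being silently corrected.
- **openpose_order** — the detector's array order is trusted: index 0 is
  left, index 1 right, regardless of position. This is the right choice
  when OpenPose's own tracking has been enabled upstream; it is
  invariant to any coordinate perturbation by construction.

## Cleaning

**Quality profile.** Per `(person, region, keypoint)`: mean confidence
over all frames with missed detections counted as 0, and completeness =
fraction of frames with c > 0. Completeness and the missing fraction
used by the removal rules are exact complements.

**Removal** applies rules in a fixed order — user-specified keypoints,
never-detected keypoints, mean confidence below a threshold, missing
fraction above a threshold — and with `apply_equally` takes the union of
the two persons' removal sets so the dyad keeps identical column sets
(required by any synchrony analysis). Removing every keypoint is an
error rather than an empty table. A keypoint removed for only some
groups is masked to NaN there; one removed everywhere loses its columns.

**Interpolation** replaces samples with confidence below a threshold
(default 0.3, logged) with a natural cubic spline fitted on frame index
against the valid samples. Natural boundary conditions and a strict
no-extrapolation rule (leading/trailing gaps stay missing) were chosen
because spline extrapolation diverges violently at recording
boundaries; frame index rather than seconds is the abscissa, which is
equivalent up to scaling for uniform sampling. Groups with fewer than
two valid samples are skipped with a warning. A second pass is a no-op,
since every sample is then valid.

**Smoothing** offers four methods with conventional mild defaults, all
overridable: centred moving average (window 5), Kolmogorov–Zurbenko
adaptive (base window 5, 3 iterations; the KZ-filtered series provides a
break detector that shrinks the local window near sharp level shifts),
Savitzky–Golay (window 11, order 3), and Butterworth (order 2, cutoff
10% of Nyquist) applied forward–backward for zero phase. Output length
always equals input length; positions missing on input are missing on
output — smoothers never invent samples. Savitzky–Golay and Butterworth
run per contiguous valid segment; segments too short for the window or
filter pad are left unfiltered.

**Descriptive statistics** use the unbiased sample variance,
linear-interpolation quantiles for the IQR, and plain moment estimators
for skewness and kurtosis (reported as excess), with no small-sample
bias correction — a determinate, documented convention.

## Kinematics

First-order backward differences on the frame grid: velocity
`v[i] = (p[i] − p[i−1])/Δt` (pixels/s), then acceleration and jerk by
repeating the difference. Two modes:

- *axis_wise*: signed per-axis series `v_x{k}`, `v_y{k}`, ….
- *euclidean*: the magnitude `√(Δx² + Δy²)/Δt` per keypoint. Higher
  derivatives difference the retained **axis components**, not the
  magnitude itself — `a[i] = √((vx[i]−vx[i−1])² + (vy[i]−vy[i−1])²)/Δt`
  — because differencing the speed magnitude is a different (and less
  informative) quantity. The axis components are therefore kept
  alongside the magnitudes in euclidean output.

The first frame of each group has no predecessor; derivatives there are
missing rather than dropped, keeping table alignment, and the export
path trims the leading underived row so kinematic CSVs start at frame 2.
Any missing operand propagates to a missing derivative. Confidence
columns pass through untouched.

## Motion energy

Per keypoint, `Δx = x_t − x_{t−1}` and `Δy = y_t − y_{t−1}`; with
coordinate aggregation these combine into the Euclidean step magnitude.
`absolute` sums magnitudes across keypoints (a linear measure of total
movement, homogeneous of degree 1 in the coordinates); `squared` sums
squared magnitudes (degree 2, weighting energetic motions more).
Missing keypoints contribute zero with a per-frame coverage fraction
recorded, so a person's series never goes missing wholesale. The series
starts at the second frame.

## Wavelet coherence

The synchrony core is written here, not delegated. Conventions follow
the standard continuous-wavelet literature:

- Morlet mother wavelet with ω₀ = 6; dyadic scales `s_j = s0·2^(j·dj)`
  with `dj = 1/12`, `s0 = 2·dt`, and J spanning up to `N·dt/s0`.
  The transform is evaluated in the Fourier domain on the demeaned,
  zero-padded (next power of two) series with unit-energy normalisation.
- Equivalent Fourier period `λ = 4π·s / (ω₀ + √(2 + ω₀²)) ≈ 1.033·s`,
  used to map scales to Hz for band summaries.
- Cone of influence: e-folding time `√2·s`, reported as the longest
  edge-unaffected period per sample.
- Coherence `R²(t,s) = |S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s))` with a
  smoothing operator S that is a scale-dependent Gaussian (σ = s) along
  time and a boxcar over 0.6 octave along scale. Both kernels are
  non-negative and identical across the three smoothed fields, so the
  Cauchy–Schwarz bound keeps R² in [0, 1] up to ~1e-9 of floating-point
  noise (asserted by property tests; values are not clipped).
- Phase is the angle of the smoothed cross spectrum `W_x·conj(W_y)`;
  positive phase means the left person leads.

Band summaries average R² over the `(t, s)` cells whose equivalent
frequency falls in `[f_lo, f_hi)`. Edge-affected cells are excluded by
default (a flag includes them), and a band no resolvable scale falls in
is an error naming the band. Input series must be equal length and
aligned; interior gaps are linearly interpolated before the transform
(the transform needs gap-free input) with the interpolated fraction
warned above 10%.

**Significance.** The null model is a pair of independent AR(1)
processes with lag-1 autocorrelation and variance fitted to each series
— the conventional red-noise null for movement data. Surrogate pairs
(default 300, minimum 100; mandatory seed) are transformed exactly like
the data; per scale, their coherence values pooled over time form the
null distribution (accumulated as 4096-bin histograms to bound memory),
and a cell is significant when observed R² exceeds the pooled 95th
percentile at its scale. Because neighbouring cells are strongly
correlated, the *realised* significant fraction under the null
fluctuates around 5% from run to run; the acceptance calibration
therefore averages the fraction over several independent white-noise
pairs rather than trusting a single map.

Note one practical subtlety: motion energy rectifies an oscillation
(the energy of an f₀ sway peaks at 2·f₀), so coherence of energy series
shows coupling at and above the movement frequency. Analyses that need
the oscillation frequency and phase lag exactly should run the
coherence on the coordinate series themselves, as the parameter-recovery
check does.

## Synthetic recordings

The generator emulates what the pipeline must survive, with known
ground truth: two BODY_25 skeletons anchored at 25% and 75% of the
frame width, sinusoidal motion components per person, an optional
coupled component (shared frequency, right person lagging by a fixed
time — defaults 0.25 Hz and 0.5 s, the slow-rhythm regime band
summaries target), white Gaussian positional noise (default 1 px),
i.i.d. Bernoulli dropout written as the `(0,0,0)` sentinel (with an
optional burst mode for interpolation edge cases), confidence drawn
from a clipped normal with a floor, and an optional scripted side-swap
along a logistic ramp for breaking the midline policy on purpose.
Schematic face and hand layouts (jittered rings anchored on nose and
wrists) can be added; only their counts and JSON layout matter, not
their geometry. Everything is deterministic given the spec's seed.

What this does *not* emulate: biomechanically valid articulation,
detector confusion between the two people, identity switches in the
`people` array, correlated (non-white) coordinate noise, or
scene-dependent confidence structure. Tests passing on these fixtures
establish the pipeline's arithmetic and bookkeeping, not detector
behaviour on real video.

## Problem sizes and determinism

The test and acceptance runs use recordings of 256–1,024 frames for
spectral checks (a 1,024-sample series at 30 FPS resolves the 0.1–0.5 Hz
band with in-cone cells to spare), a 9,000-frame recording for the
file-handling check, and 5 white-noise pairs × 300 surrogates for the
significance calibration — sizes chosen so the full suite exercises
every path at meaningful spectral resolution while remaining quick on a
single CPU. All randomness flows from explicit seeds; the end-to-end
CLI pipeline rerun with one seed is byte-identical.

## Known limitations

- Identity is purely per-frame; recordings where people trade sides
  need the detector's own tracking (`openpose_order`) or manual repair
  guided by the consistency report.
- Pixel units throughout; no metric calibration, no angular kinematics.
- Significance is pointwise, not corrected for the many correlated
  cells of a coherence map; treat the contour as descriptive.
- The rMEA export writes headerless two-column text with the sampling
  rate in a JSON sidecar; other dialects of that toolkit's input are
  not produced.
- `individual` CSV export splits by person only, not additionally by
  region.
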