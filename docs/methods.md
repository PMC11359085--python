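# Methods

This note documents the models implemented in `thermomimic`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish about real acquisitions.

## Thermal recovery model

Skin temperature after a 30 s cooling stimulus is modeled per pixel as a
double exponential `f(t) = θ1 + θ2·e^{θ3 t} + θ4·e^{θ5 t}` with
non-positive rates: θ1 is the recovered plateau (°C), θ2 and θ4 are
(negative) amplitudes encoding the cooling depression, and θ3, θ5 (1/s)
are a slow and a fast recovery rate. The initial temperature is the model
value at t = 0, i.e. θ1 + θ2 + θ4 — deliberately *not* the first sample,
which carries sensor noise.

**Fitting.** The five-parameter problem is solved by variable projection:
for fixed rates the model is linear in (θ1, θ2, θ4), so a trust-region
solver (`scipy.optimize.least_squares`, rates bounded ≤ 0) optimizes only
the two rates, with the amplitudes profiled out by linear least squares at
every step. This is the standard reformulation of exponential fitting; it
removes the amplitude/rate ill-conditioning that plagues the raw
5-parameter problem and is several times faster. The deterministic
initializer places the slow rate at 1/e-time = 20 % of the record and the
fast rate at 5 %. Up to three restarts with rate scalings (×0.3, ×3, ×10)
run only when the solver reports non-convergence; if all fail the fit
falls back to the flat model with `converged=False` rather than raising —
non-convergent pixels are excluded downstream, never fatal.

**Selection.** The margin rule keeps pixels with |f(0) − T_ref| ≤ p·T_ref.
The absolute value matters: a one-sided rule would never reject pixels that
cooled *more* than the lesion, defeating the purpose of selecting
comparably-cooled tissue. T_ref is computed over all converged lesion-area
fits *before* intersection with S, and the margin defaults to p = 0.01.

## Features and classification

d and Ed are computed from the representative (raw-average) TRCs of L* and
N*; Ed is kept signed internally but the classifier consumes |Ed|, since it
is used as a magnitude of dissimilarity. Member TRCs entering the
similitude statistics are the *fitted* curves, unit-normalized, mirroring
the treatment of the class-descriptive curves f_M and f_B, which are built
by averaging the five θ parameters across training lesions of each class
(averaging parameters, not curves — the two differ whenever rates differ)
and evaluating on the sampling grid. Feature names follow
`stat_<model>_<area>`: e.g. `rho_sd_B_L` is the standard deviation of the
correlation of the benign model against lesion-area TRCs.

**Bootstrap protocol.** Each repetition resamples the record set with
replacement to its original size and splits it 80/20. The split is made
over the *distinct* records in the resample, multiplicities preserved:
splitting raw positions would routinely place bootstrap copies of one
lesion on both sides, letting the classifier score memorized duplicates
(we measured a label-permutation null of ≈75 % accuracy under the naive
split versus the correct ≈50 % under the grouped split). A repetition is
redrawn when the test portion lacks one of the two classes or the training
portion holds fewer than two distinct records of either class (one lone
record makes the fold's descriptive model degenerate); redraws are capped
and logged. The descriptive curves f_M/f_B are rebuilt inside every
training fold — building them once on all data would leak test labels into
the features.

## Noise characterization

**Spatial.** β is the time-average of a blackbody stack minus its scalar
spatial mean; 180 frames is the reference depth, giving a per-pixel CLT
error of σ_HF/√180. Maps are characterized on the 15–40 °C grid in 5 °C
steps; at degradation time the map whose setpoint is nearest the scene's
spatio-temporal mean is applied (the selection rule is otherwise
unconstrained, and nearest-setpoint is the only choice that uses the grid).

**NUC jumps.** Shutter-based recalibration steps are detected in the first
difference of the frame-mean series. Because the recovery itself moves the
frame mean fast early on, the differences are first detrended with a
running median (window = 2·min_gap+1); deviations beyond 6× the MAD scale,
and at least 0.01 °C (below NETD nothing is a camera jump), are flagged,
subject to a 5-frame minimum gap. Each step's magnitude is removed from
all subsequent frames; the operation is idempotent and
translation-equivariant. Only frame-global steps are modeled — the
step artifacts these cameras produce are frame-global, and the camera's
internal gain logic is not observable.

**Temporal.** Per detector, the low-frequency drift is a Fourier series of
order Z (default 3) in a fundamental ω found by grid search: 200
candidates spanning periods from the record length down to 30 s, linear
least squares for the coefficients at each candidate, minimum-RSS winner.
σ_HF is the standard deviation of the residual. Per-detector ω is the
default; a shared-ω mode (fitted jointly across detectors) is available as
a faster alternative. Constant series take the documented degenerate
solution (a0 = mean, ω = smallest candidate, σ_HF = 0).

**Paired-video mode.** When a simultaneous two-camera acquisition exists,
the target's temporal noise is characterized from its own video: the
recovery model is fitted and subtracted per pixel, and the residual is
decomposed as above. A naive sequential fit absorbs ~6 % of the drift
amplitude into the recovery model (the decaying exponential resembles the
first drift cycle); one alternation pass — refit the recovery on the
drift-subtracted series, then refit the drift — reduces the amplitude
error below 1 % and is the default (`n_refine=1`).

## Degradation pipeline

Stages run strictly in the order: temporal downsampling → PSF → spatial
noise → temporal noise. The nearest-index downsampling rule (output frame
k' takes source frame round(k'·fps_src/fps_target)) introduces no
interpolation and bounds the timing error by half a source period. Frames
are convolved with reflective boundary handling. Spatial dimensions are
not resized by default; when enabled for a smaller target array, integer
block-averaging with margin cropping is used — never interpolation, which
would introduce noise uncharacteristic of the target. Synthesized
low-frequency noise re-randomizes the fundamental's phase per pixel by
default so mimicked videos do not replay the characterization record;
`paired_video` mode reuses the fitted phases verbatim, which is the
correct setting when validating against the very video that was
characterized.

## Registration

Marker corners are tracked frame-to-frame by normalized cross-correlation
template matching (7 px template, 11 px search window, 0.5 score floor;
window clipping at image borders is origin-corrected). Pairwise affine
transforms are estimated by least squares (≥3 non-collinear points; 4
used), composed relative to frame 0, and applied with bilinear sampling;
a 3-pixel border is then cropped so no retained TRC touches the marker.
First-frame corner coordinates are supplied rather than selected
interactively; the sampler and the tracker are explicit substitutes for
procedures that are usually manual or unspecified.

## Synthetic data

The generators define the study conditions: 64×64 scenes, 90 s recovery at
50 fps ground truth, ambient 20–22 °C, a centered lesion disk of radius
I/4. Per-pixel θ fields are class means plus spatially smoothed jitter
(Gaussian filter, σ = 3 px, renormalized to the configured marginal
spread), so neighboring TRCs are highly correlated as in real skin.
Default parameters (benign plateau 31.5 °C, cooled start 28 °C; malignant
plateau 32 °C with roughly doubled recovery rates, same cooled start) are
configuration, not biology: no published θ ranges exist for these tissue
classes, and all are exposed in `SkinSceneConfig`. The cooling transient
itself is not simulated — the analysis consumes only the recovery, whose
depressed starting point is encoded in the amplitudes.

Blackbody stacks are setpoint + generated fixed pattern (low/mid/high
spatial-frequency mixture at 0.1 °C RMS, zero spatial mean) + the
profile's temporal noise; the true pattern is retrievable for oracle
tests. Ambient drift is a per-detector sinusoid (0.3 °C, 60 s period,
small amplitude/phase jitter) — a Fourier-series surrogate for the
air-conditioning cycle rather than a thermostat simulation, since in-camera
NUC makes an ambient-driven physical model unidentifiable anyway. NUC
jumps are frame-global ±1 °C steps at fixed intervals.

What passing tests show — and don't. The synthetic scenes obey the
double-exponential model exactly (plus configured noise), so fit-recovery
results are upper bounds on real-data behavior; real skin adds motion,
perfusion heterogeneity, and model misfit. Mimicry correlations near 0.98
likewise reflect scenes whose signal dominates noise; they establish that
the pipeline transfers characterized noise correctly, not that any real
camera pair would reach the same coefficient.

## Problem sizes and numerics

The full-scale experiments run at 64×64 × 90 s (4 096 TRCs, the same order
as the ~7 000 TRCs of a registered clinical acquisition); unit tests use
12×12–32×32 scenes at 2–10 fps. Tolerances: PSF normalization and β
zero-mean to 1e−9; oracle equivalence of the feature primitives to 1e−10;
Fourier normal equations satisfied to 1e−8. Degenerate inputs are
contracts, not errors: constant series fit exactly, zero-variance
similitude members are skipped with a log line, non-finite pixels are
flagged invalid and excluded.

## Known limitations

Raw-count radiometric calibration, camera SDKs, deformable registration,
detector geometry/fill factor, and shutter-induced gain changes are out of
scope. The degradation model assumes the target's noise is stationary over
the acquisition and independent of scene temperature apart from the
nearest-setpoint β choice. The classifier evaluation treats one lesion as
one record; per-TRC classification is deliberately unsupported.
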