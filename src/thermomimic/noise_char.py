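"""Camera noise characterization from blackbody stacks and paired videos.

Microbolometer cameras staring at a uniform blackbody show three noise
components that the degradation model must reproduce:

* **spatial (fixed-pattern) noise** β — the time-averaged image minus its
  scalar spatial mean, capturing non-uniformities and low/mid/high spatial
  frequency structure;
* **low-frequency temporal drift** — slow oscillations driven by the room's
  air-conditioning cycle, modeled per detector as a Fourier series
  ``N_LF[k] = Σ_z a_z cos(z ω k/fs) + b_z sin(z ω k/fs)``;
* **high-frequency temporal noise** — the white Gaussian residual with
  per-detector standard deviation σ_HF.

Cameras with an aggressive non-uniformity correction (NUC) additionally show
frame-global step discontinuities ("jumps") which must be removed before the
drift can be modeled; detection operates on the frame-mean series with a
robust (MAD-based) threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import trc
from .core_io import (
    CameraProfile,
    NUCCorrectionParams,
    SpatialNoiseMap,
    TemporalNoiseModel,
    ThermalCube,
    ValidationError,
)

__all__ = [
    "extract_spatial_noise",
    "correct_nuc_jumps",
    "fit_temporal_noise_series",
    "fit_temporal_noise_multi",
    "characterize_camera",
    "extract_video_temporal_noise",
    "omega_grid",
]

#: Default Fourier order for the low-frequency drift model.
DEFAULT_FOURIER_ORDER = 3

#: Default ω grid resolution for the fundamental-frequency search.
DEFAULT_OMEGA_GRID_POINTS = 200

#: Shortest fundamental drift period considered, seconds.
DEFAULT_MIN_PERIOD_S = 30.0


# ---------------------------------------------------------------------------
# Spatial noise
# ---------------------------------------------------------------------------

def extract_spatial_noise(stack: ThermalCube, setpoint: float) -> SpatialNoiseMap:
    """Fixed-pattern noise β from a blackbody stack.

    Averaging the frames in time removes temporal noise; subtracting the
    scalar spatial mean of that average leaves the zero-mean fixed pattern.
    """
    if not np.all(np.isfinite(stack.data)):
        raise ValidationError("blackbody stack contains non-finite values")
    mean_image = stack.data.mean(axis=2)
    beta = mean_image - mean_image.mean()
    # re-center exactly: float accumulation can leave ~1e-13 residue
    beta -= beta.mean()
    return SpatialNoiseMap(beta=beta, setpoint=float(setpoint), n_frames_used=stack.n_frames)


# ---------------------------------------------------------------------------
# NUC jump correction
# ---------------------------------------------------------------------------

def correct_nuc_jumps(
    cube: ThermalCube,
    params: Optional[NUCCorrectionParams] = None,
) -> tuple[ThermalCube, list[tuple[int, float]]]:
    """Detect and remove frame-global NUC step discontinuities.

    Steps are found in the first difference of the frame-mean series: a
    running-median trend (recovery itself changes the frame mean smoothly,
    fast at first) is removed, and detrended differences beyond a
    MAD-scaled threshold are flagged.  Each detected step's magnitude is
    subtracted from all subsequent frames.  Returns the corrected cube and
    ``(first_affected_frame, magnitude)`` pairs.  Idempotent on its own
    output; a jump-free cube is returned unchanged.
    """
    params = params or NUCCorrectionParams()
    if cube.n_frames < 3:
        raise ValidationError("NUC correction needs at least 3 frames")
    m = cube.data.mean(axis=(0, 1))
    d = np.diff(m)
    window = max(2 * params.min_gap_frames + 1, 5)
    trend = ndimage.median_filter(d, size=min(window, d.size), mode="nearest")
    dev = np.abs(d - trend)
    mad = np.median(dev)
    scale = 1.4826 * mad
    threshold = max(params.jump_threshold_k * scale, params.min_jump_C)

    candidates = np.flatnonzero(dev > threshold)
    # keep the strongest candidate within any min_gap window
    accepted: list[int] = []
    for idx in sorted(candidates, key=lambda q: -dev[q]):
        if all(abs(idx - a) >= params.min_gap_frames for a in accepted):
            accepted.append(idx)
    accepted.sort()

    if not accepted:
        return cube, []

    corrected = cube.data.copy()
    jumps: list[tuple[int, float]] = []
    for q in accepted:
        magnitude = float(d[q] - trend[q])
        corrected[:, :, q + 1:] -= magnitude
        jumps.append((q + 1, magnitude))
    return ThermalCube(corrected, cube.fps, cube.t0), jumps


# ---------------------------------------------------------------------------
# Temporal (Fourier LF + Gaussian HF) noise
# ---------------------------------------------------------------------------

def omega_grid(
    n_samples: int,
    fs: float,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
    n_points: int = DEFAULT_OMEGA_GRID_POINTS,
) -> np.ndarray:
    """Candidate fundamental frequencies (rad/s), ascending.

    Periods range from the full record length down to ``min_period_s``
    (shortened if the record itself is shorter than that).
    """
    duration = n_samples / fs
    period_max = duration
    period_min = min(min_period_s, duration / 2.0)
    return np.linspace(2 * np.pi / period_max, 2 * np.pi / period_min, n_points)


def _design_matrix(omega: float, t: np.ndarray, Z: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    for z in range(1, Z + 1):
        cols.append(np.cos(z * omega * t))
        cols.append(np.sin(z * omega * t))
    return np.column_stack(cols)


def _pack_coefficients(coef: np.ndarray, Z: int) -> tuple[np.ndarray, np.ndarray]:
    """Columns [1, cos ω, sin ω, cos 2ω, ...] -> a[0..Z], b[0..Z] (b0 = 0)."""
    a = np.zeros(coef.shape[:-1] + (Z + 1,))
    b = np.zeros_like(a)
    a[..., 0] = coef[..., 0]
    for z in range(1, Z + 1):
        a[..., z] = coef[..., 2 * z - 1]
        b[..., z] = coef[..., 2 * z]
    return a, b


def fit_temporal_noise_multi(
    series: np.ndarray,
    fs: float,
    Z: int = DEFAULT_FOURIER_ORDER,
    grid: Optional[np.ndarray] = None,
    shared_omega: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the Fourier-LF + Gaussian-HF model to many series at once.

    ``series`` is (K, P): K time samples for P detectors.  For each
    candidate ω the LF coefficients solve a linear least-squares problem for
    every detector simultaneously; each detector keeps the ω minimizing its
    residual sum of squares (or, with ``shared_omega``, the ω minimizing the
    total RSS).  Returns ``(a (P, Z+1), b (P, Z+1), omega (P,), sigma_hf (P,))``.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = y.shape
    if n < 2 * (2 * Z + 2):
        raise ValidationError(f"need >= {2 * (2 * Z + 2)} samples for Fourier order {Z}")
    if not fs > 0:
        raise ValidationError("fs must be positive")
    t = np.arange(n) / fs
    if grid is None:
        grid = omega_grid(n, fs)

    means = y.mean(axis=0)
    degenerate = y.std(axis=0) <= 1e-14

    best_rss = np.full(p, np.inf)
    best_omega = np.full(p, grid[0])
    n_coef = 2 * Z + 1
    best_coef = np.zeros((p, n_coef))
    total_best = (np.inf, grid[0], None)

    for omega in grid:
        X = _design_matrix(float(omega), t, Z)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)  # (n_coef, P)
        rss = np.einsum("kp->p", (y - X @ coef) ** 2)
        if shared_omega:
            tot = float(rss.sum())
            if tot < total_best[0] - 1e-15:
                total_best = (tot, float(omega), coef)
        else:
            better = rss < best_rss - 1e-15
            if better.any():
                best_rss[better] = rss[better]
                best_omega[better] = omega
                best_coef[better] = coef.T[better]

    if shared_omega:
        _, omega_sel, coef = total_best
        best_omega[:] = omega_sel
        best_coef[:] = coef.T
        X = _design_matrix(omega_sel, t, Z)
        resid = y - X @ best_coef.T
    else:
        resid = np.empty_like(y)
        for omega in np.unique(best_omega):
            sel = best_omega == omega
            X = _design_matrix(float(omega), t, Z)
            resid[:, sel] = y[:, sel] - X @ best_coef[sel].T

    sigma_hf = resid.std(axis=0)

    # contract for rank-deficient/constant series
    if degenerate.any():
        best_coef[degenerate] = 0.0
        best_coef[degenerate, 0] = means[degenerate]
        best_omega[degenerate] = grid[0]
        sigma_hf[degenerate] = 0.0

    a, b = _pack_coefficients(best_coef, Z)
    return a, b, best_omega, sigma_hf


def fit_temporal_noise_series(
    series: np.ndarray,
    fs: float,
    Z: int = DEFAULT_FOURIER_ORDER,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Single-detector convenience wrapper around :func:`fit_temporal_noise_multi`."""
    a, b, omega, sigma_hf = fit_temporal_noise_multi(np.asarray(series)[:, None], fs, Z, grid)
    return a[0], b[0], float(omega[0]), float(sigma_hf[0])


def evaluate_lf(
    a: np.ndarray,
    b: np.ndarray,
    omega: np.ndarray,
    t: np.ndarray,
    phase: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Evaluate the Fourier LF model on times ``t``.

    ``a``/``b`` are (..., Z+1), ``omega`` (...); an optional per-detector
    ``phase`` (rad) shifts the fundamental term only.  Returns (..., len(t)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    omega = np.asarray(omega, dtype=float)
    Z = a.shape[-1] - 1
    out = np.broadcast_to(a[..., 0:1], a.shape[:-1] + (t.size,)).copy()
    for z in range(1, Z + 1):
        angle = z * omega[..., None] * t
        if phase is not None and z == 1:
            angle = angle + np.asarray(phase)[..., None]
        out += a[..., z:z + 1] * np.cos(angle) + b[..., z:z + 1] * np.sin(angle)
    return out


# ---------------------------------------------------------------------------
# Camera-level characterization
# ---------------------------------------------------------------------------

def characterize_camera(
    stacks: Sequence[tuple[ThermalCube, float]],
    profile: CameraProfile,
    Z: int = DEFAULT_FOURIER_ORDER,
    shared_omega: bool = False,
) -> CameraProfile:
    """Populate a profile's noise artifacts from blackbody stacks.

    Each ``(stack, setpoint)`` pair is NUC-corrected, then contributes one
    spatial-noise map; the per-detector temporal model is fitted on the
    longest (corrected) stack.  Deterministic.
    """
    if not stacks:
        raise ValidationError("need at least one blackbody stack")
    setpoints = [sp for _, sp in stacks]
    if len(set(setpoints)) != len(setpoints):
        raise ValidationError(f"duplicate setpoints in {setpoints}")

    nuc = profile.nuc or NUCCorrectionParams()
    spatial: dict[float, SpatialNoiseMap] = {}
    corrected: list[ThermalCube] = []
    for stack, setpoint in stacks:
        clean, _ = correct_nuc_jumps(stack, nuc)
        corrected.append(clean)
        spatial[float(setpoint)] = extract_spatial_noise(clean, setpoint)

    longest = max(corrected, key=lambda c: c.n_frames)
    i_dim, j_dim, k_dim = longest.shape
    flat = longest.data.reshape(i_dim * j_dim, k_dim).T  # (K, P)
    a, b, omega, sigma_hf = fit_temporal_noise_multi(
        flat, longest.fps, Z, shared_omega=shared_omega
    )
    model = TemporalNoiseModel(
        a=a.reshape(i_dim, j_dim, Z + 1),
        b=b.reshape(i_dim, j_dim, Z + 1),
        omega=omega.reshape(i_dim, j_dim),
        sigma_hf=sigma_hf.reshape(i_dim, j_dim),
        fs=longest.fps,
    )
    return dataclasses.replace(profile, spatial_noise=spatial, temporal_noise=model)


def extract_video_temporal_noise(
    cube: ThermalCube,
    Z: int = DEFAULT_FOURIER_ORDER,
    shared_omega: bool = False,
    n_refine: int = 1,
) -> TemporalNoiseModel:
    """Characterize temporal noise from a registered recovery video.

    For each pixel the double-exponential recovery model is fitted and
    subtracted; the residual is the pixel's temporal noise, which is then
    decomposed into the Fourier LF drift and the Gaussian HF floor.  Because
    the decaying recovery partially correlates with the first drift cycle, a
    naive sequential fit absorbs part of the drift into the recovery model;
    ``n_refine`` alternation passes (refit the recovery on the
    drift-subtracted series, then refit the drift on the new residual)
    remove most of that leakage.  Pixels whose recovery fit fails are
    flagged invalid and excluded.  This is the paired-video
    characterization mode used for mimicry validation.
    """
    i_dim, j_dim, k_dim = cube.shape
    t = cube.times - cube.t0
    n_px = i_dim * j_dim
    series_flat = cube.data.reshape(n_px, k_dim)
    valid = np.all(np.isfinite(series_flat), axis=1)

    a = np.zeros((n_px, Z + 1))
    b = np.zeros_like(a)
    omega = np.full(n_px, 1e-3)
    sigma = np.zeros(n_px)
    lf_flat = np.zeros((n_px, k_dim))

    for _pass in range(n_refine + 1):
        nt = np.zeros((n_px, k_dim))
        for p in np.flatnonzero(valid):
            fit = trc.fit_double_exponential(series_flat[p] - lf_flat[p], cube.fps)
            if not fit.converged:
                valid[p] = False
                continue
            nt[p] = series_flat[p] - fit(t)
        if not valid.any():
            break
        av, bv, ov, sv = fit_temporal_noise_multi(
            nt[valid].T, cube.fps, Z, shared_omega=shared_omega
        )
        a[valid] = av
        b[valid] = bv
        omega[valid] = ov
        sigma[valid] = sv
        if _pass < n_refine:
            lf_flat[valid] = evaluate_lf(av, bv, ov, t)

    return TemporalNoiseModel(
        a=a.reshape(i_dim, j_dim, Z + 1),
        b=b.reshape(i_dim, j_dim, Z + 1),
        omega=omega.reshape(i_dim, j_dim),
        sigma_hf=sigma.reshape(i_dim, j_dim),
        fs=cube.fps,
        valid=valid.reshape(i_dim, j_dim),
    )
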