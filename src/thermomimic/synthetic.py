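"""Synthetic thermal acquisitions: skin scenes, camera renders, blackbodies.

The clinical data this pipeline was designed around cannot be shared, so
every input is emulated:

* **skin scenes** — per-pixel double-exponential recovery after a 30 s
  cooling stimulus, in a 20–22 °C room, captured for 90 s.  A disk-shaped
  pigmented lesion carries class-dependent recovery parameters; parameter
  fields are spatially smoothed so neighbouring TRCs are highly correlated,
  as in real skin.  The cooling transient itself is not modeled: the
  analysis consumes only the recovery, whose depressed starting point is
  encoded in the θ amplitudes.
* **camera renders** — the noiseless scene pushed through a camera profile:
  temporal downsampling to the camera's frame rate, PSF blur, fixed-pattern
  β, Fourier-drift + Gaussian temporal noise, and (for NUC-afflicted
  cameras) frame-global step discontinuities.
* **blackbody stacks** — uniform setpoint plus a generated fixed pattern
  (low/mid/high spatial frequency mixture, zero spatial mean) plus the
  profile's temporal noise; the ground-truth pattern is retrievable for
  oracle comparisons.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .core_io import (
    AcquisitionRecord,
    CameraProfile,
    NUCJumpSimParams,
    SpatialNoiseMap,
    TemporalNoiseModel,
    ThermalCube,
    ValidationError,
    gaussian_psf_kernel,
)
from .degrade import apply_psf, synthesize_temporal_noise, temporal_downsample
from .degrade import add_spatial_noise as _add_beta

__all__ = [
    "ThetaDistribution",
    "SkinSceneConfig",
    "generate_trc",
    "generate_acquisition",
    "generate_blackbody_stack",
    "generate_paired_acquisition",
    "make_drift_model",
    "make_camera_profile",
    "apply_nuc_jumps",
    "CHARACTERIZATION_SETPOINTS_C",
]

#: Blackbody characterization grid (°C): 15–40 °C in 5 °C steps.
CHARACTERIZATION_SETPOINTS_C = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)

#: Smoothing scale (pixels) for the per-pixel θ jitter fields.
THETA_SMOOTHING_PX = 3.0


@dataclass
class ThetaDistribution:
    """Mean vector and diagonal spread for the five recovery parameters."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (5,) or self.sd.shape != (5,):
            raise ValidationError("theta mean and sd must have 5 entries")
        if self.mean[2] >= 0 or self.mean[4] >= 0:
            raise ValidationError("recovery rates θ3, θ5 must have negative means")
        if (self.sd < 0).any():
            raise ValidationError("theta spreads must be non-negative")


def _default_benign() -> ThetaDistribution:
    # plateau ~31.5 °C, cooled start f0 = 28 °C, slow + fast recovery terms
    return ThetaDistribution(
        mean=np.array([31.5, -2.5, -0.05, -1.0, -0.5]),
        sd=np.array([0.15, 0.08, 0.004, 0.04, 0.03]),
    )


def _default_lesion_benign() -> ThetaDistribution:
    # benign pigmented lesions recover like surrounding skin
    return ThetaDistribution(
        mean=np.array([31.5, -2.5, -0.05, -1.0, -0.5]),
        sd=np.array([0.15, 0.08, 0.004, 0.04, 0.03]),
    )


def _default_lesion_malignant() -> ThetaDistribution:
    # angiogenesis: warmer plateau and faster recovery, same cooled start
    return ThetaDistribution(
        mean=np.array([32.0, -3.0, -0.12, -1.0, -0.9]),
        sd=np.array([0.15, 0.08, 0.008, 0.04, 0.05]),
    )


@dataclass
class SkinSceneConfig:
    """Ground-truth scene: geometry, recovery statistics, protocol timing."""

    shape: tuple[int, int] = (64, 64)
    fps_truth: float = 50.0
    duration_s: float = 90.0
    lesion_center: Optional[tuple[float, float]] = None  # default: frame center
    lesion_radius_px: float = 12.0
    theta_benign: ThetaDistribution = field(default_factory=_default_benign)
    theta_lesion_benign: ThetaDistribution = field(default_factory=_default_lesion_benign)
    theta_lesion_malignant: ThetaDistribution = field(default_factory=_default_lesion_malignant)
    ambient_C: float = 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 <= self.ambient_C <= 22.0):
            raise ValidationError("ambient_C must lie in the protocol range [20, 22] °C")
        i_dim, j_dim = self.shape
        center = self.lesion_center or ((i_dim - 1) / 2.0, (j_dim - 1) / 2.0)
        self.lesion_center = (float(center[0]), float(center[1]))
        r = self.lesion_radius_px
        if (
            center[0] - r < 0
            or center[1] - r < 0
            or center[0] + r > i_dim - 1
            or center[1] + r > j_dim - 1
        ):
            raise ValidationError("lesion disk must fit inside the frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps_truth))


def generate_trc(theta: np.ndarray, K_IR: int, fps: float) -> np.ndarray:
    """Sample f(kTs) = θ1 + θ2 e^{θ3 kTs} + θ4 e^{θ5 kTs}, k = 0..K_IR−1."""
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValidationError("theta must be finite")
    if K_IR < 2 or not fps > 0:
        raise ValidationError("need K_IR >= 2 and fps > 0")
    t = np.arange(K_IR) / fps
    return th[0] + th[1] * np.exp(th[2] * t) + th[3] * np.exp(th[4] * t)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Zero-mean spatially smooth jitter with marginal standard deviation sd."""
    if sd == 0:
        return np.zeros(shape)
    raw = rng.normal(0.0, 1.0, size=shape)
    smooth = ndi.gaussian_filter(raw, THETA_SMOOTHING_PX, mode="reflect")
    scale = smooth.std()
    if scale <= 1e-12:
        return np.zeros(shape)
    return smooth / scale * sd


def _theta_fields(
    rng: np.random.Generator,
    scene: SkinSceneConfig,
    label: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel θ (I, J, 5) and the lesion mask."""
    i_dim, j_dim = scene.shape
    rows, cols = np.ogrid[:i_dim, :j_dim]
    cr, cc = scene.lesion_center
    mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= scene.lesion_radius_px**2

    skin = scene.theta_benign
    lesion = scene.theta_lesion_benign if label == "benign" else scene.theta_lesion_malignant
    theta = np.empty((i_dim, j_dim, 5))
    for c in range(5):
        base = np.where(mask, lesion.mean[c], skin.mean[c])
        jitter_skin = _smooth_field(rng, (i_dim, j_dim), skin.sd[c])
        jitter_lesion = _smooth_field(rng, (i_dim, j_dim), lesion.sd[c])
        theta[:, :, c] = base + np.where(mask, jitter_lesion, jitter_skin)
    # guard: smoothing jitter must never flip a recovery rate positive
    theta[:, :, 2] = np.minimum(theta[:, :, 2], -1e-4)
    theta[:, :, 4] = np.minimum(theta[:, :, 4], -1e-4)
    return theta, mask


def generate_acquisition(
    scene: SkinSceneConfig,
    label: str = "benign",
    return_theta: bool = False,
):
    """Noiseless ground-truth acquisition for one lesion.

    Every pixel's TRC is a double exponential with parameters drawn from the
    benign-skin distribution outside the lesion disk and from the
    class-dependent lesion distribution inside it; jitter fields are
    low-pass filtered so nearby TRCs are highly correlated.  With
    ``return_theta`` the (I, J, 5) parameter field is also returned for
    oracle checks.
    """
    if label not in ("benign", "BCC", "SCC", "MM"):
        raise ValidationError(f"invalid lesion label {label!r}")
    rng = np.random.default_rng(scene.seed)
    theta, mask = _theta_fields(rng, scene, label)
    t = np.arange(scene.n_frames) / scene.fps_truth
    data = (
        theta[:, :, 0:1]
        + theta[:, :, 1:2] * np.exp(theta[:, :, 2:3] * t)
        + theta[:, :, 3:4] * np.exp(theta[:, :, 4:5] * t)
    )
    record = AcquisitionRecord(
        cube=ThermalCube(data, fps=scene.fps_truth),
        lesion_mask=mask,
        visible=(0.8 - 0.5 * mask.astype(float)),  # flat rendering of the mask
        label=label,
        subject_id=f"synthetic-{scene.seed}",
    )
    if return_theta:
        return record, theta
    return record


# ---------------------------------------------------------------------------
# Synthetic camera profiles
# ---------------------------------------------------------------------------

def make_drift_model(
    shape: tuple[int, int],
    fs: float,
    amplitude_C: float = 0.3,
    period_s: float = 60.0,
    sigma_hf_C: float = 0.07,
    Z: int = 3,
    seed: int = 0,
    amplitude_jitter: float = 0.05,
    phase_jitter_rad: float = 0.1,
) -> TemporalNoiseModel:
    """Ambient-drift temporal model: one dominant sinusoid per detector.

    The air-conditioning cycle drives a shared oscillation; per-detector
    amplitude and phase vary slightly.  Harmonics above the fundamental are
    zero (Z only sets the stored order).
    """
    rng = np.random.default_rng(seed)
    i_dim, j_dim = shape
    omega = np.full((i_dim, j_dim), 2 * np.pi / period_s)
    amp = amplitude_C * (1.0 + amplitude_jitter * rng.normal(size=(i_dim, j_dim)))
    phase = rng.uniform(0, 2 * np.pi) + phase_jitter_rad * rng.normal(size=(i_dim, j_dim))
    a = np.zeros((i_dim, j_dim, Z + 1))
    b = np.zeros_like(a)
    a[:, :, 1] = amp * np.cos(phase)
    b[:, :, 1] = -amp * np.sin(phase)  # A cos(ωt + ψ) = A cos ψ cos ωt − A sin ψ sin ωt
    sigma = np.full((i_dim, j_dim), float(sigma_hf_C))
    return TemporalNoiseModel(a=a, b=b, omega=omega, sigma_hf=sigma, fs=fs)


def _beta_true(
    rng: np.random.Generator, shape: tuple[int, int], rms_C: float
) -> np.ndarray:
    """Fixed pattern with low/mid/high spatial-frequency parts, zero mean."""
    low = ndi.gaussian_filter(rng.normal(size=shape), 6.0, mode="reflect")
    mid = ndi.gaussian_filter(rng.normal(size=shape), 1.5, mode="reflect")
    high = rng.normal(size=shape)
    parts = []
    for weight, comp in ((0.5, low), (0.3, mid), (0.2, high)):
        std = comp.std()
        parts.append(weight * comp / std if std > 0 else np.zeros(shape))
    beta = sum(parts)
    beta -= beta.mean()
    std = beta.std()
    if std > 0:
        beta *= rms_C / std
    beta -= beta.mean()
    return beta


def make_camera_profile(
    name: str,
    fps: float,
    shape: tuple[int, int] = (64, 64),
    netd_mK: float = 70.0,
    sigma_hf_C: float = 0.07,
    drift_amplitude_C: float = 0.3,
    drift_period_s: float = 60.0,
    psf_sigma_px: float = 1.2,
    beta_rms_C: float = 0.1,
    nuc_jumps: Optional[NUCJumpSimParams] = None,
    seed: int = 0,
) -> CameraProfile:
    """Fully characterized synthetic camera profile at the given frame size."""
    rng = np.random.default_rng(seed)
    spatial: dict[float, SpatialNoiseMap] = {}
    for setpoint in CHARACTERIZATION_SETPOINTS_C:
        beta = _beta_true(rng, shape, beta_rms_C)
        spatial[setpoint] = SpatialNoiseMap(beta, setpoint, n_frames_used=180)
    temporal = None
    if sigma_hf_C > 0 or drift_amplitude_C > 0:
        temporal = make_drift_model(
            shape,
            fs=fps,
            amplitude_C=drift_amplitude_C,
            period_s=drift_period_s,
            sigma_hf_C=sigma_hf_C,
            seed=int(rng.integers(2**31)),
        )
    return CameraProfile(
        name=name,
        fps=fps,
        fpa=shape,
        netd_mK=netd_mK,
        psf=gaussian_psf_kernel(psf_sigma_px),
        spatial_noise=spatial,
        temporal_noise=temporal,
        nuc_jumps=nuc_jumps,
    )


# ---------------------------------------------------------------------------
# Blackbody stacks
# ---------------------------------------------------------------------------

def generate_blackbody_stack(
    profile: CameraProfile,
    setpoint: float,
    n_frames: int = 180,
    seed: int = 0,
    shape: Optional[tuple[int, int]] = None,
    beta_rms_C: float = 0.1,
    return_truth: bool = False,
):
    """Simulated blackbody acquisition: setpoint + fixed pattern + noise.

    The fixed pattern β_true mixes low-, mid- and high-spatial-frequency
    components with zero spatial mean.  Temporal noise comes from the
    profile's drift model (when present); NUC jumps are injected when the
    profile carries a simulation block.  With ``return_truth`` the generated
    β_true is returned alongside the cube.
    """
    if n_frames < 2:
        raise ValidationError("need at least 2 frames")
    shape = shape or profile.fpa
    rng = np.random.default_rng(seed)
    beta = _beta_true(rng, shape, beta_rms_C)
    data = np.full(shape + (n_frames,), float(setpoint)) + beta[:, :, None]
    if profile.temporal_noise is not None:
        from .degrade import _crop_model

        model = _crop_model(profile.temporal_noise, shape)
        data = data + synthesize_temporal_noise(
            model, n_frames, profile.fps, seed=int(rng.integers(2**31)), random_phase=True
        )
    cube = ThermalCube(data, fps=profile.fps)
    if profile.nuc_jumps is not None:
        cube = apply_nuc_jumps(cube, profile.nuc_jumps, seed=int(rng.integers(2**31)))
    if return_truth:
        return cube, beta
    return cube


def apply_nuc_jumps(
    cube: ThermalCube, params: NUCJumpSimParams, seed: int = 0
) -> ThermalCube:
    """Inject frame-global step offsets at fixed wall-clock intervals.

    Each step has the configured magnitude with a random sign; offsets
    accumulate, as produced by a camera's shutter-based recalibration.
    """
    rng = np.random.default_rng(seed)
    duration = cube.n_frames / cube.fps
    data = cube.data.copy()
    n_jumps = int(duration / params.interval_s)
    for n in range(1, n_jumps + 1):
        frame = int(round(n * params.interval_s * cube.fps))
        if frame >= cube.n_frames:
            break
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[:, :, frame:] += sign * params.magnitude_C
    return ThermalCube(data, cube.fps, cube.t0)


# ---------------------------------------------------------------------------
# Paired two-camera acquisitions
# ---------------------------------------------------------------------------

def _render_through_camera(
    truth: AcquisitionRecord, profile: CameraProfile, seed: int
) -> AcquisitionRecord:
    """Push the noiseless scene through one camera's optics and noise."""
    rng = np.random.default_rng(seed)
    cube = temporal_downsample(truth.cube, profile.fps)
    cube = apply_psf(cube, profile.psf)
    if profile.spatial_noise:
        cube, _ = _add_beta(cube, profile)
    if profile.temporal_noise is not None:
        from .degrade import _crop_model

        model = _crop_model(profile.temporal_noise, cube.frame_shape)
        cube = ThermalCube(
            cube.data
            + synthesize_temporal_noise(
                model, cube.n_frames, cube.fps, seed=int(rng.integers(2**31))
            ),
            cube.fps,
            cube.t0,
        )
    if profile.nuc_jumps is not None:
        cube = apply_nuc_jumps(cube, profile.nuc_jumps, seed=int(rng.integers(2**31)))
    return AcquisitionRecord(
        cube=cube,
        lesion_mask=truth.lesion_mask,
        visible=truth.visible,
        label=truth.label,
        subject_id=f"{truth.subject_id}:{profile.name}",
    )


def generate_paired_acquisition(
    scene: SkinSceneConfig,
    profile_hq: CameraProfile,
    profile_lq: CameraProfile,
    label: str = "benign",
) -> tuple[AcquisitionRecord, AcquisitionRecord]:
    """One scene rendered simultaneously through two camera profiles.

    Both records share the scene seed, so the underlying physiology is
    identical; only the optics and the (independent) noise differ.
    """
    if profile_lq.fps > profile_hq.fps:
        raise ValidationError(
            f"low-quality fps {profile_lq.fps} exceeds high-quality fps {profile_hq.fps}"
        )
    if profile_hq.fps > scene.fps_truth:
        raise ValidationError("high-quality fps exceeds the ground-truth rate")
    truth = generate_acquisition(scene, label)
    seeds = np.random.SeedSequence(scene.seed).spawn(2)
    hq = _render_through_camera(truth, profile_hq, seed=int(seeds[0].generate_state(1)[0] % 2**31))
    lq = _render_through_camera(truth, profile_lq, seed=int(seeds[1].generate_state(1)[0] % 2**31))
    return hq, lq
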