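"""Degrade a high-quality thermal video to mimic a lower-cost camera.

The model touches the three resolutions a camera trades off:

1. **temporal** — the frame sequence is downsampled in the ratio
   fps_HQ : fps_target with a nearest-source-frame rule (no interpolation);
2. **spatial** — each frame is convolved with the target camera's point
   spread function (spatial dimensions themselves are left unchanged by
   default; optional integer block-averaging is available when the target
   focal-plane array is smaller);
3. **thermal** — the target's characterized fixed-pattern noise β is added
   to every frame, followed by per-detector temporal noise: the Fourier
   low-frequency drift (optionally with a re-randomized phase on the
   fundamental) plus the white Gaussian high-frequency floor.

The stages always run in that order; a camera profile produced by
:mod:`thermomimic.noise_char` supplies every parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core_io import (
    AcquisitionRecord,
    CameraProfile,
    TemporalNoiseModel,
    ThermalCube,
    ValidationError,
)
from .noise_char import evaluate_lf

__all__ = [
    "DegradationConfig",
    "temporal_downsample",
    "downsample_indices",
    "apply_psf",
    "add_spatial_noise",
    "synthesize_temporal_noise",
    "spatial_block_downsample",
    "degrade_cube",
]


@dataclass
class DegradationConfig:
    """Configuration for one degradation run.

    ``mode='paired_video'`` reuses the fitted drift phases verbatim (the
    validation setting, where the target model was characterized from the
    very video being mimicked); ``mode='blackbody_profile'`` re-randomizes
    the fundamental's phase per pixel so mimicked videos do not replay the
    characterization record.
    """

    target_profile: CameraProfile
    mode: str = "blackbody_profile"
    seed: int = 0
    apply_stages: dict[str, bool] = field(
        default_factory=lambda: {
            "temporal": True,
            "psf": True,
            "spatial_noise": True,
            "temporal_noise": True,
        }
    )
    spatial_downsample: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("blackbody_profile", "paired_video"):
            raise ValidationError(f"unknown degradation mode {self.mode!r}")
        defaults = {"temporal": True, "psf": True, "spatial_noise": True, "temporal_noise": True}
        defaults.update(self.apply_stages)
        self.apply_stages = defaults


# ---------------------------------------------------------------------------
# Stage 1: temporal downsampling
# ---------------------------------------------------------------------------

def downsample_indices(n_frames: int, fps_src: float, fps_target: float) -> np.ndarray:
    """Source frame index for each output frame under the nearest-index rule.

    Output frame k' takes source frame round(k'·fps_src/fps_target) for
    k' = 0, 1, ... while that index stays inside the source record.
    """
    if not 0 < fps_target <= fps_src:
        raise ValidationError(
            f"temporal downsampling requires 0 < fps_target <= fps_src "
            f"(got {fps_target} > {fps_src})"
        )
    ratio = fps_src / fps_target
    max_out = int(np.ceil(n_frames * fps_target / fps_src)) + 2
    idx = np.rint(np.arange(max_out) * ratio).astype(int)
    return idx[idx < n_frames]


def temporal_downsample(cube: ThermalCube, fps_target: float) -> ThermalCube:
    """Keep every source frame nearest to the target sampling times."""
    if fps_target == cube.fps:
        return cube
    idx = downsample_indices(cube.n_frames, cube.fps, fps_target)
    return ThermalCube(cube.data[:, :, idx], fps=fps_target, t0=cube.t0)


# ---------------------------------------------------------------------------
# Stage 2: PSF blur (and optional spatial downsampling)
# ---------------------------------------------------------------------------

def apply_psf(cube: ThermalCube, psf: Optional[np.ndarray]) -> ThermalCube:
    """Convolve every frame with the target PSF (reflective boundaries)."""
    if psf is None:
        return cube
    psf = np.asarray(psf, dtype=float)
    if psf.shape[0] % 2 == 0 or psf.shape[1] % 2 == 0:
        raise ValidationError(f"PSF kernel sides must be odd, got {psf.shape}")
    if abs(float(psf.sum()) - 1.0) > 1e-9:
        raise ValidationError("PSF kernel must be normalized")
    if psf.shape == (1, 1):
        return cube
    out = ndimage.convolve(cube.data, psf[:, :, None], mode="reflect")
    return ThermalCube(out, cube.fps, cube.t0)


def spatial_block_downsample(cube: ThermalCube, factor: int) -> ThermalCube:
    """Integer block-averaging; any non-divisible margin is cropped."""
    if factor < 1:
        raise ValidationError("block factor must be >= 1")
    if factor == 1:
        return cube
    i_dim, j_dim, k_dim = cube.shape
    i_crop, j_crop = (i_dim // factor) * factor, (j_dim // factor) * factor
    if i_crop == 0 or j_crop == 0:
        raise ValidationError("frame smaller than one block")
    data = cube.data[:i_crop, :j_crop, :]
    blocks = data.reshape(i_crop // factor, factor, j_crop // factor, factor, k_dim)
    return ThermalCube(blocks.mean(axis=(1, 3)), cube.fps, cube.t0)


# ---------------------------------------------------------------------------
# Stage 3: spatial (fixed-pattern) noise
# ---------------------------------------------------------------------------

def add_spatial_noise(cube: ThermalCube, profile: CameraProfile) -> tuple[ThermalCube, float]:
    """Add the β map whose setpoint is nearest the cube's mean temperature.

    β has zero spatial mean, so per-frame spatial means are unchanged.  A β
    larger than the frame is cropped top-left anchored.  Returns the cube
    and the setpoint that was used.
    """
    setpoint = profile.nearest_setpoint(float(cube.data.mean()))
    beta = profile.spatial_noise[setpoint].beta
    i_dim, j_dim = cube.frame_shape
    if beta.shape[0] < i_dim or beta.shape[1] < j_dim:
        raise ValidationError(
            f"β map {beta.shape} smaller than frame {cube.frame_shape}"
        )
    patch = beta[:i_dim, :j_dim]
    patch = patch - patch.mean()  # cropping may break zero-mean; restore it
    return ThermalCube(cube.data + patch[:, :, None], cube.fps, cube.t0), setpoint


# ---------------------------------------------------------------------------
# Stage 4: temporal noise synthesis
# ---------------------------------------------------------------------------

def synthesize_temporal_noise(
    model: TemporalNoiseModel,
    K_IR: int,
    fps: float,
    seed: int,
    random_phase: bool = True,
) -> np.ndarray:
    """Draw an (I, J, K_IR) noise cube from a fitted temporal model.

    Low frequency: the per-detector Fourier series evaluated at k/fps, with
    a per-pixel U[0, 2π) phase offset on the fundamental when
    ``random_phase``.  High frequency: independent N(0, σ_HF²) samples.
    Detectors flagged invalid contribute zero noise.
    """
    if K_IR < 1:
        raise ValidationError("K_IR must be >= 1")
    if not fps > 0:
        raise ValidationError("fps must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(K_IR) / fps
    phase = rng.uniform(0.0, 2 * np.pi, size=model.frame_shape) if random_phase else None
    lf = evaluate_lf(model.a, model.b, model.omega, t, phase=phase)
    hf = rng.normal(0.0, 1.0, size=lf.shape) * model.sigma_hf[:, :, None]
    noise = lf + hf
    noise[~model.valid_mask] = 0.0
    return noise


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def degrade_cube(record: AcquisitionRecord, config: DegradationConfig) -> AcquisitionRecord:
    """Run the full degradation pipeline on a registered acquisition.

    Stage order is fixed: temporal downsampling, PSF blur, fixed-pattern
    noise, temporal noise.  The lesion mask is carried through unchanged
    spatially; marker-corner lists are subsampled in time alongside the
    frames.  The result carries the target camera's frame rate.
    """
    profile = config.target_profile
    stages = config.apply_stages
    cube = record.cube
    corners = record.marker_corners

    if stages.get("temporal", True) and profile.fps != cube.fps:
        idx = downsample_indices(cube.n_frames, cube.fps, profile.fps)
        if corners is not None and corners.ndim == 3:
            corners = corners[idx]
        cube = ThermalCube(cube.data[:, :, idx], fps=profile.fps, t0=cube.t0)

    mask = record.lesion_mask
    if config.spatial_downsample:
        factor = max(
            1,
            min(cube.frame_shape[0] // profile.fpa[0], cube.frame_shape[1] // profile.fpa[1]),
        )
        if factor > 1:
            cube = spatial_block_downsample(cube, factor)
            i_crop = cube.frame_shape[0] * factor
            j_crop = cube.frame_shape[1] * factor
            blocks = mask[:i_crop, :j_crop].reshape(
                cube.frame_shape[0], factor, cube.frame_shape[1], factor
            )
            mask = blocks.mean(axis=(1, 3)) >= 0.5
            corners = None

    if stages.get("psf", True):
        cube = apply_psf(cube, profile.psf)

    if stages.get("spatial_noise", True) and profile.spatial_noise:
        cube, _ = add_spatial_noise(cube, profile)

    if stages.get("temporal_noise", True) and profile.temporal_noise is not None:
        model = profile.temporal_noise
        noise = synthesize_temporal_noise(
            _crop_model(model, cube.frame_shape),
            cube.n_frames,
            cube.fps,
            seed=config.seed,
            random_phase=(config.mode == "blackbody_profile"),
        )
        cube = ThermalCube(cube.data + noise, cube.fps, cube.t0)

    return dataclasses.replace(
        record, cube=cube, lesion_mask=mask, marker_corners=corners
    )


def _crop_model(model: TemporalNoiseModel, frame_shape: tuple[int, int]) -> TemporalNoiseModel:
    """Crop a temporal-noise model to a smaller frame (top-left anchored)."""
    if model.frame_shape == frame_shape:
        return model
    i_dim, j_dim = frame_shape
    if model.frame_shape[0] < i_dim or model.frame_shape[1] < j_dim:
        raise ValidationError(
            f"temporal model {model.frame_shape} smaller than frame {frame_shape}"
        )
    return TemporalNoiseModel(
        a=model.a[:i_dim, :j_dim],
        b=model.b[:i_dim, :j_dim],
        omega=model.omega[:i_dim, :j_dim],
        sigma_hf=model.sigma_hf[:i_dim, :j_dim],
        fs=model.fs,
        valid=None if model.valid is None else model.valid_mask[:i_dim, :j_dim],
    )
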