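"""Domain containers and on-disk formats for infrared acquisitions.

An acquisition is a per-pixel temperature movie (a *thermal cube*, °C) of
skin recovering after a cooling stimulus, optionally paired with a visible
reference image, a lesion mask, and tracked marker corners.  A camera is
described by a :class:`CameraProfile`: nominal specifications (frame rate,
focal-plane-array size, NETD) plus the characterized noise artifacts that
the degradation pipeline consumes — per-setpoint fixed-pattern (spatial)
noise maps, a per-detector temporal-noise model and a point-spread-function
kernel.

On disk a cube is a multi-page float32 TIFF next to a JSON sidecar holding
the scalar metadata, with the mask and visible image as PNGs.  A single
``.npz`` archive is an accepted dialect.  Camera profiles are YAML, with
array-valued noise artifacts in a companion ``.npz`` referenced from the
YAML.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml
from PIL import Image

__all__ = [
    "ThermalCube",
    "AcquisitionRecord",
    "CameraProfile",
    "SpatialNoiseMap",
    "TemporalNoiseModel",
    "NUCCorrectionParams",
    "NUCJumpSimParams",
    "FormatError",
    "IntegrityError",
    "ValidationError",
    "read_cube",
    "write_cube",
    "load_camera_profile",
    "save_camera_profile",
    "gaussian_psf_kernel",
    "LESION_CLASSES",
    "MALIGNANT_CLASSES",
]

LESION_CLASSES = ("benign", "BCC", "SCC", "MM")
MALIGNANT_CLASSES = ("BCC", "SCC", "MM")

#: Plausible skin/blackbody temperature band (°C); values outside warn only.
PLAUSIBLE_RANGE_C = (0.0, 60.0)


class FormatError(ValueError):
    """A container on disk is not in the expected format."""


class IntegrityError(ValueError):
    """Stored data and its metadata disagree."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# Thermal cube
# ---------------------------------------------------------------------------

@dataclass
class ThermalCube:
    """I×J×K stack of per-pixel temperatures (°C) sampled at ``fps``.

    ``data[i, j, k]`` is the temperature of detector (row i, col j) in frame
    k; frame k corresponds to time ``t0 + k / fps`` seconds.
    """

    data: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"cube must be 3-D (I, J, K), got shape {self.data.shape}")
        i, j, k = self.data.shape
        if i < 1 or j < 1 or k < 2:
            raise ValidationError(f"cube needs I,J >= 1 and K >= 2 frames, got {self.data.shape}")
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0 + k/fps``."""
        return self.t0 + np.arange(self.n_frames) / self.fps

    def validate(self) -> None:
        """Check finiteness (error) and the plausible-range band (warning)."""
        finite = np.isfinite(self.data)
        if not finite.all():
            i, j, k = (int(x) for x in np.argwhere(~finite)[0])
            raise ValidationError(f"non-finite temperature at pixel (i={i}, j={j}, k={k})")
        lo, hi = PLAUSIBLE_RANGE_C
        if self.data.min() < lo or self.data.max() > hi:
            warnings.warn(
                f"cube temperatures outside plausible range [{lo}, {hi}] °C",
                stacklevel=2,
            )

    def copy(self) -> "ThermalCube":
        return ThermalCube(self.data.copy(), self.fps, self.t0)


@dataclass
class AcquisitionRecord:
    """One registered (or registerable) acquisition of one lesion."""

    cube: ThermalCube
    lesion_mask: np.ndarray
    visible: Optional[np.ndarray] = None
    marker_corners: Optional[np.ndarray] = None  # (K, 4, 2) float (row, col)
    label: Optional[str] = None  # benign / BCC / SCC / MM / None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.lesion_mask.shape != self.cube.frame_shape:
            raise ValidationError(
                f"lesion mask shape {self.lesion_mask.shape} does not match "
                f"frame shape {self.cube.frame_shape}"
            )
        if not self.lesion_mask.any() or self.lesion_mask.all():
            raise ValidationError("lesion mask must contain both lesion and non-lesion pixels")
        if self.label is not None and self.label not in LESION_CLASSES:
            raise ValidationError(f"unknown label {self.label!r}; expected one of {LESION_CLASSES}")
        if self.marker_corners is not None:
            self.marker_corners = np.asarray(self.marker_corners, dtype=float)

    @property
    def is_malignant(self) -> Optional[bool]:
        if self.label is None:
            return None
        return self.label in MALIGNANT_CLASSES


# ---------------------------------------------------------------------------
# Noise artifacts and camera profile
# ---------------------------------------------------------------------------

@dataclass
class SpatialNoiseMap:
    """Zero-mean fixed-pattern noise β extracted at one blackbody setpoint."""

    beta: np.ndarray
    setpoint: float
    n_frames_used: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise ValidationError("beta must be a 2-D map")
        mean = float(self.beta.mean())
        if abs(mean) > 1e-9:
            raise ValidationError(f"beta must have zero spatial mean, got {mean:.3e} °C")


@dataclass
class TemporalNoiseModel:
    """Per-detector Fourier-series drift plus white Gaussian residual.

    The low-frequency component of detector (i, j) at frame k (sampled at
    ``fs`` frames/s) is ``sum_z a[i,j,z] cos(z ω_ij k/fs) + b[i,j,z] sin(z ω_ij k/fs)``
    for z = 0..Z; the residual is N(0, sigma_hf[i,j]²).  ``b[..., 0]`` is
    identically 0 (sin 0 = 0).
    """

    a: np.ndarray  # (I, J, Z+1) °C
    b: np.ndarray  # (I, J, Z+1) °C
    omega: np.ndarray  # (I, J) rad/s
    sigma_hf: np.ndarray  # (I, J) °C
    fs: float
    valid: Optional[np.ndarray] = None  # (I, J) bool; None = all valid

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.sigma_hf = np.asarray(self.sigma_hf, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 3:
            raise ValidationError("a and b must both be (I, J, Z+1)")
        if self.omega.shape != self.a.shape[:2] or self.sigma_hf.shape != self.a.shape[:2]:
            raise ValidationError("omega and sigma_hf must be (I, J)")
        act = self.valid_mask
        if (self.sigma_hf[act] < 0).any():
            raise ValidationError("sigma_hf must be non-negative")
        if (self.omega[act] <= 0).any():
            raise ValidationError("omega must be positive")
        self.b[..., 0] = 0.0

    @property
    def Z(self) -> int:
        return self.a.shape[2] - 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.a.shape[:2]

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.a.shape[:2], dtype=bool)
        return np.asarray(self.valid, dtype=bool)


@dataclass
class NUCCorrectionParams:
    """Parameters for detecting/removing NUC step discontinuities."""

    jump_threshold_k: float = 6.0  # multiplier on MAD scale of frame-mean diffs
    min_gap_frames: int = 5
    min_jump_C: float = 0.01  # steps below NETD scale are not camera jumps

    def __post_init__(self) -> None:
        if not self.jump_threshold_k > 0:
            raise ValidationError("jump_threshold_k must be positive")
        if self.min_jump_C < 0:
            raise ValidationError("min_jump_C must be non-negative")


@dataclass
class NUCJumpSimParams:
    """Simulation-side NUC behavior: global step offsets at fixed intervals."""

    interval_s: float = 60.0
    magnitude_C: float = 1.0

    def __post_init__(self) -> None:
        if not self.interval_s > 0:
            raise ValidationError("interval_s must be positive")


@dataclass
class CameraProfile:
    """Static camera specs plus characterized noise artifacts."""

    name: str
    fps: float
    fpa: tuple[int, int] = (320, 240)
    netd_mK: float = 50.0
    psf: Optional[np.ndarray] = None  # normalized kernel; None = identity
    spatial_noise: dict[float, SpatialNoiseMap] = field(default_factory=dict)
    temporal_noise: Optional[TemporalNoiseModel] = None
    nuc: Optional[NUCCorrectionParams] = None
    nuc_jumps: Optional[NUCJumpSimParams] = None  # synthetic generators only

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.psf is not None:
            self.psf = np.asarray(self.psf, dtype=float)
            _check_psf(self.psf)
        self.fpa = (int(self.fpa[0]), int(self.fpa[1]))

    def nearest_setpoint(self, temperature: float) -> float:
        """Setpoint of the characterized β map closest to ``temperature``."""
        if not self.spatial_noise:
            raise ValidationError(f"profile {self.name!r} has no characterized spatial noise")
        return min(self.spatial_noise, key=lambda s: (abs(s - temperature), s))


def _check_psf(kernel: np.ndarray) -> None:
    if kernel.ndim != 2:
        raise ValidationError("PSF kernel must be 2-D")
    if kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValidationError(f"PSF kernel sides must be odd, got {kernel.shape}")
    if (kernel < 0).any():
        raise ValidationError("PSF kernel entries must be non-negative")
    s = float(kernel.sum())
    if abs(s - 1.0) > 1e-9:
        raise ValidationError(f"PSF kernel must sum to 1 (got {s!r})")


def gaussian_psf_kernel(sigma_px: float) -> np.ndarray:
    """Explicit normalized Gaussian kernel, side = 2·ceil(3σ)+1; σ=0 → 1×1."""
    if sigma_px < 0:
        raise ValidationError("sigma_px must be non-negative")
    if sigma_px == 0:
        return np.ones((1, 1))
    half = int(math.ceil(3.0 * sigma_px))
    x = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (x / sigma_px) ** 2)
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


# ---------------------------------------------------------------------------
# Cube container I/O
# ---------------------------------------------------------------------------

_SIDECAR = "meta.json"
_STACK = "cube.tif"
_MASK = "mask.png"
_VISIBLE = "visible.png"


def write_cube(record: AcquisitionRecord, path: str | Path) -> Path:
    """Write a record as TIFF stack + JSON sidecar (+ PNG mask/visible).

    ``path`` is a directory, created if needed.  The IR stack is stored as a
    multi-page float32 TIFF with pages along the frame axis.
    """
    record.cube.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(np.moveaxis(record.cube.data, 2, 0)).astype(np.float32)
    tifffile.imwrite(path / _STACK, data, photometric="minisblack")
    meta = {
        "fps": record.cube.fps,
        "t0": record.cube.t0,
        "n_frames": record.cube.n_frames,
        "label": record.label,
        "subject_id": record.subject_id,
        "corners": None
        if record.marker_corners is None
        else record.marker_corners.tolist(),
    }
    (path / _SIDECAR).write_text(json.dumps(meta, indent=1))
    Image.fromarray(record.lesion_mask.astype(np.uint8) * 255).save(path / _MASK)
    if record.visible is not None:
        vis = np.asarray(record.visible)
        if vis.dtype != np.uint8:
            vis = np.clip(vis * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(vis).save(path / _VISIBLE)
    return path


def read_cube(path: str | Path) -> AcquisitionRecord:
    """Read a record written by :func:`write_cube` (or an ``.npz`` dialect)."""
    path = Path(path)
    if path.suffix == ".npz":
        return _read_cube_npz(path)
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    stack = tifffile.imread(path / _STACK)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != meta["n_frames"]:
        raise IntegrityError(
            f"TIFF holds {stack.shape[0]} frames but sidecar declares {meta['n_frames']}"
        )
    cube = ThermalCube(np.moveaxis(stack, 0, 2), fps=meta["fps"], t0=meta.get("t0", 0.0))
    cube.validate()
    mask = np.asarray(Image.open(path / _MASK)) > 0
    visible = None
    if (path / _VISIBLE).exists():
        visible = np.asarray(Image.open(path / _VISIBLE))
    corners = meta.get("corners")
    return AcquisitionRecord(
        cube=cube,
        lesion_mask=mask,
        visible=visible,
        marker_corners=None if corners is None else np.asarray(corners, dtype=float),
        label=meta.get("label"),
        subject_id=meta.get("subject_id", ""),
    )


def _read_cube_npz(path: Path) -> AcquisitionRecord:
    with np.load(path, allow_pickle=False) as archive:
        required = {"data", "fps", "mask"}
        if not required <= set(archive.files):
            raise FormatError(f"npz cube must contain {sorted(required)}")
        cube = ThermalCube(
            archive["data"],
            fps=float(archive["fps"]),
            t0=float(archive["t0"]) if "t0" in archive.files else 0.0,
        )
        cube.validate()
        label = str(archive["label"]) if "label" in archive.files else None
        return AcquisitionRecord(
            cube=cube,
            lesion_mask=archive["mask"].astype(bool),
            visible=archive["visible"] if "visible" in archive.files else None,
            marker_corners=archive["corners"] if "corners" in archive.files else None,
            label=None if label in (None, "", "None") else label,
            subject_id=str(archive["subject_id"]) if "subject_id" in archive.files else "",
        )


# ---------------------------------------------------------------------------
# Camera profile I/O
# ---------------------------------------------------------------------------

def save_camera_profile(profile: CameraProfile, path: str | Path) -> Path:
    """Serialize a profile to YAML + companion ``.npz`` for array artifacts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    doc: dict = {
        "name": profile.name,
        "fps": float(profile.fps),
        "fpa": list(profile.fpa),
        "netd_mK": float(profile.netd_mK),
    }
    if profile.psf is not None:
        arrays["psf"] = profile.psf
    if profile.spatial_noise:
        doc["spatial_setpoints"] = sorted(float(s) for s in profile.spatial_noise)
        for sp, snm in profile.spatial_noise.items():
            arrays[f"beta_{sp:g}"] = snm.beta
            doc.setdefault("spatial_n_frames", {})[f"{sp:g}"] = int(snm.n_frames_used)
    tn = profile.temporal_noise
    if tn is not None:
        arrays.update(tn_a=tn.a, tn_b=tn.b, tn_omega=tn.omega, tn_sigma_hf=tn.sigma_hf)
        if tn.valid is not None:
            arrays["tn_valid"] = tn.valid_mask
        doc["temporal_fs"] = float(tn.fs)
    if profile.nuc is not None:
        doc["nuc"] = dataclasses.asdict(profile.nuc)
    if profile.nuc_jumps is not None:
        doc["nuc_jumps"] = dataclasses.asdict(profile.nuc_jumps)
    if arrays:
        npz_path = path.with_suffix(".npz")
        np.savez_compressed(npz_path, **arrays)
        doc["arrays"] = npz_path.name
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_camera_profile(path: str | Path) -> CameraProfile:
    """Load and validate a YAML camera profile.

    A parametric ``psf_sigma_px`` entry is expanded to an explicit normalized
    kernel.  Array artifacts live in the companion ``.npz`` named by the
    ``arrays`` key.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "name" not in doc or "fps" not in doc:
        raise FormatError(f"{path} is not a camera-profile YAML")
    arrays: dict[str, np.ndarray] = {}
    if "arrays" in doc:
        with np.load(path.parent / doc["arrays"], allow_pickle=False) as archive:
            arrays = {k: archive[k] for k in archive.files}

    psf = None
    if "psf_sigma_px" in doc:
        psf = gaussian_psf_kernel(float(doc["psf_sigma_px"]))
    elif "psf" in arrays:
        psf = arrays["psf"]

    spatial: dict[float, SpatialNoiseMap] = {}
    for sp in doc.get("spatial_setpoints", []):
        key = f"beta_{float(sp):g}"
        if key not in arrays:
            raise FormatError(f"profile declares setpoint {sp} but {key} missing from arrays")
        n_used = int(doc.get("spatial_n_frames", {}).get(f"{float(sp):g}", 0))
        spatial[float(sp)] = SpatialNoiseMap(arrays[key], float(sp), n_used)

    temporal = None
    if "tn_a" in arrays:
        temporal = TemporalNoiseModel(
            a=arrays["tn_a"],
            b=arrays["tn_b"],
            omega=arrays["tn_omega"],
            sigma_hf=arrays["tn_sigma_hf"],
            fs=float(doc["temporal_fs"]),
            valid=arrays.get("tn_valid"),
        )

    return CameraProfile(
        name=str(doc["name"]),
        fps=float(doc["fps"]),
        fpa=tuple(doc.get("fpa", (320, 240))),
        netd_mK=float(doc.get("netd_mK", 50.0)),
        psf=psf,
        spatial_noise=spatial,
        temporal_noise=temporal,
        nuc=NUCCorrectionParams(**doc["nuc"]) if "nuc" in doc else None,
        nuc_jumps=NUCJumpSimParams(**doc["nuc_jumps"]) if "nuc_jumps" in doc else None,
    )
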