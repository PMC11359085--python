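"""Marker-based affine registration of an IR sequence to its first frame.

The acquisition protocol places a plastic marker around the region of
interest; its four corners are visible in every frame.  Given the corner
coordinates in the first frame, each corner is tracked through the sequence
by normalized cross-correlation template matching, an affine transform is
estimated for each consecutive frame pair, the pairwise transforms are
composed relative to frame 0, and every frame is resampled (bilinear) onto
the frame-0 grid.  Because residual motion is bounded by a few pixels, a
3-pixel border is finally cropped so no retained TRC ever touches the
marker.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .core_io import AcquisitionRecord, ThermalCube, ValidationError

__all__ = [
    "AffineTransform",
    "TrackingLostError",
    "track_corners",
    "estimate_affine",
    "register_cube",
    "BORDER_CROP_PX",
]

#: Pixels removed from every side after alignment.
BORDER_CROP_PX = 3

#: Default square search-window width for corner tracking (pixels).
DEFAULT_SEARCH_WINDOW = 11

#: Default template patch width around a corner (pixels).
DEFAULT_TEMPLATE_SIZE = 7

#: Normalized-cross-correlation score below which tracking is declared lost.
DEFAULT_SCORE_FLOOR = 0.5


class TrackingLostError(RuntimeError):
    """A corner could not be located confidently in some frame."""


@dataclass
class AffineTransform:
    """2×3 matrix mapping homogeneous (row, col) source points to destination."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValidationError("affine matrix must be 2x3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("affine matrix must be finite")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValidationError("affine transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        lin = self.matrix[:, :2] @ other.matrix[:, :2]
        off = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return AffineTransform(np.column_stack([lin, off]))

    def inverse(self) -> "AffineTransform":
        lin = np.linalg.inv(self.matrix[:, :2])
        off = -lin @ self.matrix[:, 2]
        return AffineTransform(np.column_stack([lin, off]))


def estimate_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine transform mapping ``src`` points to ``dst``.

    Needs at least 3 non-collinear correspondences; exact for true affine
    motion, least-squares otherwise.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2 or src.shape[0] < 3:
        raise ValidationError("need matching (n>=3, 2) point arrays")
    design = np.column_stack([src, np.ones(src.shape[0])])
    if np.linalg.matrix_rank(design) < 3:
        raise ValidationError("points are collinear; affine transform is underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    return AffineTransform(coef.T)


def track_corners(
    frames: ThermalCube,
    initial_corners: np.ndarray,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    template_size: int = DEFAULT_TEMPLATE_SIZE,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Track four marker corners through the sequence by template matching.

    Each corner in frame k is located by matching a ``template_size`` patch
    (from frame k−1, centered at the previous position) inside a
    ``search_window`` neighbourhood of frame k.  Returns per-frame corner
    positions (K, 4, 2) and match scores (K, 4); frame 0 scores are 1.
    """
    corners0 = np.asarray(initial_corners, dtype=float)
    if corners0.shape != (4, 2):
        raise ValidationError("initial_corners must be four (row, col) points")
    k_dim = frames.n_frames
    positions = np.zeros((k_dim, 4, 2))
    scores = np.ones((k_dim, 4))
    positions[0] = corners0
    half_t = template_size // 2
    half_s = search_window // 2

    for k in range(1, k_dim):
        prev_frame = frames.data[:, :, k - 1]
        cur_frame = frames.data[:, :, k]
        for c in range(4):
            r0, c0 = (int(round(x)) for x in positions[k - 1, c])
            template, t_origin = _patch(prev_frame, r0, c0, half_t)
            region_half = half_s + half_t
            region, r_origin = _patch(cur_frame, r0, c0, region_half)
            response = match_template(region, template)
            if not np.isfinite(response).any():
                raise TrackingLostError(f"corner {c} untrackable at frame {k} (flat patch)")
            peak = np.unravel_index(np.nanargmax(response), response.shape)
            score = float(response[peak])
            if score < score_floor:
                raise TrackingLostError(
                    f"corner {c} lost at frame {k}: match score {score:.3f} < {score_floor}"
                )
            # displacement of the matched patch center vs the template center
            matched_center = np.array(r_origin) + np.array(peak) + half_t
            template_center = np.array(t_origin) + half_t
            positions[k, c] = positions[k - 1, c] + (matched_center - template_center)
            scores[k, c] = score
    return positions, scores


def _patch(
    image: np.ndarray, row: int, col: int, half: int
) -> tuple[np.ndarray, tuple[int, int]]:
    """Square patch clipped to the image; returns the patch and its origin."""
    i_dim, j_dim = image.shape
    r0 = min(max(row - half, 0), max(i_dim - (2 * half + 1), 0))
    c0 = min(max(col - half, 0), max(j_dim - (2 * half + 1), 0))
    return image[r0:r0 + 2 * half + 1, c0:c0 + 2 * half + 1], (r0, c0)


def register_cube(record: AcquisitionRecord) -> AcquisitionRecord:
    """Align every frame to frame 0 and crop the marker safety border.

    Per-frame corners are taken from the record when present ((K, 4, 2)
    array) or tracked from frame-0 corners ((4, 2) array).  Pairwise affine
    transforms are composed relative to frame 0; each frame is resampled by
    the composed transform with bilinear interpolation; then
    :data:`BORDER_CROP_PX` pixels are removed from every side.
    """
    cube = record.cube
    i_dim, j_dim, k_dim = cube.shape
    crop = BORDER_CROP_PX
    if i_dim <= 2 * crop or j_dim <= 2 * crop:
        raise ValidationError(
            f"frame {cube.frame_shape} too small for a {crop}-pixel border crop"
        )
    corners = record.marker_corners
    if corners is None:
        raise ValidationError("registration needs marker corners (per-frame or frame-0)")
    if corners.ndim == 2:
        corners, _ = track_corners(cube, corners)
    if corners.shape != (k_dim, 4, 2):
        raise ValidationError(f"corners must be (K, 4, 2); got {corners.shape}")

    registered = np.empty_like(cube.data)
    registered[:, :, 0] = cube.data[:, :, 0]
    to_frame = AffineTransform.identity()  # frame-0 coords -> frame-k coords
    for k in range(1, k_dim):
        pair = estimate_affine(corners[k - 1], corners[k])
        to_frame = pair.compose(to_frame)
        # output[p] = frame_k[to_frame(p)]: sample frame k at mapped frame-0 points
        registered[:, :, k] = ndimage.affine_transform(
            cube.data[:, :, k],
            to_frame.matrix[:, :2],
            offset=to_frame.matrix[:, 2],
            order=1,
            mode="nearest",
        )

    out_cube = ThermalCube(
        registered[crop:-crop, crop:-crop, :].copy(), cube.fps, cube.t0
    )
    mask = record.lesion_mask[crop:-crop, crop:-crop]
    reg_corners = np.broadcast_to(corners[0] - crop, (k_dim, 4, 2)).copy()
    return dataclasses.replace(
        record, cube=out_cube, lesion_mask=mask, marker_corners=reg_corners
    )
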