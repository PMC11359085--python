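"""Distance, energy, and statistical-similitude features for one lesion.

From the representative lesion and control TRCs two scalar contrasts are
computed:

* ``d`` — the Euclidean distance between the representative curves divided
  by the number of IR samples; large distance suggests malignancy.
* ``Ed`` — the difference of squared norms after each curve has its own
  minimum subtracted ("unbiased" curves), sensitive to smaller differences.

In addition, descriptive class models fM (malignant) and fB (benign) —
class-averaged double-exponential parameter vectors evaluated on the time
grid and scaled to unit norm — are compared against the modeled, normalized
member TRCs of the selected lesion (L*) and control (N*) sets.  For each of
the four (model × area) pairings, the mean and standard deviation of the
projection <fn, fm>, the Pearson correlation ρ(fm, fn), and the normalized
distance are recorded: 24 similitude features.  The classifier consumes the
4-vector [|Ed|, σρ_{B−L}, σproj_{B−N}, σd_{M−N}].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import AcquisitionRecord, ValidationError
from .trc import DoubleExpFit, SelectionResult, double_exponential, representative_trc

__all__ = [
    "DescriptiveModel",
    "FeatureVector",
    "euclidean_distance",
    "energy_difference",
    "build_descriptive_model",
    "similitude_features",
    "extract_features",
    "SIMILITUDE_NAMES",
    "SELECTED_FEATURE_NAMES",
    "MIN_SIMILITUDE_SET",
]

logger = logging.getLogger(__name__)

#: Minimum TRC-set size for similitude statistics; smaller sets warn.
MIN_SIMILITUDE_SET = 10

#: Naming: first letter = model class (M/B), second = area (L/N).
SIMILITUDE_NAMES = tuple(
    f"{stat}_{model}_{area}"
    for model in ("M", "B")
    for area in ("L", "N")
    for stat in ("proj_mean", "proj_sd", "rho_mean", "rho_sd", "dist_mean", "dist_sd")
)

SELECTED_FEATURE_NAMES = ("Ed_abs", "rho_sd_B_L", "proj_sd_B_N", "dist_sd_M_N")


def euclidean_distance(trc_a: np.ndarray, trc_b: np.ndarray) -> float:
    """L2 norm of the difference, divided by the number of IR samples."""
    a = np.asarray(trc_a, dtype=float)
    b = np.asarray(trc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("series must be 1-D with equal lengths")
    return float(np.linalg.norm(a - b) / a.size)


def energy_difference(trc_a: np.ndarray, trc_b: np.ndarray) -> float:
    """Signed difference of squared norms of the min-subtracted curves."""
    a = np.asarray(trc_a, dtype=float)
    b = np.asarray(trc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("series must be 1-D with equal lengths")
    ua = a - a.min()
    ub = b - b.min()
    return float(ua @ ua - ub @ ub)


@dataclass
class DescriptiveModel:
    """Unit-norm class-descriptive TRCs built from training fits only."""

    fM: np.ndarray
    fB: np.ndarray
    theta_M_mean: np.ndarray
    theta_B_mean: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.fM = np.asarray(self.fM, dtype=float)
        self.fB = np.asarray(self.fB, dtype=float)
        for name, f in (("fM", self.fM), ("fB", self.fB)):
            if abs(np.linalg.norm(f) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must have unit norm")


def _class_model(thetas: Sequence[np.ndarray], K_IR: int, fps: float) -> tuple[np.ndarray, np.ndarray]:
    theta_mean = np.mean(np.asarray(thetas, dtype=float), axis=0)
    t = np.arange(K_IR) / fps
    curve = double_exponential(theta_mean, t)
    norm = np.linalg.norm(curve)
    if norm <= 0:
        raise ValidationError("descriptive curve has zero norm")
    return curve / norm, theta_mean


def build_descriptive_model(
    fits_malignant: Iterable[DoubleExpFit],
    fits_benign: Iterable[DoubleExpFit],
    K_IR: int,
    fps: float,
) -> DescriptiveModel:
    """Average θ per class, evaluate the model curve, normalize to unit norm.

    The inputs are the representative-TRC fits of the *training* cubes of
    each class; the parameters — not the curves — are averaged.
    """
    thetas_m = [f.theta for f in fits_malignant if f.converged]
    thetas_b = [f.theta for f in fits_benign if f.converged]
    if not thetas_m or not thetas_b:
        raise ValidationError("need at least one converged training fit per class")
    fM, theta_m = _class_model(thetas_m, K_IR, fps)
    fB, theta_b = _class_model(thetas_b, K_IR, fps)
    return DescriptiveModel(fM=fM, fB=fB, theta_M_mean=theta_m, theta_B_mean=theta_b, fps=fps)


def similitude_features(trc_set: np.ndarray, model: np.ndarray) -> dict[str, float]:
    """Projection/correlation/distance statistics of a TRC set vs a model.

    ``trc_set`` is (n, K): n modeled, unit-normalized TRCs; ``model`` is the
    unit-norm descriptive curve.  Members with zero variance in time (ρ
    undefined) are skipped with a log message.  Returns the six statistics.
    """
    members = np.atleast_2d(np.asarray(trc_set, dtype=float))
    fm = np.asarray(model, dtype=float)
    if members.shape[0] == 0:
        raise ValidationError("similitude set is empty")
    if members.shape[1] != fm.size:
        raise ValidationError("member length does not match model length")
    if members.shape[0] < MIN_SIMILITUDE_SET:
        warnings.warn(
            f"similitude set has {members.shape[0]} < {MIN_SIMILITUDE_SET} TRCs",
            stacklevel=2,
        )

    variances = members.std(axis=1)
    usable = variances > 1e-14
    if not usable.all():
        logger.info("skipping %d zero-variance TRCs in similitude set", (~usable).sum())
    if not usable.any():
        raise ValidationError("all similitude-set members have zero variance")
    members = members[usable]

    proj = members @ fm
    fm_c = fm - fm.mean()
    mem_c = members - members.mean(axis=1, keepdims=True)
    rho = (mem_c @ fm_c) / (
        np.linalg.norm(mem_c, axis=1) * np.linalg.norm(fm_c)
    )
    dist = np.linalg.norm(members - fm, axis=1) / fm.size
    return {
        "proj_mean": float(proj.mean()),
        "proj_sd": float(proj.std()),
        "rho_mean": float(rho.mean()),
        "rho_sd": float(rho.std()),
        "dist_mean": float(dist.mean()),
        "dist_sd": float(dist.std()),
    }


@dataclass
class FeatureVector:
    """The 24 similitude features plus d and Ed, and the selected 4-vector."""

    d: float
    Ed: float
    similitude: dict[str, float]
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=float)
        if self.selected.shape != (4,):
            raise ValidationError("selected vector must have 4 entries")
        if self.d < 0:
            raise ValidationError("d must be non-negative")
        for key, value in self.similitude.items():
            if key.startswith("rho_mean") and not -1.0 - 1e-9 <= value <= 1.0 + 1e-9:
                raise ValidationError(f"{key} outside [-1, 1]")
            if "_sd" in key and value < 0:
                raise ValidationError(f"{key} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        out = {"d": self.d, "Ed": self.Ed}
        out.update(self.similitude)
        for name, value in zip(SELECTED_FEATURE_NAMES, self.selected):
            out[f"selected_{name}"] = float(value)
        return out


def modeled_member_curves(
    fits: np.ndarray,
    pixel_set: Iterable[tuple[int, int]],
    K_IR: int,
    fps: float,
) -> np.ndarray:
    """Evaluate and unit-normalize the fitted curves of a pixel set, (n, K)."""
    t = np.arange(K_IR) / fps
    curves = []
    for (i, j) in sorted(pixel_set):
        fit = fits[i, j]
        if not fit.converged:
            continue
        curve = fit(t)
        norm = np.linalg.norm(curve)
        if norm > 0:
            curves.append(curve / norm)
    if not curves:
        raise ValidationError("no usable modeled TRCs in pixel set")
    return np.asarray(curves)


def extract_features(
    record: AcquisitionRecord,
    selection: SelectionResult,
    model: DescriptiveModel,
    fits: np.ndarray,
) -> FeatureVector:
    """Assemble the full feature set for one acquisition.

    ``fits`` is the (I, J) per-pixel fit array used for selection; member
    curves entering the similitude statistics are the modeled (fitted)
    curves, unit-normalized, mirroring the treatment of fM/fB.
    """
    cube = record.cube
    rep_l = representative_trc(cube, selection.L_star)
    rep_n = representative_trc(cube, selection.N_star)
    d = euclidean_distance(rep_l, rep_n)
    ed = energy_difference(rep_l, rep_n)

    k_ir = cube.n_frames
    members = {
        "L": modeled_member_curves(fits, selection.L_star, k_ir, cube.fps),
        "N": modeled_member_curves(fits, selection.N_star, k_ir, cube.fps),
    }
    model_curves = {"M": model.fM, "B": model.fB}
    similitude: dict[str, float] = {}
    for model_key, fm in model_curves.items():
        for area_key, curves in members.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats = similitude_features(curves, fm)
            for stat, value in stats.items():
                similitude[f"{stat}_{model_key}_{area_key}"] = value

    selected = np.array(
        [
            abs(ed),
            similitude["rho_sd_B_L"],
            similitude["proj_sd_B_N"],
            similitude["dist_sd_M_N"],
        ]
    )
    return FeatureVector(d=d, Ed=ed, similitude=similitude, selected=selected)
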