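"""Bootstrap classifier evaluation and degradation-mimicry validation.

**Classifier evaluation.**  The unit of classification is the lesion (one
acquisition = one record).  Each bootstrap repetition resamples the record
set with replacement to its original size, splits the resample 80/20 into
training and test portions, rebuilds the class-descriptive TRCs fM/fB from
the training portion only (so no label information leaks into the features
of the test records), extracts the feature vectors, fits the classifier,
and scores the test portion.  Accuracy, TPR (overall and per malignant
subclass), TNR, and PPV are accumulated over repetitions and reported as
min/max/avg/sd percentages.

**Mimicry validation.**  A degradation model is judged by how faithfully a
degraded high-quality video reproduces the video actually captured by the
target camera: the Pearson correlation between the two TRCs is computed at
every pixel and summarized as mean ± sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import trc as trc_mod
from .core_io import AcquisitionRecord, MALIGNANT_CLASSES, ThermalCube, ValidationError
from .features import (
    DescriptiveModel,
    build_descriptive_model,
    energy_difference,
    euclidean_distance,
    modeled_member_curves,
    similitude_features,
)
from .trc import DoubleExpFit

__all__ = [
    "BootstrapConfig",
    "EvalReport",
    "MimicryReport",
    "RecordSummary",
    "prepare_record_summary",
    "bootstrap_evaluate",
    "compute_metrics",
    "validate_mimicry",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "TPR", "TPR_MM", "TPR_BCC", "TPR_SCC", "TNR", "PPV")

_CLASSIFIERS = ("random_forest", "knn", "svm_rbf", "xgboost")


@dataclass
class BootstrapConfig:
    n_reps: int = 2000
    train_frac: float = 0.8
    classifier: str = "random_forest"
    classifier_params: dict = field(default_factory=dict)
    seed: int = 0
    use_full_vector: bool = False
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValidationError("train_frac must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.classifier not in _CLASSIFIERS:
            raise ValidationError(f"classifier must be one of {_CLASSIFIERS}")


@dataclass
class MetricSummary:
    min: float
    max: float
    avg: float
    sd: float

    def __post_init__(self) -> None:
        if not self.min <= self.avg <= self.max:
            raise ValidationError("metric summary must satisfy min <= avg <= max")


@dataclass
class EvalReport:
    """Min/max/avg/sd (percent) per metric over completed repetitions."""

    metrics: dict[str, MetricSummary]
    n_reps_completed: int

    def as_dict(self) -> dict:
        return {
            name: {"min": m.min, "max": m.max, "avg": m.avg, "sd": m.sd}
            for name, m in self.metrics.items()
        } | {"n_reps_completed": self.n_reps_completed}


@dataclass
class MimicryReport:
    """Per-pixel Pearson correlations between actual and mimicked TRCs."""

    coefficients: np.ndarray
    mean: float
    sd: float
    n_trcs: int
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Record summaries: per-lesion sufficient statistics for the bootstrap
# ---------------------------------------------------------------------------

@dataclass
class RecordSummary:
    """Everything the fold-wise feature extraction needs from one record.

    The model-independent contrasts d and Ed are precomputed; the modeled,
    unit-normalized member curves of L* and N* are retained so the
    similitude statistics can be recomputed against each training fold's
    fM/fB.  ``rep_fit_L`` (the double-exponential fit of the representative
    lesion TRC) is the record's contribution to its class's descriptive
    model when it lands in a training fold.
    """

    label: str
    d: float
    Ed: float
    members_L: np.ndarray  # (nL, K) modeled + normalized
    members_N: np.ndarray  # (nN, K)
    rep_fit_L: DoubleExpFit
    K_IR: int
    fps: float

    @property
    def is_malignant(self) -> bool:
        return self.label in MALIGNANT_CLASSES


def prepare_record_summary(
    record: AcquisitionRecord,
    p: float = trc_mod.DEFAULT_SELECTION_MARGIN,
    fits: Optional[np.ndarray] = None,
) -> RecordSummary:
    """Run the per-record screening pipeline up to (but excluding) fM/fB.

    Fits every pixel, computes Tref over the lesion area, applies the
    initial-temperature selection, forms the representative TRCs, and
    collects the modeled member curves of L* and N*.
    """
    if record.label is None:
        raise ValidationError("record must carry a lesion class label")
    cube = record.cube
    if fits is None:
        fits = trc_mod.fit_cube(cube)
    lesion_fits = [fits[i, j] for (i, j) in np.argwhere(record.lesion_mask)]
    tref = trc_mod.compute_reference_temperature(lesion_fits)
    selection = trc_mod.select_trcs(fits, record.lesion_mask, tref, p)
    rep_l = trc_mod.representative_trc(cube, selection.L_star)
    rep_n = trc_mod.representative_trc(cube, selection.N_star)
    return RecordSummary(
        label=record.label,
        d=euclidean_distance(rep_l, rep_n),
        Ed=energy_difference(rep_l, rep_n),
        members_L=modeled_member_curves(fits, selection.L_star, cube.n_frames, cube.fps),
        members_N=modeled_member_curves(fits, selection.N_star, cube.n_frames, cube.fps),
        rep_fit_L=trc_mod.fit_double_exponential(rep_l, cube.fps),
        K_IR=cube.n_frames,
        fps=cube.fps,
    )


def _fold_model(train: Sequence[RecordSummary]) -> DescriptiveModel:
    malignant = [s.rep_fit_L for s in train if s.is_malignant]
    benign = [s.rep_fit_L for s in train if not s.is_malignant]
    k_ir, fps = train[0].K_IR, train[0].fps
    return build_descriptive_model(malignant, benign, k_ir, fps)


def _features_for(summary: RecordSummary, model: DescriptiveModel, full: bool) -> np.ndarray:
    import warnings

    sims: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model_key, fm in (("M", model.fM), ("B", model.fB)):
            for area_key, members in (("L", summary.members_L), ("N", summary.members_N)):
                for stat, value in similitude_features(members, fm).items():
                    sims[f"{stat}_{model_key}_{area_key}"] = value
    selected = [abs(summary.Ed), sims["rho_sd_B_L"], sims["proj_sd_B_N"], sims["dist_sd_M_N"]]
    if not full:
        return np.asarray(selected)
    return np.asarray([summary.d, summary.Ed] + [sims[k] for k in sorted(sims)])


def _make_classifier(config: BootstrapConfig, seed: int):
    params = dict(config.classifier_params)
    if config.classifier == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if config.classifier == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        params.setdefault("n_neighbors", 3)
        return KNeighborsClassifier(**params)
    if config.classifier == "svm_rbf":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", random_state=seed, **params)
    from xgboost import XGBClassifier  # optional extra

    params.setdefault("n_estimators", 100)
    return XGBClassifier(random_state=seed, **params)


def compute_metrics(
    truth: Sequence[str],
    predicted: Sequence[bool],
    subclasses: Sequence[str] = MALIGNANT_CLASSES,
) -> dict[str, float]:
    """Confusion metrics in percent; malignant is the positive class.

    ``truth`` holds lesion class labels; ``predicted`` holds boolean
    malignancy calls.  Metrics with a zero denominator are absent from the
    result, never reported as 0.
    """
    if len(truth) != len(predicted) or len(truth) == 0:
        raise ValidationError("truth and predictions must be non-empty and aligned")
    truth = list(truth)
    pred = np.asarray(predicted, dtype=bool)
    pos = np.array([label in MALIGNANT_CLASSES for label in truth])

    out: dict[str, float] = {"accuracy": 100.0 * float((pred == pos).mean())}
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    if tp + fn > 0:
        out["TPR"] = 100.0 * tp / (tp + fn)
    if tn + fp > 0:
        out["TNR"] = 100.0 * tn / (tn + fp)
    if tp + fp > 0:
        out["PPV"] = 100.0 * tp / (tp + fp)
    for sub in subclasses:
        members = [k for k, label in enumerate(truth) if label == sub]
        if members:
            out[f"TPR_{sub}"] = 100.0 * float(pred[members].mean())
    return out


def bootstrap_evaluate(
    summaries: Sequence[RecordSummary],
    config: BootstrapConfig,
) -> EvalReport:
    """Bootstrap-resampled train/test evaluation of the screening classifier.

    Per repetition: resample n records with replacement, split the resample
    80/20, build fM/fB and fit the classifier on the training portion only,
    score the test portion.  The split is made over the distinct records in
    the resample (multiplicities preserved), so all bootstrap copies of one
    lesion fall on the same side — otherwise a lesion seen in training
    would be trivially memorized when its copy appears in test.  A
    repetition whose training or test portion lacks one of the two
    top-level classes is redrawn (logged), up to ``config.max_redraws``
    extra draws per repetition.
    """
    labels = [s.label for s in summaries]
    n_mal = sum(s.is_malignant for s in summaries)
    n_ben = len(summaries) - n_mal
    if n_mal < 2 or n_ben < 2:
        raise ValidationError("need at least 2 records per top-level class")

    rng = np.random.default_rng(config.seed)
    n = len(summaries)
    n_train = int(round(config.train_frac * n))
    n_train = min(max(n_train, 1), n - 1)

    accumulated: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    completed = 0
    for rep in range(config.n_reps):
        for attempt in range(config.max_redraws + 1):
            resample = rng.integers(0, n, size=n)
            # split at the level of distinct records so duplicates of one
            # lesion never straddle the train/test boundary (a record seen
            # in training would otherwise be trivially memorized in test)
            distinct = rng.permutation(np.unique(resample))
            counts = np.bincount(resample, minlength=n)
            train_ids: list[int] = []
            allocated = 0
            for rid in distinct:
                if allocated < n_train:
                    train_ids.append(int(rid))
                    allocated += int(counts[rid])
            train_set = set(train_ids)
            train_idx = [i for i in resample if i in train_set]
            test_idx = [i for i in resample if i not in train_set]
            if not train_idx or not test_idx:
                continue
            # train needs >= 2 distinct records per class (one lone record
            # makes the fold's descriptive model and classifier degenerate);
            # relax to 1 when the cohort itself has only 2 of a class
            train_mal_ids = {i for i in train_set if summaries[i].is_malignant}
            train_ben_ids = {i for i in train_set if not summaries[i].is_malignant}
            need_mal = 2 if n_mal >= 3 else 1
            need_ben = 2 if n_ben >= 3 else 1
            test_mal = {summaries[i].is_malignant for i in test_idx}
            if (
                len(train_mal_ids) >= need_mal
                and len(train_ben_ids) >= need_ben
                and test_mal == {True, False}
            ):
                break
            logger.debug("repetition %d redraw %d: degenerate split", rep, attempt)
        else:
            logger.warning("repetition %d skipped: no valid split found", rep)
            continue

        train = [summaries[i] for i in train_idx]
        test = [summaries[i] for i in test_idx]
        model = _fold_model(train)
        x_train = np.array([_features_for(s, model, config.use_full_vector) for s in train])
        x_test = np.array([_features_for(s, model, config.use_full_vector) for s in test])
        y_train = np.array([s.is_malignant for s in train])
        clf = _make_classifier(config, seed=int(rng.integers(2**31)))
        clf.fit(x_train, y_train.astype(int))
        pred = np.asarray(clf.predict(x_test)).astype(bool)

        metrics = compute_metrics([s.label for s in test], pred)
        for name, value in metrics.items():
            accumulated[name].append(value)
        completed += 1

    out: dict[str, MetricSummary] = {}
    for name, values in accumulated.items():
        if not values:
            continue
        arr = np.asarray(values)
        out[name] = MetricSummary(
            min=float(arr.min()), max=float(arr.max()),
            avg=float(arr.mean()), sd=float(arr.std()),
        )
    return EvalReport(metrics=out, n_reps_completed=completed)


# ---------------------------------------------------------------------------
# Mimicry validation
# ---------------------------------------------------------------------------

def validate_mimicry(actual: ThermalCube, mimicked: ThermalCube) -> MimicryReport:
    """Per-pixel Pearson correlation between actual and mimicked TRCs.

    Cubes must share shape and frame rate (the mimicked cube has already
    been degraded to the actual camera's rate).  Pixels with zero temporal
    variance in either cube are excluded and counted.
    """
    if actual.shape != mimicked.shape:
        raise ValidationError(f"shape mismatch: {actual.shape} vs {mimicked.shape}")
    if actual.fps != mimicked.fps:
        raise ValidationError(f"fps mismatch: {actual.fps} vs {mimicked.fps}")
    a = actual.data - actual.data.mean(axis=2, keepdims=True)
    b = mimicked.data - mimicked.data.mean(axis=2, keepdims=True)
    na = np.linalg.norm(a, axis=2)
    nb = np.linalg.norm(b, axis=2)
    usable = (na > 1e-14) & (nb > 1e-14)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("ijk,ijk->ij", a, b) / (na * nb)
    coeffs = np.clip(rho[usable], -1.0, 1.0)
    if coeffs.size == 0:
        raise ValidationError("no pixels with temporal variance in both cubes")
    return MimicryReport(
        coefficients=coeffs,
        mean=float(coeffs.mean()),
        sd=float(coeffs.std()),
        n_trcs=int(coeffs.size),
        n_excluded=int((~usable).sum()),
    )
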