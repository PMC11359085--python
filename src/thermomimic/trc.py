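"""Per-pixel thermoregulation-curve (TRC) modeling and selection.

After a 30 s cooling stimulus, skin temperature recovers toward a plateau.
Each pixel's recovery is modeled by a double exponential

    f(t) = θ1 + θ2 · exp(θ3 t) + θ4 · exp(θ5 t),      θ3, θ5 ≤ 0,

fitted by nonlinear least squares to the sampled TRC.  The fitted initial
temperature is f(0) = θ1 + θ2 + θ4.  A reference temperature Tref — the mean
fitted initial temperature over the lesion area — anchors the selection rule

    S = {(i, j) : |f_ij(0) − Tref| ≤ p · Tref},

which keeps only pixels whose cooling was comparable to the lesion's, so the
lesion set L* = L ∩ S and the control set N* = N ∩ S start from similar
initial temperatures (default margin p = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core_io import ThermalCube, ValidationError

__all__ = [
    "DoubleExpFit",
    "SelectionResult",
    "double_exponential",
    "fit_double_exponential",
    "fit_cube",
    "compute_reference_temperature",
    "select_trcs",
    "representative_trc",
    "SelectionFailure",
]

#: Default relative selection margin p.
DEFAULT_SELECTION_MARGIN = 0.01

#: Minimum series length for a 5-parameter fit.
MIN_FIT_SAMPLES = 8


class SelectionFailure(ValueError):
    """Selection produced an empty lesion or control set."""


@dataclass
class DoubleExpFit:
    """Fitted double-exponential recovery for one pixel.

    theta = (plateau °C, amplitude °C, rate 1/s, amplitude °C, rate 1/s);
    ``f0 = θ1 + θ2 + θ4`` by construction.
    """

    theta: np.ndarray
    rms_residual: float
    converged: bool

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (5,):
            raise ValidationError("theta must have exactly 5 entries")

    @property
    def f0(self) -> float:
        return float(self.theta[0] + self.theta[1] + self.theta[3])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return double_exponential(self.theta, np.asarray(t, dtype=float))


def double_exponential(theta: Sequence[float], t: np.ndarray) -> np.ndarray:
    """Evaluate f(t) = θ1 + θ2 e^{θ3 t} + θ4 e^{θ5 t}."""
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValidationError("theta must be finite")
    return th[0] + th[1] * np.exp(th[2] * t) + th[3] * np.exp(th[4] * t)


def _amplitudes_for_rates(rates: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Best linear amplitudes (θ1, θ2, θ4) for fixed rates; residual vector.

    Variable projection: for fixed (θ3, θ5) the model is linear in the three
    amplitude parameters, solved by least squares.
    """
    basis = np.column_stack([np.ones_like(t), np.exp(rates[0] * t), np.exp(rates[1] * t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return coef, basis @ coef - y


def fit_double_exponential(series: np.ndarray, fps: float) -> DoubleExpFit:
    """Fit the double-exponential recovery model to one TRC.

    Trust-region least squares over the two (non-positive) rates with the
    three amplitudes profiled out linearly at each step; the rate
    initializer places one slow rate (1/e time at 20% of the record) and one
    fast rate (5% of the record).  Up to 3 deterministic restarts with
    perturbed rates; if none converges the fit falls back to the flat model
    (θ = (mean, 0, −1/T, 0, −1/T)) with ``converged=False`` — no exception.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < MIN_FIT_SAMPLES:
        raise ValidationError(f"series must be 1-D with >= {MIN_FIT_SAMPLES} samples")
    if not fps > 0:
        raise ValidationError("fps must be positive")
    t = np.arange(y.size) / fps
    total = t[-1] if t[-1] > 0 else 1.0

    if not np.all(np.isfinite(y)):
        theta = np.array([np.nan, 0.0, -1.0 / total, 0.0, -1.0 / total])
        return DoubleExpFit(theta, rms_residual=np.inf, converged=False)

    def residual(rates: np.ndarray) -> np.ndarray:
        return _amplitudes_for_rates(rates, t, y)[1]

    base_rates = np.array([-1.0 / (0.2 * total), -1.0 / (0.05 * total)])
    attempts = [base_rates] + [base_rates * f for f in (0.3, 3.0, 10.0)]

    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    for x0 in attempts:
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(np.array([-np.inf, -np.inf]), np.array([0.0, 0.0])),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                max_nfev=200,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if not sol.success:
            continue
        coef, _ = _amplitudes_for_rates(sol.x, t, y)
        best = (float(sol.cost), sol.x, coef)
        break  # restarts are for non-convergence only

    if best is None:
        theta = np.array([float(y.mean()), 0.0, -1.0 / total, 0.0, -1.0 / total])
        rms = float(np.sqrt(np.mean((double_exponential(theta, t) - y) ** 2)))
        return DoubleExpFit(theta, rms_residual=rms, converged=False)

    _, rates, coef = best
    theta = np.array([coef[0], coef[1], rates[0], coef[2], rates[1]])
    rms = float(np.sqrt(np.mean((double_exponential(theta, t) - y) ** 2)))
    return DoubleExpFit(theta, rms_residual=rms, converged=True)


def fit_cube(cube: ThermalCube) -> np.ndarray:
    """Fit every pixel's TRC; returns an (I, J) object array of DoubleExpFit."""
    i_dim, j_dim, _ = cube.shape
    fits = np.empty((i_dim, j_dim), dtype=object)
    for i in range(i_dim):
        for j in range(j_dim):
            fits[i, j] = fit_double_exponential(cube.data[i, j, :], cube.fps)
    return fits


def compute_reference_temperature(fits: Iterable[DoubleExpFit]) -> float:
    """Tref = mean fitted initial temperature f(0) over converged lesion fits."""
    f0s = [f.f0 for f in fits if f.converged]
    if not f0s:
        raise ValidationError("no converged fits in the lesion area")
    return float(np.mean(f0s))


@dataclass
class SelectionResult:
    """Outcome of the initial-temperature selection rule."""

    Tref: float
    p: float
    S: set = field(default_factory=set)
    L_star: set = field(default_factory=set)
    N_star: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.L_star & self.N_star:
            raise ValidationError("L* and N* must be disjoint")


def select_trcs(
    fits: np.ndarray,
    lesion_mask: np.ndarray,
    Tref: float,
    p: float = DEFAULT_SELECTION_MARGIN,
) -> SelectionResult:
    """Select pixels whose fitted f(0) lies within p·Tref of Tref.

    Non-converged pixels are excluded from S.  Raises
    :class:`SelectionFailure` if either L* or N* comes out empty (a larger
    margin p usually fixes it).
    """
    if not Tref > 0:
        raise ValidationError("Tref must be positive")
    if not 0 < p < 1:
        raise ValidationError("p must lie in (0, 1)")
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if fits.shape != lesion_mask.shape:
        raise ValidationError("fits and mask shapes differ")

    S, L_star, N_star = set(), set(), set()
    tol = p * Tref
    for i in range(fits.shape[0]):
        for j in range(fits.shape[1]):
            fit = fits[i, j]
            if not fit.converged:
                continue
            if abs(fit.f0 - Tref) <= tol:
                S.add((i, j))
                (L_star if lesion_mask[i, j] else N_star).add((i, j))
    if not L_star or not N_star:
        raise SelectionFailure(
            f"selection with p={p} left L*={len(L_star)}, N*={len(N_star)} pixels; "
            "consider a larger margin p"
        )
    return SelectionResult(Tref=float(Tref), p=float(p), S=S, L_star=L_star, N_star=N_star)


def representative_trc(cube: ThermalCube, pixel_set: Iterable[tuple[int, int]]) -> np.ndarray:
    """Pointwise mean of the raw TRCs over a pixel set."""
    pixels = list(pixel_set)
    if not pixels:
        raise ValidationError("pixel set is empty")
    rows = np.array([p[0] for p in pixels])
    cols = np.array([p[1] for p in pixels])
    return cube.data[rows, cols, :].mean(axis=0)
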