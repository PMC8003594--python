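"""Parametric time-activity models and robust nonlinear least-squares fitting.

Biodistribution time courses (%IA/g versus hours post-injection) are described
by one of three closed-form families, assigned by organ class:

* tumor — uptake-washout, ``y = a (1 - exp(-b t)) exp(-c t)``;
* eyes — uptake with physical decay only, ``y = a (1 - exp(-b t)) exp(-λ t)``
  where the terminal rate λ is fixed at the radionuclide's physical decay
  constant ``ln 2 / T_half`` and is not fitted (melanin binding in the eye is
  effectively irreversible, so biological clearance is neglected);
* all other organs — bi-exponential washout, ``y = a exp(-b t) + c exp(-d t)``.

Fitting is nonlinear least squares with a trust-region-reflective solver under
nonnegativity bounds, optionally wrapped in iteratively reweighted least
squares with Tukey bisquare weights to resist outlying animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "ModelFamily",
    "OrganClass",
    "PKModel",
    "TimeActivitySeries",
    "FitOptions",
    "FitResult",
    "IODINE131_HALF_LIFE_H",
    "physical_decay_constant",
    "assign_model_family",
    "predict",
    "fit_timeactivity",
]

#: Iodine-131 physical half-life in hours (8.02 days).
IODINE131_HALF_LIFE_H = 192.6

#: Rates are bounded away from zero so every fitted model has a finite
#: time integral; this floor is far below any physiological washout rate.
_RATE_FLOOR = 1e-9


class ModelFamily(str, Enum):
    UPTAKE_WASHOUT = "uptake_washout"
    UPTAKE_PHYSDECAY = "uptake_physdecay"
    BIEXP = "biexp"


class OrganClass(str, Enum):
    TUMOR = "tumor"
    EYE = "eye"
    OTHER = "other"


_N_PARAMS = {
    ModelFamily.UPTAKE_WASHOUT: 3,
    ModelFamily.UPTAKE_PHYSDECAY: 3,  # (a, b, lambda_phys); lambda fixed
    ModelFamily.BIEXP: 4,
}
_N_FREE = {
    ModelFamily.UPTAKE_WASHOUT: 3,
    ModelFamily.UPTAKE_PHYSDECAY: 2,
    ModelFamily.BIEXP: 4,
}


def physical_decay_constant(half_life_h: float) -> float:
    """Physical decay constant λ = ln2 / T_half, in h⁻¹.

    Parameters
    ----------
    half_life_h
        Radionuclide physical half-life in hours; must be positive.
    """
    if not half_life_h > 0:
        raise ValidationError(f"half-life must be positive, got {half_life_h}")
    return math.log(2.0) / half_life_h


def assign_model_family(organ_class: OrganClass | str) -> ModelFamily:
    """Map an organ class to its time-activity model family."""
    organ_class = OrganClass(organ_class)
    return {
        OrganClass.TUMOR: ModelFamily.UPTAKE_WASHOUT,
        OrganClass.EYE: ModelFamily.UPTAKE_PHYSDECAY,
        OrganClass.OTHER: ModelFamily.BIEXP,
    }[organ_class]


@dataclass(frozen=True)
class PKModel:
    """One parametric time-activity curve.

    ``params`` is the ordered parameter vector of the family:

    * ``uptake_washout``: (a %IA/g, b h⁻¹ uptake, c h⁻¹ washout)
    * ``uptake_physdecay``: (a %IA/g, b h⁻¹ uptake, λ_phys h⁻¹ — fixed)
    * ``biexp``: (a %IA/g, b h⁻¹, c %IA/g, d h⁻¹); value at t=0 is a + c
    """

    family: ModelFamily
    params: tuple[float, ...]

    def __post_init__(self):
        family = ModelFamily(self.family)
        object.__setattr__(self, "family", family)
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _N_PARAMS[family]:
            raise ValidationError(
                f"{family.value} takes {_N_PARAMS[family]} parameters, got {len(params)}"
            )
        amps, rates = self._split()
        if any(a < 0 for a in amps):
            raise ValidationError(f"amplitudes must be >= 0, got {params}")
        if any(r <= 0 for r in rates):
            raise ValidationError(f"rate constants must be > 0, got {params}")

    def _split(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        p = self.params
        if self.family is ModelFamily.BIEXP:
            return (p[0], p[2]), (p[1], p[3])
        return (p[0],), (p[1], p[2])

    def __call__(self, t):
        return predict(self, t)


def predict(model: PKModel, t):
    """Evaluate the model's closed form at time(s) ``t`` (hours, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be nonnegative")
    p = model.params
    if model.family is ModelFamily.BIEXP:
        a, b, c, d = p
        y = a * np.exp(-b * t) + c * np.exp(-d * t)
    else:
        a, b, c = p
        y = a * (1.0 - np.exp(-b * t)) * np.exp(-c * t)
    return y if y.ndim else float(y)


@dataclass(frozen=True)
class TimeActivitySeries:
    """Per-animal %IA/g measurements for one organ."""

    organ: str
    times: np.ndarray  # hours
    values: np.ndarray  # %IA/g
    animals: tuple[str, ...]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        animals = tuple(str(a) for a in self.animals)
        if not (len(times) == len(values) == len(animals)):
            raise ValidationError("times, values and animals must have equal length")
        if np.any(times < 0):
            raise ValidationError("times must be >= 0")
        if not np.all(np.isfinite(values)):
            raise ValidationError("%IA/g values must be finite")
        if np.any(values < 0):
            raise ValidationError("%IA/g values must be >= 0")
        # canonical order makes fitting invariant to input ordering
        order = np.lexsort((animals, times))
        object.__setattr__(self, "times", times[order])
        object.__setattr__(self, "values", values[order])
        object.__setattr__(self, "animals", tuple(animals[i] for i in order))

    @classmethod
    def from_points(cls, organ: str, points: Sequence[tuple[float, float, str]]):
        """Build from (t_hours, pia_per_g, animal) tuples."""
        t, y, a = zip(*points)
        return cls(organ, np.array(t), np.array(y), tuple(a))

    def __len__(self) -> int:
        return len(self.times)

    def n_timepoints(self) -> int:
        return len(np.unique(self.times))


@dataclass(frozen=True)
class FitOptions:
    """Solver settings for :func:`fit_timeactivity`.

    robust
        Enable iteratively reweighted least squares with Tukey bisquare
        weights (default on).
    tuning_constant
        Bisquare tuning constant; 4.685 gives 95% efficiency at the
        Gaussian model.
    max_iterations
        Maximum IRLS outer iterations.
    param_tol
        Relative parameter-change tolerance stopping the IRLS loop.
    solver_tol
        xtol/ftol/gtol passed to the inner trust-region solver.
    half_life_h
        Radionuclide physical half-life (hours); sets the fixed terminal
        rate of the uptake-physdecay family.
    """

    robust: bool = True
    tuning_constant: float = 4.685
    max_iterations: int = 100
    param_tol: float = 1e-8
    solver_tol: float = 1e-12
    half_life_h: float = IODINE131_HALF_LIFE_H


@dataclass
class FitResult:
    """Outcome of one robust time-activity fit."""

    model: PKModel
    residuals: np.ndarray
    robust_weights: np.ndarray
    converged: bool
    n_iterations: int
    objective: float  # weighted SSE
    degenerate: bool = False
    series: TimeActivitySeries | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# model functions over the *free* parameter vector


def _free_to_model(family: ModelFamily, theta: np.ndarray, lam: float) -> PKModel:
    if family is ModelFamily.UPTAKE_PHYSDECAY:
        return PKModel(family, (theta[0], theta[1], lam))
    return PKModel(family, tuple(theta))


def _eval_free(family: ModelFamily, theta: np.ndarray, lam: float, t: np.ndarray):
    if family is ModelFamily.BIEXP:
        a, b, c, d = theta
        return a * np.exp(-b * t) + c * np.exp(-d * t)
    if family is ModelFamily.UPTAKE_PHYSDECAY:
        a, b = theta
        return a * (1.0 - np.exp(-b * t)) * np.exp(-lam * t)
    a, b, c = theta
    return a * (1.0 - np.exp(-b * t)) * np.exp(-c * t)


def _jac_free(family: ModelFamily, theta: np.ndarray, lam: float, t: np.ndarray):
    if family is ModelFamily.BIEXP:
        a, b, c, d = theta
        eb, ed = np.exp(-b * t), np.exp(-d * t)
        return np.column_stack([eb, -a * t * eb, ed, -c * t * ed])
    if family is ModelFamily.UPTAKE_PHYSDECAY:
        a, b = theta
        up = 1.0 - np.exp(-b * t)
        el = np.exp(-lam * t)
        return np.column_stack([up * el, a * t * np.exp(-b * t) * el])
    a, b, c = theta
    up = 1.0 - np.exp(-b * t)
    ec = np.exp(-c * t)
    return np.column_stack([up * ec, a * t * np.exp(-b * t) * ec, -a * up * t * ec])


def _bounds(family: ModelFamily) -> tuple[np.ndarray, np.ndarray]:
    if family is ModelFamily.BIEXP:
        lo = np.array([0.0, _RATE_FLOOR, 0.0, _RATE_FLOOR])
    elif family is ModelFamily.UPTAKE_PHYSDECAY:
        lo = np.array([0.0, _RATE_FLOOR])
    else:
        lo = np.array([0.0, _RATE_FLOOR, _RATE_FLOOR])
    return lo, np.full_like(lo, np.inf)


def _timepoint_means(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tp = np.unique(t)
    means = np.array([y[t == ti].mean() for ti in tp])
    return tp, means


def _log_slope(t0: float, y0: float, t1: float, y1: float) -> float:
    """Decay rate from two positive points; NaN if not both positive."""
    if y0 <= 0 or y1 <= 0 or t1 == t0:
        return float("nan")
    return (math.log(y0) - math.log(y1)) / (t1 - t0)


def _initial_guess(family: ModelFamily, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic data-driven starting point.

    Amplitudes come from the maximum observed %IA/g; bi-exponential rates from
    log-linear curve peeling of the last and first two timepoint means; the
    uptake rate b starts at 1 h⁻¹.
    """
    tp, m = _timepoint_means(t, y)
    ymax = max(y.max(), 1e-12)
    if family is ModelFamily.UPTAKE_PHYSDECAY:
        return np.array([ymax, 1.0])
    if family is ModelFamily.UPTAKE_WASHOUT:
        c0 = _log_slope(tp[-2], m[-2], tp[-1], m[-1]) if len(tp) >= 2 else float("nan")
        if not np.isfinite(c0) or c0 <= 0:
            c0 = 0.01
        c0 = min(max(c0, 1e-4), 5.0)
        return np.array([ymax, 1.0, c0])
    # biexp: peel slow component off the tail, fast component off the head
    d0 = _log_slope(tp[-2], m[-2], tp[-1], m[-1]) if len(tp) >= 2 else float("nan")
    if not np.isfinite(d0) or d0 <= 0:
        d0 = 0.01
    d0 = min(max(d0, 1e-4), 1.0)
    c0 = min(m[-1] * math.exp(d0 * tp[-1]), 10.0 * ymax) if m[-1] > 0 else 0.1 * ymax
    r = m[:2] - c0 * np.exp(-d0 * tp[:2]) if len(tp) >= 2 else np.array([ymax, ymax])
    b0 = _log_slope(tp[0], r[0], tp[1], r[1]) if len(tp) >= 2 else float("nan")
    if not np.isfinite(b0) or b0 <= d0:
        b0 = max(10.0 * d0, 0.5)
    b0 = min(b0, 50.0)
    a0 = r[0] * math.exp(b0 * tp[0]) if r[0] > 0 else 0.5 * ymax
    a0 = min(max(a0, 1e-3 * ymax), 20.0 * ymax)
    return np.array([a0, b0, max(c0, 1e-3 * ymax), d0])


def _canonical_biexp(theta: np.ndarray) -> np.ndarray:
    """Order biexp components fast-first so parameterization is unique."""
    a, b, c, d = theta
    if d > b:
        return np.array([c, d, a, b])
    return theta


def _mad_scale(r: np.ndarray) -> float:
    """Robust residual scale: normalized median absolute deviation."""
    return 1.4826 * float(np.median(np.abs(r - np.median(r))))


def _bisquare_weights(r: np.ndarray, scale: float, k: float) -> np.ndarray:
    u = r / (k * scale)
    w = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    w[inside] = (1.0 - u[inside] ** 2) ** 2
    return w


def fit_timeactivity(
    series: TimeActivitySeries,
    family: ModelFamily | str,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one model family to a %IA/g series.

    Robust mode runs iteratively reweighted least squares: each outer pass
    solves a weighted trust-region-reflective least-squares problem, then
    recomputes Tukey bisquare weights from the residuals scaled by the
    normalized MAD. With robust mode off (or residuals numerically zero) a
    single unweighted solve is returned and all weights are 1.

    Raises
    ------
    InsufficientDataError
        If the number of distinct timepoints is below the number of free
        parameters. Non-convergence does *not* raise; it is flagged on the
        result.
    """
    family = ModelFamily(family)
    opts = options or FitOptions()
    t, y = series.times, series.values
    if series.n_timepoints() < _N_FREE[family]:
        raise InsufficientDataError(
            f"{family.value} needs >= {_N_FREE[family]} distinct timepoints, "
            f"series {series.organ!r} has {series.n_timepoints()}"
        )
    lam = physical_decay_constant(opts.half_life_h)
    lo, hi = _bounds(family)
    theta = np.clip(_initial_guess(family, t, y), lo, None)
    w = np.ones_like(y)
    converged = False
    n_outer = 0
    for n_outer in range(1, opts.max_iterations + 1):
        sw = np.sqrt(w)

        def f(th, sw=sw):
            return sw * (_eval_free(family, th, lam, t) - y)

        def jac(th, sw=sw):
            return sw[:, None] * _jac_free(family, th, lam, t)

        sol = least_squares(
            f, theta, jac=jac, bounds=(lo, hi), method="trf",
            xtol=opts.solver_tol, ftol=opts.solver_tol, gtol=opts.solver_tol,
        )
        theta_new = sol.x
        step = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12))
        theta = theta_new
        if not opts.robust:
            converged = sol.status > 0
            break
        r = _eval_free(family, theta, lam, t) - y
        scale = _mad_scale(r)
        if scale < 1e-12 * max(1.0, float(np.abs(y).max())):
            # residuals numerically zero: nothing to reweight
            w = np.ones_like(y)
            converged = sol.status > 0
            break
        w_new = _bisquare_weights(r, scale, opts.tuning_constant)
        if n_outer > 1 and step < opts.param_tol:
            converged = sol.status > 0
            break
        w = w_new
    if family is ModelFamily.BIEXP:
        theta = _canonical_biexp(theta)
    degenerate = False
    if family is ModelFamily.BIEXP:
        a, b, c, d = theta
        if abs(b - d) <= 1e-6 * max(b, d):
            # unidentifiable split: collapse to a mono-exponential
            rate = 0.5 * (b + d)
            theta = np.array([a + c, rate, 0.0, rate])
            degenerate = True
    model = _free_to_model(family, theta, lam)
    residuals = predict(model, t) - y
    return FitResult(
        model=model,
        residuals=residuals,
        robust_weights=w,
        converged=converged,
        n_iterations=n_outer,
        objective=float(np.sum(w * residuals**2)),
        degenerate=degenerate,
        series=series,
    )
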