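"""Parametric models of per-subject clinical decline.

Clinical-trial time series (functional rating scores, vital signs,
laboratory values) are summarised per subject by fitting one of four
two- or three-parameter decline curves:

====================  ======================  =========
family                value at day ``t``      arity
====================  ======================  =========
linear                ``A - k*t``             2
exponential           ``A * exp(-k*t)``       2
harmonic              ``A / (1 + k*t)``       2
weibull               ``A * exp(-(k*t)^b)``   3
====================  ======================  =========

``A`` is the model-estimated value at the start of the trial (day 0) in
the variable's own units and ``k`` is the per-day rate of progression;
``k > 0`` means decline in every family.  The Weibull shape ``b`` nests
the exponential model at ``b = 1``, which motivates the boundary
collapse rule in :func:`collapse_weibull`.  For negative ``k`` (a
variable that grows over the study) the Weibull power is evaluated as
the odd extension ``sign(k*t) * |k*t|**b`` so that growth is
representable in all four families and the ``b = 1`` identity is exact.

Fitting minimises the Gaussian negative log-likelihood with a common,
analytically profiled error SD, which reduces the criterion to the sum
of squared errors.  The optimiser is a bounded simulated-annealing
search (geometric cooling, Gaussian proposals) whose best state is
polished by a bounded trust-region least-squares step; see
:class:`AnnealConfig`.

Parameter constraints: ``k`` in [-5, 5] per day, ``b`` in [0.0001, 5],
and ``A`` in [0, 53] for the ALSFRS-R total score (the conventional
printed bound, even though the instrument maximum is 48) or
[0, 2 * max(observed)] otherwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelFamily",
    "AnnealConfig",
    "TrajectoryFit",
    "TrajectoryModel",
    "EvaluationError",
    "model_value",
    "neg_log_likelihood",
    "fit_model",
    "fit_all",
    "collapse_weibull",
    "K_BOUNDS",
    "B_BOUNDS",
    "ALSFRS_TOTAL_A_MAX",
]

K_BOUNDS = (-5.0, 5.0)
B_BOUNDS = (1e-4, 5.0)
#: Upper bound on the fitted baseline of the ALSFRS-R total score.  The
#: instrument maximum is 48; the looser bound deliberately leaves head
#: room for noisy baselines and is kept as the field convention.
ALSFRS_TOTAL_A_MAX = 53.0

_SSE_FLOOR = 1e-12


class EvaluationError(ValueError):
    """A curve was evaluated outside its domain (harmonic pole)."""


class ModelFamily(str, enum.Enum):
    """Candidate decline-curve families."""

    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    HARMONIC = "harmonic"
    WEIBULL = "weibull"

    @property
    def arity(self) -> int:
        """Number of free curve parameters (2, or 3 for Weibull)."""
        return 3 if self is ModelFamily.WEIBULL else 2


#: Deterministic family order used for reporting and tie-breaks.
FAMILY_ORDER = (
    ModelFamily.LINEAR,
    ModelFamily.EXPONENTIAL,
    ModelFamily.HARMONIC,
    ModelFamily.WEIBULL,
)


def model_value(family, A, k, t, b=None):
    """Evaluate a decline curve at times ``t`` (days).

    Parameters
    ----------
    family : ModelFamily or str
    A, k : float
        Baseline value and per-day progression rate.
    t : array_like
        Nonnegative times in days.
    b : float, optional
        Weibull shape; required iff ``family`` is Weibull.

    Returns
    -------
    ndarray or scalar of the curve value at each time.
    """
    family = ModelFamily(family)
    t = np.asarray(t, dtype=float)
    if family is ModelFamily.LINEAR:
        out = A - k * t
    elif family is ModelFamily.EXPONENTIAL:
        out = A * np.exp(-k * t)
    elif family is ModelFamily.HARMONIC:
        denom = 1.0 + k * t
        if np.any(denom <= 0):
            raise EvaluationError(
                f"harmonic curve undefined: 1 + k*t <= 0 for k={k!r}"
            )
        out = A / denom
    else:
        if b is None:
            raise ValueError("weibull family requires shape parameter b")
        u = k * t
        out = A * np.exp(-np.sign(u) * np.abs(u) ** b)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing schedule for trajectory fitting.

    Geometric cooling from ``t_initial`` down to ``t_min`` by factor
    ``cooling``, ``steps_per_temp`` Metropolis proposals per temperature,
    Gaussian proposals with SD ``proposal_frac`` of each parameter's
    bound width.  Acceptance temperatures are rescaled by the starting
    SSE so the schedule is invariant to the variable's units.  Each
    restart's best state is refined by bounded least squares
    (``polish=True``), which supplies the final precision; the annealing
    pass is responsible for basin selection only, so the default
    schedule is deliberately short.
    """

    t_initial: float = 1.0
    cooling: float = 0.85
    steps_per_temp: int = 20
    t_min: float = 1e-2
    proposal_frac: float = 0.05
    restarts: int = 1
    polish: bool = True

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.t_initial <= 0 or self.t_min <= 0:
            raise ValueError("temperatures must be positive")
        if self.restarts < 1 or self.steps_per_temp < 1:
            raise ValueError("restarts and steps_per_temp must be >= 1")


@dataclass(frozen=True)
class TrajectoryFit:
    """Result of fitting one family to one subject's series.

    ``converged`` is False for the no-fit marker returned when the
    series has too few distinct time points, in which case ``A`` is the
    value at the earliest visit (a baseline-only feature) and ``k``/
    goodness-of-fit fields are None.
    """

    family: ModelFamily
    A: float
    k: float | None
    b: float | None
    n_points: int
    sse: float | None
    rmse: float | None
    aicc: float | None
    converged: bool
    subject_id: object = None
    variable: str | None = None
    message: str = ""

    @property
    def params(self) -> tuple:
        return (self.A, self.k) if self.b is None else (self.A, self.k, self.b)

    def predict(self, t):
        """Evaluate the fitted curve at times ``t`` (days)."""
        if not self.converged:
            raise ValueError("cannot predict from a no-fit marker")
        return model_value(self.family, self.A, self.k, t, self.b)

    def summary(self) -> str:
        lines = [
            f"Trajectory fit [{self.family.value}]",
            f"  subject:  {self.subject_id}   variable: {self.variable}",
            f"  n points: {self.n_points}   converged: {self.converged}",
            f"  A (baseline) = {self.A:.6g}",
        ]
        if self.k is not None:
            lines.append(f"  k (per day)  = {self.k:.6g}")
        if self.b is not None:
            lines.append(f"  b (shape)    = {self.b:.6g}")
        if self.sse is not None:
            lines.append(
                f"  SSE = {self.sse:.6g}   RMSE = {self.rmse:.6g}   "
                f"AICc = {self.aicc if self.aicc is None else round(self.aicc, 4)}"
            )
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)


def neg_log_likelihood(t, y, family, params, sigma=None):
    """Gaussian NLL of a series under a decline curve.

    With ``sigma=None`` the error SD is profiled analytically
    (``sigma^2 = SSE/n``), so the parameter minimiser coincides with the
    least-squares minimiser.  A perfect fit (SSE 0) is floored to keep
    the profiled likelihood finite.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    family = ModelFamily(family)
    b = params[2] if family.arity == 3 else None
    try:
        resid = y - model_value(family, params[0], params[1], t, b)
    except EvaluationError:
        return np.inf
    n = y.size
    sse = max(float(resid @ resid), _SSE_FLOOR)
    if sigma is None:
        sigma2 = sse / n
        return 0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return 0.5 * n * math.log(2 * math.pi * sigma**2) + 0.5 * sse / sigma**2


# ---------------------------------------------------------------------------
# fitting machinery


def _make_sse(t, y, family):
    if family is ModelFamily.LINEAR:

        def sse(x):
            r = y - (x[0] - x[1] * t)
            return float(r @ r)

    elif family is ModelFamily.EXPONENTIAL:

        def sse(x):
            # clip the exponent: extreme SA proposals (k near -5 with t in
            # hundreds of days) would otherwise overflow; clipped regions
            # score astronomically bad SSE either way
            r = y - x[0] * np.exp(np.minimum(-x[1] * t, 150.0))
            s = float(r @ r)
            return s if math.isfinite(s) else np.inf

    elif family is ModelFamily.HARMONIC:

        def sse(x):
            denom = 1.0 + x[1] * t
            if denom[-1] <= 1e-9 or denom[0] <= 1e-9:
                return np.inf
            r = y - x[0] / denom
            return float(r @ r)

    else:

        def sse(x):
            u = x[1] * t
            with np.errstate(over="ignore"):
                r = y - x[0] * np.exp(
                    np.clip(-np.sign(u) * np.abs(u) ** x[2], -150.0, 150.0)
                )
            s = float(r @ r)
            return s if math.isfinite(s) else np.inf

    return sse


def _make_residuals(t, y, family):
    if family is ModelFamily.HARMONIC:

        def resid(x):
            return y - x[0] / (1.0 + x[1] * t)

    elif family is ModelFamily.LINEAR:

        def resid(x):
            return y - (x[0] - x[1] * t)

    elif family is ModelFamily.EXPONENTIAL:

        def resid(x):
            return y - x[0] * np.exp(np.minimum(-x[1] * t, 150.0))

    else:

        def resid(x):
            u = x[1] * t
            expo = -np.sign(u) * np.abs(u) ** x[2]
            return y - x[0] * np.exp(np.clip(expo, -150.0, 150.0))

    return resid


def _warm_start(t, y, family):
    """Cheap closed-form initial guess per family."""
    y0 = float(y[np.argmin(t)])
    if family is ModelFamily.LINEAR:
        if np.ptp(t) > 0:
            slope, intercept = np.polyfit(t, y, 1)
            return np.array([intercept, -slope])
        return np.array([y0, 0.0])
    if family in (ModelFamily.EXPONENTIAL, ModelFamily.WEIBULL):
        pos = y > 0
        if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            x = [math.exp(intercept), -slope]
        else:
            x = [max(y0, _SSE_FLOOR), 0.0]
        if family is ModelFamily.WEIBULL:
            x.append(1.0)
        return np.array(x)
    # harmonic: 1/y is linear in t when y > 0
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], 1.0 / y[pos], 1)
        if intercept > 0:
            A = 1.0 / intercept
            return np.array([A, slope * A])
    return np.array([max(y0, _SSE_FLOOR), 0.0])


def _param_bounds(family, y, a_bounds, t_max):
    if a_bounds is None:
        hi = 2.0 * float(np.max(y)) if np.max(y) > 0 else 1.0
        a_bounds = (0.0, hi)
    k_lo, k_hi = K_BOUNDS
    if family is ModelFamily.HARMONIC and t_max > 0:
        # keep 1 + k*t strictly positive on the observation window
        k_lo = max(k_lo, (1e-6 - 1.0) / t_max)
    lo = [a_bounds[0], k_lo]
    hi = [a_bounds[1], k_hi]
    if family is ModelFamily.WEIBULL:
        lo.append(B_BOUNDS[0])
        hi.append(B_BOUNDS[1])
    return np.asarray(lo), np.asarray(hi)


def _anneal_once(sse, x0, lo, hi, config, rng):
    x = x0.copy()
    fx = sse(x)
    best, fbest = x.copy(), fx
    scale = config.proposal_frac * (hi - lo)
    fscale = max(fx if np.isfinite(fx) else 1.0, 1.0)
    temp = config.t_initial
    while temp > config.t_min:
        for _ in range(config.steps_per_temp):
            cand = np.clip(x + rng.standard_normal(x.size) * scale, lo, hi)
            fc = sse(cand)
            if fc < fx or (
                np.isfinite(fc)
                and rng.random() < math.exp(-(fc - fx) / (temp * fscale))
            ):
                x, fx = cand, fc
                if fx < fbest:
                    best, fbest = x.copy(), fx
        temp *= config.cooling
    return best, fbest


def _polish(resid, x, lo, hi):
    eps = 1e-10 * (hi - lo)
    x0 = np.clip(x, lo + eps, hi - eps)
    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=200)
    except Exception:
        return x, np.inf
    return sol.x, float(2 * sol.cost)


class TrajectoryModel:
    """One subject's (time, value) series with a candidate curve family.

    Parameters
    ----------
    t, y : array_like
        Visit days (nonnegative) and measured values, equal length.
    family : ModelFamily or str, default "exponential"
    a_bounds : (lo, hi), optional
        Bounds on the baseline parameter A.  Defaults to
        ``[0, 2*max(y)]``; pass ``(0, ALSFRS_TOTAL_A_MAX)`` for the
        ALSFRS-R total score.
    subject_id, variable : metadata carried into the fit.
    """

    def __init__(self, t, y, family="exponential", a_bounds=None,
                 subject_id=None, variable=None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be equal-length 1-D arrays")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        order = np.argsort(t, kind="stable")
        self.t = t[order]
        self.y = y[order]
        self.family = ModelFamily(family)
        self.a_bounds = a_bounds
        self.subject_id = subject_id
        self.variable = variable

    @property
    def n_distinct_times(self) -> int:
        return int(np.unique(self.t).size)

    def _min_points(self) -> int:
        return self.family.arity + 1

    def _no_fit(self, message):
        return TrajectoryFit(
            family=self.family,
            A=float(self.y[0]) if self.y.size else float("nan"),
            k=None, b=None,
            n_points=int(self.y.size),
            sse=None, rmse=None, aicc=None,
            converged=False,
            subject_id=self.subject_id, variable=self.variable,
            message=message,
        )

    def fit(self, config: AnnealConfig | None = None, seed=None) -> TrajectoryFit:
        """Fit by simulated annealing + bounded least-squares polish."""
        if self.n_distinct_times < self._min_points():
            return self._no_fit(
                f"needs >= {self._min_points()} distinct time points, "
                f"got {self.n_distinct_times}; baseline-only"
            )
        config = config or AnnealConfig()
        rng = np.random.default_rng(seed)
        t, y, family = self.t, self.y, self.family
        sse = _make_sse(t, y, family)
        resid = _make_residuals(t, y, family)
        lo, hi = _param_bounds(family, y, self.a_bounds, float(t[-1]))
        x0 = np.clip(_warm_start(t, y, family), lo, hi)

        best_x, best_f = x0, sse(x0)
        for _ in range(config.restarts):
            xa, fa = _anneal_once(sse, x0, lo, hi, config, rng)
            if config.polish:
                xa2, fa2 = _polish(resid, xa, lo, hi)
                if fa2 < fa:
                    xa, fa = xa2, fa2
            if fa < best_f:
                best_x, best_f = xa, fa
        if config.polish:
            xw, fw = _polish(resid, x0, lo, hi)
            if fw < best_f:
                best_x, best_f = xw, fw

        n = int(y.size)
        p = family.arity
        sse_val = float(best_f)
        rmse = math.sqrt(max(sse_val, 0.0) / n)
        aicc_val = _aicc(sse_val, n, p) if n > p + 1 else None
        return TrajectoryFit(
            family=family,
            A=float(best_x[0]),
            k=float(best_x[1]),
            b=float(best_x[2]) if p == 3 else None,
            n_points=n,
            sse=sse_val,
            rmse=rmse,
            aicc=aicc_val,
            converged=True,
            subject_id=self.subject_id,
            variable=self.variable,
        )


def _aicc(sse, n, p):
    # Gaussian-profile AICc; duplicated in selection.aicc with input checks
    return n * math.log(max(sse, _SSE_FLOOR) / n) + 2 * p + (2 * p * (p + 1)) / (n - p - 1)


def fit_model(t, y, family, a_bounds=None, config=None, seed=None,
              subject_id=None, variable=None) -> TrajectoryFit:
    """Functional wrapper around :class:`TrajectoryModel`."""
    return TrajectoryModel(
        t, y, family, a_bounds=a_bounds, subject_id=subject_id, variable=variable
    ).fit(config=config, seed=seed)


def collapse_weibull(t, y, fit: TrajectoryFit, eps=1e-3, a_bounds=None,
                     config=None, seed=None) -> TrajectoryFit:
    """Collapse a boundary/unit Weibull fit to the exponential model.

    When the fitted shape sits within ``eps`` of its bounds (0.0001 or
    5) — or of 1, where the Weibull is exactly exponential — the series
    is refitted with the 2-parameter exponential model and that fit is
    returned; otherwise the fit is returned unchanged.
    """
    if fit.family is not ModelFamily.WEIBULL:
        raise ValueError("collapse_weibull expects a weibull fit")
    if not fit.converged:
        return fit
    b = fit.b
    near = (
        abs(b - B_BOUNDS[0]) < eps
        or abs(b - B_BOUNDS[1]) < eps
        or abs(b - 1.0) < eps
    )
    if not near:
        return fit
    exp_fit = fit_model(
        t, y, ModelFamily.EXPONENTIAL, a_bounds=a_bounds, config=config,
        seed=seed, subject_id=fit.subject_id, variable=fit.variable,
    )
    return replace(exp_fit, message=f"collapsed from weibull (b={b:.4g})")


def fit_all(t, y, a_bounds=None, config=None, seed=None, subject_id=None,
            variable=None, collapse_eps=1e-3) -> dict:
    """Fit all four families; the Weibull fit is boundary-collapsed.

    Returns a dict keyed by :class:`ModelFamily` (no-fit markers
    included for families with too few points).
    """
    fits = {}
    for i, family in enumerate(FAMILY_ORDER):
        child = None if seed is None else seed + i
        fits[family] = fit_model(
            t, y, family, a_bounds=a_bounds, config=config, seed=child,
            subject_id=subject_id, variable=variable,
        )
    wfit = fits[ModelFamily.WEIBULL]
    if wfit.converged:
        b = wfit.b
        if (
            abs(b - B_BOUNDS[0]) < collapse_eps
            or abs(b - B_BOUNDS[1]) < collapse_eps
            or abs(b - 1.0) < collapse_eps
        ):
            fits[ModelFamily.WEIBULL] = replace(
                fits[ModelFamily.EXPONENTIAL],
                message=f"collapsed from weibull (b={b:.4g})",
            )
    return fits
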