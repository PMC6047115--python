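"""Non-linear growth models for longitudinal plant traits.

Implements the three sigmoid families commonly fitted to image-derived
plant trajectories — the 3-parameter logistic, the 4-parameter logistic
(4PL) and the Gompertz curve — plus an ordinary polynomial baseline.
Per-plant fitting uses bounded trust-region non-linear least squares with
data-driven initialisation and a small number of jittered multi-starts;
models are compared by the coefficient of determination R².

Note on symbols: ``B`` here is the 4PL hill slope, not the permutation
count used by the genome-scan module; the two never meet in one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "FourPLParams",
    "GompertzParams",
    "PolynomialParams",
    "FitResult",
    "eval_logistic",
    "eval_4pl",
    "eval_gompertz",
    "r_squared",
    "fit_growth_model",
    "fit_polynomial",
    "select_model",
    "MODEL_NPARAMS",
]

# exp() overflow guard: exp(±709) is the float64 limit
_EXP_CLIP = 700.0

MODEL_NPARAMS = {"logistic": 3, "4pl": 4, "gompertz": 3}

# tie-break order when R² and parameter counts are equal
_MODEL_ORDER = ("logistic", "gompertz", "4pl")


@dataclass(frozen=True)
class LogisticParams:
    """3-parameter logistic: f(t) = L / (1 + exp(-k (t - t0)))."""

    L: float  # upper asymptote, trait units
    k: float  # growth rate, per day
    t0: float  # midpoint, DAS

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.k, self.t0], dtype=float)


@dataclass(frozen=True)
class FourPLParams:
    """4-parameter logistic: f(t) = D + (A - D) / (1 + (t/C)^B)."""

    A: float  # bottom asymptote, trait units
    B: float  # hill slope, dimensionless
    C: float  # inflection point, DAS (> 0)
    D: float  # top asymptote, trait units

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D], dtype=float)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz: f(t) = a * exp(-b * exp(-c t)), b > 0, c > 0."""

    a: float  # asymptote, trait units
    b: float  # time-axis displacement, dimensionless
    c: float  # rate, per day

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


@dataclass(frozen=True)
class PolynomialParams:
    """Polynomial baseline b0 + b1 t + ... + bn t^n, degree 2-4."""

    coefficients: tuple[float, ...]  # (b0, b1, ..., bn)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


@dataclass
class FitResult:
    """Outcome of fitting one model to one (line, replicate, trait) series."""

    model: str
    params: object
    r_squared: float
    rss: float
    converged: bool
    n_points: int
    n_params: int = field(default=0)

    def param_dict(self) -> dict[str, float]:
        p = self.params
        if isinstance(p, LogisticParams):
            return {"L": p.L, "k": p.k, "t0": p.t0}
        if isinstance(p, FourPLParams):
            return {"A": p.A, "B": p.B, "C": p.C, "D": p.D}
        if isinstance(p, GompertzParams):
            return {"a": p.a, "b": p.b, "c": p.c}
        if isinstance(p, PolynomialParams):
            return {f"b{i}": c for i, c in enumerate(p.coefficients)}
        raise TypeError(f"unknown parameter type {type(p)!r}")


def eval_logistic(p: LogisticParams | Sequence[float], t) -> np.ndarray | float:
    """Evaluate the 3-parameter logistic; overflow-safe for any finite t."""
    L, k, t0 = (p.L, p.k, p.t0) if isinstance(p, LogisticParams) else p
    t = np.asarray(t, dtype=float)
    z = np.clip(-k * (t - t0), -_EXP_CLIP, _EXP_CLIP)
    out = L / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def eval_4pl(p: FourPLParams | Sequence[float], t) -> np.ndarray | float:
    """Evaluate the 4PL curve. Requires t > 0 because of the (t/C)^B power."""
    A, B, C, D = (p.A, p.B, p.C, p.D) if isinstance(p, FourPLParams) else p
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("4PL model is defined for t > 0 only")
    if C <= 0:
        raise ValueError("4PL inflection point C must be > 0")
    # (t/C)^B via exp(B log(t/C)) with overflow clipping
    z = np.clip(B * np.log(t / C), -_EXP_CLIP, _EXP_CLIP)
    out = D + (A - D) / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def eval_gompertz(p: GompertzParams | Sequence[float], t) -> np.ndarray | float:
    """Evaluate the Gompertz curve a exp(-b exp(-c t))."""
    a, b, c = (p.a, p.b, p.c) if isinstance(p, GompertzParams) else p
    t = np.asarray(t, dtype=float)
    inner = np.clip(-c * t, -_EXP_CLIP, _EXP_CLIP)
    z = np.clip(-b * np.exp(inner), -_EXP_CLIP, _EXP_CLIP)
    out = a * np.exp(z)
    return out if out.ndim else float(out)


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Raises ``ValueError`` when the observations are constant (the total
    sum of squares vanishes and R² is undefined).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and fitted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations for R²")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: observations are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _eval_model(model: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if model == "logistic":
        return eval_logistic(theta, t)
    if model == "4pl":
        return eval_4pl(theta, t)
    if model == "gompertz":
        return eval_gompertz(theta, t)
    raise ValueError(f"unknown model {model!r}")


def _initial_guess(model: str, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Data-driven starting values.

    logistic: L ~ max y, t0 ~ DAS of half-range crossing, k from the range
    of t; 4PL: A ~ min y, D ~ max y, C ~ half-range crossing, B from a
    log-log slope between the quartile crossings; gompertz: a ~ max y with
    b, c from the same half-range landmark.
    """
    ymin, ymax = float(np.min(y)), float(np.max(y))
    yrange = ymax - ymin if ymax > ymin else max(abs(ymax), 1.0)
    half = ymin + 0.5 * yrange
    # first DAS where the series crosses its half range
    above = np.nonzero(y >= half)[0]
    t_half = float(t[above[0]]) if above.size else float(np.median(t))
    t_span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    if model == "logistic":
        return np.array([ymax, 4.0 / t_span, t_half])
    if model == "gompertz":
        # at t_half: a e^{-b e^{-c t_half}} = half  =>  pick c, solve b
        c = 4.0 / t_span
        a = ymax if ymax > 0 else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = max(half / a, 1e-6)
            b = max(-np.log(ratio) * np.exp(c * t_half), 1e-3)
        return np.array([a, min(b, 1e6), c])
    if model == "4pl":
        C = max(t_half, 1e-3)
        # slope sign from the direction of the trend; magnitude from the
        # steepness of the central rise on a log(t) axis
        lo = ymin + 0.25 * yrange
        hi = ymin + 0.75 * yrange
        i_lo = np.nonzero(y >= lo)[0]
        i_hi = np.nonzero(y >= hi)[0]
        if i_lo.size and i_hi.size and t[i_hi[0]] > t[i_lo[0]] > 0:
            # logistic in log-t: quartile-to-quartile rise spans ~2.2 logits
            B = 2.2 / np.log(t[i_hi[0]] / t[i_lo[0]])
        else:
            B = 5.0
        increasing = y[-1] >= y[0]
        if increasing:
            return np.array([ymin, abs(B), C, ymax])
        return np.array([ymax, abs(B), C, ymin])
    raise ValueError(f"unknown model {model!r}")


def _bounds(model: str, t: np.ndarray, y: np.ndarray):
    ymin, ymax = float(np.min(y)), float(np.max(y))
    yr = max(ymax - ymin, abs(ymax), 1.0)
    lo_y, hi_y = ymin - 10 * yr, ymax + 10 * yr
    if model == "logistic":
        return ([lo_y, -10.0, t[0] - 10 * (t[-1] - t[0] + 1)],
                [hi_y, 10.0, t[-1] + 10 * (t[-1] - t[0] + 1)])
    if model == "gompertz":
        return ([lo_y, 1e-9, 1e-9], [hi_y, 1e9, 10.0])
    if model == "4pl":
        return ([lo_y, -200.0, 1e-6, lo_y], [hi_y, 200.0, 10 * t[-1], hi_y])
    raise ValueError(model)


def fit_growth_model(
    t,
    y,
    model: str,
    init: Sequence[float] | None = None,
    n_starts: int = 3,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one growth model to a single time series by least squares.

    Parameters
    ----------
    t, y
        Time axis (DAS) and trait values of one (line, replicate) series.
    model
        One of ``"logistic"``, ``"4pl"``, ``"gompertz"``.
    init
        Optional starting parameter vector; defaults to data-driven
        heuristics.
    n_starts
        Number of jittered starts; the best-RSS converged solution wins.
    """
    if model not in MODEL_NPARAMS:
        raise ValueError(f"unknown model {model!r}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    npar = MODEL_NPARAMS[model]
    if t.size < npar + 1:
        raise ValueError(
            f"need at least {npar + 1} timepoints to fit {model}, got {t.size}"
        )
    if model == "4pl" and np.any(t <= 0):
        raise ValueError("4PL fitting requires all t > 0")

    theta0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(model, t, y)
    lo, hi = _bounds(model, t, y)
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
    rng = rng if rng is not None else np.random.default_rng(0)

    def resid(theta):
        return _eval_model(model, theta, t) - y

    best = None
    for s in range(max(n_starts, 1)):
        start = theta0 if s == 0 else np.clip(
            theta0 * (1.0 + 0.2 * rng.standard_normal(npar))
            + 0.05 * rng.standard_normal(npar),
            lo + 1e-12,
            hi - 1e-12,
        )
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FitResult(model=model, params=None, r_squared=-np.inf,
                         rss=np.inf, converged=False, n_points=t.size,
                         n_params=npar)

    theta = best.x
    fitted = _eval_model(model, theta, t)
    rss = float(np.sum((fitted - y) ** 2))
    try:
        r2 = r_squared(y, fitted)
    except ValueError:
        r2 = np.nan  # constant series: degenerate but not a crash
    if model == "logistic":
        params = LogisticParams(*theta)
    elif model == "4pl":
        A, B, C, D = theta
        params = FourPLParams(A=A, B=B, C=C, D=D)
    else:
        params = GompertzParams(*theta)
    converged = bool(best.success) and np.all(np.isfinite(theta))
    return FitResult(model=model, params=params, r_squared=float(r2),
                     rss=rss, converged=converged, n_points=t.size,
                     n_params=npar)


def fit_polynomial(t, y, degree: int) -> FitResult:
    """Ordinary least-squares polynomial fit of the stated degree (2-4)."""
    if not 2 <= degree <= 4:
        raise ValueError("polynomial degree must be 2, 3 or 4")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    X = np.vander(t, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design (duplicate timepoints?)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((fitted - y) ** 2))
    try:
        r2 = r_squared(y, fitted)
    except ValueError:
        r2 = np.nan
    return FitResult(model=f"poly{degree}",
                     params=PolynomialParams(tuple(float(c) for c in coef)),
                     r_squared=float(r2), rss=rss, converged=True,
                     n_points=t.size, n_params=degree + 1)


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Pick the best converged fit by R².

    Ties are broken by fewer parameters, then by a fixed model-name order,
    so selection is deterministic.
    """
    converged = [f for f in fits if f.converged and np.isfinite(f.r_squared)]
    if not converged:
        raise ValueError("no converged fits to select from")

    def key(f: FitResult):
        order = _MODEL_ORDER.index(f.model) if f.model in _MODEL_ORDER else 99
        return (-f.r_squared, f.n_params, order)

    return min(converged, key=key)
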