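"""Two-component Gaussian mixture for bimodal water-use trajectories.

Daily water use of a wheat plant typically shows two modes: a vegetative
peak (~130 DAS) and a grain-filling peak (~180 DAS). A daily curve
(DAS, ml) is treated as a weighted sample on the time axis — each DAS is
an observation weighted by that day's water amount — and a finite Gaussian
mixture is fitted by expectation-maximisation. Each component carries a
prior weight pi, a mode location mu (DAS), a spread sigma (days), and an
amplitude lambda = pi * total volume (ml). The distance between the two
modes is summarised by the separation statistic
S = (mu2 - mu1) / (2 sigma1 + 2 sigma2).

A direct non-linear least-squares fit of a two-Gaussian sum to the curve
is available as an alternative backend (``fit_watercurve(..., backend="nls")``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MixtureComponent",
    "MixtureFit",
    "curve_to_samples",
    "em_fit",
    "posterior",
    "bimodal_separation",
    "fit_watercurve",
]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class MixtureComponent:
    pi: float  # prior weight in [0, 1]
    mu: float  # mode location, DAS
    sigma: float  # mode s.d., days
    lam: float  # amplitude, ml (= pi * total volume under the curve)


@dataclass
class MixtureFit:
    """Converged mixture, components ordered by ascending mu."""

    components: list[MixtureComponent]
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    separation: float | None = None

    @property
    def m(self) -> int:
        return len(self.components)


def curve_to_samples(das, amount) -> tuple[np.ndarray, np.ndarray]:
    """Convert a daily water-use curve to weighted time-axis samples.

    Each DAS becomes one observation whose weight is that day's water
    amount (ml); negative amounts are clipped to 0.
    """
    x = np.asarray(das, dtype=float)
    w = np.clip(np.asarray(amount, dtype=float), 0.0, None)
    if x.shape != w.shape:
        raise ValueError("das and amount must have equal length")
    return x, w


def _normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * _SQRT2PI)


def _weighted_loglik(x, w, pis, mus, sigmas) -> float:
    dens = np.zeros_like(x)
    for p, m, s in zip(pis, mus, sigmas):
        dens += p * _normal_pdf(x, m, s)
    return float(np.sum(w * np.log(np.maximum(dens, 1e-300))))


def _quantile_init(x, w, m):
    """Deterministic start: split the weighted sample at its weighted
    quantiles and take component moments within each slab."""
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    total = cw[-1]
    edges = [np.searchsorted(cw, total * (k + 1) / m) for k in range(m - 1)]
    slabs = np.split(np.arange(xs.size), [e + 1 for e in edges])
    pis, mus, sigmas = [], [], []
    span = float(xs[-1] - xs[0]) if xs[-1] > xs[0] else 1.0
    for idx in slabs:
        if idx.size == 0 or ws[idx].sum() <= 0:
            pis.append(1.0 / m)
            mus.append(float(np.average(xs, weights=ws)))
            sigmas.append(span / (4 * m))
            continue
        wk = ws[idx]
        mk = float(np.average(xs[idx], weights=wk))
        vk = float(np.average((xs[idx] - mk) ** 2, weights=wk))
        pis.append(float(wk.sum() / total))
        mus.append(mk)
        sigmas.append(max(np.sqrt(vk), span / (20 * m)))
    return np.array(pis), np.array(mus), np.array(sigmas)


def em_fit(
    x,
    weights,
    m: int = 2,
    init: tuple | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    sigma_floor_frac: float = 1e-3,
) -> MixtureFit:
    """Fit an m-component Gaussian mixture to weighted observations by EM.

    The E-step computes posterior class probabilities; the M-step updates
    each component's (pi, mu, sigma) by weighted maximum likelihood using
    the posteriors as weights. Iteration stops when the log-likelihood
    improves by less than ``tol`` or after ``max_iter`` passes. A component
    whose sigma collapses below the floor (``sigma_floor_frac`` times the
    data range) is re-seeded once; a second collapse flags the fit as not
    converged.
    """
    if m < 1:
        raise ValueError("component count m must be >= 1")
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total_w = float(w.sum())
    if total_w <= 0:
        raise ValueError("weights must not all be zero")
    support = np.unique(x[w > 0])
    if support.size < 2 * m:
        raise ValueError(f"need >= {2 * m} distinct support points for m={m}")

    span = float(support[-1] - support[0])
    sigma_floor = max(sigma_floor_frac * span, 1e-12)

    if init is not None:
        pis, mus, sigmas = (np.asarray(v, dtype=float).copy() for v in init)
        pis = pis / pis.sum()
    else:
        pis, mus, sigmas = _quantile_init(x, w, m)

    ll_old = -np.inf
    trace: list[float] = []
    converged = False
    reseeded = False
    n_iter = 0
    collapse_failed = False
    for n_iter in range(1, max_iter + 1):
        # E-step
        resp = np.stack([p * _normal_pdf(x, mu, s)
                         for p, mu, s in zip(pis, mus, sigmas)])
        denom = resp.sum(axis=0)
        resp /= np.maximum(denom, 1e-300)
        # M-step (weighted by observation weight x posterior)
        wr = resp * w  # (m, n)
        nk = wr.sum(axis=1)
        pis = nk / total_w
        collapse = False
        for k in range(m):
            if nk[k] <= 0:
                collapse = True
                continue
            mus[k] = float(wr[k] @ x / nk[k])
            var = float(wr[k] @ (x - mus[k]) ** 2 / nk[k])
            sigmas[k] = np.sqrt(var)
            if sigmas[k] < sigma_floor:
                collapse = True
                sigmas[k] = sigma_floor
        if collapse:
            if not reseeded:
                # one re-seed: restart the collapsed component wide
                reseeded = True
                for k in range(m):
                    if sigmas[k] <= sigma_floor or nk[k] <= 0:
                        mus[k] = float(np.average(x, weights=w))
                        sigmas[k] = max(span / 4.0, sigma_floor)
                        pis[k] = 1.0 / m
                pis = pis / pis.sum()
            else:
                collapse_failed = True
        ll = _weighted_loglik(x, w, pis, mus, sigmas)
        trace.append(ll)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll

    order = np.argsort(mus)
    comps = [
        MixtureComponent(pi=float(pis[k]), mu=float(mus[k]),
                         sigma=float(sigmas[k]),
                         lam=float(pis[k] * total_w))
        for k in order
    ]
    fit = MixtureFit(components=comps, log_likelihood=float(trace[-1]),
                     n_iterations=n_iter,
                     converged=converged and not collapse_failed,
                     loglik_trace=trace)
    if m == 2:
        fit.separation = bimodal_separation(fit)
    return fit


def posterior(fit: MixtureFit, x) -> np.ndarray:
    """Posterior class probabilities at the points x (rows sum to 1)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    dens = np.stack([c.pi * _normal_pdf(x, c.mu, c.sigma)
                     for c in fit.components], axis=1)
    denom = dens.sum(axis=1, keepdims=True)
    # identical-component degenerate case: uniform posterior
    out = np.where(denom > 0, dens / np.maximum(denom, 1e-300),
                   1.0 / fit.m)
    return out


def bimodal_separation(fit: MixtureFit) -> float:
    """Separation S = (mu2 - mu1) / (2 sigma1 + 2 sigma2), components
    ordered by mu. Defined for exactly two components."""
    if fit.m != 2:
        raise ValueError("separation is defined for exactly 2 components")
    c1, c2 = fit.components
    return (c2.mu - c1.mu) / (2.0 * c1.sigma + 2.0 * c2.sigma)


def fit_watercurve(das, amount, backend: str = "em", **kwargs) -> MixtureFit:
    """Fit the two-mode water-use description to one daily curve.

    backend="em" converts the curve to weighted samples and runs
    :func:`em_fit`; backend="nls" fits the two-Gaussian sum
    lam1 N(t; mu1, s1) + lam2 N(t; mu2, s2) to the daily amounts directly
    by least squares. Both report amplitudes as areas (ml) so the two
    backends agree on well-resolved curves.
    """
    x, w = curve_to_samples(das, amount)
    if backend == "em":
        return em_fit(x, w, m=2, **kwargs)
    if backend != "nls":
        raise ValueError(f"unknown backend {backend!r}")

    total = float(w.sum())
    seed = em_fit(x, w, m=2)  # EM solution seeds the NLS
    c1, c2 = seed.components

    def model(theta):
        l1, m1, s1, l2, m2, s2 = theta
        return l1 * _normal_pdf(x, m1, s1) + l2 * _normal_pdf(x, m2, s2)

    theta0 = np.array([c1.lam, c1.mu, c1.sigma, c2.lam, c2.mu, c2.sigma])
    span = float(x.max() - x.min())
    lo = [0.0, x.min() - span, 1e-3, 0.0, x.min() - span, 1e-3]
    hi = [10 * total, x.max() + span, span, 10 * total, x.max() + span, span]
    sol = least_squares(lambda th: model(th) - w, theta0, bounds=(lo, hi))
    l1, m1, s1, l2, m2, s2 = sol.x
    comps = sorted(
        [MixtureComponent(pi=l1 / (l1 + l2), mu=m1, sigma=s1, lam=l1),
         MixtureComponent(pi=l2 / (l1 + l2), mu=m2, sigma=s2, lam=l2)],
        key=lambda c: c.mu,
    )
    rss = float(np.sum((model(sol.x) - w) ** 2))
    fit = MixtureFit(components=comps, log_likelihood=-rss,
                     n_iterations=int(sol.nfev), converged=bool(sol.success))
    fit.separation = bimodal_separation(fit)
    return fit
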