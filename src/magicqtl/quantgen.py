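"""Variance components, heritability and genetic correlations.

Replicated line designs (each RIL grown r times) let the phenotypic
variance of a trait or fitted curve parameter be split into a genetic
(between-line) and an environmental (within-line) part by one-way
random-effects method of moments:

    s2_e = within-line mean square
    s2_g = (between-line MS - within-line MS) / r   (truncated at 0)

Broad-sense heritability is H2 = s2_g / (s2_g + s2_e). Covariances
between two traits come from the variance of their sum,
S_i(x, y) = (s2_i(x+y) - s2_i(x) - s2_i(y)) / 2 for i in {g, e}, and
correlations are r_i = S_i / sqrt(s2_i(x) s2_i(y)).

The printed source formula for the correlation denominator is ambiguous;
the standard geometric-mean denominator is the default, the arithmetic
mean is available via ``denominator="arithmetic"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "variance_components",
    "heritability",
    "covariance_components",
    "genetic_correlation",
    "component_table",
    "correlation_matrices",
]


@dataclass
class VarianceComponents:
    trait: str
    s2_g: float  # genetic variance, trait units^2
    s2_e: float  # environmental variance, trait units^2
    n_lines: int
    n_reps: float  # effective replicate number (r0 when unbalanced)
    truncated: bool = False  # negative MoM genetic variance clipped to 0


def _as_line_rep(values) -> pd.DataFrame:
    """Accept a line x rep 2-D array or a DataFrame indexed by line."""
    if isinstance(values, pd.DataFrame):
        return values
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a line x replicate table")
    return pd.DataFrame(arr)


def variance_components(values, trait: str = "") -> VarianceComponents:
    """One-way random-effects ANOVA decomposition of a line x rep table.

    Missing cells (NaN) are allowed; the unbalanced case uses the
    replicate-weighted coefficient r0 = (N - sum n_i^2 / N) / (a - 1) in
    place of r.
    """
    df = _as_line_rep(values)
    long = df.stack().astype(float)
    counts = long.groupby(level=0).count()
    counts = counts[counts > 0]
    a = len(counts)
    if a < 2:
        raise ValueError("need >= 2 lines with data")
    if (counts < 2).all():
        raise ValueError(
            "cannot separate genetic from environmental variance with a "
            "single replicate everywhere"
        )
    N = int(counts.sum())
    grand = float(long.mean())
    means = long.groupby(level=0).mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((long - means.reindex(long.index, level=0)) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    r0 = (N - float((counts**2).sum()) / N) / (a - 1)
    s2_e = ms_within
    s2_g_raw = (ms_between - ms_within) / r0
    truncated = s2_g_raw < 0
    return VarianceComponents(trait=trait, s2_g=max(s2_g_raw, 0.0),
                              s2_e=s2_e, n_lines=a, n_reps=r0,
                              truncated=truncated)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = s2_g / (s2_g + s2_e), in [0, 1]."""
    total = vc.s2_g + vc.s2_e
    if total <= 0:
        raise ValueError("H2 undefined: total variance is zero")
    return vc.s2_g / total


def covariance_components(x, y) -> tuple[float, float]:
    """Genetic and environmental covariance of two traits measured on the
    same line x rep design, via the variance of the sum trait.

    Uses the untruncated genetic variances internally so the identity
    S(x, x) = s2(x) holds exactly even when estimates stray negative.
    """
    dx, dy = _as_line_rep(x), _as_line_rep(y)
    if dx.shape != dy.shape:
        raise ValueError("x and y must share the same line x rep design")

    def raw(values):
        vc = variance_components(values)
        g = vc.s2_g if not vc.truncated else _raw_g(values)
        return g, vc.s2_e

    def _raw_g(values):
        df = _as_line_rep(values)
        long = df.stack().astype(float)
        counts = long.groupby(level=0).count()
        counts = counts[counts > 0]
        a, N = len(counts), int(counts.sum())
        means = long.groupby(level=0).mean()
        grand = float(long.mean())
        msb = float((counts * (means - grand) ** 2).sum()) / (a - 1)
        msw = float(((long - means.reindex(long.index, level=0)) ** 2).sum()) / (N - a)
        r0 = (N - float((counts**2).sum()) / N) / (a - 1)
        return (msb - msw) / r0

    gx, ex = raw(dx)
    gy, ey = raw(dy)
    gs, es = raw(dx + dy)
    s_g = (gs - gx - gy) / 2.0
    s_e = (es - ex - ey) / 2.0
    return s_g, s_e


def genetic_correlation(
    x, y, denominator: str = "geometric"
) -> tuple[float, float]:
    """Genetic and environmental correlations of two traits.

    ``denominator="geometric"`` (default) divides the covariance by
    sqrt(s2(x) s2(y)); ``"arithmetic"`` divides by (s2(x) + s2(y)) / 2.
    Raw values outside [-1, 1] are clamped.
    """
    vcx = variance_components(_as_line_rep(x))
    vcy = variance_components(_as_line_rep(y))
    s_g, s_e = covariance_components(x, y)
    out = []
    for s, vx, vy in ((s_g, vcx.s2_g, vcy.s2_g), (s_e, vcx.s2_e, vcy.s2_e)):
        if vx <= 0 or vy <= 0:
            raise ValueError("correlation undefined: zero component variance")
        if denominator == "geometric":
            r = s / np.sqrt(vx * vy)
        elif denominator == "arithmetic":
            r = s / ((vx + vy) / 2.0)
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        out.append(float(np.clip(r, -1.0, 1.0)))
    return out[0], out[1]


def component_table(params: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter variance components and H2 from a tidy table.

    ``params`` must carry a ``line`` and a ``rep`` column plus one numeric
    column per trait/parameter. Returns one row per parameter with
    s2_g, s2_e and H2.
    """
    cols = columns or [c for c in params.columns
                       if c not in ("line", "rep")
                       and np.issubdtype(params[c].dtype, np.number)]
    rows = []
    for c in cols:
        wide = params.pivot_table(index="line", columns="rep", values=c)
        try:
            vc = variance_components(wide, trait=c)
            h2 = heritability(vc)
        except ValueError:
            continue
        rows.append({"parameter": c, "s2_g": vc.s2_g, "s2_e": vc.s2_e,
                     "H2": h2, "n_lines": vc.n_lines,
                     "truncated": vc.truncated})
    return pd.DataFrame(rows)


def correlation_matrices(
    params: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise genetic and environmental correlation matrices.

    Pairs where either trait has a zero component variance get NaN.
    """
    cols = columns or [c for c in params.columns
                       if c not in ("line", "rep")
                       and np.issubdtype(params[c].dtype, np.number)]
    wides = {c: params.pivot_table(index="line", columns="rep", values=c)
             for c in cols}
    n = len(cols)
    rg = np.full((n, n), np.nan)
    re = np.full((n, n), np.nan)
    np.fill_diagonal(rg, 1.0)
    np.fill_diagonal(re, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                g, e = genetic_correlation(wides[cols[i]], wides[cols[j]])
            except ValueError:
                continue
            rg[i, j] = rg[j, i] = g
            re[i, j] = re[j, i] = e
    return (pd.DataFrame(rg, index=cols, columns=cols),
            pd.DataFrame(re, index=cols, columns=cols))
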