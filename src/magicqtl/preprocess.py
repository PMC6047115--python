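"""Cleaning rules applied to longitudinal trait tables before fitting.

Two rules, applied in order:

1. Timepoint completeness — a DAS is kept only if every line on the
   experiment roster has at least one observation at it (days on which
   part of the population was not imaged carry no usable contrast).
2. Outlier removal — within each (line, replicate, trait) series, an
   ordinary least-squares polynomial (cubic by default) is fitted to
   value-vs-DAS and observations whose Cook's distance exceeds a
   multiple (default 4x) of the series' mean Cook's distance are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CleaningReport",
    "filter_incomplete_timepoints",
    "remove_cooks_outliers",
    "clean",
]


@dataclass
class CleaningReport:
    dropped_timepoints: list[int] = field(default_factory=list)
    removed_outliers: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0

    def to_dict(self) -> dict:
        return {
            "dropped_timepoints": list(self.dropped_timepoints),
            "removed_outliers": list(self.removed_outliers),
            "thresholds": dict(self.thresholds),
            "warnings": list(self.warnings),
            "n_in": self.n_in,
            "n_out": self.n_out,
        }


def filter_incomplete_timepoints(
    series: pd.DataFrame, roster: set[str]
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop every DAS at which any roster line is unobserved.

    ``roster`` is the set of lines (RILs plus parents) that should have
    been imaged daily. Raises if no DAS survives.
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    report = CleaningReport(n_in=len(series))
    roster = set(roster)
    present = (
        series[series["line"].isin(roster)]
        .groupby("DAS")["line"]
        .agg(lambda s: len(set(s)))
    )
    complete = set(present[present == len(roster)].index)
    all_das = set(series["DAS"].unique())
    dropped = sorted(all_das - complete)
    if not complete:
        raise ValueError("no complete timepoints: every DAS is missing lines")
    out = series[series["DAS"].isin(complete)].reset_index(drop=True)
    report.dropped_timepoints = [int(d) for d in dropped]
    report.n_out = len(out)
    report.thresholds["roster_size"] = len(roster)
    return out, report


def _cooks_distance(t: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Cook's distances of y on a degree-``degree`` polynomial in t."""
    X = sm.add_constant(np.vander(t, degree + 1, increasing=True)[:, 1:])
    fit = sm.OLS(y, X).fit()
    # an (up to rounding) exact fit has all distances identically zero;
    # without this guard float noise in ~1e-12 residuals looks structured
    scale = max(float(np.max(np.abs(y))), 1.0)
    if np.sqrt(fit.mse_resid) <= 1e-10 * scale:
        return np.zeros(len(y))
    return fit.get_influence().cooks_distance[0]


def remove_cooks_outliers(
    series: pd.DataFrame,
    trait: str | None = None,
    multiplier: float = 4.0,
    degree: int = 3,
    max_fraction: float = 0.05,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove high-influence observations per (line, rep, trait) series.

    For each series a polynomial OLS fit of value on DAS provides Cook's
    distances; points with distance strictly greater than
    ``multiplier x mean(distances)`` are dropped. Series too short to fit
    (< degree + 3 points) are left untouched with a logged warning. If a
    series would lose more than ``max_fraction`` of its points, the
    excess removals still happen but a data-quality warning is recorded.
    """
    report = CleaningReport(n_in=len(series))
    report.thresholds.update(
        {"cooks_multiplier": multiplier, "cooks_degree": degree,
         "max_outlier_fraction": max_fraction}
    )
    df = series if trait is None else series[series["trait"] == trait]
    rest = series.iloc[0:0] if trait is None else series[series["trait"] != trait]
    drop_idx = []
    for (line, rep, tr), grp in df.groupby(["line", "rep", "trait"],
                                           sort=False):
        grp = grp.sort_values("DAS")
        t = grp["DAS"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        if t.size < degree + 3:
            report.warnings.append(
                f"series ({line}, {rep}, {tr}) too short to screen"
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = _cooks_distance(t, y, degree)
        d = np.nan_to_num(d, nan=0.0, posinf=np.inf)
        thresh = multiplier * float(np.mean(d[np.isfinite(d)]))
        bad = d > thresh
        if not bad.any():
            continue
        if bad.mean() > max_fraction:
            report.warnings.append(
                f"series ({line}, {rep}, {tr}) lost "
                f"{bad.mean():.1%} of points (> {max_fraction:.0%})"
            )
        for i in np.nonzero(bad)[0]:
            report.removed_outliers.append(
                {"line": line, "rep": int(rep), "DAS": int(t[i]),
                 "trait": tr, "cooks_distance": float(d[i])}
            )
        drop_idx.extend(grp.index[bad])
    out = pd.concat([df.drop(index=drop_idx), rest]).sort_index()
    out = out.reset_index(drop=True)
    report.n_out = len(out)
    return out, report


def clean(
    series: pd.DataFrame,
    roster: set[str],
    multiplier: float = 4.0,
    degree: int = 3,
    max_fraction: float = 0.05,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Both cleaning rules in order; reports are merged."""
    step1, rep1 = filter_incomplete_timepoints(series, roster)
    step2, rep2 = remove_cooks_outliers(
        step1, multiplier=multiplier, degree=degree, max_fraction=max_fraction
    )
    merged = CleaningReport(
        dropped_timepoints=rep1.dropped_timepoints,
        removed_outliers=rep2.removed_outliers,
        thresholds={**rep1.thresholds, **rep2.thresholds},
        warnings=rep1.warnings + rep2.warnings,
        n_in=rep1.n_in,
        n_out=rep2.n_out,
    )
    return step2, merged
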