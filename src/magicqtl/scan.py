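"""Single-marker genome scans with permutation-based significance.

At every marker the lines are grouped by genotype (or, when the true
founder mosaic is known, by founder origin — the eight-class analysis a
haplotype-based multiparent scan approximates) and a one-way ANOVA tests
for a difference in mean phenotype between groups. Association strength
is reported as the F statistic and -log10 of its p-value; the fraction of
phenotypic variance explained by the marker (SSB/SST) is reported as
``marker_h2``. Genome-wide significance is calibrated by permuting the
per-line phenotype vector B times and recording the genome-wide maximum
-log10 p of each shuffle; the empirical p of an observed peak is the
fraction of null maxima that reach it. A QTL is called when the peak has
-log10 p > 4 and empirical p < alpha (default 0.05); its support
interval extends to the markers within a fixed -log10 p drop of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeData",
    "MarkerScan",
    "PermutationResult",
    "QTLCall",
    "single_marker_anova",
    "genome_scan",
    "permutation_test",
    "call_qtls",
    "longitudinal_scan",
    "parameter_scan",
    "marker_effect_regression",
]

_MIN_P = 1e-300  # -log10 p ceiling guard


@dataclass
class GenotypeData:
    """Marker map plus per-line genotype calls (and optional ground truth)."""

    markers: pd.DataFrame  # columns: marker, chrom, cM, bp
    line_names: list[str]
    genotypes: np.ndarray  # (n_lines, n_markers) allele dosage 0/1/2
    founder_origin: np.ndarray | None = None  # (n_lines, n_markers)
    founder_names: list[str] | None = None

    @classmethod
    def from_population(cls, pop) -> "GenotypeData":
        return cls(markers=pop.panel.markers.copy(),
                   line_names=list(pop.line_names),
                   genotypes=pop.genotypes,
                   founder_origin=np.asarray(pop.founder_origin),
                   founder_names=list(pop.panel.founder_names))

    @property
    def n_lines(self) -> int:
        return len(self.line_names)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def group_labels(self, grouping: str = "genotype",
                     min_het: int = 3) -> tuple[np.ndarray, list[str]]:
        """Integer class label per (marker, line); -1 = excluded.

        genotype grouping: homozygous classes 0/1 plus a heterozygote
        class when it holds at least ``min_het`` lines (otherwise those
        lines are excluded at that marker). founder grouping: the
        ground-truth founder index (requires simulated data).
        """
        if grouping == "founder":
            if self.founder_origin is None:
                raise ValueError("founder grouping needs founder_origin")
            labels = self.founder_origin.T.astype(np.int16)
            names = list(self.founder_names or
                         [f"F{i+1}" for i in range(labels.max() + 1)])
            return labels, names
        if grouping != "genotype":
            raise ValueError(f"unknown grouping {grouping!r}")
        g = self.genotypes.T  # (n_markers, n_lines)
        labels = np.full(g.shape, -1, dtype=np.int16)
        labels[g == 0] = 0
        labels[g == 2] = 1
        het = g == 1
        het_ok = het.sum(axis=1) >= min_het
        labels[het & het_ok[:, None]] = 2
        return labels, ["A", "B", "H"]


@dataclass
class MarkerScan:
    """One genome scan: per-marker statistics for one phenotype."""

    table: pd.DataFrame  # marker, chrom, cM, bp, F, p, neg_log10_p, marker_h2, mean_* columns
    trait: str
    phenotype_name: str  # DAS label or curve-parameter name
    grouping: str

    @property
    def max_neg_log10_p(self) -> float:
        return float(self.table["neg_log10_p"].max())

    @property
    def peak(self) -> pd.Series:
        return self.table.loc[self.table["neg_log10_p"].idxmax()]


@dataclass
class PermutationResult:
    B: int
    null_max_stats: np.ndarray  # genome-wide max -log10 p per shuffle
    observed_max: float
    seed: int

    @property
    def K(self) -> int:
        return int(np.sum(self.null_max_stats >= self.observed_max))

    @property
    def empirical_p(self) -> float:
        return self.K / self.B

    def empirical_p_for(self, stat: float) -> float:
        return float(np.sum(self.null_max_stats >= stat)) / self.B

    def threshold(self, alpha: float = 0.05) -> float:
        return float(np.quantile(self.null_max_stats, 1.0 - alpha))


@dataclass
class QTLCall:
    marker: str
    chrom: str
    cM: float
    bp: int
    trait: str
    phenotype_name: str
    neg_log10_p: float
    empirical_p: float
    interval_lower: int
    interval_upper: int
    passes_cutoff: bool
    marker_h2: float
    group_means: dict = field(default_factory=dict)


def single_marker_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over genotype groups.

    ``groups`` is a sequence of 1-D value arrays, one per genotype class;
    empty classes are skipped. Raises when either degrees of freedom
    vanish (fewer than two non-empty classes, or no residual replication).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups
            if np.asarray(g).size > 0]
    k = len(arrs)
    n = sum(a.size for a in arrs)
    if k < 2:
        raise ValueError("need >= 2 non-empty groups")
    if n - k < 1:
        raise ValueError("residual degrees of freedom = 0")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        return (np.inf, _MIN_P) if ssb > 0 else (0.0, 1.0)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), max(p, _MIN_P)


def _anova_batch(y: np.ndarray, labels: np.ndarray):
    """Vectorised per-marker one-way ANOVA of phenotype vectors.

    y: (n_perm, n_lines) phenotype rows (row 0 may be the observed data);
    labels: (n_markers, n_lines) class labels with -1 = excluded.
    Returns F, p, h2 arrays of shape (n_perm, n_markers) plus per-marker
    validity mask and group means (observed row only).
    """
    n_perm, n_lines = y.shape
    n_markers = labels.shape[0]
    F = np.full((n_perm, n_markers), np.nan)
    P = np.ones((n_perm, n_markers))
    H2 = np.full((n_perm, n_markers), np.nan)
    valid = np.zeros(n_markers, dtype=bool)
    means0: list[dict[int, float]] = [{} for _ in range(n_markers)]
    for m in range(n_markers):
        lab = labels[m]
        use = lab >= 0
        if use.sum() < 3:
            continue
        lab_u = lab[use]
        classes, idx = np.unique(lab_u, return_inverse=True)
        k = classes.size
        counts = np.bincount(idx, minlength=k).astype(float)
        nz = counts > 0
        if nz.sum() < 2:
            continue
        yv = y[:, use]  # (n_perm, n_use)
        n = yv.shape[1]
        dfb, dfw = k - 1, n - k
        if dfw < 1:
            continue
        onehot = np.zeros((n, k))
        onehot[np.arange(n), idx] = 1.0
        sums = yv @ onehot  # (n_perm, k)
        tot = yv.sum(axis=1)
        ssb = (sums**2 / counts).sum(axis=1) - tot**2 / n
        sst = (yv**2).sum(axis=1) - tot**2 / n
        ssw = np.maximum(sst - ssb, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / dfb) / (ssw / dfw)
            h2 = np.where(sst > 0, ssb / sst, np.nan)
        f = np.where(ssw > 0, f, np.inf)
        p = stats.f.sf(f, dfb, dfw)
        p = np.clip(np.where(np.isfinite(f), p, _MIN_P), _MIN_P, 1.0)
        F[:, m], P[:, m], H2[:, m] = f, p, np.clip(h2, 0.0, 1.0)
        valid[m] = True
        gm = sums[0] / counts
        means0[m] = {int(c): float(v) for c, v in zip(classes, gm)}
    return F, P, H2, valid, means0


def _align_phenotype(gdata: GenotypeData, phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(gdata.line_names)
        if y.isna().any():
            missing = [l for l in gdata.line_names if pd.isna(y[l])]
            raise ValueError(f"phenotype missing for lines {missing[:5]}...")
        return y.to_numpy(dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if y.size != gdata.n_lines:
        raise ValueError("phenotype length must match line count")
    return y


def genome_scan(
    gdata: GenotypeData,
    phenotype,
    grouping: str = "genotype",
    trait: str = "",
    phenotype_name: str = "",
) -> MarkerScan:
    """Single-marker ANOVA at every marker of the map.

    ``phenotype`` is one value per line (replicates already averaged),
    either an array aligned to ``gdata.line_names`` or a Series indexed
    by line.
    """
    y = _align_phenotype(gdata, phenotype)
    labels, class_names = gdata.group_labels(grouping)
    F, P, H2, valid, means = _anova_batch(y[None, :], labels)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 informative markers")
    tab = gdata.markers.copy()
    tab["F"] = F[0]
    tab["p"] = np.where(valid, P[0], np.nan)
    with np.errstate(divide="ignore"):
        tab["neg_log10_p"] = np.where(valid, -np.log10(P[0]), np.nan)
    tab["marker_h2"] = np.where(valid, H2[0], np.nan)
    for ci, cname in enumerate(class_names):
        tab[f"mean_{cname}"] = [means[m].get(ci, np.nan)
                                for m in range(len(means))]
    return MarkerScan(table=tab, trait=trait,
                      phenotype_name=phenotype_name, grouping=grouping)


def permutation_test(
    gdata: GenotypeData,
    phenotype,
    B: int = 1000,
    seed: int = 0,
    grouping: str = "genotype",
    observed_max: float | None = None,
) -> PermutationResult:
    """Genome-wide permutation null for one phenotype.

    The per-line phenotype vector is shuffled ``B`` times (jointly across
    all markers, preserving the genotype structure) and the genome-wide
    maximum -log10 p of each shuffle is recorded. ``empirical_p`` is
    K/B, the fraction of null maxima at or above the observed maximum.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = _align_phenotype(gdata, phenotype)
    labels, _ = gdata.group_labels(grouping)
    if observed_max is None:
        F, P, _, valid, _ = _anova_batch(y[None, :], labels)
        if valid.sum() < 1:
            raise ValueError("no informative marker for observed statistic")
        observed_max = float(np.max(-np.log10(P[0, valid])))
    if not np.isfinite(observed_max):
        raise ValueError("observed statistic is not finite")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(B)])
    _, P, _, valid, _ = _anova_batch(perms, labels)
    null_max = -np.log10(P[:, valid].min(axis=1))
    return PermutationResult(B=B, null_max_stats=null_max,
                             observed_max=observed_max, seed=seed)


def call_qtls(
    scan: MarkerScan,
    perm: PermutationResult,
    logp_cutoff: float = 4.0,
    alpha: float = 0.05,
    drop: float = 1.5,
    min_distance_cM: float = 20.0,
) -> list[QTLCall]:
    """Peak calling with the dual cutoff (-log10 p > 4 and empirical
    p < alpha) and drop-based support intervals.

    Per chromosome the highest marker is considered first; its support
    interval is the contiguous run of markers within ``drop`` -log10 p
    units of the peak, reported in bp. Further local peaks on the same
    chromosome are considered in turn, but markers linked to an existing
    call (in its above-cutoff run or within ``min_distance_cM`` of its
    peak) never start a second call.
    """
    calls: list[QTLCall] = []
    tab = scan.table
    mean_cols = [c for c in tab.columns if c.startswith("mean_")]
    for chrom, sub in tab.groupby("chrom", sort=False):
        sub = sub.sort_values("cM").reset_index(drop=True)
        lp = sub["neg_log10_p"].to_numpy()
        available = np.isfinite(lp)
        while available.any():
            i = int(np.nanargmax(np.where(available, lp, -np.inf)))
            peak_lp = lp[i]
            if not np.isfinite(peak_lp) or peak_lp <= logp_cutoff:
                break
            lo = i
            while lo > 0 and np.isfinite(lp[lo - 1]) and lp[lo - 1] >= peak_lp - drop:
                lo -= 1
            hi = i
            while hi < len(lp) - 1 and np.isfinite(lp[hi + 1]) and lp[hi + 1] >= peak_lp - drop:
                hi += 1
            # one call per linked region: mask the whole contiguous run of
            # markers above the cutoff around this peak, not just the
            # (possibly narrower) drop interval
            mlo = min(lo, i)
            while mlo > 0 and np.isfinite(lp[mlo - 1]) and lp[mlo - 1] > logp_cutoff:
                mlo -= 1
            mhi = max(hi, i)
            while mhi < len(lp) - 1 and np.isfinite(lp[mhi + 1]) and lp[mhi + 1] > logp_cutoff:
                mhi += 1
            emp_p = perm.empirical_p_for(peak_lp)
            row = sub.iloc[i]
            calls.append(QTLCall(
                marker=row["marker"], chrom=chrom, cM=float(row["cM"]),
                bp=int(row["bp"]), trait=scan.trait,
                phenotype_name=scan.phenotype_name,
                neg_log10_p=float(peak_lp), empirical_p=emp_p,
                interval_lower=int(sub.iloc[lo]["bp"]),
                interval_upper=int(sub.iloc[hi]["bp"]),
                passes_cutoff=bool(peak_lp > logp_cutoff and emp_p < alpha),
                marker_h2=float(row["marker_h2"]),
                group_means={c[5:]: float(row[c]) for c in mean_cols
                             if np.isfinite(row[c])},
            ))
            available[mlo:mhi + 1] = False
            near = np.abs(sub["cM"].to_numpy() - sub.iloc[i]["cM"]) < min_distance_cM
            available[near] = False
    return [c for c in calls if c.passes_cutoff]


def line_means(series: pd.DataFrame, trait: str, das: int) -> pd.Series:
    """Per-line replicate-mean phenotype of one trait at one DAS."""
    sub = series[(series["trait"] == trait) & (series["DAS"] == das)]
    return sub.groupby("line")["value"].mean()


def longitudinal_scan(
    series: pd.DataFrame,
    gdata: GenotypeData,
    trait: str,
    grouping: str = "genotype",
) -> tuple[dict[int, MarkerScan], pd.DataFrame]:
    """Genome scan at every retained DAS of one trait.

    Returns the per-DAS scans plus a tidy trajectory table (marker, DAS,
    neg_log10_p, marker_h2) for plotting significance over time.
    """
    sub = series[series["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from series")
    scans: dict[int, MarkerScan] = {}
    rows = []
    for das in sorted(sub["DAS"].unique()):
        pheno = line_means(series, trait, das)
        pheno = pheno.reindex(gdata.line_names).dropna()
        sub_gd = _subset_lines(gdata, list(pheno.index))
        scan = genome_scan(sub_gd, pheno, grouping=grouping, trait=trait,
                           phenotype_name=str(das))
        scans[int(das)] = scan
        tmp = scan.table[["marker", "chrom", "cM", "bp",
                          "neg_log10_p", "marker_h2"]].copy()
        tmp["DAS"] = int(das)
        rows.append(tmp)
    traj = pd.concat(rows, ignore_index=True)
    return scans, traj


def _subset_lines(gdata: GenotypeData, lines: list[str]) -> GenotypeData:
    if lines == gdata.line_names:
        return gdata
    idx = [gdata.line_names.index(l) for l in lines]
    return GenotypeData(
        markers=gdata.markers, line_names=lines,
        genotypes=gdata.genotypes[idx],
        founder_origin=(gdata.founder_origin[idx]
                        if gdata.founder_origin is not None else None),
        founder_names=gdata.founder_names,
    )


def parameter_scan(
    param_table: pd.DataFrame,
    gdata: GenotypeData,
    parameters: list[str] | None = None,
    grouping: str = "genotype",
    trait: str = "",
) -> dict[str, MarkerScan]:
    """Scan each fitted curve/mixture parameter as a quantitative trait.

    ``param_table`` must have ``line`` and ``rep`` columns plus numeric
    parameter columns (only converged fits should be included);
    replicates are averaged per line before scanning.
    """
    cols = parameters or [c for c in param_table.columns
                          if c not in ("line", "rep", "trait", "model")
                          and np.issubdtype(param_table[c].dtype, np.number)]
    out: dict[str, MarkerScan] = {}
    for c in cols:
        pheno = param_table.groupby("line")[c].mean()
        pheno = pheno.reindex(gdata.line_names).dropna()
        if pheno.nunique() <= 1:
            continue  # constant parameter carries no contrast
        sub_gd = _subset_lines(gdata, list(pheno.index))
        out[c] = genome_scan(sub_gd, pheno, grouping=grouping,
                             trait=trait, phenotype_name=c)
    return out


def marker_effect_regression(
    series: pd.DataFrame,
    gdata: GenotypeData,
    marker: str,
    trait: str,
) -> pd.DataFrame:
    """Per-timepoint OLS of the trait on a marker's allele dosage.

    Returns one row per DAS with the additive slope (trait units per B
    allele), its standard error and p-value — the marker-effect
    trajectory view of a QTL.
    """
    try:
        m = int(np.nonzero((gdata.markers["marker"] == marker).to_numpy())[0][0])
    except IndexError:
        raise KeyError(f"marker {marker!r} not in map") from None
    dosage = pd.Series(gdata.genotypes[:, m].astype(float),
                       index=gdata.line_names)
    if dosage.nunique() <= 1:
        raise ValueError(f"marker {marker!r} is monomorphic")
    sub = series[series["trait"] == trait]
    rows = []
    for das in sorted(sub["DAS"].unique()):
        pheno = line_means(series, trait, das)
        common = pheno.index.intersection(dosage.index)
        x = dosage[common].to_numpy()
        yv = pheno[common].to_numpy()
        if np.unique(x).size < 2 or x.size < 3:
            continue
        res = stats.linregress(x, yv)
        rows.append({"DAS": int(das), "slope": res.slope,
                     "stderr": res.stderr, "p": res.pvalue,
                     "intercept": res.intercept})
    return pd.DataFrame(rows)
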