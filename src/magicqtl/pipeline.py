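"""End-to-end orchestration: simulate/load -> clean -> fit -> map.

The pipeline mirrors the analysis a functional-mapping study runs on
image-derived trait tables: per-plant growth curves are fitted to each
sigmoid trait and a two-Gaussian mixture to daily water use; curve
parameters are decomposed into genetic and environmental variance to get
heritabilities and genetic correlations; and both single-timepoint traits
and fitted parameters are scanned genome-wide with permutation
thresholds. Every stage writes a plain CSV/JSON artifact and a manifest
records what ran, with which seed, and how many records each stage
consumed and produced.
"""

from __future__ import annotations

import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .growth import fit_growth_model, select_model
from .mixture import fit_watercurve
from .preprocess import clean
from .quantgen import component_table, correlation_matrices
from .scan import (GenotypeData, _subset_lines, call_qtls, genome_scan,
                   line_means, longitudinal_scan, parameter_scan,
                   permutation_test)
from .simulate import (SIGMOID_TRAITS, WATER_TRAIT, SimulationConfig,
                       simulate_dataset)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "validate_inputs",
    "fit_trait_parameters",
    "fit_water_parameters",
]


@dataclass
class PipelineConfig:
    outdir: str = "magicqtl_out"
    seed: int = 0
    genotype_path: str | None = None
    phenotype_path: str | None = None
    simulate: SimulationConfig | None = None
    traits: tuple[str, ...] | None = None  # default: all traits present
    models: tuple[str, ...] = ("logistic", "4pl", "gompertz")
    permutations: int = 1000
    alpha: float = 0.05
    logp_cutoff: float = 4.0
    grouping: str = "genotype"
    cooks_multiplier: float = 4.0
    cooks_degree: int = 3
    max_outlier_frac: float = 0.05
    # subset of DAS for the per-timepoint scans (None = every retained DAS)
    scan_timepoints: tuple[int, ...] | None = None

    def __post_init__(self):
        has_files = self.genotype_path is not None and self.phenotype_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError(
                "configure exactly one of (genotype_path + phenotype_path) "
                "or simulate"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            qtl = sim.pop("qtl", [])
            from .simulate import QTLEffect
            sim_cfg = SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in sim.items()
            })
            sim_cfg.qtl = tuple(
                QTLEffect(marker=q["marker"], trait=q["trait"],
                          parameter=q["parameter"],
                          effects=tuple(q["effects"]))
                for q in qtl
            )
            raw["simulate"] = sim_cfg
        for key in ("traits", "models", "scan_timepoints"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_inputs(gdata: GenotypeData, phenotypes: pd.DataFrame) -> dict:
    """Cross-check genotype and phenotype tables before analysis.

    Returns {"errors": [...], "warnings": [...]}; errors are fatal.
    """
    errors, warns = [], []
    for chrom, grp in gdata.markers.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy()
        if not np.all(np.diff(cm) > 0):
            errors.append(f"non-monotone cM positions on {chrom}")
    if gdata.markers["marker"].duplicated().any():
        errors.append("duplicate marker names in genotype table")
    geno_lines = set(gdata.line_names)
    pheno_lines = set(phenotypes["line"].unique())
    orphans = sorted(pheno_lines - geno_lines)
    if orphans:
        warns.append(
            f"{len(orphans)} phenotyped lines absent from genotype table "
            f"(excluded from mapping): {orphans[:5]}"
        )
    dup = phenotypes.duplicated(["line", "rep", "DAS", "trait"]).sum()
    if dup:
        errors.append(f"{dup} duplicate (line, rep, DAS, trait) records")
    if (phenotypes["value"] < 0).any():
        warns.append("negative phenotype values present")
    return {"errors": errors, "warnings": warns}


def fit_trait_parameters(
    series: pd.DataFrame,
    trait: str,
    models: tuple[str, ...] = ("logistic", "4pl", "gompertz"),
) -> pd.DataFrame:
    """Fit candidate growth models to every (line, rep) series of a
    sigmoid trait and keep the best model by R².

    Returns one row per (line, rep) with the selected model's parameters,
    R² and convergence flag. Non-converged series keep a row with
    ``converged = False`` so downstream stages can exclude them.
    """
    sub = series[series["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from series")
    rows = []
    for (line, rep), grp in sub.groupby(["line", "rep"], sort=True):
        grp = grp.sort_values("DAS")
        t = grp["DAS"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        fits = []
        for model in models:
            try:
                fits.append(fit_growth_model(t, y, model))
            except ValueError:
                continue
        try:
            best = select_model(fits)
        except ValueError:
            rows.append({"line": line, "rep": rep, "trait": trait,
                         "model": "none", "r_squared": np.nan,
                         "converged": False})
            continue
        rows.append({"line": line, "rep": rep, "trait": trait,
                     "model": best.model, **best.param_dict(),
                     "r_squared": best.r_squared,
                     "converged": best.converged})
    return pd.DataFrame(rows)


def fit_water_parameters(series: pd.DataFrame,
                         trait: str = WATER_TRAIT) -> pd.DataFrame:
    """Fit the two-mode mixture to every (line, rep) water-use curve."""
    sub = series[series["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from series")
    rows = []
    for (line, rep), grp in sub.groupby(["line", "rep"], sort=True):
        grp = grp.sort_values("DAS")
        try:
            fit = fit_watercurve(grp["DAS"].to_numpy(dtype=float),
                                 grp["value"].to_numpy(dtype=float))
        except ValueError:
            rows.append({"line": line, "rep": rep, "trait": trait,
                         "converged": False})
            continue
        c1, c2 = fit.components
        rows.append({"line": line, "rep": rep, "trait": trait,
                     "mu1": c1.mu, "lam1": c1.lam, "sigma1": c1.sigma,
                     "mu2": c2.mu, "lam2": c2.lam, "sigma2": c2.sigma,
                     "S": fit.separation,
                     "loglik": fit.log_likelihood,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "counts": {},
        "status": "running",
    }
    t_start = time.time()

    def stage(name):
        manifest["stages"].append(name)

    try:
        # --- data ---
        stage("data")
        if config.simulate is not None:
            panel, pop, series, truth = simulate_dataset(config.simulate)
            gdata = GenotypeData.from_population(pop)
            mio.write_genotypes(gdata, outdir / "genotypes.tsv")
            mio.write_phenotypes(series, outdir / "phenotypes.csv")
            _float_csv(truth, outdir / "true_parameters.csv")
        else:
            gdata = mio.read_genotypes(config.genotype_path)
            series = mio.read_phenotypes(config.phenotype_path)
        manifest["counts"]["markers"] = gdata.n_markers
        manifest["counts"]["lines"] = gdata.n_lines
        manifest["counts"]["phenotype_records"] = len(series)

        # --- validation ---
        stage("validate")
        report = validate_inputs(gdata, series)
        mio.write_json(report, outdir / "validation.json")
        if report["errors"]:
            raise ValueError(f"input validation failed: {report['errors']}")
        series = series[series["line"].isin(gdata.line_names)]

        traits = tuple(config.traits or
                       sorted(series["trait"].unique()))
        missing = [t for t in traits if t not in set(series["trait"])]
        if missing:
            raise ValueError(f"traits {missing} absent from phenotype table")

        # --- cleaning ---
        stage("clean")
        roster = set(series["line"].unique())
        cleaned, creport = clean(
            series[series["trait"].isin(traits)], roster,
            multiplier=config.cooks_multiplier,
            degree=config.cooks_degree,
            max_fraction=config.max_outlier_frac,
        )
        mio.write_phenotypes(cleaned, outdir / "phenotypes_clean.csv")
        mio.write_json(creport.to_dict(), outdir / "cleaning_report.json")
        manifest["counts"]["cleaned_records"] = len(cleaned)

        # --- curve fitting ---
        stage("fit")
        param_tables: dict[str, pd.DataFrame] = {}
        for trait in traits:
            if trait == WATER_TRAIT:
                tab = fit_water_parameters(cleaned, trait)
            else:
                tab = fit_trait_parameters(cleaned, trait, config.models)
            param_tables[trait] = tab
            safe = trait.replace(".", "_")
            _float_csv(tab, outdir / f"params_{safe}.csv")
        manifest["counts"]["fitted_series"] = int(
            sum(len(t) for t in param_tables.values())
        )

        # --- variance components ---
        stage("quantgen")
        h2_rows = []
        for trait, tab in param_tables.items():
            conv = tab[tab["converged"] == True]  # noqa: E712
            if conv.empty:
                continue
            ct = component_table(conv.drop(columns=["r_squared", "loglik"],
                                           errors="ignore"))
            ct.insert(0, "trait", trait)
            h2_rows.append(ct)
            rg, re = correlation_matrices(
                conv.drop(columns=["r_squared", "loglik"], errors="ignore")
            )
            safe = trait.replace(".", "_")
            rg.to_csv(outdir / f"corr_genetic_{safe}.csv",
                      float_format="%.10g")
            re.to_csv(outdir / f"corr_environmental_{safe}.csv",
                      float_format="%.10g")
        if h2_rows:
            _float_csv(pd.concat(h2_rows, ignore_index=True),
                       outdir / "heritability.csv")

        # --- scans ---
        stage("scan")
        all_calls = []
        traj_tables = []
        for trait in traits:
            # per-timepoint scans
            sub = cleaned[cleaned["trait"] == trait]
            das_all = sorted(sub["DAS"].unique())
            das_used = [d for d in das_all
                        if config.scan_timepoints is None
                        or d in config.scan_timepoints]
            scan_sub = sub[sub["DAS"].isin(das_used)]
            scans, traj = longitudinal_scan(scan_sub, gdata, trait,
                                            grouping=config.grouping)
            traj["trait"] = trait
            traj_tables.append(traj)
            for das, scan in scans.items():
                pheno = line_means(cleaned, trait, das)
                pheno = pheno.reindex(gdata.line_names).dropna()
                sub_gd = _subset_lines(gdata, list(pheno.index))
                perm = permutation_test(
                    sub_gd, pheno, B=config.permutations,
                    seed=config.seed + das, grouping=config.grouping,
                    observed_max=scan.max_neg_log10_p,
                )
                all_calls.extend(call_qtls(scan, perm,
                                           logp_cutoff=config.logp_cutoff,
                                           alpha=config.alpha))
            # parameter scans
            conv = param_tables[trait]
            conv = conv[conv["converged"] == True]  # noqa: E712
            if conv.empty:
                continue
            drop_cols = [c for c in ("r_squared", "loglik") if c in conv]
            pscans = parameter_scan(conv.drop(columns=drop_cols), gdata,
                                    grouping=config.grouping, trait=trait)
            for pname, scan in pscans.items():
                pheno = conv.groupby("line")[pname].mean()
                pheno = pheno.reindex(gdata.line_names).dropna()
                ptag = sum(pname.encode()) % 10000  # stable across runs
                sub_gd = _subset_lines(gdata, list(pheno.index))
                perm = permutation_test(
                    sub_gd, pheno, B=config.permutations,
                    seed=config.seed + ptag,
                    grouping=config.grouping,
                    observed_max=scan.max_neg_log10_p,
                )
                all_calls.extend(call_qtls(scan, perm,
                                           logp_cutoff=config.logp_cutoff,
                                           alpha=config.alpha))
                safe = f"{trait.replace('.', '_')}_{pname}"
                _float_csv(scan.table, outdir / f"scan_param_{safe}.csv")
        if traj_tables:
            _float_csv(pd.concat(traj_tables, ignore_index=True),
                       outdir / "timepoint_trajectories.csv")
        calls_df = pd.DataFrame([{
            "trait": c.trait, "phenotype": c.phenotype_name,
            "peak.SNP": c.marker, "chr": c.chrom, "cM": c.cM, "bp": c.bp,
            **{f"mean_{k}": v for k, v in sorted(c.group_means.items())},
            "h2": c.marker_h2, "logP": c.neg_log10_p,
            "P-value": c.empirical_p, "Lower": c.interval_lower,
            "Upper": c.interval_upper,
        } for c in all_calls])
        _float_csv(calls_df, outdir / "qtl_calls.csv")
        manifest["counts"]["qtl_calls"] = len(calls_df)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["traceback"] = traceback.format_exc()
        raise
    finally:
        manifest["runtime_s"] = round(time.time() - t_start, 3)
        mio.write_json(manifest, outdir / "manifest.json")
    return manifest
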