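"""Synthetic eight-founder MAGIC population with longitudinal phenotypes.

Emulates a wheat multiparent advanced-generation intercross (MAGIC)
recombinant-inbred-line panel: eight inbred founders are combined through
a funnel of two-, four- and eight-way crosses, put through extra
intercross generations, and selfed to near-homozygosity. Meiosis places
crossovers by a Poisson process on the centimorgan axis (Haldane map
function, no interference), so every RIL chromosome is a mosaic of
founder segments and the ground-truth founder origin of every marker is
known.

Phenotypes are generated from the same growth models the analysis fits:
sigmoid traits (Area, Height, senescent area) follow a 4-parameter
logistic curve; daily water use follows a two-Gaussian curve with
vegetative and grain-filling modes. QTL effects act on the latent curve
parameters via the founder allele carried at a marker; replicates share a
line's genetic parameter values but draw independent environmental
deviations and observation noise. The true per-replicate parameters are
returned alongside the observations so parameter recovery, heritability
and scan power are all testable against ground truth.

Defaults mirror a desk-scale version of the study design: 208 RILs, two
replicates, imaging window 90-190 days after sowing (DAS), three cycles
of recombination (funnel + intercrossing) and five selfing generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import eval_4pl
from .mixture import _normal_pdf

__all__ = [
    "FounderPanel",
    "RILPopulation",
    "QTLEffect",
    "SimulationConfig",
    "simulate_founders",
    "simulate_magic_rils",
    "simulate_trait_series",
    "simulate_dataset",
    "DEFAULT_TRAIT_MODELS",
]

SIGMOID_TRAITS = ("Area", "Height", "TYP.Area")
WATER_TRAIT = "water_amount"

# Baseline curve parameters per trait, in trait units (mm^2, mm, ml).
# Magnitudes follow the growth trajectories of a winter-wheat smart-house
# experiment: area and height rise sigmoidally to their asymptote around
# 130 DAS, senescent area rises late, and daily water use is bimodal with
# modes near 130 and 180 DAS.
DEFAULT_TRAIT_MODELS: dict[str, dict[str, float]] = {
    "Area": {"A": 2000.0, "B": 11.0, "C": 130.0, "D": 85000.0},
    "Height": {"A": 50.0, "B": 6.5, "C": 125.0, "D": 700.0},
    "TYP.Area": {"A": 0.0, "B": 15.0, "C": 165.0, "D": 35000.0},
    WATER_TRAIT: {"lam1": 6000.0, "mu1": 130.0, "sigma1": 10.0,
                  "lam2": 5000.0, "mu2": 180.0, "sigma2": 12.0},
}

# Observation noise s.d. per trait (~2% of the trait's dynamic range).
DEFAULT_OBS_NOISE: dict[str, float] = {
    "Area": 1700.0,
    "Height": 14.0,
    "TYP.Area": 700.0,
    WATER_TRAIT: 5.0,
}

# Replicate-level environmental s.d. on each curve parameter, as a
# fraction of the baseline parameter magnitude.
DEFAULT_PARAM_ENV_FRAC = 0.05


@dataclass(frozen=True)
class QTLEffect:
    """Additive effect of one marker on one latent curve parameter.

    ``effects`` maps founder index (0-7) to the shift added to the
    parameter when a line carries that founder's haplotype at ``marker``;
    heterozygous lines get the mean of their two haplotypes' effects.
    """

    marker: str
    trait: str
    parameter: str
    effects: tuple[float, ...]


@dataclass
class FounderPanel:
    markers: pd.DataFrame  # columns: marker, chrom, cM, bp
    founder_alleles: np.ndarray  # (n_founders, n_markers) of 0/1
    founder_names: list[str]

    @property
    def n_founders(self) -> int:
        return self.founder_alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.founder_alleles.shape[1]


@dataclass
class RILPopulation:
    panel: FounderPanel
    line_names: list[str]
    # haplotype founder labels, (n_lines, 2, n_markers)
    haplotypes: np.ndarray
    # fraction of loci per line where the two haplotype lineages differ
    residual_het: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def founder_origin(self) -> np.ndarray:
        """Primary-haplotype founder index per (line, marker)."""
        return self.haplotypes[:, 0, :]

    @property
    def genotypes(self) -> np.ndarray:
        """Allele dosage 0/1/2 of the B allele per (line, marker)."""
        alleles = self.panel.founder_alleles
        midx = np.arange(self.panel.n_markers)
        a0 = alleles[self.haplotypes[:, 0, :], midx]
        a1 = alleles[self.haplotypes[:, 1, :], midx]
        return (a0 + a1).astype(np.int8)

    def genotype_codes(self) -> np.ndarray:
        """Character codes A/H/B per (line, marker)."""
        return np.array(["A", "H", "B"])[self.genotypes]


@dataclass
class SimulationConfig:
    """Everything needed to regenerate one synthetic experiment."""

    seed: int = 0
    n_lines: int = 208
    n_reps: int = 2
    n_founders: int = 8
    # (chromosome name, length in cM, marker count)
    chromosomes: tuple[tuple[str, float, int], ...] = (
        ("chr1A", 120.0, 40),
        ("chr2D", 150.0, 40),
        ("chr4D", 120.0, 40),
        ("chr5A", 150.0, 40),
        ("chr7B", 140.0, 40),
    )
    founder_maf: tuple[float, float] = (0.25, 0.5)
    intercross_generations: int = 2  # extra rounds after the 8-way funnel
    selfing_generations: int = 5
    timepoints: tuple[int, ...] = tuple(range(90, 191, 2))
    traits: tuple[str, ...] = ("Area", "Height", "TYP.Area", WATER_TRAIT)
    baseline: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_MODELS.items()}
    )
    obs_noise: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OBS_NOISE)
    )
    # replicate-level environmental s.d. per (trait, parameter); missing
    # entries default to DEFAULT_PARAM_ENV_FRAC * |baseline value|
    param_env_sd: Mapping[tuple[str, str], float] = field(default_factory=dict)
    # line-level polygenic s.d. per (trait, parameter); default 0
    param_genetic_sd: Mapping[tuple[str, str], float] = field(default_factory=dict)
    qtl: tuple[QTLEffect, ...] = ()

    def validate(self, panel: FounderPanel | None = None) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not self.chromosomes or any(n < 2 for _, _, n in self.chromosomes):
            raise ValueError("need >= 1 chromosome with >= 2 markers")
        if any(sd < 0 for sd in self.obs_noise.values()):
            raise ValueError("observation noise s.d. must be >= 0")
        if any(sd < 0 for sd in self.param_env_sd.values()):
            raise ValueError("parameter env s.d. must be >= 0")
        if any(sd < 0 for sd in self.param_genetic_sd.values()):
            raise ValueError("parameter genetic s.d. must be >= 0")
        lo, hi = self.founder_maf
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("founder_maf bounds must satisfy 0 < lo <= hi <= 0.5")
        if panel is not None:
            known = set(panel.markers["marker"])
            for q in self.qtl:
                if q.marker not in known:
                    raise ValueError(f"QTL marker {q.marker!r} not in panel")


def simulate_founders(config: SimulationConfig) -> FounderPanel:
    """Draw founder marker alleles and map positions.

    Markers sit on an even centimorgan grid per chromosome (strictly
    increasing); physical positions are a smooth monotone map of cM. Each
    marker's minor-allele count among founders is drawn uniformly within
    the configured frequency bounds, so every marker is polymorphic.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf = config.n_founders
    rows = []
    for chrom, length, n_mark in config.chromosomes:
        cm = np.linspace(0.0, length, n_mark)
        bp = np.round(cm * 1.0e6 + 1).astype(np.int64)  # ~1 Mb per cM
        for j, (c, b) in enumerate(zip(cm, bp)):
            rows.append({"marker": f"{chrom}_m{j:03d}", "chrom": chrom,
                         "cM": float(c), "bp": int(b)})
    markers = pd.DataFrame(rows)
    n_markers = len(markers)
    lo, hi = config.founder_maf
    k_lo = max(int(np.ceil(lo * nf)), 1)
    k_hi = max(int(np.floor(hi * nf)), k_lo)
    alleles = np.zeros((nf, n_markers), dtype=np.int8)
    counts = rng.integers(k_lo, k_hi + 1, size=n_markers)
    for m in range(n_markers):
        carriers = rng.choice(nf, size=counts[m], replace=False)
        alleles[carriers, m] = 1
    names = [f"F{i + 1}" for i in range(nf)]
    return FounderPanel(markers=markers, founder_alleles=alleles,
                        founder_names=names)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, cm: np.ndarray,
            length: float, rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: crossovers by Haldane (Poisson on cM)."""
    n_x = rng.poisson(length / 100.0)
    start = rng.integers(0, 2)
    if n_x == 0:
        return (hap_a if start == 0 else hap_b).copy()
    xpos = np.sort(rng.uniform(0.0, length, size=n_x))
    phase = (start + np.searchsorted(xpos, cm, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b)


class _Meiosis:
    """Per-chromosome crossing machinery on lineage-labelled haplotypes."""

    def __init__(self, panel: FounderPanel, rng: np.random.Generator,
                 chrom_lengths: Mapping[str, float]):
        self.rng = rng
        self.chroms = []
        for chrom, grp in panel.markers.groupby("chrom", sort=False):
            self.chroms.append((chrom, grp["cM"].to_numpy(),
                                chrom_lengths[chrom]))

    def cross(self, p1, p2):
        """Offspring genome: one gamete from each parent, per chromosome."""
        child = {}
        for chrom, cm, length in self.chroms:
            g1 = _gamete(p1[chrom][0], p1[chrom][1], cm, length, self.rng)
            g2 = _gamete(p2[chrom][0], p2[chrom][1], cm, length, self.rng)
            child[chrom] = (g1, g2)
        return child

    def self_(self, p):
        return self.cross(p, p)


def simulate_magic_rils(panel: FounderPanel,
                        config: SimulationConfig) -> RILPopulation:
    """Run the crossing scheme and return the RIL panel with ground truth.

    Each line is produced independently: founders are shuffled into an
    8-way funnel (4 two-way crosses, 2 four-way, 1 eight-way); the
    configured number of extra intercross generations crosses independent
    funnel products; then the line is selfed. Haplotypes carry lineage
    labels internally so residual heterozygosity is measured as the
    fraction of loci whose two haplotypes descend from distinct ancestral
    chromosome copies — in expectation (1/2)^s after s selfings.
    """
    config.validate(panel)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    chrom_lengths = {chrom: float(length)
                     for chrom, length, _ in config.chromosomes}
    meio = _Meiosis(panel, rng, chrom_lengths)
    chrom_sizes = [(chrom, grp.shape[0])
                   for chrom, grp in panel.markers.groupby("chrom", sort=False)]
    nf = config.n_founders

    def founder_genome(founder: int, instance: int):
        """Inbred founder: both haplotypes one ancestral copy label."""
        g = {}
        for chrom, size in chrom_sizes:
            h = np.full(size, instance, dtype=np.int32)
            g[chrom] = (h, h.copy())
        return g

    def funnel(instance_base: int):
        order = rng.permutation(nf)
        leaves = [founder_genome(f, instance_base + i)
                  for i, f in enumerate(order)]
        gen = leaves
        while len(gen) > 1:
            gen = [meio.cross(gen[i], gen[i + 1])
                   for i in range(0, len(gen), 2)]
        return gen[0], order

    n_markers = panel.n_markers
    haps = np.empty((config.n_lines, 2, n_markers), dtype=np.int16)
    het = np.empty(config.n_lines)
    for li in range(config.n_lines):
        instance_map: dict[int, int] = {}

        def make(depth: int):
            base = len(instance_map)
            if depth == 0:
                genome, order = funnel(base)
                for i, f in enumerate(order):
                    instance_map[base + i] = int(f)
                return genome
            return meio.cross(make(depth - 1), make(depth - 1))

        genome = make(config.intercross_generations)
        for _ in range(config.selfing_generations):
            genome = meio.self_(genome)
        h0 = np.concatenate([genome[chrom][0] for chrom, _ in chrom_sizes])
        h1 = np.concatenate([genome[chrom][1] for chrom, _ in chrom_sizes])
        het[li] = float(np.mean(h0 != h1))
        lut = np.array([instance_map[i] for i in range(len(instance_map))],
                       dtype=np.int16)
        haps[li, 0] = lut[h0]
        haps[li, 1] = lut[h1]

    names = [f"RIL{i + 1:04d}" for i in range(config.n_lines)]
    return RILPopulation(panel=panel, line_names=names, haplotypes=haps,
                         residual_het=het)


def _line_param_effects(pop: RILPopulation, config: SimulationConfig,
                        trait: str) -> dict[str, np.ndarray]:
    """Sum of QTL effects per (parameter, line) for one trait."""
    marker_idx = {m: i for i, m in enumerate(pop.panel.markers["marker"])}
    out: dict[str, np.ndarray] = {}
    for q in config.qtl:
        if q.trait != trait:
            continue
        eff = np.asarray(q.effects, dtype=float)
        if eff.size != pop.panel.n_founders:
            raise ValueError(
                f"QTL on {q.marker} needs one effect per founder"
            )
        j = marker_idx[q.marker]
        per_line = 0.5 * (eff[pop.haplotypes[:, 0, j]]
                          + eff[pop.haplotypes[:, 1, j]])
        out[q.parameter] = out.get(q.parameter, 0.0) + per_line
    return out


def _true_params(pop, config, trait, rng):
    """Per-(line, rep) latent curve parameters: baseline + QTL + polygenic
    line effect + replicate environmental deviation."""
    base = config.baseline[trait]
    qtl_eff = _line_param_effects(pop, config, trait)
    n, r = pop.n_lines, config.n_reps
    params: dict[str, np.ndarray] = {}
    for pname, bval in base.items():
        g_sd = config.param_genetic_sd.get((trait, pname), 0.0)
        e_sd = config.param_env_sd.get(
            (trait, pname), DEFAULT_PARAM_ENV_FRAC * abs(bval)
        )
        line_val = bval + qtl_eff.get(pname, np.zeros(n))
        line_val = line_val + g_sd * rng.standard_normal(n)
        rep_val = line_val[:, None] + e_sd * rng.standard_normal((n, r))
        params[pname] = rep_val
    return params


def _curve_values(trait: str, params: Mapping[str, float],
                  t: np.ndarray) -> np.ndarray:
    if trait in SIGMOID_TRAITS:
        return np.asarray(
            eval_4pl([params["A"], params["B"],
                      max(params["C"], 1e-3), params["D"]], t)
        )
    if trait == WATER_TRAIT:
        return (max(params["lam1"], 0.0)
                * _normal_pdf(t, params["mu1"], max(params["sigma1"], 1e-3))
                + max(params["lam2"], 0.0)
                * _normal_pdf(t, params["mu2"], max(params["sigma2"], 1e-3)))
    raise ValueError(f"no generative model for trait {trait!r}")


def simulate_trait_series(
    pop: RILPopulation, config: SimulationConfig, trait: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one trait's longitudinal observations for every line x rep.

    Returns ``(series, truth)``: a tidy observation table with columns
    (line, rep, DAS, trait, value) and the true per-replicate parameter
    table used to generate it. Negative generated values are floored at 0
    (all four traits are physically non-negative).
    """
    if trait not in config.baseline:
        raise ValueError(f"no baseline parameters for trait {trait!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 11, _trait_tag(trait)])
    )
    t = np.asarray(config.timepoints, dtype=float)
    params = _true_params(pop, config, trait, rng)
    noise_sd = config.obs_noise.get(trait, 0.0)
    n, r = pop.n_lines, config.n_reps

    records = []
    truth_rows = []
    for li in range(n):
        for ri in range(r):
            p = {k: float(v[li, ri]) for k, v in params.items()}
            mu = _curve_values(trait, p, t)
            vals = mu + noise_sd * rng.standard_normal(t.size)
            np.clip(vals, 0.0, None, out=vals)
            records.append(vals)
            truth_rows.append({"line": pop.line_names[li], "rep": ri + 1,
                               "trait": trait, **p})
    values = np.concatenate(records)
    lines = np.repeat(pop.line_names, r * t.size)
    reps = np.tile(np.repeat(np.arange(1, r + 1), t.size), n)
    das = np.tile(t.astype(int), n * r)
    series = pd.DataFrame({"line": lines, "rep": reps, "DAS": das,
                           "trait": trait, "value": values})
    truth = pd.DataFrame(truth_rows)
    return series, truth


def _trait_tag(trait: str) -> int:
    return int.from_bytes(trait.encode()[:4].ljust(4, b"_"), "little") % (2**31)


def simulate_dataset(config: SimulationConfig):
    """Full synthetic experiment: panel, RILs, and all trait series.

    Returns ``(panel, pop, series, truth)`` where ``series`` stacks the
    tidy observations of every configured trait and ``truth`` stacks the
    per-replicate generating parameters.
    """
    panel = simulate_founders(config)
    pop = simulate_magic_rils(panel, config)
    all_series, all_truth = [], []
    for trait in config.traits:
        s, g = simulate_trait_series(pop, config, trait)
        all_series.append(s)
        all_truth.append(g)
    series = pd.concat(all_series, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)
    return panel, pop, series, truth
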