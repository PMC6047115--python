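# magicqtl

Functional QTL mapping for longitudinal plant-phenomics data in
multiparental (MAGIC) populations.

High-throughput phenotyping platforms image every plant of a mapping
population daily, producing trait trajectories — plant area, height,
senescent area, water use — rather than single measurements. Mapping
each day separately tells you *when* a locus matters; fitting a growth
model per plant and mapping the fitted parameters tells you *which
aspect of development* it controls. `magicqtl` implements both views for
recombinant inbred line (RIL) panels descended from several founders,
plus everything needed around them: data cleaning, growth-curve and
mixture fitting, variance-component genetics, permutation-calibrated
genome scans, and a fully synthetic MAGIC population generator so that
every stage can be validated against ground truth.

## The models

Sigmoid traits are fitted per (line, replicate) by non-linear least
squares to the logistic, the 4-parameter logistic

    f(t) = D + (A − D) / (1 + (t/C)^B)

(bottom/top asymptotes A, D; inflection C in days after sowing; hill
slope B) and the Gompertz curve a·e^(−b·e^(−ct)); the model with the
highest R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² wins. Daily water use is bimodal and
is instead described by a two-component Gaussian mixture fitted by EM on
time-axis samples weighted by daily volume, summarised by amplitudes λ,
modes μ, spreads σ and the separation S = (μ₂−μ₁)/(2σ₁+2σ₂).

With r replicates per line, one-way random-effects method of moments
splits each parameter's variance into genetic and environmental parts:
H² = s²_g/(s²_g+s²_e); covariances of parameter pairs come from the
variance of their sum, and correlations divide by √(s²(x)·s²(y)).

Scans group lines at each marker by genotype (or by founder origin when
the true mosaic is known) and test group means by one-way ANOVA; a QTL
is called when the peak −log10 p exceeds 4 **and** its permutation
empirical p (fraction of B phenotype shuffles whose genome-wide maximum
reaches the peak) is below 0.05. Support intervals use a 1.5-unit
−log10 p drop. See `docs/methods.md` for the full account.

## Worked example

Simulate a 208-line MAGIC panel with a QTL planted on the top asymptote
D of plant area, fit 4PL curves to every series, estimate heritability,
and scan the fitted D values:

```python
from magicqtl import (SimulationConfig, QTLEffect, simulate_founders,
                      simulate_magic_rils, simulate_trait_series,
                      GenotypeData, genome_scan, permutation_test,
                      call_qtls, fit_trait_parameters,
                      variance_components, heritability)

cfg = SimulationConfig(seed=42, n_lines=208, n_reps=2,
                       timepoints=tuple(range(90, 191, 4)))
panel = simulate_founders(cfg)
marker = panel.markers.loc[100, "marker"]          # a chr4D marker
cfg.qtl = (QTLEffect(marker, "Area", "D",
                     tuple(9000.0 * a for a in panel.founder_alleles[:, 100])),)
pop = simulate_magic_rils(panel, cfg)
series, truth = simulate_trait_series(pop, cfg, "Area")

params = fit_trait_parameters(series, "Area", models=("4pl",))
conv = params[params["converged"]]
wide = conv.pivot_table(index="line", columns="rep", values="D")
vc = variance_components(wide)
print(f"top asymptote D: H2 = {heritability(vc):.2f}")

gdata = GenotypeData.from_population(pop)
pheno = conv.groupby("line")["D"].mean().reindex(gdata.line_names)
scan = genome_scan(gdata, pheno, trait="Area", phenotype_name="D")
perm = permutation_test(gdata, pheno, B=1000, seed=42,
                        observed_max=scan.max_neg_log10_p)
for c in call_qtls(scan, perm):
    print(f"QTL at {c.marker} ({c.chrom}, {c.cM:.1f} cM): "
          f"-log10 p = {c.neg_log10_p:.2f}, empirical p = {c.empirical_p:.3f}, "
          f"marker h2 = {c.marker_h2:.2f}")
```

Output:

```
top asymptote D: H2 = 0.52
QTL at chr4D_m020 (chr4D, 61.5 cM): -log10 p = 54.32, empirical p = 0.000, marker h2 = 0.70
```

The planted marker is recovered exactly: the per-replicate QTL-plus-
environment structure on D yields a line heritability of 0.52, the scan
peaks at the planted chr4D marker far above the −log10 p > 4 cutoff,
none of 1000 permuted genomes reach it (empirical p < 0.001), and the
marker explains 70 % of the between-line variance in fitted D.

The same workflow is available from the shell via the `magicqtl` CLI
(`simulate`, `clean`, `fit`, `quantgen`, `scan`, `validate`, and `run`
for a YAML-configured end-to-end pipeline that writes cleaned tables,
parameter fits, heritability reports, scan tables, QTL calls and a run
manifest).

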