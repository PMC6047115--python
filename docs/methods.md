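# Methods

`magicqtl` implements functional QTL mapping for longitudinal
plant-phenomics data: instead of (or in addition to) mapping each imaging
day separately, per-plant growth curves are fitted and their parameters
are mapped as quantitative traits. This note records the models, the
numerical choices, and what the synthetic test bed does and does not
emulate.

## Growth models

Each (line, replicate, trait) time series y(t), with t in days after
sowing (DAS), is fitted by non-linear least squares to three sigmoid
families:

- logistic: f(t) = L / (1 + e^(−k(t−t0))) — upper asymptote L (trait
  units), rate k (day⁻¹), midpoint t0 (DAS);
- 4-parameter logistic (4PL): f(t) = D + (A−D) / (1 + (t/C)^B) — bottom
  and top asymptotes A, D (trait units), inflection C (DAS, > 0), hill
  slope B (dimensionless, either sign); defined for t > 0;
- Gompertz: f(t) = a·e^(−b·e^(−ct)) — asymptote a, displacement b > 0,
  rate c > 0 (day⁻¹).

Fitting uses SciPy's bounded trust-region reflective least squares.
Starting values are data-driven: A ≈ min y, D ≈ max y, C at the DAS
where the series first crosses half its range, and B from the width of
the central rise on a log-t axis (a logistic rises from its lower to its
upper quartile over ≈ 2.2 logits); analogous landmarks seed the other
models. Three starts are tried — the heuristic start plus two
multiplicatively jittered copies (20 % relative jitter, fixed RNG) — and
the lowest-RSS converged solution wins. Bounds are wide (±10 dynamic
ranges on asymptotes, |B| ≤ 200, C within ten map lengths) and exist to
keep the optimizer out of overflow regions, not to encode prior beliefs;
exponents are clipped at ±700 so every model evaluation is finite for
finite inputs.

Model selection compares the coefficient of determination
R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² of the converged fits; ties go to the model
with fewer parameters, then to a fixed name order, so selection is
deterministic. A constant series makes R² undefined; such fits are
flagged rather than raised. A polynomial baseline (degrees 2–4, ordinary
least squares) is provided for comparison experiments; polynomial
coefficients can be mapped like any other parameter, but they describe
curve shape rather than biology and are not part of the default
pipeline.

Note the symbol clash: B is the 4PL hill slope, while the permutation
count of the scan module is also conventionally called B. They never
appear in the same structure.

## Water-use mixture

Daily water use is bimodal — a vegetative mode (~130 DAS) and a
grain-filling mode (~180 DAS) — so a sigmoid is the wrong shape. The
daily curve (DAS, ml) is converted to weighted observations on the time
axis (each DAS weighted by that day's ml, negatives clipped to 0) and a
two-component Gaussian mixture is fitted by expectation–maximisation:
the E-step computes posterior class probabilities, the M-step re-fits
each component's (π, μ, σ) by weighted maximum likelihood, and iteration
stops when the log-likelihood improves by < 1e-8 or after 500 passes.
Initialisation splits the weighted sample at its weighted median and
takes component moments — deterministic given the input, so re-runs are
bit-identical. A component whose σ collapses below 1e-3 of the data
range is re-seeded once; a second collapse flags non-convergence.
Components are reported sorted by μ, with amplitude λ_k = π_k × total
volume (ml) and the mode separation S = (μ2−μ1)/(2σ1+2σ2).

A direct non-linear least-squares fit of the two-Gaussian sum
λ1·N(t;μ1,σ1) + λ2·N(t;μ2,σ2) to the daily amounts is available as an
alternative backend (`fit_watercurve(..., backend="nls")`); both report
amplitudes as areas, and on well-resolved curves they agree. The EM
backend is the default. Covariate-conditional mixture regression (class
densities depending on covariates) is deliberately not implemented:
only time-axis modes are ever mapped.

## Variance components, heritability, correlations

With r replicates per line, a one-way random-effects decomposition by
method of moments gives s²_e = within-line mean square and
s²_g = (between-line MS − within-line MS)/r, truncated at zero (and
flagged) when the raw estimate is negative. Unbalanced designs use the
replicate-weighted coefficient r0 = (N − Σn_i²/N)/(a−1). Broad-sense
heritability is H² = s²_g/(s²_g+s²_e). REML is a non-goal: the
method-of-moments estimators are exactly testable against their known
sampling distributions.

Covariances between two traits x, y come from the sum trait:
S_i(x,y) = (s²_i(x+y) − s²_i(x) − s²_i(y))/2 for i ∈ {g, e}; the
self-covariance identity S_i(x,x) = s²_i(x) then holds exactly (the
untruncated genetic variances are used inside this computation so the
identity survives negative raw estimates). Correlations divide by the
geometric mean √(s²_i(x)·s²_i(y)) — the standard definition; an
arithmetic-mean denominator (s²(x)+s²(y))/2 is selectable for
comparison, because the two differ whenever the traits have unequal
variances. Raw correlations outside [−1, 1] (possible with noisy
component estimates) are clamped.

## Cleaning rules

Two rules run before any fitting. (1) Timepoint completeness: a DAS is
kept only when every line on the roster has at least one observation at
it — days on which part of the population was not imaged carry no usable
contrast. The filter is idempotent. (2) Outliers: within each (line,
replicate, trait) series, a cubic OLS polynomial of value on DAS
provides Cook's distances, and points exceeding 4× the series' mean
distance are removed. The multiplier, the polynomial degree and the
maximum removed fraction (default 5 %, exceeded removals are flagged,
not blocked) are configurable, because "mean distance" thresholds and
reference regressions are conventions rather than uniquely determined
choices; the cubic-in-DAS reference was chosen over a growth-model
reference so that outlier screening never depends on the model being
screened for. An exact polynomial fit (residual scale below 1e-10 of
the data scale) is treated as having all-zero distances — without that
guard, floating-point noise in ~1e-12 residuals produces spuriously
structured distances.

## Genome scan

At each marker, lines are grouped by genotype class (the two homozygous
classes, plus a heterozygote class when it holds ≥ 3 lines, otherwise
those lines are excluded at that marker) and a one-way ANOVA tests for
mean differences; association strength is F and −log10 p, and the
marker's variance explained SSB/SST is reported as `marker_h2`. When the
ground-truth founder mosaic is available (simulated data) an
eight-class founder grouping reproduces the founder-effect-table view of
a multiparent analysis; ancestral-haplotype probability inference from
SNP data is out of scope. Replicates are collapsed to line means before
scanning.

Genome-wide significance comes from permutations: the per-line phenotype
vector is shuffled B times (default 1000), jointly across markers, and
the genome-wide maximum −log10 p of each shuffle forms the null; the
empirical p of an observed peak is the fraction of null maxima reaching
it. Maxing over markers controls family-wise error; per-marker
permutation p-values can be derived from the same machinery but the
max-based null drives calling. A QTL is called when the peak has
−log10 p > 4 and empirical p < α (default 0.05). Support intervals use
a drop method: the contiguous run of markers within 1.5 −log10 p units
of the peak, reported in bp; simulation puts the coverage of the true
locus at roughly the 90 % level for the planted-QTL conditions used in
the tests. One call is made per linked region — after a peak is called,
markers in its above-cutoff run or within 20 cM of the peak cannot seed
a second call on the same chromosome. No multiplicity adjustment is
applied across traits or timepoints beyond the per-scan permutation
threshold.

Per-timepoint scans repeat this at every retained DAS, producing
significance and marker-h² trajectories over time; per-parameter scans
treat each fitted curve or mixture parameter (A, B, C, D; μ1, λ1, σ1,
μ2, λ2, σ2, S) as a trait. A per-timepoint OLS regression of trait on
allele dosage gives marker-effect trajectories (slope, s.e., p per DAS).

## Synthetic MAGIC population

The simulator is first-class code, not a fixture: it defines the
conditions every recovery test runs under.

Genetics. Eight inbred founders are combined in a funnel (4 two-way → 2
four-way → 1 eight-way cross), followed by two additional intercross
generations between independent funnel products of the same line —
approximating three cycles of recombination, since the real crossing
design of the population that motivated this package is not public — and
then five selfing generations. Meiosis is Haldane: crossovers are a
Poisson process on the cM axis with no interference, which gives
closed-form expectations to test against. Haplotypes carry ancestral
copy labels internally, so residual heterozygosity is measured as the
fraction of loci whose two haplotypes descend from distinct ancestral
chromosomes — exactly (1/2)^s in expectation after s selfings, and the
simulator reproduces 3.125 % at s = 5 within Monte-Carlo error. Founder
marker alleles are drawn with the minor-allele count bounded between
configured fractions (default 2–4 of 8 founders), so every marker is
polymorphic. The default map is five chromosomes of 120–150 cM with 40
evenly spaced markers each — dense enough that a planted QTL is in tight
LD with a marker, sparse enough that scans are fast.

Phenotypes. QTL effects act on latent curve parameters, not directly on
observations — that is the generative model functional mapping assumes,
and it makes parameter recovery the natural acceptance surface. A line's
parameter value is baseline + per-founder QTL effects (averaged over its
two haplotypes) + an optional polygenic line deviation; each replicate
adds an environmental deviation (default s.d. 5 % of the baseline
magnitude per parameter), and each observation adds Gaussian noise
(defaults ≈ 2 % of each trait's dynamic range). Values are floored at 0,
since all four traits are physically non-negative. Baselines follow the
magnitudes of a winter-wheat smart-house experiment: plant area rising
to ≈ 85 000 mm² with inflection ≈ 130 DAS and hill slope ≈ 11, height to
≈ 700 mm, senescent area rising late (inflection ≈ 165 DAS), and daily
water use as a two-Gaussian curve with modes at 130 and 180 DAS and
≈ 11 L total. The default design is 208 lines × 2 replicates observed
every second day from 90 to 190 DAS.

What the simulator does not emulate: image-segmentation artefacts,
sequence-level variation, epistasis, genotype-by-environment structure,
heteroscedastic or autocorrelated observation noise, and real MAGIC
pedigree records. Passing recovery tests therefore demonstrates the
statistical machinery under its own generative assumptions; they do not
certify performance on real image-derived data, where model
misspecification (e.g., non-sigmoid growth, drift in imaging conditions)
is the dominant risk.

## Problem sizes and determinism

Test and acceptance runs use desk-scale versions of the study design:
208 lines × 2 replicates for scan calibration and power, 2000 lines for
the heterozygosity calibration, B = 200 permutations where the analysis
default is 1000, and 4–8-day phenotyping grids where the default is 2.
These sizes are the package's own choice of a configuration whose
Monte-Carlo error is small relative to the tolerances being checked.

All randomness flows from explicit integer seeds through NumPy
generators; the pipeline writes CSVs with fixed float formatting, so a
re-run under the same configuration and seed is byte-identical. Known
limitations: single-QTL-per-region calling (no multi-QTL models, no
kinship correction), method-of-moments variance components (no REML, no
standard errors on genetic correlations), and genotype-class grouping
rather than haplotype-probability regression for the scans.
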