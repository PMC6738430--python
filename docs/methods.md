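# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Study design and stratification

The pipeline analyzes LTL–methylation association separately within strata
defined by cohort × sex × ethnicity × batch, then combines evidence by
meta-analysis. Stratification handles sex, ethnicity and cohort
differences non-parametrically; regression handles age and cell
composition within a stratum. The bundled default design has 16 strata
over seven cohorts (5,713 samples; FHS, JHS, WHI, BHS, LBC1921, LBC1936,
LSADT analogs) with the published per-stratum sizes, age ranges, LTL
means/ranges and age–LTL correlations; FHS- and LSADT-like cohorts carry
family/twin structure. LTL units differ by cohort (kb for
Southern-blot-like cohorts, telomere/single-copy ratio for the qPCR-like
birth cohorts); since all association statistics are correlations computed
within a stratum, the unit never crosses a stratum boundary.

## Synthetic-data generator

Methylation: each CpG has a baseline mean drawn from a bimodal mixture
(rescaled Beta(3,8)/Beta(8,3)/Beta(2,2), mapped into [0.05, 0.95]), giving
the two-humped marginal distribution of array beta values. A random 25% of
probes are cell-type-discriminating: their reference profile gets an
independent N(0, 0.2) offset per cell type (clipped to [0.05, 0.95]).
Per-sample cell proportions are Dirichlet(10) draws; a sample's beta value
is the proportion-weighted convex mixture of the reference columns plus
N(0, 0.03) probe noise, clipped to [0, 1] (clipping affects well under 1%
of entries at these defaults and the fraction is recorded in the truth
record).

LTL within a stratum is assembled from: an age slope calibrated so the
population age–LTL correlation equals the stratum target (b_age = r·σ_LTL/σ_age);
a cell-composition effect (a fixed direction vector scaled to 1.5 LTL
units per unit proportion, ~10% of LTL variance), which also drives the
discriminating probes and therefore confounds methylation and LTL exactly
as blood composition does in real data; planted causal CpG effects;
a shared N(0, 0.25·σ²_LTL) intercept for twin pairs (`family_fraction` of
the stratum, pair members also share age); optional smoking offsets; and
residual noise scaled so the total variance matches the stratum's LTL
variance. Causal effects are expressed as LTL units per *standard
deviation* of methylation (default 0.05) and converted to per-beta-unit
coefficients by dividing by the model sd of the probe, so each causal CpG
contributes comparable signal; 88% of effects are negative by default,
matching the dominance of negative LTL–DNAm correlations in blood. Causal
CpGs are drawn from the non-discriminating probes so the causal pathway is
distinct from the cell-composition pathway — the full adjustment then
removes the confounded associations but keeps the planted ones, which is
the behavior the adjustment is meant to have.

Planted co-methylation blocks (for network tests) replace the mixture for
a set of probes with `0.12·(√ρ·f + √(1−ρ)·ε)` around a uniform baseline,
where f is either a latent N(0,1) factor or a standardized cell-type
proportion; ρ is the within-block correlation. The cell-type-driven
variant recreates the blood-cell-associated modules seen in real
co-methylation networks.

What the generator does **not** emulate: probe-type (I/II) chemistry,
array normalization artifacts, batch effects within a stratum, genomic
inter-CpG correlation structure (annotation positions are uniform per
chromosome), population stratification, and genotype-driven methylation
outside the SMR simulator. Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that the
pipeline is robust to raw-array artifacts.

The SMR simulator draws a biallelic genotype (MAF uniform in [0.1, 0.5]),
generates linear-scale methylation `m = b_zx·g + e` and trait
`y = b_xy·m + e′`, and reports per-SNP least-squares effects and standard
errors; `b_xy` comes from the truth record (zero for non-causal CpGs).

## Trait adjustment

Partial adjustment regresses LTL on age; full adjustment adds the
estimated cell proportions. Because the proportions sum to one, the design
includes all but one proportion column (the omitted one is redundant with
the intercept). In strata with family structure the model adds a
per-family random intercept fitted by REML (statsmodels MixedLM), and the
returned residuals are *conditional*: y − Xβ̂ − û_family. Whether the
original consortium analyses used conditional or marginal residuals is not
knowable from published descriptions; conditional residuals were chosen
because they actually remove family clustering from the trait, which is
the purpose of modeling it. A REML fit whose family variance collapses to
the boundary (or fails to converge) falls back to OLS with a logged note;
with zero true family variance the two coincide to numerical precision.
Constant covariates are dropped with a warning; genuinely collinear
designs raise an error naming the offending columns.

## EWAS

The biweight midcorrelation uses the standard Tukey-biweight construction
(median center, 9×MAD scale, weights zeroed at |u| ≥ 1). A vector with
MAD = 0 (possible for near-constant CpGs) falls back to mean-centering for
that vector, the convention of the reference network-analysis software.
p-values use the Student-t transform of r on n−2 df — the transform is not
pinned down by published descriptions, and the t convention keeps p
exactly calibrated for Gaussian nulls (verified at 20,000 null CpGs).
Z = sign(r)·Φ⁻¹(1 − p/2) is capped at |Z| = 40, beyond double-precision
tail resolution, so meta arithmetic stays finite. Missing beta values are
handled pairwise-complete per CpG (the published analyses are silent on
missingness). Betas are analyzed untransformed; a logit (M-value)
transform is available behind a flag. Probe filters (autosomes-only,
shared-platform, SNP-in-extension-base and multi-mapping exclusion lists)
are set intersections applied before any statistics, with removal counts
logged; the order of filtering relative to per-cohort QC is fixed here
(filters first) since the original ordering is unstated.

## Meta-analysis

The weighted-Z denominator is √(Σ wᵢ²) with wᵢ = √nᵢ — the only reading of
the printed formula under which Z_meta is standard normal under the null.
With these weights the combination is exactly associative: combining 16
strata directly equals combining the four group meta-Zs weighted by
√(group n). This identity is a regression test at 1e-12 and is also
exercised against the published top-30 CpG table: recombining the four
printed group Zs reproduces each printed global Z within 1.0 (the printed
inputs are rounded to one decimal; the largest deviation across the 30
rows is ≈0.9, which rounding alone does not fully explain — the original
p→Z path is unknown, so the pipeline fixes its own internally consistent
path and tests the identity on its own outputs). Undefined stratum
statistics are dropped per CpG, never imputed, with total n reduced
accordingly. Significance is the fixed threshold P < 1×10⁻⁷ (≈5%
family-wise error for 450K-scale studies); no FDR variant is provided.

## Positional and overlap enrichment

Subtelomeric = within the first or last 5% of the chromosome, with the
half-open convention pos < 0.05·L or pos ≥ 0.95·L (0-based); no boundary
rule is published, and this one partitions every position exactly once.
Chromosome lengths default to a bundled hg19 table and can be overridden
by file. This head/tail definition is a crude dichotomy — inter-CpG
correlation may differ near chromosome ends and bulk LTL is not
chromosome-specific — and results should be read with that caveat. The
proportion contrast is a Pearson 2×2 chi-squared without continuity
correction (flag to enable). The cis-mQTL overlap test is the exact
hypergeometric upper tail P(X ≥ k) (observed count included), with the
catalogue intersected with the analyzed-probe background; the default
background is the filtered probe set.

## SMR

Only the ratio b_GWAS/b_mQTL is published as the estimator; the test
statistic T = z²_G z²_m/(z²_G + z²_m) ~ χ²(1) and the delta-method SE
follow the method's source software. T ≤ min(z²_G, z²_m) algebraically, so
the SMR p-value can never beat either marginal test. Instruments with
|z_mQTL| < 3 are flagged weak (the criterion is unpublished and
configurable); b_mQTL = 0 leaves the ratio undefined. Allele
harmonization: direct match keeps the sign, swapped alleles flip the mQTL
sign, strand flips are resolved by complementing, anything else is dropped
and counted. The HEIDI heterogeneity test requires LD among multiple
instruments and is out of scope; the result schema reserves an empty
`heidi_p` column.

## Consensus co-methylation network

Per cohort: unsigned adjacency |bicor|^β with β = 6 (neither sign
convention nor power is published; unsigned with the customary default was
chosen and both are configurable), TOM with the standard shared-neighbor
formula, cohort TOMs rescaled multiplicatively so their 0.95 quantiles
match the first cohort, consensus = componentwise minimum (quantile 0).
Module detection is average-linkage clustering of 1−TOM with a *static*
cut at 99% of the dendrogram height range, a minimum module size of 30
(smaller clusters → "grey"), then iterative merging of the closest module
pair while eigengene dissimilarity (1 − Pearson r of eigengenes) is below
0.15. The static cut replaces the dynamic hybrid tree cut: only the merge
threshold (0.15) and the 30,000-CpG subsample are pinned by the published
analysis, and the static cut is dependency-free and easier to test.
Because the merge step needs methylation data that a TOM alone does not
carry, `detect_modules` accepts the beta matrix as an optional argument
and skips merging (with a warning) without it. Eigengenes are the first
principal component of the column-standardized module matrix,
sign-aligned to correlate positively with mean methylation. Module–trait
relationships reuse the EWAS bicor→Z transform per stratum and the
weighted-Stouffer combination across the six network strata (the
sex-stratified FHS/JHS/WHI sets — an assumption, since the composition of
the "six strata" is not spelled out).

## Problem sizes used in checks

The test suite and acceptance script run the full 16-stratum structure at
50–150 samples per stratum and 400–2,000 probes, 20,000 probes for type-I
calibration, 200 replicates × 5,000 samples for SMR consistency, and
400-probe three-cohort networks — sizes chosen so the whole suite
completes in well under a minute while keeping every statistical check
comfortably powered. The `table2` profile regenerates the full 5,713-sample
design when a full-scale synthetic run is wanted.

## Known limitations

- The generator's LTL variance decomposition (family vs residual) is a
  free parameter, not calibrated to any cohort.
- Cell identities are opaque labels; no bundled reference signatures are
  claimed to represent real leukocyte subtypes.
- No genomic-control/inflation correction, no surrogate-variable or batch
  adjustment beyond stratification, no effect-size (inverse-variance)
  meta-analysis, no reference-free deconvolution.
- Network results depend on the unpublished choices documented above
  (soft power, sign convention, tree cut); conclusions about module
  membership should be robustness-checked across those settings.
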