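# Methods

## Study design and scope

The package models a retrospective case-control design: two groups of
postmenopausal women sampled by BMI class (lean, BMI < 25 kg/m², n = 105;
obese, BMI > 30 kg/m², n = 124; intermediate BMIs not enrolled, boundary
values excluded by strict inequality), genotyped at six biallelic SNPs and
phenotyped for ten continuous traits (age, height, body mass, waist, hip,
FBM%, LBM%, BMR, SBP, DBP) plus derived BMI and WHR. Obese subjects are
the cases throughout; the major-allele homozygote (or major allele) is the
reference category.

## Hardy–Weinberg test

Minor allele frequency q is estimated per SNP per group as
(2·hom_minor + het)/(2n) over non-missing calls; expected genotype counts
are n·((1−q)², 2q(1−q), q²); the statistic Σ(obs−exp)²/exp is referred to
χ² with **1 degree of freedom** (3 cells − 1 − 1 estimated parameter). No
continuity correction and no exact test: the χ² formulation is the method
this pipeline standardises on. The degenerate case of a zero expected cell
with a nonzero observed cell is reported as χ² = +∞ with a flag rather
than an exception (it cannot arise when q is estimated from the same
counts). Default α = 0.05, configurable.

## Case-control association

For each non-reference genotype (het, minor-hom) and for the minor allele,
a 2×2 table (a = cases with index category, b = controls with index, c =
cases with reference, d = controls with reference) yields:

- **OR** = (a·d)/(b·c), computed in exact rational arithmetic before float
  conversion, so OR(index↔reference swap) is an exact reciprocal. A zero
  in b or c makes the OR undefined unless the optional Haldane–Anscombe
  +0.5 correction is enabled (off by default; flagged in output).
- **Woolf 95% CI**: exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), defined only
  when all cells are positive. z = 1.96 is used at the 0.95 level (the
  conventional rounding); other levels use the exact normal quantile.
- **p-value**: uncorrected Pearson χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
  on 1 df. No Yates correction — with the published rs1903003 CC-vs-TT
  counts the uncorrected statistic gives p = 0.0009 while the corrected
  one gives ≈ 0.0017, so only the uncorrected form matches the published
  table. Fisher's exact two-sided test (sum of hypergeometric
  probabilities of same-margin tables no more probable than observed)
  replaces the χ² whenever any expected cell is below a threshold
  (default 5, configurable).

A reproduction note: the published table's p-values for its three
smallest-count cells equal the uncorrected Pearson χ² p (0.2801, 0.1590,
0.8912), i.e. the source analysis used χ² even where this package's
default would switch to Fisher. Setting `fisher_threshold=0` reproduces
every printed p-value; the default keeps the expected-count rule because
it is the standard practice the pipeline documents. A handful of printed
CI digits also differ from the exact Woolf values by 1–3 units in the last
printed place (worst on cells containing a count of 1); this package
reports the exact formula values and does not chase those digits. Rendered
tables show percentages to 1 decimal and ORs/CI bounds to 4 significant
figures.

## Phenotype comparisons

Two-sample comparisons use the two-sided Mann–Whitney U from midranks
(U₁ + U₂ = n₁n₂). The p-value is exact by enumeration when both samples
have ≤ 8 observations and the pooled values are untied; otherwise the
normal approximation with tie-corrected variance
n₁n₂/12·((n+1) − Σ(t³−t)/(n(n−1))) is used, without continuity
correction (the exact method refuses tied data and falls back to the
approximation). Identical samples give p = 1 by convention when the
variance vanishes.

Co-existence analysis partitions subjects by their joint genotype at two
loci; samples missing at either locus join no stratum, so strata are
disjoint and cover the complete cases. Strata are summarised as mean ± SD
(SD only when n ≥ 2); strata with fewer than 5 subjects are reported but
flagged and excluded from testing — 5 is the minimum category frequency
the design admits to testing. The fat-distribution table crosses BMI class
× FAM13A genotype × PPAR-γ2 C1431 genotype, comparing WHR between the
C1431T (het) and C1431C (major-hom) rows of each cell and rendering "ns"
at p ≥ 0.05 and "−" for empty cells. Carrier rows are single genotypes as
printed (het vs major-hom vs minor-hom); no dominant-model collapsing.

## Combined-Z omnibus test

Each (SNP, phenotype) label contributes a signed Z: the tie-corrected
normal transform of the Mann–Whitney statistic comparing the phenotype
between obese and lean subjects **among carriers of that SNP's minor
allele** (≥ 5 subjects required per side; undersized comparisons are
excluded with a logged reason). Positive Z means the trait runs higher in
the obese carriers; swapping group labels negates Z. Restricting to
carriers is what makes the Z depend on the SNP and induces the cross-label
correlation the omnibus test must account for: labels share subjects and
traits. The default grouping is joint (all SNPs × all phenotypes in one
vector); per-SNP or per-phenotype subsets are a caller-side selection of
labels.

Under the global null the vector is treated as MVN(0, Σ) with Σ estimated
empirically. Default estimator: **bootstrap** — subjects resampled with
replacement within each group, the full Z vector recomputed per resample
(B = 1000 default, seeded; degenerate resamples redrawn and counted), and
the sample covariance across resamples used. A cheaper, non-default
plug-in estimator computes the correlation of per-subject centred,
group-signed midrank score contributions. Two combining rules:

- **sum** (O'Brien-type, default): T = (1ᵀz)/√(1ᵀΣ1), two-sided normal p.
  Most powerful when effects share a direction.
- **quadratic** (Wald-type): Q = zᵀΣ⁻¹z, χ² p with df = rank(Σ)
  (pseudo-inverse and a flag when Σ is rank-deficient).

With k = 1 both reduce exactly to the univariate two-sided p. A covariance
failing symmetry or positive semi-definiteness (beyond 1e−8 relative
tolerance) is rejected with a hint to increase B. Holm–Bonferroni
step-down adjustment is applied to the family of all per-label tests in a
run.

## Synthetic cohorts

The generator emulates the study conditions and nothing more:

- **Genotypes**: per SNP, drawn from HWE proportions at a group-specific
  minor allele frequency (retrospective parameterisation — one frequency
  per group rather than a population + disease model, matching how the
  case-control table is analysed). Defaults are the frequencies implied by
  the published genotype counts (e.g. rs1903003 C: 0.595 lean / 0.440
  obese; panel MAFs are high, most > 0.4, per the study's selection rule).
  SNPs are simulated **independently — no linkage disequilibrium**, which
  the study does not report; co-existence structure beyond independence is
  therefore not emulated.
- **Phenotypes**: independent Gaussians per trait per group, means and SDs
  defaulting to the published group summaries (e.g. lean body mass
  62.10 ± 6.91 kg, obese 87.27 ± 11.91 kg). Percentages are truncated to
  [0, 100] and all raw traits at 0 after effects are applied. BMI and WHR
  are derived from the simulated raw traits, so a sample's derived BMI can
  occasionally cross its group's nominal boundary; the recorded group is
  the sampling group. Cross-trait correlation (e.g. FBM% + LBM% ≈ 100, or
  mass–waist correlation) is **not** modelled: only marginal structure.
  Age is an ordinary trait; the near-identical group means in the defaults
  reproduce the study's (apparently incidental) age matching.
- **Joint effects**: an additive shift on one raw trait for samples
  carrying a stated genotype at each of two SNPs, applied before
  truncation and derivation; membership is recorded in the output for
  cross-checks. Effects on BMI/WHR are injected through their raw
  components (body mass or waist).
- **Reproducibility**: one `numpy.random.default_rng(seed)` per
  `simulate_cohort` call; the seed is recorded in the returned tuple and
  in the phenotype table metadata.

Consequently, passing tests on synthetic data demonstrate the correctness
and calibration of the statistical machinery under the stated marginal
structure — not robustness to LD, trait correlation, non-normality or
missingness patterns of real cohorts.

## Numerical and design choices

- Heterozygotes are canonicalised major-allele-first on read, so `CT` and
  `TC` are one genotype; unknown alleles and duplicate sample ids are
  parse errors naming the offending row/column.
- Missing genotypes: complete-case per SNP (dropped from that SNP's counts
  only).
- Classification boundaries are strict: BMI 25 and 30 → excluded;
  WHR 0.85 → non-visceral; hypertension is SBP ≥ 140 and/or DBP ≥ 90.
- Degenerate inputs return flagged results, not exceptions: zero-margin χ²
  (p = 1), zero-cell OR (undefined unless corrected), all-tied Mann–Whitney
  (z = 0, p = 1), fewer than two testable strata (empty comparison list).
- The pipeline writes each stage's output before the next starts, stamps a
  manifest with a config hash, seed, version and per-stage row counts, and
  skips recomputation when re-run with an identical config; failures leave
  a FAILED marker naming the stage.

## Problem sizes in the test and acceptance suites

Calibration checks use 1000 replicates (HWE at n = 200, q = 0.4;
Mann–Whitney at n = 50/50; omnibus at k = 6, AR(1) ρ = 0.5); the Fisher
oracle sweep enumerates all 135,750 tables with total ≤ 40; parameter
recovery uses 50,000 subjects per group (analytic OR) and 20,000 total
(injected shift); the end-to-end cohort-level omnibus calibration uses 120
replicates with a 99.9% binomial acceptance band. These sizes are the
package's own choices balancing statistical resolution against runtime.

## Known limitations

- No LD, no haplotypes, no multi-allelic sites, no X-chromosome handling,
  no imputation, no covariate adjustment or logistic regression, no trend
  tests, no Kruskal–Wallis across > 2 strata.
- The omnibus covariance interpretation (bootstrap over subjects) is one
  reasonable reading of an under-specified procedure; the grouping of Z's
  (joint by default) is likewise a documented choice, and no claim is made
  that either matches the original analysis exactly — no published omnibus
  statistic exists to anchor it.
- The bundled study genotype matrix reproduces per-SNP, per-group marginal
  counts only; its joint genotype structure is synthetic, so it supports
  single-SNP analyses but not reproduction of the published co-existence
  tables (subject-level data are unpublished).
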