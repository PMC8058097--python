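# Methods

## Scope and data model

`oncoage` quantifies how tumour genomic features vary with patient age
across cancer-type cohorts.  Inputs are per-tumour tables in the shapes
produced by the standard callers: allele-specific copy-number segments
(1-based inclusive coordinates, integer major/minor copies, as in ASCAT
output), GISTIC-style broad (per-arm log2) and focal (per-lesion log2)
event tables, MAF variant tables, clinical covariates, gene×sample RSEM
expression and probe×sample methylation β matrices.  The package never
calls variants or copy number itself; it consumes caller output and is
assumed to receive purity-corrected integer copy states.

All file coordinates are 1-based inclusive; every internal length is
`end − start + 1`.  Overlap tests convert to half-open intervals first,
so a region that merely touches a window boundary does not overlap it.

## Instability metrics

For one tumour with autosomal segments of length L_i and state
(n_major_i, n_minor_i):

- **Ploidy** ψ = Σ L_i (n_major_i + n_minor_i) / Σ L_i.
- **GI score** = 100 × (length with state ≠ ground) / (measured length),
  ground = (1,1) without WGD and (2,2) with WGD.
- **Percent LOH** = 100 × (length with n_minor = 0 and n_major ≥ 1) /
  (measured length).  "Exactly one parental allele" excludes total
  deletions (0,0), which retain no allele.
- **WGD call**: ψ > τ₀ − τ₁ · LOH-fraction, defaults τ₀ = 2.9,
  τ₁ = 2.0.  Upstream WGD annotations, where supplied, take precedence;
  the boundary is a documented convention, exposed in configuration,
  because public segment releases carry WGD calls without publishing
  the exact rule.

Design choices: sex chromosomes are excluded from every denominator
(stated for LOH in the source analysis; applied uniformly here for
internal consistency, configurable); denominators use measured segment
length rather than nominal genome length, so unprofiled gaps are
neutral.  These metrics are exactly invariant under splitting any
segment into adjacent pieces with the same state.

## SCNA scores

Log2 ratios are binned into class scores {−2,−1,0,1,2} with half-open
bands at −1, −0.25, 0.25 and 1 (boundary values fall upward: 1 → 2,
0.25 → 1, −0.25 → 0, −1 → −1).  A broad event is chromosome-level iff
both arms carry the same log2 value; "same" means |Δ| ≤ 1e−9
(configurable) — the tolerance exists only to absorb float formatting,
not to merge genuinely different values.  Acrocentric chromosomes have
a single arm row and are always scored arm-level.  Per-tumour raw
scores (Σ|class| per level) are rank-normalised within each cancer
type as (average rank)/N; average ranks keep the cohort mean at
(N+1)/(2N) under ties, and samples with no events enter the ranking
with raw score 0 so they anchor the low ranks.  Focal regions
overlapping a centromere or a telomere window (default 10 kb per
chromosome end; GISTIC output does not define one) are removed before
association testing.

## Mutation metrics

Non-silent variants are the nine MAF classes Frame_Shift_Del/Ins,
In_Frame_Del/Ins, Missense_Mutation, Nonsense_Mutation,
Nonstop_Mutation, Splice_Site, Translation_Start_Site.  Burden is the
per-exome non-silent count; the reported log burden is log10(burden+1)
(the transform base and offset are conventions of this package, chosen
so zero-burden samples remain representable, and are declared in output
metadata).  Hypermutation is strictly burden > 1000; gene-level
analyses retain tumours with burden strictly < 1000 and not MSI-H —
samples at exactly 1000 are neither hypermutated nor retained, a
deliberate reading of the two strict inequalities.  Substitution
spectra collapse purine-reference SNVs onto the six
pyrimidine-reference classes; indels and multi-base records are
skipped with a warning.  Gene×sample matrices binarise carriage and
keep genes mutated in strictly more than 5% of cohort samples.  Age
groups split at young = age ≤ 50; group proportions are compared with
the two-sided Fisher exact test.

## Association engine

The cascade is deliberately two-stage.  Stage 1 fits the simple
age-only model per cohort (OLS for continuous outcomes, logistic for
binary) and applies Benjamini–Hochberg across cohorts — the BH family
is "all cohorts of one analysis", recorded in every output row.
Cohorts passing adj. p < 0.05 get the stage-2 multiple model with the
selected covariates plus tumour purity; stage-2 p values are
BH-corrected across the stage-2 family.

Covariate handling: candidates missing in ≥ 10% of the cohort are
dropped, as are constants; categorical covariates are dummy-coded with
the most frequent level as reference, levels under five samples pooled
into "other" (to avoid near-singular designs); fits are complete-case
and the n used is reported.  Rank-deficient designs raise an error
naming the aliased columns; during stage 2 the offending covariate is
dropped with a warning and the model refit.

**Separation and the Firth fallback.**  Maximum-likelihood logistic
estimates diverge under (quasi-)complete separation.  A detector runs
plain Newton-Raphson on a standardized design and flags divergence when
the coefficient norm escapes a bound (15) or the log-likelihood
plateaus while the norm grows.  Flagged fits are refit by maximizing
the Jeffreys-penalized likelihood l(β) + ½ log|I(β)| with
Newton-Raphson on the hat-adjusted score
Σ[yᵢ − pᵢ + hᵢ(½ − pᵢ)]xᵢ, step-halving on the penalized likelihood,
convergence at ‖score‖ < 1e−8 within 50 iterations.  For a 2×2 table
this reproduces the add-½-to-each-cell estimate exactly, and
intercept-only fits give log((k+½)/(n−k+½)).  Confidence intervals are
Wald intervals on the penalized fit for uniformity with the ML route;
penalized-profile-likelihood intervals (the default of the classical
implementation) are a known deviation and an extension point.

Binary effect sizes are reported as odds ratio per year, exp(β_age),
with 95% Wald CIs.  Pan-cancer models always adjust for gender, race
and cancer type and are treated as single tests.

**Rank-based group tests.**  Kruskal–Wallis uses the tie-corrected H;
the p value comes from the χ² approximation except for tiny inputs
(total n ≤ 10), where the exact permutation distribution of H is
enumerated — at these sizes the χ² approximation is badly biased, so
the exact mode is part of the operation, not an option.  Dunn's
post-hoc z uses pooled ranks with tie correction
(σ² = N(N+1)/12 − ΣT/(12(N−1))), two-sided normal p, Bonferroni
multiplied over pairs.  Two-group calls also report the two-sided
Wilcoxon rank-sum p.

BH adjustment itself is delegated to `statsmodels.stats.multitest`
(checked in the test suite against a literal step-up implementation).

## Expression / methylation track

Expression is filtered to genes with RSEM > 0 in strictly more than
50% of samples and transformed log2(x+1) throughout — the +1 offset is
applied uniformly so the regression and correlation analyses share one
scale.  β values are regressed untransformed (no M-value transform).
Probe→gene mapping recomputes, per gene, the probe most negatively
Pearson-correlated with that gene's log2 expression over shared
samples; exact ties break to the lexicographically smallest probe ID so
the mapping is order-invariant.  Per-feature age regressions are OLS
with the selected covariates (plus an optional platform covariate),
complete-case per feature; zero-variance features are skipped and
excluded from the BH family, which is "all retained features of one
matrix in one cohort".  Features at adj. p < 0.05 are age-DEGs /
age-DMGs, direction = sign of the age coefficient.

Overlap genes (flagged in both layers) are classified into the four
sign quadrants; the headline percentage counts the opposite-direction
quadrants (meth↑expr↓ plus meth↓expr↑).  The gene universe for
grouping and coefficient concordance is the union of genes tested in
either layer for the partition and their intersection for
correlations; per-gene methylation–expression Pearson r uses
complete cases per gene, with at least 3 shared samples required for
any correlation.  Ranked lists for external enrichment tools sort by
age coefficient descending, ties broken by feature ID.

## Synthetic cohorts

The generator plants every effect the analysis is meant to detect, at
configurable strength, with all randomness drawn from one PCG64
generator per layer so identical parameters and seed give bit-identical
cohorts.

- **Clinical**: integer ages uniform on 30–85, categorical covariates
  from fixed multinomials with realistic missingness (5–8%), purity ~
  Beta(5,2).
- **Segments**: WGD ~ Bernoulli(logit⁻¹(α + 0.03·age)); the non-ground
  genome fraction is f = clip(0.05 + 0.003·age + ε), ε ~ N(0, 0.05),
  and a sub-share clip(0.25 + 0.002·age + ε′) of it is LOH.  The
  planted fractions are quantised to whole bases with a
  largest-remainder allocation across chromosomes, so the realized
  fraction (returned as truth) is recovered *exactly* by the GI score.
- **Mutations**: non-hypermutator burden ~ Poisson(exp(4.5 +
  0.01·age)); C>T share of SNVs rises as 0.10 + 0.004·age; half the
  SNVs are emitted in purine-strand representation to exercise the
  collapse; driver carriage is Bernoulli with a per-year odds ratio;
  hypermutators occur at rate 0.34 (age ≤ 50) / 0.11 (> 50) in the
  endometrial-like scenario, are forced above 1000 mutations and carry
  an MSI-H or POLE flag; ~10% extra Silent rows exercise the filter.
- **Expression/methylation**: planted age genes follow β = clip₀₁(μ +
  0.003·age + ε) and log2 expr = ν − 4β + δ; other genes are noise.
  Each gene carries 1–3 probes, exactly one with signal.
- **GISTIC-like events**: designated arms gain with per-year odds ratio
  1.03; other arms alter at a constant background rate; whole
  chromosomes alter both arms identically at rate 0.25; focal lesions
  sit mid-arm, clear of centromere/telomere windows.

Scenario presets (`null`, `endometrial-like`, `glioma-like`) ship as
YAML.  The default effect sizes are kept small enough that the clip₀₁
boundary bias is negligible, which is what makes the CI-coverage
recovery tests valid.

What the simulator does **not** emulate: realistic breakpoint
processes, mutational-signature composition, subclonality, linkage
between layers beyond the planted couplings, batch structure, or
cohort-specific covariate distributions.  Passing recovery tests
therefore demonstrate estimator correctness under the assumed
generative model, not robustness to the messiness of real tumour data.

## Numerical conventions and problem sizes

- Probability clipping at 1e−12 in logistic likelihoods; tiny ridge
  (1e−10) in the separation detector's information matrix only.
- Exact-tie tolerance for "most negative probe": strict improvement by
  more than 1e−15 is required to displace an earlier (lexicographically
  smaller) probe.
- Packaged arm models: hg19 lengths and centromere intervals from the
  UCSC gap track, with acrocentric short arms (13–15, 21, 22) folded
  into the centromere interval so their p extent is empty; a
  three-chromosome toy genome (two metacentric, one acrocentric) is
  used by the test-bed and simulator defaults.
- Calibration and recovery suites run at the sizes stated in their
  tests: 1000 null screening experiments of 10 cohorts × 200 samples;
  100 replicates per recovery at n = 500–800 samples; 100 replicates of
  the expression/methylation pipeline at 120–300 genes.  These sizes
  were chosen to keep Monte-Carlo error well inside the asserted
  bounds.

## Known limitations

- The WGD boundary is a stand-in convention; tumours near the boundary
  may be misclassified relative to any specific caller's annotation.
- Wald intervals undercover slightly for penalized fits near
  separation; profile-likelihood intervals would be preferable there.
- The GI/LOH denominators treat male X hemizygosity by exclusion; no
  sex-specific handling is attempted.
- Stage-1 screens are age-only by design; confounding that masks a
  marginal association will drop a cohort before adjustment.
- Complete-case analysis can bias stage-2 estimates when missingness
  is informative; no imputation is provided.
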