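# Methods

`drugmwas` implements a multi-cohort metagenome-wide association analysis of
drug exposures: per-cohort multivariable linear models on transformed
microbial features, combined by inverse-variance fixed-effect meta-analysis
with a heterogeneity gate, surrounded by the standard community-ecology,
resistome and post-hoc analyses, and driven (in tests and examples) by a
synthetic multi-cohort generator with a machine-readable truth table.

## Inputs and screening

Three profile dialects are read as feature-major TSV: MetaPhlAn-style
taxonomic tables (pipe-delimited lineages, values in percent), HUMAnN-style
pathway tables (reads-per-kilobase, optionally with `pathway|species`
stratified rows), and ShortBRED-style antibiotic-resistance (AR) marker
tables with a marker→gene (ARO) map. Metadata carries cohort, age (years),
sex, BMI (kg/m²), sequencing depth (reads), disease labels (IBS yes/no;
CD/UC/IBDU), binary drug-category exposures, and dose (mg/day) / subtype
annotations where known.

Before any analysis, samples are excluded if flagged for stoma, pouch or
short-bowel anatomy, or if sequencing depth is below 10 million reads
(`min_depth`, configurable). Exclusion is idempotent and reported per sample.
Missing age/BMI excludes a sample from model fitting only (with a logged
warning), not from diversity summaries: excluding at point of use avoids
silently shrinking unrelated analyses.

## Taxonomic end-points and transforms

The taxonomic analysis unit is the *end-point*: the lowest observed,
non-redundant clade per lineage branch. "Redundant" is operationalised
purely from the labels — a clade is dropped iff a descendant clade is
observed — so no reference tree is needed. Internal clades whose abundance
exceeds the sum of their observed children (unclassified residual mass) are
reported but never promoted to pseudo-features.

Percent-scale taxa are converted once to proportions (0–1). End-points are
then filtered per cohort and the criteria conjoined: a taxon is kept iff in
*every* cohort it is present in strictly more than 10% of samples
(`taxa_prevalence = 0.10`; ties at exactly 10% fail) and its mean proportion
is at least 1e-4 (`taxa_mean_abundance`, i.e. 0.01%). Survivors receive the
variance-stabilising arcsine-square-root transform, arcsin(√p) ∈ [0, π/2].

Pathways are converted to within-sample relative abundance, filtered on
prevalence (> 10% in every cohort), and natural-log transformed with zeros
kept exactly at zero. Log10 and a pseudocount alternative exist but are off
by default; "keep the zeros" is the literal default because zero pathway
abundance is a structural, not a sampling, zero in these profiles.

## Community ecology

Shannon diversity H = −Σ p log p (nats) is computed on end-point
compositions; Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) feeds PERMANOVA.
PERMANOVA uses the Gower-centred inner-product decomposition of the distance
matrix against a one-term design — either a categorical grouping
(dummy-coded) or a single numeric regressor, which is how the number of
drugs per participant is tested. The permutation p-value is
(1 + #{F′ ≥ F}) / (1 + n_perm), so it is never zero; with n small enough
that n! ≤ n_perm the permutation distribution is enumerated exhaustively
instead. Permutation comparisons are made on the model sum of squares
(monotone in F because the total SS is permutation-invariant), which is
robust when the residual SS collapses to floating-point noise under perfect
separation. Default `n_permutations = 10000`.

Richness/drug tests use the unpaired two-sample rank-sum (Mann–Whitney)
test, two-sided: exact enumeration when both groups have ≤ 50 observations
and no ties, normal approximation with tie correction otherwise. (The
two-sample setting has no pairing, so a signed-rank test is not applicable;
this matches the default behaviour of the two-sample `wilcox.test`.)

## Association models

For each cohort and each drug with at least `min_users = 5` users there, an
OLS model with intercept relates each transformed feature to the exposure
indicator, adjusting for age, sex (female = 1), BMI, sequencing depth and
disease. Disease enters as an IBS yes/no dummy in the population and IBS
cohorts, and as UC/IBDU dummies (CD reference) in the IBD cohort.
Sequencing depth is scaled to millions of reads purely for numerical
conditioning. Two modes:

* **single** — one model per drug (feature ~ drug + covariates);
* **multi** — one model per cohort containing *all* eligible drug
  indicators; each drug's coefficient comes from that joint fit. This is
  the polypharmacy adjustment: a null drug correlated with a causal one is
  inflated in single mode and recalibrated in multi mode.

All features sharing a design are solved in one vectorised least-squares
call; SE comes from σ̂²(XᵀX)⁻¹ with df = n − rank(X), t = β/SE, and p from
the t distribution. Rank-deficient designs trigger a drop-and-flag policy:
the collinear drug covariate with fewest users is removed and the fit
flagged. Constant features are flagged degenerate and never meta-combined.
Drugs eligible in only one cohort (e.g. IBD-only therapies) are fitted there
but marked non-meta-eligible; within their own cohort they still serve as
covariates in multi mode, because they are real exposures there.

## Meta-analysis and the significance gate

Per-cohort (β, SE) pairs are combined with weights wᵢ = 1/SEᵢ²:
β_meta = Σwβ/Σw, SE_meta = (Σw)^(−1/2), z = β_meta/SE_meta,
p = 2Φ(−|z|) — a fixed-effect combination; cross-cohort inconsistency is
handled by the gate rather than by random-effects τ² estimation.
Benjamini–Hochberg adjustment runs within a declared family: taxa and
pathways are adjusted separately, and within a kind each model mode forms
one family (configurable). Associations with FDR < 0.1 are tested for
heterogeneity with Cochran's Q = Σwᵢ(βᵢ − β_meta)², referred to χ²(k−1).
Final status: **significant** iff FDR < 0.05 and heterogeneity p > 0.05;
FDR < 0.05 with heterogeneity p ≤ 0.05 is **heterogeneous**; fewer than two
usable cohorts is **not-combined** (cohort statistics passed through).

## Resistome

Marker quantifications are aggregated to ARO gene level as the arithmetic
mean over each gene's markers. Genes detected in fewer than 10% of all
analysed participants (pooled across cohorts — the rule is about
participants, not cohorts) are excluded. The per-sample AR burden defaults
to gene *richness* (count of detected genes); summed abundance is a
configurable alternative, since "total count of AR genes" admits both
readings. Drug users are contrasted against participants using *no drug at
all* (not merely non-users of the tested drug) per cohort with the rank-sum
test, BH per cohort; a relaxed FDR < 0.25 report is emitted alongside.

## Post-hoc follow-ups

Post-hoc contrasts run by default only on meta-significant associations (a
flag opens them to all features). Species-stratified pathway contributions
are normalised to within-sample relative abundance over the stratified
table, log-transformed with zeros kept, and rank-tested users vs non-users
with BH over contributors. Dose contrasts dichotomise users at a per-drug
threshold with high = dose ≥ threshold (40 mg/day for PPIs, 1000 mg/day for
metformin). Subtype contrasts require ≥ 5 subtype users and compare them to
participants free of the whole parent category. Dose/subtype tests run per
cohort with a pooled option. Spearman correlations use tie-corrected ranks
with an exact permutation p for n ≤ 10 and the t approximation above.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes —
three cohorts of unequal size, cohort-specific disease labelling, binary
drug exposures, compositional zero-inflated taxa, pathways as species
mixtures, AR genes tracking a driver species — with every random draw under
one seeded stream (sub-streams per cohort derived deterministically, so the
same seed reproduces the data byte for byte).

* **Drugs.** Exposures are thresholded latent Gaussians; correlated pairs
  use a bivariate copula whose latent correlation is solved numerically
  (Brent's method on the bivariate normal CDF) to hit the target rank
  correlation of the binary indicators, with an explicit Fréchet-bound
  feasibility check. Doses come from each drug's discrete set, subtypes
  from a multinomial.
* **Taxa.** Per-species zero-inflated log-normal intensities closed to
  compositions; lineage labels come from a deterministic template whose
  internal clades are exact sums of their children, so end-point extraction
  removes precisely the internal rows and kingdom totals close to 100.
* **Effects.** Configured on the *transformed* scale in units of the
  feature's transformed-scale SD. For a user of the drug, the target
  taxon's arcsine value is shifted by exactly δ and the remaining taxa are
  rescaled to preserve closure — so the association model's estimand equals
  the configured effect, making parameter recovery a sharp test. Pathway
  effects multiply the user's contributor rows by exp(δ) on the raw scale.
* **Pathways.** Community totals are the sum of the per-species stratified
  rows plus an unclassified noise remainder — an identity that holds to
  machine precision by construction.
* **AR genes.** A coupled gene's log value is the driver species' log
  abundance plus Gaussian noise sized (via the Spearman→Pearson relation
  ρ = 2 sin(πρ_s/6)) to hit the target rank correlation.
* **Covariates.** Age ~ N(45, 14), BMI ~ N(25, 4.5), sex ~ Bernoulli(0.6
  female), depth ~ LogNormal(median 2.2e7, σ = 0.35) — so roughly 1% of
  samples fall under the 10-million-read exclusion and exercise that path.

Presets: `null` (no effects — every downstream hit is a false positive;
cohort sizes 600/250/150, 500 taxa, 5 drugs), `effects` (twenty ±0.5-SD
taxon effects across five drug categories, plus one stronger 1.0-SD PPI
effect on the AR-driver species modelling the hallmark enrichment of oral
streptococci under acid suppression, which propagates into the resistome),
`confounded` (a causal drug plus a correlated null drug, rank correlation
0.7, for the deconfounding check), and `reference` (the published analysed
cohort sizes 1124/454/305, published per-cohort drug prevalences, and the
strongly correlated inhaler pair at 0.78).

What the generator does *not* emulate: taxon–taxon covariance networks,
strain-level structure, batch effects, realistic dysbiosis signatures, or
disease–drug confounding beyond what the covariate scheme induces. Passing
tests therefore demonstrate statistical correctness and calibration of the
machinery under the assumed data-generating process, not biological
validity on real cohorts.

## Numerical choices and degenerate inputs

* BH via the standard step-up (statsmodels), verified against a literal
  brute-force implementation of the definition.
* OLS solved by LAPACK least squares; verified against an independent
  normal-equations solver (and statsmodels) to 1e-8 on random designs.
* Permutation p-values always include the observed statistic; ties count as
  at-least-as-extreme with a 1e-10 relative tolerance.
* All-zero abundance vectors, constant groupings, constant features and
  empty user groups raise or are flagged-and-skipped with a logged reason —
  never silently dropped.
* Injected-effect arcsine shifts are clipped to [0, π/2]; effect targets in
  the presets sit in the prevalent-species block so the default filters keep
  them (the truth table marks any filtered-out effect unevaluable).

## Problem sizes used by the test and acceptance runs

The shipped acceptance computation uses the study-condition sizes
(600/250/150; 500 taxa and 5 drugs for the null calibration over 20
generator seeds) and estimates the effect-recovery rate over three
generator replicates (60 injected pairs) because a single 20-pair draw has
a binomial standard error of ~7 percentage points. The deconfounding
contrast uses 200 simulations at n = 250, and generator calibration uses
50 drug-matrix draws at the published population-cohort size (1124). Unit
tests use smaller fixtures of the same structure.

## Known limitations

* Fixed-effect meta-analysis only; no random-effects or leave-one-cohort-out
  sensitivity.
* Single-term PERMANOVA; no covariate-adjusted (marginal) partitioning,
  strata or ordinations.
* The FDR family definition (kind × mode) is a declared choice; pooling
  modes or including single-cohort drugs would change the adjusted values.
* Dose information is used only through dichotomisation at the per-drug
  threshold; no dose-response modelling.
* The exact Spearman p enumerates permutations and is practical only for
  n ≤ 10, as implemented.
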