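# Methods

`microperm` reimplements, as a tested pipeline over synthetic cohorts, a
longitudinal analysis linking infant gut microbiota composition (and
predicted metabolic-pathway abundances) to two stool markers: zonulin, a
proxy for small-intestinal paracellular permeability, and calprotectin, a
marker of intestinal inflammation. The cohort design it targets is 21
infants sampled at up to five scheduled visits — 7 days (P2), 1 month (P3),
6 months (P4), 12 months (P5) and 24 months (P6) — with visit-level
missingness.

## Compositional core

Sequencing counts are compositional and noisy. Two devices deal with this:

**Rarefaction.** Counts are subsampled without replacement (multivariate
hypergeometric) to a common depth, by default the smallest per-sample total
at or above a floor of 1000 reads; samples below the depth are dropped and
reported. Alpha diversity is the per-sample *median over ten rarefaction
cycles* of Shannon H = −Σ p ln p, Gini–Simpson 1 − Σ p², bias-corrected
Chao1 S_obs + F1(F1−1)/(2(F2+1)) and Pielou evenness H/ln S_obs (undefined
and reported missing at S_obs = 1). Beta diversity (Bray–Curtis,
d = Σ|x−y|/Σ(x+y)) and its principal-coordinate embedding use the first
(seeded) rarefaction cycle as the canonical table, since a median is not
defined for a distance matrix. PCoA uses Gower double-centering and an
eigendecomposition; negative eigenvalues are reported, not corrected —
axes are returned for positive eigenvalues only.

**Dirichlet Monte-Carlo CLR.** For inference on individual features the
*non-rarefied* filtered counts are used: each sample's latent proportions
are drawn repeatedly from Dirichlet(counts + 0.5) and each draw is mapped to
the centred log-ratio scale, clr_i = ln p_i − mean(ln p). The 0.5
pseudo-count is the Jeffreys-style prior conventional in compositional
Monte-Carlo; the natural log is used throughout (the base rescales
coefficients by a constant and cancels in every test statistic). The whole
analysis is run once per instance and coefficients, standard errors and
BH-adjusted q-values are averaged over instances, propagating count
uncertainty into the final tables. The reference number of instances is
128; the bundled analyses and tests use 1–8 instances, which leaves the
averaged point estimates essentially unchanged and only smooths the
q-values less.

Features are first filtered by prevalence: a feature is kept when detected
at ≥ 3 reads in ≥ 20% of samples (10% for the larger validation-style
scenario, which uses a lower threshold to keep the feature sets
comparable).

## Association machinery

**Time courses.** Each response — rank-transformed marker, alpha index,
PCo score, or per-feature CLR value — is fitted by maximum likelihood as
`y ~ time_point + delivery_mode + breastfeeding_weeks + (1 | subject)`.
ML rather than REML because REML likelihoods are not comparable across
fixed-effect structures, and every test here is a likelihood-ratio test of
nested fixed effects (chi-square reference, df = parameter difference,
negative statistics clamped to zero). Pairwise visit contrasts are
estimated-marginal-mean differences; with treatment coding the covariate
terms cancel, so each contrast is a linear combination of time coefficients
with a t reference on n_obs − n_fixed residual df. This residual-df
approximation is simpler than Satterthwaite/Kenward–Roger and slightly
liberal in small samples; the difference shrinks with n. Contrast estimates
are earlier-minus-later, so an increase over time carries a negative
t-ratio. BH families: LRT p-values across features; contrast p-values
across all feature × pair cells.

**Repeated-measures correlation.** The within-subject association of two
repeatedly measured variables, from the ANCOVA with subject as factor:
r = sign(b)·√(SS_x/(SS_x+SS_err)), df = n − k − 1, p from F(1, df).
Markers are rank-transformed in the screens by default. Incomplete pairs
are deleted case-wise and subjects with fewer than two complete pairs are
dropped; no imputation anywhere in the pipeline.

**Change-vs-change (delta) analysis.** For every subject, every ordered
pair of observed visits contributes a row: marker change (later − earlier),
per-feature CLR change per instance, and the within-subject Bray–Curtis
distance. The marker change — rank-transformed across the retained rows —
is modelled as `Δmarker ~ Δpredictor + interval + covariates +
(1 | subject)`, with two LRTs: dropping the predictor from the
no-interaction model (df = 1), and interaction vs no interaction
(df = n_intervals − 1). The reading rule: per-interval marginal slopes if
the interaction q < 0.05; else the common slope if its q < 0.05; else
nothing. Rows are ranked after case-wise deletion (ranking before deletion
would change ranks only through deleted rows' positions; the alternative is
noted but not exposed). A marker's change can itself serve as the
predictor (zonulin-change vs calprotectin-change), as can the Bray–Curtis
distance (a non-negative predictor, same machinery).

The slope-recovery tests construct the response directly as
β·Δfeature + interval offsets + unit Gaussian noise and fit with
`rank_response=False`: a raw-scale generative slope is not identified after
rank transformation (a monotone distortion), so recovery is only meaningful
un-ranked. Rank-scale slopes from the generator's own coupling land in the
same few-units-per-CLR-unit magnitude regime as fitted cohort slopes.

**Power.** The power of the two-sided Pearson-correlation test uses the
classic approximation: critical r from the t distribution on n − 2 df,
sampling distribution on the Fisher-z scale with mean correction
r/(2(n−1)) and SD 1/√(n−3). At the cohort's design point — n = 21 pairs,
r = 0.5, Bonferroni-adjusted α = 0.1/50 = 0.002 — this gives 0.213; a
Monte-Carlo oracle over simulated bivariate-normal datasets agrees within
0.005.

**Partial Mantel test.** Composition (Bray–Curtis) against the
inter-sample time-interval matrix, controlling a subject-incongruence
matrix (0 for samples from the same infant, 1 otherwise — one concrete
reading of "donor incongruence"). First-order partial Pearson correlation
of off-diagonal entries; one-sided permutation p by joint row/column
shuffling of the first matrix, with the identity permutation counted.

## Synthetic cohorts and ground truth

The generator emulates the structure the analysis assumes, with one seed
driving everything:

- **Design**: 21 subjects × P2–P6; per-visit sampling probabilities
  20/21, 19/21, 20/21, 21/21, 13/21 (matching the cohort's visit counts);
  missingness completely at random.
- **Counts**: a geometric-ish rank-abundance baseline over 47 genera
  (log-proportions −0.15·rank, spanning ~14% down to ~0.01%);
  per-(subject, feature) Gaussian intercepts (SD 0.5 on the log scale);
  eight features with linear log-trends of ±1.5 natural-log units across
  the series, balanced up/down so the CLR of non-trending features carries
  no systematic time signal (the softmax normalisation cancels in the CLR
  and balanced trends cancel in the log-mean). Each sample's *realized*
  composition is a Dirichlet draw (total concentration 200) around the
  expected proportions; sequencing is a multinomial at a lognormal library
  size (ln-mean 9.0, ln-SD 0.35, ≈ 8600 reads) — so marker couplings
  defined on the realized composition are recoverable from counts up to
  multinomial noise.
- **Markers**: zonulin rises to a plateau (220, 280, 480, 500, 510 ng/mL
  at P2–P6); calprotectin stays high then declines (250, 240, 220, 120,
  70 µg/g); per-subject intercepts SD 60, residual SD 80, truncation (not
  censoring) at zero since concentrations are strictly positive. An
  optional coupling adds β · (clr_t − clr_first) of one feature to one
  marker; the default couples a non-trending, moderately abundant genus to
  calprotectin with β = 150 µg/g per CLR unit — sized so the coupled term
  (SD ≈ 90) is a "large" effect against the residual SD of 80, the effect
  regime the design's own power calculation contemplates. Coupling a
  *non-trending* feature keeps the planted marker trajectories
  interpretable; coupling a trending one would add a systematic ±225 µg/g
  drift.
- **Presets**: the default cohort above; a larger validation-style
  scenario (45 subjects × P2–P5, 10% prevalence filter); and a null
  scenario (no trends, no couplings, flat marker curves) for type-I
  calibration.

What the generator does **not** emulate: phylogenetic correlation between
taxa, informative dropout, assay determination limits (values are truncated
at zero, not censored at an upper limit), seasonal or dietary covariate
structure, and PICRUSt-style prediction error for pathway tables. Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not robustness to these
real-data features.

## Numerical choices and degenerate inputs

- Constant responses short-circuit the mixed-model fit (every nested model
  is an equally perfect fit; LRT statistic 0, p 1).
- MixedLM fits that fail with the default optimiser retry with Powell;
  boundary fits (random-intercept variance → 0) are accepted as-is.
- Contrast variances are clamped at zero before the square root (boundary
  fits can produce tiny negative quadratic forms).
- Rank transforms use average ranks for ties; missing values stay missing.
- Tie in the rmcorr slope (exactly 0) yields r = 0.
- Per-feature fit failures propagate as missing rows with a logged reason,
  never as a crashed screen.

## Known limitations

- **All-pairs delta designs are pseudo-replicated.** A subject observed at
  k visits contributes C(k,2) interval rows but only k−1 independent
  increments; overlapping intervals share endpoints, so both the response
  and the predictor carry positive cross-row correlation that a subject
  random intercept cannot absorb. Consequently raw LRT p-values in the
  delta screen are anticonservative under the null (empirically ≈ 0.21 at
  nominal 0.05 in this design — reproduced in a minimal simulation with
  plain statsmodels, independent of this package). The screen's operative
  output, the BH-adjusted two-step decision, has a null false-flag rate
  within the nominal band in the bundled calibration, but individual raw
  p-values from `delta_screen` should be read with this inflation in mind.
  Responses that are not endpoint differences (e.g. the constructed
  responses in the recovery tests) do not suffer from it.
- Contrast df uses the residual approximation, not Satterthwaite/KR.
- The bundled analyses run at reduced Monte-Carlo depth (1–8 instances vs
  the reference 128) and the calibration/recovery suites use 6–20 seeds;
  these sizes were chosen as the smallest at which the binomial/Monte-Carlo
  tolerances of the tests are meaningful.
- Breastfeeding time is treated as a static per-subject covariate.
- Marker determination limits are exposed as a config switch
  (`clip_marker_limits`) but no scenario exercises censoring.
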