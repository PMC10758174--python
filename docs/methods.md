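# Methods

This note documents the models implemented in `culturedist`, the choices
made where the design was genuinely open, and what the synthetic study
generator does and does not emulate.

## The study design

Two cohorts rate the same 29 substance-use risk factors on a 4-point
influence scale (1 = no influence … 4 = a lot of influence): a general
population sample ("GPS", young adults, n = 48) whose shared pattern
defines a cultural model of substance-use risk, and a treatment group
("TG", persons under treatment for substance use, n = 133) whose
members are located relative to that model.  Each TG member also
completes a 14-item perceived-stigma scale (6 dichotomous + 8 four-point
items, summed; range 8–38 under the package's default coding) and an
adapted Internalized Stigma of Mental Illness scale for self-stigma
(four-point items, summed).

## Consensus foundations (`culturedist.consensus`)

**Agreement.** Informant-by-informant agreement is the Pearson
correlation of rating profiles across items (ratings treated as
interval; pairwise-complete under missing data).  A chance-corrected
match coefficient, `(m − 1/4)/(3/4)` with `m` the share of identical
codes, is available via `agreement_method="match"`; it is the classic
consensus-theory coefficient for categorical answers and is the better
estimator when ratings arise from a discrete key-matching process (see
*Parameter recovery* below).

**Competences.** A minimum-residual single-factor solution of the
agreement matrix: communalities are iterated on the diagonal (start =
each row's largest absolute off-diagonal entry, cap 500 iterations,
tolerance 1e-6) and the first-factor loadings are the per-informant
cultural competences.  Consensus is declared by the conventional 3:1
rule on the first-to-second eigenvalue ratio of the communality-adjusted
matrix, *and* the absence of competences below −0.1.  The second clause
matters: two antagonistic subgroups holding opposed answer keys produce
a strong *bipolar* first factor — the eigenvalue ratio stays large — and
are caught only by their negative loadings.

**Answer key.** Competence-weighted mean rating per item, negatives
clipped to zero for weighting (consensus theory reads negative loadings
as model violation, not information), reported unrounded and rounded to
the 1–4 scale.

**Respondent reliability.** Cronbach's alpha of the *transposed* matrix
(informants as parallel measures of the key, items as cases) — the
internal-consistency consensus model for rating data.  Note an
arithmetic fact that shapes interpretation: with ~48 informants, alpha
is mechanically close to 1 whenever pairwise agreement is substantial
(mean inter-informant r of 0.5 gives alpha ≈ 0.98).  A reliability near
0.87 at that sample size implies mean inter-informant correlation of
only ~0.12 — substantial aggregate reliability despite weak pairwise
agreement, which is exactly the regime in which formal consensus
analysis fails while the internal-consistency model still certifies a
shared key.

**Residual agreement.** The consensus component (outer product of the
loadings) is removed from the agreement matrix; informants are
partitioned by the sign of the residual's leading eigenvector.  A split
is declared only when the leading residual eigenvalue dominates the
second by a factor ≥ 2 (noise residuals have a flat spectrum) and the
residual is not degenerate (all entries within 0.1 of zero).  Reported
strength is the leading eigenvalue's share of the positive residual
spectrum.

## Q-mode cultural distance (`culturedist.distance`)

Profile dissimilarity between pooled GPS + TG informants is
`1 − Pearson r` of the two rating profiles — shape-only, so individual
differences in rating *elevation* are deliberately ignored; a squared-
Euclidean option keeps them for sensitivity analysis.  The full
symmetric matrix is embedded by nonmetric (Kruskal) MDS — SMACOF with
monotone-regression disparities, best of `n_starts` random starts
(default 20 for a single analysis; replicate sweeps in the tests and the
acceptance script use 4, which changes stress in the third decimal),
maximum 300 iterations, relative tolerance 1e-6.  Kruskal stress-1 is
recomputed from the final configuration by isotonic regression of the
configuration distances on the dissimilarities.  On synthetic default
studies the 2-D stress is ≈ 0.26 (the study reports 0.24 on its data).

Cultural distance of a TG member is the squared Euclidean distance of
their coordinates from the GPS centroid (the arithmetic mean of GPS
coordinates).  The configuration is identified only up to rotation,
reflection and translation; distances are invariant to all three, and
the tests verify this with random orthogonal transforms.  Raw distances
are right-skewed and are natural-log transformed (zero distances are
offset by half the smallest positive distance first).  Quartiles of log
distance are assigned by rank with sizes as equal as possible, extra
members going to the more proximate quartiles first (n = 133 →
34/33/33/33, the extra member in quartile 1).

## R-mode internalization scales (`culturedist.factors`)

Principal components of the item Pearson-correlation matrix (items share
a scale, but standardisation matches ordinary EFA practice for skewed
ratings); retained components are varimax-rotated (Kaiser algorithm),
ordered by rotated variance and sign-aligned so each factor's largest
|loading| is positive.  Retention defaults to the scree elbow — the
maximiser of the eigenvalue sequence's second difference — with a manual
override; the pipeline fixes two factors, matching the study design.
The elbow rule is known to collapse to one factor when the leading
factor dominates, which is why the override exists.

Items join the factor where |loading| ≥ 0.40 (the threshold implied by
the published table's bolding boundary: 0.406 is assigned, 0.372 is
not), ties going to the larger |loading|.  Scale scores are plain sums
of the 1–4 ratings (17-item psychosocial scale IPSMR, range 17–68;
5-item experiential scale IEMR, range 5–20); informants missing any item
of a scale get a missing score — no imputation.  Reliability is
closed-form Cronbach's alpha.

## Stigma scoring (`culturedist.stigma`)

Perceived stigma: sum of six 0/1 items and eight 1–4 items.  The 0/1 and
1–4 codings are package defaults chosen so the published sample mean
(19.1) is interior to the feasible range [8, 38]; the instrument's
printed coding is not public, so both are configurable.  Self-stigma:
plain sum of k four-point items (default k = 29, the original ISMI
length) with reverse-coded items honoured from a config list.

## Association layer (`culturedist.association`)

* Hierarchical polynomial regression of an outcome on continuous log
  distance: orthonormal polynomial basis (QR of the centred Vandermonde
  matrix), cumulative R², per-degree increment, and F-change tests.
* Quartile trend ANOVA: one-way ANOVA with the between-groups sum of
  squares split into a linear component — orthogonal polynomial contrast
  (−3, −1, 1, 3), generalised to unequal n by centring the group scores
  with size weights — and the 2-df nonlinear remainder.  Effect size is
  eta = sqrt(SS_between/SS_total).  The identity SS_lin + SS_nonlin =
  SS_between holds on every input and is tested.
* A summary-statistics oracle computes the identical decomposition from
  per-group (mean, sd, n) rows alone and exactly equals the raw-data
  ANOVA when the summaries are exact — this is what lets published
  quartile tables be checked without raw data.
* Post-hoc contrasts of the distal quartile: Tukey HSD (Scheffé
  optionally).  At the study's size (n = 33/group) and a one-pooled-s.d.
  deficit, Tukey-adjusted per-contrast power is ≈ 0.93, so all three
  distal contrasts land jointly in roughly 80% of replicates — a useful
  reminder that "post-hoc significant" is not guaranteed even under a
  solid effect.
* Variance heterogeneity: median-centred Levene test, with per-group
  variances reported so the most variable group can be named.
* Dichotomised influence: count of items rated 3–4 per informant, with
  per-quartile means.

### Reconstructing the published quartile table

Feeding the published quartile means/s.d.s (IEMR row: 15.9 ± 1.9,
17.0 ± 2.5, 16.5 ± 2.9, 13.4 ± 4.7; equal sizes totalling 133) to the
summary oracle reproduces overall F = 8.4, nonlinear F = 7.3 and
eta = 0.4045 at printed precision, and linear F = 10.55 against a
printed 10.6.  The inputs are rounded to one decimal; propagating that
rounding through the linear contrast gives an uncertainty of roughly
±0.5 on the linear F and ±0.002 on eta, so those statistics are checked
within their propagation bands.  The published self-stigma quartile-2
s.d. (± 2.5) is inconsistent with the printed F-ratios for that row
(reconstruction would need ≈ 10) and is treated as a typographical
error: carried verbatim in the packaged table, excluded from checks.

## Synthetic study generator (`culturedist.simulate`)

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without the (non-deposited) raw
data.

**GPS.** A shared skewed-high answer key (22 of 29 items keyed 3–4,
alternating 4/3; the rest 2/1) and per-informant competences uniform on
(0.5, 0.9).  Each informant reports the key on exactly a fraction
*competence* of items (randomly placed; "stratified" mode) and draws the
rest from a skewed categorical over 1–4 with probabilities
(0.05, 0.15, 0.45, 0.35).  Stratified matching makes the competence
parameter the informant's *realised* share of key agreement; an
independent-Bernoulli mode is available but adds binomial noise that
blurs parameter recovery at 29 items.

**Parameter recovery and its limits.** With 29 items, the realised
alignment of a rating profile with the key carries irreducible noise of
about 0.1 — comparable to the spread of competences themselves — so
*no* estimator based on profile correlations can recover the competence
parameter with correlation much above ~0.7.  The chance-corrected match
coefficient conditions on exact code matches, which under stratified
generation are pinned to the competence, and recovers it at median
r ≈ 0.83.  Recovery tests therefore run the match-agreement route.

**Calibrated reliability preset.**
`SyntheticConfig.reliability_calibration()` lowers competences to
U(0.25, 0.45), the regime the published respondent reliability (0.871
at 48 informants) implies; the preset's measured reliability is
0.85–0.92 across seeds.  The default competence range describes a
strongly consensual cohort and yields reliabilities near 0.98 — both
regimes are real; they answer different questions.

**TG.** Four deviation classes (sizes 34/33/33/33).  A member's
personal key equals the GPS key on an "influential inventory" of items
and is down-rated (1–2) elsewhere; inventory sizes 22/23/20/14 and
adherences 0.99/0.87/0.80/0.92 were fixed once, by forward arithmetic,
so the dichotomised influential-item counts land near the published
quartile profile (22.2/23.2/20.6/14.5) and the estimated log distance
orders the classes (Spearman with true class ≈ 0.80 median).  The
most distal class has both the smallest inventory and per-informant
inventory sampling, which also reproduces the published finding of
higher variance in the distal group.

**Outcomes.** Self-stigma totals are drawn normal per class around the
published quartile targets (39.1/43.9/43.2/37.6, s.d.s 9.7/10.0/10.1/
10.9 — an inverted-U); perceived stigma is flat (19.1 ± 4.1, truncated
to [8, 38]).  When hard scale bounds are set, the underlying normal is
moment-matched so the *realised* truncated means and s.d.s equal the
targets; naive redraw at a nearby floor would shift means by several
points.  Self-stigma is unbounded by default because the published
distal-class moments are unrealisable under any normal truncated at the
29-point sum floor (the s.d. exceeds the distance to the floor),
implying the original instrument used different length or coding.

**What the generator does not emulate.** Ratings are conditionally
independent given the personal key — no item-difficulty structure, no
response styles, no acquiescence; outcomes depend on distance class
only, with no covariates (sex, treatment modality, time in treatment);
and the two-factor R-mode structure of the real TG emerges only from
the inventory dichotomy, not from distinct psychosocial/experiential
latent factors (a separate two-factor generator exists for factor-
recovery tests).  Passing tests therefore show the *methods* behave
correctly under the design's assumed structure, not that the published
substantive findings would replicate in new data.

**Replication signature.** On generator defaults, the full pipeline
reproduces the qualitative signature — distal class lowest on IPSMR,
IEMR, influential-item count and self-stigma; perceived stigma flat;
self-stigma trend predominantly nonlinear — in 29/50 seeded replicates
(the binding limb is self-stigma's distal minimum: the published gap,
39.1 vs 37.6, is smaller than the group-mean standard error 10/√33, so
no generator honouring the published targets can make it reliable).
Grouped by *estimated* quartile instead of true class the joint rate
drops to ~0.24, the additional attenuation coming from ~50%
quartile/class misclassification at the achievable distance-recovery
level.

## Problem sizes and runtime

Default analyses use the study's sizes (48 + 133 informants, 29 items).
Replicate sweeps use 10 seeds (distance recovery), 20 seeds (competence
recovery), 50 seeds (signature), and 1000 replicates (Levene type-I
rate); nonmetric MDS inside sweeps uses 4 random starts.  A full test
run completes in roughly a quarter hour on one CPU.
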