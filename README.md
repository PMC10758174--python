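# culturedist

Cultural consensus, cultural distance, and stigma: a toolkit for the
*cultural distance* study design in psychiatric/epidemiological
anthropology.

## The problem

A social group's shared understanding of a domain — here, the risk
factors for substance use and misuse — can be formalised as a **cultural
model**: a consensus "answer key" that members hold to varying degrees
(their **cultural competence**).  When a second group occupies a
different social position (here, persons under treatment for substance
use), each of its members can be *located* relative to the first group's
model, and that location can be related to outcomes such as perceived
stigma (stigma one believes society holds) and self-stigma (stigma
turned inward).

`culturedist` implements that full chain for informant-by-item rating
data (29 risk-factor items rated 1–4 by default):

1. **Consensus foundations** — informant agreement matrix, minimum-
   residual competence estimation, the 3:1 eigenvalue consensus rule,
   competence-weighted answer key, respondent reliability (Cronbach's
   alpha over the transposed matrix — the internal-consistency consensus
   model), and residual-agreement subgrouping.
2. **Q-mode cultural distance** — profile dissimilarities
   (1 − Pearson r, elevation-free), nonmetric MDS (Kruskal stress-1),
   and each treatment-group member's squared Euclidean distance from
   the general-population centroid:

   `distance_i = Σ_d (coord_i,d − centroid_d)²`

   log-transformed and split into quartiles (1 = most proximate).
3. **R-mode internalization scales** — varimax-rotated PCA of the item
   correlations, scree-elbow retention, |loading| ≥ 0.40 item
   assignment, summed scales (the 17-item *Internalized Psychosocial
   Model of Risk*, IPSMR, and 5-item *Internalized Experiential Model of
   Risk*, IEMR) with alphas.
4. **Stigma scoring** — the 14-item perceived-stigma scale (6
   dichotomous + 8 four-point items) and an adapted ISMI self-stigma
   scale.
5. **Association** — polynomial trend regression on continuous log
   distance; quartile trend ANOVA with linear/nonlinear orthogonal
   decomposition and eta = √(SS_between/SS_total); Tukey post-hoc
   contrasts of the distal quartile; median-centred Levene variance
   test; dichotomised influential-item counts.  A summary-statistics
   ANOVA oracle reconstructs all of this from published per-group
   (mean, sd, n) rows alone.
6. **Synthetic study generator** — GPS/TG cohorts with a planted answer
   key, competence distribution, graded deviation classes and stigma
   outcomes, so the whole pipeline is testable without the study's
   (non-deposited) raw data.

Each stage follows the model/results pattern: build a model from data,
`fit()` it, read estimates and diagnostics off the results object.

## Worked example

```python
from culturedist import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(seed=1, n_starts=4))
print(results.summary())
```

The run generates a synthetic study (48 general-population raters, 133
treatment-group members in four planted deviation classes) and pushes it
through all five stages.  Abridged output:

```
Cultural consensus analysis
========================================
Informants:              48
Eigenvalue ratio:        8.19
Consensus (>= 3:1):     True
Mean competence:         0.726
Respondent reliability:  0.982

Cultural distance (Q-mode)
========================================
Kruskal stress-1: 0.259
TG members:       133

quartile   n    mean log distance
       1   34      -6.75
       2   33      -3.72
       3   33      -1.12
       4   33       0.05

Quartile trend ANOVA: IPSMR
================================================
group         mean      sd       n
1             14.0     0.2      34
2             14.1     0.7      33
3             13.0     1.7      33
4             11.7     1.6      33

Overall F (df 3,129)   = 27.2   p = 0.000
Linear F (df 1,129)    = 69.9   p = 0.000
Nonlinear F (df 2,129) = 5.8   p = 0.004
eta = 0.6222
```

Reading it: the general-population cohort shows strong consensus
(eigenvalue ratio 8.2 ≫ 3), the 2-D nonmetric embedding fits with
stress 0.26, log cultural distance rises monotonically across quartiles,
and the psychosocial internalization score falls sharply in the most
distal quartile (overall F(3,129) = 27.2, eta = 0.62) — the distal
group rates far fewer risk factors as influential.

The same machinery reconstructs a published quartile table from its
printed summaries alone:

```python
from culturedist import GroupSummary, summary_stat_anova

iemr = summary_stat_anova([
    GroupSummary(1, 15.9, 1.9, 133 / 4),
    GroupSummary(2, 17.0, 2.5, 133 / 4),
    GroupSummary(3, 16.5, 2.9, 133 / 4),
    GroupSummary(4, 13.4, 4.7, 133 / 4),
])
print(round(iemr.f_overall, 1), round(iemr.eta, 4))   # 8.4 0.4045
```

A thin CLI mirrors the library:
`culturedist consensus|distance|factors|anova|simulate|run --help`.

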