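# Methods

## Scope and model

The package implements a composite-phenotype screening workflow for heat
tolerance in lactating dairy cows, plus the expression-level follow-up on
the selected extremes. Its statistical core is deliberately simple and
fully specified: a temperature-humidity index for heat load, PCA-weighted
membership-function ranking for selection, pooled t contrasts with
Bonferroni adjustment for group description, and an inclusive
threshold rule for differential expression. Everything is deterministic
given a seed.

## THI

`thi_value` evaluates `THI = (1.8·AT + 32) − (0.55 − 0.0055·RH)·(1.8·AT − 26)`
with AT in °C and RH in percent. The partial derivative with respect to AT
is `1.8·(0.45 + 0.0055·RH) > 0`, so THI is strictly increasing in AT at
every humidity — this is what lets the environment generator calibrate a
series to a target mean THI by root-finding a single AT offset. RH supplied
in (0, 1] is rejected as a probable fraction rather than silently rescaled:
a 0.65-vs-65 confusion would shift THI by several units without any other
symptom. THI is never rounded internally; summaries round to one decimal at
the reporting layer only.

## RW ranking

`pca_fit` eigendecomposes the correlation matrix of the cows × indexes
table by default (covariance by flag). The indexes carry incommensurate
units — °C, breaths/min, kg — so correlation PCA is the right default: the
full ranking is then invariant under any per-index positive affine
rescaling, which the test suite asserts. Contribution rates are fractions
of the total eigenvalue sum over **all** components; only the weights
`Wᵢ = Pᵢ/ΣPᵢ` renormalise over the retained ones (default 2, configurable,
with a cumulative-contribution retention rule available to the caller via
`cumulative_contribution`).

Eigenvector signs are arbitrary, so each retained component is oriented to
make the sum of its loadings on higher-is-worse indexes negative. All three
default indexes (RT, RR, milk-yield decline) are stress-burden measures, so
larger component scores — hence larger membership values and larger RW —
consistently mean greater tolerance. Index direction is input metadata
(`directions`), defaulting to higher-is-worse.

Membership values are min–max normalised per component **across cows** (the
normalisation is indexed by principal component, not by cow). A component
whose scores are constant raises an error rather than imputing 0.5: such a
component carries no ranking information, and silent imputation would bias
RW. Ranking ties are broken by lexicographic cow id, making output stable
across runs and platforms.

## Group statistics

`group_ttest` is the pooled-variance two-sample Student's t (df =
n₁ + n₂ − 2), with Welch available by flag; the pooled test is the default
because group variances are not estimable with any precision at n = 3 per
group. Bonferroni adjustment is `min(1, m·p)` with the family size m an
explicit argument — the family is the set of indexes jointly reported (six
in the standard contrast table), a modelling decision the code never
guesses. ELISA precision gates are coefficients of variation,
`100·sd/mean` with sample sd, at 10% (intra-assay, per replicate group)
and 15% (inter-assay, across runs).

## Differential expression

FPKM is computed exactly as `counts·10⁹/(length·library size)`. The DEG
rule is `|log₂FC| ≥ 1.4 AND p ≤ 0.05`, both boundaries inclusive; no
multiple-testing correction is applied to these p-values. Fold changes use
group means with a shared pseudocount (default 0.01 on FPKM, 1 on counts)
so zero-expression genes stay finite. The internal p-value is a two-sided
pooled t on log₂(FPKM + ε) per gene — a deliberately plain choice that is
adequate at the bench scale this package targets; per-gene p-values from a
dedicated DE tool (e.g. a negative-binomial GLM with dispersion shrinkage)
can be supplied as a column and take precedence. Genes with NaN statistics
are marked non-significant with a logged warning, never passed.

qPCR arithmetic: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt subtracts
the calibrator group's mean ΔCt, relative expression is 2^−ΔΔCt. The
concordance statistic is the fraction of panel genes whose RNA-seq log₂FC
sign matches the sign of the log₂ qPCR ratio.

## Synthetic herd generator

The generator emulates the study conditions the analysis assumes:

* **Herd**: 42 cows, half assigned to a latent tolerant class (the split is
  a fixed count, not a random draw, so every simulated herd is evaluable).
  Cow-level (RT, RR, milk decline) values are multivariate normal within
  class, with class means at the published HT/NHT group summaries and sds
  reconstructed from the printed SEMs as SEM·√3 (n = 3 per group is what
  those summaries were computed from; the conversion is an assumption and
  every value is overridable). Within-class correlation among the three
  stress indexes defaults to 0.5 — stressed cows tend to be stressed on all
  axes, but the true correlation is unknown; it is a single configurable
  number. Daily readings add small measurement noise (0.05 °C, 2
  breaths/min, 1.2 kg); draws below physiological bounds (RT > 35 °C,
  RR ≥ 1, yield ≥ 0) are floored and counted in the log. ELISA analytes are
  drawn per cow from the class summaries with 2% replicate-well noise.
* **Environment**: two 7-day periods, 7 readings/day (07:00–19:00, every
  2 h). AT follows a diurnal cosine peaking at 14:00 plus Gaussian noise,
  RH moves in anti-phase; a constant AT offset is solved by Brent's method
  so the period mean THI hits the target exactly (86 hot month, 72
  thermoneutral — a hot-summer profile for a high-yield herd). Targets
  requiring mean AT outside −20…55 °C are rejected as infeasible.
* **Expression**: negative-binomial counts (dispersion 0.1, typical of
  bulk RNA-seq; variance = μ + 0.1·μ²) over 2000 genes, log-normal
  baseline means, uniform gene lengths 200–10000 bp, 3 samples per group.
  5% of genes get a planted group shift of |log₂FC| = 2 with random sign,
  applied to the HT group. The planted truth (gene, true log₂FC, flag) is
  returned separately, as are the hidden cow class labels, so the analysis
  path cannot consume them by accident.
* **qPCR**: a 7-gene panel drawn from the planted genes; target Ct encodes
  the true fold change relative to a reference gene near Ct 20, with
  0.15-cycle technical noise.

Every generator is a pure function of (config, seed); the bundle splits one
seed into independent sub-streams. What the generator does **not** emulate:
real weather autocorrelation, seasonal drift in milk yield unrelated to
heat, count-level GC/length biases, batch effects, or any genetic structure
among cows. Passing recovery tests therefore demonstrate that the pipeline
arithmetic is correct and well-conditioned at the study's effect sizes —
not that the screen would achieve the same accuracy on field data.

## Numerical choices and degenerate inputs

* Eigendecomposition via `numpy.linalg.eigh` on the symmetric
  correlation/covariance matrix; eigenvalues clipped at 0 to absorb −1e−17
  round-off; tests cross-check a brute-force characteristic-polynomial
  solver at 1e−8.
* ΣPᵢ = 1 and ΣWᵢ = 1 are enforced to 1e−9.
* Zero-variance index columns, constant component scores, zero pooled
  variances, empty periods, zero library sizes and missing Ct values all
  raise typed errors naming the offender; nothing degrades to NaN silently.
* All tables are UTF-8 CSV/TSV with a "." decimal point regardless of
  locale; round-tripping a written table reproduces values exactly.

## Problem sizes

The test suite and the acceptance script run everything at the study's own
scale: 42-cow herds, 2000-gene matrices with 3 samples per group, 200
replicate herds for the selection-recovery study, 100 replicate matrices
for DEG sensitivity, 500 replicates for the contrast re-simulation. These
sizes give Monte-Carlo standard errors comfortably below the margins being
asserted while keeping a full run in the tens of seconds.

## Known limitations

* The internal DE p-value ignores count overdispersion structure beyond
  what the log transform absorbs; it is a screening default, not a
  substitute for a dispersion-modelling DE analysis.
* The published 71.22/26.90/1.88% contribution split cannot be re-derived
  here because the underlying 42-cow index table was never deposited; it is
  used only as a worked input for the weight and cumulative-contribution
  arithmetic.
* Re-simulating the published group contrasts at n = 3 per group shows that
  two-sample t power at those exact effect sizes is below 95% for three of
  the six indexes (HSP70, cortisol, milk decline) — a single significant
  observed dataset does not imply high replication probability at n = 3.
  The acceptance suite reports this honestly rather than inflating the
  simulated effect sizes.
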