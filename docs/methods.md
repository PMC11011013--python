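# Methods

## Scope and model

`bovigs` implements a genomic-prediction workflow for dairy-cattle linear
type (body conformation) traits in which the response variable is a
deregressed estimated breeding value (DEBV) and marker effects are estimated
by Bayesian whole-genome regression:

    y_i = mu + sum_j Z_ij u_j delta_j + e_i,      e_i ~ N(0, sigma_e^2 / w_i)

* `y_i` — DEBV of animal i (including or excluding the parent average),
* `Z_ij` — centred additive genotype of animal i at SNP j,
* `delta_j ~ Bernoulli(1 - pi)` — mixture indicator; `pi` is the prior
  fraction of markers with exactly zero effect,
* `u_j | delta_j = 1 ~ N(0, sigma_uj^2)` — BayesB gives each locus its own
  variance with a scaled-inverse-chi-square prior (marginally a t-distributed
  effect); BayesC shares one variance across all included loci,
* `w_i` — reliability-derived record weight entering as a heterogeneous
  residual variance.

Downstream, posterior samples are partitioned into 1-Mb windows for GWAS,
and prediction accuracy is estimated by K-means cross-validation that
clusters animals by pedigree relationship so that training and validation
sets are as unrelated as the data allow.

## Deregression and weights

EBVs are shrunken predictors; regressing markers directly on EBVs double
counts pedigree information and under-disperses the response.  Two response
modes are provided:

* **incPA** — `DEBV = EBV / r2` with reliability `r2` unchanged.
  Re-regression (`DEBV * r2`) reproduces the EBV exactly, which the test
  suite checks to 1e-8.
* **excPA** — the parent-average information source is removed first.
  EBV information is partitioned into a PA source and an own/progeny source
  via effective record counts.  With `lambda = (1 - h2)/h2` and the 2x2
  pedigree relationship inverse `[[4, -2], [-2, 2]] * lambda` linking the PA
  pseudo-animal and the individual, the record counts solve a quadratic in
  the two reliabilities (`alpha = 1/(0.5 - r2_PA)`,
  `delta = (0.5 - r2_PA)/(1 - r2)`); the derivation and closed form are in
  `deregress.py`.  A forward check (tests) confirms the solved counts
  reproduce both input reliabilities through the mixed-model equations.
  PA reliability is `(r2_sire + r2_dam)/4`, with an absent parent
  reliability proxied by the animal's own; animals with no parent average,
  or with no information beyond the PA, are dropped with a logged reason.

Record weights default to

    w = (1 - h2) / {[c + (1 - r2)/r2] * h2}

with `c = 0.4` the fraction of genetic variance not captured by markers.
The printed rendering of this formula is typographically ambiguous (flat
product vs. denominator); the adopted reading follows the weighting-factor
source it derives from, increases with reliability (more reliable records
weigh more), and stays finite on r2 in (0,1).  The flat-product reading is
kept behind `reading="flat"` for comparison.

## Sampler

Single-site Gibbs, JIT-compiled with numba.  Per iteration: (1) `mu` from
its weighted-normal full conditional; (2) per locus, `delta_j` from its full
conditional with `u_j` integrated out analytically (log Bayes factor
`0.5 [log(sigma_e^2 / (sigma_uj^2 C_j)) + r_j^2 / (C_j sigma_e^2)]` with
`C_j = z_j' W z_j + sigma_e^2 / sigma_uj^2`), then `u_j` from its normal
full conditional when included; (3) effect variances from
scaled-inverse-chi-square conditionals (locus-specific for BayesB, df
`nu + 1`; common for BayesC, df `nu + m` over the `m` included loci;
excluded BayesB loci redraw from the prior); (4) `sigma_e^2` from the
weighted residual sum of squares.  Production schedule: 110,000 iterations,
10,000 burn-in, thinning 10, i.e. 10,000 retained samples; tests and the
desk-scale studies use proportionally scaled-down chains (1,200–11,000
iterations), which the bookkeeping arithmetic covers identically.

Priors: `nu_effects = 4.2`; the effect-variance scale is solved from a
target genetic variance (default half the response variance) divided by
`(1 - pi) * sum_j 2 p_j q_j`, the standard calibration that keeps the
implied genomic variance constant across `pi` levels.  Residual df 4 with
scale matched to the residual share of the response variance.  Both are
exposed in `BayesConfig` because the original analyses do not report them.

Genotypes are centred by twice the allele frequency computed **on the
training fold only**, and the frequencies are stored with the fit so
prediction of validation animals reuses training centring (no leakage).
The canonical coding is allele dosage 0/1/2; the -10/0/10 dialect is an I/O
convention under which effects scale by 1/10 and predictions are invariant
(tested).  Fixed `sigma_u^2`/`sigma_e^2` switches exist for oracle testing:
at `pi = 0`, unit weights and fixed variances the sampler is Bayesian ridge
regression and is checked against the closed form.

## Window variance partitioning

Windows tile each chromosome in 1-Mb blocks: `Mb = floor((pos - 1)/1e6)`,
id `chr_Mb`.  For every retained sample the per-window genomic values are
`g_w = Z_c,w u_w`, and the window's share of genetic variance is

    share_w = var(g_w) / sum_w' var(g_w') * 100

using the population (1/n) variance across animals (shares are scale-free,
so the denominator convention is inert).  The reported GV% is the posterior
mean of per-sample shares — not the share of posterior-mean effects, which
understates the variance of mixture posteriors.  Normalising by the sum of
window variances (rather than by the variance of the summed genomic value)
makes shares nonnegative and sum to exactly 100 per sample; with unlinked
loci the two denominators agree in expectation, and under linkage the
difference is the between-window covariance, which this decomposition
deliberately excludes from any single window.  Windows with GV% >= 1.0 are
flagged; with ~2,500 windows the infinitesimal expectation is 0.04% per
window, so the threshold is a ~25-fold enrichment.  Skipped samples (zero
total genetic variance) are counted and logged.

## Relationship matrix and cross-validation

The numerator relationship matrix is built by the tabular recursion
(`a_ij = (a_sj + a_dj)/2`, diagonal `1 + F` with `F = a_sd / 2`), vectorised
row-wise over the topologically sorted pedigree.  The test suite proves it
exact against an independent recursive-kinship oracle on *all* pedigrees of
up to five animals and on random eight-animal pedigrees.

Folds: relationship is converted to the normalised distance
`d_ij = 1 - a_ij / sqrt(a_ii a_jj)` (inbred diagonals do not distort
distances), embedded by classical MDS (components covering >= 90% of the
positive eigenvalue mass, capped at 20), and clustered by Lloyd K-means
with 25 restarts, keeping the best inertia.  Per-fold diagnostics mirror
standard practice: mean inbreeding, mean of per-animal maximum
relationships within/between folds, and mean pairwise relationship
within/between, plus an unweighted across-fold average row.

Accuracy is the Pearson correlation between predicted molecular breeding
values and the DEBV response within each validation fold; the summary is
the unweighted fold mean with SE = sd(fold accuracies)/sqrt(k).  No
division by sqrt(h2) or sqrt(reliability) is applied by default — the
correlation with the response is reported as-is, which matches the
magnitude range published for low-heritability conformation traits; the
rescaling is a one-line wrapper if wanted.  Per-fold chains are seeded
`base_seed + fold`.

## Synthetic data: what it does and does not emulate

Generators provide the statistical structure the pipeline assumes, not a
population-genetic reconstruction:

* multi-generation random-mating pedigrees (non-overlapping generations,
  no selection);
* unlinked biallelic loci gene-dropped from Hardy-Weinberg founders with
  uniform founder MAF on [0.05, 0.5] — no LD map; window-GWAS power is
  exercised by *planting* causal loci in a chosen window instead;
* mixture-architecture traits: `delta_j ~ Bern(1 - pi)`, non-null effects
  normal and rescaled so the realised genetic variance is exact, residuals
  realising the requested h2 (defaults pi = 0.99, h2 = 0.3, inside the
  0.03–0.33 heritability range of the published conformation traits);
* EBV records with reliability uniform on a requested range and noise
  calibrated so `cor(EBV, TBV)^2 = r2` — the textbook meaning of
  reliability — plus parent EBVs/reliabilities joined from the same table;
* three injected QC failure modes (missingness > 5%, sample MAF < 0.01,
  complete heterozygote excess) with a manifest for exact-removal tests.

Consequences: passing tests demonstrate correctness of the algorithms and
their statistical calibration under this generating process.  They do not
demonstrate performance under LD (imputation, panel merging and LD-aware
simulation are out of scope), selection, or the reliability heterogeneity
of a national evaluation.  Published window/gene hits and accuracy tables
depend on the real data and are not reproduction targets.

## Numerical choices and degenerate inputs

* QC thresholds are strict inequalities ("below" removes), applied
  sequentially (map -> call rate -> MAF -> HWE) so per-criterion counts sum
  to the total; a SNP exactly at MAF 0.01 is retained.  HWE uses the
  Pearson chi-square (1 df); monomorphic SNPs fit HWE exactly (p = 1) and
  are removed by the MAF rule instead.  SNPs with zero calls get call rate
  0 and undefined-but-filterable MAF/HWE.
* Missing genotype sentinel is -1 internally, NA in text formats; unknown
  parent sentinel is 0.  Pedigree order is generation depth with stable
  ties, so files round-trip byte-stably; cycles are fatal and named;
  parents never defined as animals are added as founders with a warning.
* The indicator's log-odds are clamped at |35| before exponentiation;
  a diverging residual variance raises with context rather than NaN-ing.
* Degenerate K-means inputs: singleton folds report NaN within-fold
  diagnostics; k > n is an error; ties at distance zero co-cluster.
* Constant MBV or DEBV in a validation fold yields an NA fold accuracy,
  excluded from the mean with a warning.

## Desk-scale study sizes

The repeatable studies (tests and `scripts/acceptance.py`) use sizes chosen
to make their statistical claims decidable while keeping each study in the
low minutes on one core: parameter recovery uses ~1,020 animals x 2,000
SNPs with chains of 2,000 iterations over 10 seeds; the cross-validation
comparison uses ~600 animals x 1,000 SNPs, 5 folds, 5 seeds; the ridge
oracle uses the 20 x 50 instance with an 11,000-iteration chain.  At these
sizes the in-sample recovery correlation (~0.99) and the incPA/excPA
ordering are stable across seeds.

## Known limitations

* No LD, so model-frequency-based fine-mapping behaviour under correlated
  markers is untested here.
* `pi` is fixed per run, never estimated from data.
* Only the overall mean enters as a fixed effect, as in the model above.
* The excPA PA-reliability proxy (own reliability for a missing parent
  reliability) is a pragmatic default; with full parent reliability data
  the exact partition is used.
* Variant-effect classes beyond genic/intergenic (+ distance) require an
  external annotation resource and are not produced.
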