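# bovigs

Genomic prediction of body-conformation (linear type) traits in dairy
cattle, built around deregressed breeding values and Bayesian whole-genome
regression.  The package is aimed at animal-breeding researchers who want a
tested, reusable implementation of the full analysis chain — SNP quality
control, deregression, BayesB/BayesC marker-effect estimation, 1-Mb-window
GWAS, and relatedness-aware cross-validation — together with synthetic-data
generators so that every stage can be exercised and validated without
access to proprietary evaluation data.

## The model

Marker effects are estimated from deregressed EBVs (DEBVs) under the
mixture whole-genome regression

    y_i = μ + Σ_j Z_ij u_j δ_j + e_i,   e_i ~ N(0, σ²_e / w_i)

with δ_j ~ Bernoulli(1 − π) the indicator that SNP j has a non-zero effect,
u_j | δ_j = 1 ~ N(0, σ²_uj) (locus-specific variance in **BayesB**, one
common variance in **BayesC**), and π ∈ {0.75, 0.90, 0.99, 0.995, ...} the
prior fraction of null markers.  Record weights

    w_i = (1 − h²) / {[c + (1 − r²_i)/r²_i] · h²},   c = 0.4

account for heterogeneous DEBV reliability r²_i.  DEBV responses come in
two flavours: including the parent average (incPA: EBV/r²) or excluding it
(excPA: effective-record partition of EBV information into parent-average
and own/progeny sources).  Posterior sampling is by single-site Gibbs
(numba-compiled); the production schedule of 110,000 iterations with 10,000
burn-in and thinning 10 retains exactly 10,000 samples.

Per retained sample, genetic variance is partitioned into 1-Mb windows;
windows explaining ≥ 1.0% of genetic variance are flagged (a ~25-fold
enrichment over the 0.04% infinitesimal expectation at ~2,500 windows).
Prediction accuracy — Pearson correlation between molecular breeding values
and the DEBV response in the validation fold — is estimated by 5-fold
cross-validation whose folds are K-means clusters of the pedigree
numerator-relationship matrix, minimising training–validation relatedness.

## Worked example

```python
import numpy as np
import bovigs as bg

# synthetic herd: 200 founders, two generations, 1,000 unlinked SNPs
ped   = bg.simulate_pedigree(n_founders=200, n_generations=2,
                             offspring_per_mating=2, seed=7)
geno  = bg.gene_drop_genotypes(ped, n_snps=1000, seed=8, n_chromosomes=10)
trait = bg.simulate_trait(geno, pi=0.99, h2=0.3, seed=9)
ebv   = bg.simulate_ebv_records(trait, ped, rel_low=0.3, rel_high=0.9, seed=10)

params = bg.TraitParams("SIM", sigma_a2=0.3, sigma_e2=0.7)
debv   = bg.deregress(ebv, params, mode="incPA")

cfg = bg.BayesConfig(method="BayesB", pi=0.99, chain_length=2000,
                     burn_in=400, thin=4, seed=11)
fit = bg.fit_bayes(geno, debv, cfg)
mbv = bg.predict_mbv(fit, geno)
print(f"cor(MBV, TBV) = {np.corrcoef(mbv, trait.tbv)[0, 1]:.3f}")

prof  = bg.window_variance_profile(fit, geno)
print(prof.sort_values("gv_percent", ascending=False).head(3))

folds = bg.kmeans_folds(bg.build_nrm(ped), k=5, seed=12, restarts=10)
cv    = bg.run_cv(geno, debv, folds,
                  bg.BayesConfig(method="BayesC", pi=0.99, chain_length=1200,
                                 burn_in=200, thin=4, seed=13,
                                 store_samples=False))
print(f"CV accuracy = {cv.mean_accuracy:.3f} (SE {cv.standard_error:.3f})")
```

Output:

```
cor(MBV, TBV) = 0.996
window_id  n_snps  gv_percent
      9_9      10       68.07
      2_1      10       13.41
      6_8      10        5.67
CV accuracy = 0.707 (SE 0.045)
```

The fitted molecular breeding values track the simulated true breeding
values almost perfectly in-sample; the window profile concentrates the
genetic variance in the few windows that happen to contain the ~10 causal
SNPs of this sparse (π = 0.99) architecture; and honest out-of-fold
accuracy, with folds deliberately built to separate relatives, is lower
than the in-sample figure — exactly the gap relatedness-aware validation
is meant to expose.

The same stages are scriptable from a shell via the `bovigs` CLI
(`simulate`, `qc`, `deregress`, `fit`, `gwas`, `cv`); run
`bovigs COMMAND --help` for options.

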