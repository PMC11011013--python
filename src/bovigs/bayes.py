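"""Weighted BayesB/BayesC whole-genome regression by single-site Gibbs.

Model:  y_i = mu + sum_j Z_ij u_j delta_j + e_i,  e_i ~ N(0, sigma_e^2 / w_i)

with delta_j ~ Bernoulli(1 - pi) and, given delta_j = 1,
u_j ~ N(0, sigma_uj^2).  BayesB gives every locus its own variance with a
scaled-inverse-chi-square prior (marginally a t-distributed effect);
BayesC shares one common variance across included loci.  The indicator is
sampled from its full conditional with the effect integrated out
analytically, then the effect from its normal full conditional.  Record
weights (from deregression) enter as heterogeneous residual variances.

The sweep is JIT-compiled (numba); genotypes are centred by twice the
training allele frequency, and centring/frequencies are stored with the
result so prediction uses the training-fold centring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import CODING_DOSAGE, CODING_PM10, GenotypeMatrix
from .deregress import DebvTable


@dataclass(frozen=True)
class BayesConfig:
    """Sampler settings.  Defaults follow the production chain schedule;
    tests and desk-scale runs pass scaled-down chains."""

    method: str = "BayesC"              # "BayesB" | "BayesC"
    pi: float = 0.995                   # prior P(marker effect == 0)
    chain_length: int = 110_000
    burn_in: int = 10_000
    thin: int = 10
    nu_effects: float = 4.2             # prior df for marker-effect variance
    nu_residual: float = 4.0
    target_genetic_variance: float | None = None  # default: 0.5 * var(y)
    fix_sigma_u: float | None = None    # fixed common effect variance (testing)
    fix_sigma_e: float | None = None    # fixed residual variance (testing)
    seed: int = 0
    store_samples: bool = True          # keep thinned effect vectors (float32)

    def __post_init__(self):
        if self.method not in ("BayesB", "BayesC"):
            raise ValueError("method must be BayesB or BayesC")
        if not 0.0 <= self.pi < 1.0:
            raise ValueError("pi must be in [0, 1)")
        if self.burn_in >= self.chain_length or self.thin < 1:
            raise ValueError("invalid chain schedule")

    @property
    def n_retained(self) -> int:
        """Retained posterior samples: every thin-th draw after burn-in."""
        return int(np.ceil((self.chain_length - self.burn_in) / self.thin))


@dataclass
class McmcResult:
    """Posterior summaries and (optionally) thinned effect samples."""

    config: BayesConfig
    snp_ids: np.ndarray
    animal_ids: list[str]
    posterior_mean_mu: float
    effects: np.ndarray            # posterior mean u_j * delta_j (dosage012 scale)
    model_freq: np.ndarray         # mean of delta_j over retained samples
    sigma_u_samples: np.ndarray    # common (BayesC) / locus-mean (BayesB) variance
    sigma_e_samples: np.ndarray
    allele_freq: np.ndarray        # training allele frequencies (centring)
    effect_samples: np.ndarray | None = None  # (n_retained, k) float32
    coding: str = CODING_DOSAGE

    @property
    def n_retained(self) -> int:
        return len(self.sigma_e_samples)


@njit(cache=True)
def _gibbs(Z, y, w, pi, bayesb, chain, burnin, thin, nu_u, scale_u, nu_e,
           scale_e, fix_u, fix_e, sig_u0, sig_e0, seed, store):
    """Single-site Gibbs sweep.  Z is (k, n) centred, row-contiguous."""
    np.random.seed(seed)
    k, n = Z.shape
    n_ret = (chain - burnin + thin - 1) // thin

    zw = np.empty((k, n))
    zdz = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            zw[j, i] = Z[j, i] * w[i]
            s += w[i] * Z[j, i] * Z[j, i]
        zdz[j] = s
    sw = w.sum()

    u = np.zeros(k)
    delta = np.zeros(k, dtype=np.uint8)
    sig_uj = np.full(k, sig_u0)   # per-locus (BayesB); [0] doubles as common
    sig_u = sig_u0
    sig_e = sig_e0
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= sw
    e = y - mu  # residual vector (u = 0 initially)

    delta_sum = np.zeros(k)
    u_mean = np.zeros(k)
    mu_sum = 0.0
    sig_u_out = np.empty(n_ret)
    sig_e_out = np.empty(n_ret)
    samples = np.zeros((n_ret if store else 1, k), dtype=np.float32)

    log_prior_odds = np.log((1.0 - pi) / pi) if pi > 0.0 else np.inf
    ridx = 0
    for it in range(chain):
        # (1) overall mean
        r = 0.0
        for i in range(n):
            r += w[i] * (e[i] + mu)
        mu_new = r / sw + np.random.normal() * np.sqrt(sig_e / sw)
        dmu = mu - mu_new
        for i in range(n):
            e[i] += dmu
        mu = mu_new

        # (2) per-locus indicator and effect
        for j in range(k):
            uj = u[j]
            rhs = zdz[j] * uj
            for i in range(n):
                rhs += zw[j, i] * e[i]
            var_u = sig_uj[j] if bayesb else sig_u
            C = zdz[j] + sig_e / var_u
            if pi > 0.0:
                log_odds = log_prior_odds + 0.5 * (
                    np.log(sig_e / (var_u * C)) + rhs * rhs / (C * sig_e))
                if log_odds > 35.0:
                    inc = True
                elif log_odds < -35.0:
                    inc = False
                else:
                    inc = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
            else:
                inc = True
            if inc:
                unew = rhs / C + np.random.normal() * np.sqrt(sig_e / C)
                delta[j] = 1
            else:
                unew = 0.0
                delta[j] = 0
            d = unew - uj
            if d != 0.0:
                for i in range(n):
                    e[i] -= Z[j, i] * d
                u[j] = unew

        # (3) effect variances
        if fix_u <= 0.0:
            if bayesb:
                for j in range(k):
                    if delta[j] == 1:
                        sig_uj[j] = (nu_u * scale_u + u[j] * u[j]) / np.random.chisquare(nu_u + 1.0)
                    else:
                        sig_uj[j] = nu_u * scale_u / np.random.chisquare(nu_u)
            else:
                m = 0
                ssu = 0.0
                for j in range(k):
                    if delta[j] == 1:
                        m += 1
                        ssu += u[j] * u[j]
                sig_u = (nu_u * scale_u + ssu) / np.random.chisquare(nu_u + m)

        # (4) residual variance (weighted SSE)
        if fix_e <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += w[i] * e[i] * e[i]
            sig_e = (sse + nu_e * scale_e) / np.random.chisquare(n + nu_e)
            if not np.isfinite(sig_e) or sig_e <= 0.0:
                raise ValueError("residual variance diverged during sampling")

        if it >= burnin and (it - burnin) % thin == 0:
            for j in range(k):
                delta_sum[j] += delta[j]
                u_mean[j] += u[j]
            mu_sum += mu
            if bayesb:
                s = 0.0
                for j in range(k):
                    s += sig_uj[j]
                sig_u_out[ridx] = s / k
            else:
                sig_u_out[ridx] = sig_u
            sig_e_out[ridx] = sig_e
            if store:
                for j in range(k):
                    samples[ridx, j] = np.float32(u[j])
            ridx += 1

    model_freq = delta_sum / n_ret
    post_u = u_mean / n_ret
    return post_u, model_freq, mu_sum / n_ret, sig_u_out, sig_e_out, samples


def _prepare_response(genotypes: GenotypeMatrix, debv_table: DebvTable):
    t = debv_table.table
    geno_index = {a: i for i, a in enumerate(genotypes.animal_ids)}
    missing = [a for a in t["animal"] if a not in geno_index]
    if missing:
        raise ValueError(f"DEBV animals without genotypes: {missing[:5]}")
    rows = np.array([geno_index[a] for a in t["animal"]])
    return rows, t["debv"].to_numpy(dtype=float), t["weight"].to_numpy(dtype=float)


def fit_bayes(genotypes: GenotypeMatrix, debv_table: DebvTable,
              config: BayesConfig) -> McmcResult:
    """Fit weighted BayesB/BayesC to DEBV responses.

    Genotypes must be complete (post-QC); animals in the DEBV table must be
    a subset of the genotyped animals.  Returns posterior means, model
    frequencies, variance samples, and (by default) thinned effect samples
    for window variance partitioning.
    """
    if np.any(genotypes.calls == -1):
        raise ValueError("genotypes contain missing calls; apply QC/fill first")
    rows, y, w = _prepare_response(genotypes, debv_table)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    G = genotypes.calls[rows].astype(np.float64)
    p = G.mean(axis=0) / 2.0  # training allele frequency
    Z = np.ascontiguousarray((G - 2.0 * p).T)  # (k, n)

    k, n = Z.shape
    vary = float(np.var(y))
    target_var = config.target_genetic_variance or 0.5 * vary
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    if sum2pq <= 0:
        raise ValueError("all SNPs monomorphic in training set")
    var_u = target_var / ((1.0 - config.pi) * sum2pq)
    scale_u = var_u * (config.nu_effects - 2.0) / config.nu_effects
    resid_target = max(vary - target_var, 0.1 * vary)
    scale_e = resid_target * (config.nu_residual - 2.0) / config.nu_residual

    sig_u0 = config.fix_sigma_u if config.fix_sigma_u else var_u
    sig_e0 = config.fix_sigma_e if config.fix_sigma_e else resid_target

    post_u, model_freq, mu, sig_u_s, sig_e_s, samples = _gibbs(
        Z, np.asarray(y, float), np.asarray(w, float), float(config.pi),
        config.method == "BayesB", config.chain_length, config.burn_in,
        config.thin, float(config.nu_effects), float(scale_u),
        float(config.nu_residual), float(scale_e),
        float(config.fix_sigma_u or 0.0), float(config.fix_sigma_e or 0.0),
        float(sig_u0), float(sig_e0), int(config.seed) % (2**31),
        bool(config.store_samples))

    return McmcResult(
        config=config, snp_ids=genotypes.markers.snp_ids,
        animal_ids=[genotypes.animal_ids[i] for i in rows],
        posterior_mean_mu=float(mu), effects=post_u, model_freq=model_freq,
        sigma_u_samples=sig_u_s, sigma_e_samples=sig_e_s, allele_freq=p,
        effect_samples=samples if config.store_samples else None)


def convert_effects(effects: np.ndarray, src: str, dst: str) -> np.ndarray:
    """Rescale marker effects between genotype coding conventions.

    The pm10 design matrix is 10x the dosage design, so effects scale by
    1/10 going dosage -> pm10 (and 10x back); predictions are invariant.
    """
    if src == dst:
        return np.asarray(effects, float).copy()
    if (src, dst) == (CODING_DOSAGE, CODING_PM10):
        return np.asarray(effects, float) / 10.0
    if (src, dst) == (CODING_PM10, CODING_DOSAGE):
        return np.asarray(effects, float) * 10.0
    raise ValueError(f"unknown coding conversion {src!r} -> {dst!r}")


def predict_mbv(result_or_effects, genotypes: GenotypeMatrix,
                allele_freq: np.ndarray | None = None,
                coding: str | None = None) -> np.ndarray:
    """Molecular breeding values MBV_i = sum_j (Z_ij - 2 p_j) u_j.

    Centring uses the training allele frequencies recorded with the fit (or
    passed explicitly).  Effects may be on either coding scale if the
    convention is declared; they are converted to the dosage scale.
    """
    if isinstance(result_or_effects, McmcResult):
        effects = result_or_effects.effects
        allele_freq = result_or_effects.allele_freq if allele_freq is None else allele_freq
        coding = result_or_effects.coding if coding is None else coding
    else:
        effects = np.asarray(result_or_effects, dtype=float)
        if coding is None:
            raise ValueError("coding convention must be declared with raw effect vectors")
    effects = convert_effects(effects, coding, CODING_DOSAGE)
    if len(effects) != genotypes.n_snps:
        raise ValueError("effect vector length != SNP count")
    Z = genotypes.dosage(impute_mean=True)
    if allele_freq is None:
        allele_freq = Z.mean(axis=0) / 2.0
    return (Z - 2.0 * np.asarray(allele_freq)) @ effects
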