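"""Synthetic pedigree, genotype, trait and EBV generators.

The generators reproduce the statistical structure the downstream stages
assume: a multi-generation random-mating pedigree, unlinked biallelic SNPs
gene-dropped from Hardy-Weinberg founders, traits with a mixture genetic
architecture (a fraction pi of markers has exactly zero effect), and EBV
records whose reliability r2 has its textbook meaning cor(EBV, TBV)^2 = r2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, EbvTable, GenotypeMatrix, MarkerMap, Pedigree


@dataclass
class TrueTrait:
    """Ground truth for a simulated trait."""

    effects: np.ndarray       # per-SNP substitution effect u_j (0 where null)
    null_mask: np.ndarray     # True where delta_j = 0
    tbv: np.ndarray           # true breeding values Z_c @ u, per genotyped animal
    phenotypes: np.ndarray    # y = TBV + e
    animal_ids: list[str]
    pi: float
    h2: float
    sigma_a2: float
    sigma_e2: float
    seed: int


def simulate_pedigree(n_founders: int, n_generations: int,
                      offspring_per_mating: int, seed: int) -> Pedigree:
    """Random-mating pedigree with non-overlapping generations.

    Founders are paired at random (no selfing); each pair leaves
    ``offspring_per_mating`` offspring, and each later generation mates the
    same way.  If a generation has an odd size one animal is left unmated.
    """
    if n_founders < 2 or n_founders % 2:
        raise ValueError("n_founders must be even and >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    current = [f"G0_{i:05d}" for i in range(n_founders)]
    rows += [(a, "0", "0") for a in current]
    for g in range(1, n_generations + 1):
        perm = rng.permutation(len(current))
        nxt = []
        counter = 0
        for p in range(len(current) // 2):
            sire = current[perm[2 * p]]
            dam = current[perm[2 * p + 1]]
            for _ in range(offspring_per_mating):
                child = f"G{g}_{counter:05d}"
                counter += 1
                rows.append((child, sire, dam))
                nxt.append(child)
        current = nxt
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))


def _sequential_map(n_snps: int, n_chromosomes: int, spacing_bp: int) -> MarkerMap:
    per = int(np.ceil(n_snps / n_chromosomes))
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), per)[:n_snps]
    pos = np.concatenate([
        1 + spacing_bp * np.arange(np.sum(chrom == c)) for c in range(1, n_chromosomes + 1)
        if np.any(chrom == c)
    ])
    snp = np.array([f"SNP{i:06d}" for i in range(n_snps)])
    return MarkerMap(pd.DataFrame({"snp_id": snp, "chromosome": chrom, "position_bp": pos}))


def gene_drop_genotypes(pedigree: Pedigree, n_snps: int, maf_low: float = 0.05,
                        maf_high: float = 0.5, seed: int = 0,
                        n_chromosomes: int = 10,
                        spacing_bp: int = 100_000) -> GenotypeMatrix:
    """Drop unlinked biallelic loci through the pedigree.

    Founder allele frequencies are uniform on [maf_low, maf_high]; founders
    are in Hardy-Weinberg proportions and offspring receive one allele per
    parent with transmission probability g/2 (Mendelian sampling at unlinked
    loci).  Map positions are laid out sequentially, ``spacing_bp`` apart,
    across ``n_chromosomes`` chromosomes.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("founder MAF range must satisfy 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    calls = np.empty((n, n_snps), dtype=np.int8)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            calls[i] = rng.binomial(2, p).astype(np.int8)
        else:
            pat = (rng.binomial(1, calls[s] / 2.0) if s >= 0
                   else rng.binomial(1, p)).astype(np.int8)
            mat = (rng.binomial(1, calls[d] / 2.0) if d >= 0
                   else rng.binomial(1, p)).astype(np.int8)
            calls[i] = pat + mat
    markers = _sequential_map(n_snps, n_chromosomes, spacing_bp)
    return GenotypeMatrix(pedigree.animals, markers, calls)


def simulate_trait(genotypes: GenotypeMatrix, pi: float, h2: float, seed: int,
                   sigma_a2: float = 1.0,
                   planted_window: str | None = None,
                   planted_share: float = 0.0,
                   planted_n_causal: int = 5) -> TrueTrait:
    """Mixture-architecture trait: delta_j ~ Bern(1-pi), u_j ~ N(0, s2).

    Non-null effects are rescaled so the realised var(Z_c u) equals
    sigma_a2 exactly; residuals realise the requested h2.  Optionally a
    1-Mb window can be "planted" with ``planted_n_causal`` causal SNPs
    jointly explaining ``planted_share`` of the genetic variance, for
    window-GWAS power studies.
    """
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must be in [0, 1)")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = genotypes.n_snps
    z = genotypes.dosage(impute_mean=True)
    zc = z - z.mean(axis=0)

    if planted_window is not None:
        from .windows import assign_windows
        win = assign_windows(genotypes.markers)
        in_win = np.flatnonzero(win == planted_window)
        if len(in_win) == 0:
            raise ValueError(f"no SNPs in window {planted_window!r}")
        if not 0.0 < planted_share < 1.0:
            raise ValueError("planted_share must be in (0, 1)")
    else:
        in_win = np.array([], dtype=int)

    for attempt in range(2):
        null_mask = rng.random(k) < pi
        if planted_window is not None:
            null_mask[in_win] = True  # background nulls inside the window
            chosen = rng.choice(in_win, size=min(planted_n_causal, len(in_win)), replace=False)
            null_mask[chosen] = False
        if not null_mask.all():
            break
    else:
        raise ValueError("all-null effect draw twice; increase k or lower pi")

    u = np.zeros(k)
    u[~null_mask] = rng.standard_normal(np.count_nonzero(~null_mask))

    def _scale(idx: np.ndarray, target_var: float) -> None:
        g = zc[:, idx] @ u[idx]
        v = g.var()
        if v > 0:
            u[idx] *= np.sqrt(target_var / v)

    if planted_window is not None and len(in_win):
        rest = np.setdiff1d(np.flatnonzero(~null_mask), in_win)
        _scale(np.intersect1d(np.flatnonzero(~null_mask), in_win), planted_share * sigma_a2)
        if len(rest):
            _scale(rest, (1.0 - planted_share) * sigma_a2)
    else:
        _scale(np.flatnonzero(~null_mask), sigma_a2)

    tbv = zc @ u
    sigma_e2 = sigma_a2 * (1.0 - h2) / h2
    y = tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=len(tbv))
    return TrueTrait(effects=u, null_mask=null_mask, tbv=tbv, phenotypes=y,
                     animal_ids=list(genotypes.animal_ids), pi=pi, h2=h2,
                     sigma_a2=sigma_a2, sigma_e2=sigma_e2, seed=seed)


def simulate_ebv_records(true_trait: TrueTrait, pedigree: Pedigree,
                         rel_low: float, rel_high: float, seed: int) -> EbvTable:
    """EBV records with heterogeneous reliability.

    Per animal: r2 ~ U(rel_low, rel_high); EBV = r2*TBV + eps with
    var(eps) = r2*(1-r2)*sigma_a2, so cor(EBV, TBV)^2 = r2 in expectation.
    Sire/dam EBVs (and reliabilities) are joined from the same table where
    the parent is itself genotyped; the parent average follows.
    """
    if not 0.0 < rel_low <= rel_high < 1.0:
        raise ValueError("need 0 < rel_low <= rel_high < 1")
    rng = np.random.default_rng(seed)
    ids = true_trait.animal_ids
    tbv = pd.Series(true_trait.tbv, index=ids)
    r2 = rng.uniform(rel_low, rel_high, size=len(ids))
    eps = rng.normal(0.0, np.sqrt(r2 * (1 - r2) * true_trait.sigma_a2))
    ebv = r2 * tbv.to_numpy() + eps
    t = pd.DataFrame({"animal": ids, "ebv": ebv, "rel": r2})
    ped = pedigree.table.set_index("animal")
    own = t.set_index("animal")
    sire = ped.reindex(ids)["sire"]
    dam = ped.reindex(ids)["dam"]
    if sire.isna().any():
        raise ValueError("animal missing from pedigree")
    t["sire_ebv"] = own["ebv"].reindex(sire).to_numpy()
    t["dam_ebv"] = own["ebv"].reindex(dam).to_numpy()
    t["sire_rel"] = own["rel"].reindex(sire).to_numpy()
    t["dam_rel"] = own["rel"].reindex(dam).to_numpy()
    return EbvTable(t)


def corrupt_for_qc(genotypes: GenotypeMatrix, frac_lowcall: float,
                   frac_lowmaf: float, frac_hwe_violating: float,
                   seed: int) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Inject the three QC failure modes into disjoint SNP subsets.

    Returns the corrupted matrix and a manifest {criterion: [snp ids]}.
    low call rate: 10% of calls set missing; low MAF: column resampled at
    p < 0.01; HWE violation: all calls heterozygous.
    """
    fracs = (frac_lowcall, frac_lowmaf, frac_hwe_violating)
    if any(f < 0 for f in fracs) or sum(fracs) > 0.5:
        raise ValueError("corruption fractions must be >= 0 and sum to <= 0.5")
    rng = np.random.default_rng(seed)
    n, k = genotypes.calls.shape
    calls = genotypes.calls.copy()
    counts = [int(round(f * k)) for f in fracs]
    chosen = rng.choice(k, size=sum(counts), replace=False)
    sets = np.split(chosen, np.cumsum(counts)[:-1])
    snp_ids = genotypes.markers.snp_ids
    manifest: dict[str, list[str]] = {}
    for j in sets[0]:
        n_miss = max(int(np.ceil(0.10 * n)), int(np.floor(0.05 * n)) + 1)
        rows = rng.choice(n, size=n_miss, replace=False)
        calls[rows, j] = MISSING
    manifest["low_call_rate"] = sorted(snp_ids[sets[0]].tolist())
    for j in sets[1]:
        # rare-allele column with sample MAF strictly below 0.01
        n_het = int(rng.integers(0, max(int(np.ceil(0.02 * n)) - 1, 0) + 1))
        col = np.zeros(n, dtype=np.int8)
        if n_het:
            col[rng.choice(n, size=n_het, replace=False)] = 1
        calls[:, j] = col
    manifest["low_maf"] = sorted(snp_ids[sets[1]].tolist())
    for j in sets[2]:
        calls[:, j] = 1  # complete heterozygote excess
    manifest["hwe_violation"] = sorted(snp_ids[sets[2]].tolist())
    return GenotypeMatrix(genotypes.animal_ids, genotypes.markers, calls,
                          genotypes.coding), manifest
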