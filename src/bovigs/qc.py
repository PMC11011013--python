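"""SNP quality control: per-SNP statistics and sequential filtering.

Filters mirror standard panel QC: drop unmapped/non-autosomal SNPs, then
call rate < 0.95, then MAF < 0.01, then Hardy-Weinberg equilibrium
p < 1e-4 ("below" thresholds are strict inequalities, so a SNP sitting
exactly on a threshold is retained).  Filters apply sequentially, so the
per-criterion removal counts sum to the total removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DEFAULT_AUTOSOMES, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    call_rate: float = 0.95
    maf: float = 0.01
    hwe_p: float = 1e-4

    def __post_init__(self):
        if not (0 <= self.call_rate <= 1 and 0 <= self.maf <= 0.5 and 0 <= self.hwe_p <= 1):
            raise ValueError("QC thresholds out of range")


@dataclass
class QcReport:
    """Per-criterion removal counts, in application order, plus the removed SNPs."""

    removed_by: dict[str, int]
    removed_snps: pd.DataFrame  # columns: snp_id, criterion
    n_input: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by.values())

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "removed_by": dict(self.removed_by)}


def hwe_chisq_p(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Pearson chi-square (1 df) HWE test on genotype counts.

    Monomorphic SNPs fit HWE exactly (p = 1); SNPs with zero non-missing
    calls return NaN.
    """
    n0 = np.asarray(n0, float); n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 = chi2 + term
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p == 0) | (p == 1)
    pval = np.where(mono, 1.0, pval)
    return np.where(n == 0, np.nan, pval)


def compute_snp_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP genotype counts, call rate, MAF and HWE p-value.

    MAF is computed on non-missing calls; a SNP with no calls gets
    call_rate 0 and NaN maf/hwe_p (filterable but undefined).
    """
    if genotypes.n_animals < 1:
        raise ValueError("need at least one animal")
    c = genotypes.calls
    n_animals = c.shape[0]
    n0 = (c == 0).sum(axis=0)
    n1 = (c == 1).sum(axis=0)
    n2 = (c == 2).sum(axis=0)
    n = n0 + n1 + n2
    call_rate = n / n_animals
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
    maf = np.where(n > 0, np.minimum(p, 1 - p), np.nan)
    hwe_p = hwe_chisq_p(n0, n1, n2)
    return pd.DataFrame({
        "snp_id": genotypes.markers.snp_ids,
        "chromosome": genotypes.markers.chromosomes,
        "n0": n0, "n1": n1, "n2": n2, "n_missing": n_animals - n,
        "call_rate": call_rate, "maf": maf, "hwe_p": hwe_p,
    })


def apply_qc(genotypes: GenotypeMatrix,
             thresholds: QcThresholds = QcThresholds(),
             autosomes=DEFAULT_AUTOSOMES) -> tuple[GenotypeMatrix, QcReport]:
    """Sequentially filter SNPs: map -> call rate -> MAF -> HWE."""
    stats_df = compute_snp_stats(genotypes)
    k = genotypes.n_snps
    keep = np.ones(k, dtype=bool)
    removed: list[tuple[str, str]] = []
    counts: dict[str, int] = {}

    def _drop(mask: np.ndarray, criterion: str) -> None:
        mask = mask & keep
        counts[criterion] = int(mask.sum())
        for s in stats_df.loc[mask, "snp_id"]:
            removed.append((s, criterion))
        keep[mask] = False

    chrom = stats_df["chromosome"].to_numpy()
    _drop(~np.isin(chrom, list(autosomes)), "unmapped_or_non_autosomal")
    cr = stats_df["call_rate"].to_numpy()
    _drop(cr < thresholds.call_rate, "call_rate")
    maf = stats_df["maf"].to_numpy()
    _drop(np.isnan(maf) | (maf < thresholds.maf), "maf")
    hwe = stats_df["hwe_p"].to_numpy()
    _drop(np.isnan(hwe) | (hwe < thresholds.hwe_p), "hwe")

    if not keep.any():
        raise ValueError("QC removed every SNP; review thresholds or input data")
    filtered = genotypes.subset(snp_mask=keep)
    report = QcReport(removed_by=counts,
                      removed_snps=pd.DataFrame(removed, columns=["snp_id", "criterion"]),
                      n_input=k, n_retained=int(keep.sum()))
    return filtered, report
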