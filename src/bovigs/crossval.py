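"""Pedigree relationship matrix, relatedness-minimising folds, and CV accuracy.

The numerator relationship matrix (NRM) is built by the tabular recursion
with inbreeding on the diagonal.  Fold construction converts the NRM into a
distance d_ij = 1 - a_ij / sqrt(a_ii a_jj), embeds it by classical
multidimensional scaling, and runs Lloyd K-means with restarts, so that
validation animals are less related to the training set than random folds
would be.  Genomic prediction accuracy is the Pearson correlation between
predicted molecular breeding values and the DEBV response in each
validation fold, averaged over folds with an across-fold standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .bayes import BayesConfig, fit_bayes, predict_mbv
from .datatypes import GenotypeMatrix, Pedigree
from .deregress import DebvTable

log = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    animal_ids: list[str]
    a: np.ndarray  # symmetric, diagonal 1 + F

    def __post_init__(self):
        if self.a.shape != (len(self.animal_ids),) * 2:
            raise ValueError("matrix shape mismatch")

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.a) - 1.0

    def submatrix(self, animals) -> "RelationshipMatrix":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = np.array([idx[a] for a in animals])
        return RelationshipMatrix(list(animals), self.a[np.ix_(rows, rows)])


@dataclass
class ClusterAssignment:
    animal_ids: list[str]
    fold: np.ndarray  # 1..k per animal

    @property
    def k(self) -> int:
        return int(self.fold.max())

    def sizes(self) -> dict[int, int]:
        vals, cnt = np.unique(self.fold, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def members(self, f: int) -> list[str]:
        return [a for a, g in zip(self.animal_ids, self.fold) if g == f]


@dataclass
class AccuracyResult:
    fold_accuracy: dict[int, float]
    mean_accuracy: float
    standard_error: float


def build_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular (recursive) NRM with inbreeding.

    a_ij = 0.5 (a_sj + a_dj) for j preceding i; a_ii = 1 + 0.5 a_sd.
    The pedigree is topologically sorted on construction, so each row only
    references earlier rows.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * a[s, :i]
            if d >= 0:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(pedigree.animals, a)


def _mds_embed(dist: np.ndarray, var_target: float = 0.9, max_dim: int = 20) -> np.ndarray:
    """Classical MDS: top components covering >= var_target of the positive
    eigenvalue mass, capped at max_dim."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    if not pos.any():
        return np.zeros((n, 1))
    vals_p, vecs_p = vals[pos], vecs[:, pos]
    csum = np.cumsum(vals_p) / vals_p.sum()
    m = min(int(np.searchsorted(csum, var_target) + 1), max_dim, len(vals_p))
    return vecs_p[:, :m] * np.sqrt(vals_p[:m])


def kmeans_folds(rel: RelationshipMatrix, k: int = 5, seed: int = 0,
                 restarts: int = 25) -> ClusterAssignment:
    """Relatedness-minimising folds via MDS embedding + Lloyd K-means."""
    n = len(rel.animal_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than animals")
    d = np.diag(rel.a)
    dist = 1.0 - rel.a / np.sqrt(np.outer(d, d))
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    x = _mds_embed(dist)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**31))
    labels = km.fit_predict(x)
    return ClusterAssignment(list(rel.animal_ids), labels.astype(int) + 1)


def cluster_relatedness_stats(rel: RelationshipMatrix,
                              assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-fold relatedness diagnostics plus an unweighted "Avg." row.

    Per fold: n, inBreC (mean inbreeding), a_max_within / a_max_between
    (mean over members of each member's maximum relationship to another
    member / to any non-member), a_ij_within / a_ij_between (mean pairwise
    relationship within the fold / across to all non-members).  Singleton
    folds report NaN within-fold statistics.
    """
    idx = {a: i for i, a in enumerate(rel.animal_ids)}
    a = rel.a
    f_coef = rel.inbreeding()
    rows = []
    for f in sorted(set(assignment.fold.tolist())):
        members = np.array([idx[m] for m in assignment.members(f)])
        others = np.setdiff1d(np.arange(len(rel.animal_ids)), members)
        sub = a[np.ix_(members, members)]
        off = sub[~np.eye(len(members), dtype=bool)]
        if len(members) > 1:
            masked = np.where(np.eye(len(members), dtype=bool), -np.inf, sub)
            amax_w = float(masked.max(axis=1).mean())
            aij_w = float(off.mean())
        else:
            amax_w, aij_w = np.nan, np.nan
            log.info("fold %d is a singleton; within-fold stats undefined", f)
        if len(others):
            cross = a[np.ix_(members, others)]
            amax_b = float(cross.max(axis=1).mean())
            aij_b = float(cross.mean())
        else:
            amax_b, aij_b = np.nan, np.nan
        rows.append({"fold": f, "n": len(members),
                     "inBreC": float(f_coef[members].mean()),
                     "a_max_within": amax_w, "a_max_between": amax_b,
                     "a_ij_within": aij_w, "a_ij_between": aij_b})
    t = pd.DataFrame(rows)
    avg = summarize_cluster_stats(t)
    avg_row = {"fold": "Avg.", "n": int(t["n"].sum()), **avg}
    return pd.concat([t, pd.DataFrame([avg_row])], ignore_index=True)


def summarize_cluster_stats(per_fold: pd.DataFrame) -> dict[str, float]:
    """Unweighted across-fold averages of the relatedness diagnostics."""
    cols = ["inBreC", "a_max_within", "a_max_between", "a_ij_within", "a_ij_between"]
    return {c: float(per_fold[c].mean()) for c in cols if c in per_fold.columns}


def run_cv(genotypes: GenotypeMatrix, debv_table: DebvTable,
           assignment: ClusterAssignment, config: BayesConfig) -> AccuracyResult:
    """K-fold CV accuracy: train on out-of-fold animals, correlate predicted
    MBV with the DEBV response inside the fold.  Per-fold chains are seeded
    as config.seed + fold index."""
    t = debv_table.table
    fold_of = dict(zip(assignment.animal_ids, assignment.fold.tolist()))
    missing = [a for a in t["animal"] if a not in fold_of]
    if missing:
        raise ValueError(f"animals without fold assignment: {missing[:5]}")
    folds = sorted(set(assignment.fold.tolist()))
    acc: dict[int, float] = {}
    for f in folds:
        in_fold = t["animal"].map(fold_of) == f
        train_tab = DebvTable(t.loc[~in_fold].reset_index(drop=True), debv_table.mode)
        val_tab = t.loc[in_fold]
        if len(train_tab.table) == 0 or len(val_tab) == 0:
            raise ValueError(f"fold {f} leaves an empty training or validation set")
        cfg = BayesConfig(**{**config.__dict__, "seed": config.seed + f,
                             "store_samples": False})
        fit = fit_bayes(genotypes, train_tab, cfg)
        val_geno = genotypes.subset(animals=val_tab["animal"].tolist())
        mbv = predict_mbv(fit, val_geno)
        debv = val_tab["debv"].to_numpy(dtype=float)
        if np.std(mbv) == 0 or np.std(debv) == 0:
            log.warning("fold %d: constant MBV or DEBV; accuracy undefined", f)
            acc[f] = np.nan
            continue
        acc[f] = float(np.corrcoef(mbv, debv)[0, 1])
    vals = np.array([v for v in acc.values() if np.isfinite(v)])
    if len(vals) == 0:
        raise ValueError("no fold produced a defined accuracy")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return AccuracyResult(fold_accuracy=acc, mean_accuracy=mean, standard_error=se)
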