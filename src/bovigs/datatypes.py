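"""Domain types shared by every stage of the pipeline.

Genotypes are held as additive allele counts (0/1/2, the ``dosage012``
convention) with ``-1`` marking a missing call.  The GenSel-style -10/0/10
convention (``gensel_pm10``) is supported as an input/output dialect via the
exact affine map g -> 10*(g - 1); marker-effect estimates scale by 1/10
between the two conventions while predicted breeding values are invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # internal missing-genotype sentinel (dosage012 scale)
UNKNOWN_PARENT = "0"
DEFAULT_AUTOSOMES = tuple(range(1, 30))  # Bos taurus autosomes BTA1..BTA29

CODING_DOSAGE = "dosage012"
CODING_PM10 = "gensel_pm10"


def convert_calls(calls: np.ndarray, src: str, dst: str) -> np.ndarray:
    """Convert a genotype-call array between coding conventions.

    The map dosage012 -> gensel_pm10 is g -> 10*(g-1); the missing sentinel
    -1 maps to -20 and back, so the conversion round-trips exactly.
    """
    if src == dst:
        return calls.copy()
    arr = calls.astype(np.int16)
    if (src, dst) == (CODING_DOSAGE, CODING_PM10):
        return (10 * (arr - 1)).astype(np.int16)
    if (src, dst) == (CODING_PM10, CODING_DOSAGE):
        if np.any((arr % 10) != 0):
            raise ValueError("calls are not on the -10/0/10 grid")
        return (arr // 10 + 1).astype(np.int16)
    raise ValueError(f"unknown coding conversion {src!r} -> {dst!r}")


@dataclass
class MarkerMap:
    """SNP id, chromosome and 1-based bp position for each marker.

    Stored sorted by (chromosome, position); chromosome 0 means unmapped.
    """

    table: pd.DataFrame  # columns: snp_id, chromosome, position_bp

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp_id", "chromosome", "position_bp"]
        missing_cols = [c for c in required if c not in t.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns {missing_cols}")
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp ids in map: {dups[:5]}")
        if (t["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1")
        self.table = (
            t[required]
            .astype({"snp_id": str, "chromosome": int, "position_bp": int})
            .sort_values(["chromosome", "position_bp"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()


@dataclass
class GenotypeMatrix:
    """Animals x SNPs additive genotype calls tied to a marker map.

    ``calls`` is integer-coded on the dosage012 scale with -1 for missing,
    regardless of the dialect the data were read from; ``coding`` records
    that source dialect for writers.
    """

    animal_ids: list[str]
    markers: MarkerMap
    calls: np.ndarray
    coding: str = CODING_DOSAGE

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (animals x SNPs)")
        n, k = self.calls.shape
        if n != len(self.animal_ids):
            raise ValueError("row count != number of animal ids")
        if k != len(self.markers):
            raise ValueError("column count != map length")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls outside {0,1,2,missing}")

    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def calls_in_coding(self, coding: str) -> np.ndarray:
        return convert_calls(self.calls, CODING_DOSAGE, coding) if coding != CODING_DOSAGE else self.calls.copy()

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Float dosage matrix; missing as NaN or column-mean imputed."""
        z = self.calls.astype(np.float64)
        z[self.calls == MISSING] = np.nan
        if impute_mean:
            col_mean = np.nanmean(z, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(z))
            z[idx] = col_mean[idx[1]]
        return z

    def subset(self, animals=None, snp_mask=None) -> "GenotypeMatrix":
        calls = self.calls
        ids = self.animal_ids
        mmap = self.markers
        if animals is not None:
            index = {a: i for i, a in enumerate(self.animal_ids)}
            rows = [index[a] for a in animals]
            calls = calls[rows]
            ids = list(animals)
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            calls = calls[:, snp_mask]
            mmap = MarkerMap(self.markers.table.loc[snp_mask].reset_index(drop=True))
        return GenotypeMatrix(ids, mmap, calls, self.coding)


class PedigreeCycleError(ValueError):
    """Raised when an animal is (transitively) its own ancestor."""


@dataclass
class Pedigree:
    """(animal, sire, dam) records, topologically sorted on construction.

    Unknown parents carry the sentinel "0".  A parent that appears only in a
    sire/dam column is implicitly added as a founder (with a warning).
    """

    table: pd.DataFrame = field(repr=False)  # columns: animal, sire, dam

    def __post_init__(self) -> None:
        t = self.table[["animal", "sire", "dam"]].astype(str).copy()
        t = t.replace({"sire": {"": UNKNOWN_PARENT, "nan": UNKNOWN_PARENT},
                       "dam": {"": UNKNOWN_PARENT, "nan": UNKNOWN_PARENT}})
        if t["animal"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        known = set(t["animal"])
        phantoms = []
        for col in ("sire", "dam"):
            for p in t[col]:
                if p != UNKNOWN_PARENT and p not in known:
                    phantoms.append(p)
                    known.add(p)
        if phantoms:
            log.warning("pedigree: %d parents never defined; added as founders", len(phantoms))
            extra = pd.DataFrame({"animal": sorted(set(phantoms)),
                                  "sire": UNKNOWN_PARENT, "dam": UNKNOWN_PARENT})
            t = pd.concat([extra, t], ignore_index=True)
        self.table = self._toposort(t)

    @staticmethod
    def _toposort(t: pd.DataFrame) -> pd.DataFrame:
        """Kahn's algorithm; parents precede offspring. Cycles are fatal."""
        animals = t["animal"].tolist()
        idx = {a: i for i, a in enumerate(animals)}
        sire = t["sire"].tolist()
        dam = t["dam"].tolist()
        n = len(animals)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p != UNKNOWN_PARENT:
                    if p == animals[i]:
                        raise PedigreeCycleError(f"animal {animals[i]} is its own parent")
                    children[idx[p]].append(i)
                    indeg[i] += 1
        order: list[int] = []
        queue = [i for i in range(n) if indeg[i] == 0]
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < n:
            cyc = [animals[i] for i in range(n) if indeg[i] > 0]
            raise PedigreeCycleError(f"pedigree contains a cycle involving: {cyc}")
        # stable order: generation depth, input position breaking ties, so an
        # already-sorted pedigree round-trips unchanged
        depth = np.zeros(n, dtype=int)
        for i in order:
            for p in (sire[i], dam[i]):
                if p != UNKNOWN_PARENT:
                    depth[i] = max(depth[i], depth[idx[p]] + 1)
        final = np.argsort(depth, kind="stable")
        return t.iloc[final].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def animals(self) -> list[str]:
        return self.table["animal"].tolist()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row indices in topological order; -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.animals)}
        sire = np.array([pos.get(s, -1) if s != UNKNOWN_PARENT else -1
                         for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) if d != UNKNOWN_PARENT else -1
                        for d in self.table["dam"]], dtype=np.int64)
        return sire, dam

    def founders(self) -> list[str]:
        t = self.table
        m = (t["sire"] == UNKNOWN_PARENT) & (t["dam"] == UNKNOWN_PARENT)
        return t.loc[m, "animal"].tolist()


@dataclass(frozen=True)
class TraitParams:
    """Variance components and derived parameters for one trait.

    c is the fraction of genetic variance not captured by the markers, used
    by the deregression weighting (default 0.4).
    """

    trait_code: str
    sigma_a2: float
    sigma_e2: float
    c: float = 0.4

    def __post_init__(self) -> None:
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must be in [0, 1]")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class EbvTable:
    """Per-animal EBV, reliability and (optional) parent information.

    Columns: animal, ebv, rel, and optionally sire_ebv/dam_ebv (plus
    sire_rel/dam_rel when known).  parent_average is derived and present
    only where both parent EBVs are.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("animal", "ebv", "rel"):
            if col not in t.columns:
                raise ValueError(f"EBV table missing column {col!r}")
        t["animal"] = t["animal"].astype(str)
        r = t["rel"].to_numpy(dtype=float)
        if np.any((r <= 0) | (r >= 1)):
            raise ValueError("reliabilities must lie strictly in (0, 1)")
        for col in ("sire_ebv", "dam_ebv", "sire_rel", "dam_rel"):
            if col not in t.columns:
                t[col] = np.nan
        both = t["sire_ebv"].notna() & t["dam_ebv"].notna()
        t["parent_average"] = np.where(both, (t["sire_ebv"] + t["dam_ebv"]) / 2.0, np.nan)
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DebvTable:
    """Deregressed EBVs with Garrick-style weights for one response mode."""

    table: pd.DataFrame  # columns: animal, debv, rel, weight
    mode: str  # "incPA" | "excPA"
    dropped: pd.DataFrame | None = None  # columns: animal, reason

    def __post_init__(self) -> None:
        if self.mode not in ("incPA", "excPA"):
            raise ValueError("mode must be incPA or excPA")
        w = self.table["weight"].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
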