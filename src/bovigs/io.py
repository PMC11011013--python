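"""Readers and writers for the plain-text interchange formats.

Genotypes: TSV matrix (rows = animals, columns = SNP ids, NA for missing)
or the PLINK ``.raw`` additive dialect (FID IID PAT MAT SEX PHENOTYPE then
one column per SNP).  Map: TSV (snp_id, chromosome, position_bp).
Pedigree: CSV (animal, sire, dam; unknown parent 0 or empty).  EBV table:
TSV (animal, ebv, rel[, sire_ebv, dam_ebv, sire_rel, dam_rel]).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CODING_DOSAGE,
    CODING_PM10,
    MISSING,
    EbvTable,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    convert_calls,
)

log = logging.getLogger(__name__)

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_map(path) -> MarkerMap:
    t = pd.read_csv(path, sep="\t")
    return MarkerMap(t)


def write_map(markers: MarkerMap, path) -> None:
    markers.table.to_csv(path, sep="\t", index=False)


def _parse_calls(frame: pd.DataFrame, coding: str, path) -> np.ndarray:
    vals = frame.to_numpy(dtype=object)
    flat = pd.to_numeric(pd.Series(vals.ravel()), errors="coerce").to_numpy()
    raw_na = pd.isna(vals.ravel())
    bad = np.isnan(flat) & ~raw_na
    if bad.any():
        i = int(np.argmax(bad))
        r, c = divmod(i, vals.shape[1])
        raise ValueError(f"{path}: non-numeric genotype at data row {r + 1}, column {frame.columns[c]!r}")
    allowed = {CODING_DOSAGE: (0, 1, 2), CODING_PM10: (-10, 0, 10)}[coding]
    ok = np.isnan(flat) | np.isin(flat, allowed)
    if not ok.all():
        i = int(np.argmax(~ok))
        r, c = divmod(i, vals.shape[1])
        raise ValueError(
            f"{path}: genotype {flat[i]!r} not in {allowed} or NA at data row {r + 1}, column {frame.columns[c]!r}"
        )
    calls = flat.reshape(vals.shape)
    out = np.where(np.isnan(calls), MISSING, calls).astype(np.int16)
    if coding == CODING_PM10:
        filled = np.where(np.isnan(calls), -20, calls).astype(np.int16)
        out = convert_calls(filled, CODING_PM10, CODING_DOSAGE)
    return out.astype(np.int8)


def read_genotypes(path, markers: MarkerMap, format_hint: str = "auto",
                   coding: str = CODING_DOSAGE) -> GenotypeMatrix:
    """Read a genotype table and align its SNP columns with the map.

    format_hint: "tsv" (animal-indexed matrix), "plink_raw", or "auto"
    (decided from the header).  SNP columns not present in the map are a
    hard error listing the offenders.
    """
    path = Path(path)
    sep = r"\s+" if path.suffix == ".raw" else "\t"
    t = pd.read_csv(path, sep=sep)
    fmt = format_hint
    if fmt == "auto":
        fmt = "plink_raw" if list(t.columns[:6]) == _PLINK_META else "tsv"
    if fmt == "plink_raw":
        ids = t["IID"].astype(str).tolist()
        snp_cols = [c for c in t.columns if c not in _PLINK_META]
        # PLINK .raw appends the counted allele as SNP_A; strip it
        stripped = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        frame = t[snp_cols]
        frame.columns = stripped
    else:
        first = t.columns[0]
        ids = t[first].astype(str).tolist()
        frame = t.drop(columns=[first])
    known = set(markers.snp_ids)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        raise ValueError(f"{path}: SNP ids absent from map: {unknown[:10]}"
                         + (" ..." if len(unknown) > 10 else ""))
    # align column order with the (sorted) map
    frame = frame[[s for s in markers.snp_ids if s in frame.columns]]
    if frame.shape[1] != len(markers):
        missing = sorted(known - set(frame.columns))
        raise ValueError(f"{path}: map SNPs missing from genotype file: {missing[:10]}")
    calls = _parse_calls(frame, coding, path)
    log.info("read %d animals x %d SNPs from %s (%s)", len(ids), frame.shape[1], path, fmt)
    return GenotypeMatrix(ids, markers, calls, coding=coding)


def write_genotypes(g: GenotypeMatrix, path, coding: str | None = None) -> None:
    coding = coding or g.coding
    calls = g.calls_in_coding(coding).astype(float)
    sentinel = MISSING if coding == CODING_DOSAGE else -20
    calls[calls == sentinel] = np.nan
    t = pd.DataFrame(calls, columns=g.markers.snp_ids)
    t.insert(0, "animal", g.animal_ids)
    t.to_csv(path, sep="\t", index=False, na_rep="NA",
             float_format="%.0f")


def read_pedigree(path) -> Pedigree:
    t = pd.read_csv(path, dtype=str, keep_default_na=False)
    t.columns = [c.lower() for c in t.columns]
    return Pedigree(t[["animal", "sire", "dam"]])


def write_pedigree(p: Pedigree, path) -> None:
    p.table.to_csv(path, index=False)


def read_ebv_table(path) -> EbvTable:
    t = pd.read_csv(path, sep="\t")
    return EbvTable(t)


def write_ebv_table(e: EbvTable, path) -> None:
    e.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene spans as (chromosome, start, end, symbol), 1-based inclusive.

    Accepts GFF3 (rows with type 'gene'; symbol from Name= or ID=) or a
    4-column TSV with a header.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                symbol = attrs.get("Name", attrs.get("ID", "NA"))
                rows.append((int(f[0]), int(f[3]), int(f[4]), symbol))
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "symbol"])
    t = pd.read_csv(path, sep="\t")
    return t[["chromosome", "start", "end", "symbol"]]
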