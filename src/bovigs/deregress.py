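"""Deregression of EBVs into response variables for marker regression.

Two response modes:

* ``incPA`` — the full EBV is deregressed by dividing by its reliability
  (DEBV = EBV / r2); re-regressing (multiplying by r2) recovers the EBV
  exactly.  The DEBV reliability used for weighting is the original r2.

* ``excPA`` — the parent-average (PA) contribution is removed first using
  the effective-record partition of EBV information into a PA source and an
  own-performance/progeny source.  With lambda = (1 - h2)/h2 and the 2x2
  pedigree inverse [[4, -2], [-2, 2]]*lambda linking the PA pseudo-animal
  and the individual, the unknown effective record counts follow from the
  two reliabilities:

      alpha  = 1 / (0.5 - r2_PA)
      delta  = (0.5 - r2_PA) / (1 - r2)
      n_PA   = lambda*(alpha/2 - 4) + (lambda/2)*sqrt(alpha^2 + 16/delta)
      n_own  = delta*n_PA + 2*lambda*(2*delta - 1)

  The deregressed own-information response is y* / n_own where
  y* = -2*lambda*PA + (n_own + 2*lambda)*EBV, with reliability
  r2_DEBV = n_own / (n_own + lambda).

Record weights account for heterogeneous DEBV reliability; the default
("garrick") reading is

    w = (1 - h2) / {[c + (1 - r2)/r2] * h2}

which increases with reliability.  A "flat" reading
w = (1 - h2)*[c + (1 - r2)/r2]/h2 is kept behind a switch for comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import DebvTable, EbvTable, TraitParams

log = logging.getLogger(__name__)

MODES = ("incPA", "excPA")
READINGS = ("garrick", "flat")


def compute_weight(h2: float, r2, c: float = 0.4, reading: str = "garrick"):
    """Eq.-style weighting factor for a DEBV record of reliability r2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    if c < 0:
        raise ValueError("c must be >= 0")
    r2 = np.asarray(r2, dtype=float)
    if np.any((r2 <= 0.0) | (r2 >= 1.0)):
        raise ValueError("r2 must lie strictly in (0, 1)")
    bracket = c + (1.0 - r2) / r2
    if reading == "garrick":
        w = (1.0 - h2) / (bracket * h2)
    elif reading == "flat":
        w = (1.0 - h2) * bracket / h2
    else:
        raise ValueError(f"unknown reading {reading!r}")
    return w if w.ndim else float(w)


def _garrick_exc_pa(ebv, pa, r2, r2_pa, h2):
    """Remove the PA information source from an EBV (vectorised).

    Returns (debv, r2_debv, ok_mask); animals whose EBV carries no own
    information beyond the PA (r2 <= r2_PA, or degenerate effective record
    counts) are flagged not-ok.
    """
    lam = (1.0 - h2) / h2
    r2_pa = np.clip(r2_pa, 1e-9, 0.5 - 1e-9)
    ok = r2 > r2_pa
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2)
    with np.errstate(invalid="ignore"):
        n_pa = lam * (alpha / 2.0 - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
        n_own = delta * n_pa + 2.0 * lam * (2.0 * delta - 1.0)
        ok &= np.isfinite(n_own) & (n_own > 0)
        y_star = -2.0 * lam * pa + (n_own + 2.0 * lam) * ebv
        debv = y_star / n_own
        r2_debv = n_own / (n_own + lam)
    return debv, r2_debv, ok


def deregress(ebv_table: EbvTable, trait_params: TraitParams, mode: str = "incPA",
              c: float | None = None, reading: str = "garrick",
              min_reliability: float = 1e-6) -> DebvTable:
    """Turn an EBV table into a DEBV response table with per-record weights.

    excPA requires a parent average; the PA reliability is
    (r2_sire + r2_dam)/4, taking an absent parent reliability equal to the
    animal's own (a neutral proxy when parent records are not in the table).
    Animals are dropped, with a reason, when the mode cannot produce a
    positive-information response for them.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    h2 = trait_params.h2
    c = trait_params.c if c is None else c
    t = ebv_table.table.copy()
    dropped: list[tuple[str, str]] = []

    if mode == "incPA":
        debv = t["ebv"] / t["rel"]
        rel = t["rel"].to_numpy(dtype=float)
        out = pd.DataFrame({"animal": t["animal"], "debv": debv, "rel": rel})
    else:
        has_pa = t["parent_average"].notna()
        for a in t.loc[~has_pa, "animal"]:
            dropped.append((a, "no_parent_average"))
        t = t.loc[has_pa].reset_index(drop=True)
        sire_rel = t["sire_rel"].fillna(t["rel"]).to_numpy(dtype=float)
        dam_rel = t["dam_rel"].fillna(t["rel"]).to_numpy(dtype=float)
        r2_pa = (sire_rel + dam_rel) / 4.0
        debv, rel, ok = _garrick_exc_pa(
            t["ebv"].to_numpy(dtype=float), t["parent_average"].to_numpy(dtype=float),
            t["rel"].to_numpy(dtype=float), r2_pa, h2)
        for a in t.loc[~ok, "animal"]:
            dropped.append((a, "no_own_information"))
        out = pd.DataFrame({"animal": t["animal"], "debv": debv, "rel": rel}).loc[ok]

    low = out["rel"] <= min_reliability
    for a in out.loc[low, "animal"]:
        dropped.append((a, "reliability_too_low"))
    out = out.loc[~low].reset_index(drop=True)
    if dropped:
        log.info("deregress(%s): dropped %d animals", mode, len(dropped))
    out["weight"] = compute_weight(h2, out["rel"].to_numpy(), c=c, reading=reading)
    return DebvTable(table=out, mode=mode,
                     dropped=pd.DataFrame(dropped, columns=["animal", "reason"]))
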