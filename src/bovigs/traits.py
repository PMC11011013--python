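"""Published variance components for Korean Holstein conformation traits.

Additive genetic (sigma_a2) and residual (sigma_e2) variances from the
national genetic evaluation; heritability is derived as
h2 = sigma_a2 / (sigma_a2 + sigma_e2).  These serve as realistic trait
parameter sets for simulation and for the deregression weighting.
"""

from __future__ import annotations

from .datatypes import TraitParams

# trait_code: (sigma_a2, sigma_e2)
_COMPONENTS: dict[str, tuple[float, float]] = {
    # body traits
    "ANG": (0.106, 0.777),
    "BCS": (0.109, 0.474),
    "BDE": (0.218, 0.605),
    "CWI": (0.124, 0.671),
    "HHE": (0.027, 0.302),
    "LOC": (0.027, 0.844),
    "OCS": (1.027, 5.599),
    "STA": (0.411, 0.873),
    # rump traits
    "LST": (0.075, 0.683),
    "RAN": (0.527, 1.190),
    "RWI": (0.164, 0.806),
    # feet and leg traits
    "BQL": (0.064, 0.529),
    "FAN": (0.073, 1.017),
    "HDE": (0.031, 0.513),
    "RLR": (0.092, 1.073),
    "RLS": (0.108, 0.823),
    # udder traits
    "FTL": (0.328, 1.219),
    "FTP": (0.194, 0.934),
    "FUA": (0.178, 1.170),
    "RTP": (0.077, 0.769),
    "RUH": (0.252, 1.239),
    "RUW": (0.114, 0.932),
    "UDE": (0.418, 0.833),
    "USU": (0.115, 0.960),
    "UTX": (0.077, 0.769),
}


def conformation_trait(code: str, c: float = 0.4) -> TraitParams:
    """Return the published TraitParams for a conformation trait code."""
    try:
        sa2, se2 = _COMPONENTS[code.upper()]
    except KeyError:
        raise KeyError(f"unknown trait code {code!r}; known: {sorted(_COMPONENTS)}") from None
    return TraitParams(trait_code=code.upper(), sigma_a2=sa2, sigma_e2=se2, c=c)


def all_conformation_traits(c: float = 0.4) -> dict[str, TraitParams]:
    return {code: conformation_trait(code, c) for code in _COMPONENTS}
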