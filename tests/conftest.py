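import numpy as np
import pytest
from hypothesis import settings

import bovigs as bg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate simulated dataset shared by read-only tests.

    ~360 animals over 3 generations, 600 unlinked SNPs on 6 chromosomes,
    a sparse trait (pi=0.95, h2=0.4) and EBV records of mixed reliability.
    """
    ped = bg.simulate_pedigree(120, 2, 2, seed=11)
    geno = bg.gene_drop_genotypes(ped, 600, seed=12, n_chromosomes=6)
    trait = bg.simulate_trait(geno, pi=0.95, h2=0.4, seed=13)
    ebv = bg.simulate_ebv_records(trait, ped, 0.3, 0.9, seed=14)
    params = bg.TraitParams("SIM", sigma_a2=0.4, sigma_e2=0.6)
    return {"pedigree": ped, "genotypes": geno, "trait": trait,
            "ebv": ebv, "params": params}


@pytest.fixture(scope="session")
def quick_fit(small_dataset):
    """One short BayesC fit reused by bookkeeping/window tests."""
    debv = bg.deregress(small_dataset["ebv"], small_dataset["params"], mode="incPA")
    cfg = bg.BayesConfig(method="BayesC", pi=0.95, chain_length=1100,
                         burn_in=100, thin=10, seed=21)
    res = bg.fit_bayes(small_dataset["genotypes"], debv, cfg)
    return {"result": res, "debv": debv, "config": cfg}


def kinship(pedigree: bg.Pedigree) -> np.ndarray:
    """Independent oracle: recursive coancestry f(i,j); A = 2f.

    Classic kinship recursion (equivalent to summing (1/2)^L path
    contributions over common ancestors), implemented without the tabular
    row-filling used by the package.
    """
    sire, dam = pedigree.parent_indices()
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + f(sire[i], dam[i]))
        if i < j:  # recurse on the later-born animal (topological order)
            i, j = j, i
        return 0.5 * (f(sire[i], j) + f(dam[i], j))

    n = len(pedigree)
    a = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            a[i, j] = a[j, i] = 2.0 * f(i, j)
    return a
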