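import numpy as np
import pytest

from ssrpop.io import MISSING, GenotypeMatrix, LocusInfo


def make_genotypes(calls, repeat_unit=2, ids=None, loci=None):
    """Build a GenotypeMatrix from a nested list [[(a, b), ...], ...]."""
    arr = np.array(calls, dtype=np.int64)
    n, L = arr.shape[0], arr.shape[1]
    if ids is None:
        ids = [f"A{i + 1}" for i in range(n)]
    if loci is None:
        loci = [
            LocusInfo(f"L{j + 1}", repeat_unit=repeat_unit) for j in range(L)
        ]
    return GenotypeMatrix(ids, loci, arr)


@pytest.fixture
def two_pop_fixed():
    """Two strata fixed for disjoint alleles at every locus: complete
    differentiation (Fst = 1, Phi = 1)."""
    calls = [[(200, 200)] * 3, [(200, 200)] * 3, [(200, 200)] * 3,
             [(208, 208)] * 3, [(208, 208)] * 3, [(208, 208)] * 3]
    g = make_genotypes(calls)
    strata = {"A": ["A1", "A2", "A3"], "B": ["A4", "A5", "A6"]}
    return g, strata


@pytest.fixture(scope="session")
def small_panel():
    """A 3-population synthetic panel reused by read-only tests."""
    from ssrpop.simulate import SimulationConfig, simulate_panel

    cfg = SimulationConfig.small(
        n_pops=3, n_per_pop=40, divergence_fst=0.5, seed=42
    )
    return simulate_panel(cfg)
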