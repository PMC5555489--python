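import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cervmap import mapbuild, pedio, simdata

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One 100 cM chromosome, 240 gametes, error-free genotypes + truth."""
    tm = simdata.simulate_true_map(1, 100, 100.0, female_ratio=1.0,
                                   pericentromeric_multiplier=1.0, seed=11)
    ped = simdata.simulate_pedigree(40, 40, 3, seed=12)
    gm, truth = simdata.simulate_gametes_and_genotypes(ped, tm, seed=13)
    subs = pedio.build_subpedigrees(ped, set(gm.calls.index))
    return {"truemap": tm, "pedigree": ped, "genotypes": gm, "truth": truth, "subpeds": subs}


@pytest.fixture(scope="session")
def phased_small(small_sim):
    gs = mapbuild.phase_all(small_sim["subpeds"], small_sim["genotypes"])
    order = [gs.col[m] for m in small_sim["truemap"].groups["G1"].markers]
    return gs, order


def make_genotypes(rows: dict[str, list[int]], chrom: str = "1") -> pedio.GenotypeMatrix:
    """Tiny genotype matrix from per-individual call lists."""
    calls = pd.DataFrame(rows).T.astype(np.int8)
    n = calls.shape[1]
    calls.columns = [f"m{i+1}" for i in range(n)]
    markers = pd.DataFrame(
        {"chrom": chrom, "bp": (np.arange(n) + 1) * 1_000_000,
         "x_linked": False, "pseudoautosomal": False},
        index=calls.columns,
    )
    return pedio.GenotypeMatrix(calls, markers)
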