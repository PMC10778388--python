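import numpy as np
import pandas as pd
import pytest

import gselect as gs


@pytest.fixture(scope="session")
def small_geno():
    """60 x 120 clean-ish panel with a little missingness."""
    gm, _ = gs.simulate_genotypes(60, 120, seed=11, missing_rate=0.03)
    return gm


@pytest.fixture(scope="session")
def clean_geno():
    """Panel guaranteed to pass every QC step untouched."""
    gm, _ = gs.simulate_genotypes(
        80, 150, maf_sampler=lambda r, size: r.uniform(0.2, 0.5, size=size), seed=21)
    return gm


@pytest.fixture(scope="session")
def trio_pedigree():
    return gs.PedigreeTable(pd.DataFrame(
        {"animal": ["s1", "d1", "o1"], "sire": ["0", "0", "s1"], "dam": ["0", "0", "d1"]}))


@pytest.fixture(scope="session")
def qtl_fixture():
    """n=400, m=500 panel with one planted QTL explaining 40% of variance."""
    gm, _ = gs.simulate_genotypes(400, 500, seed=7)
    Z = gs.centered_dosages(gm)
    q = 250
    rng = np.random.default_rng(1)
    u = Z[:, q].copy()
    e = rng.normal(0.0, np.sqrt(u.var() * 60.0 / 40.0), gm.n_animals)
    yc = pd.Series(u + e - (u + e).mean(), index=gm.animal_ids)
    return gm, Z, yc, q
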