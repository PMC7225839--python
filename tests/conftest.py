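import numpy as np
import pytest

import maizegs as mg


@pytest.fixture(scope="session")
def small_panel():
    """A small diverse panel with a polygenic trait (h2 = 0.75)."""
    cfg = mg.SimConfig(n_ind=200, n_chrom=5, markers_per_chrom=120,
                       n_qtl=30, h2_target=0.75, seed=11)
    geno = mg.simulate_panel(cfg)
    records, arch = mg.simulate_phenotypes(geno, cfg)
    lsm = mg.ls_means(records).reindex(geno.line_ids.astype(str)).to_numpy()
    return {"cfg": cfg, "geno": geno, "records": records, "arch": arch, "y": lsm}


@pytest.fixture(scope="session")
def small_dh():
    """A DH population of 120 lines from two maximally divergent parents."""
    cfg = mg.SimConfig(pop_type="dh", n_ind=120, n_chrom=5,
                       markers_per_chrom=100, n_qtl=20, h2_target=0.75, seed=23)
    rng = np.random.default_rng(5)
    p1 = 2.0 * rng.integers(0, 2, cfg.n_markers).astype(float)
    p2 = 2.0 - p1
    geno = mg.simulate_dh(cfg, p1, p2)
    records, arch = mg.simulate_phenotypes(geno, cfg)
    lsm = mg.ls_means(records).reindex(geno.line_ids.astype(str)).to_numpy()
    return {"cfg": cfg, "geno": geno, "records": records, "arch": arch, "y": lsm}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
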