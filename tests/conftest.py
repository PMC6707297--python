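import numpy as np
import pandas as pd
import pytest

import epitwas as et


@pytest.fixture(scope="session")
def small_cfg():
    return et.SimulationConfig(n_samples=200, n_snps_per_gene=20,
                               effect_sd=0.2, seed=11)


@pytest.fixture(scope="session")
def gene_block(small_cfg):
    """One simulated gene: genotypes, architecture, expression at level 0.5."""
    G = et.simulate_genotypes(small_cfg)
    beta, ann = et.simulate_gene_architecture(small_cfg, G.snps)
    y = et.simulate_expression(G, beta, 0.5, small_cfg.noise_sd, seed=5)
    return G, beta, ann, y


@pytest.fixture(scope="session")
def stacked_panel():
    """Multi-gene panel with stacked eQTL and annotation tables."""
    cfg = et.SimulationConfig(n_samples=300, n_snps_per_gene=20,
                              effect_sd=0.2, seed=21)
    panel = et.simulate_gene_panel(cfg, 80, seed=21, level=0.8)
    eqtls, anns = [], []
    for g in panel:
        eqtls.append(et.marginal_eqtl_scan(g["G"], g["y"], gene_id=g["gene_id"]))
        anns.append(g["ann"].matrix)
    eqtl = pd.concat(eqtls, ignore_index=True)
    ann = et.AnnotationSet(np.vstack(anns), ["regulatory"])
    return panel, eqtl, ann
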