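import numpy as np
import pandas as pd
import pytest

from cardiogwas.syndata import SimConfig, simulate_panel, simulate_phenotypes


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic panel shared across tests."""
    cfg = SimConfig(n_lines=60, n_per_line=10, n_variants=400,
                    genome_length=80_000, n_causal_mean=5, n_causal_var=3,
                    outlier_rate=0.0, seed=7)
    panel, genes, genome = simulate_panel(cfg)
    pheno, covariates, truth = simulate_phenotypes(panel, cfg)
    return {"config": cfg, "panel": panel, "genes": genes, "genome": genome,
            "pheno": pheno, "covariates": covariates, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
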