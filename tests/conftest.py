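import numpy as np
import pandas as pd
import pytest

import methtx
from methtx.simulate import SimulationParams, _beta_binomial


@pytest.fixture(scope="session")
def design():
    return methtx.generate_design(n_per_group=5, seed=0)


@pytest.fixture(scope="session")
def small_genome():
    return methtx.generate_genome(n_genes=100, n_cpgs=2000, seed=1)


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_genes=100, n_cpgs=2000, seed=1)


@pytest.fixture(scope="session")
def small_dataset(design, small_genome, small_params):
    counts, truth = methtx.simulate_expression(small_genome, design, small_params)
    meth, truth = methtx.simulate_methylation(small_genome, design, small_params, truth)
    return counts, meth, truth


def make_meth_table(design, stage, p_conv, p_gf, n_sites, coverage=30, phi=0.05,
                    seed=0, spacing=1000):
    """Long methylation table for one stage with group-specific mean levels."""
    rng = np.random.default_rng(seed)
    sub = design.loc[design["stage"] == stage].reset_index(drop=True)
    n_samp = len(sub)
    cov = 5 + rng.poisson(max(coverage - 5, 0), size=(n_sites, n_samp))
    p = np.where((sub["condition"] == "CONV_R").to_numpy(), p_conv, p_gf)
    x = _beta_binomial(rng, cov, np.broadcast_to(p, (n_sites, n_samp)), phi)
    pos = np.repeat(np.arange(1, n_sites + 1) * spacing, n_samp)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "sample_id": np.tile(sub["sample_id"].to_numpy(), n_sites),
            "X": x.ravel(),
            "N": cov.ravel(),
        }
    )
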