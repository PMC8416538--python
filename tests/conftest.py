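"""Shared fixtures: small simulated datasets built once per session."""
import numpy as np
import pandas as pd
import pytest

from mtgp import (
    BlueTable,
    GibbsConfig,
    PlotTable,
    SimConfig,
    fit_env_blues,
    grm_vanraden,
    make_psd,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_single_trait():
    """100 lines x 800 markers, one environment, one trait, h2 = 0.5."""
    cfg = SimConfig(
        n_lines=100, n_markers=800, n_families=10, n_envs=1,
        trait_names=("YLD",), h2={"YLD": 0.5}, seed=2,
    )
    g = simulate_genotypes(cfg)
    plot, truth = simulate_phenotypes(g, cfg)
    G = make_psd(grm_vanraden(g))
    blues, _ = fit_env_blues(plot, "E1", "YLD")
    return {"cfg": cfg, "geno": g, "plot": plot, "truth": truth, "G": G,
            "blues": blues}


@pytest.fixture(scope="session")
def small_two_trait():
    """60 lines, one environment, two strongly correlated traits."""
    cfg = SimConfig(
        n_lines=60, n_markers=400, n_families=6, n_envs=1,
        trait_names=("A", "B"), h2={"A": 0.5, "B": 0.7},
        genetic_sd={"A": 1.0, "B": 1.0},
        Sigma_t_corr=np.array([[1.0, 0.9], [0.9, 1.0]]),
        seed=5,
    )
    g = simulate_genotypes(cfg)
    plot, truth = simulate_phenotypes(g, cfg)
    G = make_psd(grm_vanraden(g))
    tables = [fit_env_blues(plot, "E1", t)[0] for t in cfg.trait_names]
    return {"cfg": cfg, "geno": g, "truth": truth, "G": G,
            "blues": BlueTable.concat(tables)}


@pytest.fixture
def balanced_plot_table():
    df = pd.DataFrame(
        {
            "line": ["g1", "g1", "g2", "g2"],
            "env": "E1",
            "rep": ["R1", "R2", "R1", "R2"],
            "trait": "T",
            "value": [4.0, 6.0, 8.0, 10.0],
        }
    )
    return PlotTable(df)


@pytest.fixture
def quick_chain():
    return GibbsConfig(n_burn=200, n_iter=800, thin=2, seed=7)
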