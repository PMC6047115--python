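import numpy as np
import pytest

from magicqtl.simulate import (QTLEffect, SimulationConfig,
                               simulate_founders, simulate_magic_rils)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study design: 208 lines, 2 reps, sparse DAS grid."""
    return SimulationConfig(
        seed=11,
        n_lines=208,
        n_reps=2,
        timepoints=tuple(range(90, 191, 4)),
    )


@pytest.fixture(scope="session")
def population(small_config):
    panel = simulate_founders(small_config)
    return panel, simulate_magic_rils(panel, small_config)


@pytest.fixture(scope="session")
def qtl_config(population):
    """Config planting a biallelic QTL on parameter D of Area.

    Founders carrying the B allele at the chosen marker get +9000 mm^2 on
    the top asymptote, which with the default 5% environmental spread
    puts the marker's share of line variance near 30%.
    """
    panel, _ = population
    marker = "chr4D_m020"
    j = int(np.nonzero((panel.markers["marker"] == marker).to_numpy())[0][0])
    alleles = panel.founder_alleles[:, j]
    cfg = SimulationConfig(
        seed=11,
        n_lines=208,
        n_reps=2,
        timepoints=tuple(range(90, 191, 4)),
        qtl=(QTLEffect(marker=marker, trait="Area", parameter="D",
                       effects=tuple(9000.0 * a for a in alleles)),),
    )
    return cfg, marker
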