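import numpy as np
import pandas as pd
import pytest

from toxqtl import (
    QTLSpec,
    make_marker_map,
    simulate_phenotypes,
    simulate_riail_genotypes,
    simulate_wild_panel,
)


@pytest.fixture(scope="session")
def marker_map():
    """Small six-chromosome map: 40 markers per chromosome, 50 cM each."""
    return make_marker_map(n_markers_per_chrom=40)


@pytest.fixture(scope="session")
def riail_panel(marker_map):
    """120 simulated recombinant inbred advanced intercross lines."""
    return simulate_riail_genotypes(120, marker_map, n_intercross_generations=10, seed=11)


@pytest.fixture(scope="session")
def wild_panel(marker_map):
    """Structured wild panel: 150 strains, 3 subpopulations, divergence 0.2."""
    return simulate_wild_panel(
        150, marker_map, n_subpopulations=3, fst_like_divergence=0.2, seed=12
    )


@pytest.fixture(scope="session")
def qtl_trait(riail_panel):
    """RIAIL trait with one 30%-variance QTL mid-chromosome II."""
    marker = riail_panel.markers.query("chrom == 'II'").iloc[20]["marker"]
    trait = simulate_phenotypes(
        riail_panel, [QTLSpec(marker, 0.30)], polygenic_h2=0.1, seed=13
    )
    return marker, trait
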