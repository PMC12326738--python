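import numpy as np
import pandas as pd
import pytest

from senescreen import simulate
from senescreen.screen import fit_gene_effects
from senescreen.simulate import NON_TARGETING


@pytest.fixture(scope="session")
def small_screen():
    """A modest two-arm screen with known truth, shared across test modules."""
    lib = simulate.make_library(120, 5, 40, seed=10)
    genes = [g for g in lib["gene"].unique() if g != NON_TARGETING]
    eff = simulate.make_effects(genes, n_essential=10, n_common=10,
                                n_inflammaging=10, beta=1.0, seed=11)
    sim = simulate.simulate_screen(lib, eff, depth=300, dispersion=0.05,
                                   n_replicates=2, seed=12)
    return sim


@pytest.fixture(scope="session")
def small_results(small_screen):
    """Fitted per-gene results for both conditions of the small screen."""
    return {
        cond: fit_gene_effects(small_screen.counts, small_screen.design, cond)
        for cond in ("rss", "iss")
    }


@pytest.fixture(scope="session")
def toy_genome():
    """Toy genome with AR(1) LD blocks plus a 10%-coverage annotation."""
    gene_map, snp_map = simulate.simulate_genome(
        20, 4000, 80, 50_000_000, seed=21)
    rng = np.random.default_rng(22)
    a = np.zeros(len(snp_map), dtype=int)
    a[rng.choice(len(snp_map), 400, replace=False)] = 1
    annot = pd.DataFrame({"base": np.ones(len(snp_map), dtype=int), "set": a})
    return gene_map, snp_map, annot
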