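import numpy as np
import pandas as pd
import pytest

from tempopgen import glcore, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_cohort():
    """A compact simulated cohort reused across modules."""
    cfg = simulate.SimConfig(
        n_sites=80,
        n_causal_per_trait=4,
        years=(2000, 2009),
        n_per_year=12,
        seed=11,
    )
    truth, samples, gl = simulate.simulate_full(cfg)
    return cfg, truth, samples, gl


def gl_matrix_from_genotypes(genotypes, chrom="chr1", spacing=1000, positions=None):
    """Certain-genotype GLMatrix for handcrafted tests."""
    g = np.asarray(genotypes)
    S, N = g.shape
    if positions is None:
        positions = (np.arange(S) + 1) * spacing
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "major": "A", "minor": "C"}
    )
    return glcore.GLMatrix(sites, glcore.certain_gl(g), [f"i{k}" for k in range(N)])
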