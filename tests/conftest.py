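import numpy as np
import pandas as pd
import pytest

from letharank.io import FoldChangeProfile, GeneMatrix, PipelineConfig
from letharank.simulate import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A quick, fully structured world shared by read-only tests."""
    return generate_world(WorldConfig(
        n_genes=300, n_cell_lines=16, n_kd_genes=60, seed=7,
    ))


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(master_seed=7, neighborhood_k=20, n_stability_seeds=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profiles(rng, n_genes=100, n_profiles=10, with_p=True):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    out = []
    for m in range(n_profiles):
        fc = pd.Series(rng.standard_normal(n_genes), index=genes)
        pv = pd.Series(rng.random(n_genes), index=genes) if with_p else None
        out.append(FoldChangeProfile(profile_id=f"P{m:02d}", log2fc=fc, p_value=pv))
    return out


def random_matrix(rng, n_genes=50, n_samples=10, prefix="G"):
    genes = [f"{prefix}{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    return GeneMatrix(pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples,
    ))
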