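import numpy as np
import pandas as pd
import pytest

from salttol.config import SimulationConfig, StageSpec
from salttol.genotype_qc import GenotypeMatrix
from salttol import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genotypes=60, n_snps=120, n_causal=3,
                            causal_effect_sizes=[0.6, 0.6, 0.6], seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return sd.generate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_genotypes):
    table, latent = sd.generate_phenotypes(small_config, small_genotypes)
    return table, latent


def toy_matrix(calls, ref="A", alt="T", chrom="1"):
    """GenotypeMatrix from a (markers x samples) array of 0/1/2/-1 codes."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    markers = pd.DataFrame({
        "id": [f"m{i}" for i in range(m)],
        "chrom": chrom,
        "pos": np.arange(1, m + 1) * 100,
        "ref": ref,
        "alt": alt,
    })
    return GenotypeMatrix([f"s{j}" for j in range(n)], markers, calls)


@pytest.fixture
def tmp_run_dir(tmp_path):
    return str(tmp_path / "run")
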