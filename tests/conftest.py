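import numpy as np
import pandas as pd
import pytest

from rhizolink import FeatureMatrix, SyntheticConfig, generate_dataset, run_all
from rhizolink.datatypes import BLANK

#: small study used by fast unit tests
SMALL_CONFIG = SyntheticConfig(n_genes=40, n_enzyme_genes=15, n_features=80, seed=1)

#: the full default study design (19 accessions x 3 replicates, ~500 features,
#: ~200 genes, 5 planted links)
DEFAULT_CONFIG = SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(DEFAULT_CONFIG)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default synthetic study."""
    return run_all(dataset=default_dataset, nboot=50, seed=1)


@pytest.fixture(scope="session")
def collision_result():
    """Pipeline run with a second enzyme gene sharing link 0's stop pattern."""
    cfg = SyntheticConfig(seed=1, planted_pattern_collision=True)
    return run_all(cfg, nboot=10, seed=1)


def make_matrix(
    values: np.ndarray,
    accessions: list[str],
    n_replicates: int = 3,
    n_blanks: int = 0,
    transformed: bool = False,
    rt=None,
    mz=None,
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from a plain array (features x samples).

    Columns are ordered accession-major (all replicates of accession 1, ...),
    blanks last.
    """
    values = np.asarray(values, dtype=float)
    rows = []
    for acc in accessions:
        for rep in range(1, n_replicates + 1):
            rows.append((f"{acc}_r{rep}", acc, rep, rep, False))
    for b in range(1, n_blanks + 1):
        rows.append((f"BLANK_b{b}", BLANK, b, (b - 1) % n_replicates + 1, True))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "accession", "replicate", "batch", "is_blank"]
    ).set_index("sample_id")
    assert values.shape[1] == len(samples)
    fids = [f"F{i + 1:03d}" for i in range(values.shape[0])]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 900, len(fids)),
            "rt": rt if rt is not None else np.linspace(1, 10, len(fids)),
            "mode": "ESI(-)",
        },
        index=pd.Index(fids, name="feature_id"),
    )
    intensities = pd.DataFrame(values, index=features.index, columns=samples.index)
    return FeatureMatrix(intensities, features, samples, transformed=transformed)
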