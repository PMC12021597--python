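from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def alignment_digest() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "alignment_digest.tsv", sep="\t")


@pytest.fixture
def toy_abundance() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "toy_abundance.tsv", sep="\t", index_col=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_abundance_table(rng: np.random.Generator, n_features=6, n_samples=5) -> pd.DataFrame:
    values = rng.gamma(2.0, 10.0, size=(n_features, n_samples))
    return pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
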