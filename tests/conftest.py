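import numpy as np
import pandas as pd
import pytest

from otuwas import OtuCountTable, PhenotypeFrame, RelAbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    return OtuCountTable(
        ["s1", "s2", "s3"],
        ["otu_a", "otu_b"],
        np.array([[5, 0], [2, 7], [0, 1]]),
    )


def random_count_table(rng, n_samples=8, n_otus=12, max_count=50):
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    counts[:, 0] += 1  # avoid all-zero rows
    return OtuCountTable(
        [f"s{i}" for i in range(n_samples)],
        [f"otu{j}" for j in range(n_otus)],
        counts,
    )


def make_pheno(weights, sexes=None, cages=None, adjusted=False):
    n = len(weights)
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "sex": sexes if sexes is not None else ["male"] * n,
            "cage": cages if cages is not None else ["c1"] * n,
            "phenotype_raw": np.asarray(weights, dtype=float),
        }
    )
    if adjusted:
        df["phenotype_adj"] = df["phenotype_raw"] - df["phenotype_raw"].mean()
    return PhenotypeFrame(df)


def rel_from_matrix(ab, normalized=True):
    ab = np.asarray(ab, dtype=float)
    return RelAbundanceTable(
        [f"s{i}" for i in range(ab.shape[0])],
        [f"otu{j}" for j in range(ab.shape[1])],
        ab,
        normalized=normalized,
    )
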