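from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from profilesets import (
    OmicsFeatureMatrix,
    ProfileSpec,
    SampleRoles,
    SyntheticSpec,
    generate,
    merge_features,
)

SAMPLES = ["S1", "S2", "S3", "S4"]


def make_matrix(
    n_genes: int = 12,
    n_samples: int = 4,
    label: str = "expression",
    seed: int = 0,
    prefix: str = "g",
) -> OmicsFeatureMatrix:
    """Random validated matrix with deterministic contents."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"{prefix}{i + 1}" for i in range(n_genes)],
        columns=SAMPLES[:n_samples],
    )
    return OmicsFeatureMatrix.from_dataframe(df, label)


def write_tsv(path, df: pd.DataFrame, id_name: str = "gene") -> None:
    out = df.copy()
    out.index.name = id_name
    out.to_csv(path, sep="\t")


@pytest.fixture
def roles() -> SampleRoles:
    return SampleRoles("S1", "S2", "S3")


@pytest.fixture
def planted_input():
    """Default planted-signal analysis input plus the planted IDs."""
    feats, roles_, planted = generate(SyntheticSpec(seed=7))
    ai = merge_features(feats, roles_, ProfileSpec(("up", "up")))
    return ai, planted
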