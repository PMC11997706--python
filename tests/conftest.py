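import numpy as np
import pandas as pd
import pytest

from mirpair import (
    CohortSpec,
    DilutionSpec,
    generate_cohort,
    generate_dilution_series,
    published_model,
)


@pytest.fixture(scope="session")
def small_cohort():
    """174-subject cohort with one planted pair and low noise."""
    spec = CohortSpec(
        n_benign=140,
        n_malignant=34,
        n_mirna=12,
        n_sites=5,
        planted_pairs=[("miR-0001", "miR-0002", 0.2)],
        noise_sd=0.05,
        subject_offset_sd=0.5,
        detection_dropout_rate=0.0,
        detection_threshold=10,
        seed=42,
    )
    matrix, metadata = generate_cohort(spec)
    return matrix, metadata


@pytest.fixture(scope="session")
def noiseless_dilution():
    spec = DilutionSpec(
        true_slopes={"miR-A": 1.0, "miR-B": 0.8},
        replicate_noise_sd=0.0,
        seed=0,
    )
    return generate_dilution_series(spec)


@pytest.fixture(scope="session")
def earlyguard():
    return published_model()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_metadata(n, hemolysis=(), no_consensus=(), categories=None):
    """Hand-built subject metadata frame for QC tests."""
    ids = [f"S{i:04d}" for i in range(n)]
    cats = categories or {}
    return pd.DataFrame(
        {
            "label": ["benign"] * n,
            "category": [cats.get(i, "Benign") for i in range(n)],
            "site": [f"site_{i % 3}" for i in range(n)],
            "hemolysis": [i in set(hemolysis) for i in range(n)],
            "consensus": [i not in set(no_consensus) for i in range(n)],
        },
        index=pd.Index(ids, name="subject_id"),
    )
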