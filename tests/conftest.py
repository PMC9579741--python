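import numpy as np
import pytest

import libtype as lt
from libtype.simulate import SIGNATURE_TYPES, jitter_signature


@pytest.fixture(scope="session")
def synth_db():
    """5-type synthetic reference database at default study conditions."""
    return lt.generate_reference_db(n_per_type=50, seed=0)


@pytest.fixture(scope="session")
def features_labels(synth_db):
    return lt.feature_matrix(synth_db)


@pytest.fixture(scope="session")
def ref_model(features_labels):
    X, labels = features_labels
    return lt.fit_reference_map(X, labels=labels)


@pytest.fixture(scope="session")
def ref_grid(ref_model, features_labels):
    _, labels = features_labels
    return lt.build_grid(ref_model.reference_coords, labels)


@pytest.fixture(scope="session")
def held_out_profiles():
    """10 fresh jittered profiles per signature type, with their true labels."""
    rng = np.random.default_rng(123)
    profiles, truth = [], []
    for t in SIGNATURE_TYPES:
        sig = lt.make_signature(t)
        for i in range(10):
            jit = jitter_signature(sig, rng)
            seed = int(rng.integers(0, 2**31 - 1))
            profiles.append(
                lt.sample_profile(jit, 100_000, seed=seed, sample_id=f"holdout_{t}_{i}")
            )
            truth.append(t)
    return profiles, truth


def write_fastq(path, records):
    """Write (id, seq, qual) triples as a 4-line FASTQ file."""
    with open(path, "wt") as fh:
        for ident, seq, qual in records:
            fh.write(f"@{ident}\n{seq}\n+\n{qual}\n")
    return path
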