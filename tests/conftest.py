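"""Shared fixtures. The expensive session fixtures (synthetic staging cohort
and its cross-validation) are built once and reused by the staging and
acceptance tests."""

import numpy as np
import pandas as pd
import pytest

from somnostage import (ArchitectureParams, FeatureConfig, simulate_cohort,
                        cross_validate, epoch_record, extract_features,
                        preprocess)

#: fixed study seed for the synthetic staging cohort
STAGING_SEED = 42


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def staging_features():
    """Feature matrix of a 20-subject, 1-h-per-night labelled cohort with
    well-separated stage spectral templates (the staging study conditions)."""
    cohort = simulate_cohort(
        n_exposed=10, n_sham=10, base=ArchitectureParams.scaled_to(1.0),
        nights=1, seed=STAGING_SEED, generate_eeg=True)
    frames = []
    for rec in cohort:
        h, r = rec.hypnograms[0], rec.recordings[0]
        r = preprocess(r, target_rate=100.0)
        epochs = epoch_record(r, "Pz-Oz")
        frames.append(extract_features(epochs, FeatureConfig(),
                                       stages=h.labels[: len(epochs)],
                                       subject_id=rec.subject_id))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def staging_cv(staging_features):
    """Subject-grouped 10-fold CV of the full staging pipeline."""
    return cross_validate(staging_features, folds=10, k=8, seed=STAGING_SEED)
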