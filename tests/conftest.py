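"""Shared fixtures.

The heavy artefacts — the default synthetic cohort pushed through the
full 67-session pipeline, and the label-shuffled null run — are
session-scoped so the acceptance checks and the end-to-end unit tests
share one computation.
"""

import numpy as np
import pytest
from hypothesis import settings

import specfinger as sf
from specfinger.preprocess import preprocess_set

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition synthetic cohort (192 positive / 202 negative)."""
    return sf.generate_cohort(sf.SyntheticCohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Full pipeline fit on the default cohort, 67 sessions."""
    model = sf.SpectralFingerprintModel(default_cohort, master_seed=1)
    return model.fit()


@pytest.fixture(scope="session")
def null_run(default_cohort):
    """Label-shuffled run of the same cohort: scoring, selection and the
    ensemble all see permuted labels, so any residual accuracy reflects
    leakage, optimism of whole-cohort selection, or classifier bias."""
    fm = preprocess_set(default_cohort, sf.DEFAULT_REGIONS)
    rng = np.random.default_rng(7)
    lab = np.asarray(fm.labels, dtype=object)
    shuffled = lab[rng.permutation(lab.size)]
    scores = sf.score_wavenumbers(fm.X, shuffled)
    sel = sf.select_wavenumbers(scores)
    config = sf.EnsembleConfig(n_sessions=67, master_seed=1)
    run = sf.run_ensemble(fm.X[:, sel.selected], shuffled, config)
    summaries = sf.summarize_observations(run.records, shuffled, config, fm.sample_ids)
    return run, summaries


@pytest.fixture(scope="session")
def small_feature_matrix():
    """A small cohort through preprocessing, for fast feature-level tests."""
    cohort = sf.generate_cohort(
        sf.SyntheticCohortConfig(seed=4, n_positive=40, n_negative=40)
    )
    return preprocess_set(cohort, sf.DEFAULT_REGIONS)
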