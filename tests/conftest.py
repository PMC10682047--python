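"""Shared fixtures: generated cohorts and trained classifiers.

All data are synthesized at test time with fixed seeds.  The two trained
models are session-scoped because fitting is by far the most expensive step;
tests must not mutate them (adaptation copies the network).
"""

import numpy as np
import pytest

import larynet as ln
from larynet.preprocess import assemble_dataset, default_split, identity_class_map


@pytest.fixture(scope="session")
def profile():
    return ln.SubjectProfile("P00")


@pytest.fixture(scope="session")
def cohort13():
    """16 training + 2 held-out subjects, all 13 classes, 2 reps each."""
    return ln.synthesize_cohort(18, reps_per_class=2, seed=42)


@pytest.fixture(scope="session")
def dataset13(cohort13):
    split = default_split(cohort13, n_test=2)
    return assemble_dataset(cohort13, identity_class_map(), split,
                            n_sequences=4, length=1000, seed=42)


@pytest.fixture(scope="session")
def results13(dataset13):
    """2D-SFE fitted on the 13-class cohort at reduced epochs."""
    return ln.SFEClassifier(dataset13).fit(epochs=20, seed=0)


@pytest.fixture(scope="session")
def adapt_results():
    """Model trained on 6 ordinary subjects with 2 perturbed new subjects.

    The held-out subjects carry a consistent ~10 % spectral shift plus a
    weaker sEMG and more noise, emulating electrode placement and anatomy
    differences on a new wearer, so zero-shot transfer visibly degrades.
    """
    cohort = ln.synthesize_cohort(8, reps_per_class=2, seed=42)
    for i, sid in enumerate(sorted(cohort)[-2:]):
        prof = ln.SubjectProfile(
            sid, cardiac_amp=0.015, resp_amp=0.05, semg_gain=0.6,
            spectral_jitter=0.10, baseline_noise_sd=0.005,
        )
        cohort[sid] = ln.synth.synthesize_subject_recordings(prof, seed=1000 + i)
    split = default_split(cohort, n_test=2)
    ds = assemble_dataset(cohort, identity_class_map(), split,
                          n_sequences=4, seed=42)
    return ln.SFEClassifier(ds).fit(epochs=20, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
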