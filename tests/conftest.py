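import numpy as np
import pytest

from rnaiface import (
    ModelSpec,
    SignalSpec,
    assemble,
    cross_validate,
    encode_chain,
    make_folds,
    synth_profile_dataset,
)


def build_chain_datasets(n_chains, chain_len, spec):
    """Encode a planted-signal synthetic dataset chain by chain."""
    profiles, annotations = synth_profile_dataset(n_chains, chain_len, spec)
    return {
        ann.chain_id: encode_chain(prof, ann)
        for prof, ann in zip(profiles, annotations)
    }


def run_planted_cv(algorithm, effect_size, seed=7, n_chains=20, chain_len=100):
    """Chain-level 5-fold CV on the planted-signal dataset; returns CVResult."""
    spec = SignalSpec(effect_size=effect_size, seed=seed)
    by_chain = build_chain_datasets(n_chains, chain_len, spec)
    folds = make_folds([(c, len(d)) for c, d in by_chain.items()], k=5, seed=seed)
    return cross_validate(by_chain, ModelSpec(algorithm=algorithm, seed=seed), folds)


@pytest.fixture(scope="session")
def planted_cv_svmrbf():
    """5-fold CV of the RBF SVM on 20 chains x 100 residues, effect size 3."""
    return run_planted_cv("SVMRBF", effect_size=3.0)


@pytest.fixture(scope="session")
def planted_cv_consensus():
    """5-fold CV of the SVMRBF+RF100 consensus on the same planted dataset."""
    return run_planted_cv("CONSENSUS", effect_size=3.0)


@pytest.fixture(scope="session")
def null_cv_svmrbf():
    """5-fold CV with the signal removed (effect size 0): labels independent
    of features, so pooled AUC should hover around 0.5."""
    return run_planted_cv("SVMRBF", effect_size=0.0)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """A small assembled planted-signal dataset for classifier unit tests."""
    spec = SignalSpec(effect_size=3.0, seed=11)
    by_chain = build_chain_datasets(6, 60, spec)
    return assemble(list(by_chain.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
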