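"""Shared fixtures: a session-scoped synthetic corpus and its featurization.

The corpus (three environment subsets, 300 s per recording) is generated once
and reused by the integration and acceptance tests; unit tests build their own
small inputs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from coughkit.pipeline import CorpusDataset, featurize_corpus
from coughkit.synthetic import default_corpus_configs, generate_corpus

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

#: Seed of the shared corpus.  Fixed once; the acceptance tests treat the
#: resulting corpus as the study data.
CORPUS_SEED = 42
CORPUS_DURATION_S = 300.0


@pytest.fixture(scope="session")
def corpus_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    configs, labels = default_corpus_configs(seed=CORPUS_SEED,
                                             duration_s=CORPUS_DURATION_S)
    return generate_corpus(configs, labels, out)


@pytest.fixture(scope="session")
def dataset(corpus_manifest) -> CorpusDataset:
    return featurize_corpus(corpus_manifest)
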