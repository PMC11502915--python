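import numpy as np
import pytest

from cxrcad import synthdata as sd
from cxrcad.preprocess import (
    PreprocessConfig,
    preprocess_image,
    standardize_case_labels,
)
from cxrcad.synthdata import SyntheticCase


@pytest.fixture(scope="session")
def gen_config():
    return sd.GeneratorConfig()


@pytest.fixture(scope="session")
def small_cases(gen_config):
    """A reusable batch of phantom cases with panel labels."""
    cases = sd.generate_cases(gen_config, 40, seed=123)
    panel = sd.LabelerPanelConfig(seed=7)
    labels = sd.labels_for_cases(cases, panel)
    return cases, labels


@pytest.fixture(scope="session")
def standardized_cases(small_cases):
    cases, labels = small_cases
    cfg = PreprocessConfig.test_profile()
    std = [SyntheticCase(c.case_id,
                         [preprocess_image(im, cfg) for im in c.images],
                         [], c.patient_meta) for c in cases]
    std_labels = [standardize_case_labels(l, [im.shape for im in c.images],
                                          cfg)
                  for c, l in zip(cases, labels)]
    return std, std_labels


def brute_force_auc(scores, labels):
    """Pair-counting ROC AUC oracle: wins + half-ties over pos x neg pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (pos.size * neg.size)
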