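import numpy as np
import pytest

from hfamark.features import training_table
from hfamark.simulate import SimulationConfig, sample_feature_cohort

FS = 1000.0


@pytest.fixture(scope="session")
def strong_cohort():
    """Feature-level cohort with a strong configured SOZ/non-epileptic
    separation, for classifier unit tests (small for speed)."""
    cfg = SimulationConfig(
        n_patients=12,
        channels_per_patient=40,
        rate_params={"soz": 4.0, "spiking": 1.5, "resected_other": 0.8, "non_epileptic": 0.3},
        rate_sigma=0.8,
        seed=101,
    )
    features, patients = sample_feature_cohort(cfg)
    return features, patients


@pytest.fixture(scope="session")
def strong_training(strong_cohort):
    features, _ = strong_cohort
    table = training_table(features)
    return table, table["label"].astype(int).to_numpy()


def auroc_pair_counting(scores, labels):
    """Exhaustive pair-counting AUROC oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (pos.size * neg.size)
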