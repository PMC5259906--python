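import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from gtpsite import model, synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reduced_config():
    """Desk-scale study conditions: 22 proteins, ~3.5% positive residues."""
    return synthetic.SyntheticConfig().reduced()


@pytest.fixture(scope="session")
def signal_dataset(reduced_config):
    return synthetic.generate_dataset(reduced_config)


@pytest.fixture(scope="session")
def signal_cv(signal_dataset):
    """Full-pipeline 5-fold CV (PSSM+SAAP) on the desk-scale dataset."""
    records, profiles, _ = signal_dataset
    return model.cross_validate(records, profiles, config=model.PipelineConfig())


@pytest.fixture(scope="session")
def null_aucs(reduced_config):
    """Pooled CV AUC on four replicate no-signal datasets.

    Positives cluster in segments, so a single desk-scale null dataset
    has few independent positive units and a noisy AUC; the replicate
    mean is the stable estimator.
    """
    aucs = []
    for seed in range(4):
        cfg = synthetic.SyntheticConfig(seed=seed).reduced().null()
        records, profiles, _ = synthetic.generate_dataset(cfg)
        res = model.cross_validate(records, profiles, config=model.PipelineConfig())
        aucs.append(res.pooled.auc)
    return aucs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
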