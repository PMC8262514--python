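import numpy as np
import pytest

from intakevar import SyntheticConfig, TransformSpec, generate


@pytest.fixture(scope="session")
def lognormal_recalls():
    """500 subjects x 2 days, log-scale truth beta = 2/3."""
    cfg = SyntheticConfig(n_subjects=500, n_days=2, mu=0.0, s_b2=0.25,
                          s_w2=0.50, lambda_true=0.0, seed=7)
    data, truth = generate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def zinc_like_recalls():
    """Repeat-day population with usual intake ~11 (zinc-like units)."""
    cfg = SyntheticConfig(n_subjects=500, n_days=2, mu=2.0, s_b2=0.25,
                          s_w2=0.50, lambda_true=0.0, seed=3)
    data, truth = generate(cfg)
    return data, truth


@pytest.fixture
def log_spec():
    return TransformSpec(lam=0.0)


@pytest.fixture
def identity_spec():
    return TransformSpec(lam=1.0)


@pytest.fixture(scope="session")
def survey_design():
    return {"n_strata": 24, "clusters_per_stratum": 2,
            "weight_model": "variable", "cluster_effect_sd": 0.15}
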