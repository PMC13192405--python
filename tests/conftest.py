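import warnings

import numpy as np
import pandas as pd
import pytest

from melsim import (
    DgpConfig,
    EmaDataset,
    MelsParams,
    MelsSettings,
    fit_mels,
    generate_observations,
    generate_subject_truth,
    make_fixture,
)

warnings.filterwarnings("ignore", message=".*subjects; MELS estimates.*")


def dataset_from_values(values_per_subject: dict) -> EmaDataset:
    """Build an EmaDataset from {subject_id: iterable of values}."""
    rows = []
    for sid, vals in values_per_subject.items():
        for j, v in enumerate(vals, start=1):
            rows.append((sid, j, float(v), True))
    return EmaDataset(pd.DataFrame(rows, columns=["subject_id", "occasion", "value", "observed"]))


def simulate_dataset(cfg: DgpConfig, seed: int):
    rng = np.random.default_rng(seed)
    truth = generate_subject_truth(cfg, rng)
    data = generate_observations(truth, cfg, rng)
    return truth, data


@pytest.fixture(scope="session")
def quickfit():
    """20-subject fixture plus its (converged) MELS fit, shared across tests."""
    data, truth = make_fixture("quickfit20", seed=3)
    fit = fit_mels(data, MelsSettings(n_quad=15))
    assert fit.converged
    return data, truth, fit


@pytest.fixture(scope="session")
def oracle_limit_dataset():
    """20 subjects x 8 occasions with (near-)homogeneous within-subject
    variance — the regime where the random-intercept closed form applies."""
    cfg = DgpConfig(n_subjects=20, n_obs=8, sd_logscale=1e-4, seed=7)
    return simulate_dataset(cfg, 7)[1]


@pytest.fixture(scope="session")
def replicate_300x30():
    """One full-size replicate from known parameters, for EB diagnostics."""
    cfg = DgpConfig(n_subjects=300, n_obs=30, sd_logscale=0.6, seed=42)
    truth, data = simulate_dataset(cfg, 42)
    true_params = MelsParams(beta0=0.0, tau0=0.0, sigma_v=1.0, sigma_w=1.2, rho_vw=0.0)
    return truth, data, true_params
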