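import logging

import numpy as np
import pytest

from neopain.core import Trace
from neopain.features import extract_feature_table
from neopain.synthetic import CohortConfig, make_template, simulate_cohort

logging.getLogger("neopain").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def template500():
    return make_template(500.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort at the default (moderate-effect) settings."""
    return simulate_cohort(CohortConfig(n_subjects=6, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort with unit responsiveness: closed-loop ground truth."""
    cfg = CohortConfig(n_subjects=4, seed=7, eeg_noise_sd_uv=0.0,
                       responsiveness_sd=0.0, eeg_amp_uv=10.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_table(clean_cohort):
    table, _ = extract_feature_table(clean_cohort)
    return table


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table, _ = extract_feature_table(small_cohort)
    return table


def embed_template_epoch(template, amplitude=1.0, delay_s=0.0, noise_sd=0.0,
                         rng=None, span=(-0.5, 1.0)):
    """An EEG-like epoch containing the template at a given amplitude and
    latency shift, used as constructed input across tests."""
    fs = template.fs
    n = int(round((span[1] - span[0]) * fs))
    t = span[0] + np.arange(n) / fs
    from neopain.synthetic import template_curve, _template_norm
    x = amplitude * template_curve(t - delay_s) / _template_norm(fs)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        x = x + rng.normal(0.0, noise_sd, n)
    return Trace(x, fs, span[0])
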