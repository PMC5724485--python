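import copy

import numpy as np
import pytest

from trajarea.config import default_config, simple_config
from trajarea.generator import generate_trial
from trajarea.occasions import OccasionSpec


def make_specs(times=(15, 27, 39), outcome="score", baseline="score_9",
               covariates=("centre", "maternal_education")):
    """Occasion specs for the simple one-instrument battery."""
    return [
        OccasionSpec.from_dict(
            dict(label=f"t{t}", time=t, outcome=f"{outcome}_{t}", baseline=baseline,
                 covariates=list(covariates))
        )
        for t in times
    ]


def trial_missingness():
    """Visit-missingness pattern matching the published per-occasion Ns."""
    return {
        "control": {9: 0.0, 15: 0.0, 27: 1 / 26, 39: 2 / 26},
        "intervention": {9: 0.0, 15: 1 / 28, 27: 5 / 28, 39: 1 / 28},
    }


def null_default_config(**overrides):
    """Full default battery with intervention moments forced equal to control."""
    cfg = default_config(**overrides)
    for inst in cfg.instruments:
        inst.means = {"control": dict(inst.means["control"]),
                      "intervention": dict(inst.means["control"])}
        inst.sds = {"control": dict(inst.sds["control"]),
                    "intervention": dict(inst.sds["control"])}
    return cfg


@pytest.fixture
def small_dataset():
    cfg = simple_config(n_per_arm=40, seed=42, missingness=trial_missingness())
    return generate_trial(cfg)


@pytest.fixture
def complete_dataset():
    cfg = simple_config(n_per_arm=30, seed=7, missingness={})
    return generate_trial(cfg)


@pytest.fixture
def default_dataset():
    return generate_trial(default_config(seed=12))
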