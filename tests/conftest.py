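import numpy as np
import pytest

from fogkit.datamodel import Medication, StopCondition, Task, TrialMetadata
from fogkit.detector import (
    DetectorConfig,
    InitialBlockConfig,
    RefinementConfig,
    TrainConfig,
)
from fogkit.simulate import SimConfig, simulate_trial


def small_detector_config(seed: int = 0, epochs: int = 12) -> DetectorConfig:
    """Reduced-size detector used throughout the tests.

    Seven dilated layers give a ~4 s receptive field at 64 Hz; 16 filters and
    a single refinement stage are ample for the synthetic class structure.
    """
    return DetectorConfig(
        initial_block=InitialBlockConfig(n_layers=7, filters_per_layer=16, dropout=0.1),
        refinement_block=RefinementConfig(n_stages=1, layers_per_stage=7, filters=16),
        train=TrainConfig(epochs=epochs, learning_rate=5e-3, seed=seed),
    )


def clinical_metadata(subject="S1", trial="t0", task=Task.TUG, dual=True):
    return TrialMetadata(subject, trial, task, Medication.OFF, dual, StopCondition.NONE)


@pytest.fixture(scope="session")
def overfit_trials():
    """Five high-severity clinical trials for capacity/overfit checks."""
    cfg = SimConfig(seed=1)
    return [
        simulate_trial(cfg, clinical_metadata(trial=f"t{i}"), seed=100 + i, severity=2.0)
        for i in range(5)
    ]
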