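import numpy as np
import pytest
from hypothesis import settings

from vertpsm import NeutralCalibration, PopulationHistory, PSMParameters

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def reference_cal() -> NeutralCalibration:
    """Neutral calibration at the published scale: sigma_r = 0.018, n = 64."""
    return NeutralCalibration(mu_r=0.0, sigma_r=0.018, n_neutral=64)


@pytest.fixture()
def default_params() -> PSMParameters:
    return PSMParameters.default()


def make_history(counts, generations=None, labels=None, experiment_id="test"):
    counts = np.asarray(counts, dtype=float)
    n, J = counts.shape
    if generations is None:
        generations = np.arange(n, dtype=float) * 10.0
    if labels is None:
        labels = tuple(f"s{j + 1}" for j in range(J))
    return PopulationHistory(
        experiment_id=experiment_id,
        subpopulation_labels=tuple(labels),
        generations=np.asarray(generations, dtype=float),
        counts=counts,
    )


@pytest.fixture()
def history_factory():
    return make_history
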