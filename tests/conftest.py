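import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neuropose.datasets import NeuronDataset
from neuropose.design import TaskDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


def make_tilt_dataset(rows, design=None, spike_times=None,
                      response_window=(46.0, 1000.0)):
    """Build a minimal tilt-task dataset from (tilt, slant, distance,
    spike_count, reported_tilt) tuples."""
    design = design or TaskDesign()
    df = pd.DataFrame(rows, columns=["tilt", "slant", "distance_cm",
                                     "spike_count", "reported_tilt"])
    df.insert(0, "neuron_id", "toy")
    df.insert(1, "task", "tilt")
    df.insert(2, "block", 0)
    df["saccade_dir"] = np.nan
    df["saccade_latency_ms"] = np.nan
    return NeuronDataset("toy", design, df, spike_times=spike_times,
                         response_window=response_window)


@pytest.fixture(scope="session")
def tuned_neuron(design):
    """One pose-tuned simulated neuron, counts only (session-cached)."""
    from neuropose import synth
    rng = np.random.default_rng(1234)
    truth = synth.make_ground_truth(design, rng, cross_distance_jitter=0.0)
    data = synth.simulate_neuron(truth, design, n_blocks=10, seed=99,
                                 spike_times="none")
    return truth, data
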