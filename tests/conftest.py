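import numpy as np
import pytest

from agile_har import pipeline as pl
from agile_har import simulate as sim
from agile_har.backbone import TrainConfig
from agile_har.simulate import DriftSpec, inject_drift


@pytest.fixture(scope="session")
def train_stream() -> sim.LabeledStream:
    """Reference 100 s training stream (default simulator conditions)."""
    return sim.generate_stream(sim.SimulatorConfig(duration=6000, seed=11))


@pytest.fixture(scope="session")
def pipeline_cfg() -> pl.PipelineConfig:
    cfg = pl.PipelineConfig()
    cfg.train = TrainConfig(epochs=12, seed=0)
    return cfg


@pytest.fixture(scope="session")
def trained_model(train_stream, pipeline_cfg) -> pl.TrainedModel:
    """Backbone + importance table trained once for the whole session."""
    return pl.fit_pipeline(train_stream, pipeline_cfg)


@pytest.fixture(scope="session")
def drift_stream() -> sim.LabeledStream:
    """Held-out stream with a 2-sigma mean shift on all channels mid-way."""
    stream = sim.generate_stream(sim.SimulatorConfig(duration=6400, seed=99))
    return inject_drift(stream, DriftSpec(onset=3600, kind="mean_shift", magnitude=2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
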