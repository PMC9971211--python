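import warnings

import pytest

from methylsignal import (FisherBaselineModel, MethylSignalModel,
                          PipelineConfig, simulate_experiment)
from methylsignal.simulate import GenomeSpec, SimulationDesign


@pytest.fixture(scope="session")
def planted_experiment():
    """Default desk-scale experiment with 20 strongly planted genes."""
    return simulate_experiment(GenomeSpec(), SimulationDesign(seed=42))


@pytest.fixture(scope="session")
def sd_results(planted_experiment):
    samples, truth = planted_experiment
    model = MethylSignalModel(samples, truth.genes, PipelineConfig(seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


@pytest.fixture(scope="session")
def baseline_results(planted_experiment):
    samples, truth = planted_experiment
    return FisherBaselineModel(samples, truth.genes, PipelineConfig()).fit()
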