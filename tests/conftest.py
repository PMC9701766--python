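import pytest

import spinereg as sr
from spinereg.experiment import ExperimentConfig, run_validation_experiment
from spinereg.projection import default_environment


@pytest.fixture(scope="session")
def env():
    return default_environment()


@pytest.fixture(scope="session")
def nominal_shapes():
    return sr.default_shape_set(seed=0)


@pytest.fixture(scope="session")
def nominal_vertebra(nominal_shapes):
    return sr.make_vertebra(nominal_shapes[2])


@pytest.fixture(scope="session")
def straight_spine(nominal_shapes):
    """Wedge-free straight stack: all intersegmental angles zero."""
    import dataclasses

    shapes = [dataclasses.replace(s, wedge_angle=0.0) for s in nominal_shapes]
    plan = sr.SagittalPlan((0.0,) * 5, (10.0,) * 5)
    return sr.assemble_spine(shapes, plan)


@pytest.fixture(scope="session")
def lordotic_spine(nominal_shapes):
    """Wedge-free model with five equal 10-degree segments (LL = 50)."""
    import dataclasses

    shapes = [dataclasses.replace(s, wedge_angle=0.0) for s in nominal_shapes]
    plan = sr.SagittalPlan((10.0,) * 5, (11.0,) * 5)
    return sr.assemble_spine(shapes, plan)


@pytest.fixture(scope="session")
def batch_experiment():
    """The seeded 20-case, two-repeat synthetic registration experiment
    with exact full silhouette-derived contours (shared across the
    accuracy/reproducibility acceptance checks)."""
    cfg = ExperimentConfig(n_cases=20, seed=1)
    return run_validation_experiment(cfg)
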