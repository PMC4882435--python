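import numpy as np
import pytest

from ampharm.fixtures import load_table1, load_table2, load_table3, load_table4
from ampharm.simulate import DoseResponseExperiment, default_concentrations


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def table4():
    return load_table4()


def make_experiment(
    basal=0.0,
    top=100.0,
    pec50=9.0,
    hill=1.0,
    concentrations=None,
    noise_sd=0.0,
    n_replicates=1,
    seed=0,
    construct="X",
    receptor="AM1",
    experiment="e1",
):
    """Build a synthetic experiment directly from analytic curve values."""
    from ampharm.fitting import logistic4

    concs = tuple(concentrations or default_concentrations())
    logc = np.log10(np.array(concs))
    mean = logistic4(logc, basal, top, pec50, hill)
    rng = np.random.default_rng(seed)
    points = []
    for c, mu in zip(concs, mean):
        if noise_sd > 0:
            reps = mu + noise_sd * rng.standard_normal(n_replicates)
        else:
            reps = np.full(n_replicates, mu)
        points.append((float(c), tuple(float(r) for r in reps)))
    return DoseResponseExperiment(
        construct=construct,
        receptor=receptor,
        experiment=experiment,
        points=tuple(points),
    )
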