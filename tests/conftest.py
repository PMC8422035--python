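import pytest
from hypothesis import HealthCheck, settings

from skilldiag.data_io import load_builtin_item_bank, load_builtin_qmatrix
from skilldiag.experiment import StudyConfig, run_study
from skilldiag.oracles import make_toy_suite

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def qmatrix():
    return load_builtin_qmatrix()


@pytest.fixture(scope="session")
def item_bank():
    return load_builtin_item_bank()


@pytest.fixture(scope="session")
def toy_suite():
    return {case.name: case for case in make_toy_suite()}


@pytest.fixture(scope="session")
def desk_study():
    """Shared reduced-scale study run: 4 subskill correlations, 3
    replications of N = 1,500, 11-point quadrature, all three models.

    Pooled classification rates at this scale carry a sampling error of
    roughly 0.007, well inside the 0.03 tolerance used by the
    reproduction checks.
    """
    config = StudyConfig(
        correlations=(0.1, 0.3, 0.5, 0.9), n_persons=1500,
        n_replications=3, quad_points=11, base_seed=0, keep_scores=True,
    )
    return run_study(config)
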