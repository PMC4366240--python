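import numpy as np
import pytest

from p53targets.pipeline import run_pipeline
from p53targets.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run at the default study-structured configuration.

    Session-scoped: the end-to-end checks (ranking quality, pass-set
    precision/recall, HC recovery, CGI enrichment) all read from this single
    run so the suite pays the simulation cost once.
    """
    return run_pipeline(SimulationConfig())


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for fast smoke tests."""
    return SimulationConfig(
        n_genes=120,
        n_bound_genes=24,
        n_responsive_genes=24,
        n_target_genes=15,
        seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20150319)
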