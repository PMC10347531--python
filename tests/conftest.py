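import numpy as np
import pytest

from freqec import CohortSpec, CouplingEdge, default_network_labels, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_cohort():
    """Small coupled cohort reused by mechanics tests (not effect-size tests)."""
    edge = CouplingEdge(source=5, target=2, band=1, lag=1,
                        strength_controls=0.0, strength_patients=0.6)
    spec = CohortSpec(
        n_patients=10,
        n_controls=12,
        n_components=8,
        network_labels=default_network_labels(8),
        n_timepoints=200,
        bands=((0.12, 0.18), (0.04, 0.08), (0.01, 0.04)),
        coupling_edges=(edge,),
        seed=7,
    )
    metadata, tcs, truth = generate_cohort(spec)
    return spec, metadata, tcs, truth
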