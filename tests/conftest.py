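import math

import pytest
from hypothesis import settings

from tractflux import CultureObservation, FluctuationExperiment

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_experiment(
    n_total: float,
    f: float,
    n_cultures: int = 11,
    strain: str = "fixture",
    tract_id: str = "fixture",
    sel_fraction: float = 1.0,
    ns_dilution: float = 1e-6,
) -> FluctuationExperiment:
    """Experiment of identical cultures with exact population size and frequency.

    ns_colonies = N * ns_dilution and sel_colonies = f * N * sel_fraction,
    possibly fractional (analytic fixture, not a simulated plate).
    """
    cultures = [
        CultureObservation(
            culture_id=f"{strain}.c{i}",
            sel_colonies=f * n_total * sel_fraction,
            sel_plating_fraction=sel_fraction,
            ns_colonies=n_total * ns_dilution,
            ns_dilution_fraction=ns_dilution,
        )
        for i in range(n_cultures)
    ]
    return FluctuationExperiment(strain=strain, tract_id=tract_id, cultures=cultures)


def drake_frequency(mu: float, n_total: float) -> float:
    """Forward evaluation f = mu * ln(N * mu); inverse of the Drake solve."""
    return mu * math.log(n_total * mu)


@pytest.fixture
def experiment_factory():
    return make_experiment
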