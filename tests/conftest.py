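import numpy as np
import pytest
from hypothesis import settings

from solnmr import (EnsembleSpec, InjectionSchedule, simulate_ensemble)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def paper_schedule() -> InjectionSchedule:
    """Printed experimental layout: 20 x 2 uL of 500 uM titrant into
    50 uM macromolecule in a 200 uL cell at 25 C."""
    return InjectionSchedule(n_injections=20, injection_volume=2.0,
                             cell_volume=200.0, cell_conc=50.0,
                             syringe_conc=500.0, temperature=298.15)


@pytest.fixture
def small_ensemble():
    """10-model, 12-residue synthetic ensemble with a high-scatter segment
    (residues 5-7 at 1.3 A, rest at 0.3 A)."""
    scatter = tuple(1.3 if 5 <= r <= 7 else 0.3 for r in range(1, 13))
    return simulate_ensemble(EnsembleSpec(
        n_models=10, n_residues=12, scatter_profile=scatter, seed=7,
        sidechain_scale=2.0))
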