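from __future__ import annotations

import pytest

from tnbc_claims import MoleculeCatalog, SimulationConfig, simulate


@pytest.fixture(scope="session")
def catalog() -> MoleculeCatalog:
    return MoleculeCatalog()


@pytest.fixture(scope="session")
def demo_cohort():
    """A 300-patient simulated cohort with planted contaminants."""
    cfg = SimulationConfig(
        n_patients=300,
        seed=42,
        contaminant_fractions={
            "screening_only": 0.05,
            "hormone_therapy_user": 0.05,
            "pre2012_activity": 0.03,
        },
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """A 600-patient cohort with no contaminants (for recovery tests)."""
    return simulate(SimulationConfig(n_patients=600, seed=7))
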