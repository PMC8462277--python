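import numpy as np
import pytest

from mitoveritas import MitogenomeScreen, make_cohort, simulate_panel
from mitoveritas.simulate import PanelConfig

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(BASES, size=length).tobytes().decode()


@pytest.fixture(scope="session")
def panel():
    """Default simulated reference panel (8 species x 2 individuals)."""
    return simulate_panel(PanelConfig(), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 60-record defect cohort."""
    return make_cohort(seed=42, n=60)


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Full screen of the default cohort (shared: fitting takes ~1 min)."""
    return MitogenomeScreen.from_cohort(default_cohort).fit()
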