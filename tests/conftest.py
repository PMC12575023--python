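import numpy as np
import pytest

from micronet.core import DoseDesign, OtuTable


@pytest.fixture(scope="session")
def design() -> DoseDesign:
    return DoseDesign()


@pytest.fixture
def toy_table() -> OtuTable:
    """Five OTUs with prevalences (1, 1, 2, 3, 5) over five samples."""
    counts = np.array(
        [
            [3, 0, 1, 2, 9],
            [0, 0, 0, 5, 4],
            [0, 0, 2, 0, 1],
            [0, 4, 0, 3, 2],
            [0, 0, 0, 0, 7],
        ]
    )
    samples = tuple(f"s{i}" for i in range(1, 6))
    groups = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(samples)}
    return OtuTable(samples, tuple(f"o{i}" for i in range(1, 6)), counts, groups)


@pytest.fixture(scope="session")
def simulated():
    """One default simulated dose-response table shared across tests."""
    from micronet.simulate import simulate_otu_table

    return simulate_otu_table(seed=1)
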