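import numpy as np
import pytest

from umicna.panel import Panel
from umicna.counts import UmiCountMatrix, normalize
from umicna.reference import build_pseudo_reference
from umicna.simulate import SimPanel, simulate_controls


@pytest.fixture(scope="session")
def small_panel() -> Panel:
    """Three regions over two genes on one chromosome."""
    return Panel(
        [
            ("chr1", 100, 200, "ALPHA"),
            ("chr1", 300, 400, "ALPHA"),
            ("chr1", 600, 700, "BETA"),
        ]
    )


@pytest.fixture(scope="session")
def sim_panel() -> SimPanel:
    """Desk-scale synthetic panel: 8 genes x 10 regions."""
    return SimPanel.build(n_genes=8, regions_per_gene=10, seed=101)


@pytest.fixture(scope="session")
def control_matrix(sim_panel) -> UmiCountMatrix:
    return simulate_controls(sim_panel, n_samples=5, seed=202)


@pytest.fixture(scope="session")
def reference(control_matrix):
    return build_pseudo_reference(normalize(control_matrix))
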