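import numpy as np
import pytest

from erythrokit import synthetic as syn


@pytest.fixture(scope="session")
def bead_events():
    """Default noisy bead acquisition at the six manufacturer diameters."""
    return syn.gen_bead_events(syn.BeadSpec(), seed=101)


@pytest.fixture(scope="session")
def bead_calibration(bead_events):
    from erythrokit import morphometry as mm

    return mm.fit_bead_calibration(bead_events)


@pytest.fixture(scope="session")
def erythroid_events():
    """Two nucleated stages (7.5 / 6.7 μm) plus 30% enucleated reticulocytes."""
    stages = [
        syn.StageSpec("epor", 0.35, 7.5, 0.08, 0.08, 0.02),
        syn.StageSpec("bclxl", 0.35, 6.7, 0.08, 0.20, 0.03),
        syn.StageSpec("retic", 0.30, 5.6, 0.09, 0.0, 0.0, nucleated=False),
    ]
    return syn.gen_erythroid_events(stages, n=50_000, seed=202)


@pytest.fixture(scope="session")
def cbc_panel():
    return syn.gen_cbc_panel(syn.study1_design(), seed=303)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
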