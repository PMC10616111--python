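import numpy as np
import pytest

from riboscreen.screen import run_screen
from riboscreen.simulate import SimScenario, simulate_scenario


@pytest.fixture(scope="session")
def default_sim():
    """Default two-condition scenario: 30 coding transcripts, 100 lncRNAs
    (20 translated lncORFs with planted 4-fold induction, 80 decoys)."""
    return simulate_scenario(SimScenario(seed=1))


@pytest.fixture(scope="session")
def default_screen(default_sim):
    transcripts, _, _, alignments, libraries = default_sim
    return run_screen(transcripts, alignments, libraries)


@pytest.fixture(scope="session")
def fidelity_sim():
    """Small clean scenario (no background) for signal-recovery checks."""
    scen = SimScenario(
        seed=3,
        n_coding=2,
        n_lnc=2,
        frac_translated_lnc=1.0,
        periodicity=0.9,
        utr_leak=0.05,
        n_reps=1,
        reads_per_lib_ribo=20_000,
        reads_per_lib_rna=5_000,
        background=0.0,
    )
    return scen, simulate_scenario(scen)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
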