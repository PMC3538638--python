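import numpy as np
import pytest
from hypothesis import settings

from mfe2dh import BondProgram, BondWatch, make_toy_dimer, simulate_trajectory

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_dimer():
    """Small two-chain reference structure with a threonine analog at
    residue 5 and an asparagine analog at residue 9."""
    return make_toy_dimer(12, seed=7, residue_types={5: "THR", 9: "ASN"})


@pytest.fixture(scope="session")
def jitter_trajectory(toy_dimer):
    """50-frame unprogrammed ensemble around the toy dimer."""
    return simulate_trajectory(toy_dimer, {}, n_frames=50, seed=11, label="toy")


@pytest.fixture(scope="session")
def breaking_trajectory(toy_dimer):
    """Trajectory where the A-chain Thr5 OG1 -> Asn9 N bond steps 3 -> 5 A
    at 40% of the run, in both monomers."""
    prog = BondProgram("breaking", 3.0, 5.0, break_fraction=0.4)
    watches = {
        BondWatch(("A", 5, "OG1"), ("A", 9, "N")): prog,
        BondWatch(("B", 5, "OG1"), ("B", 9, "N")): prog,
    }
    return simulate_trajectory(toy_dimer, watches, n_frames=200, seed=13, label="breaking")
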