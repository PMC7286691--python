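import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rloopflank.reactivity import RlfMember, SubstrateMap
from rloopflank.synthetic import ReplicateActivity, SimulationConfig, TrueRateProfile


def rates_for_q(q, t=2.0):
    """Rate constants producing oxidation probabilities q at quench time t."""
    return tuple(-math.log1p(-qi) / t for qi in q)


@pytest.fixture
def two_thymine_profile():
    """Two probed thymines with q = [0.2, 0.5] at t = 2 min."""
    return TrueRateProfile("sub1", rates_for_q([0.2, 0.5]), quench_time_min=2.0)


@pytest.fixture
def unit_activity():
    return ReplicateActivity("rep1", 1.0)


@pytest.fixture
def big_config():
    return SimulationConfig(n_molecules=10**6, seed=20260101)


@pytest.fixture
def flank_substrate():
    """A duplex with a probed flank: 5 thymines on the labeled strand.

    Positions count from the 5'-labeled end; position 10 is the reference
    thymine, positions 3-7 form the R-loop flank (this labeling's share).
    """
    #        123456789012345
    seq   = "GCTTTTTCATGCGCA"
    comp  = "TGCGCATGAAAAAGC"
    return SubstrateMap(
        substrate_id="sub1",
        strand_sequences={"NTS": seq, "TS": comp},
        labeled_strand="NTS",
        probed_thymines=(3, 4, 5, 6, 7, 10),
        reference_thymine=10,
        quench_time_min=2.0,
        rlf_members=tuple(
            RlfMember(label=f"T{i}", strand="NTS", position=p)
            for i, p in enumerate((3, 4, 5, 6, 7), start=1)
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
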