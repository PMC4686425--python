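import numpy as np
import pytest

from kogbody import simulate as sim


@pytest.fixture
def formation_truth():
    """Canonical glucose-starvation formation parameters used across tests."""
    return {"A": 0.49, "tau": 11.0, "c": 0.08}


@pytest.fixture
def lane_batch():
    """Noiseless lanes spanning the full phosphorylation range.

    wt_t0 is fully shifted (rich medium), wt_60 fully collapsed (starved);
    intermediate lanes have known mixed fractions.
    """
    fractions = {"wt_t0": 1.0, "q1": 0.75, "q2": 0.5, "q3": 0.25, "wt_60": 0.0}
    lanes = [
        sim.simulate_lane(
            sim.LaneSimSpec(phospho_fraction=f, noise_sd=0.0, seed=i),
            lane_id=lane_id,
        )
        for i, (lane_id, f) in enumerate(fractions.items())
    ]
    return lanes, fractions
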