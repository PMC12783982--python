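import numpy as np
import pandas as pd
import pytest

import odorpop as op
from odorpop.simulate import RecordingSession, Unit


@pytest.fixture(scope="session")
def control_session():
    session, truths = op.generate_session(op.control_preset(n_units=30, seed=7))
    return session, truths


@pytest.fixture(scope="session")
def mutant_session():
    session, truths = op.generate_session(op.mutant_preset(n_units=30, seed=8))
    return session, truths


def make_session(unit_spikes: dict, trials: pd.DataFrame, duration: float,
                 genotype="control", region="MOB") -> RecordingSession:
    """Hand-crafted session from {unit_id: spike time list}."""
    units = [
        Unit(uid, tetrode_id=i, spike_times=np.asarray(sorted(times), dtype=float))
        for i, (uid, times) in enumerate(unit_spikes.items())
    ]
    return RecordingSession(
        session_id=f"handmade-{genotype}",
        genotype=genotype,
        region=region,
        units=units,
        trials=trials.reset_index(drop=True),
        duration=duration,
    )


def simple_trials(odour_carbons, onsets, duration=0.5) -> pd.DataFrame:
    onsets = np.asarray(onsets, dtype=float)
    return pd.DataFrame(
        {
            "trial_id": np.arange(onsets.size),
            "odour_carbon": np.asarray(odour_carbons, dtype=int),
            "onset_s": onsets,
            "offset_s": onsets + duration,
        }
    )
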