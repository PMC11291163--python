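import numpy as np
import pandas as pd
import pytest

from cptstates import synthetic as syn
from cptstates.behavior import BehaviorSession


def make_session(outcomes, stage="stage3", trial_spacing_s=10.0, latency_s=1.5,
                 corrections=None, session_length_s=None):
    """Build a BehaviorSession from a list of outcomes ('hit'/'miss'/'FA'/'CR')."""
    rows = []
    for i, out in enumerate(outcomes):
        onset = 5.0 + i * trial_spacing_s
        stim = "S+" if out in ("hit", "miss") else "S-"
        resp = onset + latency_s if out in ("hit", "FA") else np.nan
        corr = bool(corrections[i]) if corrections is not None else False
        rows.append(
            {
                "trial_index": i,
                "stimulus": stim,
                "onset_s": onset,
                "response_s": resp,
                "outcome": out,
                "correction": corr,
            }
        )
    length = session_length_s or (5.0 + len(outcomes) * trial_spacing_s + 10.0)
    return BehaviorSession(pd.DataFrame(rows), session_length_s=length, stage=stage)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic session: 40 neurons, 10 minutes."""
    return syn.SyntheticConfig(
        n_neurons=40,
        session_length_s=600.0,
        state_mean_dwell_s=(40.0, 40.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return syn.generate_session(small_config)


@pytest.fixture(scope="session")
def strong_session():
    """Medium session with strong planted peri-event modulation."""
    cfg = syn.SyntheticConfig(
        n_neurons=60,
        session_length_s=1200.0,
        p_respond_engaged=0.95,
        p_respond_disengaged=0.1,
        frac_up=0.2,
        frac_down=0.1,
        event_effect_size=2.0,
        seed=11,
    )
    return cfg, syn.generate_session(cfg)
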