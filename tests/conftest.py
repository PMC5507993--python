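import numpy as np
import pytest

from passnet.event_model import MatchLog, PassEvent
from passnet.synthetic_match import SimParams


def ev(
    t,
    actor,
    action="pass",
    receiver=None,
    completed=None,
    zone=2,
    team="A",
    half=1,
    restart="open_play",
    match_id="m1",
):
    """Shorthand PassEvent constructor for hand-built fixtures."""
    if completed is None:
        completed = action == "pass" and receiver is not None
    return PassEvent(
        match_id=match_id,
        half=half,
        t=float(t),
        team=team,
        actor=actor,
        action=action,
        receiver=receiver,
        completed=completed,
        zone=zone,
        restart=restart,
    )


def make_log(events, team_ids=("A", "B"), half_durations=(2700.0, 2700.0), match_id="m1"):
    return MatchLog(
        match_id=match_id, team_ids=team_ids, half_durations=half_durations, events=events
    )


@pytest.fixture
def tiny_log():
    """Ten events: two full possessions (A then B) and a lone incomplete pass."""
    events = [
        ev(0, 1, receiver=2),
        ev(2, 2, receiver=3),
        ev(4, 3, receiver=5, zone=3),
        ev(6, 5, "loss", zone=3),
        ev(10, 4, team="B", receiver=6),
        ev(12, 6, team="B", receiver=9, zone=3),
        ev(14, 9, "shot", team="B", zone=4),
        ev(20, 7, "pass", completed=False, zone=1),
        ev(25, 2, receiver=8, half=2),
        ev(27, 8, "loss", zone=2, half=2),
    ]
    return make_log(events)


@pytest.fixture
def sim_params():
    """Small, fast simulator settings with the default planted model."""
    return SimParams(seed=123, n_matches=2, mean_possessions_per_period=10)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
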