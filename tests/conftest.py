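import numpy as np
import pytest

from airbreath import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_cfg():
    """Study config scaled down for fast unit tests."""
    cfg = sim.SimConfig(seed=42, n_groups=3)
    cfg.respirometry.n_cycles = 12
    return cfg


def random_trial(rng, n_fish=4, duration=900.0, n_events=None):
    """A random small trial over the full ethogram, for oracle checks."""
    from airbreath.ethogram import BehaviourEvent, Trial

    roster = tuple(f"f{i}" for i in range(n_fish))
    n = int(rng.integers(0, 25)) if n_events is None else n_events
    events = []
    for _ in range(n):
        actor = str(rng.choice(roster))
        behaviour = str(rng.choice(["breath", "attack", "push", "avoid"]))
        target = None
        if behaviour in ("attack", "push"):
            target = str(rng.choice([f for f in roster if f != actor]))
        events.append(
            BehaviourEvent(
                time=float(np.round(rng.uniform(0, duration), 1)),
                fish_id=actor,
                behaviour=behaviour,
                target_id=target,
            )
        )
    return Trial(
        group_id="g", oxygen_level="100", roster=roster,
        events=events, duration=duration,
    )
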