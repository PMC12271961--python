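from pathlib import Path

import pandas as pd
import pytest

import inactigraphy as ig

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"
GOLDEN_DIR = Path(__file__).parent / "data" / "golden"


def make_sessions(rows, participant_id="p1", day="2022-03-01"):
    """Build a session frame from (app_id, start_clock, end_clock) tuples.

    Clock values are 'HH:MM' strings or float hours; values >= 24 roll into
    the next day.
    """
    base = pd.Timestamp(day)

    def at(clock):
        h = ig.nights.parse_clock(clock) if not isinstance(clock, (int, float)) \
            else float(clock)
        return base + pd.Timedelta(hours=h)

    return pd.DataFrame({
        "participant_id": participant_id,
        "app_id": [r[0] for r in rows],
        "start": [at(r[1]) for r in rows],
        "end": [at(r[2]) for r in rows],
    })


@pytest.fixture(scope="session")
def default_map():
    return ig.default_mapping()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic null cohort shared across read-only tests."""
    cfg = ig.scenario("null", n_participants=30, n_days=7, seed=11)
    return ig.simulate_cohort(cfg)
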