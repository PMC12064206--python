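import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from leisurenet import default_config, generate_diaries
from leisurenet.network import ActivityNetwork


def make_diary_frame(rows: list[dict]) -> pd.DataFrame:
    """Fill canonical diary columns around the fields a test cares about."""
    defaults = dict(person_id="P1", age=15, sex="female", education="middle",
                    swb_score=2, health_score=1, leisure_satisfaction=3,
                    day_type="weekday", activity_code="Reading books", minutes=30)
    return pd.DataFrame([{**defaults, **row} for row in rows])


def as_network(graph: nx.Graph, **kwargs) -> ActivityNetwork:
    for a, b in graph.edges:
        graph.edges[a, b].setdefault("weight", 1.0)
    return ActivityNetwork(graph=graph, threshold_used=kwargs.pop("tau", 0.0), **kwargs)


@pytest.fixture(scope="session")
def default_diaries() -> pd.DataFrame:
    """One default synthetic dataset shared across tests (seed 42)."""
    return generate_diaries(default_config(seed=42))


@pytest.fixture()
def toy_diaries() -> pd.DataFrame:
    """Two high-SWB diarists: A does {Sleeping, Watching live TV},
    B does {Sleeping} on weekdays."""
    return make_diary_frame([
        {"person_id": "A", "activity_code": "Sleeping", "minutes": 400},
        {"person_id": "A", "activity_code": "Watching live TV", "minutes": 60},
        {"person_id": "B", "activity_code": "Sleeping", "minutes": 380},
    ])
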