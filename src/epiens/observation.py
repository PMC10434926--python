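"""Observation models: sparse, time-stamped perfect tests of node states.

Two regimes are modelled.  Under *random testing*, each node is tested on
each day with a probability that depends on its true state that day (the
infected are tested more often, as they are more likely to show symptoms).
Under *contact tracing*, the same base testing runs, but whenever a node is
observed infectious on day t, all of its network neighbors are tested on
day t+1; positives found by tracing trigger further tracing.

Tests are perfect: an observation reports the node's true state.  A node may
be tested on several days; at most one record is kept per (node, day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import Network
from .outbreak_sim import I, LABEL_TO_STATE, STATE_LABELS, OutbreakTrajectory

__all__ = [
    "Observation",
    "ObservationSet",
    "random_testing",
    "contact_tracing",
    "observed_fraction",
    "DEFAULT_TEST_PROBS",
]

# Default state-dependent daily test probabilities, keyed by target observed
# fraction of the population on the ER benchmark (7-day outbreak).
DEFAULT_TEST_PROBS = {
    0.16: {"q_S": 0.016, "q_I": 0.090, "q_R": 0.033},
    0.30: {"q_S": 0.035, "q_I": 0.175, "q_R": 0.064},
    0.50: {"q_S": 0.070, "q_I": 0.320, "q_R": 0.120},
}


@dataclass(frozen=True)
class Observation:
    """One record: node ``node`` was observed in ``state`` on day ``day``."""

    node: int
    day: int
    state: int  # integer code S=0, I=1, R=2

    @property
    def state_label(self) -> str:
        return str(STATE_LABELS[self.state])


@dataclass
class ObservationSet:
    """The data D = {(i_o, t_o, O)} consumed by every inference method."""

    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = {(o.node, o.day) for o in self.observations}
        if len(seen) != len(self.observations):
            raise ValueError("duplicate (node, day) observation records")
        self.observations = sorted(self.observations, key=lambda o: (o.day, o.node))

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def by_day(self) -> dict[int, list[Observation]]:
        out: dict[int, list[Observation]] = {}
        for o in self.observations:
            out.setdefault(o.day, []).append(o)
        return out

    @property
    def last_day(self) -> int | None:
        return max((o.day for o in self.observations), default=None)

    def observed_nodes(self) -> set[int]:
        return {o.node for o in self.observations}

    def nodes_observed_infected(self) -> set[int]:
        return {o.node for o in self.observations if o.state == I}

    def nodes_observed_on(self, day: int) -> set[int]:
        return {o.node for o in self.observations if o.day == day}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": [o.node for o in self.observations],
                "day": [o.day for o in self.observations],
                "state": [o.state_label for o in self.observations],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        df = pd.read_csv(path)
        obs = [
            Observation(int(r.node), int(r.day), LABEL_TO_STATE[r.state])
            for r in df.itertuples()
        ]
        return cls(observations=obs)


def _daily_base_tests(
    trajectory: OutbreakTrajectory,
    q: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Draw (day, node) base-testing events for days 1..T.

    Day 0 is never tested: observing the seeding event itself is excluded.
    """
    events = []
    n = trajectory.n_nodes
    for t in range(1, trajectory.T + 1):
        p = q[trajectory.states[t]]
        tested = np.flatnonzero(rng.random(n) < p)
        events.extend((t, int(i)) for i in tested)
    return events


def random_testing(
    trajectory: OutbreakTrajectory,
    q_S: float,
    q_I: float,
    q_R: float,
    rng: np.random.Generator,
) -> ObservationSet:
    """State-dependent daily testing: on each day 1..T each node is tested
    with the probability matching its true state; each test is a perfect
    observation of that state."""
    for name, v in (("q_S", q_S), ("q_I", q_I), ("q_R", q_R)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    q = np.array([q_S, q_I, q_R])
    obs = [
        Observation(node, day, int(trajectory.states[day, node]))
        for day, node in _daily_base_tests(trajectory, q, rng)
    ]
    return ObservationSet(observations=obs)


def contact_tracing(
    trajectory: OutbreakTrajectory,
    network: Network,
    q_S: float,
    q_I: float,
    q_R: float,
    rng: np.random.Generator,
) -> ObservationSet:
    """Base daily testing plus tracing: every neighbor of a node observed
    infectious on day t is tested (with certainty) on day t+1; positives
    found by tracing recursively trigger further tracing."""
    for name, v in (("q_S", q_S), ("q_I", q_I), ("q_R", q_R)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if trajectory.T < 1:
        raise ValueError("trajectory must span at least 2 days")
    q = np.array([q_S, q_I, q_R])
    base = _daily_base_tests(trajectory, q, rng)
    tested_by_day: dict[int, set[int]] = {}
    for day, node in base:
        tested_by_day.setdefault(day, set()).add(node)

    records: dict[tuple[int, int], int] = {}
    for t in range(1, trajectory.T + 1):
        for node in sorted(tested_by_day.get(t, ())):
            key = (node, t)
            if key in records:
                continue
            state = int(trajectory.states[t, node])
            records[key] = state
            if state == I and t + 1 <= trajectory.T:
                nxt = tested_by_day.setdefault(t + 1, set())
                nxt.update(int(j) for j in network.neighbors(node))

    obs = [Observation(node, day, st) for (node, day), st in records.items()]
    return ObservationSet(observations=obs)


def observed_fraction(obs: ObservationSet, n_nodes: int) -> float:
    """Fraction of distinct nodes with at least one test record."""
    return len(obs.observed_nodes()) / n_nodes
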