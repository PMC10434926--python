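"""Discrete-time stochastic SIR simulation with heterogeneous susceptibility.

The epidemic model: each node is Susceptible, Infected or Recovered.  On
each day, a susceptible node i with m infectious neighbors becomes infected
with probability 1 − (1−β_i)^m, where β_i is node i's own per-contact daily
transmission rate (susceptibility-side heterogeneity: every infectious
neighbor independently infects i with probability β_i).  An infectious node
recovers with daily probability 1/D, where D is the mean infectious period.
Updates are synchronous: day-(t+1) states depend only on day-t states, and a
node infected on day t+1 cannot recover or transmit that same day.

Transmission rates are heterogeneous across nodes; the default sampler draws
them from a two-component Gaussian mixture ("bimodal"), emulating a
population in which a fraction enjoys partial protection (e.g. vaccination)
and is less susceptible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import Network

__all__ = [
    "S",
    "I",
    "R",
    "STATE_LABELS",
    "TransmissionParams",
    "OutbreakTrajectory",
    "sample_bimodal_beta",
    "sample_powerlaw_beta",
    "simulate_sir",
    "attack_rate",
    "DEFAULT_OUTBREAK",
]

# integer state codes used throughout the package
S, I, R = 0, 1, 2
STATE_LABELS = np.array(["S", "I", "R"])
LABEL_TO_STATE = {"S": S, "I": I, "R": R}


@dataclass
class TransmissionParams:
    """Per-node transmission rates β_i and mean infectious period D (days)."""

    beta: np.ndarray
    D: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any((self.beta < 0) | (self.beta > 1)):
            raise ValueError("all transmission rates must lie in [0, 1]")
        if self.D < 1:
            raise ValueError(f"mean infectious period must be >= 1 day, got {self.D}")


@dataclass
class OutbreakTrajectory:
    """Ground-truth per-node state for every day 0..T.

    ``states`` has shape (T+1, N) with integer codes S=0, I=1, R=2.
    """

    states: np.ndarray
    seeds: np.ndarray

    @property
    def T(self) -> int:
        return self.states.shape[0] - 1

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    def state_at(self, node: int, day: int) -> int:
        return int(self.states[day, node])

    def ever_infected(self) -> np.ndarray:
        """Boolean mask of nodes that were ever infected (monotone SIR ⇒
        equivalent to not susceptible on the final day)."""
        return self.states[-1] != S

    def infectious_at_end(self) -> np.ndarray:
        return self.states[-1] == I

    def to_frame(self) -> pd.DataFrame:
        days, nodes = np.meshgrid(
            np.arange(self.T + 1), np.arange(self.n_nodes), indexing="ij"
        )
        return pd.DataFrame(
            {
                "node": nodes.ravel(),
                "day": days.ravel(),
                "state": STATE_LABELS[self.states.ravel()],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OutbreakTrajectory":
        df = pd.read_csv(path)
        T = int(df["day"].max())
        n = int(df["node"].max()) + 1
        states = np.zeros((T + 1, n), dtype=np.int8)
        states[df["day"], df["node"]] = [LABEL_TO_STATE[s] for s in df["state"]]
        seeds = np.flatnonzero(states[0] == I)
        return cls(states=states, seeds=seeds)


# ----------------------------------------------------------------------
# transmission-rate samplers
# ----------------------------------------------------------------------

def sample_bimodal_beta(
    n: int,
    frac_low: float,
    low_mean: float,
    low_sd: float,
    high_mean: float,
    high_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-node rates from a two-component Gaussian mixture.

    ``floor(frac_low * n)`` randomly chosen nodes draw from
    N(low_mean, low_sd²) (the partially protected group); the rest draw from
    N(high_mean, high_sd²).  Values are clipped to [0, 1].
    """
    if not 0 <= frac_low <= 1:
        raise ValueError(f"frac_low must lie in [0, 1], got {frac_low}")
    if low_sd < 0 or high_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    beta = rng.normal(high_mean, high_sd, size=n)
    n_low = int(np.floor(frac_low * n))
    low_idx = rng.choice(n, size=n_low, replace=False)
    beta[low_idx] = rng.normal(low_mean, low_sd, size=n_low)
    return np.clip(beta, 0.0, 1.0)


def sample_powerlaw_beta(
    n: int,
    exponent: float,
    beta_min: float,
    beta_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw i.i.d. rates from a power law p(β) ∝ β^{-exponent} truncated to
    [beta_min, beta_max], via inverse-CDF sampling."""
    if beta_min <= 0 or beta_max > 1 or beta_min > beta_max:
        raise ValueError(
            f"need 0 < beta_min <= beta_max <= 1, got [{beta_min}, {beta_max}]"
        )
    if beta_min == beta_max:
        return np.full(n, beta_min)
    u = rng.random(n)
    if exponent == 1.0:
        return beta_min * (beta_max / beta_min) ** u
    a = 1.0 - exponent
    lo, hi = beta_min ** a, beta_max ** a
    return (lo + u * (hi - lo)) ** (1.0 / a)


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------

def simulate_sir(
    network: Network,
    params: TransmissionParams,
    seeds: np.ndarray,
    T: int,
    rng: np.random.Generator,
) -> OutbreakTrajectory:
    """Run one stochastic SIR realization for T days.

    Seeds are infectious on day 0; everyone else susceptible.  Synchronous
    daily updates: infection probability 1 − (1−β_i)^m for a susceptible i
    with m infectious neighbors, recovery probability 1/D for each node
    already infectious at day t.
    """
    n = network.n_nodes
    seeds = np.asarray(seeds, dtype=np.int64)
    if seeds.size == 0:
        raise ValueError("at least one seed is required")
    if np.any((seeds < 0) | (seeds >= n)):
        raise ValueError("seed index out of range")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    beta = params.beta
    if beta.shape[0] != n:
        raise ValueError("beta vector length must equal the node count")

    indptr, indices = network.csr
    rows = network.entry_rows

    states = np.zeros((T + 1, n), dtype=np.int8)
    current = np.zeros(n, dtype=np.int8)
    current[seeds] = I
    states[0] = current

    p_rec = 1.0 / params.D
    for t in range(T):
        infectious = current == I
        # m_i = number of infectious neighbors of i
        m = np.bincount(rows, weights=infectious[indices].astype(float), minlength=n)
        p_inf = 1.0 - (1.0 - beta) ** m
        new_inf = (current == S) & (rng.random(n) < p_inf)
        new_rec = infectious & (rng.random(n) < p_rec)
        current = current.copy()
        current[new_inf] = I
        current[new_rec] = R
        states[t + 1] = current

    return OutbreakTrajectory(states=states, seeds=seeds)


def attack_rate(trajectory: OutbreakTrajectory) -> float:
    """Fraction of nodes ever infected by the end of the simulation."""
    return float(trajectory.ever_infected().mean())


# Default growth-phase outbreak configuration for the ER benchmark.
# Chosen so that, on ER(1000, <k>=2.6) with the bimodal rates below and a
# 7-day horizon, the mean attack rate falls in the 25-35% growth-phase band.
DEFAULT_OUTBREAK = {
    "seed_frac": 0.08,
    "T": 7,
    "D": 3.0,
    "low_mean": 0.18,
    "low_sd": 0.01,
    "high_mean": 0.22,
    "high_sd": 0.01,
    "frac_low": 0.5,
}


def default_outbreak(
    network: Network, rng: np.random.Generator, **overrides
) -> tuple[OutbreakTrajectory, TransmissionParams]:
    """Simulate one outbreak under the packaged default configuration."""
    cfg = {**DEFAULT_OUTBREAK, **overrides}
    n = network.n_nodes
    beta = sample_bimodal_beta(
        n,
        cfg["frac_low"],
        cfg["low_mean"],
        cfg["low_sd"],
        cfg["high_mean"],
        cfg["high_sd"],
        rng,
    )
    params = TransmissionParams(beta=beta, D=cfg["D"])
    n_seeds = max(1, int(round(cfg["seed_frac"] * n)))
    seeds = rng.choice(n, size=n_seeds, replace=False)
    traj = simulate_sir(network, params, seeds, cfg["T"], rng)
    return traj, params
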