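"""Shared fixtures: small graphs, an independent batched Monte-Carlo SIR
oracle, and session-scoped benchmark tables reused by the slower statistical
tests (so each expensive ensemble experiment runs once per session)."""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
import pytest

from epiens.experiments import build_network, run_replicate
from epiens.networks import Network


# ----------------------------------------------------------------------
# independent Monte-Carlo SIR oracle (vectorized across runs; written
# separately from epiens.outbreak_sim so it can serve as its oracle too)
# ----------------------------------------------------------------------

def mc_sir_frequencies(
    network: Network,
    beta: np.ndarray,
    D: float,
    seed_nodes: list[int],
    T: int,
    runs: int,
    rng_seed: int,
) -> np.ndarray:
    """Empirical per-day state frequencies, shape (T+1, N, 3).

    Synchronous daily dynamics: susceptible i with m infectious neighbors is
    infected w.p. 1-(1-beta_i)^m; infectious recovers w.p. 1/D; a node
    infected on a day cannot recover the same day.
    """
    rng = np.random.default_rng(rng_seed)
    n = network.n_nodes
    _, indices = network.csr
    agg = network.aggregator
    state = np.zeros((runs, n), dtype=np.int8)
    state[:, seed_nodes] = 1
    freq = np.zeros((T + 1, n, 3))
    for t in range(T + 1):
        for x in range(3):
            freq[t, :, x] = (state == x).mean(axis=0)
        if t == T:
            break
        infectious = (state == 1).astype(float)
        m = (agg @ infectious[:, indices].T).T
        p_inf = 1.0 - (1.0 - beta) ** m
        new_inf = (state == 0) & (rng.random((runs, n)) < p_inf)
        new_rec = (state == 1) & (rng.random((runs, n)) < 1.0 / D)
        state[new_inf] = 1
        state[new_rec] = 2
    return freq


@pytest.fixture(scope="session")
def mc_oracle():
    return mc_sir_frequencies


# ----------------------------------------------------------------------
# benchmark networks and experiment tables
# ----------------------------------------------------------------------

ER_SPEC = {"family": "er", "n": 1000, "mean_degree": 2.6, "seed": 7}
SF_SPEC = {"family": "powerlaw", "n": 2044, "gamma": 2.5, "k_min": 1, "seed": 11}
MASTER_SEED = 42
N_REPS = 20

# calibrated state-dependent daily test probabilities per target observed
# fraction on the 7-day ER outbreak
Q_BY_RATE = {
    16: {"q_S": 0.016, "q_I": 0.090, "q_R": 0.033},
    30: {"q_S": 0.035, "q_I": 0.175, "q_R": 0.064},
    50: {"q_S": 0.070, "q_I": 0.320, "q_R": 0.120},
}


@pytest.fixture(scope="session")
def er_network() -> Network:
    return build_network(ER_SPEC, MASTER_SEED)


@pytest.fixture(scope="session")
def sf_network() -> Network:
    return build_network(SF_SPEC, MASTER_SEED)


@pytest.fixture(scope="session")
def er_benchmark(er_network) -> pd.DataFrame:
    """ER benchmark table over 20 outbreak replicates.

    Rows: (setting, method, replicate, auc, attack_rate, observed_fraction)
    where setting is 'r16' (all five methods, plus 'ens_k50'), 'r30' and
    'r50' (ensemble only).
    """
    rows = []
    for rep in range(N_REPS):
        for label, q in Q_BY_RATE.items():
            methods = (
                ["ens", "dmp1", "dmp2", "degree", "contact"]
                if label == 16
                else ["ens"]
            )
            cfg = {"methods": methods, "observation": {"model": "random", **q}}
            res = run_replicate(er_network, cfg, MASTER_SEED, rep)
            for m, auc in res["auc"].items():
                rows.append(
                    {
                        "setting": f"r{label}",
                        "method": m,
                        "replicate": rep,
                        "auc": auc,
                        "attack_rate": res["attack_rate"],
                        "observed_fraction": res["observed_fraction"],
                    }
                )
        cfg = {"methods": ["ens"], "inference": {"K": 50}}
        res = run_replicate(er_network, cfg, MASTER_SEED, rep)
        rows.append(
            {
                "setting": "r16",
                "method": "ens_k50",
                "replicate": rep,
                "auc": res["auc"]["ens"],
                "attack_rate": res["attack_rate"],
                "observed_fraction": res["observed_fraction"],
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sf_benchmark(sf_network) -> pd.DataFrame:
    """SF (configuration-model, γ=2.5) benchmark: all methods, ~15% observed."""
    rows = []
    cfg = {
        "methods": ["ens", "dmp1", "dmp2", "degree", "contact"],
        "observation": {"model": "random", **Q_BY_RATE[16]},
    }
    for rep in range(N_REPS):
        res = run_replicate(sf_network, cfg, MASTER_SEED, rep)
        for m, auc in res["auc"].items():
            rows.append(
                {
                    "setting": "sf",
                    "method": m,
                    "replicate": rep,
                    "auc": auc,
                    "attack_rate": res["attack_rate"],
                    "observed_fraction": res["observed_fraction"],
                }
            )
    return pd.DataFrame(rows)


def paired_margin(df: pd.DataFrame, method_a: str, method_b: str) -> tuple[float, float]:
    """Mean paired AUC difference (a − b) and its standard error."""
    wide = df.pivot_table(index="replicate", columns="method", values="auc")
    diff = (wide[method_a] - wide[method_b]).dropna()
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(len(diff)))
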