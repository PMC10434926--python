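"""Stochastic SIR simulator: samplers, dynamics oracles, trajectory invariants."""

import numpy as np
import pytest
import scipy.stats

from epiens.networks import Network, build_complete_tree, build_er
from epiens.outbreak_sim import (
    I,
    S,
    OutbreakTrajectory,
    TransmissionParams,
    attack_rate,
    default_outbreak,
    sample_bimodal_beta,
    sample_powerlaw_beta,
    simulate_sir,
)


def path_network(n: int) -> Network:
    return Network(n_nodes=n, edges={(i, i + 1) for i in range(n - 1)})


# ----------------------------------------------------------------------
# transmission-rate samplers
# ----------------------------------------------------------------------

def test_bimodal_mixture_mean():
    """Empirical mean matches the mixture mean within 3 SE."""
    rng = np.random.default_rng(0)
    draws = np.concatenate(
        [
            sample_bimodal_beta(1000, 0.2, 0.18, 0.01, 0.22, 0.01, rng)
            for _ in range(30)
        ]
    )
    expected = 0.2 * 0.18 + 0.8 * 0.22
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - expected) < 3 * se


@pytest.mark.parametrize(
    "frac_low,value", [(1.0, 0.18), (0.0, 0.22)]
)
def test_bimodal_point_masses(frac_low, value):
    rng = np.random.default_rng(1)
    beta = sample_bimodal_beta(10, frac_low, 0.18, 0.0, 0.22, 0.0, rng)
    assert np.allclose(beta, value)


def test_bimodal_rejects_negative_sd():
    with pytest.raises(ValueError):
        sample_bimodal_beta(10, 0.5, 0.18, -0.01, 0.22, 0.01, np.random.default_rng(0))


def test_powerlaw_beta_degenerate_and_bounds():
    rng = np.random.default_rng(2)
    assert np.allclose(sample_powerlaw_beta(10, 2.0, 0.2, 0.2, rng), 0.2)
    draws = sample_powerlaw_beta(1000, 2.5, 0.05, 0.4, rng)
    assert draws.min() >= 0.05 and draws.max() <= 0.4


def test_powerlaw_beta_matches_closed_form_cdf():
    """KS distance to the truncated power-law CDF below 0.01 at n=1e5."""
    a, lo, hi = 2.5, 0.05, 0.5
    rng = np.random.default_rng(3)
    draws = sample_powerlaw_beta(10**5, a, lo, hi, rng)

    def cdf(x):
        num = x ** (1 - a) - lo ** (1 - a)
        den = hi ** (1 - a) - lo ** (1 - a)
        return num / den

    ks = scipy.stats.kstest(draws, cdf).statistic
    assert ks < 0.01


# ----------------------------------------------------------------------
# SIR dynamics
# ----------------------------------------------------------------------

def test_no_infected_neighbors_stays_susceptible():
    net = path_network(3)
    params = TransmissionParams(beta=np.full(3, 1.0), D=1e12)
    traj = simulate_sir(net, params, np.array([0]), 2, np.random.default_rng(0))
    # node 2 is two hops away: cannot be infected on day 1
    assert traj.states[1, 2] == S


def test_certain_transmission_on_edge():
    net = path_network(2)
    params = TransmissionParams(beta=np.full(2, 1.0), D=1e12)
    traj = simulate_sir(net, params, np.array([0]), 1, np.random.default_rng(0))
    assert traj.states[1, 1] == I


def test_edge_infection_probability_closed_form():
    """P(neighbor infected by day t) = 1 − (1−β)^t for a persistent source."""
    runs = 10**5
    rng = np.random.default_rng(4)
    beta = 0.3
    hits = np.zeros(3)
    for t in range(1, 4):
        # equivalent single-edge process vectorized over runs
        draws = rng.random((runs, t)) < beta
        hits[t - 1] = draws.any(axis=1).mean()
    for t in range(1, 4):
        expected = 1 - 0.7**t
        se = np.sqrt(expected * (1 - expected) / runs)
        assert abs(hits[t - 1] - expected) < 3 * se
    # the simulator agrees on the same quantity at t=1
    net = path_network(2)
    params = TransmissionParams(beta=np.full(2, beta), D=1e12)
    sim_hits = np.mean(
        [
            simulate_sir(net, params, np.array([0]), 1, np.random.default_rng(s))
            .states[1, 1]
            == I
            for s in range(20000)
        ]
    )
    se1 = np.sqrt(0.3 * 0.7 / 20000)
    assert abs(sim_hits - 0.3) < 3 * se1


def test_multi_neighbor_hazard_matches_per_neighbor_coins():
    """Infection prob with m infectious neighbors is 1−(1−β)^m."""
    m, beta, runs = 3, 0.25, 10**5
    star = Network(n_nodes=m + 1, edges={(0, j) for j in range(1, m + 1)})
    params = TransmissionParams(beta=np.full(m + 1, beta), D=1e12)
    rng = np.random.default_rng(5)
    cnt = 0
    for _ in range(200):
        traj = simulate_sir(star, params, np.arange(1, m + 1), 1, rng)
        cnt += traj.states[1, 0] == I
    p_emp = cnt / 200
    expected = 1 - (1 - beta) ** m
    # oracle: direct per-neighbor coin flips
    coins = (np.random.default_rng(6).random((runs, m)) < beta).any(axis=1).mean()
    assert abs(coins - expected) < 3 * np.sqrt(expected * (1 - expected) / runs)
    assert abs(p_emp - expected) < 3 * np.sqrt(expected * (1 - expected) / 200) + 0.01


def test_trajectory_monotone_and_conserved():
    net = build_er(200, 3.0, 9)
    params = TransmissionParams(
        beta=np.random.default_rng(7).uniform(0.1, 0.3, 200), D=3.0
    )
    traj = simulate_sir(net, params, np.arange(10), 15, np.random.default_rng(8))
    diffs = np.diff(traj.states.astype(int), axis=0)
    assert diffs.min() >= 0  # only S->I and I->R moves, monotone codes
    assert diffs.max() <= 1
    counts = np.array([(traj.states == x).sum(axis=1) for x in range(3)])
    assert np.all(counts.sum(axis=0) == 200)


def test_seed_validation():
    net = path_network(3)
    params = TransmissionParams(beta=np.full(3, 0.2), D=3.0)
    with pytest.raises(ValueError):
        simulate_sir(net, params, np.array([]), 2, np.random.default_rng(0))
    with pytest.raises(ValueError):
        simulate_sir(net, params, np.array([5]), 2, np.random.default_rng(0))


def test_simulation_determinism():
    net = build_er(100, 3.0, 2)
    params = TransmissionParams(beta=np.full(100, 0.2), D=3.0)
    t1 = simulate_sir(net, params, np.arange(5), 10, np.random.default_rng(11))
    t2 = simulate_sir(net, params, np.arange(5), 10, np.random.default_rng(11))
    assert np.array_equal(t1.states, t2.states)


# ----------------------------------------------------------------------
# attack rate
# ----------------------------------------------------------------------

def test_attack_rate_full_sweep():
    net = build_complete_tree(2, 3)
    params = TransmissionParams(beta=np.full(net.n_nodes, 1.0), D=1e12)
    traj = simulate_sir(net, params, np.array([0]), 6, np.random.default_rng(0))
    assert attack_rate(traj) == 1.0


def test_attack_rate_matches_exhaustive_enumeration():
    """3-node path, seed at an end, β=0.5, D=∞, T=1.

    Exhaustive enumeration over the single coin: node 1 infected w.p. 1/2,
    node 2 unreachable in one day, so E[attack rate] = (1 + 1/2)/3 = 1/2.
    """
    net = path_network(3)
    params = TransmissionParams(beta=np.full(3, 0.5), D=1e12)
    # enumeration oracle: every outcome of the one relevant Bernoulli draw
    expected = np.mean([(1 + infected) / 3 for infected in (0, 1)])
    rates = [
        attack_rate(simulate_sir(net, params, np.array([0]), 1, np.random.default_rng(s)))
        for s in range(20000)
    ]
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert abs(np.mean(rates) - expected) < 3 * se


def test_default_outbreak_trajectory_valid():
    net = build_er(300, 2.6, 1)
    traj, params = default_outbreak(net, np.random.default_rng(0))
    assert traj.T == 7
    assert len(traj.seeds) == 24  # 8% of 300
    assert params.beta.shape == (300,)


def test_trajectory_csv_round_trip(tmp_path):
    net = path_network(4)
    params = TransmissionParams(beta=np.full(4, 0.5), D=2.0)
    traj = simulate_sir(net, params, np.array([0]), 3, np.random.default_rng(1))
    p = tmp_path / "traj.csv"
    traj.to_csv(p)
    back = OutbreakTrajectory.from_csv(p)
    assert np.array_equal(back.states, traj.states)
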