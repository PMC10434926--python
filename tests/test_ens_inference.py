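"""Ensemble inference: initialization, Bayes updates, covariance regression,
and qualitative behavior of the full daily assimilation cycle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiens.ens_inference import (
    Ensemble,
    InferenceConfig,
    backward_update,
    bayes_posterior,
    covariability_adjust,
    init_ensemble,
    run_inference,
)
from epiens.master_eq import HazardSeries, ProbabilityState, integrate
from epiens.networks import Network, build_er
from epiens.observation import Observation, ObservationSet
from epiens.outbreak_sim import I, R, S


def path_network(n: int) -> Network:
    return Network(n_nodes=n, edges={(i, i + 1) for i in range(n - 1)})


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------

def test_init_zero_p0_is_all_susceptible():
    net = path_network(5)
    cfg = InferenceConfig(K=10, p0=0.0)
    ens = init_ensemble(net, cfg, np.random.default_rng(0))
    assert np.allclose(ens.pS, 1.0)
    assert np.allclose(ens.pI, 0.0)


def test_init_beta_prior_mean():
    net = path_network(4)
    cfg = InferenceConfig(K=1000, beta_lo=0.1, beta_hi=0.3)
    ens = init_ensemble(net, cfg, np.random.default_rng(1))
    se = (0.3 - 0.1) / np.sqrt(12) / np.sqrt(ens.beta.size)
    assert abs(ens.beta.mean() - 0.2) < 3 * se


def test_default_ensemble_size_is_100():
    assert InferenceConfig().K == 100


def test_config_validation():
    with pytest.raises(ValueError):
        InferenceConfig(K=1)
    with pytest.raises(ValueError):
        InferenceConfig(p0=1.5)
    with pytest.raises(ValueError):
        InferenceConfig(beta_lo=0.4, beta_hi=0.2)


# ----------------------------------------------------------------------
# backward temporal propagation (Bayes)
# ----------------------------------------------------------------------

def test_flat_likelihood_returns_prior():
    prior = np.array([0.3, 0.5, 0.2])
    post = bayes_posterior(prior, np.array([0.7, 0.7, 0.7]))
    assert np.allclose(post, prior)


def test_hand_bayes_two_state():
    post = bayes_posterior(np.array([0.5, 0.5, 0.0]), np.array([0.2, 0.8, 0.5]))
    assert np.allclose(post, [0.2, 0.8, 0.0])


def test_impossible_observation_falls_back_to_likelihood_argmax():
    post = bayes_posterior(np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.3, 0.7]))
    assert np.allclose(post, [0.0, 0.0, 1.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_bayes_posterior_normalized(seed):
    rng = np.random.default_rng(seed)
    prior = rng.random(3)
    prior /= prior.sum()
    post = bayes_posterior(prior, rng.random(3))
    assert post.sum() == pytest.approx(1.0)
    assert np.all(post >= 0)


def test_backward_update_lag_zero_clamps():
    net = path_network(3)
    member = init_ensemble(net, InferenceConfig(K=2, p0=0.5), np.random.default_rng(2)).member(0)
    obs = Observation(1, 4, I)
    hz = HazardSeries(start_day=4, values=np.zeros((0, 3)))
    post, rec = backward_update(member, obs, 4, hz, D=3.0)
    assert np.allclose(post, [0.0, 1.0, 0.0])
    assert rec.node == 1


def test_backward_update_agrees_with_manual_likelihood():
    """Lag-2 observation of state I: posterior ∝ prior · column of the
    2-day transition-matrix product, computed by hand."""
    net = path_network(2)
    D = 3.0
    prior = np.array([0.6, 0.4, 0.0])
    member = init_ensemble(net, InferenceConfig(K=2, p0=0.0), np.random.default_rng(0)).member(0)
    member.prob.pS[0], member.prob.pI[0], member.prob.pR[0] = prior
    hs = np.array([[0.2, 0.0], [0.5, 0.0]])  # node 0 hazards on the two days
    hz = HazardSeries(start_day=0, values=hs)
    post, _ = backward_update(member, Observation(0, 2, I), 0, hz, D)
    # manual: P(I at 2 | S at 0) = h1(1-1/D) + (1-h1) h2 ; P(I|I) = (1-1/D)^2
    lik_S = 0.2 * (1 - 1 / D) + (1 - 0.2) * 0.5
    lik_I = (1 - 1 / D) ** 2
    manual = prior * np.array([lik_S, lik_I, 0.0])
    manual /= manual.sum()
    assert np.allclose(post, manual)


# ----------------------------------------------------------------------
# cross-ensemble covariability adjustment
# ----------------------------------------------------------------------

def hand_ensemble(pS, pI, pR) -> Ensemble:
    pS, pI, pR = (np.array(x, dtype=float) for x in (pS, pI, pR))
    return Ensemble(pS=pS, pI=pI, pR=pR, beta=np.full_like(pS, 0.2))


def test_zero_covariance_leaves_neighbors_unchanged():
    # neighbor marginals identical across members -> cov = 0 -> C = 0
    net = path_network(2)
    ens = hand_ensemble(
        pS=[[0.9, 0.5], [0.5, 0.5], [0.1, 0.5]],
        pI=[[0.1, 0.5], [0.5, 0.5], [0.9, 0.5]],
        pR=[[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]],
    )
    before = ens.pI[:, 1].copy()
    deltas = np.array([[0.1, -0.1, 0.0], [0.0, 0.0, 0.0], [-0.1, 0.1, 0.0]])
    covariability_adjust(ens, 0, deltas, net, var_floor=1e-10)
    assert np.allclose(ens.pI[:, 1], before)


def test_perfect_correlation_copies_delta():
    """P(X_j) = P(X_i) across members gives C = 1: neighbor deltas equal the
    observed node's deltas before projection."""
    net = path_network(2)
    ens = hand_ensemble(
        pS=[[0.8, 0.8], [0.5, 0.5], [0.2, 0.2]],
        pI=[[0.2, 0.2], [0.5, 0.5], [0.8, 0.8]],
        pR=[[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]],
    )
    deltas = np.array([[-0.1, 0.1, 0.0]] * 3)
    before = np.stack([ens.pS[:, 1], ens.pI[:, 1], ens.pR[:, 1]], axis=1)
    covariability_adjust(ens, 0, deltas, net, var_floor=1e-10)
    after = np.stack([ens.pS[:, 1], ens.pI[:, 1], ens.pR[:, 1]], axis=1)
    assert np.allclose(after - before, deltas, atol=1e-12)


def test_three_member_hand_covariance_regression():
    """C computed by hand covariance/variance on a 3-member ensemble; the
    adjusted neighbor values match manual arithmetic (no projection active)."""
    net = path_network(2)
    xi = np.array([0.2, 0.5, 0.8])  # observed node pI
    yj = np.array([0.3, 0.4, 0.6])  # neighbor pI
    ens = hand_ensemble(
        pS=np.stack([1 - xi, 1 - yj], axis=1),
        pI=np.stack([xi, yj], axis=1),
        pR=np.zeros((3, 2)),
    )
    deltas = np.zeros((3, 3))
    deltas[:, 1] = [0.05, -0.02, 0.01]  # only the I component adjusted
    deltas[:, 0] = -deltas[:, 1]
    # manual regression coefficients (sample cov / var, ddof=1)
    C_I = np.cov(xi, yj, ddof=1)[0, 1] / np.var(xi, ddof=1)
    C_S = np.cov(1 - xi, 1 - yj, ddof=1)[0, 1] / np.var(1 - xi, ddof=1)
    manual_pI = yj + C_I * deltas[:, 1]
    manual_pS = (1 - yj) + C_S * deltas[:, 0]
    total = manual_pI + manual_pS  # pR stays 0 (zero variance, zero delta)
    covariability_adjust(ens, 0, deltas, net, var_floor=1e-10)
    assert np.allclose(ens.pI[:, 1], manual_pI / total)
    assert np.allclose(ens.pS[:, 1], manual_pS / total)


def test_adjusted_triples_on_simplex_after_projection():
    net = path_network(3)
    rng = np.random.default_rng(5)
    ens = init_ensemble(net, InferenceConfig(K=20, p0=0.8), rng)
    deltas = rng.uniform(-0.8, 0.8, size=(20, 3))
    covariability_adjust(ens, 1, deltas, net, var_floor=1e-10)
    total = ens.pS + ens.pI + ens.pR
    assert np.allclose(total, 1.0)
    assert ens.pI.min() >= 0 and ens.pI.max() <= 1


# ----------------------------------------------------------------------
# full inference loop
# ----------------------------------------------------------------------

def test_no_observations_equals_pure_forecast():
    net = path_network(6)
    cfg = InferenceConfig(K=8, p0=0.05)
    est = run_inference(net, ObservationSet([]), 5, cfg, np.random.default_rng(7))
    # oracle: integrate each member independently and average
    ens = init_ensemble(net, cfg, np.random.default_rng(7))
    means = []
    for t in range(6):
        means.append(ens.pI.mean(axis=0))
    expected = []
    per_member = []
    for k in range(cfg.K):
        ps = ProbabilityState(ens.pS[k], ens.pI[k], ens.pR[k])
        per_member.append(integrate(ps, net, ens.beta[k], cfg.D, 5))
    for t in range(6):
        expected.append(np.mean([m[t].pI for m in per_member], axis=0))
    assert np.allclose(est.mean_pI, np.array(expected), atol=1e-9)


def test_single_infected_observation_risk_decays_with_distance():
    """One observed infection at the end of a path: final-day risk is
    maximal at the observed node and decays monotonically along the path."""
    net = path_network(7)
    T = 5
    obs = ObservationSet([Observation(0, T, I)])
    cfg = InferenceConfig(K=50, p0=0.01)
    est = run_inference(net, obs, T, cfg, np.random.default_rng(9))
    final = est.final
    assert final[0] == pytest.approx(1.0)  # clamped on the last day
    assert np.all(np.diff(final) < 0)


def test_observations_beyond_horizon_rejected():
    net = path_network(3)
    obs = ObservationSet([Observation(0, 9, S)])
    with pytest.raises(ValueError):
        run_inference(net, obs, 5, InferenceConfig(K=4), np.random.default_rng(0))


def test_inference_determinism():
    net = build_er(80, 3.0, 3)
    obs = ObservationSet([Observation(3, 2, I), Observation(10, 4, S)])
    cfg = InferenceConfig(K=10)
    a = run_inference(net, obs, 5, cfg, np.random.default_rng(11))
    b = run_inference(net, obs, 5, cfg, np.random.default_rng(11))
    assert np.array_equal(a.mean_pI, b.mean_pI)


def test_members_stay_on_simplex_through_cycles():
    net = build_er(60, 3.0, 4)
    rng = np.random.default_rng(13)
    obs = ObservationSet(
        [Observation(int(n), int(d), int(s)) for n, d, s in
         zip(rng.choice(60, 12, replace=False), rng.integers(1, 6, 12),
             rng.choice([S, I, R], 12, p=[0.5, 0.4, 0.1]))]
    )
    cfg = InferenceConfig(K=12)
    est = run_inference(net, obs, 6, cfg, rng)
    assert np.all((est.mean_pI >= 0) & (est.mean_pI <= 1))
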