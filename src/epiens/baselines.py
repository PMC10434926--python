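"""Competing risk-ranking methods: Degree, Contact, and modified DMP.

*Degree* ranks nodes by their number of contacts; *Contact* by their number
of distinct neighbors ever observed infectious.  The *dynamic message
passing* (DMP) baseline integrates the standard SIR edge-message equations
(θ, φ) forward from day 0 — exact on trees — and is modified here to absorb
observations by clamping observed nodes' marginals at their observation
days and rescaling the clamped nodes' outgoing φ messages proportionally.
Two transmission-rate modes mirror the ensemble method's uniform prior:
``fixed`` uses the prior mean for every node; ``uniform`` draws each node's
rate from the prior.

The DMP observation modification is a reconstruction (the clamping scheme
is the simplest consistent with absorbing state observations into forward
messages); it is used for relative comparison of ranking methods, not as a
calibrated posterior.
"""

from __future__ import annotations

import numpy as np

from .networks import Network
from .observation import ObservationSet
from .outbreak_sim import I, R, S

__all__ = ["degree_scores", "contact_scores", "dmp_scores"]


def degree_scores(network: Network) -> np.ndarray:
    """score(i) = |∂i|."""
    return network.degrees.astype(float)


def contact_scores(network: Network, obs: ObservationSet) -> np.ndarray:
    """score(i) = number of distinct neighbors of i ever observed infectious."""
    observed_I = obs.nodes_observed_infected()
    scores = np.zeros(network.n_nodes)
    for v in observed_I:
        scores[network.neighbors(v)] += 1.0
    return scores


# ----------------------------------------------------------------------
# modified dynamic message passing
# ----------------------------------------------------------------------

class _DMPEdges:
    """Directed-edge bookkeeping over the CSR entries of a network.

    Entry e carries the message from sender ``indices[e]`` to receiver
    ``rows[e]``; ``reverse[e]`` is the index of the opposite direction.
    """

    def __init__(self, network: Network):
        indptr, indices = network.csr
        self.receiver = network.entry_rows
        self.sender = indices
        pos = {}
        for e, (i, j) in enumerate(zip(self.receiver, self.sender)):
            pos[(int(i), int(j))] = e
        self.reverse = np.array(
            [pos[(int(j), int(i))] for i, j in zip(self.receiver, self.sender)],
            dtype=np.int64,
        )
        self.n = network.n_nodes
        self.nnz = len(indices)

    def cavity_product(self, theta: np.ndarray) -> np.ndarray:
        """For each entry e = (i ← j), Π_{l∈∂j\\i} θ_{l→j}.

        Evaluated from per-node full products with explicit zero handling
        (a single zero factor zeroes every cavity except the one that
        excludes it).
        """
        nonzero = theta > 0.0
        logs = np.where(nonzero, np.log(np.where(nonzero, theta, 1.0)), 0.0)
        log_prod = np.bincount(self.receiver, weights=logs, minlength=self.n)
        zeros = np.bincount(self.receiver, weights=(~nonzero).astype(float), minlength=self.n)
        prod_nonzero = np.exp(log_prod)

        excl = self.reverse  # entry whose θ is excluded: (j ← i)
        j = self.sender  # cavity is over edges into the sender
        excl_zero = ~nonzero[excl]
        n_zeros_j = zeros[j]
        out = np.where(
            excl_zero,
            np.where(n_zeros_j == 1, prod_nonzero[j], 0.0),
            np.where(n_zeros_j == 0, prod_nonzero[j] / np.where(nonzero[excl], theta[excl], 1.0), 0.0),
        )
        return np.clip(out, 0.0, 1.0)


def dmp_scores(
    network: Network,
    obs: ObservationSet,
    T: int,
    mode: str = "fixed",
    beta_lo: float = 0.10,
    beta_hi: float = 0.30,
    D: float = 3.0,
    p0: float | np.ndarray = 0.01,
    rng: np.random.Generator | None = None,
    beta: np.ndarray | None = None,
    return_history: bool = False,
):
    """Final-day infection marginals from observation-clamped forward DMP.

    Every node starts with infection probability ``p0`` (a scalar, or a
    per-node vector — e.g. an indicator for known seeds).  At each day with
    observations, observed nodes' marginals are overwritten by the observed
    indicator and their outgoing φ messages rescaled by the ratio of new to
    old infection marginal.  Returns P(I_i^T) as the ranking score.

    ``beta`` overrides the rate vector (e.g. to hand the true rates to the
    baseline); otherwise ``mode`` selects the prior mean (``fixed``) or
    per-node uniform draws (``uniform``, requires ``rng``).
    """
    n = network.n_nodes
    if beta is not None:
        beta = np.asarray(beta, dtype=float)
    elif mode == "fixed":
        beta = np.full(n, 0.5 * (beta_lo + beta_hi))
    elif mode == "uniform":
        if rng is None:
            raise ValueError("mode='uniform' requires an rng")
        beta = rng.uniform(beta_lo, beta_hi, size=n)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    edges = _DMPEdges(network)
    lam = beta[edges.receiver]  # rate of transmission along j→i is β_i
    rec = 1.0 / D

    pI = np.broadcast_to(np.asarray(p0, dtype=float), (n,)).copy()
    pS0 = 1.0 - pI
    pS = pS0.copy()
    pR = np.zeros(n)

    theta = np.ones(edges.nnz)
    phi = pI[edges.sender].copy()
    pS_cav = pS0[edges.sender].copy()

    obs_by_day = obs.by_day()
    history: dict[str, list[np.ndarray]] = {"theta": [], "marginals": []}

    def clamp(day: int) -> None:
        for o in obs_by_day.get(day, ()):  # noqa: B023
            old_pI = pI[o.node]
            new = np.zeros(3)
            new[o.state] = 1.0
            out_edges = np.flatnonzero(edges.sender == o.node)
            if old_pI > 1e-12:
                phi[out_edges] *= new[I] / old_pI
            else:
                phi[out_edges] = new[I]
            phi[out_edges] = np.minimum(phi[out_edges], 1.0)
            pS[o.node], pI[o.node], pR[o.node] = new[S], new[I], new[R]

    clamp(0)
    for t in range(T):
        theta_new = np.clip(theta - lam * phi, 0.0, 1.0)
        pS_cav_new = pS0[edges.sender] * edges.cavity_product(theta_new)
        phi = (1.0 - lam) * (1.0 - rec) * phi + np.clip(pS_cav - pS_cav_new, 0.0, 1.0)
        phi = np.clip(phi, 0.0, 1.0)
        theta, pS_cav = theta_new, pS_cav_new

        pR = pR + pI * rec
        pS = pS0 * np.exp(
            np.bincount(
                edges.receiver,
                weights=np.log(np.maximum(theta, 1e-300)),
                minlength=n,
            )
        )
        pS = np.where(
            np.bincount(edges.receiver, weights=(theta <= 0).astype(float), minlength=n) > 0,
            0.0,
            pS,
        )
        pI = np.clip(1.0 - pS - pR, 0.0, 1.0)
        clamp(t + 1)
        history["theta"].append(theta.copy())
        history["marginals"].append(np.stack([pS, pI, pR], axis=1))

    if return_history:
        return pI.copy(), history
    return pI.copy()
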