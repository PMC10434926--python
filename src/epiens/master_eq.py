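"""Per-node SIR master equations under the neighbor-independence approximation.

The state of the system is the collection of per-node marginals
(P(S_i^t), P(I_i^t), P(R_i^t)).  With the daily infection hazard

    h_i(t) = 1 − Π_{j∈∂i} (1 − β_i P(I_j^t)),

the one-day update is

    P(S_i^{t+1}) = P(S_i^t) (1 − h_i(t))
    P(I_i^{t+1}) = P(I_i^t) (1 − 1/D) + P(S_i^t) h_i(t)
    P(R_i^{t+1}) = P(R_i^t) + P(I_i^t)/D

which conserves the probability simplex exactly.  The independence
approximation is exact on trees and accurate on sparse locally tree-like
graphs; on dense clustered graphs it overestimates spread.

Single-node conditional state-transition likelihoods over a day range —
needed to propagate a later observation backward in time by Bayes' rule —
are products of per-day 3×3 transition matrices built from the same hazards.

The array core functions accept leading batch dimensions (used by the
ensemble machinery, which stacks K members as a (K, N) batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import Network

__all__ = [
    "ProbabilityState",
    "HazardSeries",
    "infection_hazard",
    "forward_step",
    "integrate",
    "conditional_likelihood",
]

logger = logging.getLogger("epiens")

# tolerance below which negative probabilities from floating error are
# silently clipped; larger violations indicate an update bug and are logged
_CLIP_WARN_TOL = 1e-12


@dataclass
class ProbabilityState:
    """Per-node marginals (pS, pI, pR) at one day; each of shape (N,)."""

    pS: np.ndarray
    pI: np.ndarray
    pR: np.ndarray
    day: int = 0

    def __post_init__(self) -> None:
        self.pS = np.asarray(self.pS, dtype=float)
        self.pI = np.asarray(self.pI, dtype=float)
        self.pR = np.asarray(self.pR, dtype=float)
        if not (self.pS.shape == self.pI.shape == self.pR.shape):
            raise ValueError("pS, pI, pR must share a shape")
        total = self.pS + self.pI + self.pR
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("per-node probabilities must sum to 1 (tol 1e-9)")

    @property
    def n_nodes(self) -> int:
        return self.pS.shape[-1]

    def copy(self) -> "ProbabilityState":
        return ProbabilityState(self.pS.copy(), self.pI.copy(), self.pR.copy(), self.day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "day": self.day,
                "pS": self.pS,
                "pI": self.pI,
                "pR": self.pR,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class HazardSeries:
    """Per-node daily infection hazards over a contiguous day range.

    ``values[d]`` is the hazard acting during day ``start_day + d``, i.e. in
    the transition from day ``start_day + d`` to ``start_day + d + 1``.
    ``values`` has shape (n_days, ..., N) — batch dimensions allowed.
    """

    start_day: int
    values: np.ndarray

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def day_slice(self, t_from: int, t_to: int) -> np.ndarray:
        """Hazards for the transitions covering (t_from, t_to]."""
        lo = t_from - self.start_day
        hi = t_to - self.start_day
        if lo < 0 or hi > self.n_days:
            raise ValueError(
                f"hazards cover days [{self.start_day}, "
                f"{self.start_day + self.n_days}), requested ({t_from}, {t_to}]"
            )
        return self.values[lo:hi]


# ----------------------------------------------------------------------
# array core
# ----------------------------------------------------------------------

def infection_hazard(pI: np.ndarray, beta: np.ndarray, network: Network) -> np.ndarray:
    """h_i = 1 − Π_{j∈∂i}(1 − β_i pI_j) for all nodes, batched.

    ``pI`` and ``beta`` have shape (..., N); the product over neighbors is
    evaluated as a per-entry log sum aggregated by a sparse 0/1 matrix, so
    degree-zero nodes get hazard 0 exactly.
    """
    _, indices = network.csr
    rows = network.entry_rows
    with np.errstate(divide="ignore"):
        terms = np.log1p(-beta[..., rows] * pI[..., indices])
    batch = terms.shape[:-1]
    flat = terms.reshape(-1, terms.shape[-1]) if batch else terms[None, :]
    # (N x nnz) @ (nnz x B) -> per-node log-sums
    sums = (network.aggregator @ flat.T).T
    h = -np.expm1(sums)
    h = np.clip(h, 0.0, 1.0)
    return h.reshape(*batch, network.n_nodes) if batch else h[0]


def step_arrays(
    pS: np.ndarray,
    pI: np.ndarray,
    pR: np.ndarray,
    h: np.ndarray,
    D: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-day master-equation update given precomputed hazards."""
    rec = pI / D
    new_pS = pS * (1.0 - h)
    new_pI = pI - rec + pS * h
    new_pR = pR + rec
    return new_pS, new_pI, new_pR


def clip_simplex(
    pS: np.ndarray, pI: np.ndarray, pR: np.ndarray, warn: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project (pS, pI, pR) back onto the probability simplex.

    Components are clipped to [0, 1] and each triple renormalized; an
    all-zero triple falls back to the uniform distribution.  ``warn=True``
    logs violations beyond floating error — appropriate after a pure
    integration step, which is analytically simplex-conserving; the
    covariability adjustment projects deliberately off-simplex values and
    passes ``warn=False``.
    """
    if warn:
        worst = min(pS.min(initial=0.0), pI.min(initial=0.0), pR.min(initial=0.0))
        if worst < -_CLIP_WARN_TOL:
            logger.warning(
                "probability component %.3e below zero before clipping", worst
            )
    pS = np.clip(pS, 0.0, 1.0)
    pI = np.clip(pI, 0.0, 1.0)
    pR = np.clip(pR, 0.0, 1.0)
    total = pS + pI + pR
    zero = total <= 0.0
    if np.any(zero):
        pS = np.where(zero, 1.0 / 3.0, pS)
        pI = np.where(zero, 1.0 / 3.0, pI)
        pR = np.where(zero, 1.0 / 3.0, pR)
        total = np.where(zero, 1.0, total)
    return pS / total, pI / total, pR / total


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def forward_step(
    prob: ProbabilityState,
    network: Network,
    beta: np.ndarray,
    D: float,
) -> ProbabilityState:
    """Advance the marginals one day."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[-1] != prob.n_nodes or prob.n_nodes != network.n_nodes:
        raise ValueError("beta / state / network sizes do not match")
    h = infection_hazard(prob.pI, beta, network)
    pS, pI, pR = step_arrays(prob.pS, prob.pI, prob.pR, h, D)
    pS, pI, pR = clip_simplex(pS, pI, pR)
    return ProbabilityState(pS, pI, pR, day=prob.day + 1)


def integrate(
    prob: ProbabilityState,
    network: Network,
    beta: np.ndarray,
    D: float,
    n_days: int,
) -> list[ProbabilityState]:
    """Run ``n_days`` forward steps; returns [input, day+1, ..., day+n_days]."""
    if n_days < 0:
        raise ValueError(f"n_days must be >= 0, got {n_days}")
    out = [prob]
    for _ in range(n_days):
        out.append(forward_step(out[-1], network, beta, D))
    return out


def daily_transition_matrix(h: float, D: float) -> np.ndarray:
    """3×3 one-day state-transition matrix for a single node with hazard h."""
    rec = 1.0 / D
    return np.array(
        [
            [1.0 - h, h, 0.0],
            [0.0, 1.0 - rec, rec],
            [0.0, 0.0, 1.0],
        ]
    )


def conditional_likelihood(
    node: int,
    t_from: int,
    t_to: int,
    hazards: HazardSeries,
    D: float,
) -> np.ndarray:
    """L[X, O] = P(node in state O at t_to | state X at t_from).

    The product of the node's per-day transition matrices over the days in
    (t_from, t_to], with hazards read from ``hazards``.  Rows sum to one.
    """
    if t_to < t_from:
        raise ValueError(f"t_to must be >= t_from, got {t_from} -> {t_to}")
    hs = hazards.day_slice(t_from, t_to)
    L = np.eye(3)
    for d in range(hs.shape[0]):
        L = L @ daily_transition_matrix(float(hs[d, ..., node]), D)
    return L


def likelihood_columns_batch(h_lag: np.ndarray, state: int, D: float) -> np.ndarray:
    """Batched likelihood column P(obs state at t+L | X at t) for one node.

    ``h_lag`` has shape (L, K): the node's hazard on each of the L days, per
    batch member.  Returns shape (K, 3) — the column of the L-day transition
    matrix corresponding to the observed state, for each member.  Exploits
    the chain structure: rows for I and R have closed forms; the S row is
    accumulated iteratively.
    """
    L, K = h_lag.shape
    rec = 1.0 / D
    # row X=S evolved forward L days
    rowS = np.zeros((K, 3))
    rowS[:, 0] = 1.0
    for d in range(L):
        h = h_lag[d]
        s, i, r = rowS[:, 0].copy(), rowS[:, 1].copy(), rowS[:, 2].copy()
        rowS[:, 0] = s * (1.0 - h)
        rowS[:, 1] = i * (1.0 - rec) + s * h
        rowS[:, 2] = r + i * rec
    stay_I = (1.0 - rec) ** L
    cols = np.empty((K, 3))
    cols[:, 0] = rowS[:, state]
    cols[:, 1] = {0: 0.0, 1: stay_I, 2: 1.0 - stay_I}[state]
    cols[:, 2] = 1.0 if state == 2 else 0.0
    return cols
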