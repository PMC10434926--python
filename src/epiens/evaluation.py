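"""Evaluation of infection-risk rankings against simulation ground truth.

The target label is "infectious on the final day" (the quantity every
method estimates); ranking quality is summarized by the ROC curve, the
tie-aware AUC (equivalent to the normalized Mann–Whitney U statistic), and
the number of true infections found among the top-k ranked nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .observation import ObservationSet
from .outbreak_sim import OutbreakTrajectory

__all__ = ["EvaluationResult", "evaluate", "topk_curve"]


@dataclass
class EvaluationResult:
    roc: np.ndarray  # (n_points, 2) of (FPR, TPR)
    auc: float
    eval_set: np.ndarray  # node indices evaluated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.roc[:, 0], "tpr": self.roc[:, 1]})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _truth(trajectory: OutbreakTrajectory, ever_infected: bool) -> np.ndarray:
    return (
        trajectory.ever_infected() if ever_infected else trajectory.infectious_at_end()
    ).astype(int)


def evaluate(
    scores: np.ndarray,
    trajectory: OutbreakTrajectory,
    obs: ObservationSet | None = None,
    eval_policy: str = "all",
    ever_infected: bool = False,
) -> EvaluationResult:
    """ROC / AUC of a ranking against final-day infectious status.

    ``eval_policy='all'`` evaluates every node (the default);
    ``'unobserved'`` excludes nodes observed on the final day, whose status
    is trivially known.  ``ever_infected=True`` switches the truth label to
    "ever infected".  Raises for single-class truth, where the AUC is
    undefined.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != trajectory.n_nodes:
        raise ValueError("scores length must equal the node count")
    truth = _truth(trajectory, ever_infected)

    if eval_policy == "all":
        nodes = np.arange(trajectory.n_nodes)
    elif eval_policy == "unobserved":
        if obs is None:
            raise ValueError("eval_policy='unobserved' requires the observation set")
        excluded = obs.nodes_observed_on(trajectory.T)
        nodes = np.array(
            [i for i in range(trajectory.n_nodes) if i not in excluded], dtype=int
        )
    else:
        raise ValueError(f"unknown eval_policy {eval_policy!r}")

    y, s = truth[nodes], scores[nodes]
    if len(np.unique(y)) < 2:
        raise ValueError(
            "AUC undefined: the evaluation set contains a single truth class "
            f"({'all' if y[0] else 'no'} nodes infectious on the final day)"
        )
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return EvaluationResult(roc=np.column_stack([fpr, tpr]), auc=auc, eval_set=nodes)


def topk_curve(
    scores: np.ndarray,
    trajectory: OutbreakTrajectory,
    ks: list[int],
    seed: int = 0,
    ever_infected: bool = False,
) -> dict[int, int]:
    """hits(k) = number of truly infectious nodes among the top k by score.

    Ties are broken by a fixed-seed random shuffle so that coarse scores
    (e.g. Degree) are not ordered by node index.
    """
    scores = np.asarray(scores, dtype=float)
    n = trajectory.n_nodes
    if any(k > n or k < 0 for k in ks):
        raise ValueError("every k must lie in [0, N]")
    truth = _truth(trajectory, ever_infected)
    perm = np.random.default_rng(seed).permutation(n)
    order = np.lexsort((perm, -scores))  # primary: score desc; tie: shuffled
    hits_sorted = np.cumsum(truth[order])
    return {k: (0 if k == 0 else int(hits_sorted[k - 1])) for k in ks}
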