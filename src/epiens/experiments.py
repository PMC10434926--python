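"""Config-driven experiment pipelines and the scaling benchmark.

An experiment is: build (or load) a network, then per replicate simulate an
outbreak, draw observations, run every requested ranking method, and score
each against the simulation truth.  A single master seed deterministically
spawns per-replicate, per-role child seeds, so adding a method to the list
never perturbs the simulated outbreaks.

Configs are plain dictionaries (YAML on disk); packaged configurations for
the standard benchmarks live under ``epiens/configs``.
"""

from __future__ import annotations

import importlib.resources
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import contact_scores, degree_scores, dmp_scores
from .ens_inference import InferenceConfig, run_inference
from .evaluation import evaluate, topk_curve
from .networks import (
    Network,
    build_complete_tree,
    build_er,
    build_powerlaw_config,
    build_random_regular,
    read_edge_list,
)
from .observation import contact_tracing, observed_fraction, random_testing
from .outbreak_sim import (
    DEFAULT_OUTBREAK,
    TransmissionParams,
    attack_rate,
    sample_bimodal_beta,
    sample_powerlaw_beta,
    simulate_sir,
)

__all__ = [
    "load_config",
    "packaged_config",
    "build_network",
    "run_replicate",
    "run_experiment",
    "scaling_benchmark",
]

METHODS = ("ens", "dmp1", "dmp2", "degree", "contact")

# role ids for deterministic per-replicate seed spawning
_ROLE_OUTBREAK, _ROLE_OBS, _ROLE_INFER, _ROLE_DMP, _ROLE_TIE = range(5)
_ROLE_NETWORK = 99


def child_rng(master_seed: int, replicate: int, role: int) -> np.random.Generator:
    """Deterministic child generator for (replicate, role)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate, role))
    return np.random.default_rng(ss)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def packaged_config(name: str) -> dict:
    """Load one of the packaged benchmark configs (e.g. ``er_16``)."""
    ref = importlib.resources.files("epiens") / "configs" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def build_network(spec: dict, master_seed: int = 0) -> Network:
    family = spec["family"]
    seed = spec.get("seed")
    if seed is None:
        seed = int(
            np.random.SeedSequence(
                entropy=master_seed, spawn_key=(0, _ROLE_NETWORK)
            ).generate_state(1)[0]
            % 2**31
        )
    if family == "tree":
        return build_complete_tree(spec["branching"], spec["depth"])
    if family == "er":
        return build_er(spec["n"], spec["mean_degree"], seed)
    if family == "powerlaw":
        return build_powerlaw_config(
            spec["n"], spec["gamma"], spec.get("k_min", 1), seed
        )
    if family == "regular":
        return build_random_regular(spec["n"], spec["k"], seed)
    if family == "edge_list":
        return read_edge_list(spec["path"])
    raise ValueError(f"unknown network family {family!r}")


def _sample_beta(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec.get("kind", "bimodal")
    if kind == "bimodal":
        return sample_bimodal_beta(
            n,
            spec.get("frac_low", DEFAULT_OUTBREAK["frac_low"]),
            spec.get("low_mean", DEFAULT_OUTBREAK["low_mean"]),
            spec.get("low_sd", DEFAULT_OUTBREAK["low_sd"]),
            spec.get("high_mean", DEFAULT_OUTBREAK["high_mean"]),
            spec.get("high_sd", DEFAULT_OUTBREAK["high_sd"]),
            rng,
        )
    if kind == "powerlaw":
        return sample_powerlaw_beta(
            n, spec["exponent"], spec["beta_min"], spec["beta_max"], rng
        )
    if kind == "constant":
        return np.full(n, spec["value"])
    raise ValueError(f"unknown beta kind {kind!r}")


# ----------------------------------------------------------------------
# one replicate
# ----------------------------------------------------------------------

def run_replicate(
    network: Network, config: dict, master_seed: int, replicate: int
) -> dict:
    """Simulate, observe, rank with every configured method, and evaluate.

    Returns a dict with the trajectory, observations, per-method scores and
    per-method AUC (None when the truth is single-class).
    """
    ob = {**DEFAULT_OUTBREAK, **config.get("outbreak", {})}
    T = int(ob["T"])
    n = network.n_nodes

    rng_out = child_rng(master_seed, replicate, _ROLE_OUTBREAK)
    beta_true = _sample_beta(ob.get("beta", {}), n, rng_out)
    params = TransmissionParams(beta=beta_true, D=float(ob["D"]))
    n_seeds = max(1, int(round(ob["seed_frac"] * n)))
    seeds = rng_out.choice(n, size=n_seeds, replace=False)
    traj = simulate_sir(network, params, seeds, T, rng_out)

    obs_spec = config.get("observation", {"model": "random"})
    rng_obs = child_rng(master_seed, replicate, _ROLE_OBS)
    q = (
        float(obs_spec.get("q_S", 0.016)),
        float(obs_spec.get("q_I", 0.090)),
        float(obs_spec.get("q_R", 0.033)),
    )
    if obs_spec.get("model", "random") == "contact":
        obs = contact_tracing(traj, network, *q, rng_obs)
    else:
        obs = random_testing(traj, *q, rng_obs)

    inf_spec = config.get("inference", {})
    icfg = InferenceConfig(
        K=int(inf_spec.get("K", 100)),
        beta_lo=float(inf_spec.get("beta_lo", 0.10)),
        beta_hi=float(inf_spec.get("beta_hi", 0.30)),
        p0=float(inf_spec.get("p0", 0.01)),
        D=float(inf_spec.get("D", ob["D"])),
    )

    methods = config.get("methods", list(METHODS))
    scores: dict[str, np.ndarray] = {}
    for m in methods:
        if m == "ens":
            rng_inf = child_rng(master_seed, replicate, _ROLE_INFER)
            scores[m] = run_inference(network, obs, T, icfg, rng_inf).final
        elif m == "dmp1":
            scores[m] = dmp_scores(
                network, obs, T, mode="fixed",
                beta_lo=icfg.beta_lo, beta_hi=icfg.beta_hi, D=icfg.D, p0=icfg.p0,
            )
        elif m == "dmp2":
            rng_dmp = child_rng(master_seed, replicate, _ROLE_DMP)
            scores[m] = dmp_scores(
                network, obs, T, mode="uniform",
                beta_lo=icfg.beta_lo, beta_hi=icfg.beta_hi, D=icfg.D, p0=icfg.p0,
                rng=rng_dmp,
            )
        elif m == "degree":
            scores[m] = degree_scores(network)
        elif m == "contact":
            scores[m] = contact_scores(network, obs)
        else:
            raise ValueError(f"unknown method {m!r}")

    tie_seed = int(
        child_rng(master_seed, replicate, _ROLE_TIE).integers(2**31)
    )
    aucs: dict[str, float | None] = {}
    single_class = len(np.unique(traj.infectious_at_end())) < 2
    for m, s in scores.items():
        aucs[m] = None if single_class else evaluate(s, traj, obs).auc

    return {
        "trajectory": traj,
        "observations": obs,
        "observed_fraction": observed_fraction(obs, n),
        "attack_rate": attack_rate(traj),
        "scores": scores,
        "auc": aucs,
        "tie_seed": tie_seed,
    }


def run_experiment(config: dict, outdir: str | Path | None = None) -> pd.DataFrame:
    """Run all replicates of an experiment; returns the tidy metrics table.

    Columns: method, replicate, observation_rate, attack_rate, auc.  If
    ``outdir`` is given, writes ``metrics.csv``, ``topk.csv`` and a
    provenance copy of the config.
    """
    master_seed = int(config.get("seed", 0))
    network = build_network(config["network"], master_seed)
    replicates = int(config.get("replicates", 1))
    ks = config.get(
        "topk", [max(1, network.n_nodes // 20) * m for m in (1, 2, 4)]
    )

    rows, topk_rows = [], []
    for rep in range(replicates):
        res = run_replicate(network, config, master_seed, rep)
        for m, auc in res["auc"].items():
            rows.append(
                {
                    "method": m,
                    "replicate": rep,
                    "observation_rate": res["observed_fraction"],
                    "attack_rate": res["attack_rate"],
                    "auc": auc,
                }
            )
            hits = topk_curve(
                res["scores"][m], res["trajectory"], list(ks), seed=res["tie_seed"]
            )
            topk_rows.extend(
                {"method": m, "replicate": rep, "k": k, "hits": h}
                for k, h in hits.items()
            )

    metrics = pd.DataFrame(rows)
    topk = pd.DataFrame(topk_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        topk.to_csv(outdir / "topk.csv", index=False)
        provenance = {
            "config": config,
            "seed": master_seed,
            "epiens_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        (outdir / "experiment.json").write_text(json.dumps(provenance, indent=2))
    return metrics


# ----------------------------------------------------------------------
# scaling benchmark
# ----------------------------------------------------------------------

def _timed_inference(
    n_nodes: int,
    mean_degree: float,
    n_obs: int,
    K: int,
    master_seed: int,
    repeat: int,
    method: str = "ens",
) -> float:
    """Wall-clock seconds for one inference run at the given problem size."""
    rng = child_rng(master_seed, repeat, 7)
    net = build_er(n_nodes, mean_degree, int(rng.integers(2**31)))
    beta = sample_bimodal_beta(
        n_nodes, 0.5, 0.18, 0.01, 0.22, 0.01, rng
    )
    params = TransmissionParams(beta=beta, D=3.0)
    seeds = rng.choice(n_nodes, size=max(1, n_nodes // 25), replace=False)
    traj = simulate_sir(net, params, seeds, 7, rng)
    obs = random_testing(traj, 0.05, 0.2, 0.08, rng)
    # fix the observation count exactly by sub/over-sampling records
    records = list(obs)
    if len(records) > n_obs:
        idx = rng.choice(len(records), size=n_obs, replace=False)
        from .observation import ObservationSet

        obs = ObservationSet(observations=[records[i] for i in sorted(idx)])
    cfg = InferenceConfig(K=K)
    start = time.perf_counter()
    if method == "ens":
        run_inference(net, obs, 7, cfg, rng)
    elif method == "dummy":  # constant-work control for the harness itself
        float(np.sin(np.arange(200_000)).sum())
    else:
        raise ValueError(f"unknown benchmark method {method!r}")
    return time.perf_counter() - start


def scaling_benchmark(
    sweep: str,
    levels: list,
    repeats: int = 3,
    base: dict | None = None,
    master_seed: int = 0,
    method: str = "ens",
) -> tuple[pd.DataFrame, float]:
    """Time the inference across a sweep of one problem-size dimension.

    ``sweep`` is one of ``n_nodes``, ``n_obs``, ``mean_degree``, ``K``.
    Returns the per-run timing table and the fitted slope of
    log(runtime) vs log(level).  Slopes are reported, not asserted: they
    depend on hardware and on implementation constants.
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 sweep levels to fit a slope")
    if sweep not in {"n_nodes", "n_obs", "mean_degree", "K"}:
        raise ValueError(f"unknown sweep dimension {sweep!r}")
    base = {"n_nodes": 3000, "mean_degree": 3.0, "n_obs": 200, "K": 100, **(base or {})}
    rows = []
    for level in levels:
        sizes = {**base, sweep: level}
        for rep in range(repeats):
            rt = _timed_inference(
                int(sizes["n_nodes"]),
                float(sizes["mean_degree"]),
                int(sizes["n_obs"]),
                int(sizes["K"]),
                master_seed,
                rep,
                method=method,
            )
            rows.append({"sweep": sweep, "level": level, "repeat": rep, "runtime_s": rt})
    df = pd.DataFrame(rows)
    med = df.groupby("level")["runtime_s"].median()
    slope = float(np.polyfit(np.log(med.index.astype(float)), np.log(med.values), 1)[0])
    return df, slope
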