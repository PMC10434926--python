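# Methods

This note documents the models implemented in `epiens`, the parameters
that matter, the numerical choices, and what the synthetic benchmarks do
and do not demonstrate.

## Epidemic model

Outbreaks are simulated as a discrete-time (daily), synchronous SIR process
on an undirected simple graph.  On the transition from day `t` to `t+1`:

* a susceptible node `i` with `m` infectious neighbours at day `t` becomes
  infectious with probability `1 − (1−β_i)^m` — each infectious neighbour
  is an independent exposure, and `β_i` is a property of the *susceptible*
  node (susceptibility-side heterogeneity, e.g. vaccination status);
* a node infectious at day `t` recovers with probability `1/D`;
* a node infected on day `t+1` can neither transmit nor recover on day
  `t+1` (updates read only day-`t` states).

Recovery is therefore geometric with mean `D` days.  `β` and `D` have
units of probability/day and days.

### Transmission-rate heterogeneity

The default sampler draws `β_i` from a two-component Gaussian mixture:
a fraction `frac_low` of nodes from `N(0.18, 0.01²)` (partially protected)
and the rest from `N(0.22, 0.01²)`, clipped to `[0, 1]`.  Default
`frac_low = 0.5`; 20% and 80% variants ship as packaged configs.  A
truncated power-law sampler is provided for transmissibility-heterogeneity
experiments.

### Default growth-phase configuration

The packaged default outbreak targets the *growth phase* of an epidemic,
when inference is most actionable: on an ER network with 1,000 nodes and
mean degree 2.6, seeding 8% of nodes uniformly at random and running for
`T = 7` days with `D = 3` yields a mean attack rate (fraction ever
infected) of ≈29%, inside the 25–35% band that defines the regime.  The
seed fraction is the calibrated quantity; with ⟨k⟩ = 2.6 and β̄ ≈ 0.2 the
daily growth factor is only ≈1.2, so a 7-day window needs a substantial
seed set to reach the band — a choice that mimics inference starting after
undetected community spread, not at patient zero.

## Observation models

*Random testing*: on each day `1..T` each node is tested independently
with a probability depending on its true state that day — defaults
`q_S = 0.016`, `q_I = 0.090`, `q_R = 0.033`, calibrated so that ≈16% of
nodes acquire at least one test record on the default ER outbreak
(packaged variants target ≈30% and ≈50%).  Infectious nodes are tested
more because they are more likely symptomatic.  Tests are perfect
(sensitivity = specificity = 1) and day 0 is never tested, so the seeding
event itself is not observed.  Repeat tests of a node on later days are
kept; at most one record exists per (node, day).

*Contact tracing*: the same base testing, plus: every neighbour of a node
observed infectious on day `t` is tested with certainty on day `t+1`,
recursively.  Base rates are reduced in the packaged config so the
observed fraction stays in the 10–50% operating range.

## Master equations

Per-node marginals `(pS, pI, pR)` evolve under an independence
approximation over neighbours.  With hazard
`h_i(t) = 1 − Π_{j∈∂i} (1 − β_i pI_j(t))`, the one-day update

```
pS' = pS (1 − h)
pI' = pI (1 − 1/D) + pS h
pR' = pR + pI / D
```

conserves the probability simplex analytically; floating-point negatives
beyond 1e−12 trigger a log warning before clipping.  The equations are
stated in continuous form in the literature; the daily update above is the
Euler discretisation with Δt = 1 day, matching the simulator and the daily
assimilation cycle exactly.

**Accuracy.**  These are individual-based mean-field equations.  They are
exact when each neighbour's infectious indicator is uncorrelated across
days (e.g. a never-recovering clamped source), and a good approximation on
sparse, locally tree-like graphs.  They are *not* exact on trees: the
hazard of node `i` includes the infection probability of `i`'s own
offspring — probability mass that arrived through `i` — and ignores the
day-to-day correlation of a neighbour's infectious state.  Both effects
bias the marginals toward over-predicting infection (on a depth-3 ternary
tree with β = 0.2, D = 3 and a deterministic root seed, marginals deviate
from 10⁵-run Monte-Carlo frequencies by up to ≈0.16 at day 7).  Exactness
on trees belongs to the cavity (message-passing) equations, implemented
here as the DMP baseline, which matches the same Monte-Carlo check within
sampling error.  For *ranking*, what matters is the relative ordering of
marginals after daily correction against observations, which the
over-prediction bias distorts far less than it distorts the absolute
values.  Dense, clustered graphs degrade the approximation further; no
loop corrections are attempted.

Single-node conditional likelihoods `P(state O at t_o | state X at t)` are
products of per-day 3×3 transition matrices
`[[1−h, h, 0], [0, 1−1/D, 1/D], [0, 0, 1]]` with the node's hazards read
from a forecast.

## Ensemble inference

The ensemble holds `K = 100` members (K = 50 gives statistically
indistinguishable rankings; K ≥ 2 is required for covariances).  Each
member starts with per-node `pI ~ U(0, p0)`, `p0 = 0.01`, `pR = 0`, and a
rate vector `β ~ U(0.10, 0.30)^N` — a prior that brackets the bimodal
truth without matching it, by design: robustness to rate mis-specification
is the point of the method.

Each day `t`, up to and including the most recent observation day:

1. Every member integrates a throwaway copy (no adjustments) from `t` to
   the last observation day; per-day hazards are stored per member.  Using
   per-member forecasts (rather than the ensemble mean) preserves spread.
2. Observations with `t_o ≥ t` are assimilated in ascending `(t_o, node)`
   order — assimilation is sequential, so the order is fixed for
   determinism.  For each observation, each member's marginals at the
   observed node get the Bayes update (same-day observations use the
   identity likelihood, i.e. a hard clamp); if an observation has zero
   posterior mass under a member's prior, the posterior falls back to the
   likelihood's argmax (logged).  The correction is then regressed onto
   the node's *direct* neighbours with the cross-ensemble coefficient
   `C = cov/var` computed from pre-update member values per state
   component; adjusted triples are projected to the simplex by clipping to
   `[0,1]` and renormalising (an all-zero triple falls back to uniform).
   Farther nodes receive information only through integration.
3. All members step one day forward.

Observations are re-assimilated every day up to their date, so information
is continuously reconciled with the evolving state.  After the loop the
ensemble integrates freely to `T`; the per-day ensemble mean of `pI` is
recorded and the final-day vector is the risk ranking.

### Robust regression guards

Re-assimilating the same observation daily collapses the ensemble spread
at observed nodes.  Two guards protect the neighbour regression from the
resulting sampling artifacts (both active only in the daily cycle; the
low-level operation exposes the raw regression for verification):

* **Correlation screening** — coefficients whose cross-ensemble
  |correlation| is below `2/√K` (the sampling-noise level) are zeroed.
* **Trust region** — `C` is damped by `min(1, 3·sd_node/rms(ΔP))`, so a
  correction is never extrapolated beyond ≈3 ensemble standard deviations
  of the observed node.  Without this, a hard clamp (ΔP ≈ 0.3) applied
  through a slope estimated on ±0.006 fluctuations can send a neighbour's
  infection probability to 0 or 1 with arbitrary sign.

A variance floor (`1e−10`) additionally guards the division itself.

## Baselines

*Degree* scores nodes by `|∂i|`; *Contact* by the number of distinct
neighbours ever observed infectious.  The *DMP* baseline integrates the
standard SIR edge-message equations (θ, φ; cavity products with explicit
zero handling) forward from a uniform initial infection probability `p0`,
with rates either fixed at the prior mean (DMP1) or drawn per node from
the prior (DMP2); a true-rate override exists for sensitivity experiments.
Observations enter by clamping observed nodes' marginals at their
observation days and rescaling the clamped node's outgoing φ messages by
the ratio of new to old infection marginal.  This modification is a
reconstruction — the message equations have no canonical way to absorb
state observations — so DMP results here support relative method
comparisons, not calibrated posteriors.

## Evaluation

Truth is "infectious on day `T`" (the inference target); an ever-infected
variant is available behind a flag.  AUC is tie-aware (mid-rank;
equivalent to Mann–Whitney U normalised), so heavily tied rankings like
Degree are neither penalised nor favoured.  All nodes are evaluated by
default; an `unobserved` policy excludes nodes observed on day `T`, whose
status is trivially known.  Top-k hit counts break score ties by a
fixed-seed shuffle.  Undefined-AUC inputs (single-class truth) raise with
an explanatory message.

## Experiment driver and problem sizes

Experiments are YAML-configured; a master seed spawns per-replicate,
per-role child seeds (outbreak, observation, inference, DMP draws,
tie-breaks), so adding a method to a config never perturbs the simulated
outbreaks, and metric CSVs are byte-identical across re-runs.  The
benchmark suites used in the tests run 20 outbreak replicates per setting
on ER(1000, ⟨k⟩ = 2.6) and on a 2,044-node configuration-model scale-free
network (γ = 2.5), sizes at which a full 100-member inference replicate
takes well under a second; the acceptance script averages 12 replicates
for the headline AUC and 50 for the attack-rate calibration.  A scaling
harness times the inference across sweeps of `n_nodes`, `n_obs`,
`mean_degree` or `K` and reports the fitted log-log slope; slopes are
hardware- and implementation-dependent and are reported, not asserted.

## What the synthetic benchmarks show — and don't

The generators produce idealised networks (no community structure,
clustering, assortativity or temporal contact dynamics) and the
observation models assume perfect tests with state-dependent but otherwise
independent sampling.  Passing benchmarks therefore demonstrates that the
assimilation machinery extracts and propagates the information the
observations carry under a mis-specified rate prior — not that real-world
surveillance data, with imperfect tests, reporting delays and mis-measured
contact networks, would yield the same accuracy.  Known limitations:
mean-field bias on dense/clustered graphs; the DMP observation
modification is a reconstruction; transmission rates are inferred only
through the prior ensemble, never estimated from data; and the ensemble,
lacking inflation or localisation machinery from geophysical data
assimilation, relies on the simple guards above against collapse.
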