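"""Sampler-correctness diagnostics.

The main tool is a Geweke-style joint-distribution test: statistics of
(state, data) drawn by (a) forward simulation from the prior and (b) a
successive-conditional chain (one MCMC sweep on the data, then data
regenerated from the state) must agree in distribution if every sweep
leaves the joint invariant.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .inference import (
    McmcConfig,
    ModelHyper,
    ModelState,
    ensure_theta_chain,
    mcmc_sweep,
)
from .model import AttributeMatrix, NodeParams, generate_observation, sample_root_theta
from .nodes import ROOT
from .tssbp import OccupancyCounts, StickState, assign_via_uniform, sample_sticks


def prior_forward_sample(
    n: int, hyper: ModelHyper, rng: np.random.Generator, resample_c: bool = True
) -> Tuple[ModelState, AttributeMatrix]:
    """One exact joint draw (state, data) from the generative model."""
    hyper = hyper.copy()
    if resample_c:
        hyper.sparsity.c = np.asarray(
            rng.uniform(hyper.sparsity.c_lower, hyper.sparsity.c_upper, hyper.sparsity.D)
        )
    sticks = StickState()
    sample_sticks(sticks, hyper.tree, ROOT, rng)
    params = NodeParams({ROOT: sample_root_theta(hyper.sparsity, rng)})
    state = ModelState(sticks, params, OccupancyCounts(), [], hyper)
    assignments = []
    for _ in range(n):
        z = assign_via_uniform(sticks, hyper.tree, rng.random(), rng)
        ensure_theta_chain(state, z, rng)
        assignments.append(z)
    state.assignments = assignments
    state.counts = OccupancyCounts.from_assignments(assignments)
    data = regenerate_data(state, rng)
    return state, data


def regenerate_data(state: ModelState, rng: np.random.Generator) -> AttributeMatrix:
    """Redraw every observation from its likelihood at the current state."""
    n = len(state.assignments)
    D = state.hyper.sparsity.D
    X = np.empty((n, D), dtype=np.int8)
    for i, z in enumerate(state.assignments):
        X[i] = generate_observation(z, state.params, state.hyper.noise, rng)
    ids = [f"i{i:05d}" for i in range(n)]
    names = [f"attr{d:03d}" for d in range(D)]
    return AttributeMatrix(X, ids, names)


def monitored_stats(state: ModelState, data: AttributeMatrix) -> Dict[str, float]:
    """Scalar functionals of (state, data) compared by the Geweke test."""
    depths = [len(z) for z in state.assignments]
    return {
        "mean_depth": float(np.mean(depths)),
        "mean_root_theta": float(np.mean(state.params.theta[ROOT])),
        "data_mean": float(np.mean(data.X)),
        "max_depth": float(np.max(depths)),
        "mean_c": float(np.mean(state.hyper.sparsity.c)),
    }


def geweke_samples(
    n: int,
    hyper: ModelHyper,
    config: McmcConfig,
    n_forward: int,
    n_chain: int,
    seed: int,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Collect monitored statistics from both simulation schemes."""
    rng = np.random.default_rng(seed)
    fwd: Dict[str, List[float]] = {}
    for _ in range(n_forward):
        state, data = prior_forward_sample(n, hyper, rng, config.resample_c)
        for k, v in monitored_stats(state, data).items():
            fwd.setdefault(k, []).append(v)
    chain: Dict[str, List[float]] = {}
    state, data = prior_forward_sample(n, hyper, rng, config.resample_c)
    for _ in range(n_chain):
        mcmc_sweep(state, data, config, rng)
        data = regenerate_data(state, rng)
        for k, v in monitored_stats(state, data).items():
            chain.setdefault(k, []).append(v)
    return (
        {k: np.asarray(v) for k, v in fwd.items()},
        {k: np.asarray(v) for k, v in chain.items()},
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    tau = 1.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return max(1.0, n / tau)


def geweke_zscores(
    fwd: Dict[str, np.ndarray], chain: Dict[str, np.ndarray]
) -> Dict[str, float]:
    """z-score of the mean difference per statistic, ESS-corrected."""
    out = {}
    for k in fwd:
        a, b = fwd[k], chain[k]
        se_a = a.std(ddof=1) / np.sqrt(len(a))
        se_b = b.std(ddof=1) / np.sqrt(effective_sample_size(b))
        se = np.sqrt(se_a**2 + se_b**2)
        out[k] = float((a.mean() - b.mean()) / se) if se > 0 else 0.0
    return out
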