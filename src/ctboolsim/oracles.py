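"""Exact references for small networks: closed forms and master-equation integration.

These are independent of the Gillespie path: probabilities are obtained by
integrating the chemical master equation of the full continuous-time Markov
chain over all ``2**n`` states (practical up to ~12 nodes), or from closed
forms for one-node systems.  They serve as oracles in the test suite and as
convergence checks; they are never used to produce ensemble results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .simulate import CompiledNetwork, SimulationConfig, _default_initial

__all__ = [
    "window_average_exponential",
    "telegraph_window_marginals",
    "master_equation_windows",
]


def window_average_exponential(
    p_inf: float, p0: float, lam: float, t0: np.ndarray, t1: np.ndarray
) -> np.ndarray:
    """Time average of ``p_inf + (p0 - p_inf) e^(-lam t)`` over [t0, t1]."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if lam == 0.0:
        return np.full_like(t0, p0)
    return p_inf + (p0 - p_inf) * (np.exp(-lam * t0) - np.exp(-lam * t1)) / (
        lam * (t1 - t0)
    )


def telegraph_window_marginals(
    u: float, d: float, p0: float, window_starts: np.ndarray, tick: float
) -> np.ndarray:
    """Exact window-averaged ON probability of a telegraph (two-state) node.

    The node flips up at rate ``u`` when OFF and down at rate ``d`` when ON;
    the solution is ``P(t) = p_inf + (p0 - p_inf) e^(-(u+d) t)`` with
    ``p_inf = u / (u + d)``.
    """
    starts = np.asarray(window_starts, dtype=float)
    return window_average_exponential(u / (u + d), p0, u + d, starts, starts + tick)


MAX_ORACLE_NODES = 12


def _initial_distribution(network, config: SimulationConfig, compiled: CompiledNetwork) -> np.ndarray:
    n = len(compiled.names)
    probs = _default_initial(network, config)
    joint_nodes: set[int] = set()
    joint_spec = []
    for names, dist in config.joint:
        idxs = [compiled.index[nm] for nm in names]
        joint_nodes.update(idxs)
        joint_spec.append((idxs, dist))
    p0 = np.ones(2**n)
    for m in range(2**n):
        p = 1.0
        for i in range(n):
            if i in joint_nodes:
                continue
            bit = (m >> i) & 1
            p *= probs[i] if bit else 1.0 - probs[i]
        for idxs, dist in joint_spec:
            bits = tuple((m >> i) & 1 for i in idxs)
            p *= dist.get(bits, 0.0)
        p0[m] = p
    return p0


def master_equation_windows(
    network, config: SimulationConfig, substeps: int = 64
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact window-averaged probabilities by master-equation integration.

    Builds the full ``2**n x 2**n`` transition-rate matrix, propagates the
    state distribution with matrix exponentials on a fine grid and averages
    within each window (trapezoid rule with ``substeps`` sub-intervals per
    window).  Returns ``(marginals, joint)`` frames shaped like the
    corresponding :class:`~ctboolsim.simulate.EnsembleResult` fields.
    """
    compiled = CompiledNetwork(network)
    n = len(compiled.names)
    if n > MAX_ORACLE_NODES:
        raise ValueError(f"master-equation oracle capped at {MAX_ORACLE_NODES} nodes")
    n_states = 2**n
    rate_matrix = np.zeros((n_states, n_states))
    for m in range(n_states):
        state = [(m >> i) & 1 for i in range(n)]
        for i in range(n):
            r = compiled.rate(i, state)
            if r > 0.0:
                rate_matrix[m, m ^ (1 << i)] = r
        rate_matrix[m, m] = -rate_matrix[m].sum()

    tracked = tuple(config.tracked) if config.tracked else tuple(network.outputs)
    if not tracked:
        tracked = tuple(network.nodes)
    tracked_idx = [compiled.index[nm] for nm in tracked]

    max_time, tick = float(config.max_time), float(config.time_tick)
    n_windows = int(np.ceil(max_time / tick - 1e-12))
    starts = np.arange(n_windows) * tick
    widths = np.full(n_windows, tick)
    widths[-1] = max_time - (n_windows - 1) * tick

    p = _initial_distribution(network, config, compiled)
    propagators: dict[float, np.ndarray] = {}
    window_means = np.zeros((n_windows, n_states))
    for w in range(n_windows):
        dt = widths[w] / substeps
        step = propagators.get(dt)
        if step is None:
            step = propagators[dt] = expm(rate_matrix.T * dt)
        weights = np.full(substeps + 1, dt)
        weights[0] = weights[-1] = dt / 2
        acc = weights[0] * p
        for k in range(substeps):
            p = step @ p
            acc += weights[k + 1] * p
        window_means[w] = acc / widths[w]

    # collapse to joint states of the tracked nodes
    key_of = [
        "".join(str((m >> i) & 1) for i in tracked_idx) for m in range(n_states)
    ]
    joint = pd.DataFrame(0.0, index=starts, columns=sorted(set(key_of)))
    for m in range(n_states):
        joint[key_of[m]] += window_means[:, m]
    marginals = pd.DataFrame(index=starts)
    for pos, name in enumerate(tracked):
        cols = [c for c in joint.columns if c[pos] == "1"]
        marginals[name] = joint[cols].sum(axis=1) if cols else 0.0
    return marginals, joint
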