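"""Continuous-time kinetic Monte-Carlo (Gillespie) simulation of Boolean networks.

The model is a continuous-time Markov chain on the state transition graph:
in state ``s``, node ``i`` is eligible to flip up at rate ``k_up[i]`` when
``s_i = 0`` and its rule evaluates to 1, and to flip down at rate
``k_down[i]`` when ``s_i = 1`` and its rule evaluates to 0.  Waiting times
are exponential in the total eligible rate and the flipping node is chosen
proportionally to its rate.  A state with no eligible transition is a fixed
point and is held until ``max_time``.

Ensemble statistics follow the MaBoSS convention: the probability reported
for a time window is the trajectory-averaged fraction of time spent in a
(joint) state within that window, not the instantaneous end-of-window state;
the asymptotic phenotype score is the last window's value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import expressions as ex

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "EnsembleResult",
    "ConvergenceWarning",
    "eligible_transitions",
    "run_trajectory",
    "simulate_ensemble",
    "phenotype_scores",
]


class ConvergenceWarning(UserWarning):
    """Emitted when the last two time windows still differ noticeably."""


JointAssignment = tuple[tuple[str, ...], dict[tuple[int, ...], float]]


@dataclass
class SimulationConfig:
    """Run parameters for a trajectory ensemble.

    Parameters
    ----------
    n_trajectories:
        Ensemble size; default 5000.
    max_time:
        Simulation horizon in model-time units; chosen per model so the
        ensemble reaches its asymptotic regime (a :class:`ConvergenceWarning`
        is emitted otherwise).
    time_tick:
        Width of the probability windows, model-time units.
    seed:
        Root seed; all randomness derives from it via per-trajectory
        substreams, so results are independent of scheduling.
    initial:
        Per-node Bernoulli probability of starting ON.  Nodes absent from
        the mapping default to 0 for input nodes and 0.5 otherwise.
    joint:
        Optional joint initial assignments ``(names, {bits: prob})`` which
        override the per-node marginals for the listed nodes.
    tracked:
        Nodes whose marginal and joint-state probabilities are recorded;
        defaults to the network's output nodes.
    """

    n_trajectories: int = 5000
    max_time: float = 20.0
    time_tick: float = 1.0
    seed: int = 0
    initial: dict[str, float] = field(default_factory=dict)
    joint: list[JointAssignment] = field(default_factory=list)
    tracked: Sequence[str] | None = None
    trailing_windows: int = 2
    convergence_tol: float = 0.01

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be positive")
        if self.time_tick <= 0:
            raise ValueError("time_tick must be positive")
        if self.time_tick > self.max_time:
            raise ValueError("time_tick must not exceed max_time")
        for name, p in self.initial.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"initial probability of {name!r} is {p}, not in [0, 1]")
        for names, dist in self.joint:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"joint initial assignment for {names} sums to {total}, not 1"
                )

    def replace(self, **kwargs) -> "SimulationConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class Trajectory:
    """One Gillespie realisation: initial state and ordered flip events."""

    initial: dict[str, int]
    events: list[tuple[float, str, int]]  # (time, node, new value)
    end_time: float


# ---------------------------------------------------------------------------
# Rule compilation
# ---------------------------------------------------------------------------


class CompiledNetwork:
    """Truth-table compilation of a network for the simulation inner loop."""

    __slots__ = ("names", "index", "regs", "tables", "k_up", "k_down", "dependents")

    def __init__(self, network):
        self.names: tuple[str, ...] = tuple(network.nodes)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.regs: list[list[int]] = []
        self.tables: list[np.ndarray] = []
        self.k_up = [network.k_up[n] for n in self.names]
        self.k_down = [network.k_down[n] for n in self.names]
        dependents: list[set[int]] = [set((i,)) for i in range(len(self.names))]
        for i, name in enumerate(self.names):
            var_order, table = ex.truth_table(network.rules[name])
            self.regs.append([self.index[v] for v in var_order])
            self.tables.append(table)
            for r in self.regs[-1]:
                dependents[r].add(i)
        self.dependents = [sorted(d) for d in dependents]

    def target(self, i: int, state: Sequence[int]) -> int:
        bits = 0
        for j, r in enumerate(self.regs[i]):
            bits |= state[r] << j
        return int(self.tables[i][bits])

    def rate(self, i: int, state: Sequence[int]) -> float:
        t = self.target(i, state)
        if state[i] == 0 and t == 1:
            return self.k_up[i]
        if state[i] == 1 and t == 0:
            return self.k_down[i]
        return 0.0


def eligible_transitions(network, state: Mapping[str, int]) -> list[tuple[str, float]]:
    """Nodes eligible to flip in ``state`` with their firing rates.

    Empty iff ``state`` is a fixed point of the asynchronous dynamics.
    """
    out = []
    for name in network.nodes:
        target = ex.evaluate(network.rules[name], state)
        current = int(state[name])
        if current == 0 and target == 1:
            out.append((name, network.k_up[name]))
        elif current == 1 and target == 0:
            out.append((name, network.k_down[name]))
    return out


# ---------------------------------------------------------------------------
# Core Gillespie loop
# ---------------------------------------------------------------------------


def _gillespie(
    compiled: CompiledNetwork,
    state: list[int],
    rng: np.random.Generator,
    max_time: float,
    on_hold: Callable[[float, float, list[int]], None],
    events: list[tuple[float, str, int]] | None = None,
) -> None:
    n = len(state)
    rates = [compiled.rate(i, state) for i in range(n)]
    total = sum(rates)
    t = 0.0
    while True:
        if total <= 0.0:
            on_hold(t, max_time, state)
            return
        dt = rng.standard_exponential() / total
        t_next = t + dt
        if t_next >= max_time:
            on_hold(t, max_time, state)
            return
        on_hold(t, t_next, state)
        u = rng.random() * total
        acc = 0.0
        j = n - 1
        for i in range(n):
            acc += rates[i]
            if u < acc:
                j = i
                break
        state[j] ^= 1
        if events is not None:
            events.append((t_next, compiled.names[j], state[j]))
        for d in compiled.dependents[j]:
            rates[d] = compiled.rate(d, state)
        total = sum(rates)
        t = t_next


def _default_initial(network, config: SimulationConfig) -> np.ndarray:
    probs = np.empty(len(network.nodes))
    inputs = set(network.inputs)
    for i, name in enumerate(network.nodes):
        if name in config.initial:
            probs[i] = config.initial[name]
        else:
            probs[i] = 0.0 if name in inputs else 0.5
    return probs


def _sample_initial(
    probs: np.ndarray,
    joint: list[tuple[list[int], list[tuple[tuple[int, ...], float]]]],
    rng: np.random.Generator,
) -> list[int]:
    state = (rng.random(len(probs)) < probs).astype(int).tolist()
    for idxs, dist in joint:
        u = rng.random()
        acc = 0.0
        for bits, prob in dist:
            acc += prob
            if u < acc:
                for pos, b in zip(idxs, bits):
                    state[pos] = b
                break
    return state


def run_trajectory(
    network,
    init: Mapping[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Trajectory:
    """Run one Gillespie trajectory from an explicit initial state."""
    compiled = CompiledNetwork(network)
    state = [int(init[n]) for n in compiled.names]
    events: list[tuple[float, str, int]] = []
    _gillespie(compiled, state, rng, config.max_time, lambda *_: None, events)
    return Trajectory(initial=dict(init), events=events, end_time=config.max_time)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    """Time-windowed probabilities from a trajectory ensemble.

    ``joint`` holds, per window, the probability of each joint state of the
    tracked nodes (columns are bit strings in tracked-node order);
    ``marginals`` the per-node ON probabilities.  Both use the window start
    time as index.  Rows of ``joint`` sum to 1 and each marginal equals the
    sum of the joint states with that node ON, by construction.
    """

    tracked: tuple[str, ...]
    outputs: tuple[str, ...]
    window_starts: np.ndarray
    time_tick: float
    joint: pd.DataFrame
    marginals: pd.DataFrame
    n_trajectories: int
    seed: int
    variant_counts: dict[int, int] | None = None

    def phenotype_scores(self) -> pd.Series:
        """Asymptotic (last window) ON probability per output node."""
        outs = [n for n in self.outputs if n in self.marginals.columns]
        return self.marginals.iloc[-1][outs]

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table (window, entity, probability)."""
        m = self.marginals.copy()
        m.index.name = "window_start"
        tidy = m.reset_index().melt(
            id_vars="window_start", var_name="entity", value_name="probability"
        )
        j = self.joint.copy()
        j.columns = [
            "{" + ",".join(f"{n}={b}" for n, b in zip(self.tracked, col)) + "}"
            for col in j.columns
        ]
        j.index.name = "window_start"
        tidy_j = j.reset_index().melt(
            id_vars="window_start", var_name="entity", value_name="probability"
        )
        return pd.concat([tidy, tidy_j], ignore_index=True)


def simulate_ensemble(
    network,
    config: SimulationConfig,
    *,
    variant_networks: Sequence | None = None,
    variant_sampler: Callable[[np.random.Generator], int] | None = None,
) -> EnsembleResult:
    """Estimate window probabilities from ``config.n_trajectories`` runs.

    ``variant_networks``/``variant_sampler`` support trajectory mixtures
    (gradual drug inhibition): per trajectory, ``variant_sampler`` draws an
    index into ``variant_networks`` from a dedicated assignment stream, so
    the dynamics substreams coincide with a plain run of the chosen variant.
    """
    if variant_networks is None:
        variant_networks = [network]
    compiled_variants = [CompiledNetwork(v) for v in variant_networks]
    base = compiled_variants[0]
    tracked = tuple(config.tracked) if config.tracked else tuple(network.outputs)
    if not tracked:
        tracked = tuple(network.nodes)
    for name in tracked:
        if name not in base.index:
            raise KeyError(f"tracked node {name!r} is not in the network")
    tracked_idx = [base.index[n] for n in tracked]

    max_time, tick = float(config.max_time), float(config.time_tick)
    n_windows = int(np.ceil(max_time / tick - 1e-12))
    widths = np.full(n_windows, tick)
    widths[-1] = max_time - (n_windows - 1) * tick
    starts = np.arange(n_windows) * tick

    probs = _default_initial(network, config)
    joint_spec = [
        ([base.index[n] for n in names], list(dist.items()))
        for names, dist in config.joint
    ]

    occupancy: dict[tuple[int, ...], np.ndarray] = {}

    def on_hold(t0: float, t1: float, state: list[int]) -> None:
        if t1 <= t0:
            return
        key = tuple(state[i] for i in tracked_idx)
        arr = occupancy.get(key)
        if arr is None:
            arr = occupancy[key] = np.zeros(n_windows)
        w0 = min(int(t0 / tick), n_windows - 1)
        w1 = min(int(t1 / tick - 1e-12), n_windows - 1)
        if w0 == w1:
            arr[w0] += t1 - t0
        else:
            arr[w0] += (w0 + 1) * tick - t0
            if w1 > w0 + 1:
                arr[w0 + 1 : w1] += tick
            arr[w1] += t1 - w1 * tick

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_trajectories)
    assignment_rng = None
    variant_counts: dict[int, int] | None = None
    if variant_sampler is not None:
        assignment_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(2**31,)))
        )
        variant_counts = {}

    for child in children:
        rng = np.random.Generator(np.random.PCG64(child))
        if variant_sampler is not None:
            v = variant_sampler(assignment_rng)
            variant_counts[v] = variant_counts.get(v, 0) + 1
            compiled = compiled_variants[v]
        else:
            compiled = base
        state = _sample_initial(probs, joint_spec, rng)
        _gillespie(compiled, state, rng, max_time, on_hold)

    keys = sorted(occupancy)
    norm = config.n_trajectories * widths
    joint = pd.DataFrame(
        {"".join(map(str, k)): occupancy[k] / norm for k in keys}, index=starts
    )
    marginals = pd.DataFrame(index=starts)
    for pos, name in enumerate(tracked):
        cols = [c for c in joint.columns if c[pos] == "1"]
        marginals[name] = joint[cols].sum(axis=1) if cols else 0.0

    if n_windows >= 2:
        last = marginals.iloc[-1].to_numpy()
        drift = np.abs(last - marginals.iloc[-2].to_numpy())
        # tolerate Monte-Carlo jitter on top of the drift threshold
        noise = 3.0 * np.sqrt(
            np.clip(last * (1.0 - last), 0.0, None) / config.n_trajectories
        )
        excess = float((drift - noise).max())
        if excess > config.convergence_tol:
            warnings.warn(
                f"last two windows differ by up to {drift.max():.3f} beyond "
                f"Monte-Carlo noise (tolerance {config.convergence_tol}); "
                "increase max_time",
                ConvergenceWarning,
                stacklevel=2,
            )

    return EnsembleResult(
        tracked=tracked,
        outputs=tuple(network.outputs),
        window_starts=starts,
        time_tick=tick,
        joint=joint,
        marginals=marginals,
        n_trajectories=config.n_trajectories,
        seed=config.seed,
        variant_counts=variant_counts,
    )


def phenotype_scores(result: EnsembleResult) -> dict[str, float]:
    """Mapping output node -> asymptotic activation probability."""
    return result.phenotype_scores().to_dict()
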