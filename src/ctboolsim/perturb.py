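"""Genetic and pharmacological perturbations of Boolean networks.

Genetic perturbations replace a node's rule by a constant: knock-out (KO,
forced 0) or gain-of-function / overexpression (OE, forced 1).  Drugs are
modelled as *gradual* node inhibition: at inhibition level ``alpha`` a
fraction ``alpha`` of the trajectory ensemble carries the knocked-out node
and the remaining ``1 - alpha`` the intact rule (``mixture_ko_wt``
semantics), so 0% inhibition is exactly the wild type and 100% the proper
knock-out.  An alternative ``frozen_on_off`` semantics freezes the target
(self-identity rule) and starts it ON with probability ``1 - alpha``.
Phenotype scores of a dosed model are ensemble averages over all
trajectories, i.e. over the mixture.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .expressions import Const, Var, count_binary_ops, swap_binary_op, to_string
from .simulate import EnsembleResult, SimulationConfig, simulate_ensemble

__all__ = [
    "Perturbation",
    "DrugSpec",
    "ConditionPreset",
    "apply_mutation",
    "apply_drug",
    "simulate_drug",
    "apply_preset",
    "condition_presets",
    "dose_response",
    "combination_conditions",
    "combination_screen",
    "enumerate_mutants",
    "mutant_screen",
    "rule_robustness_scan",
    "DEFAULT_LEVELS",
]

logger = logging.getLogger(__name__)

#: Default inhibition grid: no inhibition up to proper knock-out.
DEFAULT_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class Perturbation:
    """A set of node forcings; order 1 = single mutant, 2 = double mutant."""

    forcings: tuple[tuple[str, int], ...]

    def __post_init__(self):
        seen: dict[str, int] = {}
        for node, value in self.forcings:
            if value not in (0, 1):
                raise ValueError(f"forced value must be 0 or 1, got {value!r}")
            if node in seen and seen[node] != value:
                raise ValueError(f"conflicting forcings for node {node!r}")
            seen[node] = value
        object.__setattr__(
            self, "forcings", tuple(sorted(seen.items()))
        )

    @property
    def order(self) -> int:
        return len(self.forcings)

    @property
    def label(self) -> str:
        return "+".join(f"{n}:{v}" for n, v in self.forcings) or "wild_type"


def apply_mutation(network, perturbation: Perturbation):
    """Replace each perturbed node's rule by the forced constant.

    Rates are untouched; an empty perturbation returns the network unchanged.
    """
    out = network
    for node, value in perturbation.forcings:
        out = out.with_rule(node, Const(value))
    return out


# ---------------------------------------------------------------------------
# Condition presets (growth media as input-node assignments)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionPreset:
    """A named, complete assignment of the model's input nodes."""

    name: str
    assignment: Mapping[str, int] = field(default_factory=dict)


def apply_preset(network, config: SimulationConfig, preset: ConditionPreset) -> SimulationConfig:
    """Fix the input nodes' initial probabilities to the preset's values.

    The preset must assign every input node (and nothing else); inputs never
    flip, so the assignment holds for the whole simulation.
    """
    inputs = set(network.inputs)
    missing = inputs - set(preset.assignment)
    if missing:
        raise ValueError(f"preset {preset.name!r} leaves inputs unassigned: {sorted(missing)}")
    extra = set(preset.assignment) - inputs
    if extra:
        raise ValueError(f"preset {preset.name!r} assigns non-input nodes: {sorted(extra)}")
    initial = dict(config.initial)
    initial.update({n: float(v) for n, v in preset.assignment.items()})
    return config.replace(initial=initial)


def condition_presets(
    network,
    varying: Sequence[str] = ("EGF", "Androgen"),
    on: Sequence[str] = ("Nutrients",),
) -> dict[str, ConditionPreset]:
    """Growth-medium presets over the network's inputs.

    All inputs default OFF except those in ``on``; each subset of ``varying``
    defines one preset (named 'none', 'EGF', 'EGF+Androgen', ...), emulating
    nutrient-rich media with or without growth factor / androgen.
    """
    varying = [v for v in varying if v in network.inputs]
    base = {n: 1 if n in on else 0 for n in network.inputs}
    presets = {}
    for r in range(len(varying) + 1):
        for combo in itertools.combinations(varying, r):
            assignment = dict(base)
            for v in combo:
                assignment[v] = 1
            name = "+".join(combo) if combo else "none"
            presets[name] = ConditionPreset(name=name, assignment=assignment)
    return presets


# ---------------------------------------------------------------------------
# Gradual drug inhibition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugSpec:
    """Inhibition level per target node, with the mixture semantics mode."""

    targets: tuple[tuple[str, float], ...]
    mode: str = "mixture_ko_wt"

    def __post_init__(self):
        if self.mode not in ("mixture_ko_wt", "frozen_on_off"):
            raise ValueError(f"unknown drug semantics mode {self.mode!r}")
        object.__setattr__(self, "targets", tuple(self.targets))
        for node, alpha in self.targets:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"inhibition level of {node!r} is {alpha}, not in [0, 1]")


def apply_drug(network, config: SimulationConfig, spec: DrugSpec):
    """Prepare a dosed simulation.

    Returns ``(variant_networks, variant_probs, variant_sampler, config)``.
    In ``mixture_ko_wt`` mode, variant ``m`` has target ``j`` knocked out iff
    bit ``j`` of ``m`` is set, and each trajectory draws its variant with
    independent per-target Bernoulli(alpha) trials, giving the product law
    over joint assignments.  In ``frozen_on_off`` mode a single frozen
    network is returned with the target starting ON with probability
    ``1 - alpha``.
    """
    for node, _ in spec.targets:
        if node not in network.rules:
            raise KeyError(f"drug target {node!r} is not in the network")
    if spec.mode == "frozen_on_off":
        frozen = network
        initial = dict(config.initial)
        for node, alpha in spec.targets:
            frozen = frozen.with_rule(node, Var(node))
            initial[node] = 1.0 - alpha
        return [frozen], [1.0], None, config.replace(initial=initial)

    names = [node for node, _ in spec.targets]
    alphas = np.array([alpha for _, alpha in spec.targets])
    k = len(names)
    variants = []
    probs = []
    for mask in range(2**k):
        variant = network
        p = 1.0
        for j in range(k):
            if mask >> j & 1:
                variant = variant.with_rule(names[j], Const(0))
                p *= alphas[j]
            else:
                p *= 1.0 - alphas[j]
        variants.append(variant)
        probs.append(p)

    def sampler(rng: np.random.Generator) -> int:
        mask = 0
        for j in range(k):
            if rng.random() < alphas[j]:
                mask |= 1 << j
        return mask

    return variants, probs, sampler, config


def simulate_drug(
    network, config: SimulationConfig, spec: DrugSpec,
    preset: ConditionPreset | None = None,
) -> EnsembleResult:
    """Simulate a dosed model; scores are averaged over the full ensemble."""
    if preset is not None:
        config = apply_preset(network, config, preset)
    variants, _, sampler, config = apply_drug(network, config, spec)
    return simulate_ensemble(
        network, config, variant_networks=variants, variant_sampler=sampler
    )


# ---------------------------------------------------------------------------
# Dose and combination grids
# ---------------------------------------------------------------------------


def dose_response(
    network,
    config: SimulationConfig,
    target: str,
    levels: Sequence[float] = DEFAULT_LEVELS,
    preset: ConditionPreset | None = None,
    mode: str = "mixture_ko_wt",
) -> pd.DataFrame:
    """Phenotype scores across a single-target inhibition grid.

    One simulation per level; the alpha = 0 row is the untreated reference
    (added if absent from ``levels``).
    """
    levels = sorted(set(levels) | {0.0})
    rows = []
    for alpha in levels:
        spec = DrugSpec(targets=((target, alpha),), mode=mode)
        scores = simulate_drug(network, config, spec, preset).phenotype_scores()
        for phenotype, score in scores.items():
            rows.append({
                "target": target,
                "level": alpha,
                "preset": preset.name if preset else "",
                "phenotype": phenotype,
                "score": score,
            })
    return pd.DataFrame(rows)


def combination_conditions(
    targets: Sequence[str], levels: Sequence[float] = DEFAULT_LEVELS
) -> list[dict]:
    """All simulation conditions of a single + pairwise combination screen.

    Every target alone at each level, plus every unordered pair on the full
    level x level grid: ``t*L + C(t,2)*L**2`` conditions (17 targets and 6
    levels give 4,998).
    """
    conditions = []
    for target in targets:
        for alpha in levels:
            conditions.append({"targets": ((target, alpha),)})
    for a, b in itertools.combinations(targets, 2):
        for alpha_a in levels:
            for alpha_b in levels:
                conditions.append({"targets": ((a, alpha_a), (b, alpha_b))})
    return conditions


def combination_screen(
    network,
    config: SimulationConfig,
    targets: Sequence[str],
    levels: Sequence[float] = DEFAULT_LEVELS,
    preset: ConditionPreset | None = None,
    mode: str = "mixture_ko_wt",
) -> pd.DataFrame:
    """Run the full single + pairwise dose grid and collect phenotype scores."""
    if len(targets) < 2:
        raise ValueError("combination screen needs at least 2 targets")
    rows = []
    for condition in combination_conditions(targets, levels):
        spec = DrugSpec(targets=condition["targets"], mode=mode)
        scores = simulate_drug(network, config, spec, preset).phenotype_scores()
        (ta, la), *rest = condition["targets"]
        tb, lb = rest[0] if rest else (None, np.nan)
        for phenotype, score in scores.items():
            rows.append({
                "target_a": ta,
                "level_a": la,
                "target_b": tb,
                "level_b": lb,
                "preset": preset.name if preset else "",
                "phenotype": phenotype,
                "score": score,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exhaustive mutant analysis
# ---------------------------------------------------------------------------


def enumerate_mutants(
    network,
    perturbable: Sequence[str] | None = None,
    orders: Sequence[int] = (1, 2),
) -> Iterator[Perturbation]:
    """All single and double KO/OE perturbations of the perturbable nodes.

    The default perturbable set is every node except the outputs; with ``n``
    nodes this yields ``2n`` singles and ``4 C(n,2)`` doubles, ``2 n**2`` in
    total (127 perturbable nodes give 32,258).
    """
    if perturbable is None:
        perturbable = [n for n in network.nodes if n not in network.outputs]
    perturbable = list(perturbable)
    if not perturbable:
        raise ValueError("perturbable node set is empty")
    if 1 in orders:
        for node in perturbable:
            for value in (0, 1):
                yield Perturbation(forcings=((node, value),))
    if 2 in orders:
        for a, b in itertools.combinations(perturbable, 2):
            for va in (0, 1):
                for vb in (0, 1):
                    yield Perturbation(forcings=((a, va), (b, vb)))


def mutant_screen(
    network,
    config: SimulationConfig,
    perturbable: Sequence[str] | None = None,
    orders: Sequence[int] = (1, 2),
    preset: ConditionPreset | None = None,
) -> pd.DataFrame:
    """Simulate every enumerated mutant plus the wild type.

    Returns a tidy frame (perturbation, order, phenotype, score) whose first
    rows are the wild-type reference (label ``wild_type``, order 0).
    """
    if preset is not None:
        config = apply_preset(network, config, preset)
    rows = []

    def add(label: str, order: int, net) -> None:
        scores = simulate_ensemble(net, config).phenotype_scores()
        for phenotype, score in scores.items():
            rows.append({
                "perturbation": label,
                "order": order,
                "phenotype": phenotype,
                "score": score,
            })

    add("wild_type", 0, network)
    for p in enumerate_mutants(network, perturbable, orders):
        add(p.label, p.order, apply_mutation(network, p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rule robustness (AND <-> OR swaps)
# ---------------------------------------------------------------------------


def rule_robustness_scan(
    network,
    config: SimulationConfig,
    baseline: EnsembleResult | None = None,
) -> pd.DataFrame:
    """Sensitivity of phenotype scores to single AND <-> OR gate swaps.

    One simulation per binary-operator occurrence across all rules; the
    reported ``shift`` is the largest absolute phenotype-score change
    relative to the unedited model.
    """
    if baseline is None:
        baseline = simulate_ensemble(network, config)
    base_scores = baseline.phenotype_scores()
    rows = []
    for node in network.nodes:
        rule = network.rules[node]
        for op_index in range(count_binary_ops(rule)):
            edited_rule = swap_binary_op(rule, op_index)
            edited = network.with_rule(node, edited_rule)
            scores = simulate_ensemble(edited, config).phenotype_scores()
            shift = float((scores - base_scores).abs().max())
            rows.append({
                "node": node,
                "op_index": op_index,
                "edited_rule": to_string(edited_rule),
                "shift": shift,
            })
    return pd.DataFrame(rows, columns=["node", "op_index", "edited_rule", "shift"])
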