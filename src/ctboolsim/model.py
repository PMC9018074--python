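"""Boolean signalling networks: representation, parsing, validation, influence graph.

A :class:`BooleanNetwork` carries an ordered node list, one logical rule per
node, and strictly positive activation (``k_up``) and inhibition (``k_down``)
transition rates per node, which give the continuous-time Markov process its
timescales.  *Input* nodes represent microenvironmental conditions (growth
factors, oxygen, ...); they carry a self rule, are never regulated by other
nodes and therefore never flip during simulation — their initial probability
is their value throughout.  *Output* nodes are phenotype read-outs
(e.g. Proliferation, Apoptosis) whose asymptotic activation probabilities are
the model's predictions.

Two text formats are supported: the BoolNet ``targets, factors`` rule table
and a documented subset of the MaBoSS ``.bnd``/``.cfg`` pair (see
``docs/methods.md`` for the exact grammar).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx

from . import expressions as ex
from .expressions import Const, Expr, RuleParseError, Var
from .simulate import SimulationConfig

__all__ = [
    "BooleanNetwork",
    "parse_boolnet",
    "serialise_boolnet",
    "parse_maboss",
    "serialise_maboss",
    "evaluate_rule",
    "influence_graph",
    "network_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean model with per-node transition rates.

    Parameters
    ----------
    nodes:
        Ordered node names; the canonical index order for states.
    rules:
        Logical rule per node.  Input nodes carry the self rule
        ``Var(name)``, which never produces a transition.
    k_up, k_down:
        Strictly positive activation / inhibition rates per node
        (model-time unit⁻¹); default 1.0.
    inputs:
        Unregulated condition nodes.
    outputs:
        Phenotype read-out nodes; disjoint from inputs.
    """

    nodes: tuple[str, ...]
    rules: dict[str, Expr]
    k_up: dict[str, float] = field(default_factory=dict)
    k_down: dict[str, float] = field(default_factory=dict)
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        ku = {n: float(self.k_up.get(n, 1.0)) for n in self.nodes}
        kd = {n: float(self.k_down.get(n, 1.0)) for n in self.nodes}
        object.__setattr__(self, "k_up", ku)
        object.__setattr__(self, "k_down", kd)
        self.validate()

    def validate(self) -> None:
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise ValueError("duplicate node names")
        for name in self.nodes:
            if name not in self.rules:
                raise ValueError(f"node {name!r} has no rule")
            for lit in ex.variables(self.rules[name]):
                if lit not in declared:
                    raise ValueError(
                        f"rule of {name!r} references undeclared node {lit!r}"
                    )
        for name in self.inputs:
            if name not in declared:
                raise ValueError(f"input {name!r} is not a declared node")
            rule = self.rules[name]
            ok = isinstance(rule, Const) or rule == Var(name)
            if not ok:
                raise ValueError(
                    f"input node {name!r} must carry a constant or self rule"
                )
        overlap = set(self.inputs) & set(self.outputs)
        if overlap:
            raise ValueError(f"outputs overlap inputs: {sorted(overlap)}")
        for name in self.outputs:
            if name not in declared:
                raise ValueError(f"output {name!r} is not a declared node")
        for name in self.nodes:
            if self.k_up[name] <= 0 or self.k_down[name] <= 0:
                raise ValueError(f"rates of {name!r} must be strictly positive")

    # -- functional updates -------------------------------------------------

    def with_rule(self, node: str, rule: Expr) -> "BooleanNetwork":
        if node not in self.rules:
            raise KeyError(node)
        rules = dict(self.rules)
        rules[node] = rule
        inputs = self.inputs
        if node in inputs and not (isinstance(rule, Const) or rule == Var(node)):
            inputs = tuple(n for n in inputs if n != node)
        return replace(self, rules=rules, inputs=inputs)

    def with_outputs(self, outputs: tuple[str, ...]) -> "BooleanNetwork":
        return replace(self, outputs=tuple(outputs))

    def with_rates(self, k_up: dict[str, float], k_down: dict[str, float]) -> "BooleanNetwork":
        ku = dict(self.k_up)
        ku.update(k_up)
        kd = dict(self.k_down)
        kd.update(k_down)
        return replace(self, k_up=ku, k_down=kd)


def evaluate_rule(expr: Expr, state) -> int:
    """Evaluate one rule on a complete binary state (mapping name -> 0/1)."""
    return ex.evaluate(expr, state)


# ---------------------------------------------------------------------------
# BoolNet "targets, factors" dialect
# ---------------------------------------------------------------------------


def parse_boolnet(text: str) -> BooleanNetwork:
    """Parse a BoolNet-style two-column rule table.

    One ``target, factors`` line per node; an optional header line.  Nodes
    appearing only as factors are auto-declared as inputs (self rule).  A
    node whose rule is exactly itself is likewise classified as an input.
    """
    targets: list[str] = []
    rules: dict[str, Expr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
            continue
        if "," not in line:
            raise RuleParseError(f"expected 'target, factors' but got {line!r}", lineno)
        target, rule_text = line.split(",", 1)
        target = target.strip()
        if not target or target[0] not in ex._NAME_START or any(
            c not in ex._NAME_BODY for c in target
        ):
            raise RuleParseError(f"invalid target name {target!r}", lineno)
        if target in rules:
            raise RuleParseError(f"duplicate target {target!r}", lineno)
        rules[target] = ex.parse_expression(rule_text.strip(), line=lineno)
        targets.append(target)

    nodes = list(targets)
    inputs = [t for t in targets if rules[t] == Var(t)]
    for target in targets:
        for lit in ex.variables(rules[target]):
            if lit not in rules:
                rules[lit] = Var(lit)
                nodes.append(lit)
                inputs.append(lit)
    return BooleanNetwork(nodes=tuple(nodes), rules=rules, inputs=tuple(inputs))


def serialise_boolnet(network: BooleanNetwork) -> str:
    """Serialise to the BoolNet dialect (rates are not representable here)."""
    lines = ["targets, factors"]
    for name in network.nodes:
        lines.append(f"{name}, {ex.to_string(network.rules[name], 'boolnet')}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# MaBoSS .bnd / .cfg subset
# ---------------------------------------------------------------------------

_NODE_BLOCK = re.compile(r"node\s+([A-Za-z_][\w/-]*)\s*\{([^}]*)\}", re.DOTALL)
_COND_RATE = re.compile(
    r"^@logic\s*\?\s*([0-9.eE+-]+)\s*:\s*([0-9.eE+-]+)$"
)


def _parse_rate(value: str, which: str, node: str) -> float:
    value = value.strip()
    m = _COND_RATE.match(value)
    if m:
        then_v, else_v = float(m.group(1)), float(m.group(2))
        if which == "rate_up":
            if else_v != 0.0:
                raise ValueError(
                    f"unsupported rate_up conditional for node {node!r}: "
                    "non-zero rate when logic is false"
                )
            return then_v
        if then_v != 0.0:
            raise ValueError(
                f"unsupported rate_down conditional for node {node!r}: "
                "non-zero rate when logic is true"
            )
        return else_v
    try:
        return float(value)
    except ValueError:
        raise ValueError(
            f"unsupported {which} expression for node {node!r}: {value!r} "
            "(numeric constants or '@logic ? a : b' only)"
        ) from None


def parse_maboss(bnd_text: str, cfg_text: str) -> tuple[BooleanNetwork, SimulationConfig]:
    """Parse a MaBoSS ``.bnd``/``.cfg`` pair (documented subset).

    The ``.bnd`` file declares node blocks with a ``logic`` expression and
    optional numeric (or ``@logic ? a : b`` conditional) ``rate_up`` /
    ``rate_down``.  The ``.cfg`` file carries ``istate`` initial-condition
    probabilities, ``sample_count``, ``max_time``, ``time_tick``, ``seed``
    and ``is_internal`` flags.  Unsupported constructs raise, they are never
    silently ignored.
    """
    stripped = re.sub(r"//[^\n]*", "", bnd_text)
    rules: dict[str, Expr] = {}
    k_up: dict[str, float] = {}
    k_down: dict[str, float] = {}
    nodes: list[str] = []
    covered = 0
    for m in _NODE_BLOCK.finditer(stripped):
        covered += len(m.group(0))
        name, body = m.group(1), m.group(2)
        if name in rules:
            raise ValueError(f"duplicate node block {name!r}")
        nodes.append(name)
        for stmt in filter(None, (s.strip() for s in body.split(";"))):
            if "=" not in stmt:
                raise ValueError(f"unsupported statement in node {name!r}: {stmt!r}")
            key, value = (s.strip() for s in stmt.split("=", 1))
            if key == "logic":
                rules[name] = ex.parse_expression(value)
            elif key in ("rate_up", "rate_down"):
                rate = _parse_rate(value, key, name)
                (k_up if key == "rate_up" else k_down)[name] = rate
            else:
                raise ValueError(f"unsupported attribute {key!r} in node {name!r}")
        if name not in rules:
            raise ValueError(f"node {name!r} has no logic attribute")
    leftover = re.sub(_NODE_BLOCK, "", stripped).strip()
    if leftover:
        raise ValueError(f"unsupported .bnd construct: {leftover.splitlines()[0]!r}")

    inputs = [n for n in nodes if rules[n] == Var(n)]
    for name in list(nodes):
        for lit in ex.variables(rules[name]):
            if lit not in rules:
                rules[lit] = Var(lit)
                nodes.append(lit)
                inputs.append(lit)

    # -- .cfg ---------------------------------------------------------------
    initial: dict[str, float] = {}
    joint: list[tuple[tuple[str, ...], dict[tuple[int, ...], float]]] = []
    internal_flags: dict[str, bool] = {}
    params: dict[str, float] = {}
    cfg_clean = re.sub(r"//[^\n]*", "", cfg_text)
    for lineno, raw in enumerate(cfg_clean.splitlines(), start=1):
        line = raw.strip().rstrip(";").strip()
        if not line:
            continue
        m = re.fullmatch(r"\[([\w/,\s-]+)\]\.istate\s*=\s*(.+)", line)
        if m:
            names = tuple(s.strip() for s in m.group(1).split(","))
            for n in names:
                if n not in rules:
                    raise ValueError(f"line {lineno}: istate references unknown node {n!r}")
            dist: dict[tuple[int, ...], float] = {}
            for part in m.group(2).split(","):
                pm = re.fullmatch(r"\s*([0-9.eE+-]+)\s*\[([\s01,]+)\]\s*", part)
                if not pm:
                    raise ValueError(f"line {lineno}: malformed istate term {part!r}")
                prob = float(pm.group(1))
                bits = tuple(int(b) for b in pm.group(2).replace(",", " ").split())
                if len(bits) != len(names):
                    raise ValueError(
                        f"line {lineno}: istate assignment arity mismatch for {names}"
                    )
                if bits in dist:
                    raise ValueError(f"line {lineno}: duplicate istate assignment {bits}")
                dist[bits] = prob
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"line {lineno}: istate probabilities for {names} sum to {total}, not 1"
                )
            if len(names) == 1:
                initial[names[0]] = dist.get((1,), 0.0)
            else:
                joint.append((names, dist))
            continue
        m = re.fullmatch(r"([A-Za-z_][\w/-]*)\.istate\s*=\s*([01])", line)
        if m:
            if m.group(1) not in rules:
                raise ValueError(f"line {lineno}: istate references unknown node {m.group(1)!r}")
            initial[m.group(1)] = float(m.group(2))
            continue
        m = re.fullmatch(r"([A-Za-z_][\w/-]*)\.is_internal\s*=\s*(TRUE|FALSE|1|0)", line)
        if m:
            if m.group(1) not in rules:
                raise ValueError(f"line {lineno}: is_internal flag on unknown node {m.group(1)!r}")
            internal_flags[m.group(1)] = m.group(2) in ("TRUE", "1")
            continue
        m = re.fullmatch(r"(sample_count|max_time|time_tick|seed)\s*=\s*([0-9.eE+-]+)", line)
        if m:
            params[m.group(1)] = float(m.group(2))
            continue
        raise ValueError(f"line {lineno}: unsupported .cfg construct {line!r}")

    outputs: tuple[str, ...] = ()
    if internal_flags:
        outputs = tuple(
            n for n in nodes
            if not internal_flags.get(n, False) and n not in inputs
        )

    network = BooleanNetwork(
        nodes=tuple(nodes), rules=rules, k_up=k_up, k_down=k_down,
        inputs=tuple(inputs), outputs=outputs,
    )
    config = SimulationConfig(
        n_trajectories=int(params.get("sample_count", 5000)),
        max_time=params.get("max_time", 20.0),
        time_tick=params.get("time_tick", 1.0),
        seed=int(params.get("seed", 0)),
        initial=initial,
        joint=joint,
        tracked=outputs or None,
    )
    return network, config


def serialise_maboss(
    network: BooleanNetwork, config: SimulationConfig | None = None
) -> tuple[str, str]:
    """Serialise to the MaBoSS dialect subset; returns (bnd_text, cfg_text)."""
    bnd_lines = []
    for name in network.nodes:
        bnd_lines.append(f"node {name} {{")
        bnd_lines.append(f"  logic = {ex.to_string(network.rules[name], 'maboss')};")
        bnd_lines.append(f"  rate_up = {network.k_up[name]!r};")
        bnd_lines.append(f"  rate_down = {network.k_down[name]!r};")
        bnd_lines.append("}")
    cfg_lines = []
    if config is not None:
        cfg_lines += [
            f"sample_count = {config.n_trajectories};",
            f"max_time = {config.max_time!r};",
            f"time_tick = {config.time_tick!r};",
            f"seed = {config.seed};",
        ]
        for name in network.nodes:
            p = config.initial.get(name, None)
            if p is not None:
                cfg_lines.append(f"[{name}].istate = {p!r} [1], {1.0 - p!r} [0];")
        for names, dist in config.joint:
            terms = ", ".join(
                f"{prob!r} [{', '.join(str(b) for b in bits)}]"
                for bits, prob in dist.items()
            )
            cfg_lines.append(f"[{', '.join(names)}].istate = {terms};")
        tracked = set(config.tracked or network.outputs)
        if tracked:
            for name in network.nodes:
                if name not in tracked and name not in network.inputs:
                    cfg_lines.append(f"{name}.is_internal = TRUE;")
    return "\n".join(bnd_lines) + "\n", "\n".join(cfg_lines) + "\n"


# ---------------------------------------------------------------------------
# Influence graph
# ---------------------------------------------------------------------------


def influence_graph(network: BooleanNetwork) -> nx.DiGraph:
    """Signed influence graph derived from the rules' semantics.

    An arc (r, t) exists iff r occurs in t's rule *and* flipping r changes
    the rule's value in at least one regulator context; its ``sign``
    attribute is 'activator', 'inhibitor' or 'dual'.  One arc per
    (regulator, target) pair.  Literals with no semantic effect produce no
    arc (a warning is logged).  Input self rules are bookkeeping for "held
    constant" and contribute no arc.
    """
    graph = nx.DiGraph()
    graph.add_nodes_from(network.nodes)
    for target in network.nodes:
        rule = network.rules[target]
        if target in network.inputs and rule == Var(target):
            continue
        signs = ex.regulator_signs(rule)
        for lit in ex.variables(rule):
            if lit not in signs:
                logger.warning(
                    "literal %r in rule of %r has no semantic effect; no arc",
                    lit, target,
                )
        for regulator, sign in signs.items():
            graph.add_edge(regulator, target, sign=sign)
    return graph


def network_summary(network: BooleanNetwork) -> dict[str, int]:
    """Counts table: nodes, arcs, inputs, outputs."""
    graph = influence_graph(network)
    return {
        "nodes": len(network.nodes),
        "arcs": graph.number_of_edges(),
        "inputs": len(network.inputs),
        "outputs": len(network.outputs),
    }
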