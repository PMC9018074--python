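"""Toy Boolean models with exact oracles, and synthetic omics cohorts.

Three toy kinds cover the dynamical regimes the simulator must get right:

``telegraph``
    One node flipping up at rate ``u`` and down at rate ``d``; its ON
    probability has the closed form ``p_inf + (p0 - p_inf) e^(-(u+d) t)``.
``cascade``
    A linear activation chain driven by one input; reaches an all-ON fixed
    point when the input is ON.
``mini_tumour``
    A miniature tumour-signalling motif: a growth-factor input drives two
    redundant kinase branches (ERK-like and MYC-like) that activate a
    Proliferation output, while a death-signal input activates a caspase
    that triggers Apoptosis and vetoes Proliferation.  The redundant
    branches make the pair of branch inhibitors synergistic on
    Proliferation (Bliss CI < 1), mirroring combined pathway inhibition in
    signalling models of cancer.

Synthetic cohorts emulate tumour omics with two latent groups: group B
carries a gain-of-function driver of a Proliferation activator at high
frequency and a standardised expression shift ``delta`` on driver-linked
genes.  Expression is simple per-gene Gaussian noise — enough to test
signal recovery, with no claim to RNA-seq realism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import oracles
from .expressions import parse_expression
from .model import BooleanNetwork, parse_boolnet, serialise_boolnet, serialise_maboss
from .personalise import NodeGeneMap
from .simulate import SimulationConfig

__all__ = [
    "ToyOracle",
    "SyntheticCohortSpec",
    "CohortData",
    "make_toy_model",
    "make_synthetic_signalling_model",
    "generate_cohort",
    "write_fixture",
    "mini_tumour_node_map",
]


@dataclass
class ToyOracle:
    """Machine-readable exact reference for a toy model's dynamics."""

    kind: str
    network: BooleanNetwork
    params: dict = field(default_factory=dict)

    def expected_marginals(self, config: SimulationConfig) -> pd.DataFrame:
        """Exact window-averaged ON probabilities for the tracked nodes."""
        if self.kind == "telegraph":
            u, d = self.params["u"], self.params["d"]
            tick = config.time_tick
            n_windows = int(np.ceil(config.max_time / tick - 1e-12))
            starts = np.arange(n_windows) * tick
            p0 = config.initial.get("A", 0.5)
            values = oracles.telegraph_window_marginals(u, d, p0, starts, tick)
            return pd.DataFrame({"A": values}, index=starts)
        marginals, _ = oracles.master_equation_windows(self.network, config)
        return marginals

    def expected_joint(self, config: SimulationConfig) -> pd.DataFrame:
        _, joint = oracles.master_equation_windows(self.network, config)
        return joint


def make_toy_model(kind: str, **params) -> tuple[BooleanNetwork, ToyOracle]:
    """Build a toy network plus its exact oracle.

    ``telegraph(u, d)``; ``cascade(length)``; ``mini_tumour(redundant)``.
    """
    if kind == "telegraph":
        u = float(params.pop("u", 2.0))
        d = float(params.pop("d", 1.0))
        _reject_extra(params, kind)
        network = BooleanNetwork(
            nodes=("A",),
            rules={"A": parse_expression("!A")},
            k_up={"A": u},
            k_down={"A": d},
            outputs=("A",),
        )
        return network, ToyOracle(kind=kind, network=network, params={"u": u, "d": d})

    if kind == "cascade":
        length = int(params.pop("length", 3))
        _reject_extra(params, kind)
        if length < 1:
            raise ValueError("cascade length must be >= 1")
        lines = ["targets, factors", "C1, I"]
        for i in range(2, length + 1):
            lines.append(f"C{i}, C{i - 1}")
        network = parse_boolnet("\n".join(lines)).with_outputs((f"C{length}",))
        return network, ToyOracle(kind=kind, network=network, params={"length": length})

    if kind == "mini_tumour":
        _reject_extra(params, kind)
        text = "\n".join([
            "targets, factors",
            "ERK, GrowthFactor",
            "MYC, GrowthFactor",
            "Casp8, DeathSignal",
            "Proliferation, (ERK | MYC) & !Casp8",
            "Apoptosis, Casp8",
        ])
        network = parse_boolnet(text).with_outputs(("Proliferation", "Apoptosis"))
        return network, ToyOracle(kind=kind, network=network)

    raise ValueError(f"unknown toy model kind {kind!r}")


def _reject_extra(params: dict, kind: str) -> None:
    if params:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(params)}")


def make_synthetic_signalling_model(
    n_nodes: int = 133,
    n_inputs: int = 9,
    n_outputs: int = 6,
    seed: int = 0,
    max_regulators: int = 3,
) -> BooleanNetwork:
    """A randomly wired synthetic signalling network at a realistic scale.

    Synthetic stand-in for a large curated signalling model: ``n_inputs``
    unregulated condition nodes, a regulated core, and ``n_outputs``
    phenotype read-outs regulated by core nodes.  Wiring is random
    (each regulated node gets 1..max_regulators upstream regulators with
    random signs and connectives); the object is scale, not biology.
    """
    if n_inputs + n_outputs >= n_nodes:
        raise ValueError("need at least one core node")
    rng = np.random.default_rng(seed)
    inputs = [f"I{i}" for i in range(1, n_inputs + 1)]
    n_core = n_nodes - n_inputs - n_outputs
    core = [f"N{i}" for i in range(1, n_core + 1)]
    outputs = [f"O{i}" for i in range(1, n_outputs + 1)]

    rules = {name: parse_expression(name) for name in inputs}

    def random_rule(pool: list[str]) -> str:
        k = int(rng.integers(1, max_regulators + 1))
        regs = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        terms = [f"!{r}" if rng.random() < 0.3 else r for r in regs]
        connective = " & " if rng.random() < 0.5 else " | "
        return connective.join(terms)

    for i, name in enumerate(core):
        pool = inputs + core[:i] if i else inputs
        rules[name] = parse_expression(random_rule(pool))
    for name in outputs:
        rules[name] = parse_expression(random_rule(core))

    return BooleanNetwork(
        nodes=tuple(inputs + core + outputs),
        rules=rules,
        inputs=tuple(inputs),
        outputs=tuple(outputs),
    )


# ---------------------------------------------------------------------------
# Synthetic omics cohorts
# ---------------------------------------------------------------------------


def mini_tumour_node_map() -> NodeGeneMap:
    """Gene panel for the mini_tumour toy (ERK as a two-gene family)."""
    return NodeGeneMap(
        mapping={
            "GrowthFactor": ["EGF"],
            "ERK": ["MAPK1", "MAPK3"],
            "MYC": ["MYC"],
            "Casp8": ["CASP8"],
            "DeathSignal": ["TNF"],
        },
        aggregator={"ERK": "mean"},
    )


@dataclass
class SyntheticCohortSpec:
    """Generator conditions for a two-group synthetic omics cohort.

    Defaults describe a 488-sample cohort split evenly into two latent
    groups; group B carries a gain-of-function driver mutation on
    ``driver_gene`` at probability 0.8 (versus a 0.05 background in group
    A) and a ``delta`` = 2 standardised expression shift on the
    driver-linked genes.  ``background_cna_rate`` optionally sprinkles
    group-independent copy-number events on non-driver genes (off by
    default: the group structure is defined by mutation frequency and
    expression shift alone).
    """

    n_samples: int = 488
    mixing: float = 0.5
    driver_gene: str = "MYC"
    driver_effect: str = "gain_of_function"
    mutation_prob: dict[str, float] = field(
        default_factory=lambda: {"A": 0.05, "B": 0.8}
    )
    shifted_genes: tuple[str, ...] = ("EGF", "MYC")
    delta: float = 2.0
    sigma: float = 1.0
    background_cna_rate: float = 0.0
    gene_panel: tuple[str, ...] = ("EGF", "MAPK1", "MAPK3", "MYC", "CASP8", "TNF")
    seed: int = 0

    def __post_init__(self):
        if not self.gene_panel:
            raise ValueError("empty gene panel")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing fraction must be in [0, 1]")
        for group, p in self.mutation_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mutation probability for group {group!r} not in [0, 1]")
        if self.delta < 0 or self.sigma < 0:
            raise ValueError("delta and sigma must be >= 0")


@dataclass
class CohortData:
    """Synthetic cohort tables in the personalisation input dialects."""

    mutations: pd.DataFrame  # sample, gene, effect
    cna: pd.DataFrame  # sample, gene, state
    expression: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> group

    def write(self, directory: str) -> list[str]:
        os.makedirs(directory, exist_ok=True)
        paths = []
        for name, df in (("mutations", self.mutations), ("cna", self.cna)):
            path = os.path.join(directory, f"{name}.tsv")
            df.to_csv(path, sep="\t", index=False)
            paths.append(path)
        path = os.path.join(directory, "expression.tsv")
        self.expression.rename_axis("gene").to_csv(path, sep="\t")
        paths.append(path)
        path = os.path.join(directory, "labels.tsv")
        self.labels.rename_axis("sample").rename("group").to_csv(path, sep="\t")
        paths.append(path)
        return paths


def generate_cohort(spec: SyntheticCohortSpec) -> CohortData:
    """Draw a reproducible two-group cohort under the spec's conditions."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    n_b = int(round(n * spec.mixing))
    groups = np.array(["A"] * (n - n_b) + ["B"] * n_b)
    rng.shuffle(groups)
    labels = pd.Series(groups, index=samples)

    mut_rows = []
    for sample, group in labels.items():
        if rng.random() < spec.mutation_prob.get(group, 0.0):
            mut_rows.append(
                {"sample": sample, "gene": spec.driver_gene, "effect": spec.driver_effect}
            )
    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "effect"])

    cna_rows = []
    background = [g for g in spec.gene_panel if g != spec.driver_gene]
    for sample in samples:
        for gene in background:
            if rng.random() < spec.background_cna_rate:
                state = "amplified" if rng.random() < 0.5 else "deleted"
                cna_rows.append({"sample": sample, "gene": gene, "state": state})
    cna = pd.DataFrame(cna_rows, columns=["sample", "gene", "state"])

    values = rng.normal(0.0, spec.sigma, size=(len(spec.gene_panel), n))
    expression = pd.DataFrame(values, index=list(spec.gene_panel), columns=samples)
    shift = spec.delta * spec.sigma
    b_mask = (labels == "B").to_numpy()
    for gene in spec.shifted_genes:
        if gene in expression.index:
            expression.loc[gene, b_mask] += shift

    return CohortData(mutations=mutations, cna=cna, expression=expression, labels=labels)


# ---------------------------------------------------------------------------
# Fixtures on disk
# ---------------------------------------------------------------------------


def write_fixture(
    network: BooleanNetwork,
    fmt: str,
    directory: str,
    name: str = "model",
    config: SimulationConfig | None = None,
) -> list[str]:
    """Write a model as a re-parseable fixture; formats: boolnet, maboss."""
    os.makedirs(directory, exist_ok=True)
    if fmt == "boolnet":
        path = os.path.join(directory, f"{name}.bnet")
        with open(path, "w") as fh:
            fh.write(serialise_boolnet(network))
        return [path]
    if fmt == "maboss":
        if config is None:
            config = SimulationConfig(tracked=network.outputs or None)
        bnd, cfg = serialise_maboss(network, config)
        bnd_path = os.path.join(directory, f"{name}.bnd")
        cfg_path = os.path.join(directory, f"{name}.cfg")
        with open(bnd_path, "w") as fh:
            fh.write(bnd)
        with open(cfg_path, "w") as fh:
            fh.write(cfg)
        return [bnd_path, cfg_path]
    raise ValueError(f"unsupported fixture format {fmt!r} (boolnet or maboss)")
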