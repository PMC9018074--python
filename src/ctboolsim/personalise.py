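"""Tailoring a generic Boolean model to per-sample omics profiles.

Discrete alterations (mutations with a curated effect class, copy-number
states) *force* the mapped node: gain-of-function and amplification force 1,
loss-of-function and deletion force 0, with mutations taking precedence over
copy number on conflict.  Continuous values (cohort-normalised expression in
[0, 1]) *modulate* the mapped node: its initial ON probability becomes the
value ``x`` and its transition rates become ``k_up = (x/(1-x))**(F/2)`` and
``k_down = ((1-x)/x)**(F/2)``, an odds-power form that is neutral at
``x = 0.5``, keeps ``k_up * k_down = 1`` and is steered by the
amplification exponent ``F``.  The formula is isolated in
:func:`rates_from_value` so an alternative mapping can be swapped in.

Because a node may represent a protein complex or family, a node-to-genes
map with a per-node aggregator (mean/min/max) translates gene-level values
to node-level ones.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expressions import Const
from .simulate import SimulationConfig

__all__ = [
    "OmicsProfile",
    "NodeGeneMap",
    "PersonalisationRecipe",
    "PersonalisedModel",
    "normalize_continuous",
    "aggregate_node_values",
    "rates_from_value",
    "apply_discrete",
    "apply_continuous",
    "personalise_sample",
    "personalise_cohort",
    "load_mutations_tsv",
    "load_cna_tsv",
    "load_expression_tsv",
    "load_node_map_tsv",
    "cohort_profiles",
]

logger = logging.getLogger(__name__)

MUTATION_EFFECTS = ("gain_of_function", "loss_of_function", "unknown")
CNA_STATES = ("amplified", "deleted", "neutral")


@dataclass
class OmicsProfile:
    """One sample's omics layers keyed by gene identifier."""

    sample: str
    mutations: dict[str, str] = field(default_factory=dict)
    cna: dict[str, str] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for gene, effect in self.mutations.items():
            if effect not in MUTATION_EFFECTS:
                raise ValueError(f"unknown mutation effect {effect!r} for {gene!r}")
        for gene, state in self.cna.items():
            if state not in CNA_STATES:
                raise ValueError(f"unknown CNA state {state!r} for {gene!r}")


@dataclass
class NodeGeneMap:
    """Node -> gene list, with an aggregator per node (default mean)."""

    mapping: dict[str, list[str]]
    aggregator: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for node, agg in self.aggregator.items():
            if agg not in ("mean", "min", "max"):
                raise ValueError(f"unknown aggregator {agg!r} for node {node!r}")

    def validate_against(self, network) -> None:
        unknown = set(self.mapping) - set(network.nodes)
        if unknown:
            raise ValueError(f"mapped nodes not in the network: {sorted(unknown)}")

    def nodes_for_gene(self, gene: str) -> list[str]:
        return [node for node, genes in self.mapping.items() if gene in genes]


@dataclass
class PersonalisationRecipe:
    """Which omics layers act how.

    ``discrete_layers`` force nodes to 0/1, ``continuous_layers`` modulate
    the targets in ``continuous_targets`` (initial conditions and/or
    transition rates).  ``amplification`` is the exponent F of the
    rate mapping; ``clamp`` bounds continuous values away from 0 and 1.
    The default mirrors a tumour-cohort setting: mutations and CNA discrete,
    expression continuous for both rates and initial conditions.
    """

    discrete_layers: tuple[str, ...] = ("mutations", "cna")
    continuous_layers: tuple[str, ...] = ("expression",)
    continuous_targets: tuple[str, ...] = ("initial_conditions", "transition_rates")
    amplification: float = 1.0
    clamp: float = 0.01

    def __post_init__(self):
        if not self.discrete_layers and not self.continuous_layers:
            raise ValueError("recipe enables no omics layer")
        if self.amplification < 0:
            raise ValueError("amplification exponent must be >= 0")
        if not 0.0 < self.clamp < 0.5:
            raise ValueError("clamp must be in (0, 0.5)")


@dataclass
class PersonalisedModel:
    """A base network plus one sample's forcings and modulations."""

    base: object
    sample: str
    forced: dict[str, int] = field(default_factory=dict)
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def network(self):
        """Materialise the personalised network (forcings and rates applied)."""
        net = self.base
        for node, value in self.forced.items():
            net = net.with_rule(node, Const(value))
        if self.rates:
            net = net.with_rates(
                {n: r[0] for n, r in self.rates.items()},
                {n: r[1] for n, r in self.rates.items()},
            )
        return net

    def config(self, base_config: SimulationConfig, pin_explicit: bool = True) -> SimulationConfig:
        """Simulation config with personalised initial conditions.

        Initial probabilities listed explicitly in ``base_config`` are
        treated as experimental conditions (growth media, stimuli) and by
        default are *not* overridden by continuous personalisation
        (``pin_explicit``).  Forced nodes always start at their forced
        value, so their activation probability equals the forcing for the
        entire run.
        """
        initial = dict(base_config.initial)
        for node, p in self.initial.items():
            if pin_explicit and node in base_config.initial:
                continue
            initial[node] = p
        initial.update({n: float(v) for n, v in self.forced.items()})
        return base_config.replace(initial=initial)


# ---------------------------------------------------------------------------
# Continuous layer
# ---------------------------------------------------------------------------


def normalize_continuous(matrix: pd.DataFrame, method: str = "sigmoid_z") -> pd.DataFrame:
    """Cohort-normalise a genes x samples matrix into [0, 1].

    ``minmax``: per-gene (x - min) / (max - min).  ``sigmoid_z``: logistic
    of the per-gene robust z-score (median / MAD), which maps the cohort
    median to 0.5 and is insensitive to outliers.  All-constant genes map to
    0.5 with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("cohort normalisation needs at least 2 samples")
    if method == "minmax":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        constant = span[:, 0] == 0.0
        span[constant] = 1.0
        out = (values - lo) / span
        out[constant] = 0.5
    elif method == "sigmoid_z":
        med = np.median(values, axis=1, keepdims=True)
        mad = np.median(np.abs(values - med), axis=1, keepdims=True) * 1.4826
        constant = mad[:, 0] == 0.0
        mad[constant] = 1.0
        out = 1.0 / (1.0 + np.exp(-(values - med) / mad))
        out[constant] = 0.5
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    if constant.any():
        genes = matrix.index[np.flatnonzero(constant)].tolist()
        logger.warning("all-constant genes mapped to 0.5: %s", genes)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def aggregate_node_values(
    values: Mapping[str, float], node_map: NodeGeneMap
) -> dict[str, float]:
    """Collapse gene-level values in [0, 1] to node-level ones.

    Missing genes are dropped with a warning; a node with no available gene
    is absent from the output (left untouched downstream).
    """
    out: dict[str, float] = {}
    for node, genes in node_map.mapping.items():
        available = [values[g] for g in genes if g in values]
        missing = [g for g in genes if g not in values]
        if missing:
            logger.warning("node %r: genes missing from data: %s", node, missing)
        if not available:
            logger.warning("node %r has no available genes; left untouched", node)
            continue
        agg = node_map.aggregator.get(node, "mean")
        if agg == "mean":
            out[node] = float(np.mean(available))
        elif agg == "min":
            out[node] = float(np.min(available))
        else:
            out[node] = float(np.max(available))
    return out


def rates_from_value(x: float, amplification: float = 1.0) -> tuple[float, float]:
    """Odds-power mapping of a normalised value to (k_up, k_down).

    ``k_up = (x/(1-x))**(F/2)``, ``k_down = ((1-x)/x)**(F/2)``: neutral at
    0.5, symmetric, and ``k_up * k_down = 1`` so only the balance of the
    two transitions is personalised, not the overall timescale.
    """
    odds = x / (1.0 - x)
    k_up = odds ** (amplification / 2.0)
    return k_up, 1.0 / k_up


# ---------------------------------------------------------------------------
# Discrete layer
# ---------------------------------------------------------------------------

_DISCRETE_VALUE = {
    "gain_of_function": 1,
    "loss_of_function": 0,
    "amplified": 1,
    "deleted": 0,
}


def _layer_forcings(
    calls: Mapping[str, str], node_map: NodeGeneMap, layer: str
) -> tuple[dict[str, int], dict[str, list[str]], list[dict]]:
    forced: dict[str, int] = {}
    genes_per_node: dict[str, list[str]] = {}
    provenance = []
    for gene, call in calls.items():
        if call in ("unknown", "neutral"):
            if call == "unknown":
                logger.warning("%s: unknown-effect mutation on %r ignored", layer, gene)
            continue
        value = _DISCRETE_VALUE[call]
        for node in node_map.nodes_for_gene(gene):
            if node in forced and forced[node] != value:
                genes = genes_per_node[node] + [gene]
                raise ValueError(
                    f"contradictory {layer} calls for node {node!r}: genes {genes}"
                )
            forced[node] = value
            genes_per_node.setdefault(node, []).append(gene)
            provenance.append(
                {"layer": layer, "gene": gene, "raw": call, "node": node,
                 "decision": f"force {value}"}
            )
    return forced, genes_per_node, provenance


def apply_discrete(
    network,
    profile: OmicsProfile,
    node_map: NodeGeneMap,
    recipe: PersonalisationRecipe,
) -> tuple[dict[str, int], list[dict]]:
    """Node forcings from the discrete layers; mutations beat CNA on conflict."""
    node_map.validate_against(network)
    forced: dict[str, int] = {}
    provenance: list[dict] = []
    if "cna" in recipe.discrete_layers:
        cna_forced, _, prov = _layer_forcings(profile.cna, node_map, "cna")
        forced.update(cna_forced)
        provenance += prov
    if "mutations" in recipe.discrete_layers:
        mut_forced, _, prov = _layer_forcings(profile.mutations, node_map, "mutations")
        for node, value in mut_forced.items():
            if node in forced and forced[node] != value:
                provenance.append(
                    {"layer": "mutations", "gene": None, "raw": None, "node": node,
                     "decision": f"mutation overrides cna: force {value}"}
                )
            forced[node] = value
        provenance += prov
    return forced, provenance


def apply_continuous(
    network,
    node_values: Mapping[str, float],
    recipe: PersonalisationRecipe,
    forced: Mapping[str, int] | None = None,
) -> tuple[dict[str, tuple[float, float]], dict[str, float], list[dict]]:
    """Rate and initial-condition modulation from node-level values.

    Values are clamped to ``[clamp, 1 - clamp]``; nodes already forced by
    the discrete layers are skipped (forcing dominates modulation).
    """
    forced = forced or {}
    rates: dict[str, tuple[float, float]] = {}
    initial: dict[str, float] = {}
    provenance: list[dict] = []
    eps = recipe.clamp
    for node, raw in node_values.items():
        if node in forced:
            provenance.append(
                {"layer": "expression", "gene": None, "raw": raw, "node": node,
                 "decision": "skipped: node is forced"}
            )
            continue
        x = min(max(float(raw), eps), 1.0 - eps)
        if "initial_conditions" in recipe.continuous_targets:
            initial[node] = x
        if "transition_rates" in recipe.continuous_targets:
            rates[node] = rates_from_value(x, recipe.amplification)
        provenance.append(
            {"layer": "expression", "gene": None, "raw": raw, "node": node,
             "decision": f"modulate x={x:g}"}
        )
    return rates, initial, provenance


# ---------------------------------------------------------------------------
# Whole-sample and cohort drivers
# ---------------------------------------------------------------------------


def personalise_sample(
    network,
    profile: OmicsProfile,
    node_map: NodeGeneMap,
    recipe: PersonalisationRecipe,
    node_values: Mapping[str, float] | None = None,
) -> PersonalisedModel:
    """Build one sample's personalised model.

    ``node_values`` are the sample's cohort-normalised, node-aggregated
    continuous values; when None they are derived from
    ``profile.expression`` (assumed already normalised to [0, 1]).
    """
    forced, provenance = ({}, [])
    if recipe.discrete_layers:
        forced, provenance = apply_discrete(network, profile, node_map, recipe)
    rates: dict[str, tuple[float, float]] = {}
    initial: dict[str, float] = {}
    if recipe.continuous_layers and "expression" in recipe.continuous_layers:
        if node_values is None:
            node_values = aggregate_node_values(profile.expression, node_map)
        rates, initial, prov = apply_continuous(network, node_values, recipe, forced)
        provenance += prov
    if not forced and not rates and not initial:
        logger.warning(
            "sample %r has no usable data; returning the generic model", profile.sample
        )
    return PersonalisedModel(
        base=network, sample=profile.sample, forced=forced,
        rates=rates, initial=initial, provenance=provenance,
    )


def personalise_cohort(
    network,
    profiles: Sequence[OmicsProfile],
    node_map: NodeGeneMap,
    recipe: PersonalisationRecipe,
    expression: pd.DataFrame | None = None,
    normalisation: str = "sigmoid_z",
) -> list[PersonalisedModel]:
    """One personalised model per sample.

    ``expression`` is the raw genes x samples cohort matrix; it is
    normalised across the cohort and aggregated to nodes here, so every
    sample is scaled against the same reference distribution.
    """
    if not profiles:
        raise ValueError("empty cohort")
    node_map.validate_against(network)
    values_per_sample: dict[str, dict[str, float]] = {}
    if expression is not None and "expression" in recipe.continuous_layers:
        normed = normalize_continuous(expression, normalisation)
        for sample in normed.columns:
            values_per_sample[sample] = aggregate_node_values(
                normed[sample].to_dict(), node_map
            )
    models = []
    for profile in profiles:
        models.append(
            personalise_sample(
                network, profile, node_map, recipe,
                node_values=values_per_sample.get(profile.sample),
            )
        )
    return models


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------


def load_mutations_tsv(path_or_buffer) -> pd.DataFrame:
    """Mutation calls: columns sample, gene, effect."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    _require_columns(df, ("sample", "gene", "effect"), "mutations")
    return df


def load_cna_tsv(path_or_buffer) -> pd.DataFrame:
    """Copy-number states: columns sample, gene, state."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    _require_columns(df, ("sample", "gene", "state"), "cna")
    return df


def load_expression_tsv(path_or_buffer) -> pd.DataFrame:
    """Expression matrix: gene rows x sample columns, first column 'gene'."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError("expression table must have 'gene' as its first column")
    return df.set_index("gene")


def load_node_map_tsv(path_or_buffer) -> NodeGeneMap:
    """Node-gene map: columns node, genes (comma-separated), optional aggregator."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    _require_columns(df, ("node", "genes"), "node map")
    mapping = {
        row.node: [g.strip() for g in str(row.genes).split(",") if g.strip()]
        for row in df.itertuples()
    }
    aggregator = {}
    if "aggregator" in df.columns:
        aggregator = {
            row.node: row.aggregator
            for row in df.itertuples()
            if isinstance(row.aggregator, str)
        }
    return NodeGeneMap(mapping=mapping, aggregator=aggregator)


def cohort_profiles(
    mutations: pd.DataFrame, cna: pd.DataFrame | None, samples: Iterable[str]
) -> list[OmicsProfile]:
    """Assemble per-sample profiles from long-format mutation/CNA tables."""
    mut_by_sample = dict(tuple(mutations.groupby("sample"))) if len(mutations) else {}
    cna_by_sample = (
        dict(tuple(cna.groupby("sample"))) if cna is not None and len(cna) else {}
    )
    profiles = []
    for sample in samples:
        m = mut_by_sample.get(sample)
        c = cna_by_sample.get(sample)
        profiles.append(
            OmicsProfile(
                sample=sample,
                mutations=dict(zip(m["gene"], m["effect"])) if m is not None else {},
                cna=dict(zip(c["gene"], c["state"])) if c is not None else {},
            )
        )
    return profiles


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")
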