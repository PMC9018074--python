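import io

import numpy as np
import pandas as pd
import pytest

from ctboolsim.model import parse_boolnet
from ctboolsim.personalise import (
    NodeGeneMap,
    OmicsProfile,
    PersonalisationRecipe,
    aggregate_node_values,
    apply_continuous,
    apply_discrete,
    cohort_profiles,
    load_node_map_tsv,
    normalize_continuous,
    personalise_cohort,
    personalise_sample,
    rates_from_value,
)
from ctboolsim.simulate import SimulationConfig, simulate_ensemble
from ctboolsim.synthetic import make_toy_model, mini_tumour_node_map


@pytest.fixture()
def net():
    return make_toy_model("mini_tumour")[0]


@pytest.fixture()
def node_map():
    return mini_tumour_node_map()


# -- normalisation ----------------------------------------------------------

def test_minmax_normalisation_spans_unit_interval():
    matrix = pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [6.0]}, index=["G"])
    out = normalize_continuous(matrix, "minmax")
    assert out.loc["G"].tolist() == [0.0, 0.5, 1.0]


def test_constant_gene_maps_to_half():
    matrix = pd.DataFrame({"s1": [3.0], "s2": [3.0]}, index=["G"])
    for method in ("minmax", "sigmoid_z"):
        assert (normalize_continuous(matrix, method).loc["G"] == 0.5).all()


def test_sigmoid_z_is_half_at_the_median():
    matrix = pd.DataFrame(
        {f"s{i}": [float(i)] for i in range(1, 6)}, index=["G"]
    )
    out = normalize_continuous(matrix, "sigmoid_z")
    assert out.loc["G", "s3"] == pytest.approx(0.5)
    assert out.loc["G"].is_monotonic_increasing


def test_single_sample_cohort_rejected():
    with pytest.raises(ValueError, match="at least 2 samples"):
        normalize_continuous(pd.DataFrame({"s1": [1.0]}, index=["G"]))


# -- aggregation ------------------------------------------------------------

def test_aggregators_mean_and_min():
    nm = NodeGeneMap(
        mapping={"AMPK": ["g1", "g2"], "CPLX": ["g3", "g4"]},
        aggregator={"CPLX": "min"},
    )
    values = {"g1": 0.2, "g2": 0.4, "g3": 0.9, "g4": 0.1}
    out = aggregate_node_values(values, nm)
    assert out["AMPK"] == pytest.approx(0.3)
    assert out["CPLX"] == pytest.approx(0.1)


def test_node_with_no_available_genes_is_absent():
    nm = NodeGeneMap(mapping={"X": ["missing"]})
    assert aggregate_node_values({"g1": 0.5}, nm) == {}


# -- discrete forcing -------------------------------------------------------

def test_effect_classes_force_expected_values(net, node_map):
    profile = OmicsProfile(
        sample="s",
        mutations={"CASP8": "loss_of_function"},
        cna={"MYC": "amplified", "EGF": "deleted"},
    )
    forced, _ = apply_discrete(net, profile, node_map, PersonalisationRecipe())
    assert forced == {"Casp8": 0, "MYC": 1, "GrowthFactor": 0}


def test_mutation_takes_precedence_over_cna(net, node_map):
    profile = OmicsProfile(
        sample="s",
        mutations={"MYC": "loss_of_function"},
        cna={"MYC": "amplified"},
    )
    forced, _ = apply_discrete(net, profile, node_map, PersonalisationRecipe())
    assert forced["MYC"] == 0


def test_unknown_effect_is_ignored(net, node_map):
    profile = OmicsProfile(sample="s", mutations={"MYC": "unknown"})
    forced, _ = apply_discrete(net, profile, node_map, PersonalisationRecipe())
    assert forced == {}


def test_contradictory_same_layer_calls_raise(net):
    nm = NodeGeneMap(mapping={"ERK": ["MAPK1", "MAPK3"]})
    profile = OmicsProfile(
        sample="s",
        mutations={"MAPK1": "gain_of_function", "MAPK3": "loss_of_function"},
    )
    with pytest.raises(ValueError, match="MAPK"):
        apply_discrete(net, profile, nm, PersonalisationRecipe())


# -- continuous modulation --------------------------------------------------

def test_neutral_value_leaves_rates_and_initial_at_default(net):
    rates, initial, _ = apply_continuous(net, {"ERK": 0.5}, PersonalisationRecipe())
    assert rates["ERK"] == (1.0, 1.0)
    assert initial["ERK"] == 0.5


def test_odds_power_formula_at_extreme_value(net):
    recipe = PersonalisationRecipe(amplification=1.0, clamp=0.01)
    rates, initial, _ = apply_continuous(net, {"ERK": 0.99}, recipe)
    k_up, k_down = rates["ERK"]
    assert k_up == pytest.approx(np.sqrt(99), rel=1e-12)
    assert k_down == pytest.approx(1 / np.sqrt(99), rel=1e-12)
    assert initial["ERK"] == 0.99


def test_values_outside_clamp_are_clamped(net):
    recipe = PersonalisationRecipe(clamp=0.05)
    rates, initial, _ = apply_continuous(net, {"ERK": 1.0}, recipe)
    assert initial["ERK"] == 0.95
    assert rates["ERK"][0] == pytest.approx((0.95 / 0.05) ** 0.5)


def test_rate_product_is_one_for_any_value_and_exponent(net):
    for x in np.linspace(0.01, 0.99, 9):
        for f in (0.5, 1.0, 2.0):
            k_up, k_down = rates_from_value(float(x), f)
            assert k_up * k_down == pytest.approx(1.0, rel=1e-9)


def test_forced_nodes_skip_continuous_modulation(net):
    rates, initial, prov = apply_continuous(
        net, {"MYC": 0.9}, PersonalisationRecipe(), forced={"MYC": 1}
    )
    assert "MYC" not in rates and "MYC" not in initial
    assert any("skipped" in p["decision"] for p in prov)


# -- whole samples and cohorts ----------------------------------------------

def test_cohort_size_is_preserved_and_deterministic(net, node_map):
    samples = [f"s{i}" for i in range(12)]
    profiles = [
        OmicsProfile(sample=s, mutations={"MYC": "gain_of_function"} if i % 3 == 0 else {})
        for i, s in enumerate(samples)
    ]
    expr = pd.DataFrame(
        np.linspace(0, 1, 6 * 12).reshape(6, 12),
        index=["EGF", "MAPK1", "MAPK3", "MYC", "CASP8", "TNF"],
        columns=samples,
    )
    recipe = PersonalisationRecipe()
    m1 = personalise_cohort(net, profiles, node_map, recipe, expr)
    m2 = personalise_cohort(net, profiles, node_map, recipe, expr)
    assert len(m1) == 12
    for a, b in zip(m1, m2):
        assert a.forced == b.forced and a.rates == b.rates and a.initial == b.initial


def test_empty_cohort_rejected(net, node_map):
    with pytest.raises(ValueError, match="empty cohort"):
        personalise_cohort(net, [], node_map, PersonalisationRecipe())


def test_sample_without_usable_data_keeps_generic_model(net, node_map, caplog):
    pm = personalise_sample(
        net, OmicsProfile(sample="empty"), node_map, PersonalisationRecipe()
    )
    assert pm.forced == {} and pm.rates == {} and pm.initial == {}
    assert pm.network().rules == net.rules


def test_node_map_against_unknown_node_rejected(net):
    nm = NodeGeneMap(mapping={"NotANode": ["g"]})
    with pytest.raises(ValueError, match="NotANode"):
        nm.validate_against(net)


def test_node_map_tsv_round_trip():
    text = "node\tgenes\taggregator\nERK\tMAPK1, MAPK3\tmin\nMYC\tMYC\t\n"
    nm = load_node_map_tsv(io.StringIO(text))
    assert nm.mapping == {"ERK": ["MAPK1", "MAPK3"], "MYC": ["MYC"]}
    assert nm.aggregator == {"ERK": "min"}


def test_cohort_profiles_assembles_layers():
    mutations = pd.DataFrame(
        {"sample": ["s1"], "gene": ["MYC"], "effect": ["gain_of_function"]}
    )
    cna = pd.DataFrame({"sample": ["s2"], "gene": ["EGF"], "state": ["deleted"]})
    profiles = cohort_profiles(mutations, cna, ["s1", "s2"])
    assert profiles[0].mutations == {"MYC": "gain_of_function"}
    assert profiles[1].cna == {"EGF": "deleted"}


# -- dynamical consequences -------------------------------------------------

def test_monotonicity_of_asymptotic_activity_in_continuous_value():
    # one free telegraph-like node personalised through the odds-power map:
    # its stationary ON probability is x itself, so monotone in x
    net = parse_boolnet("A, !A\n").with_outputs(("A",))
    recipe = PersonalisationRecipe()
    scores = []
    for x in np.linspace(0.1, 0.9, 9):
        rates, initial, _ = apply_continuous(net, {"A": float(x)}, recipe)
        pnet = net.with_rates({"A": rates["A"][0]}, {"A": rates["A"][1]})
        config = SimulationConfig(
            n_trajectories=2000, max_time=12.0, time_tick=1.0, seed=9,
            initial={"A": initial["A"]},
        )
        score = simulate_ensemble(pnet, config).phenotype_scores()["A"]
        assert score == pytest.approx(x, abs=0.05)
        scores.append(score)
    assert all(b > a for a, b in zip(scores, scores[1:]))


def test_forcing_dominates_for_every_recipe(net, node_map):
    profile = OmicsProfile(
        sample="s", mutations={"MYC": "gain_of_function"},
        expression={"MYC": 0.1, "EGF": 0.2},
    )
    for targets in (("initial_conditions",), ("transition_rates",),
                    ("initial_conditions", "transition_rates")):
        recipe = PersonalisationRecipe(continuous_targets=targets)
        pm = personalise_sample(net, profile, node_map, recipe)
        config = pm.config(
            SimulationConfig(n_trajectories=300, max_time=6.0, time_tick=1.0, seed=1)
        )
        result = simulate_ensemble(pm.network(), config.replace(tracked=("MYC",)))
        assert result.marginals["MYC"].iloc[-1] == 1.0  # asymptotically exact
        assert np.allclose(result.marginals["MYC"], 1.0, atol=1e-12)
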