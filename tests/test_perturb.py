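import numpy as np
import pytest

from ctboolsim.expressions import Const
from ctboolsim.model import parse_boolnet
from ctboolsim.perturb import (
    ConditionPreset,
    DrugSpec,
    Perturbation,
    apply_drug,
    apply_mutation,
    apply_preset,
    combination_conditions,
    combination_screen,
    condition_presets,
    dose_response,
    enumerate_mutants,
    rule_robustness_scan,
    simulate_drug,
)
from ctboolsim.simulate import SimulationConfig, simulate_ensemble


# -- genetic perturbations --------------------------------------------------

def test_ko_replaces_rule_by_constant(mini_tumour):
    net, _ = mini_tumour
    mutant = apply_mutation(net, Perturbation((("ERK", 0),)))
    assert mutant.rules["ERK"] == Const(0)
    assert mutant.k_up == net.k_up  # rates untouched


def test_empty_perturbation_is_identity(mini_tumour):
    net, _ = mini_tumour
    assert apply_mutation(net, Perturbation(())) is net


def test_conflicting_forcings_rejected():
    with pytest.raises(ValueError, match="conflicting"):
        Perturbation((("A", 0), ("A", 1)))


def test_ko_of_sole_activator_abolishes_output(growth_config):
    # P's only activation route is the cascade through C1
    net = parse_boolnet("C1, I\nP, C1\n").with_outputs(("P",))
    config = SimulationConfig(
        n_trajectories=1000, max_time=10.0, time_tick=1.0, seed=4,
        initial={"I": 1.0, "C1": 0.0, "P": 0.0},
    )
    wt = simulate_ensemble(net, config).phenotype_scores()["P"]
    ko = apply_mutation(net, Perturbation((("C1", 0),)))
    mut = simulate_ensemble(ko, config).phenotype_scores()["P"]
    assert wt > 0.95
    assert mut == 0.0


def test_oe_of_input_equals_setting_it_on(mini_tumour, growth_config):
    net, _ = mini_tumour
    config = growth_config.replace(initial={"GrowthFactor": 1.0, "DeathSignal": 0.0})
    oe = apply_mutation(net, Perturbation((("GrowthFactor", 1),)))
    r_oe = simulate_ensemble(oe, config).phenotype_scores()
    r_on = simulate_ensemble(net, config).phenotype_scores()
    assert r_oe.to_dict() == pytest.approx(r_on.to_dict(), abs=0.03)


# -- enumeration ------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [(1, 2), (2, 8), (3, 18), (10, 200)])
def test_enumeration_count_is_twice_n_squared(n, expected):
    rules = "\n".join(f"N{i}, N{i}" for i in range(n))
    net = parse_boolnet(rules)
    mutants = list(enumerate_mutants(net))
    assert len(mutants) == expected == 2 * n * n
    assert len(set(mutants)) == expected  # no duplicates
    assert all(
        len({node for node, _ in p.forcings}) == p.order for p in mutants
    )  # no same-node double


def test_default_perturbable_set_excludes_outputs(mini_tumour):
    net, _ = mini_tumour
    labels = {p.label for p in enumerate_mutants(net, orders=(1,))}
    assert not any("Proliferation" in l or "Apoptosis" in l for l in labels)
    assert "GrowthFactor:1" in labels  # inputs remain perturbable


def test_enumeration_at_exhaustive_screen_scale():
    net = parse_boolnet("\n".join(f"N{i}, N{i}" for i in range(127)))
    assert sum(1 for _ in enumerate_mutants(net)) == 32_258


# -- presets ----------------------------------------------------------------

def test_presets_assign_every_input(mini_tumour):
    net, _ = mini_tumour
    presets = condition_presets(net, varying=("GrowthFactor",), on=())
    assert set(presets) == {"none", "GrowthFactor"}
    config = SimulationConfig(max_time=5.0, time_tick=1.0)
    applied = apply_preset(net, config, presets["GrowthFactor"])
    assert applied.initial["GrowthFactor"] == 1.0
    assert applied.initial["DeathSignal"] == 0.0


def test_incomplete_preset_rejected(mini_tumour):
    net, _ = mini_tumour
    bad = ConditionPreset(name="partial", assignment={"GrowthFactor": 1})
    with pytest.raises(ValueError, match="unassigned"):
        apply_preset(net, SimulationConfig(max_time=5.0, time_tick=1.0), bad)


# -- drugs ------------------------------------------------------------------

def test_full_inhibition_equals_knockout_bit_identically(mini_tumour, growth_config):
    net, _ = mini_tumour
    spec = DrugSpec(targets=(("ERK", 1.0), ("MYC", 1.0)))
    dosed = simulate_drug(net, growth_config, spec)
    ko = apply_mutation(net, Perturbation((("ERK", 0), ("MYC", 0))))
    plain = simulate_ensemble(ko, growth_config)
    assert dosed.joint.equals(plain.joint)


def test_zero_inhibition_equals_wild_type_bit_identically(mini_tumour, growth_config):
    net, _ = mini_tumour
    spec = DrugSpec(targets=(("ERK", 0.0),))
    dosed = simulate_drug(net, growth_config, spec)
    plain = simulate_ensemble(net, growth_config)
    assert dosed.joint.equals(plain.joint)


def test_joint_assignment_fractions_follow_product_law(mini_tumour, growth_config):
    net, _ = mini_tumour
    config = growth_config.replace(n_trajectories=5000)
    spec = DrugSpec(targets=(("ERK", 0.5), ("MYC", 0.5)))
    result = simulate_drug(net, config, spec)
    counts = result.variant_counts
    # each of the four joint assignments expected at 25%
    bound = 2.576 * np.sqrt(0.25 * 0.75 / 5000)  # binomial 99%
    for mask in range(4):
        assert abs(counts.get(mask, 0) / 5000 - 0.25) < bound


def test_variant_probabilities_are_exact_products(mini_tumour, growth_config):
    net, _ = mini_tumour
    spec = DrugSpec(targets=(("ERK", 0.3), ("MYC", 0.6)))
    _, probs, _, _ = apply_drug(net, growth_config, spec)
    assert probs == pytest.approx([0.7 * 0.4, 0.3 * 0.4, 0.7 * 0.6, 0.3 * 0.6])


def test_frozen_mode_fixes_target_activity_fraction(mini_tumour, growth_config):
    net, _ = mini_tumour
    spec = DrugSpec(targets=(("ERK", 0.3),), mode="frozen_on_off")
    config = growth_config.replace(tracked=("ERK",))
    result = simulate_drug(net, config, spec)
    # frozen: never flips, so every window holds the initial 70/30 split
    assert np.allclose(result.marginals["ERK"], 0.7, atol=0.03)


def test_invalid_inhibition_level_rejected():
    with pytest.raises(ValueError, match="not in"):
        DrugSpec(targets=(("ERK", 1.2),))


# -- dose and combination grids ---------------------------------------------

def test_dose_grid_spans_requested_levels(growth_config):
    net = parse_boolnet("S, S\nP, S\n").with_outputs(("P",))
    config = SimulationConfig(
        n_trajectories=800, max_time=8.0, time_tick=1.0, seed=6, initial={"S": 1.0}
    )
    levels = (0.0, 0.5, 1.0)
    grid = dose_response(net, config, "S", levels)
    assert sorted(grid["level"].unique()) == list(levels)
    assert len(grid) == len(levels)  # one output phenotype
    scores = grid.set_index("level")["score"]
    # target directly activates the output: non-increasing dose response
    assert scores[0.0] >= scores[0.5] - 0.03 >= scores[1.0] - 0.06
    assert scores[0.5] == pytest.approx(0.5, abs=0.05)


@pytest.mark.parametrize(
    "n_targets,n_levels,expected",
    [(2, 2, 8), (2, 3, 15), (17, 6, 4998)],
)
def test_combination_condition_counts(n_targets, n_levels, expected):
    targets = [f"T{i}" for i in range(n_targets)]
    levels = list(np.linspace(0, 1, n_levels))
    assert len(combination_conditions(targets, levels)) == expected


def test_pair_grid_contains_single_marginals_at_partner_zero(mini_tumour, growth_config):
    net, _ = mini_tumour
    config = growth_config.replace(n_trajectories=1500)
    table = combination_screen(net, config, ["ERK", "MYC"], levels=(0.0, 1.0))
    singles = table[table["target_b"].isna()]
    pairs = table[table["target_b"].notna()]
    for row in pairs[(pairs["level_b"] == 0.0)].itertuples():
        single = singles[
            (singles["target_a"] == row.target_a)
            & (singles["level_a"] == row.level_a)
            & (singles["phenotype"] == row.phenotype)
        ]["score"].iloc[0]
        assert row.score == pytest.approx(single, abs=0.04)


# -- rule robustness --------------------------------------------------------

def test_robustness_scan_edit_count_and_equivalence(growth_config):
    net = parse_boolnet(
        "A, I\nB, I & I\nP, A | B\n"  # three rules, two binary operators
    ).with_outputs(("P",))
    config = SimulationConfig(
        n_trajectories=400, max_time=6.0, time_tick=1.0, seed=8, initial={"I": 1.0}
    )
    table = rule_robustness_scan(net, config)
    assert len(table) == 2
    # I & I <-> I | I is logically equivalent: identical compiled dynamics
    b_shift = table[table["node"] == "B"]["shift"].iloc[0]
    assert b_shift == 0.0


def test_robustness_scan_skips_operatorless_rules(growth_config):
    net = parse_boolnet("A, I\nP, !A\n").with_outputs(("P",))
    config = SimulationConfig(
        n_trajectories=200, max_time=4.0, time_tick=1.0, seed=8, initial={"I": 1.0}
    )
    assert rule_robustness_scan(net, config).empty
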