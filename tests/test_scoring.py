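import math

import numpy as np
import pandas as pd
import pytest

from ctboolsim.scoring import (
    PSI_KINDS,
    bliss_ci,
    bliss_from_screen,
    drug_effect,
    epistasis_from_screen,
    epistasis_score,
    fitness_from_probabilities,
    pca_mutant_map,
    psi_null,
    rank_auc,
    rank_interventions,
    select_best_psi,
)


# -- drug effect ------------------------------------------------------------

@pytest.mark.parametrize(
    "p_ref,p_treated,direction,expected",
    [
        (0.8, 0.4, "decrease", 0.5),
        (0.8, 0.8, "decrease", 0.0),
        (0.8, 0.9, "decrease", 0.0),  # wrong-direction change clips to 0
        (0.2, 0.6, "increase", 0.5),
        (0.2, 0.2, "increase", 0.0),
    ],
)
def test_drug_effect_fractions(p_ref, p_treated, direction, expected):
    assert drug_effect(p_ref, p_treated, direction) == pytest.approx(expected)


def test_drug_effect_undefined_denominator_is_nan():
    assert math.isnan(drug_effect(0.0, 0.0, "decrease"))
    assert math.isnan(drug_effect(1.0, 0.5, "increase"))


# -- Bliss ------------------------------------------------------------------

def test_bliss_ci_values():
    assert bliss_ci(0.5, 0.5, 0.75) == pytest.approx(1.0)
    assert bliss_ci(0.3, 0.4, 0.9) == pytest.approx(0.58 / 0.9)
    assert math.isnan(bliss_ci(0.3, 0.4, 0.0))


def test_bliss_identity_on_random_effect_grid():
    rng = np.random.default_rng(17)
    for _ in range(200):
        e_a, e_b = rng.random(2)
        e_ab = e_a + e_b - e_a * e_b
        if e_ab > 0:
            assert bliss_ci(e_a, e_b, e_ab) == pytest.approx(1.0, rel=1e-12)


# -- psi null models --------------------------------------------------------

def test_psi_closed_forms():
    assert psi_null(1.0, 1.0, "LOG") == pytest.approx(1.0)
    assert psi_null(0.2, 0.3, "ADD") == pytest.approx(0.5)
    assert psi_null(0.5, 0.5, "MLT") == pytest.approx(0.25)
    assert psi_null(0.7, 0.4, "MIN") == pytest.approx(0.4)
    for y in (0.0, 0.5, 2.0):
        assert psi_null(0.0, y, "LOG") == pytest.approx(0.0)  # annihilator
    with pytest.raises(ValueError, match="unknown psi kind"):
        psi_null(1, 1, "GEO")


def test_psi_at_neutral_fitness():
    # wild type fitness is 1; all nulls except ADD leave it neutral
    for kind in ("LOG", "MLT", "MIN"):
        assert psi_null(1.0, 1.0, kind) == pytest.approx(1.0)
    assert psi_null(1.0, 1.0, "ADD") == pytest.approx(2.0)


# -- fitness and epistasis --------------------------------------------------

def test_fitness_normalises_by_wild_type():
    assert fitness_from_probabilities(0.4, 0.4) == pytest.approx(1.0)
    assert fitness_from_probabilities(0.2, 0.4) == pytest.approx(0.5)  # deleterious
    assert math.isnan(fitness_from_probabilities(0.2, 0.0))
    assert math.isnan(fitness_from_probabilities(0.2, 5e-5))  # below floor


def test_epistasis_zero_iff_null_matches():
    assert epistasis_score(0.5, 0.5, 0.25, "MLT") == pytest.approx(0.0)
    assert epistasis_score(0.5, 0.5, 0.1, "MLT") == pytest.approx(-0.15)
    for kind in PSI_KINDS:
        f_a, f_b = 0.7, 1.2
        assert epistasis_score(
            f_a, f_b, psi_null(f_a, f_b, kind), kind
        ) == pytest.approx(0.0)
    assert math.isnan(epistasis_score(float("nan"), 1.0, 1.0, "ADD"))


# -- null-model selection ---------------------------------------------------

def _pairs_under(kind, rng, n=30, noise=0.0):
    f_a = rng.uniform(0.0, 1.5, n)
    f_b = rng.uniform(0.0, 1.5, n)
    f_ab = psi_null(f_a, f_b, kind) + rng.normal(0.0, noise, n)
    return pd.DataFrame({"fA": f_a, "fB": f_b, "fAB": f_ab})


def test_select_best_psi_exact_generation_gives_r_one():
    rng = np.random.default_rng(3)
    best, corr = select_best_psi(_pairs_under("MLT", rng))
    assert best == "MLT"
    assert corr["MLT"] == pytest.approx(1.0)


def test_select_best_psi_with_small_noise():
    rng = np.random.default_rng(4)
    best, _ = select_best_psi(_pairs_under("ADD", rng, noise=0.02))
    assert best == "ADD"


def test_select_best_psi_preconditions():
    with pytest.raises(ValueError, match="at least 3"):
        select_best_psi(pd.DataFrame({"fA": [1, 1], "fB": [1, 1], "fAB": [1, 2]}))
    with pytest.raises(ValueError, match="zero variance"):
        select_best_psi(pd.DataFrame({"fA": [1, 2, 3], "fB": [1, 2, 3], "fAB": [1, 1, 1]}))


# -- screen-level helpers ---------------------------------------------------

def _toy_screen():
    rows = [("wild_type", 0, 0.8), ("A:0", 1, 0.4), ("B:0", 1, 0.6),
            ("A:0+B:0", 2, 0.2), ("C:1", 1, 0.9)]
    return pd.DataFrame(
        [{"perturbation": p, "order": o, "phenotype": "Proliferation", "score": s}
         for p, o, s in rows]
    )


def test_rank_interventions_orders_by_signed_change():
    screen = _toy_screen()
    top = rank_interventions(screen, "Proliferation", "decrease", 2)
    assert top["perturbation"].tolist() == ["A:0+B:0", "A:0"]
    up = rank_interventions(screen, "Proliferation", "increase", 1)
    assert up["perturbation"].iloc[0] == "C:1"


def test_rank_interventions_ties_break_lexicographically():
    screen = pd.DataFrame(
        [{"perturbation": p, "phenotype": "P", "score": s}
         for p, s in [("wild_type", 0.5), ("B:0", 0.2), ("A:0", 0.2)]]
    )
    ranked = rank_interventions(screen, "P", "decrease")
    assert ranked["perturbation"].tolist() == ["A:0", "B:0"]


def test_rank_interventions_k_larger_than_table():
    full = rank_interventions(_toy_screen(), "Proliferation", "decrease", 100)
    assert len(full) == 4


def test_rank_interventions_unknown_phenotype():
    with pytest.raises(KeyError):
        rank_interventions(_toy_screen(), "Invasion", "decrease", 3)


def test_epistasis_from_screen_recovers_fitness_and_pairs():
    table, selected, corr = epistasis_from_screen(
        pd.concat([_toy_screen(),
                   pd.DataFrame([{"perturbation": "A:0+C:1", "order": 2,
                                  "phenotype": "Proliferation", "score": 0.45},
                                 {"perturbation": "B:0+C:1", "order": 2,
                                  "phenotype": "Proliferation", "score": 0.675}])],
                  ignore_index=True),
        "Proliferation",
    )
    assert set(table["pair"]) == {"A:0+B:0", "A:0+C:1", "B:0+C:1"}
    row = table[table["pair"] == "A:0+B:0"].iloc[0]
    assert row["fA"] == pytest.approx(0.5) and row["fAB"] == pytest.approx(0.25)
    assert selected in PSI_KINDS and selected == max(corr, key=corr.get)


def test_bliss_from_screen_flags_redundant_pair_synergy():
    # singles useless alone, pair fully effective: classic synergy
    rows = []
    for ta, la, tb, lb, score in [
        ("X", 0.0, None, np.nan, 0.8), ("X", 1.0, None, np.nan, 0.8),
        ("Y", 0.0, None, np.nan, 0.8), ("Y", 1.0, None, np.nan, 0.8),
        ("X", 1.0, "Y", 1.0, 0.1), ("X", 0.0, "Y", 1.0, 0.8),
    ]:
        rows.append({"target_a": ta, "level_a": la, "target_b": tb, "level_b": lb,
                     "preset": "", "phenotype": "P", "score": score})
    ci = bliss_from_screen(pd.DataFrame(rows), "P")
    assert len(ci) == 1  # only the both-present pair condition
    assert ci["CI"].iloc[0] < 1.0


# -- AUC and PCA ------------------------------------------------------------

def test_rank_auc_limits():
    assert rank_auc([1, 2, 3], [0, 0.5]) == 1.0
    assert rank_auc([0], [1, 2]) == 0.0
    assert rank_auc([1, 2], [1, 2]) == pytest.approx(0.5)


def test_pca_reference_maps_to_origin_and_variance_sorted():
    rng = np.random.default_rng(9)
    matrix = pd.DataFrame(
        rng.random((10, 4)),
        index=[f"m{i}" for i in range(9)] + ["wild_type"],
        columns=list("WXYZ"),
    )
    coords, explained = pca_mutant_map(matrix, "wild_type")
    assert np.allclose(coords.loc["wild_type"], 0.0, atol=1e-12)
    assert np.all(np.diff(explained) <= 1e-12)
    assert explained.sum() == pytest.approx(1.0)


def test_pca_two_conditions_single_axis():
    matrix = pd.DataFrame(
        [[0.0, 0.0], [0.6, 0.8]], index=["wild_type", "m"], columns=["P", "Q"]
    )
    coords, explained = pca_mutant_map(matrix, "wild_type")
    assert explained[0] == pytest.approx(1.0)
    assert abs(coords.loc["m", "PC1"]) == pytest.approx(1.0)  # distance preserved


def test_pca_constant_matrix_rejected():
    matrix = pd.DataFrame([[0.2, 0.2]] * 3, index=list("abc"), columns=["P", "Q"])
    with pytest.raises(ValueError, match="constant"):
        pca_mutant_map(matrix, "a")
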