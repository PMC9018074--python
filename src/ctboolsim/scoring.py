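"""Drug-effect, synergy and genetic-interaction scoring.

Drug efficiency ``E`` for a phenotype is the fraction of the achievable
change realised by the treatment (decrease: ``(P_ref - P) / P_ref``;
increase: ``(P - P_ref) / (1 - P_ref)``), so ``E`` is 0 for no effect and 1
for a complete one.  Synergy of a drug pair is quantified by the Bliss
independence Combination Index ``CI = (Ea + Eb - Ea*Eb) / Eab``; CI < 1
flags synergy.

Genetic interactions use phenotype *fitness* values ``f = P_mutant / P_wt``
(wild type normalised to 1; f < 1 deleterious, f > 1 beneficial) and the
epistasis score ``eps = f_AB - psi(f_A, f_B)`` where ``psi`` is one of four
null models of non-interaction: additive, log, multiplicative, min.  The
null model best describing a screen is the one whose predictions correlate
best (Pearson) with the observed double-mutant fitness values.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "drug_effect",
    "bliss_ci",
    "bliss_from_screen",
    "psi_null",
    "PSI_KINDS",
    "fitness_from_probabilities",
    "epistasis_score",
    "epistasis_from_screen",
    "select_best_psi",
    "rank_interventions",
    "rank_auc",
    "pca_mutant_map",
]

logger = logging.getLogger(__name__)

#: Null-model tie-break order.
PSI_KINDS = ("ADD", "LOG", "MLT", "MIN")


def drug_effect(p_ref: float, p_treated: float, direction: str = "decrease") -> float:
    """Drug efficiency in [0, 1] relative to the untreated probability.

    NaN when the reference makes the denominator undefined (``p_ref`` 0 for
    a decrease, 1 for an increase).  Changes opposite to the desired
    direction clip to 0.
    """
    if direction == "decrease":
        if p_ref == 0.0:
            return float("nan")
        return max(0.0, (p_ref - p_treated) / p_ref)
    if direction == "increase":
        if p_ref == 1.0:
            return float("nan")
        return max(0.0, (p_treated - p_ref) / (1.0 - p_ref))
    raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")


def bliss_ci(e_a: float, e_b: float, e_ab: float) -> float:
    """Bliss independence Combination Index; CI < 1 flags synergy.

    ``CI = (Ea + Eb - Ea*Eb) / Eab``; NaN when the combined effect is 0.
    """
    if not e_ab or math.isnan(e_ab) or math.isnan(e_a) or math.isnan(e_b):
        return float("nan")
    return (e_a + e_b - e_a * e_b) / e_ab


def psi_null(x, y, kind: str):
    """Non-interaction prediction for a double perturbation.

    ADD: x + y; LOG: log2((2^x - 1)(2^y - 1) + 1); MLT: x*y; MIN: min(x, y).
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "ADD":
        out = x + y
    elif kind == "LOG":
        out = np.log2((np.exp2(x) - 1.0) * (np.exp2(y) - 1.0) + 1.0)
    elif kind == "MLT":
        out = x * y
    elif kind == "MIN":
        out = np.minimum(x, y)
    else:
        raise ValueError(f"unknown psi kind {kind!r}; expected one of {PSI_KINDS}")
    return out if out.ndim else float(out)


def fitness_from_probabilities(
    p_mutant: float, p_wildtype: float, floor: float = 1e-4
) -> float:
    """Phenotype fitness ``f = P_mutant / P_wt``; NaN below the wild-type floor.

    The floor avoids fabricating huge fitness values (and hence spurious
    interactions) from near-zero wild-type probabilities.
    """
    if p_wildtype < floor:
        logger.info(
            "wild-type probability %g below floor %g; fitness undefined",
            p_wildtype, floor,
        )
        return float("nan")
    return p_mutant / p_wildtype


def epistasis_score(f_a: float, f_b: float, f_ab: float, kind: str) -> float:
    """Genetic-interaction score ``eps = f_AB - psi(f_A, f_B)``.

    Zero exactly when the double mutant matches the null prediction;
    negative deviations are aggravating, positive alleviating.  NaN inputs
    propagate.
    """
    return f_ab - psi_null(f_a, f_b, kind)


def select_best_psi(table: pd.DataFrame) -> tuple[str, dict[str, float]]:
    """Pick the null model whose predictions best correlate with ``f_AB``.

    ``table`` needs columns ``fA``, ``fB``, ``fAB``; rows with any NaN are
    dropped.  Returns the winning kind and the Pearson r per kind; ties are
    broken in the fixed order ADD < LOG < MLT < MIN.
    """
    clean = table[["fA", "fB", "fAB"]].dropna()
    if len(clean) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(clean)}")
    observed = clean["fAB"].to_numpy()
    if np.ptp(observed) == 0.0:
        raise ValueError("observed double-mutant fitness has zero variance")
    correlations: dict[str, float] = {}
    for kind in PSI_KINDS:
        predicted = psi_null(clean["fA"].to_numpy(), clean["fB"].to_numpy(), kind)
        if np.ptp(predicted) == 0.0:
            correlations[kind] = float("nan")
            continue
        correlations[kind] = float(stats.pearsonr(observed, predicted).statistic)
    best = max(
        PSI_KINDS,
        key=lambda k: (correlations[k] if not math.isnan(correlations[k]) else -np.inf),
    )
    return best, correlations


def bliss_from_screen(
    screen: pd.DataFrame, phenotype: str, direction: str = "decrease"
) -> pd.DataFrame:
    """Combination Index per dose pair from a combination-screen table.

    ``screen`` is the output of
    :func:`ctboolsim.perturb.combination_screen`; the untreated reference is
    the level-0 single row.  Rows are produced for every pair condition with
    both levels positive (CI is undefined when one drug is absent).
    """
    sub = screen[screen["phenotype"] == phenotype]
    singles = sub[sub["target_b"].isna()]
    ref_rows = singles[singles["level_a"] == 0.0]
    if ref_rows.empty:
        raise ValueError("screen has no untreated (level 0) reference row")
    p_ref = float(ref_rows["score"].iloc[0])
    single_effect = {
        (row.target_a, row.level_a): drug_effect(p_ref, row.score, direction)
        for row in singles.itertuples()
    }
    rows = []
    pairs = sub[sub["target_b"].notna()]
    for row in pairs.itertuples():
        if row.level_a == 0.0 or row.level_b == 0.0:
            continue
        e_a = single_effect.get((row.target_a, row.level_a), float("nan"))
        e_b = single_effect.get((row.target_b, row.level_b), float("nan"))
        e_ab = drug_effect(p_ref, row.score, direction)
        rows.append({
            "target_a": row.target_a,
            "level_a": row.level_a,
            "target_b": row.target_b,
            "level_b": row.level_b,
            "phenotype": phenotype,
            "direction": direction,
            "Ea": e_a,
            "Eb": e_b,
            "Eab": e_ab,
            "CI": bliss_ci(e_a, e_b, e_ab),
        })
    return pd.DataFrame(
        rows,
        columns=[
            "target_a", "level_a", "target_b", "level_b",
            "phenotype", "direction", "Ea", "Eb", "Eab", "CI",
        ],
    )


def epistasis_from_screen(
    screen: pd.DataFrame, phenotype: str, floor: float = 1e-4
) -> tuple[pd.DataFrame, str, dict[str, float]]:
    """Fitness and epistasis table from a tidy mutant-screen table.

    Singles provide ``fA``/``fB``, doubles ``fAB`` (all normalised by the
    wild-type probability); the best-correlating null model is selected
    across all pairs and the epistasis score is reported under it.
    Returns ``(table, selected_psi, pearson_r_per_psi)``.
    """
    sub = screen[screen["phenotype"] == phenotype]
    if sub.empty:
        raise KeyError(f"phenotype {phenotype!r} not present in the screen")
    wt_rows = sub[sub["perturbation"] == "wild_type"]
    if wt_rows.empty:
        raise ValueError("screen lacks the wild-type reference row")
    p_wt = float(wt_rows["score"].iloc[0])
    fitness = {
        row.perturbation: fitness_from_probabilities(row.score, p_wt, floor)
        for row in sub.itertuples()
        if row.perturbation != "wild_type"
    }
    rows = []
    for label, f_ab in fitness.items():
        parts = label.split("+")
        if len(parts) != 2:
            continue
        f_a, f_b = fitness.get(parts[0]), fitness.get(parts[1])
        if f_a is None or f_b is None:
            continue
        rows.append({
            "pair": label, "single_a": parts[0], "single_b": parts[1],
            "fA": f_a, "fB": f_b, "fAB": f_ab,
        })
    table = pd.DataFrame(rows, columns=["pair", "single_a", "single_b", "fA", "fB", "fAB"])
    selected, correlations = select_best_psi(table)
    table["psi"] = selected
    table["epsilon"] = [
        epistasis_score(r.fA, r.fB, r.fAB, selected) for r in table.itertuples()
    ]
    return table, selected, correlations


def rank_interventions(
    screen: pd.DataFrame, phenotype: str, direction: str, k: int | None = None
) -> pd.DataFrame:
    """Top-k perturbations by signed phenotype change versus wild type.

    ``screen`` is a tidy mutant-screen table with a ``wild_type`` row.
    Sorting is by the change in the requested direction; ties break
    lexicographically on the perturbation label.
    """
    sub = screen[screen["phenotype"] == phenotype]
    if sub.empty:
        raise KeyError(f"phenotype {phenotype!r} not present in the screen")
    wt_rows = sub[sub["perturbation"] == "wild_type"]
    if wt_rows.empty:
        raise ValueError("screen lacks the wild-type reference row")
    wt = float(wt_rows["score"].iloc[0])
    out = sub[sub["perturbation"] != "wild_type"].copy()
    out["delta"] = out["score"] - wt
    ascending = direction == "decrease"
    if direction not in ("decrease", "increase"):
        raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    out = out.sort_values(
        ["delta", "perturbation"], ascending=[ascending, True]
    ).reset_index(drop=True)
    return out if k is None else out.head(k)


def rank_auc(positives, negatives) -> float:
    """Rank-based AUC: probability a positive outranks a negative.

    Mann-Whitney U scaled by the number of pairs; 0.5 means no separation.
    """
    positives = np.asarray(positives, dtype=float)
    negatives = np.asarray(negatives, dtype=float)
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both groups must be non-empty")
    u = stats.mannwhitneyu(positives, negatives, alternative="two-sided").statistic
    return float(u / (positives.size * negatives.size))


def pca_mutant_map(
    matrix: pd.DataFrame, reference: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component map of phenotype signatures, wild-type centred.

    ``matrix`` is conditions x outputs; the row named ``reference`` (the
    wild type) is subtracted from every row — *not* the column means — so
    the reference maps exactly to the origin and distances read as
    phenotype shifts away from it.  Returns the coordinates and the
    explained-variance ratios in descending order.
    """
    if reference not in matrix.index:
        raise KeyError(f"reference row {reference!r} not in matrix")
    if len(matrix) < 2:
        raise ValueError("need at least 2 conditions")
    centred = matrix.to_numpy(dtype=float) - matrix.loc[reference].to_numpy(dtype=float)
    if np.allclose(centred, 0.0):
        raise ValueError("matrix is constant: no variation to map")
    _, singular, vt = np.linalg.svd(centred, full_matrices=False)
    coords = centred @ vt.T
    variance = singular**2
    explained = variance / variance.sum()
    columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.index, columns=columns), explained
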