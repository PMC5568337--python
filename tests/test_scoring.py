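import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from iopgrs import (
    VariantPanel,
    estimate_allele_ors,
    simulate_genotypes,
    unweighted_grs,
    weighted_grs,
)
from iopgrs.errors import ContractError, DegenerateLabelsError, SchemaError


def _frame(rows, panel):
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        columns=panel.rsids,
        index=[f"P{i}" for i in range(len(rows))],
    )


@pytest.fixture(scope="module")
def panel():
    return VariantPanel.uniform(frequency=0.5)


# -- unweighted --------------------------------------------------------------


@pytest.mark.parametrize(
    "row,expected",
    [
        ([0] * 9, 0.0),
        ([2] * 9, 18.0),
        ([1, 0, 2, 1, 0, 1, 2, 0, 1], 8.0),
    ],
)
def test_unweighted_grs_is_the_risk_allele_count(panel, row, expected):
    sv = unweighted_grs(_frame([row], panel), panel)
    assert sv.scores[0] == expected
    assert sv.kind == "unweighted"


def test_unweighted_bounds_on_random_matrices(panel):
    g = simulate_genotypes(panel, 500, seed=6)
    sv = unweighted_grs(g, panel)
    assert sv.scores.min() >= 0
    assert sv.scores.max() <= panel.max_score


def test_missing_rsid_column_is_named_in_error(panel):
    g = _frame([[0] * 9], panel).drop(columns=["rs2472493"])
    with pytest.raises(SchemaError, match="rs2472493"):
        unweighted_grs(g, panel)


def test_exclude_policy_drops_and_counts_missing_rows(panel):
    g = _frame([[1] * 9, [2] * 9], panel)
    g.iloc[0, 3] = np.nan
    sv = unweighted_grs(g, panel, missing_policy="exclude")
    assert list(sv.participant_ids) == ["P1"]
    assert sv.n_missing_handled == 1
    assert not sv.imputed


def test_mean_impute_policy_keeps_rows_and_flags(panel):
    g = _frame([[0] * 9, [2] * 9, [2] * 9], panel)
    g.iloc[0, 0] = np.nan  # observed mean dosage at that variant = 2.0
    sv = unweighted_grs(g, panel, missing_policy="mean_impute")
    assert len(sv.scores) == 3
    assert sv.imputed and sv.n_missing_handled == 1
    assert sv.scores[0] == pytest.approx(2.0)  # 0*8 + imputed 2.0


def test_unknown_missing_policy_rejected(panel):
    with pytest.raises(ContractError):
        unweighted_grs(_frame([[0] * 9], panel), panel, missing_policy="drop")


# -- weighted ----------------------------------------------------------------


def test_null_weights_give_zero_scores(panel):
    g = _frame([[1, 0, 2, 1, 0, 1, 2, 0, 1]], panel)
    weights = {r: 0.0 for r in panel.rsids}  # every OR = 1
    sv = weighted_grs(g, weights, panel=panel)
    assert sv.scores[0] == 0.0
    assert sv.kind == "weighted"
    assert sv.weights_used == weights


def test_single_variant_log_or_closed_form(panel):
    row = [0] * 9
    row[2] = 2
    weights = {r: 0.0 for r in panel.rsids}
    weights[panel.rsids[2]] = np.log(2.0)
    sv = weighted_grs(_frame([row], panel), weights, panel=panel)
    assert sv.scores[0] == pytest.approx(2 * np.log(2.0), abs=1e-12)


def test_missing_weight_for_panel_variant_is_schema_error(panel):
    weights = {r: 0.1 for r in panel.rsids[:-1]}
    with pytest.raises(SchemaError, match=panel.rsids[-1]):
        weighted_grs(_frame([[0] * 9], panel), weights, panel=panel)


@settings(derandomize=True, max_examples=50)
@given(
    dosages=st.lists(st.integers(0, 2), min_size=9, max_size=9),
    w=st.floats(-1.5, 1.5, allow_nan=False),
)
def test_equal_weights_are_proportional_to_unweighted(dosages, w):
    panel = VariantPanel.uniform(frequency=0.5)
    g = _frame([dosages], panel)
    u = unweighted_grs(g, panel).scores[0]
    s = weighted_grs(g, {r: w for r in panel.rsids}, panel=panel).scores[0]
    assert s == pytest.approx(w * u, abs=1e-9)


@settings(derandomize=True, max_examples=40)
@given(
    dosages=st.lists(st.integers(0, 2), min_size=9, max_size=9),
    idx=st.integers(0, 8),
)
def test_incrementing_one_dosage_moves_scores_by_weight(dosages, idx):
    """+1 dosage at one variant raises the unweighted score by exactly 1 and
    the weighted score by exactly that variant's weight."""
    if dosages[idx] == 2:
        dosages = list(dosages)
        dosages[idx] = 1
    bumped = list(dosages)
    bumped[idx] += 1
    panel = VariantPanel.uniform(frequency=0.5)
    weights = {r: 0.1 * (i + 1) for i, r in enumerate(panel.rsids)}
    g = _frame([dosages, bumped], panel)
    u = unweighted_grs(g, panel).scores
    w = weighted_grs(g, weights, panel=panel).scores
    assert u[1] - u[0] == pytest.approx(1.0, abs=1e-12)
    assert w[1] - w[0] == pytest.approx(weights[panel.rsids[idx]], abs=1e-12)


def test_permuting_rows_permutes_scores(panel, rng):
    g = simulate_genotypes(panel, 50, seed=9)
    g.index = [f"P{i}" for i in range(50)]
    perm = rng.permutation(50)
    sv = unweighted_grs(g, panel)
    sv_perm = unweighted_grs(g.iloc[perm], panel)
    assert np.array_equal(sv.scores[perm], sv_perm.scores)
    assert list(sv_perm.participant_ids) == [f"P{i}" for i in perm]


# -- per-allele OR estimation ------------------------------------------------


def test_identical_dosage_distributions_give_or_one(panel):
    rows = [[d] * 9 for d in (0, 1, 2)] * 2  # one of each dosage per class
    labels = [True] * 3 + [False] * 3
    table = estimate_allele_ors(_frame(rows, panel), labels)
    for entry in table.entries:
        assert entry.odds_ratio == pytest.approx(1.0, abs=1e-6)


def _brute_force_binary_dosage_or():
    """Independent MLE oracle on the 4-cell dataset: dosage in {0,2},
    30 cases / 10 controls at dosage 2 and 10 cases / 30 controls at 0."""

    def negloglik(theta):
        b0, b1 = theta
        ll = 0.0
        for dosage, cases, controls in ((2, 30, 10), (0, 10, 30)):
            eta = b0 + b1 * dosage
            p = 1.0 / (1.0 + np.exp(-eta))
            ll += cases * np.log(p) + controls * np.log(1 - p)
        return -ll

    res = optimize.minimize(negloglik, x0=[0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return float(np.exp(res.x[1]))


def test_binary_dosage_or_matches_contingency_oracle(panel):
    """Per-allele OR on a {0,2}-dosage dataset equals the square root of the
    2x2 table OR (9 -> 3.0/allele), cross-checked against a brute-force MLE."""
    rows = [[2] * 9] * 30 + [[0] * 9] * 10 + [[2] * 9] * 10 + [[0] * 9] * 30
    labels = [True] * 40 + [False] * 40
    table = estimate_allele_ors(_frame(rows, panel), labels)
    oracle = _brute_force_binary_dosage_or()
    assert oracle == pytest.approx(3.0, abs=1e-6)
    for entry in table.entries:
        assert entry.odds_ratio == pytest.approx(oracle, abs=1e-6)


def test_or_estimates_center_on_truth_with_nominal_coverage():
    """Per-allele OR of 1.2: estimates center on the truth and the Wald 95%
    CI covers it at roughly the nominal rate over seeded replicates."""
    true_or = 1.2
    n = 4000
    reps = 250
    rng = np.random.default_rng(123)
    log_ors, covered = [], 0
    for _ in range(reps):
        dosage = rng.binomial(2, 0.5, n)
        eta = -0.5 + np.log(true_or) * dosage
        case = rng.random(n) < 1 / (1 + np.exp(-eta))
        g = pd.DataFrame({"rs1": dosage}, index=[f"P{i}" for i in range(n)])
        entry = estimate_allele_ors(g, case)["rs1"]
        log_ors.append(np.log(entry.odds_ratio))
        covered += entry.ci_low <= true_or <= entry.ci_high
    mc_se = np.std(log_ors, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(log_ors) - np.log(true_or)) <= 3 * mc_se
    assert 0.91 <= covered / reps <= 0.985


def test_all_one_class_labels_rejected(panel):
    g = _frame([[1] * 9] * 4, panel)
    with pytest.raises(DegenerateLabelsError):
        estimate_allele_ors(g, [True, True, True, True])


def test_separated_variant_is_flagged_not_estimated(panel):
    rows = [[2] * 9] * 10 + [[0] * 9] * 10
    labels = [True] * 10 + [False] * 10  # dosage predicts status perfectly
    table = estimate_allele_ors(_frame(rows, panel), labels)
    for entry in table.entries:
        assert entry.separated
        assert np.isnan(entry.odds_ratio)
    assert table.weights() == {}
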