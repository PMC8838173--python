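"""Match grading, kappa statistics, exact intervals and Fisher's test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from dieteval.classification import (
    classification_accuracy,
    cohen_kappa,
    confusion_table,
    fisher_exact,
    grade_match,
    kappa_summary,
    sensitivity_specificity,
    uniform_kappa,
    uniform_kappa_ci,
)
from dieteval.records import NutrientVector, Segment
from dieteval.taxonomy import load_taxonomy


def _seg(food_type, label=None):
    return Segment(label=label or food_type, food_type=food_type, weight_g=100.0,
                   nutrients=NutrientVector())


# ---------------------------------------------------------------- grading

def test_synonym_is_exact(tax):
    ref = _seg("fruiting_vegetables", "tomatoes")
    app = _seg("fruiting_vegetables", "cherry tomatoes")
    assert grade_match(ref, app, flags={"synonym"}, tax=tax).value == "E"


def test_slight_variant_same_type_is_close(tax):
    ref = _seg("red_meat", "beef")
    app = _seg("red_meat", "veal")
    assert grade_match(ref, app, flags={"slight_variant"}, tax=tax).value == "C"


def test_same_group_wrong_type_is_far(tax):
    # pasta vs rice share the grains category but sit in different groups in
    # this fixture; bread vs pasta share the cereals group -> far match
    assert grade_match(_seg("pasta"), _seg("bread"), tax=tax).value == "F"


def test_wrong_group_is_mismatch(tax):
    # carrot vs potato: vegetables vs potatoes/legumes group
    assert grade_match(_seg("root_vegetables", "carrot"), _seg("tubers", "potato"), tax=tax).value == "M"


def test_unknown_flag_rejected(tax):
    with pytest.raises(ValueError):
        grade_match(_seg("pasta"), _seg("pasta"), flags={"bogus"}, tax=tax)


def test_grade_counts_sum_to_found():
    grades = pd.DataFrame({"grade": list("EECCCFMM") + ["E"] * 10})
    table = classification_accuracy(grades, by=None)
    row = table.loc["total"]
    assert row.n == 18 == row.n_E + row.n_C + row.n_F + row.n_M
    assert row.pct_E + row.pct_C + row.pct_F + row.pct_M == pytest.approx(100.0)


def test_accuracy_on_printed_counts():
    grades = pd.DataFrame({"grade": ["E"] * 302 + ["C"] * 29 + ["F"] * 4 + ["M"] * 10})
    row = classification_accuracy(grades, by=None).loc["total"]
    assert round(row.pct_E, 1) == 87.5 and round(row.hw_E, 1) == 3.5
    assert round(row.pct_C, 1) == 8.4
    assert round(row.pct_F, 1) == 1.2 and round(row.pct_M, 1) == 2.9


def test_all_exact_input():
    row = classification_accuracy(pd.DataFrame({"grade": ["E"] * 7}), by=None).loc["total"]
    assert (row.pct_E, row.pct_C, row.pct_F, row.pct_M) == (100.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------- Cohen kappa

def test_cohen_kappa_binary_reconstruction():
    # one-vs-rest cells implied by a perfectly sensitive, nearly specific group
    kappa, se = cohen_kappa(np.array([[13, 0], [4, 328]]))
    assert round(kappa, 4) == 0.8607
    assert se > 0


def test_cohen_kappa_perfect_diagonal():
    kappa, _ = cohen_kappa(np.diag([5, 9, 3]))
    assert kappa == pytest.approx(1.0)


def test_cohen_kappa_degenerate_rejected():
    with pytest.raises(ValueError):
        cohen_kappa(np.array([[7, 0], [0, 0]]))


@pytest.mark.parametrize("seed", range(6))
def test_cohen_kappa_matches_marginal_oracle(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 30, size=(4, 4))
    m[0, 0] += 5  # keep Pe < 1
    n = m.sum()
    po = np.trace(m) / n
    pe = float(np.sum(m.sum(axis=0) * m.sum(axis=1))) / n**2
    expected = (po - pe) / (1 - pe)
    kappa, _ = cohen_kappa(m)
    assert kappa == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- uniform kappa

@pytest.mark.parametrize(
    "po, q, expected",
    [(331 / 345, 37, 0.958), (341 / 345, 2, 0.977)],
)
def test_uniform_kappa_printed_values(po, q, expected):
    assert round(uniform_kappa(po, q), 3) == expected


def test_uniform_kappa_anchor_points():
    assert uniform_kappa(1.0, 5) == pytest.approx(1.0)
    assert uniform_kappa(1 / 5, 5) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        uniform_kappa(0.5, 1)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=40),
       st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
def test_uniform_kappa_increasing_in_po(q, po1, po2):
    lo, hi = sorted((po1, po2))
    assert uniform_kappa(lo, q) <= uniform_kappa(hi, q) <= 1.0


def test_uniform_kappa_equals_cohen_under_uniform_marginals():
    # equal marginals on every label: chance agreement is 1/q for both indices
    m = np.full((4, 4), 2) + np.diag([10, 10, 10, 10])
    kappa, _ = cohen_kappa(m)
    po = np.trace(m) / m.sum()
    assert kappa == pytest.approx(uniform_kappa(po, 4), abs=1e-12)


def test_uniform_kappa_ci_degenerate_all_agree():
    assert uniform_kappa_ci([1] * 30, q=2, B=500, seed=1) == (1.0, 1.0)


def test_uniform_kappa_ci_degenerate_all_disagree():
    lo, hi = uniform_kappa_ci([0] * 30, q=5, B=500, seed=1)
    assert lo == hi == pytest.approx(-1 / 4)


def test_uniform_kappa_ci_consistent_with_printed_interval():
    # 341 agreements of 345 binary indicators: the study printed [0.954;0.994]
    indicators = [1] * 341 + [0] * 4
    for seed in (0, 1, 2):
        lo, hi = uniform_kappa_ci(indicators, q=2, B=2000, seed=seed)
        assert lo == pytest.approx(0.954, abs=0.01)
        assert hi == pytest.approx(0.994, abs=0.01)


def test_uniform_kappa_ci_warns_on_small_B():
    with pytest.warns(UserWarning):
        uniform_kappa_ci([1, 0, 1, 1], q=2, B=50, seed=0)


# ---------------------------------------------------------------- sens/spec

def test_sens_spec_printed_cells():
    res = sensitivity_specificity(tp=13, fn=0, fp=4, tn=328)
    assert res.sensitivity == pytest.approx(100.0)
    assert round(res.sens_ci[0], 1) == 75.3 and res.sens_ci[1] == pytest.approx(100.0)

    res = sensitivity_specificity(tp=6, fn=1, fp=1, tn=300)
    assert round(res.sensitivity, 1) == 85.7
    assert round(res.sens_ci[0], 1) == 42.1 and round(res.sens_ci[1], 1) == 99.6


@pytest.mark.parametrize("n", [5, 13, 40])
def test_clopper_pearson_closed_forms(n):
    # x = n: lower bound is 0.025^(1/n); x = 0: upper bound is 1 - 0.025^(1/n)
    full = sensitivity_specificity(tp=n, fn=0, fp=1, tn=10)
    assert full.sens_ci[0] / 100 == pytest.approx(0.025 ** (1 / n), abs=1e-9)
    none = sensitivity_specificity(tp=0, fn=n, fp=1, tn=10)
    assert none.sensitivity == 0.0
    assert none.sens_ci[1] / 100 == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-9)


def test_sens_spec_zero_denominator_flagged():
    res = sensitivity_specificity(tp=0, fn=0, fp=2, tn=10)
    assert "sensitivity" in res.undefined and math.isnan(res.sensitivity)


# ---------------------------------------------------------------- Fisher

def _fisher_enumeration(table):
    """Two-sided p: sum of probabilities of equally or less likely tables."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def test_fisher_example():
    assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(0.00276, abs=5e-5)


def test_fisher_identical_rows():
    assert fisher_exact([[4, 6], [4, 6]]) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_fisher_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    table = rng.integers(0, 15, size=(2, 2))
    if table.sum() == 0:
        table[0, 0] = 1
    assert fisher_exact(table) == pytest.approx(_fisher_enumeration(table), abs=1e-10)


# ---------------------------------------------------------------- confusion & convergence

def test_confusion_table_totals(tax):
    pairs = [("pasta", "pasta"), ("pasta", "bread"), ("rice", "rice"), ("tubers", "berries")]
    conf = confusion_table(pairs, "group", tax)
    assert conf.n == 4
    assert conf.table.shape == (23, 23)
    tp, fn, fp, tn = conf.binary_for("Cereals & cereal-based products")
    assert (tp, fn, fp, tn) == (2, 0, 0, 2)


def test_kappa_summary_bundles_consistently(tax, small_study):
    ref, app, links = small_study
    ref_by_id = {r.record_id: r for r in ref}
    app_by_id = {r.record_id: r for r in app}
    found = links[links["grade"] != "I"]
    pairs = [
        (ref_by_id[r.record_id].segments[int(r.ref_idx)].food_type,
         app_by_id[r.record_id].segments[int(r.app_idx)].food_type)
        for r in found.itertuples(index=False)
    ]
    conf = confusion_table(pairs, "type", tax)
    indicators = [int(a == b) for a, b in pairs]
    ks = kappa_summary(conf, indicators, B=300, seed=0)
    assert ks.uniform_ci[0] - 1e-9 <= ks.uniform_kappa <= ks.uniform_ci[1] + 1e-9
    assert ks.uniform_kappa == pytest.approx(uniform_kappa(np.mean(indicators), 37))


def test_sensitivity_converges_to_confusion_kernel():
    # three one-type groups with a known misclassification kernel: estimated
    # per-group sensitivity approaches the kernel diagonal (n = 5000)
    tax3 = load_taxonomy([("t1", "g1", "c1"), ("t2", "g2", "c1"), ("t3", "g3", "c2")])
    kernel = np.array([[0.9, 0.08, 0.02], [0.05, 0.85, 0.10], [0.0, 0.07, 0.93]])
    rng = np.random.default_rng(42)
    types = ["t1", "t2", "t3"]
    pairs = []
    for _ in range(5000):
        i = rng.integers(3)
        j = rng.choice(3, p=kernel[i])
        pairs.append((types[i], types[j]))
    conf = confusion_table(pairs, "group", tax3)
    for i, g in enumerate(["g1", "g2", "g3"]):
        tp, fn, fp, tn = conf.binary_for(g)
        sens = sensitivity_specificity(tp, fn, fp, tn).sensitivity / 100
        assert sens == pytest.approx(kernel[i, i], abs=0.02)
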