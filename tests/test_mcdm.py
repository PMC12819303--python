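"""Entropy weights, AHP consistency, weight combination and TOPSIS ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forageval import ValidationError, mcdm
from forageval.mcdm import (
    Criterion,
    DecisionMatrix,
    ahp_weights,
    build_decision_matrix,
    combine_weights,
    default_criteria,
    entropy_weights,
    pairwise_from_judgments,
    topsis_rank,
)


def dm(values, directions=None, groups=None, criteria=None):
    values = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    if criteria is not None:
        values.columns = criteria
    directions = directions or {c: "benefit" for c in values.columns}
    return DecisionMatrix(values=values, directions=directions, groups=groups or {})


# --- entropy ---------------------------------------------------------------

def test_constant_column_gets_zero_weight():
    m = dm({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]})
    w = entropy_weights(m)
    assert w["b"] == 0.0
    assert w["a"] == pytest.approx(1.0)
    assert w.sum() == pytest.approx(1.0, abs=1e-10)


def test_entropy_hand_oracle_3x2():
    m = dm({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]})
    # aligned column a -> (0, .5, 1); p = (0, 1/3, 2/3)
    p = [0.0, 1 / 3, 2 / 3]
    e1 = -sum(x * math.log(x) for x in p if x > 0) / math.log(3)
    aligned = mcdm._align_directions(m)
    pa = aligned["a"] / aligned["a"].sum()
    e_ours = -(pa[pa > 0] * np.log(pa[pa > 0])).sum() / np.log(3)
    assert e_ours == pytest.approx(e1, rel=1e-12)
    assert entropy_weights(m)["a"] == pytest.approx(1.0)


def test_cost_criterion_alignment_inverts():
    # min-max inversion: aligning x as cost equals aligning -x as benefit
    m_cost = dm({"a": [1.0, 2.0, 4.0]}, directions={"a": "cost"})
    m_neg = dm({"a": [-1.0, -2.0, -4.0]})
    assert mcdm._align_directions(m_cost)["a"].tolist() == pytest.approx(
        mcdm._align_directions(m_neg)["a"].tolist()
    )


def test_all_constant_matrix_falls_back_uniform():
    m = dm({"a": [1.0, 1.0], "b": [2.0, 2.0]})
    w = entropy_weights(m)
    assert w.tolist() == pytest.approx([0.5, 0.5])


def test_duplicated_criterion_splits_weight():
    m1 = dm({"a": [1.0, 2.0, 3.0], "b": [5.0, 1.0, 2.0]})
    w1 = entropy_weights(m1)
    m2 = dm({"a": [1.0, 2.0, 3.0], "a2": [1.0, 2.0, 3.0], "b": [5.0, 1.0, 2.0]})
    w2 = entropy_weights(m2)
    assert w2["a"] == pytest.approx(w2["a2"])
    assert w2["a"] / w2["b"] == pytest.approx(w1["a"] / w1["b"], rel=1e-9)


# --- AHP -------------------------------------------------------------------

def test_consistent_matrix_recovers_ratios_with_zero_cr():
    v = np.array([4.0, 2.0, 1.0, 0.5])
    a = pd.DataFrame(np.outer(v, 1 / v))
    res = ahp_weights(a)
    assert res.weights.to_numpy() == pytest.approx(v / v.sum(), abs=1e-9)
    assert res.lambda_max == pytest.approx(4.0, abs=1e-9)
    assert res.cr == pytest.approx(0.0, abs=1e-9)
    assert res.consistent


def test_expert_judgment_matrix_weights_and_cr():
    res = ahp_weights(pairwise_from_judgments([3.0, 5.0, 3.0]))
    assert res.weights.to_numpy() == pytest.approx([0.637, 0.258, 0.105], abs=1e-3)
    assert res.cr == pytest.approx(0.0332, abs=5e-4)
    assert res.consistent  # CR < 0.1 reliability gate


def test_n2_cr_is_zero_by_convention():
    res = ahp_weights(pairwise_from_judgments([7.0], labels=["x", "y"]))
    assert res.cr == 0.0
    assert res.weights["x"] > res.weights["y"]


def test_non_reciprocal_matrix_rejected():
    a = pd.DataFrame([[1.0, 2.0], [0.7, 1.0]])
    with pytest.raises(ValidationError, match="reciprocal"):
        ahp_weights(a)


def test_out_of_range_order_rejected():
    n = 11
    a = pd.DataFrame(np.eye(n) + 0.0)
    a[:] = 1.0
    with pytest.raises(ValidationError, match="random-index"):
        ahp_weights(a)


# --- combination -----------------------------------------------------------

def test_single_group_collapses_to_entropy():
    entropy = pd.Series({"a": 0.7, "b": 0.3})
    expert = pd.Series({"yield": 1.0})
    w = combine_weights(entropy, expert, groups={"a": "yield", "b": "yield"})
    assert w.tolist() == pytest.approx([0.7, 0.3])


def test_hierarchical_hand_example():
    ahp = ahp_weights(pairwise_from_judgments([3.0, 5.0, 3.0]))
    entropy = pd.Series(
        {"c1": 1 / 6, "c2": 1 / 6, "c3": 1 / 6, "c4": 1 / 6, "c5": 1 / 6, "c6": 1 / 6}
    )
    groups = {"c1": "yield", "c2": "yield", "c3": "quality", "c4": "quality",
              "c5": "stability", "c6": "stability"}
    w = combine_weights(entropy, ahp.weights, groups=groups)
    assert w.tolist() == pytest.approx(
        [0.3185, 0.3185, 0.129, 0.129, 0.0525, 0.0525], abs=1e-3
    )
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_multiplicative_uniform_expert_is_identity():
    entropy = pd.Series({"a": 0.2, "b": 0.5, "c": 0.3})
    expert = pd.Series({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
    w = combine_weights(entropy, expert, scheme="multiplicative")
    assert w.tolist() == pytest.approx(entropy.tolist())


def test_missing_group_tag_is_an_error():
    entropy = pd.Series({"a": 0.5, "b": 0.5})
    expert = pd.Series({"yield": 1.0})
    with pytest.raises(Exception, match="group"):
        combine_weights(entropy, expert, groups={"a": "yield"})


# --- TOPSIS ----------------------------------------------------------------

def test_ideal_alternative_gets_closeness_one():
    m = dm({"a": [10.0, 5.0, 1.0], "b": [8.0, 2.0, 1.0]})
    w = pd.Series({"a": 0.5, "b": 0.5})
    res = topsis_rank(m, w)
    assert res.table["closeness"].iloc[0] == pytest.approx(1.0)
    assert res.table["rank"].iloc[0] == 1
    assert ((res.table["closeness"] >= 0) & (res.table["closeness"] <= 1)).all()


def test_symmetric_pair_closenesses_sum_to_one():
    m = dm({"a": [1.0, 3.0], "b": [4.0, 2.0]})
    w = pd.Series({"a": 0.5, "b": 0.5})
    res = topsis_rank(m, w)
    assert res.table["closeness"].sum() == pytest.approx(1.0, rel=1e-10)


@settings(deadline=None, max_examples=40)
@given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100.0))
def test_rank_invariance_to_positive_column_scaling(seed, scale):
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(rng.uniform(1, 10, size=(5, 3)), columns=["a", "b", "c"])
    m1 = dm(vals.copy(), directions={"a": "benefit", "b": "cost", "c": "benefit"})
    scaled = vals.copy()
    scaled["b"] = scaled["b"] * scale
    m2 = dm(scaled, directions={"a": "benefit", "b": "cost", "c": "benefit"})
    w = pd.Series({"a": 0.2, "b": 0.5, "c": 0.3})
    r1, r2 = topsis_rank(m1, w), topsis_rank(m2, w)
    assert (r1.table["rank"] == r2.table["rank"]).all()


def test_zero_norm_column_with_positive_weight_is_error():
    m = dm({"a": [0.0, 0.0], "b": [1.0, 2.0]})
    w = pd.Series({"a": 0.5, "b": 0.5})
    with pytest.raises(ValidationError, match="zero-norm"):
        topsis_rank(m, w)
    # with zero weight the dead column is inert
    res = topsis_rank(m, pd.Series({"a": 0.0, "b": 1.0}))
    assert res.table["rank"].tolist() == [2, 1]


def test_ranks_are_dense_permutation():
    m = dm({"a": [1.0, 2.0, 2.0, 5.0]})
    res = topsis_rank(m, pd.Series({"a": 1.0}))
    assert sorted(res.table["rank"].unique()) == [1, 2, 3]  # tie shares a rank


# --- decision matrix construction ------------------------------------------

def test_default_design_gives_eight_alternatives(preset_data):
    m = build_decision_matrix(preset_data)
    assert m.values.shape[0] == 8
    assert "SG-YM-2024" in m.values.index
    assert m.directions["CV"] == "cost" and m.directions["Wi"] == "cost"
    assert m.groups["GY"] == "yield" and m.groups["starch"] == "quality"


def test_fiber_criteria_enter_as_cost(preset_data):
    crit = default_criteria() + [Criterion("ADF", "cost", "quality")]
    m = build_decision_matrix(preset_data, crit)
    assert m.directions["ADF"] == "cost"


def test_missing_trait_error_lists_available(preset_data):
    with pytest.raises(ValidationError, match="available"):
        build_decision_matrix(preset_data, [Criterion("nope", "benefit", "yield")])


def test_cell_means_enter_the_matrix(preset_data):
    m = build_decision_matrix(preset_data)
    cell = preset_data[
        (preset_data.genotype == "SG")
        & (preset_data.location == "YM")
        & (preset_data.year == "2024")
    ]["GY"].mean()
    assert m.values.loc["SG-YM-2024", "GY"] == pytest.approx(cell)
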