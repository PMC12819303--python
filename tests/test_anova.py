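"""Factorial ANOVA, Tukey HSD and cell summaries against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from forageval import DesignError, anova
from forageval.anova import (
    anova_per_environment,
    anova_three_way,
    compact_letter_display,
    significance_stars,
    summarize_cells,
    tukey_hsd,
)
from forageval.synthetic import TraitSpec, TrialDesign, generate_trial

from conftest import random_balanced_trial

TERM_MAP = {
    "C(genotype)": "genotype",
    "C(location)": "location",
    "C(year)": "year",
    "C(genotype):C(location)": "genotype:location",
    "C(genotype):C(year)": "genotype:year",
    "C(location):C(year)": "location:year",
    "C(genotype):C(location):C(year)": "genotype:location:year",
    "Residual": "Residual",
}


def statsmodels_oracle(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """OLS projection decomposition of the full factorial, as the reference."""
    fit = ols(f"{trait} ~ C(genotype) * C(location) * C(year)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    tab.index = [TERM_MAP[t] for t in tab.index]
    return tab


@pytest.mark.parametrize("seed", range(10))
def test_term_ss_match_projection_oracle(seed):
    df = random_balanced_trial(seed)
    ours = anova_three_way(df, "y")
    ref = statsmodels_oracle(df, "y")
    for term in ours.index:
        assert ours.loc[term, "ss"] == pytest.approx(ref.loc[term, "sum_sq"], rel=1e-8)
        assert ours.loc[term, "df"] == int(ref.loc[term, "df"])
        if term != "Residual":
            assert ours.loc[term, "p"] == pytest.approx(ref.loc[term, "PR(>F)"], rel=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_ss_additivity_and_df_bookkeeping(seed):
    df = random_balanced_trial(100 + seed)
    tab = anova_three_way(df, "y")
    y = df["y"].to_numpy()
    ss_total = ((y - y.mean()) ** 2).sum()
    assert tab["ss"].sum() == pytest.approx(ss_total, rel=1e-10)
    assert tab["df"].sum() == len(df) - 1
    assert (tab["ss"] >= 0).all()


def test_row_order_permutation_invariance():
    df = random_balanced_trial(42)
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    pd.testing.assert_frame_equal(anova_three_way(df, "y"), anova_three_way(shuffled, "y"))


def test_all_identical_observations_report_na():
    df = random_balanced_trial(0)
    df["y"] = 5.0
    tab = anova_three_way(df, "y")
    assert (tab["ss"] == 0).all()
    assert tab["F"].isna().all() and tab["p"].isna().all()


def test_pure_genotype_effect_isolates_in_genotype_term():
    spec = TraitSpec("y", baseline=10.0, residual_sd=0.0, genotype_effects={"SG": 2.0})
    df = generate_trial(TrialDesign(), [spec], seed=0)
    tab = anova_three_way(df, "y")
    assert tab.loc["genotype", "ss"] > 0
    others = tab.drop(["genotype", "Residual"])
    assert np.allclose(others["ss"], 0.0, atol=1e-10 * tab.loc["genotype", "ss"])


def test_unbalanced_design_is_rejected():
    df = random_balanced_trial(1).drop(index=[0])
    with pytest.raises(DesignError, match="unbalanced"):
        anova_three_way(df, "y")


def test_per_environment_gives_four_one_way_tables():
    spec = TraitSpec("y", baseline=10.0, residual_sd=0.0, genotype_effects={"SG": 4.0})
    df = generate_trial(TrialDesign(), [spec], seed=0)
    tables = anova_per_environment(df, "y")
    assert sorted(tables) == ["HZ-2023", "HZ-2024", "YM-2023", "YM-2024"]
    # two groups of n=3 shifted by delta: SS(G) = 3*delta^2/2
    for tab in tables.values():
        assert tab.loc["genotype", "ss"] == pytest.approx(3 * 4.0**2 / 2, rel=1e-12)


def test_identical_genotypes_give_f_zero():
    df = random_balanced_trial(3)
    # make SG a copy of CK within each environment
    base = df[df.genotype == "CK"].set_index(["location", "year", "replicate"])["y"]
    df.loc[df.genotype == "SG", "y"] = base.loc[
        list(zip(df[df.genotype == "SG"].location,
                 df[df.genotype == "SG"].year,
                 df[df.genotype == "SG"].replicate))
    ].to_numpy()
    tables = anova_per_environment(df, "y")
    for tab in tables.values():
        assert tab.loc["genotype", "F"] == pytest.approx(0.0, abs=1e-18)
        assert tab.loc["genotype", "p"] == pytest.approx(1.0)


# --- Tukey -----------------------------------------------------------------

def test_tukey_two_identical_groups():
    res = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    row = res.pairs.iloc[0]
    assert row["diff"] == 0.0
    assert row["p"] == pytest.approx(1.0)
    assert res.letters["a"] == res.letters["b"]


def test_tukey_k2_equals_pooled_t_test():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
    res = tukey_hsd({"a": a, "b": b})
    from scipy import stats

    t, p = stats.ttest_ind(a, b, equal_var=True)
    row = res.pairs.iloc[0]
    assert row["q"] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-10)
    assert row["p"] == pytest.approx(p, rel=1e-4)


def test_tukey_matches_statsmodels_on_fixture():
    rng = np.random.default_rng(21)
    groups = {k: rng.normal(mu, 1.0, 5) for k, mu in [("a", 0), ("b", 0.5), ("c", 1), ("d", 8)]}
    res = tukey_hsd(groups)
    values = np.concatenate(list(groups.values()))
    labels = np.repeat(list(groups), [len(v) for v in groups.values()])
    ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
    ref_frame = pd.DataFrame(ref.summary().data[1:], columns=ref.summary().data[0])
    for _, row in res.pairs.iterrows():
        match = ref_frame[
            ((ref_frame.group1 == row.group1) & (ref_frame.group2 == row.group2))
            | ((ref_frame.group1 == row.group2) & (ref_frame.group2 == row.group1))
        ].iloc[0]
        assert row["p"] == pytest.approx(float(match["p-adj"]), abs=2e-3)
        assert row["significant"] == bool(match["reject"])
    # the far-shifted group earns a letter no other group shares
    d_letters = set(res.letters["d"])
    assert all(d_letters.isdisjoint(set(res.letters[g])) for g in "abc")


def test_all_identical_data_has_no_significant_pairs():
    res = tukey_hsd({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0], "c": [2.0, 2.0, 2.0]})
    assert not res.pairs["significant"].any()
    assert len(set(res.letters.values())) == 1


def test_compact_letter_display_orders_by_mean():
    means = {"hi": 10.0, "mid": 5.0, "lo": 1.0}
    sig = {frozenset(("hi", "lo")), frozenset(("hi", "mid")), frozenset(("mid", "lo"))}
    letters = compact_letter_display(means, sig)
    assert letters == {"hi": "a", "mid": "b", "lo": "c"}
    # only the extreme pair differs: middle shares both letters
    letters = compact_letter_display(means, {frozenset(("hi", "lo"))})
    assert letters["hi"] == "a" and letters["lo"] == "b" and set(letters["mid"]) == {"a", "b"}


# --- cell summaries --------------------------------------------------------

def test_cell_summary_hand_values():
    df = pd.DataFrame(
        {"genotype": "CK", "location": "HZ", "year": "2023",
         "replicate": [1, 2, 3], "y": [8.0, 10.0, 12.0]}
    )
    out = summarize_cells(df, "y")
    assert out["mean"].iloc[0] == pytest.approx(10.0)
    assert out["se"].iloc[0] == pytest.approx(2 / np.sqrt(3), rel=1e-12)
    assert out["cv"].iloc[0] == pytest.approx(20.0, rel=1e-12)


def test_cell_summary_cv_scale_invariance_and_constants():
    df = pd.DataFrame(
        {"genotype": "CK", "location": "HZ", "year": "2023",
         "replicate": [1, 2, 3], "y": [8.0, 10.0, 12.0]}
    )
    scaled = df.assign(y=df.y * 7.3)
    assert summarize_cells(scaled, "y")["cv"].iloc[0] == pytest.approx(
        summarize_cells(df, "y")["cv"].iloc[0], rel=1e-12
    )
    const = df.assign(y=4.2)
    assert summarize_cells(const, "y")["cv"].iloc[0] == 0.0


def test_significance_star_thresholds():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(1e-5) == "****"
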