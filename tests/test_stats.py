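"""Group statistics: textbook oracles, classical identities, degenerate inputs."""

import numpy as np
import pytest
from scipy import stats as sps

from coping.stats import (
    StatsDataError,
    one_way_anova,
    pearson_r2,
    tukey_hsd,
    two_sample_t,
    two_way_anova,
)
import pandas as pd


def test_one_way_constant_groups_give_f_zero():
    rep = one_way_anova({"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5, 5]})
    (eff,) = rep.effects
    assert eff.statistic == 0.0 and eff.p_value == 1.0


def test_one_way_textbook_fixture():
    """Hand sums of squares: SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3."""
    rep = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
    (eff,) = rep.effects
    assert eff.statistic == pytest.approx(3.0)
    assert eff.df == (2.0, 6.0)
    assert eff.p_value == pytest.approx(float(sps.f.sf(3.0, 2, 6)))


def test_one_way_scale_invariance():
    groups = {"a": [1.0, 2.5, 3.1], "b": [4.0, 5.2, 6.3]}
    doubled = {k: [2 * v for v in vs] for k, vs in groups.items()}
    a, b = one_way_anova(groups), one_way_anova(doubled)
    assert a.effects[0].statistic == pytest.approx(b.effects[0].statistic)
    assert a.effects[0].p_value == pytest.approx(b.effects[0].p_value)


def test_one_way_requires_two_observations_per_group():
    with pytest.raises(StatsDataError):
        one_way_anova({"a": [1.0], "b": [2.0, 3.0]})


def test_f_equals_t_squared_for_two_groups(rng):
    a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 12)
    f_rep = one_way_anova({"a": a, "b": b})
    t_rep = two_sample_t(a, b, equal_var=True)
    assert f_rep.effects[0].statistic == pytest.approx(
        t_rep.effects[0].statistic ** 2
    )
    assert f_rep.effects[0].p_value == pytest.approx(t_rep.effects[0].p_value)


def _cells_frame(cell_means, n_per_cell, noise_sd, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for (s, d), m in cell_means.items():
        for _ in range(n_per_cell):
            rows.append((s, d, m + noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["stress", "drug", "y"])


def test_two_way_constant_cells_give_zero_f():
    means = {(s, d): 7.0 for s in "cpa" for d in "vC"}
    rep = two_way_anova(_cells_frame(means, 3, 0.0, 1), "y")
    assert all(e.statistic == 0.0 and e.p_value == 1.0 for e in rep.effects)


def test_two_way_additive_design_has_zero_interaction():
    stress_eff = {"c": 0.0, "p": 5.0, "a": -3.0}
    drug_eff = {"v": 0.0, "C": 2.0}
    means = {(s, d): 10 + stress_eff[s] + drug_eff[d] for s in "cpa" for d in "vC"}
    rep = two_way_anova(_cells_frame(means, 4, 0.0, 1), "y")
    stress, drug, interaction = rep.effects
    assert interaction.statistic == pytest.approx(0.0, abs=1e-6)
    assert stress.statistic > 1e6 and drug.statistic > 1e6  # zero noise


def test_two_way_balanced_matches_hand_decomposition():
    """Balanced 3x2 design: compare against the classical balanced-design
    sums-of-squares decomposition computed directly in this test."""
    means = {
        ("c", "v"): 20.0, ("c", "C"): 35.0,
        ("p", "v"): 38.0, ("p", "C"): 25.0,
        ("a", "v"): 23.0, ("a", "C"): 23.0,
    }
    df = _cells_frame(means, 6, 4.0, 7)
    rep = two_way_anova(df, "y")

    y = df["y"].to_numpy()
    grand = y.mean()
    ss_a = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2 for _, sub in df.groupby("stress")
    )
    ss_b = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2 for _, sub in df.groupby("drug")
    )
    cell_mean = df.groupby(["stress", "drug"])["y"].transform("mean")
    ss_resid = ((df["y"] - cell_mean) ** 2).sum()
    ss_cells = sum(
        len(sub) * (sub["y"].mean() - grand) ** 2
        for _, sub in df.groupby(["stress", "drug"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    n = len(df)
    ms_resid = ss_resid / (n - 6)
    expected = {
        "stress": (ss_a / 2) / ms_resid,
        "drug": (ss_b / 1) / ms_resid,
        "stress:drug": (ss_ab / 2) / ms_resid,
    }
    for eff in rep.effects:
        assert eff.statistic == pytest.approx(expected[eff.name]), eff.name


def test_two_way_empty_cell_names_the_cell():
    df = _cells_frame({(s, d): 1.0 for s in "cp" for d in "vC"}, 3, 1.0, 2)
    df = df[~((df["stress"] == "p") & (df["drug"] == "C"))]
    with pytest.raises(StatsDataError, match="stress=p, drug=C"):
        two_way_anova(df, "y")


def test_tukey_identical_groups_symmetric_ci():
    rep = tukey_hsd([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["a"] * 3 + ["b"] * 3)
    (c,) = rep.comparisons
    assert c.mean_diff == 0.0
    assert c.ci_low == pytest.approx(-c.ci_high)


def test_tukey_matches_studentized_range_formula(rng):
    """CIs equal diff +/- q(0.95; k, df)/sqrt(2) * sqrt(MSE (1/ni + 1/nj))."""
    groups = {"g1": rng.normal(10, 2, 8), "g2": rng.normal(13, 2, 8), "g3": rng.normal(15, 2, 8)}
    values = np.concatenate(list(groups.values()))
    labels = ["g1"] * 8 + ["g2"] * 8 + ["g3"] * 8
    rep = tukey_hsd(values, labels)
    df_resid = 24 - 3
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_resid
    q = sps.studentized_range.ppf(0.95, 3, df_resid)
    for c in rep.comparisons:
        diff = groups[c.group_b].mean() - groups[c.group_a].mean()
        half = q / np.sqrt(2) * np.sqrt(mse * (1 / 8 + 1 / 8))
        assert c.mean_diff == pytest.approx(diff)
        assert c.ci_low == pytest.approx(diff - half, abs=1e-6)
        assert c.ci_high == pytest.approx(diff + half, abs=1e-6)
        assert (c.p_adj < 0.05) == (c.ci_low > 0 or c.ci_high < 0)


def test_tukey_equal_n_gives_equal_widths(rng):
    values = rng.normal(0, 1, 15)
    labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
    widths = {
        (c.group_a, c.group_b): c.ci_high - c.ci_low
        for c in tukey_hsd(values, labels).comparisons
    }
    assert max(widths.values()) == pytest.approx(min(widths.values()))


def test_t_identical_samples():
    rep = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    (eff,) = rep.effects
    assert eff.statistic == 0.0 and eff.p_value == 1.0
    c = rep.comparisons[0]
    assert c.mean_diff == 0.0
    assert c.ci_low == pytest.approx(-c.ci_high)  # symmetric about 0


def test_t_textbook_fixture():
    """{1,2,3} vs {4,5,6}: pooled sp^2 = 1, t = -3/sqrt(2/3), df = 4."""
    rep = two_sample_t([1, 2, 3], [4, 5, 6])
    (eff,) = rep.effects
    expected_t = -3 / np.sqrt(2 / 3)
    assert eff.statistic == pytest.approx(expected_t)
    assert eff.df[0] == 4.0
    assert eff.p_value == pytest.approx(2 * sps.t.sf(abs(expected_t), 4))
    c = rep.comparisons[0]
    assert c.ci_low < c.mean_diff == -3.0 < c.ci_high


def test_t_antisymmetry(rng):
    a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
    fwd = two_sample_t(a, b, equal_var=False)
    rev = two_sample_t(b, a, equal_var=False)
    assert fwd.effects[0].statistic == pytest.approx(-rev.effects[0].statistic)
    assert fwd.effects[0].p_value == pytest.approx(rev.effects[0].p_value)


def test_t_matches_scipy(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1.5, 14)
    for equal_var in (True, False):
        rep = two_sample_t(a, b, equal_var=equal_var)
        ref = sps.ttest_ind(a, b, equal_var=equal_var)
        assert rep.effects[0].statistic == pytest.approx(ref.statistic)
        assert rep.effects[0].p_value == pytest.approx(ref.pvalue)
        lo, hi = ref.confidence_interval()
        assert rep.comparisons[0].ci_low == pytest.approx(lo)
        assert rep.comparisons[0].ci_high == pytest.approx(hi)


def test_t_too_small_sample_raises():
    with pytest.raises(StatsDataError):
        two_sample_t([1.0], [2.0, 3.0])


def test_pearson_exact_negative_line():
    x = np.arange(10.0)
    rep = pearson_r2(x, -2 * x + 7)
    assert rep.extras["r2"] == pytest.approx(1.0)
    assert rep.extras["r"] == pytest.approx(-1.0)
    assert rep.effects[0].p_value < 1e-10


def test_pearson_constant_vector_raises():
    with pytest.raises(StatsDataError, match="zero variance"):
        pearson_r2([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


def test_pearson_matches_direct_arithmetic(rng):
    x = rng.normal(300, 100, 10)
    y = -1.5 * x + rng.normal(0, 150, 10)
    rep = pearson_r2(x, y)
    r_direct = ((x - x.mean()) * (y - y.mean())).sum() / (
        np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
    )
    assert rep.extras["r"] == pytest.approx(r_direct)
    t = r_direct * np.sqrt(8 / (1 - r_direct**2))
    assert rep.effects[0].p_value == pytest.approx(2 * sps.t.sf(abs(t), 8))
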