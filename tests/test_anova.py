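import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from metaconf import bonferroni_pairwise, gg_epsilon, mixed_anova
from metaconf.anova import DesignError, condition_pairs


# ---------------------------------------------------------------------------
# Brute-force cell-means sums-of-squares oracles (balanced, equal group sizes)
# ---------------------------------------------------------------------------

def split_plot_oracle_2way(y):
    """y[g, s, j]: G groups x n subjects x b within levels."""
    G, n, b = y.shape
    m = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_gs = y.mean(axis=2)
    m_j = y.mean(axis=(0, 1))
    m_gj = y.mean(axis=1)
    ss_a = n * b * ((m_g - m) ** 2).sum()
    ss_s = b * ((m_gs - m_g[:, None]) ** 2).sum()
    ss_b = G * n * ((m_j - m) ** 2).sum()
    ss_ab = n * ((m_gj - m_g[:, None] - m_j[None, :] + m) ** 2).sum()
    resid = y - m_gs[:, :, None] - m_gj[:, None, :] + m_g[:, None, None]
    ss_err = (resid**2).sum()
    out = {}
    out["A"] = (ss_a, (G - 1, G * (n - 1)), ss_a / (G - 1) / (ss_s / (G * (n - 1))))
    den = ss_err / ((b - 1) * G * (n - 1))
    out["B"] = (ss_b, (b - 1, (b - 1) * G * (n - 1)), ss_b / (b - 1) / den)
    out["AB"] = (ss_ab, ((G - 1) * (b - 1), (b - 1) * G * (n - 1)),
                 ss_ab / ((G - 1) * (b - 1)) / den)
    out["_err"] = {"S(A)": ss_s, "BS(A)": ss_err}
    return out


def split_plot_oracle_3way(y):
    """y[g, s, j, k]: G groups x n subjects x b x c within levels."""
    G, n, b, c = y.shape
    m = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_gs = y.mean(axis=(2, 3))
    m_j = y.mean(axis=(0, 1, 3))
    m_k = y.mean(axis=(0, 1, 2))
    m_gj = y.mean(axis=(1, 3))
    m_gk = y.mean(axis=(1, 2))
    m_jk = y.mean(axis=(0, 1))
    m_gjk = y.mean(axis=1)
    m_gsj = y.mean(axis=3)
    m_gsk = y.mean(axis=2)

    ss = {}
    ss["A"] = n * b * c * ((m_g - m) ** 2).sum()
    ss_s = b * c * ((m_gs - m_g[:, None]) ** 2).sum()
    ss["B"] = G * n * c * ((m_j - m) ** 2).sum()
    ss["AB"] = n * c * ((m_gj - m_g[:, None] - m_j[None, :] + m) ** 2).sum()
    ss["C"] = G * n * b * ((m_k - m) ** 2).sum()
    ss["AC"] = n * b * ((m_gk - m_g[:, None] - m_k[None, :] + m) ** 2).sum()
    ss["BC"] = G * n * ((m_jk - m_j[:, None] - m_k[None, :] + m) ** 2).sum()
    ss["ABC"] = n * ((m_gjk - m_gj[:, :, None] - m_gk[:, None, :] - m_jk[None, :, :]
                      + m_g[:, None, None] + m_j[None, :, None] + m_k[None, None, :] - m) ** 2).sum()
    err_b = c * ((m_gsj - m_gs[:, :, None] - m_gj[:, None, :] + m_g[:, None, None]) ** 2).sum()
    err_c = b * ((m_gsk - m_gs[:, :, None] - m_gk[:, None, :] + m_g[:, None, None]) ** 2).sum()
    resid = (y - m_gsj[:, :, :, None] - m_gsk[:, :, None, :] - m_gjk[:, None, :, :]
             + m_gs[:, :, None, None] + m_gj[:, None, :, None] + m_gk[:, None, None, :]
             - m_g[:, None, None, None])
    err_bc = (resid**2).sum()

    dfs = {"A": G - 1, "B": b - 1, "AB": (G - 1) * (b - 1), "C": c - 1,
           "AC": (G - 1) * (c - 1), "BC": (b - 1) * (c - 1),
           "ABC": (G - 1) * (b - 1) * (c - 1)}
    errs = {"A": (ss_s, G * (n - 1)), "B": (err_b, (b - 1) * G * (n - 1)),
            "AB": (err_b, (b - 1) * G * (n - 1)), "C": (err_c, (c - 1) * G * (n - 1)),
            "AC": (err_c, (c - 1) * G * (n - 1)), "BC": (err_bc, (b - 1) * (c - 1) * G * (n - 1)),
            "ABC": (err_bc, (b - 1) * (c - 1) * G * (n - 1))}
    out = {}
    for e in dfs:
        e_ss, e_df = errs[e]
        out[e] = (ss[e], (dfs[e], e_df), (ss[e] / dfs[e]) / (e_ss / e_df))
    out["_err_total"] = ss_s + err_b + err_c + err_bc
    return out


def _long(y, within_names):
    """Long DataFrame from y[g, s, *within] with unique subject ids."""
    G, n = y.shape[:2]
    wlv = [list("L" + str(i) for i in range(d)) for d in y.shape[2:]]
    rows = []
    for g in range(G):
        for s in range(n):
            for idx in itertools.product(*(range(d) for d in y.shape[2:])):
                row = {"agent_id": f"g{g}s{s}", "agent_group": f"grp{g}",
                       "value": y[(g, s) + idx]}
                for name, lv, i in zip(within_names, wlv, idx):
                    row[name] = lv[i]
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed_anova vs oracles
# ---------------------------------------------------------------------------

def test_two_way_matches_ss_oracle(rng):
    y = rng.normal(10, 2, size=(2, 6, 3))
    oracle = split_plot_oracle_2way(y)
    tab = mixed_anova(_long(y, ["w"]), dv="value", subject="agent_id",
                      between="agent_group", within=["w"], gg="never").set_index("effect")
    for key, name in (("A", "agent_group"), ("B", "w"), ("AB", "agent_group * w")):
        ss, (df1, df2), f = oracle[key]
        row = tab.loc[name]
        assert row["ss"] == pytest.approx(ss, abs=1e-8)
        assert (row["df1"], row["df2"]) == (df1, df2)
        assert row["F"] == pytest.approx(f, abs=1e-8)


def test_three_way_matches_ss_oracle(rng):
    y = rng.normal(50, 5, size=(2, 5, 2, 3))
    oracle = split_plot_oracle_3way(y)
    tab = mixed_anova(_long(y, ["w1", "w2"]), dv="value", subject="agent_id",
                      between="agent_group", within=["w1", "w2"], gg="never").set_index("effect")
    names = {"A": "agent_group", "B": "w1", "AB": "agent_group * w1", "C": "w2",
             "AC": "agent_group * w2", "BC": "w1 * w2", "ABC": "agent_group * w1 * w2"}
    for key, name in names.items():
        ss, (df1, df2), f = oracle[key]
        row = tab.loc[name]
        assert row["ss"] == pytest.approx(ss, abs=1e-8)
        assert (row["df1"], row["df2"]) == (df1, df2)
        assert row["F"] == pytest.approx(f, abs=1e-8)
    # generalized eta squared: SS_eff / (SS_eff + all error SS)
    tot = oracle["_err_total"]
    for key, name in names.items():
        ss = oracle[key][0]
        assert tab.loc[name, "ges"] == pytest.approx(ss / (ss + tot), abs=1e-10)


def test_two_way_matches_pingouin(rng):
    y = rng.normal(0, 1, size=(2, 12, 4)) + np.arange(4) * 0.5
    df = _long(y, ["w"])
    mine = mixed_anova(df, dv="value", subject="agent_id", between="agent_group",
                       within=["w"], gg="never").set_index("effect")
    ref = pg.mixed_anova(data=df, dv="value", subject="agent_id",
                         between="agent_group", within="w", correction=True).set_index("Source")
    for mine_name, ref_name in (("agent_group", "agent_group"), ("w", "w"),
                                ("agent_group * w", "Interaction")):
        assert mine.loc[mine_name, "ss"] == pytest.approx(ref.loc[ref_name, "SS"], rel=1e-10)
        assert mine.loc[mine_name, "F"] == pytest.approx(ref.loc[ref_name, "F"], rel=1e-10)
        assert mine.loc[mine_name, "p_uncorrected"] == pytest.approx(
            ref.loc[ref_name, "p_unc"], abs=1e-12)
    # epsilon definitions differ only in covariance pooling; they stay close
    assert mine.loc["w", "eps"] == pytest.approx(ref.loc["w", "eps"], abs=0.02)


def test_pure_within_epsilon_matches_pingouin_exactly(rng):
    y = rng.normal(0, 1, size=(1, 15, 4)) * np.array([1.0, 1.5, 3.0, 0.5])
    df = _long(y, ["w"])
    mine = mixed_anova(df, dv="value", subject="agent_id", between=None,
                       within=["w"], gg="always").set_index("effect")
    wide = df.pivot(index="agent_id", columns="w", values="value")
    eps_ref = pg.epsilon(wide, correction="gg")
    assert mine.loc["w", "eps"] == pytest.approx(float(eps_ref), abs=1e-10)
    _, w_p = pg.sphericity(df, dv="value", subject="agent_id", within="w")[-2:]
    assert mine.loc["w", "mauchly_p"] == pytest.approx(w_p, abs=1e-8)


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def test_gg_epsilon_compound_symmetry_is_one():
    s = np.full((4, 4), 0.3) + np.eye(4) * 0.7
    assert gg_epsilon(s) == pytest.approx(1.0)


def test_gg_epsilon_two_levels_is_one(rng):
    a = rng.normal(size=(2, 2))
    assert gg_epsilon(a @ a.T) == 1.0


def test_gg_epsilon_fixed_3x3_closed_form():
    s = np.array([[2.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 3.0]])
    k = 3
    sbar = s.mean()
    diag_bar = np.trace(s) / k
    row_bar = s.mean(axis=1)
    num = (k * (diag_bar - sbar)) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (row_bar**2).sum() + k**2 * sbar**2)
    assert gg_epsilon(s) == pytest.approx(num / den, abs=1e-12)
    assert 1 / (k - 1) <= gg_epsilon(s) <= 1.0


def test_gg_epsilon_rejects_asymmetric():
    with pytest.raises(ValueError):
        gg_epsilon(np.array([[1.0, 0.2], [0.5, 1.0]]))


def test_two_level_within_reports_epsilon_one(rng):
    y = rng.normal(size=(2, 8, 2))
    tab = mixed_anova(_long(y, ["w"]), dv="value", subject="agent_id",
                      between="agent_group", within=["w"]).set_index("effect")
    assert tab.loc["w", "eps"] == 1.0


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

def test_null_design_gives_small_f(rng):
    y = rng.normal(0, 1, size=(2, 40, 3))  # no true effects
    tab = mixed_anova(_long(y, ["w"]), dv="value", subject="agent_id",
                      between="agent_group", within=["w"])
    assert (tab["F"] < 5).all()
    assert (tab["p"] > 0.01).all()


def test_missing_cells_raise_and_drop_incomplete_recovers(rng):
    y = rng.normal(size=(2, 6, 3))
    df = _long(y, ["w"])
    df = df[~((df["agent_id"] == "g0s0") & (df["w"] == "L2"))]
    with pytest.raises(DesignError, match="missing within-cells"):
        mixed_anova(df, dv="value", subject="agent_id", between="agent_group", within=["w"])
    tab = mixed_anova(df, dv="value", subject="agent_id", between="agent_group",
                      within=["w"], drop_incomplete=True)
    assert tab.attrs["n_dropped"] == 1
    assert tab.attrs["n_subjects"] == 11


def test_subject_in_two_groups_rejected(rng):
    y = rng.normal(size=(2, 4, 2))
    df = _long(y, ["w"])
    df.loc[df["agent_id"] == "g0s0", "agent_id"] = "g1s0"
    with pytest.raises(DesignError, match="more than one between level"):
        mixed_anova(df, dv="value", subject="agent_id", between="agent_group", within=["w"])


# ---------------------------------------------------------------------------
# Bonferroni pairwise
# ---------------------------------------------------------------------------

def _posthoc_data(rng, shift=0.0):
    rows = []
    for g in ("a", "b"):
        for s in range(12):
            for c in ("x", "y", "z"):
                mu = shift if (g, c) == ("a", "x") else 0.0
                rows.append({"agent_id": f"{g}{s}", "agent_group": g, "condition": c,
                             "value": rng.normal(mu, 1)})
    return pd.DataFrame(rows)


def test_single_comparison_adjusted_equals_raw(rng):
    df = _posthoc_data(rng)
    fam = condition_pairs("condition", ["x", "y"], fixed={"agent_group": "a"})
    tab = bonferroni_pairwise(df, dv="value", subject="agent_id", comparisons=fam)
    assert tab.iloc[0]["p_bonf"] == pytest.approx(tab.iloc[0]["p_raw"])
    assert tab.iloc[0]["paired"]


def test_bonferroni_caps_at_one_and_is_monotone(rng):
    df = _posthoc_data(rng)
    fam = condition_pairs("condition", ["x", "y", "z"], fixed={"agent_group": "a"})
    tab = bonferroni_pairwise(df, dv="value", subject="agent_id", comparisons=fam)
    assert (tab["m"] == 3).all()
    assert (tab["p_bonf"] <= 1.0).all()
    assert np.all(np.diff(tab.sort_values("p_raw")["p_bonf"]) >= -1e-12)
    high = tab[tab["p_raw"] > 1 / 3]
    assert (high["p_bonf"] == 1.0).all()


def test_between_group_comparison_is_independent(rng):
    df = _posthoc_data(rng, shift=3.0)
    fam = [({"agent_group": "a", "condition": "x"}, {"agent_group": "b", "condition": "x"})]
    tab = bonferroni_pairwise(df, dv="value", subject="agent_id", comparisons=fam)
    assert not tab.iloc[0]["paired"]
    assert tab.iloc[0]["df"] == 22
    assert tab.iloc[0]["p_bonf"] < 0.01


def test_null_family_type_i_control(rng):
    """With identical cell distributions, a Bonferroni family of three paired
    comparisons flags anything in at most ~alpha of simulated datasets
    (binomial 3-sigma margin around the 5% familywise bound)."""
    hits = 0
    n_sim = 200
    for _ in range(n_sim):
        df = _posthoc_data(rng)
        fam = condition_pairs("condition", ["x", "y", "z"], fixed={"agent_group": "a"})
        tab = bonferroni_pairwise(df, dv="value", subject="agent_id", comparisons=fam)
        hits += int((tab["p_bonf"] < 0.05).any())
    assert hits / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)


def test_empty_family_rejected(rng):
    with pytest.raises(ValueError):
        bonferroni_pairwise(_posthoc_data(rng), dv="value", subject="agent_id", comparisons=[])
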