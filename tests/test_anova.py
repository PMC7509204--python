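"""Mixed ANOVA decomposition against pingouin, textbook formulas and contracts."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from vagalflex.anova import (MixedAnovaModel, anova_f, generalized_eta_squared,
                             paired_contrast)


def _one_within(rng, n_per_group=4, groups=("low", "medium", "high"),
                effects=(0.0, 1.0, 2.0), w_effect=2.0):
    rows = []
    i = 0
    for g, ge in zip(groups, np.resize(effects, len(groups))):
        for _ in range(n_per_group):
            for lev, we in (("a", 0.0), ("b", w_effect)):
                rows.append(dict(subject=f"s{i}", grp=g, w=lev,
                                 y=rng.normal(10 + ge + we, 1.0)))
            i += 1
    return pd.DataFrame(rows)


def _two_within(rng, n_per_group=4):
    rows = []
    for i in range(2 * n_per_group):
        g = "g1" if i < n_per_group else "g2"
        for w1 in ("a", "b"):
            for w2 in ("c", "d"):
                mu = (w1 == "b") * 1.5 + (w2 == "d") * 0.5 + (g == "g2") * 1.0
                rows.append(dict(subject=f"s{i}", grp=g, w1=w1, w2=w2,
                                 y=rng.normal(mu, 1.0)))
    return pd.DataFrame(rows)


def test_f_and_ges_helpers():
    assert anova_f(10.0, 1, 20.0, 10) == pytest.approx(5.0)
    assert generalized_eta_squared(5.0, [5.0, 10.0]) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        anova_f(-1.0, 1, 5.0, 4)
    with pytest.raises(ValueError):
        generalized_eta_squared(-2.0, [1.0])


def test_mixed_anova_matches_pingouin_one_within(rng):
    df = _one_within(rng)
    res = MixedAnovaModel(df, dv="y", subject="subject", within=("w",),
                          between="grp", flex_coding="categorical").fit()
    ref = pg.mixed_anova(df, dv="y", within="w", subject="subject",
                         between="grp", effsize="ng2").set_index("Source")
    assert res.table.loc["grp", "SS_num"] == pytest.approx(ref.loc["grp", "SS"])
    assert res.table.loc["grp", "F"] == pytest.approx(ref.loc["grp", "F"])
    assert res.table.loc["w", "F"] == pytest.approx(ref.loc["w", "F"])
    assert res.table.loc["grp x w", "F"] == pytest.approx(
        ref.loc["Interaction", "F"])
    assert res.table.loc["grp", "ges"] == pytest.approx(ref.loc["grp", "ng2"])
    assert res.table.loc["w", "ges"] == pytest.approx(ref.loc["w", "ng2"])


def test_mixed_anova_matches_textbook_means_oracle(rng):
    """Balanced 2-within x 2-group design vs explicit means-based formulas."""
    df = _two_within(rng)
    res = MixedAnovaModel(df, dv="y", subject="subject", within=("w1", "w2"),
                          between="grp", flex_coding="categorical").fit()
    piv = df.pivot_table(index="subject", columns=["w1", "w2"], values="y")
    Y = piv.to_numpy()
    n, m = Y.shape
    grp = df.groupby("subject")["grp"].first().reindex(piv.index).to_numpy()
    cells = list(piv.columns)
    grand = Y.mean()

    # between stratum
    ss_grp = sum((grp == g).sum() * m * (Y[grp == g].mean() - grand) ** 2
                 for g in ("g1", "g2"))
    subj_mean = Y.mean(axis=1)
    ss_serr = sum(m * (subj_mean[i] - Y[grp == grp[i]].mean()) ** 2
                  for i in range(n))
    assert res.table.loc["grp", "SS_num"] == pytest.approx(ss_grp, abs=1e-6)
    assert res.error_ss["between"] == pytest.approx(ss_serr, abs=1e-6)

    # within main effects via level means
    for fac, pos in (("w1", 0), ("w2", 1)):
        ss = 0.0
        for lev in sorted({c[pos] for c in cells}):
            mask = np.array([c[pos] == lev for c in cells])
            ss += n * mask.sum() * (Y[:, mask].mean() - grand) ** 2
        assert res.table.loc[fac, "SS_num"] == pytest.approx(ss, abs=1e-6)

    # within-by-within interaction via cell means
    ss_int = 0.0
    for ci, c in enumerate(cells):
        m1 = np.array([cc[0] == c[0] for cc in cells])
        m2 = np.array([cc[1] == c[1] for cc in cells])
        ss_int += n * (Y[:, ci].mean() - Y[:, m1].mean()
                       - Y[:, m2].mean() + grand) ** 2
    assert res.table.loc["w1 x w2", "SS_num"] == pytest.approx(ss_int, abs=1e-6)

    # decomposition is exhaustive on a balanced design
    total = ((Y - grand) ** 2).sum()
    ss_all = (res.table["SS_num"].sum()
              + sum(res.error_ss.values()))
    assert ss_all == pytest.approx(total, abs=1e-6)
    assert ((res.table["ges"] >= 0) & (res.table["ges"] <= 1)).all()


def test_linear_coding_gives_single_df_trend(rng):
    df = _one_within(rng, effects=(0.0, 1.0, 2.0))
    res = MixedAnovaModel(df, dv="y", subject="subject", within=("w",),
                          between="grp", flex_coding="linear").fit()
    n = df.subject.nunique()
    assert res.table.loc["grp", "df_num"] == 1
    assert res.table.loc["grp", "df_den"] == n - 2
    # the trend term captures more of the ordered effect per df than the
    # 2-df categorical term
    cat = MixedAnovaModel(df, dv="y", subject="subject", within=("w",),
                          between="grp", flex_coding="categorical").fit()
    assert res.table.loc["grp", "F"] > cat.table.loc["grp", "F"] * 0.9


def test_unbalanced_cells_and_singleton_group_raise(rng):
    df = _one_within(rng)
    with pytest.raises(ValueError):
        MixedAnovaModel(df.drop(index=0), dv="y", subject="subject",
                        within=("w",), between="grp")
    bad = df.copy()
    bad.loc[bad.subject == "s0", "grp"] = "solo"
    with pytest.raises(ValueError):
        MixedAnovaModel(bad, dv="y", subject="subject", within=("w",),
                        between="grp")


def test_simple_interaction_detects_group_specific_effect(rng):
    # interaction (w1 x w2) present only in group g1
    rows = []
    for i in range(16):
        g = "g1" if i < 8 else "g2"
        for w1 in ("a", "b"):
            for w2 in ("c", "d"):
                mu = 3.0 if (g == "g1" and w1 == "b" and w2 == "d") else 0.0
                rows.append(dict(subject=f"s{i}", grp=g, w1=w1, w2=w2,
                                 y=rng.normal(mu, 0.8)))
    df = pd.DataFrame(rows)
    res = MixedAnovaModel(df, dv="y", subject="subject", within=("w1", "w2"),
                          between="grp", flex_coding="categorical").fit()
    f1, df1, dfe, p1 = res.simple_interaction("g1", ("w1", "w2"))
    f2, _, _, p2 = res.simple_interaction("g2", ("w1", "w2"))
    assert dfe == 16 - 1 - 1
    assert p1 < 0.01 and f1 > f2
    assert p2 > 0.05


def test_paired_contrast_on_generator_data():
    """Congruency contrast on simulated trials: incongruent reliably slower."""
    import vagalflex as vf
    from vagalflex.cohort import CohortSpec, generate_trials

    spec = CohortSpec(interference_ms=120.0)
    rows = []
    for i in range(40):
        tr = generate_trials("LELS", 0.0, spec, seed=i)
        cell = tr.groupby("congruency")["rt_ms"].mean()
        for cong, rt in cell.items():
            rows.append(dict(subject=f"s{i}", congruency=cong, rt_ms=rt))
    long = pd.DataFrame(rows)
    t, df, p = paired_contrast(long, dv="rt_ms", subject="subject",
                               factor="congruency")
    assert t < -2 and p < 0.001 and df == 39


def test_paired_contrast_errors():
    d = pd.DataFrame({"subject": ["s0", "s0"], "congruency": ["a", "b"],
                      "rt_ms": [1.0, 2.0]})
    with pytest.raises(ValueError):
        paired_contrast(d, dv="rt_ms", subject="subject", factor="congruency")
    with pytest.raises(ValueError):
        paired_contrast(d, dv="rt_ms", subject="subject", factor="congruency",
                        where={"congruency": "zzz"})
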