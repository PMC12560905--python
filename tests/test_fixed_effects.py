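import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lactaqg.fixed_effects import (
    FixedEffectsSpec,
    bw_class,
    compute_vif,
    dim_stage,
    factor_f_tests,
    fit_lsm,
    letter_display,
    parity_class,
    predict_mid_from_early,
)


# -- level builders ----------------------------------------------------------


def test_parity_pooling():
    assert list(parity_class([1, 4, 5, 6, 9])) == ["1", "4", ">=5", ">=5", ">=5"]


def test_dim_stage_boundaries():
    assert list(dim_stage([100, 101, 200, 201])) == ["early", "mid", "mid", "late"]


def test_bw_class_edges():
    got = list(bw_class([480.0, 500.0, 500.1, 700.0, 700.1]))
    assert got == ["<= 500", "<= 500", "(500, 550]", "(650, 700]", "> 700"]


# -- LSMEANS -----------------------------------------------------------------


def _balanced_records(noise=0.0, seed=0):
    """Fully crossed parity x season design, r replicates per cell."""
    rng = np.random.default_rng(seed)
    rows = []
    effects_p = {1: 0.0, 2: 1.0, 3: 2.5, 4: 3.0, 5: 4.0}
    effects_s = {"spring": 0.0, "summer": -1.0, "fall": 0.5, "winter": 2.0}
    for p, s, r in itertools.product(effects_p, effects_s, range(4)):
        rows.append({
            "parity": p, "season": s, "dim": 120, "bw_kg": 580.0,
            "dmy_kg": 25.0 + effects_p[p] + effects_s[s] + noise * rng.standard_normal(),
        })
    return pd.DataFrame(rows)


def test_balanced_lsm_equals_marginal_means():
    df = _balanced_records(noise=0.3)
    spec = FixedEffectsSpec(factors=("parity", "season"))
    table = fit_lsm(df, spec, "dmy_kg")
    frame = table.to_frame().set_index(["factor", "level"])
    for p, sub in df.groupby("parity"):
        level = ">=5" if p >= 5 else str(p)
        assert frame.loc[("parity", level), "lsm"] == pytest.approx(
            sub["dmy_kg"].mean(), abs=1e-9)
    for s, sub in df.groupby("season"):
        assert frame.loc[("season", s), "lsm"] == pytest.approx(
            sub["dmy_kg"].mean(), abs=1e-9)


def test_clearly_separated_levels_get_distinct_letters():
    df = _balanced_records(noise=0.05, seed=3)
    spec = FixedEffectsSpec(factors=("parity", "season"))
    frame = fit_lsm(df, spec, "dmy_kg").to_frame()
    parity = frame[frame["factor"] == "parity"].set_index("level")
    # effects 0 / 1 / 2.5 / 3 / 4 with sd 0.05: all pairwise significant
    assert parity.loc[">=5", "letters"] == "A"
    assert parity.loc["4", "letters"] == "B"
    assert parity.loc["3", "letters"] == "C"
    assert parity.loc["2", "letters"] == "D"
    assert parity.loc["1", "letters"] == "E"


def test_empty_level_raises_unless_allowed():
    df = _balanced_records(noise=0.1)
    spec = FixedEffectsSpec(factors=("parity", "season", "dim_stage"))
    with pytest.raises(ValueError, match="empty level"):
        fit_lsm(df, spec, "dmy_kg")  # all records are mid-lactation
    with pytest.warns(UserWarning, match="empty level"):
        fit_lsm(df, spec, "dmy_kg", allow_empty_levels=True)


def test_letter_display_chain():
    # A > B significant, A-AB and AB-B not: classic {A, AB, B} pattern
    p = np.array([[1.0, 0.2, 0.01],
                  [0.2, 1.0, 0.30],
                  [0.01, 0.30, 1.0]])
    letters = letter_display(p, means=[3.0, 2.0, 1.0])
    assert letters == ["A", "AB", "B"]


def test_letter_display_all_different():
    p = np.full((3, 3), 0.001)
    np.fill_diagonal(p, 1.0)
    assert letter_display(p, means=[1.0, 3.0, 2.0]) == ["C", "A", "B"]


def test_letter_display_invariant_to_input_order():
    p = np.array([[1.0, 0.2, 0.01],
                  [0.2, 1.0, 0.30],
                  [0.01, 0.30, 1.0]])
    base = letter_display(p, means=[3.0, 2.0, 1.0])
    perm = [2, 0, 1]
    p2 = p[np.ix_(perm, perm)]
    means2 = [1.0, 3.0, 2.0]
    permuted = letter_display(p2, means2)
    assert [permuted[perm.index(i)] for i in range(3)] == base


# -- diagnostics -------------------------------------------------------------


def test_vif_matches_pairwise_correlation():
    rng = np.random.default_rng(5)
    x1 = rng.standard_normal(500)
    x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(500)
    report = compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
    r2 = np.corrcoef(x1, x2)[0, 1] ** 2
    assert report.vif["x1"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)
    assert report.vif["x2"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)


def test_vif_flags_perfect_collinearity():
    x = np.arange(50.0)
    with pytest.warns(UserWarning, match="collinearity"):
        report = compute_vif(pd.DataFrame({"a": x, "b": 2 * x + 1, "c": x ** 2}))
    assert report.vif["a"] == np.inf
    assert report.warnings


# -- early -> mid prediction -------------------------------------------------


def _two_stage_records(n_cows=20, seed=2):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cows):
        base = rng.normal(28, 3)
        for dim in (30, 60, 90):       # early
            rows.append({"ear_tag": f"C{i:02d}", "dim": dim,
                         "dmy_kg": base + rng.normal(0, 0.5),
                         "my_morn_kg": rng.normal(9, 1),
                         "my_noon_kg": rng.normal(9, 1),
                         "my_night_kg": rng.normal(9, 1),
                         "fat_pct": rng.normal(3.9, 0.2),
                         "protein_pct": rng.normal(3.3, 0.2)})
        for dim in (130, 170):         # mid
            rows.append({"ear_tag": f"C{i:02d}", "dim": dim,
                         "dmy_kg": base, "my_morn_kg": 9.0, "my_noon_kg": 9.0,
                         "my_night_kg": 9.0, "fat_pct": 3.9, "protein_pct": 3.3})
    return pd.DataFrame(rows)


def test_predict_mid_from_early_runs_and_bounds_r2():
    out = predict_mid_from_early(_two_stage_records())
    assert out["n_cows"] == 20
    assert 0.0 <= out["r2"] <= 1.0
    assert set(out["coefficients"]) == {"dmy_kg", "my_morn_kg", "my_noon_kg",
                                        "my_night_kg", "fat_pct", "protein_pct"}
    # mid yield is the cow's base level, early dmy tracks it closely
    assert out["r2"] > 0.9


def test_predict_mid_perfect_copy_gives_r2_one():
    df = _two_stage_records()
    early_mean = (df[df["dim"] <= 100].groupby("ear_tag")["dmy_kg"].mean())
    df.loc[df["dim"] > 100, "dmy_kg"] = (
        df.loc[df["dim"] > 100, "ear_tag"].map(early_mean))
    out = predict_mid_from_early(df)
    assert out["r2"] == pytest.approx(1.0, abs=1e-9)


def test_predict_requires_enough_cows():
    with pytest.raises(ValueError, match="at least"):
        predict_mid_from_early(_two_stage_records(n_cows=4))


# -- F tests -----------------------------------------------------------------


def test_single_factor_f_test_matches_one_way_anova():
    df = _balanced_records(noise=1.0, seed=9)
    spec = FixedEffectsSpec(factors=("parity",))
    out = factor_f_tests(df, spec, "dmy_kg").set_index("factor")
    groups = [g["dmy_kg"].to_numpy() for _, g in df.groupby("parity")]
    F_ref, p_ref = stats.f_oneway(*groups)
    assert out.loc["parity", "F"] == pytest.approx(F_ref, rel=1e-9)
    assert out.loc["parity", "p"] == pytest.approx(p_ref, rel=1e-9)


def test_f_tests_report_each_factor(small_herd):
    _, _, records, _ = small_herd
    spec = FixedEffectsSpec(factors=("parity", "season"))
    out = factor_f_tests(records, spec, "dmy_kg")
    assert set(out["factor"]) == {"parity", "season"}
    assert (out["p"] <= 1.0).all() and (out["p"] >= 0.0).all()
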