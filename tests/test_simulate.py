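import numpy as np
import pandas as pd
import pytest

from lactaqg.pedigree import Pedigree, PedigreeRecord, build_A
from lactaqg.qc import clean, standardize
from lactaqg.simulate import (
    DEFAULT_COMPONENTS,
    SimScenario,
    scenario_from_dict,
    scenario_to_dict,
    simulate_breeding_values,
    simulate_herd,
    simulate_pedigree,
)


def _tiny(**kw):
    base = dict(seed=1, n_generations=3, males_per_gen=6, females_per_gen=60,
                sires_per_gen=5, n_cows_with_records=80, records_per_cow=3)
    base.update(kw)
    return SimScenario(**base)


def test_determinism_under_fixed_seed():
    ped1, rec1, _ = simulate_herd(_tiny())
    ped2, rec2, _ = simulate_herd(_tiny())
    assert ped1.ids == ped2.ids
    pd.testing.assert_frame_equal(rec1, rec2)


def test_different_seeds_differ():
    _, rec1, _ = simulate_herd(_tiny(seed=1))
    _, rec2, _ = simulate_herd(_tiny(seed=2))
    assert not rec1["dmy_kg"].equals(rec2["dmy_kg"])


def test_pedigree_structure():
    scen = _tiny()
    ped = simulate_pedigree(scen)
    assert len(ped) == scen.n_generations * (scen.males_per_gen + scen.females_per_gen)
    # founders have no parents; every later animal has both parents
    for r in ped.records:
        if r.birth_year == 2000:
            assert r.sire == "" and r.dam == ""
        else:
            assert r.sire in ped.index and r.dam in ped.index


def test_scenario_validation():
    with pytest.raises(ValueError):
        _tiny(missingness_rate=1.5)
    with pytest.raises(ValueError):
        _tiny(sires_per_gen=99)
    with pytest.raises(ValueError):
        _tiny(n_cows_with_records=10_000)


def test_founder_breeding_value_variance():
    ped = Pedigree.from_records([PedigreeRecord(f"F{i}") for i in range(40_000)])
    bv = simulate_breeding_values(ped, [[0.449]], seed=0, trait_names=("t",))
    assert bv["t"].var(ddof=1) == pytest.approx(0.449, rel=0.05)
    assert bv["t"].mean() == pytest.approx(0.0, abs=0.02)


def test_parent_offspring_covariance():
    # many independent trios: cov(sire, child) = 0.5 sigma2_a
    rows = []
    for i in range(30_000):
        rows += [PedigreeRecord(f"S{i}"), PedigreeRecord(f"D{i}"),
                 PedigreeRecord(f"X{i}", sire=f"S{i}", dam=f"D{i}")]
    ped = Pedigree.from_records(rows)
    bv = simulate_breeding_values(ped, [[1.0]], seed=3, trait_names=("t",))
    s = bv.loc[[f"S{i}" for i in range(30_000)], "t"].to_numpy()
    x = bv.loc[[f"X{i}" for i in range(30_000)], "t"].to_numpy()
    assert np.cov(s, x)[0, 1] == pytest.approx(0.5, abs=0.02)
    assert x.var(ddof=1) == pytest.approx(1.0, rel=0.05)


def test_zero_additive_variance_gives_zero_values():
    ped = simulate_pedigree(_tiny())
    bv = simulate_breeding_values(ped, [[0.0]], seed=0, trait_names=("t",))
    assert (bv["t"] == 0.0).all()


def test_multitrait_breeding_value_covariance():
    ped = Pedigree.from_records([PedigreeRecord(f"F{i}") for i in range(40_000)])
    cov = np.array([[0.165, 0.551 * np.sqrt(0.165 * 0.068)],
                    [0.551 * np.sqrt(0.165 * 0.068), 0.068]])
    bv = simulate_breeding_values(ped, cov, seed=1, trait_names=("a", "b"))
    emp = np.cov(bv.to_numpy().T)
    np.testing.assert_allclose(emp, cov, rtol=0.06)


def test_trait_means_without_fixed_effects():
    # wide parent base (all 60 males used as sires) keeps genetic drift of
    # the generation means small enough for a tight tolerance
    scen = SimScenario(seed=1, n_generations=2, males_per_gen=60,
                       females_per_gen=300, sires_per_gen=60,
                       n_cows_with_records=300, records_per_cow=5,
                       fixed_effect_scale=0.0)
    _, rec, _ = simulate_herd(scen)
    assert rec["dmy_kg"].mean() == pytest.approx(28.5, abs=0.6)
    assert rec["fat_pct"].mean() == pytest.approx(3.94, abs=0.25)
    assert rec["protein_pct"].mean() == pytest.approx(3.35, abs=0.15)


def test_shift_yields_close_exactly():
    _, rec, _ = simulate_herd(_tiny())
    total = rec["my_morn_kg"] + rec["my_noon_kg"] + rec["my_night_kg"]
    np.testing.assert_allclose(total, rec["dmy_kg"], atol=1e-12)


def test_records_have_valid_dim_and_dates():
    _, rec, _ = simulate_herd(_tiny())
    assert rec["dim"].between(15, 308).all()
    dates = pd.to_datetime(rec["test_date"])
    assert dates.notna().all()
    # no within-cow duplicate test days
    assert not rec.duplicated(subset=["ear_tag", "test_date"]).any()


def test_generation_depth_of_relationships():
    """Pedigree oracle: mean relationship of a cow to its paternal half sibs
    is at least 0.25."""
    scen = _tiny()
    ped = simulate_pedigree(scen)
    A = build_A(ped)
    sire_of = {r.animal: r.sire for r in ped.records}
    last_gen = [r.animal for r in ped.records if r.birth_year == 2004 and r.sex == "F"]
    a, b = last_gen[0], None
    for cand in last_gen[1:]:
        if sire_of[cand] == sire_of[a]:
            b = cand
            break
    assert b is not None
    assert A.loc(a, b) >= 0.25 - 1e-12


def test_outlier_injection_bookkeeping():
    scen = _tiny(outlier_rate=0.05, seed=9)
    _, rec, truth = simulate_herd(scen)
    rows = truth.injected_outlier_rows
    assert len(rows) > 0
    assert (rec.loc[rows, "dmy_kg"] > 60).all()
    cleaned, report = clean(standardize(rec))
    outlier_stage = next(s for s in report.stages if "Outlier" in s.name)
    assert outlier_stage.records_removed == len(rows)


def test_duplicate_injection_bookkeeping():
    scen = _tiny(duplicate_rate=0.1, seed=4)
    _, rec, truth = simulate_herd(scen)
    n_dup = len(truth.injected_duplicate_rows)
    base = scen.n_cows_with_records * scen.records_per_cow
    assert len(rec) == base + n_dup
    _, report = clean(standardize(rec))
    dup_stage = next(s for s in report.stages if "Duplicate" in s.name)
    assert dup_stage.records_removed == n_dup


def test_missingness_injection():
    scen = _tiny(missingness_rate=0.2, seed=5)
    _, rec, _ = simulate_herd(scen)
    assert rec["fat_pct"].isna().mean() == pytest.approx(0.2, abs=0.06)
    assert rec["dmy_kg"].notna().all()


def test_scenario_round_trip():
    scen = _tiny(genetic_corr={("dmy_kg", "fat_pct"): -0.4})
    back = scenario_from_dict(scenario_to_dict(scen))
    assert back == scen


def test_generative_h2_values():
    for trait, (va, vm, vpe, ve) in DEFAULT_COMPONENTS.items():
        h2 = va / (va + vm + vpe + ve)
        assert h2 == pytest.approx(
            {"dmy_kg": 0.382, "fat_pct": 0.292, "protein_pct": 0.360}[trait],
            abs=5e-4)
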