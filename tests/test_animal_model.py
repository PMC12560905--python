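import numpy as np
import pandas as pd
import pytest

from lactaqg.animal_model import (
    AnimalModel,
    VarianceComponents,
    genetic_correlations,
    heritability,
    reml_fit,
    repeatability,
    stage_stratified_fit,
)
from lactaqg.fixed_effects import FixedEffectsSpec
from lactaqg.pedigree import build_A
from lactaqg.simulate import SimScenario, simulate_herd


def _herd(**kw):
    base = dict(seed=21, n_generations=3, males_per_gen=6, females_per_gen=40,
                sires_per_gen=5, n_cows_with_records=60, records_per_cow=4)
    base.update(kw)
    return simulate_herd(SimScenario(**base))


SPEC_PS = FixedEffectsSpec(factors=("parity", "season"))


# -- derived-parameter arithmetic -------------------------------------------


def test_heritability_and_repeatability_arithmetic():
    vc = VarianceComponents.from_scalars("dmy_kg", 0.449, 0.031, 0.288, 0.407)
    assert heritability(vc)["dmy_kg"] == pytest.approx(0.449 / 1.175)
    assert round(heritability(vc)["dmy_kg"], 3) == 0.382
    # repeatability counts additive + permanent environment in the numerator
    assert repeatability(vc)["dmy_kg"] == pytest.approx((0.449 + 0.288) / 1.175)


def test_genetic_correlation_arithmetic():
    cov = 0.551 * np.sqrt(0.165 * 0.068)
    vc = VarianceComponents(
        ("fat_pct", "protein_pct"),
        np.array([[0.165, cov], [cov, 0.068]]),
        np.diag([0.008, 0.003]), np.diag([0.092, 0.038]),
        np.diag([0.300, 0.080]))
    rg, rp = genetic_correlations(vc)
    assert rg.loc["fat_pct", "protein_pct"] == pytest.approx(0.551)
    assert abs(rp.loc["fat_pct", "protein_pct"]) < abs(
        rg.loc["fat_pct", "protein_pct"])


def test_variance_components_validation():
    with pytest.raises(ValueError, match="positive semidefinite"):
        VarianceComponents(("t",), [[-0.1]], [[0.0]], [[0.0]], [[1.0]])
    with pytest.raises(ValueError, match="1x1"):
        VarianceComponents(("t",), np.eye(2), [[0.0]], [[0.0]], [[1.0]])


# -- MME solutions against dense GLS/BLUP oracles ---------------------------


def test_mme_fixed_effects_match_dense_gls():
    ped, rec, _ = _herd()
    model = AnimalModel(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                        random=("a", "pe"))
    vc = VarianceComponents.from_scalars("dmy_kg", 0.45, 0.0, 0.29, 0.41)
    mme = model.build_mme(vc)

    A = build_A(ped).values
    W = model.W.toarray()
    sa, spe = model.effect_slices["a"], model.effect_slices["pe"]
    X = W[:, model.effect_slices["fixed"]]
    Za = W[:, sa]
    Zp = W[:, spe]
    V = (0.45 * Za @ A @ Za.T + 0.29 * Zp @ Zp.T
         + 0.41 * np.eye(model.n_records))
    Vi = np.linalg.inv(V)
    y = model.Y[:, 0]
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    np.testing.assert_allclose(mme.effects("fixed", "dmy_kg"), beta, atol=1e-8)

    # BLUP of breeding values: a_hat = sigma2_a A Za' V^-1 (y - X beta)
    a_hat = 0.45 * A @ Za.T @ Vi @ (y - X @ beta)
    np.testing.assert_allclose(mme.effects("a", "dmy_kg"), a_hat, atol=1e-8)


def test_restricted_likelihood_matches_dense_formula():
    ped, rec, _ = _herd(seed=22)
    model = AnimalModel(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                        random=("a", "pe"))
    vc = VarianceComponents.from_scalars("dmy_kg", 0.3, 0.0, 0.2, 0.5)
    m2ll = model.minus2_restricted_loglik(vc)

    A = build_A(ped).values
    W = model.W.toarray()
    X = W[:, model.effect_slices["fixed"]]
    Za = W[:, model.effect_slices["a"]]
    Zp = W[:, model.effect_slices["pe"]]
    V = 0.3 * Za @ A @ Za.T + 0.2 * Zp @ Zp.T + 0.5 * np.eye(model.n_records)
    Vi = np.linalg.inv(V)
    y = model.Y[:, 0]
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    dense = (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + y @ P @ y)
    assert m2ll == pytest.approx(dense, abs=1e-8)


def test_blup_shrinks_to_zero_with_vanishing_additive_variance():
    ped, rec, _ = _herd()
    model = AnimalModel(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                        random=("a",))
    vc = VarianceComponents.from_scalars("dmy_kg", 1e-8, 0.0, 0.0, 1.0)
    mme = model.build_mme(vc)
    assert np.abs(mme.effects("a", "dmy_kg")).max() < 1e-4


def test_mme_collapses_to_ols_without_genetic_signal():
    ped, rec, _ = _herd()
    model = AnimalModel(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                        random=("a",))
    vc = VarianceComponents.from_scalars("dmy_kg", 1e-10, 0.0, 0.0, 1.0)
    mme = model.build_mme(vc)
    X = model.W.toarray()[:, model.effect_slices["fixed"]]
    beta_ols, *_ = np.linalg.lstsq(X, model.Y[:, 0], rcond=None)
    np.testing.assert_allclose(mme.effects("fixed", "dmy_kg"), beta_ols, atol=1e-6)


# -- fitting behaviour -------------------------------------------------------


def test_h2_invariant_under_trait_rescaling():
    ped, rec, _ = _herd(seed=30)
    res1 = reml_fit(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                    random=("a", "pe"), compute_se=False)
    rec2 = rec.assign(dmy_kg=rec["dmy_kg"] * 2.0)
    res2 = reml_fit(rec2, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                    random=("a", "pe"), compute_se=False)
    assert res2.h2["dmy_kg"] == pytest.approx(res1.h2["dmy_kg"], abs=1e-8)
    # variances scale with the square of the unit change
    c1, c2 = res1.vc.for_trait("dmy_kg"), res2.vc.for_trait("dmy_kg")
    assert c2["sigma2_e"] == pytest.approx(4.0 * c1["sigma2_e"], rel=1e-6)


def test_standard_errors_are_finite_and_positive():
    ped, rec, _ = _herd(seed=31, n_cows_with_records=70)
    res = reml_fit(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                   random=("a", "pe"))
    assert res.h2_se["dmy_kg"] > 0
    ses = res.component_se()
    assert all(np.isfinite(v) for v in ses.values())
    frame = res.components_frame()
    assert {"sigma2_a", "h2", "h2_se", "repeatability"} <= set(frame.columns)


def test_summary_mentions_key_quantities():
    ped, rec, _ = _herd(seed=32)
    res = reml_fit(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                   random=("a", "pe"), compute_se=False)
    text = res.summary()
    assert "restricted log-likelihood" in text
    assert "h2" in text and "sigma2_a" in text


def test_breeding_values_indexed_by_pedigree():
    ped, rec, _ = _herd(seed=33)
    res = reml_fit(rec, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                   random=("a", "pe"), compute_se=False)
    ebv = res.breeding_values()
    assert list(ebv.index) == ped.ids
    assert np.isfinite(ebv.to_numpy()).all()


def test_stage_stratified_fits_partition_records():
    ped, rec, _ = _herd(seed=34, n_cows_with_records=80, records_per_cow=5)
    fits = stage_stratified_fit(rec, ped, traits=("dmy_kg",),
                                random=("a", "pe"), compute_se=False)
    assert set(fits) <= {"early", "mid", "late"}
    total = sum(f.model.n_records for f in fits.values())
    assert total == len(rec)
    for f in fits.values():
        assert 0.0 <= f.h2["dmy_kg"] <= 1.0


def test_recorded_animal_missing_from_pedigree_raises():
    ped, rec, _ = _herd()
    rec2 = pd.concat([rec, rec.iloc[[0]].assign(ear_tag="GHOST")],
                     ignore_index=True)
    with pytest.raises(ValueError, match="absent from pedigree"):
        AnimalModel(rec2, ped, traits=("dmy_kg",))


def test_additive_term_is_mandatory():
    ped, rec, _ = _herd()
    with pytest.raises(ValueError, match="mandatory"):
        AnimalModel(rec, ped, traits=("dmy_kg",), random=("pe",))


def test_phantom_dam_warning():
    # founder females have unknown dams -> maternal term needs phantoms
    ped, rec, _ = _herd()
    # give one record to a founder female (unknown dam)
    founder = next(r.animal for r in ped.records
                   if r.sex == "F" and not r.dam)
    extra = rec.iloc[[0]].assign(ear_tag=founder)
    rec2 = pd.concat([rec, extra], ignore_index=True)
    with pytest.warns(UserWarning, match="phantom"):
        AnimalModel(rec2, ped, traits=("dmy_kg",), fixed=SPEC_PS,
                    random=("a", "m"))
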