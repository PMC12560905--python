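"""Pedigree-based animal models estimated by REML.

The repeatability animal model fitted here is

    y = Xb + Z_a a + Z_m m + Z_pe p + e,
    a ~ N(0, Sigma_a x A),   m ~ N(0, Sigma_m x A_m),
    p ~ N(0, Sigma_pe x I),  e ~ N(0, Sigma_e x I),

with fixed effects b (parity, season, lactation stage, body-weight class),
additive genetic effects a over the whole pedigree with numerator
relationship matrix A, maternal genetic effects m indexed by the dam of the
recorded cow (covariance on the same pedigree; records whose cow has an
unknown dam get a phantom, unrelated dam level), cow-level
permanent-environment effects p, and i.i.d. residuals.  In multi-trait mode
every random term carries a trait-by-trait covariance matrix (Sigma_a etc.)
and the direct-maternal genetic covariance is fixed at zero.

Estimation maximises the restricted log-likelihood evaluated through the
sparse mixed-model equations,

    -2 l_R = log|R| + log|G| + log|C| + y' P y   (+ const),

profiling out the residual variance in single-trait mode (Nelder-Mead over
log variance ratios) and optimising Cholesky-parameterised covariance
matrices with L-BFGS-B in multi-trait mode.  Standard errors come from the
finite-difference observed-information matrix of the restricted likelihood;
heritability and correlation SEs use the delta method on it.

Usage::

    model = AnimalModel(records, pedigree, traits=("dmy_kg",))
    res = model.fit()
    res.summary()
    res.h2["dmy_kg"], res.h2_se["dmy_kg"], res.repeatability["dmy_kg"]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from .fixed_effects import FixedEffectsSpec, _design
from .pedigree import Pedigree, build_A_inverse, inbreeding

__all__ = [
    "AnimalModel", "AnimalModelResults", "VarianceComponents", "MMESystem",
    "build_mme", "reml_fit", "heritability", "repeatability",
    "genetic_correlations", "stage_stratified_fit",
]


def _factor(C):
    """Sparse LU tuned for the symmetric positive-definite MME matrix.

    Diagonal pivoting (``DiagPivotThresh: 0``) is both stable and fast for a
    positive-definite system: it keeps the fill-reducing symmetric ordering
    intact, so factorisation cost depends only on the sparsity pattern, not
    on the magnitudes that near-singular covariance components can inject.
    """
    return splu(C, permc_spec="MMD_AT_PLUS_A",
                options={"SymmetricMode": True, "DiagPivotThresh": 0.0})


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class VarianceComponents:
    """(Co)variance matrices of the model's random terms.

    Each matrix is trait-by-trait (1x1 in single-trait mode): ``cov_a``
    additive genetic, ``cov_m`` maternal genetic, ``cov_pe`` permanent
    environment, ``cov_e`` residual.  Terms absent from the fitted model
    carry zero matrices.
    """

    traits: tuple[str, ...]
    cov_a: np.ndarray
    cov_m: np.ndarray
    cov_pe: np.ndarray
    cov_e: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.traits)
        for name in ("cov_a", "cov_m", "cov_pe", "cov_e"):
            M = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if M.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{name} is not positive semidefinite")
            setattr(self, name, M)

    @classmethod
    def from_scalars(cls, trait: str, sigma2_a: float, sigma2_m: float = 0.0,
                     sigma2_pe: float = 0.0, sigma2_e: float = 1.0) -> "VarianceComponents":
        one = lambda v: np.array([[float(v)]])
        return cls((trait,), one(sigma2_a), one(sigma2_m), one(sigma2_pe), one(sigma2_e))

    def for_trait(self, trait: str) -> dict[str, float]:
        i = self.traits.index(trait)
        return {
            "sigma2_a": float(self.cov_a[i, i]),
            "sigma2_m": float(self.cov_m[i, i]),
            "sigma2_pe": float(self.cov_pe[i, i]),
            "sigma2_e": float(self.cov_e[i, i]),
        }

    def total(self, trait: str) -> float:
        return sum(self.for_trait(trait).values())


def heritability(vc: VarianceComponents, trait: str | None = None) -> dict[str, float]:
    """Narrow-sense heritability per trait:
    ``h2 = sigma2_a / (sigma2_a + sigma2_m + sigma2_pe + sigma2_e)``."""
    out = {}
    for t in ([trait] if trait else vc.traits):
        tot = vc.total(t)
        if tot <= 0:
            raise ValueError(f"zero total variance for {t}")
        out[t] = vc.for_trait(t)["sigma2_a"] / tot
    return out


def repeatability(vc: VarianceComponents, trait: str | None = None) -> dict[str, float]:
    """Repeatability per trait, the conventional
    ``r = (sigma2_a + sigma2_pe) / total`` (maternal variance in the
    denominator only)."""
    out = {}
    for t in ([trait] if trait else vc.traits):
        tot = vc.total(t)
        if tot <= 0:
            raise ValueError(f"zero total variance for {t}")
        c = vc.for_trait(t)
        out[t] = (c["sigma2_a"] + c["sigma2_pe"]) / tot
    return out


def genetic_correlations(vc: VarianceComponents) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genetic (rg, from the additive covariance) and phenotypic (rp, from
    the summed covariance) correlation matrices.  Pairs where either trait
    has zero additive variance are reported as missing."""
    k = len(vc.traits)
    P = vc.cov_a + vc.cov_m + vc.cov_pe + vc.cov_e
    rg = np.full((k, k), np.nan)
    rp = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if vc.cov_a[i, i] > 0 and vc.cov_a[j, j] > 0:
                rg[i, j] = vc.cov_a[i, j] / np.sqrt(vc.cov_a[i, i] * vc.cov_a[j, j])
            if P[i, i] > 0 and P[j, j] > 0:
                rp[i, j] = P[i, j] / np.sqrt(P[i, i] * P[j, j])
    t = list(vc.traits)
    return (pd.DataFrame(rg, index=t, columns=t),
            pd.DataFrame(rp, index=t, columns=t))


@dataclass
class MMESystem:
    """Henderson's mixed-model equations at a given set of components."""

    coefficient: sp.csr_matrix
    rhs: np.ndarray
    solution: np.ndarray
    effect_slices: dict[str, slice]
    traits: tuple[str, ...]
    n_columns_per_trait: int

    def effects(self, term: str, trait: str) -> np.ndarray:
        t = self.traits.index(trait)
        s = self.effect_slices[term]
        off = t * self.n_columns_per_trait
        return self.solution[off + s.start: off + s.stop]


class AnimalModel:
    """Single- or multi-trait repeatability animal model on test-day records.

    Parameters
    ----------
    data : DataFrame of cleaned test-day records (one row per cow-day) with
        the trait columns, ``ear_tag``, and the fixed-effect source columns
        (``parity``, ``season``, ``dim``, ``bw_kg``).
    pedigree : the Pedigree covering every recorded cow.
    traits : trait column names (1 = univariate, >=2 = multi-trait).
    fixed : FixedEffectsSpec for the fixed part (default: parity + season +
        lactation stage + body-weight class).
    random : subset of {"a", "m", "pe"}; the additive term is mandatory.
    """

    def __init__(self, data: pd.DataFrame, pedigree: Pedigree,
                 traits=("dmy_kg",), fixed: FixedEffectsSpec | None = None,
                 random=("a", "m", "pe")):
        self.traits = tuple(traits)
        if not self.traits:
            raise ValueError("at least one trait required")
        self.random = tuple(random)
        if "a" not in self.random:
            raise ValueError("the additive genetic term is mandatory")
        self.pedigree = pedigree
        self.fixed_spec = fixed or FixedEffectsSpec()

        df = data.copy()
        missing = sorted(set(df["ear_tag"].astype(str)) - set(pedigree.index))
        if missing:
            raise ValueError(
                f"{len(missing)} recorded animal(s) absent from pedigree: "
                + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""))

        factors = self.fixed_spec.factor_frame(df)
        Y = df[list(self.traits)].apply(pd.to_numeric, errors="coerce")
        keep = Y.notna().all(axis=1) & factors.notna().all(axis=1)
        df, factors, Y = df.loc[keep], factors.loc[keep], Y.loc[keep]
        factors = factors.apply(lambda s: s.cat.remove_unused_categories())
        self.records = df.reset_index(drop=True)

        X, _ = _design(factors)
        n = X.shape[0]
        self.n_records = n
        self.n_fixed = X.shape[1]
        self.Y = Y.to_numpy(float)

        q = len(pedigree)
        animal_pos = self.records["ear_tag"].astype(str).map(pedigree.index).to_numpy()
        Za = sp.coo_matrix((np.ones(n), (np.arange(n), animal_pos)), shape=(n, q)).tocsr()

        blocks = [sp.csr_matrix(X)]
        slices = {"fixed": slice(0, self.n_fixed)}
        offset = self.n_fixed
        prior_mats: dict[str, sp.csr_matrix] = {}
        logdets: dict[str, float] = {}
        sizes: dict[str, int] = {}

        Ainv = build_A_inverse(pedigree)
        logdet_A = -_sparse_logdet(Ainv)

        blocks.append(Za)
        slices["a"] = slice(offset, offset + q)
        prior_mats["a"] = Ainv
        logdets["a"] = logdet_A
        sizes["a"] = q
        offset += q

        if "m" in self.random:
            dam_of = {r.animal: r.dam for r in pedigree.records}
            dams = self.records["ear_tag"].astype(str).map(dam_of)
            phantom_ids = sorted(self.records.loc[dams == "", "ear_tag"].astype(str).unique())
            if phantom_ids:
                warnings.warn(
                    f"{len(phantom_ids)} recorded cow(s) have an unknown dam; "
                    "their maternal effect uses a phantom unrelated dam")
            phantom_index = {c: q + i for i, c in enumerate(phantom_ids)}
            qm = q + len(phantom_ids)
            cols = [
                pedigree.index[d] if d else phantom_index[c]
                for c, d in zip(self.records["ear_tag"].astype(str), dams)
            ]
            Zm = sp.coo_matrix((np.ones(n), (np.arange(n), cols)), shape=(n, qm)).tocsr()
            Am_inv = sp.block_diag([Ainv, sp.identity(len(phantom_ids))]).tocsr() \
                if phantom_ids else Ainv
            blocks.append(Zm)
            slices["m"] = slice(offset, offset + qm)
            prior_mats["m"] = Am_inv
            logdets["m"] = logdet_A
            sizes["m"] = qm
            offset += qm

        if "pe" in self.random:
            cows = self.records["ear_tag"].astype(str)
            cow_levels = pd.Categorical(cows)
            c = len(cow_levels.categories)
            Zp = sp.coo_matrix((np.ones(n), (np.arange(n), cow_levels.codes)),
                               shape=(n, c)).tocsr()
            blocks.append(Zp)
            slices["pe"] = slice(offset, offset + c)
            prior_mats["pe"] = sp.identity(c, format="csr")
            logdets["pe"] = 0.0
            sizes["pe"] = c
            offset += c
            per_cow = n / c
            if per_cow < 2:
                warnings.warn(
                    f"average {per_cow:.2f} records per cow; the permanent-"
                    "environment variance is weakly identified below 2")

        self.effect_slices = slices
        self.term_sizes = sizes
        self.term_logdets = logdets
        self.ncol = offset
        W = sp.hstack(blocks).tocsr()
        self.W = W
        self.WtW = (W.T @ W).tocsr()
        self.WtY = np.asarray(W.T @ self.Y)            # (ncol, k)
        self.YtY = self.Y.T @ self.Y                   # (k, k)
        # zero-padded prior matrices: Sigma^{-1} (kron) B adds the G^{-1} block
        self._padded: dict[str, sp.csr_matrix] = {}
        for term, M in prior_mats.items():
            P = sp.lil_matrix((self.ncol, self.ncol))
            s = slices[term]
            P[s, s] = M
            self._padded[term] = P.tocsr()

    # -- restricted likelihood --------------------------------------------

    def _assemble(self, Einv: np.ndarray, term_invs: dict[str, np.ndarray]):
        C = sp.kron(sp.csr_matrix(Einv), self.WtW)
        for term, Sinv in term_invs.items():
            C = C + sp.kron(sp.csr_matrix(Sinv), self._padded[term])
        rhs = (np.asarray(Einv) @ self.WtY.T).ravel()
        return C.tocsc(), rhs

    def minus2_restricted_loglik(self, vc: VarianceComponents,
                                 return_solution: bool = False):
        """-2 restricted log-likelihood (without the 2 pi constant) at ``vc``."""
        k = len(self.traits)
        if np.linalg.cond(vc.cov_e) > 1e12:
            raise np.linalg.LinAlgError("cov_e is numerically singular")
        Einv = np.linalg.inv(vc.cov_e)
        m2ll = self.n_records * _logdet_psd(vc.cov_e)
        term_invs = {}
        for term in self.effect_slices:
            if term == "fixed":
                continue
            S = {"a": vc.cov_a, "m": vc.cov_m, "pe": vc.cov_pe}[term]
            if np.linalg.cond(S) > 1e12:
                raise np.linalg.LinAlgError(
                    f"cov_{term} is numerically singular")
            term_invs[term] = np.linalg.inv(S)
            m2ll += self.term_sizes[term] * _logdet_psd(S) + k * self.term_logdets[term]
        C, rhs = self._assemble(Einv, term_invs)
        lu = _factor(C)
        logdet_C = float(np.log(np.abs(lu.U.diagonal())).sum())
        sol = lu.solve(rhs)
        yRy = float(np.sum(Einv * self.YtY))
        ypy = yRy - float(sol @ rhs)
        # y'Py is a non-negative quadratic form; a negative value (or a
        # non-finite likelihood) can only come from numerical breakdown of
        # the factorisation and must not be mistaken for a high likelihood
        m2ll += logdet_C + ypy
        if ypy < -1e-6 * max(1.0, abs(yRy)) or not np.isfinite(m2ll):
            raise np.linalg.LinAlgError(
                "numerical breakdown in restricted-likelihood evaluation")
        if return_solution:
            return m2ll, sol
        return m2ll

    def _profiled_m2ll_univariate(self, gammas: dict[str, float],
                                  return_aux: bool = False):
        """Profiled -2 l_R over variance ratios gamma = sigma2_x / sigma2_e."""
        C = self.WtW.copy()
        logdet_G = 0.0
        for term, g in gammas.items():
            C = C + self._padded[term] / g
            logdet_G += self.term_sizes[term] * np.log(g) + self.term_logdets[term]
        lu = _factor(C.tocsc())
        logdet_C = float(np.log(np.abs(lu.U.diagonal())).sum())
        rhs = self.WtY[:, 0]
        sol = lu.solve(rhs)
        ypy = float(self.YtY[0, 0] - sol @ rhs)
        if ypy <= 0:
            raise np.linalg.LinAlgError(
                "numerical breakdown in restricted-likelihood evaluation")
        nu = self.n_records - self.n_fixed
        sigma2_e = ypy / nu
        m2ll = nu * np.log(sigma2_e) + logdet_C + logdet_G + nu
        if return_aux:
            return m2ll, sigma2_e, sol
        return m2ll

    # -- fitting -----------------------------------------------------------

    def fit(self, init: VarianceComponents | None = None, compute_se: bool = True,
            maxiter: int = 2000, options: dict | None = None) -> "AnimalModelResults":
        if self.n_records <= self.n_fixed:
            raise ValueError("fewer records than fixed-effect parameters")
        if len(self.traits) == 1:
            return self._fit_univariate(init, compute_se, maxiter, options)
        return self._fit_multitrait(init, compute_se, maxiter, options)

    def _fit_univariate(self, init, compute_se, maxiter, options):
        terms = [t for t in ("a", "m", "pe") if t in self.effect_slices]
        y = self.Y[:, 0]
        var_y = float(np.var(y, ddof=1))
        if init is not None:
            c = init.for_trait(self.traits[0])
            se0 = max(c["sigma2_e"], 1e-8 * var_y)
            x0 = np.log([max(c[f"sigma2_{t}"], 1e-4 * se0) / se0 for t in terms])
        else:
            x0 = np.log(np.full(len(terms), 0.3))
        LO, HI = -14.0, 8.0

        def objective(x):
            xc = np.clip(x, LO, HI)
            penalty = 1e4 * float(np.sum((x - xc) ** 2))
            g = {t: float(np.exp(v)) for t, v in zip(terms, xc)}
            try:
                return self._profiled_m2ll_univariate(g) + penalty
            except (np.linalg.LinAlgError, RuntimeError):
                return 1e12

        opts = {"xatol": 1e-3, "fatol": 1e-4, "maxiter": maxiter, "maxfev": maxiter}
        if options:
            opts.update(options)
        res = minimize(objective, x0, method="Nelder-Mead", options=opts)
        xhat = np.clip(res.x, LO, HI)
        gam = {t: float(np.exp(v)) for t, v in zip(terms, xhat)}
        m2ll, sigma2_e, sol = self._profiled_m2ll_univariate(gam, return_aux=True)
        comp = {f"sigma2_{t}": gam.get(t, 0.0) * sigma2_e for t in ("a", "m", "pe")}
        vc = VarianceComponents.from_scalars(self.traits[0], comp["sigma2_a"],
                                            comp["sigma2_m"], comp["sigma2_pe"],
                                            sigma2_e)
        if not res.success:
            warnings.warn("REML did not converge within the iteration budget; "
                          "returning the best point found", ConvergenceWarning)
        return self._build_results(vc, m2ll, res, compute_se, sol)

    def _fit_multitrait(self, init, compute_se, maxiter, options):
        k = len(self.traits)
        terms = [t for t in ("a", "m", "pe") if t in self.effect_slices] + ["e"]
        if init is None:
            init = self._default_multitrait_init()
        mats0 = {"a": init.cov_a, "m": init.cov_m, "pe": init.cov_pe, "e": init.cov_e}
        x0 = np.concatenate([_chol_param(mats0[t], ridge=1e-4 * np.trace(mats0["e"]))
                             for t in terms])
        nper = k * (k + 1) // 2

        def unpack(x):
            out = {}
            for i, t in enumerate(terms):
                out[t] = _chol_unparam(x[i * nper:(i + 1) * nper], k)
            return out

        def objective(x):
            try:
                m = unpack(x)
                vc = VarianceComponents(self.traits, m["a"],
                                        m.get("m", np.zeros((k, k))),
                                        m.get("pe", np.zeros((k, k))), m["e"])
                return self.minus2_restricted_loglik(vc)
            except (np.linalg.LinAlgError, RuntimeError, ValueError):
                return 1e12

        opts = {"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6}
        if options:
            opts.update(options)
        # keep the Cholesky factors in a numerically sane range: log-diagonals
        # within [-12, 12], off-diagonal entries bounded by the same scale
        bounds = []
        for _ in terms:
            for i in range(k):
                for j in range(i + 1):
                    bounds.append((-12.0, 12.0) if i == j else (-1e3, 1e3))
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options=opts)
        m = unpack(res.x)
        vc = VarianceComponents(self.traits, m["a"], m.get("m", np.zeros((k, k))),
                                m.get("pe", np.zeros((k, k))), m["e"])
        m2ll, sol = self.minus2_restricted_loglik(vc, return_solution=True)
        if not res.success:
            warnings.warn("multi-trait REML did not converge within the "
                          "iteration budget; returning the best point found",
                          ConvergenceWarning)
        return self._build_results(vc, m2ll, res, compute_se, sol)

    def _default_multitrait_init(self) -> VarianceComponents:
        """Univariate fits for the diagonals; phenotypic-correlation-based
        initial guesses for the additive and residual covariances."""
        k = len(self.traits)
        diag = {}
        for t in self.traits:
            sub = AnimalModel(self.records, self.pedigree, traits=(t,),
                              fixed=self.fixed_spec, random=self.random)
            r = sub.fit(compute_se=False)
            diag[t] = r.vc.for_trait(t)
        Rphen = np.corrcoef(self.Y.T)
        mats = {}
        for term in ("a", "m", "pe", "e"):
            V = np.zeros((k, k))
            for i, t in enumerate(self.traits):
                V[i, i] = max(diag[t][f"sigma2_{term}"], 1e-8)
            if term in ("a", "e"):
                for i in range(k):
                    for j in range(i + 1, k):
                        # start the cross-covariances at half the phenotypic
                        # correlation to stay inside the PSD cone
                        V[i, j] = V[j, i] = 0.5 * Rphen[i, j] * np.sqrt(V[i, i] * V[j, j])
            mats[term] = V
        return VarianceComponents(self.traits, mats["a"], mats["m"], mats["pe"], mats["e"])

    # -- results -----------------------------------------------------------

    def _build_results(self, vc, m2ll, opt_res, compute_se, solution):
        se_info = None
        if compute_se:
            se_info = self._observed_information(vc)
        return AnimalModelResults(model=self, vc=vc, m2ll=float(m2ll),
                                  converged=bool(opt_res.success),
                                  n_evaluations=int(opt_res.get("nfev", 0))
                                  if isinstance(opt_res, dict) else int(opt_res.nfev),
                                  solution=np.asarray(solution),
                                  information=se_info)

    def _active_param_labels(self) -> list[tuple[str, int, int]]:
        k = len(self.traits)
        labels = []
        for term in ("a", "m", "pe", "e"):
            if term != "e" and term not in self.effect_slices:
                continue
            for i in range(k):
                for j in range(i, k):
                    labels.append((term, i, j))
        return labels

    def _vc_to_vector(self, vc: VarianceComponents) -> np.ndarray:
        mats = {"a": vc.cov_a, "m": vc.cov_m, "pe": vc.cov_pe, "e": vc.cov_e}
        return np.array([mats[t][i, j] for t, i, j in self._active_param_labels()])

    def _vector_to_vc(self, x: np.ndarray) -> VarianceComponents:
        k = len(self.traits)
        mats = {t: np.zeros((k, k)) for t in ("a", "m", "pe", "e")}
        for v, (t, i, j) in zip(x, self._active_param_labels()):
            mats[t][i, j] = mats[t][j, i] = v
        return VarianceComponents(self.traits, mats["a"], mats["m"], mats["pe"], mats["e"])

    def _observed_information(self, vc: VarianceComponents):
        """Finite-difference Hessian of -2 l_R over the active components;
        the inverse of half of it estimates the sampling covariance of the
        REML estimates (the average-information role)."""
        x0 = self._vc_to_vector(vc)
        labels = self._active_param_labels()
        npar = len(x0)
        steps = np.maximum(1e-5, 1e-4 * np.abs(x0))

        def f(x):
            try:
                trial = self._vector_to_vc(x)
            except ValueError:
                return np.nan
            try:
                return self.minus2_restricted_loglik(trial)
            except (np.linalg.LinAlgError, RuntimeError):
                return np.nan

        H = np.full((npar, npar), np.nan)
        f0 = f(x0)
        fp = np.empty(npar)
        fm = np.empty(npar)
        for i in range(npar):
            ei = np.zeros(npar)
            ei[i] = steps[i]
            fp[i], fm[i] = f(x0 + ei), f(x0 - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
        for i in range(npar):
            for j in range(i + 1, npar):
                ei = np.zeros(npar); ei[i] = steps[i]
                ej = np.zeros(npar); ej[j] = steps[j]
                fpp = f(x0 + ei + ej)
                fmm = f(x0 - ei - ej)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * steps[i] * steps[j])
        with np.errstate(all="ignore"):
            info = 0.5 * np.where(np.isnan(H), 0.0, H)
            cov = np.linalg.pinv(info)
        return {"labels": labels, "hessian_m2ll": H, "cov": cov}

    # -- MME access --------------------------------------------------------

    def build_mme(self, vc: VarianceComponents) -> MMESystem:
        """Assemble and solve Henderson's equations at fixed components."""
        k = len(self.traits)
        Einv = np.linalg.inv(vc.cov_e)
        term_invs = {}
        for term in self.effect_slices:
            if term == "fixed":
                continue
            S = {"a": vc.cov_a, "m": vc.cov_m, "pe": vc.cov_pe}[term]
            term_invs[term] = np.linalg.inv(S)
        C, rhs = self._assemble(Einv, term_invs)
        sol = _factor(C).solve(rhs)
        return MMESystem(coefficient=C.tocsr(), rhs=rhs, solution=sol,
                         effect_slices=self.effect_slices, traits=self.traits,
                         n_columns_per_trait=self.ncol)


def _sparse_logdet(M: sp.spmatrix) -> float:
    lu = _factor(M.tocsc())
    return float(np.log(np.abs(lu.U.diagonal())).sum())


def _logdet_psd(M: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    return float(val)


def _chol_param(V: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Lower-Cholesky parameters (log diagonal, free off-diagonal)."""
    k = V.shape[0]
    L = np.linalg.cholesky(V + ridge * np.eye(k))
    out = []
    for i in range(k):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _chol_unparam(x: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(min(x[idx], 30.0)) if i == j else x[idx]
            idx += 1
    return L @ L.T


@dataclass
class AnimalModelResults:
    """REML estimates with uncertainties and derived genetic parameters."""

    model: AnimalModel
    vc: VarianceComponents
    m2ll: float
    converged: bool
    n_evaluations: int
    solution: np.ndarray
    information: dict | None = None

    @property
    def loglik(self) -> float:
        nu = self.model.n_records * len(self.model.traits) - \
            self.model.n_fixed * len(self.model.traits)
        return -0.5 * (self.m2ll + nu * np.log(2 * np.pi))

    @property
    def h2(self) -> dict[str, float]:
        return heritability(self.vc)

    @property
    def repeatability(self) -> dict[str, float]:
        return repeatability(self.vc)

    @property
    def rg(self) -> pd.DataFrame:
        return genetic_correlations(self.vc)[0]

    @property
    def rp(self) -> pd.DataFrame:
        return genetic_correlations(self.vc)[1]

    def component_se(self) -> dict[tuple[str, int, int], float]:
        if self.information is None:
            raise ValueError("fit with compute_se=True to obtain SEs")
        cov = self.information["cov"]
        return {lab: float(np.sqrt(max(cov[i, i], 0.0)))
                for i, lab in enumerate(self.information["labels"])}

    @property
    def h2_se(self) -> dict[str, float]:
        """Delta-method SE of h2 from the observed-information covariance."""
        if self.information is None:
            raise ValueError("fit with compute_se=True to obtain SEs")
        labels = self.information["labels"]
        cov = self.information["cov"]
        out = {}
        for ti, trait in enumerate(self.vc.traits):
            comp = self.vc.for_trait(trait)
            tot = sum(comp.values())
            va = comp["sigma2_a"]
            grad = np.zeros(len(labels))
            for i, (term, a, b) in enumerate(labels):
                if a == ti and b == ti:
                    grad[i] = ((tot - va) / tot ** 2 if term == "a" else -va / tot ** 2)
            out[trait] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        return out

    @property
    def rg_se(self) -> pd.DataFrame:
        """Delta-method SEs of the genetic correlations."""
        if self.information is None:
            raise ValueError("fit with compute_se=True to obtain SEs")
        labels = self.information["labels"]
        cov = self.information["cov"]
        k = len(self.vc.traits)
        out = np.full((k, k), np.nan)
        A = self.vc.cov_a
        for i in range(k):
            for j in range(i + 1, k):
                if A[i, i] <= 0 or A[j, j] <= 0:
                    continue
                r = A[i, j] / np.sqrt(A[i, i] * A[j, j])
                grad = np.zeros(len(labels))
                for idx, (term, a, b) in enumerate(labels):
                    if term != "a":
                        continue
                    if (a, b) in ((i, j), (j, i)):
                        grad[idx] = 1.0 / np.sqrt(A[i, i] * A[j, j])
                    elif (a, b) == (i, i):
                        grad[idx] = -0.5 * r / A[i, i]
                    elif (a, b) == (j, j):
                        grad[idx] = -0.5 * r / A[j, j]
                out[i, j] = out[j, i] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        t = list(self.vc.traits)
        return pd.DataFrame(out, index=t, columns=t)

    def breeding_values(self, trait: str | None = None) -> pd.Series:
        """Predicted additive genetic effects (BLUP) for every pedigree animal."""
        trait = trait or self.model.traits[0]
        t = self.model.traits.index(trait)
        s = self.model.effect_slices["a"]
        off = t * self.model.ncol
        return pd.Series(self.solution[off + s.start: off + s.stop],
                         index=self.model.pedigree.ids, name=f"ebv_{trait}")

    def components_frame(self) -> pd.DataFrame:
        rows = []
        ses = self.component_se() if self.information is not None else {}
        for trait in self.vc.traits:
            ti = self.vc.traits.index(trait)
            c = self.vc.for_trait(trait)
            rows.append({
                "trait": trait, **c,
                "h2": self.h2[trait], "repeatability": self.repeatability[trait],
                "h2_se": self.h2_se[trait] if self.information is not None else np.nan,
                "sigma2_a_se": ses.get(("a", ti, ti), np.nan),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Animal model REML fit",
            "=" * 64,
            f"traits: {', '.join(self.vc.traits)}",
            f"records: {self.model.n_records}   pedigree: {len(self.model.pedigree)}"
            f"   fixed params: {self.model.n_fixed}",
            f"random terms: {', '.join(t for t in self.model.effect_slices if t != 'fixed')}",
            f"restricted log-likelihood: {self.loglik:.4f}   "
            f"converged: {self.converged}   evaluations: {self.n_evaluations}",
            "-" * 64,
            self.components_frame().to_string(index=False,
                                              float_format=lambda v: f"{v:.4f}"),
        ]
        if len(self.vc.traits) > 1:
            lines += ["-" * 64, "genetic correlations (rg):",
                      self.rg.to_string(float_format=lambda v: f"{v:.3f}"),
                      "phenotypic correlations (rp):",
                      self.rp.to_string(float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "traits": list(self.vc.traits),
            "components": {t: self.vc.for_trait(t) for t in self.vc.traits},
            "h2": self.h2, "repeatability": self.repeatability,
            "loglik": self.loglik, "converged": self.converged,
            "n_evaluations": self.n_evaluations,
        }
        if self.information is not None:
            out["h2_se"] = self.h2_se
        if len(self.vc.traits) > 1:
            out["rg"] = self.rg.to_dict()
            out["rp"] = self.rp.to_dict()
        return out


# -- functional wrappers mirroring the pipeline vocabulary ------------------


def build_mme(records, ped, spec_or_model, vc: VarianceComponents) -> MMESystem:
    """Assemble and solve the mixed-model equations at fixed components."""
    if isinstance(spec_or_model, AnimalModel):
        return spec_or_model.build_mme(vc)
    model = AnimalModel(records, ped, traits=vc.traits, **(spec_or_model or {}))
    return model.build_mme(vc)


def reml_fit(records, ped, traits=("dmy_kg",), init=None, random=("a", "m", "pe"),
             fixed=None, compute_se=True, **options) -> AnimalModelResults:
    model = AnimalModel(records, ped, traits=traits, fixed=fixed, random=random)
    return model.fit(init=init, compute_se=compute_se, **options)


def stage_stratified_fit(records: pd.DataFrame, ped, traits=("dmy_kg",),
                         stages=("early", "mid", "late"), **kwargs
                         ) -> dict[str, AnimalModelResults]:
    """Independent REML fits per lactation stage (early <=100 d, mid
    101-200 d, late >=201 d); empty stages are skipped with a warning."""
    from .fixed_effects import dim_stage

    stage_col = dim_stage(records["dim"])
    # the stage factor is constant within a stratum, so it leaves the model
    fixed = kwargs.pop("fixed", None) or FixedEffectsSpec(
        factors=("parity", "season", "bw_class"))
    out = {}
    for stage in stages:
        sub = records.loc[np.asarray(stage_col == stage)]
        if sub.empty:
            warnings.warn(f"lactation stage {stage!r} has no records; skipped")
            continue
        out[stage] = reml_fit(sub, ped, traits=traits, fixed=fixed, **kwargs)
    return out
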