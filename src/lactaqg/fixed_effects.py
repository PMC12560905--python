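"""Non-genetic (fixed) effects on test-day traits.

Least-squares means per factor level under an additive OLS model with
equal-weight averaging over the other factors (classical LSMEANS),
Bonferroni-adjusted pairwise comparisons rendered as a compact letter
display, variance-inflation diagnostics for the body-weight covariates, and
the early-to-mid lactation prediction regression.

Factors follow dairy test-day conventions: parity pooled at 1, 2, 3, 4 and
>=5; calendar seasons (spring Mar-May, summer Jun-Aug, fall Sep-Nov, winter
Dec-Feb); lactation stage early (<=100 d), mid (101-200 d), late (>=201 d);
and six mature-body-weight classes with edges at 500/550/600/650/700 kg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PARITY_LEVELS = ("1", "2", "3", "4", ">=5")
SEASON_LEVELS = ("spring", "summer", "fall", "winter")
STAGE_LEVELS = ("early", "mid", "late")
DEFAULT_BW_EDGES = (500.0, 550.0, 600.0, 650.0, 700.0)


def parity_class(parity) -> pd.Categorical:
    p = pd.to_numeric(pd.Series(parity), errors="coerce")
    lab = np.where(p >= 5, ">=5", p.astype("Int64").astype(str))
    return pd.Categorical(lab, categories=PARITY_LEVELS, ordered=True)


def dim_stage(dim) -> pd.Categorical:
    d = pd.to_numeric(pd.Series(dim), errors="coerce")
    lab = np.where(d <= 100, "early", np.where(d <= 200, "mid", "late"))
    return pd.Categorical(lab, categories=STAGE_LEVELS, ordered=True)


def bw_class(bw_kg, edges=DEFAULT_BW_EDGES) -> pd.Categorical:
    b = pd.to_numeric(pd.Series(bw_kg), errors="coerce")
    edges = tuple(edges)
    labels = [f"<= {edges[0]:g}"] + [
        f"({lo:g}, {hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f"> {edges[-1]:g}"]
    idx = np.searchsorted(np.asarray(edges), b.to_numpy())
    lab = np.asarray(labels, dtype=object)[idx]
    return pd.Categorical(lab, categories=labels, ordered=True)


@dataclass
class FixedEffectsSpec:
    """Which factors enter the additive model, and their level definitions."""

    factors: tuple[str, ...] = ("parity", "season", "dim_stage", "bw_class")
    bw_edges: tuple[float, ...] = DEFAULT_BW_EDGES

    def factor_frame(self, records: pd.DataFrame) -> pd.DataFrame:
        """Categorical factor columns derived from a cleaned record table."""
        out = pd.DataFrame(index=records.index)
        builders = {
            "parity": lambda: parity_class(records["parity"]),
            "season": lambda: pd.Categorical(
                records["season"].astype(str), categories=SEASON_LEVELS),
            "dim_stage": lambda: dim_stage(records["dim"]),
            "bw_class": lambda: bw_class(records["bw_kg"], self.bw_edges),
        }
        for f in self.factors:
            out[f] = builders[f]()
        return out


@dataclass
class LsmRow:
    factor: str
    level: str
    n: int
    lsm: float
    se: float
    letters: str


@dataclass
class LsmTable:
    trait: str
    rows: list[LsmRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        df.insert(0, "trait", self.trait)
        return df


def _design(factors: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Treatment-coded design matrix with intercept; returns column map."""
    cols: dict[tuple[str, str], int] = {}
    mats = [np.ones((len(factors), 1))]
    j = 1
    for f in factors.columns:
        cat = factors[f].cat.remove_unused_categories()
        levels = list(cat.cat.categories)
        dummies = pd.get_dummies(cat).reindex(columns=levels).to_numpy(float)
        for lev in levels[1:]:
            cols[(f, lev)] = j
            mats.append(dummies[:, [levels.index(lev)]])
            j += 1
    return np.hstack(mats), cols


def fit_lsm(records: pd.DataFrame, spec: FixedEffectsSpec, trait: str,
            alpha: float = 0.05, allow_empty_levels: bool = False) -> LsmTable:
    """Least-squares means with Bonferroni letter groups for every factor.

    LSM of a level is the model prediction at that level averaged with equal
    weight over the levels of every other factor.  Pairwise within-factor
    contrasts are t-tests on the OLS fit, Bonferroni-multiplied by the
    number of pairs in that factor.
    """
    factors = spec.factor_frame(records)
    y = pd.to_numeric(records[trait], errors="coerce")
    keep = y.notna() & factors.notna().all(axis=1)
    y = y[keep].to_numpy(float)
    factors = factors.loc[keep]

    present = {f: list(factors[f].cat.remove_unused_categories().cat.categories)
               for f in factors.columns}
    declared = {f: list(factors[f].cat.categories) for f in factors.columns}
    for f in factors.columns:
        empty = set(declared[f]) - set(present[f])
        if empty:
            if not allow_empty_levels:
                raise ValueError(f"factor {f!r} has empty level(s): {sorted(empty)}")
            warnings.warn(f"factor {f!r}: dropping empty level(s) {sorted(empty)}")

    X, colmap = _design(factors)
    n, p = X.shape
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < p:
        raise ValueError("rank-deficient fixed-effects design beyond factor aliasing")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(resid @ resid) / dof

    def lsm_vector(factor: str, level: str) -> np.ndarray:
        """Equal-weight prediction row for one factor level."""
        v = np.zeros(p)
        v[0] = 1.0
        for g in factors.columns:
            levels = present[g]
            if g == factor:
                if level != levels[0]:
                    v[colmap[(g, level)]] = 1.0
            else:
                w = 1.0 / len(levels)
                for lev in levels[1:]:
                    v[colmap[(g, lev)]] = w
        return v

    table = LsmTable(trait=trait)
    for f in factors.columns:
        levels = present[f]
        L = np.array([lsm_vector(f, lev) for lev in levels])
        est = L @ beta
        ses = np.sqrt(np.einsum("ij,jk,ik->i", L, XtX_inv, L) * s2)
        # Bonferroni-adjusted pairwise p-values
        k = len(levels)
        pmat = np.ones((k, k))
        n_pairs = k * (k - 1) // 2
        for i, j in itertools.combinations(range(k), 2):
            c = L[i] - L[j]
            se_d = np.sqrt(float(c @ XtX_inv @ c) * s2)
            t = (est[i] - est[j]) / se_d if se_d > 0 else 0.0
            praw = 2.0 * stats.t.sf(abs(t), dof)
            pmat[i, j] = pmat[j, i] = min(1.0, praw * n_pairs)
        letters = letter_display(pmat, est, alpha=alpha)
        counts = factors[f].value_counts()
        for i, lev in enumerate(levels):
            table.rows.append(LsmRow(f, str(lev), int(counts[lev]),
                                     float(est[i]), float(ses[i]), letters[i]))
    return table


def letter_display(p_adjusted: np.ndarray, means=None, alpha: float = 0.05) -> list[str]:
    """Compact letter display (insert-and-absorb).

    Distinct letters mark significantly different pairs (adjusted p < alpha);
    letters are assigned in descending-mean order so the largest mean gets
    'A', making the output invariant to level input order.
    """
    P = np.asarray(p_adjusted, dtype=float)
    k = P.shape[0]
    order = list(np.argsort(-np.asarray(means))) if means is not None else list(range(k))
    pos = {lev: r for r, lev in enumerate(order)}

    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if P[i, j] < alpha:
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.extend([col - {i}, col - {j}])
            # absorb columns that became subsets of others
            columns = [c for c in columns
                       if c and not any(c < o for o in columns if o is not c)]
    # deduplicate and order columns by their highest-ranked member
    uniq: list[set[int]] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min(pos[m] for m in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for lev in range(k):
        out.append("".join(alphabet[ci] for ci, c in enumerate(uniq) if lev in c))
    return out


@dataclass
class DiagnosticsReport:
    vif: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def compute_vif(design: pd.DataFrame) -> DiagnosticsReport:
    """Variance inflation factors: ``VIF_j = 1 / (1 - R2_j)`` from regressing
    covariate j on the remaining covariates (with intercept)."""
    df = design.apply(pd.to_numeric, errors="coerce").dropna()
    if df.shape[1] < 2:
        raise ValueError("VIF needs at least two covariate columns")
    report = DiagnosticsReport(vif={})
    for col in df.columns:
        yj = df[col].to_numpy(float)
        Xo = np.column_stack([np.ones(len(df))] +
                             [df[c].to_numpy(float) for c in df.columns if c != col])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            report.vif[col] = float("inf")
            msg = f"perfect collinearity: {col} is an exact combination of the others"
            report.warnings.append(msg)
            warnings.warn(msg)
        else:
            report.vif[col] = float(1.0 / (1.0 - r2))
    return report


EARLY_PREDICTORS = ("dmy_kg", "my_morn_kg", "my_noon_kg", "my_night_kg",
                    "fat_pct", "protein_pct")


def predict_mid_from_early(records: pd.DataFrame,
                           predictors=EARLY_PREDICTORS) -> dict:
    """Regress mid-lactation mean daily yield on early-lactation traits.

    Cows contribute one row each: the response is their mean daily milk
    yield over days 101-200, predictors are their early (<=100 d) trait
    means.  Returns standardized coefficients and R^2.  Note that when the
    three shift yields close exactly to the daily total the design is
    singular; the minimum-norm solution is returned with a warning and the
    R^2 remains well defined.
    """
    df = records.copy()
    df["_stage"] = dim_stage(df["dim"])
    early = df[df["_stage"] == "early"].groupby("ear_tag")[list(predictors)].mean()
    mid = df[df["_stage"] == "mid"].groupby("ear_tag")["dmy_kg"].mean()
    both = early.join(mid.rename("mid_dmy"), how="inner").dropna()
    n = len(both)
    if n < len(predictors) + 2:
        raise ValueError(f"need at least {len(predictors) + 2} cows with early "
                         f"and mid records, got {n}")
    Xz = stats.zscore(both[list(predictors)].to_numpy(float), ddof=1)
    yz = stats.zscore(both["mid_dmy"].to_numpy(float), ddof=1)
    X = np.column_stack([np.ones(n), Xz])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("singular early-trait design (exact shift closure); "
                      "reporting the minimum-norm coefficients")
    beta, *_ = np.linalg.lstsq(X, yz, rcond=None)
    resid = yz - X @ beta
    r2 = 1.0 - float(resid @ resid) / float(yz @ yz)
    coefs = dict(zip(predictors, map(float, beta[1:])))
    return {"coefficients": coefs, "r2": float(r2), "n_cows": n}


def factor_f_tests(records: pd.DataFrame, spec: FixedEffectsSpec, trait: str) -> pd.DataFrame:
    """Extra-sum-of-squares F-test for each factor in the additive model."""
    factors = spec.factor_frame(records)
    y = pd.to_numeric(records[trait], errors="coerce")
    keep = y.notna() & factors.notna().all(axis=1)
    y = y[keep].to_numpy(float)
    factors = factors.loc[keep]

    def rss(fr: pd.DataFrame) -> tuple[float, int]:
        X, _ = _design(fr)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_full, p_full = rss(factors)
    dof = len(y) - p_full
    rows = []
    for f in factors.columns:
        rss_red, p_red = rss(factors.drop(columns=[f]))
        df1 = p_full - p_red
        F = ((rss_red - rss_full) / df1) / (rss_full / dof)
        rows.append({"factor": f, "F": F, "df1": df1, "df2": dof,
                     "p": float(stats.f.sf(F, df1, dof))})
    return pd.DataFrame(rows)
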