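"""Synthetic dairy-herd generator.

Emulates a mid-size intensively recorded herd: a discrete-generation
pedigree (founder bulls and cows, hierarchical sire > dam families) and
multi-trait test-day records drawn from the exact generative model the
animal model assumes,

    y = mu + parity + season + stage + bw_class + a + m(dam) + pe + e,

with breeding values gene-dropped down the pedigree (founders N(0, Sigma_a);
non-founders mid-parent plus Mendelian sampling with variance
``0.5 (1 - (F_s + F_d)/2) Sigma_a``), maternal genetic values drawn the same
way on an independent realisation, cow-level permanent-environment effects
and record-level residuals.  Defaults mirror the kind of dairy herd this
package targets: trait means DMY 28.5 kg, fat 3.94 %, protein 3.35 %; variance
components sigma_a^2/sigma_m^2/sigma_pe^2/sigma_e^2 of 0.449/0.031/0.288/0.407
(DMY), 0.165/0.008/0.092/0.300 (FP) and 0.068/0.003/0.038/0.080 (PP); days in
milk restricted to lactation weeks 3-44; season offsets ordered winter >
fall > spring > summer and a parity curve peaking at parity 4.

Optional corruption (missingness, impossible outliers, duplicate rows) is
injected on request so the QC pipeline can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord, inbreeding

TRAITS = ("dmy_kg", "fat_pct", "protein_pct")

#: generative variance components per trait: (additive, maternal,
#: permanent-environment, residual), residuals chosen so that the
#: narrow-sense heritabilities equal 0.382 / 0.292 / 0.360.
DEFAULT_COMPONENTS = {
    "dmy_kg": (0.449, 0.031, 0.288, 0.407),
    "fat_pct": (0.165, 0.008, 0.092, 0.300),
    "protein_pct": (0.068, 0.003, 0.038, 0.080),
}

DEFAULT_MEANS = {"dmy_kg": 28.5, "fat_pct": 3.94, "protein_pct": 3.35}

#: genetic correlations used when traits are simulated jointly
DEFAULT_GENETIC_CORR = {
    ("dmy_kg", "fat_pct"): -0.435,
    ("dmy_kg", "protein_pct"): -0.809,
    ("fat_pct", "protein_pct"): 0.551,
}

# fixed-effect profiles, in units of the trait's phenotypic SD, applied
# scaled per trait.  Orderings: parity rises to 4 then declines; winter
# high / summer low; inverted-U over lactation with the mid stage highest;
# yield increases with body-weight class with a drop in the heaviest class.
_PARITY_PROFILE = np.array([-0.8, 0.1, 0.5, 0.7, 0.3])
_SEASON_PROFILE = {"spring": 0.1, "summer": -0.5, "fall": 0.2, "winter": 0.5}
_STAGE_PROFILE = np.array([0.0, 0.35, -0.35])  # early, mid, late
_BW_PROFILE = np.array([-0.6, -0.3, 0.0, 0.25, 0.4, 0.2])

_SEASON_OF_MONTH = {
    **{m: "spring" for m in (3, 4, 5)},
    **{m: "summer" for m in (6, 7, 8)},
    **{m: "fall" for m in (9, 10, 11)},
    **{m: "winter" for m in (12, 1, 2)},
}


@dataclass
class SimScenario:
    """Configuration of one simulated herd.

    Pedigree: ``n_generations`` discrete generations of
    ``males_per_gen + females_per_gen`` animals each; every non-founder has
    a sire (one of ``sires_per_gen`` selected males) and a dam from the
    previous generation, dams mated to a single sire (paternal half-sib /
    maternal sib family structure).  Records: ``n_cows_with_records``
    females of the last generation, ``records_per_cow`` test days each over
    days in milk 15-308 (lactation weeks 3-44).
    """

    n_generations: int = 3
    males_per_gen: int = 25
    females_per_gen: int = 500
    sires_per_gen: int = 25
    n_cows_with_records: int = 450
    records_per_cow: int = 5
    record_generations: int = 2  # females of this many most-recent generations record
    traits: Sequence[str] = TRAITS
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_MEANS))
    components: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_COMPONENTS.items()})
    genetic_corr: dict = field(default_factory=lambda: dict(DEFAULT_GENETIC_CORR))
    residual_corr: dict = field(default_factory=dict)
    fixed_effect_scale: float = 1.0
    missingness_rate: float = 0.0
    outlier_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("missingness_rate", self.missingness_rate),
            ("outlier_rate", self.outlier_rate),
            ("duplicate_rate", self.duplicate_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for n in (self.n_generations, self.males_per_gen, self.females_per_gen,
                  self.sires_per_gen, self.n_cows_with_records, self.records_per_cow):
            if n <= 0:
                raise ValueError("all scenario counts must be positive")
        if self.sires_per_gen > self.males_per_gen:
            raise ValueError("sires_per_gen cannot exceed males_per_gen")
        n_recordable = self.females_per_gen * min(
            self.record_generations, max(1, self.n_generations - 1))
        if self.n_cows_with_records > n_recordable:
            raise ValueError("not enough recordable females in the pedigree")

    def component_matrices(self) -> dict[str, np.ndarray]:
        """Cross-trait covariance matrix per random term (a, m, pe, e).

        Genetic correlations apply to the additive term; ``residual_corr``
        (same keying) to the residual; maternal and permanent-environment
        terms are uncorrelated across traits.
        """
        t = list(self.traits)
        k = len(t)
        out = {}
        for idx, term in enumerate(("a", "m", "pe", "e")):
            V = np.zeros((k, k))
            for i, ti in enumerate(t):
                V[i, i] = self.components[ti][idx]
            corr = self.genetic_corr if term == "a" else (
                self.residual_corr if term == "e" else {})
            for i, ti in enumerate(t):
                for j, tj in enumerate(t):
                    if i < j:
                        r = corr.get((ti, tj), corr.get((tj, ti), 0.0))
                        V[i, j] = V[j, i] = r * np.sqrt(V[i, i] * V[j, j])
            _require_psd(V, term)
            out[term] = V
        return out


def _require_psd(V: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(V)
    if w.min() < -1e-10:
        raise ValueError(f"{name} covariance matrix is not positive semidefinite")


@dataclass
class SimTruth:
    """Generative ground truth, never consumed by the estimation code."""

    breeding_values: pd.DataFrame
    maternal_values: pd.DataFrame
    pe_values: pd.DataFrame
    components: dict
    fixed_effects: dict
    injected_outlier_rows: list = field(default_factory=list)
    injected_duplicate_rows: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "components": {k: list(map(float, v)) for k, v in self.components.items()},
            "fixed_effects": self.fixed_effects,
            "breeding_values": self.breeding_values.to_dict(orient="list"),
            "maternal_values": self.maternal_values.to_dict(orient="list"),
            "pe_values": self.pe_values.to_dict(orient="list"),
            "injected_outlier_rows": list(map(int, self.injected_outlier_rows)),
            "injected_duplicate_rows": list(map(int, self.injected_duplicate_rows)),
        }


def simulate_pedigree(scenario: SimScenario, rng: np.random.Generator | None = None) -> Pedigree:
    """Discrete-generation pedigree with hierarchical sire/dam families."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    records: list[PedigreeRecord] = []
    prev_males: list[str] = []
    prev_females: list[str] = []
    for g in range(scenario.n_generations):
        males, females = [], []
        if g == 0:
            for i in range(scenario.males_per_gen):
                a = f"G0M{i:04d}"
                records.append(PedigreeRecord(a, sex="M", birth_year=2000))
                males.append(a)
            for i in range(scenario.females_per_gen):
                a = f"G0F{i:04d}"
                records.append(PedigreeRecord(a, sex="F", birth_year=2000))
                females.append(a)
        else:
            sires = list(rng.choice(prev_males, size=scenario.sires_per_gen, replace=False))
            # each dam mated to one sire -> paternal half-sib families
            mate_of = {d: sires[i % len(sires)] for i, d in enumerate(prev_females)}
            n_new = scenario.males_per_gen + scenario.females_per_gen
            dams = rng.choice(prev_females, size=n_new, replace=True)
            for i in range(n_new):
                sex = "M" if i < scenario.males_per_gen else "F"
                a = f"G{g}{sex}{i:04d}"
                d = str(dams[i])
                records.append(
                    PedigreeRecord(a, sire=mate_of[d], dam=d, sex=sex, birth_year=2000 + 2 * g)
                )
                (males if sex == "M" else females).append(a)
        prev_males, prev_females = males, females
    return Pedigree.from_records(records)


def simulate_breeding_values(
    ped: Pedigree,
    covariance: np.ndarray,
    seed: int | np.random.Generator,
    trait_names: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """Gene-drop multi-trait breeding values down a sorted pedigree.

    Founders are N(0, Sigma); non-founders are the mid-parent average plus a
    Mendelian-sampling deviation with covariance
    ``0.5 (1 - (F_s + F_d)/2) Sigma`` (an unknown parent contributes F = -1,
    i.e. behaves as an unrelated non-inbred founder).  The resulting vectors
    have covariance ``A (kron) Sigma``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    k = covariance.shape[0]
    _require_psd(covariance, "additive")
    # eigh-based square root tolerates singular covariance (zero variance)
    w, U = np.linalg.eigh(covariance)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    n = len(ped)
    par = ped.parent_indices()
    F = np.array([v for v in inbreeding(ped).values()])
    values = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = par[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        mid = np.zeros(k)
        if s >= 0:
            mid += 0.5 * values[s]
        if d >= 0:
            mid += 0.5 * values[d]
        msv = 0.5 * (1.0 - 0.5 * (Fs + Fd))
        values[i] = mid + np.sqrt(msv) * (z[i] @ L.T)
    return pd.DataFrame(values, index=ped.ids, columns=list(trait_names)[:k])


def _stage_of_dim(dim: np.ndarray) -> np.ndarray:
    """Lactation stage index: 0 early (<=100 d), 1 mid (101-200), 2 late (>=201)."""
    return np.where(dim <= 100, 0, np.where(dim <= 200, 1, 2))


def simulate_records(
    ped: Pedigree,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw test-day records for last-generation females under the animal model."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    traits = list(scenario.traits)
    k = len(traits)
    mats = scenario.component_matrices()

    rec_years = {2000 + 2 * g
                 for g in range(max(1, scenario.n_generations - scenario.record_generations),
                                scenario.n_generations)}
    cows = [r.animal for r in ped.records if r.sex == "F" and r.birth_year in rec_years]
    if len(cows) < scenario.n_cows_with_records:
        raise ValueError("pedigree has too few recordable females")
    cows = list(rng.choice(cows, size=scenario.n_cows_with_records, replace=False))

    a = simulate_breeding_values(ped, mats["a"], rng, traits)
    m = simulate_breeding_values(ped, mats["m"], rng, traits)

    n_cows = len(cows)
    pe = rng.multivariate_normal(np.zeros(k), mats["pe"], size=n_cows, method="eigh")
    pe_df = pd.DataFrame(pe, index=cows, columns=traits)

    dam_of = {r.animal: r.dam for r in ped.records}
    cow_parity = rng.integers(1, 8, size=n_cows)          # raw parity 1..7
    cow_bw = np.clip(rng.normal(590.0, 60.0, size=n_cows), 430.0, 780.0)
    bw_edges = np.array([500.0, 550.0, 600.0, 650.0, 700.0])
    cow_bw_class = np.searchsorted(bw_edges, cow_bw)       # 0..5
    calving_day = rng.integers(0, 365, size=n_cows)        # day offset into 2022

    rows = []
    nrec = scenario.records_per_cow
    e = rng.multivariate_normal(np.zeros(k), mats["e"], size=n_cows * nrec, method="eigh")
    fixed_effects = {
        "parity": (scenario.fixed_effect_scale * _PARITY_PROFILE).tolist(),
        "season": {s: scenario.fixed_effect_scale * v for s, v in _SEASON_PROFILE.items()},
        "stage": (scenario.fixed_effect_scale * _STAGE_PROFILE).tolist(),
        "bw_class": (scenario.fixed_effect_scale * _BW_PROFILE).tolist(),
    }
    sds = {t: np.sqrt(sum(scenario.components[t])) for t in traits}

    idx = 0
    base = pd.Timestamp("2022-01-01")
    for c, cow in enumerate(cows):
        dims = np.sort(rng.choice(np.arange(15, 309), size=nrec, replace=False))
        parity_cls = min(int(cow_parity[c]), 5) - 1       # 0..4, >=5 pooled
        calved = base + pd.Timedelta(days=int(calving_day[c]))
        for rix in range(nrec):
            dim = int(dims[rix])
            date = calved + pd.Timedelta(days=dim)
            season = _SEASON_OF_MONTH[date.month]
            stage = int(_stage_of_dim(np.array([dim]))[0])
            rec = {
                "ear_tag": cow,
                "test_date": date.strftime("%Y-%m-%d"),
                "parity": int(cow_parity[c]),
                "season": season,
                "dim": dim,
                "bw_kg": round(float(cow_bw[c]), 1),
            }
            for t_i, t in enumerate(traits):
                fx = (
                    fixed_effects["parity"][parity_cls]
                    + fixed_effects["season"][season]
                    + fixed_effects["stage"][stage]
                    + fixed_effects["bw_class"][cow_bw_class[c]]
                ) * sds[t]
                dam = dam_of.get(cow, "")
                mval = m.at[dam, t] if dam else 0.0
                rec[t] = (
                    scenario.trait_means[t] + fx
                    + a.at[cow, t] + mval + pe_df.at[cow, t] + e[idx, t_i]
                )
            if "dmy_kg" in traits:
                w = rng.dirichlet([60.0, 62.0, 61.0])  # morning/noon/night split
                shifts = rec["dmy_kg"] * w
                rec["my_morn_kg"] = shifts[0]
                rec["my_noon_kg"] = shifts[1]
                # force exact closure of the shift decomposition
                rec["my_night_kg"] = rec["dmy_kg"] - shifts[0] - shifts[1]
            rows.append(rec)
            idx += 1

    df = pd.DataFrame(rows)
    truth = SimTruth(
        breeding_values=a, maternal_values=m, pe_values=pe_df,
        components={t: tuple(scenario.components[t]) for t in traits},
        fixed_effects=fixed_effects,
    )
    _inject_corruption(df, scenario, rng, truth)
    return df, truth


def _inject_corruption(df: pd.DataFrame, scenario: SimScenario,
                       rng: np.random.Generator, truth: SimTruth) -> None:
    """In-place missingness / impossible-outlier / duplicate injection."""
    n = len(df)
    if scenario.missingness_rate > 0:
        targets = ["fat_pct", "protein_pct", "bw_kg"]
        for col in targets:
            if col in df.columns:
                mask = rng.random(n) < scenario.missingness_rate
                df.loc[mask, col] = np.nan
    if scenario.outlier_rate > 0 and "dmy_kg" in df.columns:
        mask = rng.random(n) < scenario.outlier_rate
        out_rows = np.flatnonzero(mask)
        df.loc[out_rows, "dmy_kg"] = rng.uniform(61.0, 90.0, size=len(out_rows))
        truth.injected_outlier_rows = out_rows.tolist()
    if scenario.duplicate_rate > 0:
        n_dup = int(round(scenario.duplicate_rate * n))
        if n_dup:
            pick = rng.choice(n, size=n_dup, replace=False)
            truth.injected_duplicate_rows = pick.tolist()
            dup = df.iloc[pick]
            new = pd.concat([df, dup], ignore_index=True)
            df.drop(df.index, inplace=True)
            for col in new.columns:
                df[col] = new[col]


def simulate_herd(scenario: SimScenario) -> tuple[Pedigree, pd.DataFrame, SimTruth]:
    """Pedigree + records + truth from one scenario (single seed stream)."""
    rng = np.random.default_rng(scenario.seed)
    ped = simulate_pedigree(scenario, rng)
    records, truth = simulate_records(ped, scenario, rng)
    return ped, records, truth


def scenario_to_dict(scenario: SimScenario) -> dict:
    d = asdict(scenario)
    d["genetic_corr"] = {f"{a}:{b}": v for (a, b), v in scenario.genetic_corr.items()}
    d["residual_corr"] = {f"{a}:{b}": v for (a, b), v in scenario.residual_corr.items()}
    d["traits"] = list(scenario.traits)
    return d


def scenario_from_dict(d: dict) -> SimScenario:
    d = dict(d)
    for key in ("genetic_corr", "residual_corr"):
        if key in d and d[key]:
            d[key] = {tuple(k.split(":")): v for k, v in d[key].items()}
    if "components" in d:
        d["components"] = {k: tuple(v) for k, v in d["components"].items()}
    if "traits" in d:
        d["traits"] = tuple(d["traits"])
    return SimScenario(**d)
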