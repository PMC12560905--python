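"""Descriptive statistics for test-day traits.

Conventions: sample SD (n-1 denominator); CV = SD/mean x 100; skewness and
kurtosis are the biased moment estimators ``m3/m2^{3/2}`` and ``m4/m2^2``
(Pearson, non-excess, so a normal sample sits near 3) — the usual choices in
descriptive tables for production traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_LABELS = {
    "dmy_kg": "DMY (kg)",
    "my_morn_kg": "MY-Morn (kg)",
    "my_noon_kg": "MY-Noon (kg)",
    "my_night_kg": "MY-Night (kg)",
    "fat_pct": "FP (%)",
    "protein_pct": "PP (%)",
}


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    n: int
    mean: float
    sd: float
    cv_pct: float
    min: float
    max: float
    skewness: float
    kurtosis: float  # Pearson (non-excess)

    def as_row(self) -> dict:
        return {
            "trait": TRAIT_LABELS.get(self.trait, self.trait),
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "cv_pct": self.cv_pct, "min": self.min, "max": self.max,
            "skewness": self.skewness, "kurtosis": self.kurtosis,
        }


def summarize(values, trait: str = "") -> TraitSummary:
    """Summary statistics of one trait vector (missing values dropped)."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("constant input: skewness/kurtosis undefined")
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return TraitSummary(
        trait=trait, n=n, mean=mean, sd=sd,
        cv_pct=float(sd / mean * 100.0),
        min=float(x.min()), max=float(x.max()),
        skewness=float(stats.skew(x, bias=True)),
        kurtosis=float(stats.kurtosis(x, fisher=False, bias=True)),
    )


def summarize_frame(df: pd.DataFrame, traits=None) -> pd.DataFrame:
    traits = traits or [t for t in TRAIT_LABELS if t in df.columns]
    return pd.DataFrame([summarize(df[t], t).as_row() for t in traits])


def normality_screen(summary: TraitSummary, threshold: float = 0.5) -> tuple[bool, str]:
    """Flag traits whose |skewness| exceeds ``threshold`` for transformation."""
    if abs(summary.skewness) > threshold:
        return True, (
            f"{summary.trait or 'trait'}: |skewness| = {abs(summary.skewness):.2f} "
            f"> {threshold:g}; a variance-stabilising transform is recommended"
        )
    return False, (
        f"{summary.trait or 'trait'}: skewness {summary.skewness:.2f} within "
        f"+/-{threshold:g}; analysis on the raw scale"
    )


def box_cox(values, lambda_grid=None) -> tuple[float, np.ndarray]:
    """Power transform ``y -> (y^lambda - 1)/lambda`` (log at lambda = 0).

    The exponent is chosen on ``lambda_grid`` (default -2..2 by 0.01) by
    maximising the Box-Cox profile log-likelihood.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lambda_grid is None:
        lambda_grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    grid = np.asarray(lambda_grid, dtype=float)
    ll = np.array([stats.boxcox_llf(lmb, x) for lmb in grid])
    best = float(grid[int(np.argmax(ll))])
    if best == 0.0:
        transformed = np.log(x)
    else:
        transformed = (x ** best - 1.0) / best
    return best, transformed


def plot_histograms(df: pd.DataFrame, traits=None, path=None):
    """Optional per-trait histogram panel (matplotlib figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traits = traits or [t for t in TRAIT_LABELS if t in df.columns]
    fig, axes = plt.subplots(1, len(traits), figsize=(3 * len(traits), 2.6))
    for ax, t in zip(np.atleast_1d(axes), traits):
        ax.hist(df[t].dropna(), bins=30, color="#4878d0")
        ax.set_title(TRAIT_LABELS.get(t, t), fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
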