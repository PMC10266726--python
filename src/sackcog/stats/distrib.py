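"""Distribution-level tools: ECDF confidence bands, stochastic-dominance
checks, the squared-random-effect exchangeability test, and
difficulty-metric correlations."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ECDFBand",
    "ecdf_band",
    "plot_ecdf_bands",
    "DominanceReport",
    "dominance_check",
    "wilcoxon_squared_effects",
    "difficulty_correlations",
    "CorrelationReport",
]


@dataclass(frozen=True)
class ECDFBand:
    """Empirical CDF with pointwise confidence bounds.

    The variance at each grid point is Greenwood's estimator, which with
    fully observed (uncensored) data reduces to the binomial form
    ``F (1 - F) / n``; bounds are normal-approximation and clipped to
    [0, 1].
    """

    grid: np.ndarray
    F: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n: int
    alpha: float

    def evaluate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Step-evaluate (F, lower, upper) at arbitrary points."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.grid, x, side="right") - 1
        F = np.where(idx >= 0, self.F[np.clip(idx, 0, None)], 0.0)
        z = sps.norm.ppf(1 - self.alpha / 2)
        var = F * (1 - F) / self.n
        lower = np.clip(F - z * np.sqrt(var), 0.0, 1.0)
        upper = np.clip(F + z * np.sqrt(var), 0.0, 1.0)
        return F, lower, upper


def plot_ecdf_bands(bands: dict[str, "ECDFBand"], ax=None, title: str | None = None):
    """Step-plot one or more ECDFs with shaded pointwise confidence bands.

    Returns the matplotlib Axes.  Typical use: placebo vs pooled-drug
    distributions of an attempt-level outcome.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, band in bands.items():
        (line,) = ax.step(band.grid, band.F, where="post", label=label)
        ax.fill_between(band.grid, band.lower, band.upper, step="post",
                        alpha=0.2, color=line.get_color())
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def ecdf_band(samples: np.ndarray, alpha: float = 0.05) -> ECDFBand:
    """Empirical CDF of a fully observed sample with pointwise
    100(1-alpha)% Greenwood bounds."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[~np.isnan(samples)]
    n = len(samples)
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    grid = np.unique(samples)
    F = np.searchsorted(np.sort(samples), grid, side="right") / n
    z = sps.norm.ppf(1 - alpha / 2)
    var = F * (1 - F) / n
    half = z * np.sqrt(var)
    return ECDFBand(
        grid=grid, F=F,
        lower=np.clip(F - half, 0.0, 1.0),
        upper=np.clip(F + half, 0.0, 1.0),
        n=n, alpha=alpha,
    )


@dataclass(frozen=True)
class DominanceReport:
    """Pointwise band-separation summary on the merged grid.

    ``frac_a_below`` is the fraction of grid points where A's upper bound
    lies strictly below B's lower bound — there the CDF of A is credibly
    smaller, i.e. A first-order stochastically dominates B (larger values
    under A).  ``direction`` is "A", "B" or "none" by majority.
    """

    grid: np.ndarray
    a_below: np.ndarray
    b_below: np.ndarray
    frac_a_below: float
    frac_b_below: float
    frac_separated: float

    @property
    def direction(self) -> str:
        if self.frac_a_below == self.frac_b_below:
            return "none"
        return "A" if self.frac_a_below > self.frac_b_below else "B"


def dominance_check(band_a: ECDFBand, band_b: ECDFBand) -> DominanceReport:
    """Compare two ECDF bands on their merged grid."""
    grid = np.union1d(band_a.grid, band_b.grid)
    _, lo_a, up_a = band_a.evaluate(grid)
    _, lo_b, up_b = band_b.evaluate(grid)
    a_below = up_a < lo_b
    b_below = up_b < lo_a
    return DominanceReport(
        grid=grid, a_below=a_below, b_below=b_below,
        frac_a_below=float(a_below.mean()),
        frac_b_below=float(b_below.mean()),
        frac_separated=float((a_below | b_below).mean()),
    )


def wilcoxon_squared_effects(
    effects_a: np.ndarray, effects_b: np.ndarray
) -> tuple[float, float]:
    """Signed-rank test that the *squares* of paired participant effects are
    exchangeable between two conditions.

    The test statistic is the Wilcoxon signed-rank statistic of
    ``a_i^2 - b_i^2``; a small p with smaller squares under B indicates the
    B effects are stochastically smaller in magnitude (shrinkage).  Exact
    null distribution for up to 25 non-zero pairs, normal approximation
    with continuity correction beyond.  Two-sided.
    """
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired effect vectors must have equal length")
    if len(a) < 6:
        raise ValueError(f"need at least 6 complete pairs, got {len(a)}")
    d = a**2 - b**2
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all squared-effect differences are zero (degenerate data)")
    use_exact = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
    res = sps.wilcoxon(
        d, zero_method="wilcox",
        method="exact" if use_exact else "approx",
        correction=not use_exact,
        alternative="two-sided",
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationReport:
    corr: pd.DataFrame       # pairwise Pearson correlations
    se_z: float              # Fisher-scale standard error, 1/sqrt(n-3)
    ci_lower: pd.DataFrame   # back-transformed 95% bounds
    ci_upper: pd.DataFrame
    n: int

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        return self.corr.round(ndigits)


def difficulty_correlations(profiles) -> CorrelationReport:
    """Pairwise Pearson correlations between the three difficulty metrics
    over a set of instances.

    Standard errors use the Fisher z transform (SE_z = 1/sqrt(n-3)); the
    reported confidence bounds are back-transformed.  A constant metric has
    no defined correlation and raises.
    """
    rows = []
    for p in profiles:
        rows.append(
            {"instance_id": p.instance_id, "sahni_k": p.sahni_k,
             "dp_complexity": p.dp_complexity, "minizinc_props": p.minizinc_props}
        )
    df = pd.DataFrame(rows).set_index("instance_id")
    if df["minizinc_props"].isna().any():
        raise ValueError("all profiles must carry minizinc_props for the "
                         "three-way correlation table")
    n = len(df)
    if n < 4:
        raise ValueError(f"need at least 4 profiles, got {n}")
    metrics = ["sahni_k", "dp_complexity", "minizinc_props"]
    for m in metrics:
        if df[m].nunique() == 1:
            raise ValueError(f"metric {m!r} is constant; correlation undefined")
    corr = df[metrics].astype(float).corr(method="pearson")
    se_z = 1.0 / np.sqrt(n - 3)
    z = np.arctanh(np.clip(corr.values, -0.999999, 0.999999))
    zcrit = sps.norm.ppf(0.975)
    lo = pd.DataFrame(np.tanh(z - zcrit * se_z), index=corr.index, columns=corr.columns)
    hi = pd.DataFrame(np.tanh(z + zcrit * se_z), index=corr.index, columns=corr.columns)
    return CorrelationReport(corr=corr, se_z=float(se_z), ci_lower=lo,
                             ci_upper=hi, n=n)
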