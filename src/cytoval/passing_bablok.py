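"""Passing-Bablok method-comparison regression, implemented from scratch.

The slope is the shifted median of all pairwise slopes (offset by the count
of slopes below -1 so the estimator is invariant under swapping the axes),
with distribution-free confidence intervals from the classical
normal-approximation rank rule.  Slopes from x-ties are skipped and slopes
exactly equal to -1 are discarded.  No constant bias is declared when the
intercept CI contains 0; no proportional bias when the slope CI contains 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateDataError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class PBRegressionResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n_pairs: int
    gamma: float = 0.95
    constant_bias: bool = False
    proportional_bias: bool = False

    def __post_init__(self) -> None:
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1]):
            raise ValidationError("slope must lie inside its CI")
        if not (self.intercept_ci[0] <= self.intercept <= self.intercept_ci[1]):
            raise ValidationError("intercept must lie inside its CI")


@dataclass(frozen=True)
class BiasVerdict:
    constant_bias: bool
    proportional_bias: bool
    direction: str | None  # "overestimation" / "underestimation" when biased
    good_fit: bool


def pairwise_slopes(x, y) -> tuple[np.ndarray, int]:
    """All pairwise slopes, sorted ascending, plus the shift count K.

    Slopes are ``(y_j - y_i) / (x_j - x_i)`` over i < j with distinct x;
    slopes equal to -1 are dropped, and K counts slopes below -1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 points")
    if np.all(x == x[0]):
        raise DegenerateDataError("all x values identical")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    keep = dx != 0
    slopes = (y[j] - y[i])[keep] / dx[keep]
    k = int(np.sum(slopes < -1))
    slopes = np.sort(slopes[slopes != -1])
    return slopes, k


def _shifted_median(slopes: np.ndarray, k: int) -> float:
    """Median of the sorted slopes at rank offset k (1-based ranks)."""
    n = len(slopes)
    if n % 2:
        idx = (n + 1) // 2 + k  # 1-based
        if not (1 <= idx <= n):
            raise InsufficientDataError("offset median rank out of range")
        return float(slopes[idx - 1])
    lo, hi = n // 2 + k, n // 2 + 1 + k
    if not (1 <= lo and hi <= n):
        raise InsufficientDataError("offset median ranks out of range")
    return float(0.5 * (slopes[lo - 1] + slopes[hi - 1]))


def fit(x, y, gamma: float = 0.95) -> PBRegressionResult:
    """Fit y on x and derive confidence intervals and bias flags.

    CI ranks: with N retained slopes and n points,
    ``C = z_{(1+gamma)/2} * sqrt(n(n-1)(2n+5)/18)``,
    ``M1 = round((N - C)/2)`` and ``M2 = N - M1 + 1``; the slope CI is the
    pair of order statistics at ranks ``M1 + K`` and ``M2 + K``.  The
    intercept is ``median(y - slope*x)``; its CI reuses that median rule at
    the slope CI bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slopes, k = pairwise_slopes(x, y)
    n, n_slopes = len(x), len(slopes)
    if n_slopes == 0:
        raise InsufficientDataError("no valid pairwise slopes")
    slope = _shifted_median(slopes, k)

    w = norm.ppf((1 + gamma) / 2)
    c = w * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_slopes - c) / 2))
    m2 = n_slopes - m1 + 1
    lo_rank, hi_rank = m1 + k, m2 + k
    if not (1 <= lo_rank <= n_slopes and 1 <= hi_rank <= n_slopes):
        raise InsufficientDataError(
            f"too few slopes ({n_slopes}) for a {gamma:.0%} CI at n={n}")
    slope_lo = float(slopes[lo_rank - 1])
    slope_hi = float(slopes[hi_rank - 1])

    intercept = float(np.median(y - slope * x))
    intercept_ci = (float(np.median(y - slope_hi * x)),
                    float(np.median(y - slope_lo * x)))
    return PBRegressionResult(
        slope=slope,
        slope_ci=(slope_lo, slope_hi),
        intercept=intercept,
        intercept_ci=intercept_ci,
        n_pairs=n,
        gamma=gamma,
        constant_bias=not (intercept_ci[0] <= 0 <= intercept_ci[1]),
        proportional_bias=not (slope_lo <= 1 <= slope_hi),
    )


def assess_bias(result: PBRegressionResult) -> BiasVerdict:
    """Turn a fitted result into constant/proportional-bias verdicts."""
    proportional = not (result.slope_ci[0] <= 1 <= result.slope_ci[1])
    constant = not (result.intercept_ci[0] <= 0 <= result.intercept_ci[1])
    direction = None
    if proportional:
        direction = "overestimation" if result.slope > 1 else "underestimation"
    return BiasVerdict(
        constant_bias=constant,
        proportional_bias=proportional,
        direction=direction,
        good_fit=not (constant or proportional),
    )


def plot_fit(x, y, result: PBRegressionResult, path, title: str = "") -> None:
    """Scatter with identity line and the fitted line, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = max(x.max(), y.max()) * 1.05 if len(x) else 1.0
    ax.plot([0, lim], [0, lim], color="grey", lw=1, label="identity")
    xs = np.linspace(0, lim, 2)
    ax.plot(xs, result.intercept + result.slope * xs, color="C0",
            label=(f"fit: y = {result.slope:.3f}x + {result.intercept:.3f}"))
    ax.scatter(x, y, s=25, color="C3", zorder=3)
    ax.set_xlabel("expected (%)")
    ax.set_ylabel("measured (%)")
    ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
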