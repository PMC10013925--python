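"""Estimation of pi0, the proportion of true null hypotheses.

Two independent estimators are provided. The rank-based local-FDR method
averages q-value-like quantities over the ranked p-values; the Storey
smoother evaluates pi0(lambda) = #{p > lambda} / (n (1 - lambda)) on a grid
and extrapolates to lambda -> 1 with a cubic smoothing spline. Both are
meaningful only for well-behaved (uniform or anti-conservative) p-value
sets; the pipeline enforces that gate, the functions themselves do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

DEFAULT_LAMBDA_GRID = np.round(np.arange(1, 20) * 0.05, 10)
DEFAULT_SPLINE_DF = 3.0


@dataclass(frozen=True)
class Pi0Estimate:
    """A method-tagged pi0 estimate in [0, 1]."""

    method: str
    value: float
    n: int
    lambda_grid: np.ndarray | None = None
    warning: str | None = None
    raw: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"method": self.method, "value": float(self.value), "n": int(self.n)}
        if self.lambda_grid is not None:
            out["lambda_grid"] = [float(x) for x in self.lambda_grid]
        if self.warning:
            out["warning"] = self.warning
        return out


def _clean(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return values


def pi0_lfdr(values) -> Pi0Estimate:
    """Rank-based local-FDR estimate of pi0.

    Sort the p-values in decreasing order p(1) >= ... >= p(n) and pair p(j)
    with rank i_j = n + 1 - j. With q_j = min(n p(j) / i_j, 1), the estimate
    is 2 * sum_j i_j q_j / (n (n + 1)), clamped to [0, 1]. On a pure-uniform
    set each q_j is close to 1 and the estimate is close to 1.
    """
    p = _clean(values)
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 finite p-values")
    p = np.sort(p)[::-1]
    i = np.arange(n, 0, -1, dtype=float)
    q = np.minimum(n * p / i, 1.0)
    est = 2.0 * float(np.sum(i * q)) / (n * (n + 1.0))
    return Pi0Estimate(method="lfdr_rank", value=float(np.clip(est, 0.0, 1.0)), n=n)


def _reinsch_penalty(x: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline roughness penalty K = Q R^{-1} Q' (Reinsch form)."""
    n = x.size
    h = np.diff(x)
    R = np.zeros((n - 2, n - 2))
    Q = np.zeros((n, n - 2))
    for j in range(n - 2):
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
        Q[j, j] = 1.0 / h[j]
        Q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
        Q[j + 2, j] = 1.0 / h[j + 1]
    return Q @ linalg.solve(R, Q.T, assume_a="pos")


def smoothing_spline_fit(x, y, df: float = DEFAULT_SPLINE_DF) -> np.ndarray:
    """Fit a natural cubic smoothing spline with a given effective df.

    Minimizes ||y - f||^2 + a * integral f''(t)^2 dt over natural cubic
    splines with knots at the x's; the penalty a is solved so that the
    trace of the smoother matrix (I + aK)^{-1} equals ``df``. Returns the
    fitted values at the knots. df must lie in (2, n): df -> n reproduces
    interpolation, df -> 2 the least-squares line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for a cubic smoothing spline")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if not 2.0 < df < n:
        raise ValueError(f"df must lie in (2, {n})")
    K = _reinsch_penalty(x)
    # K is symmetric PSD with a two-dimensional null space (linear trends);
    # eigendecomposition makes both the trace equation and the fit stable:
    # trace (I + aK)^-1 = sum_i 1 / (1 + a w_i), strictly decreasing in a.
    w, V = linalg.eigh(K)
    w = np.maximum(w, 0.0)

    def trace_df(log_a: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(log_a) * w))) - df

    log_a = optimize.brentq(trace_df, -40.0, 40.0, xtol=1e-12)
    shrink = 1.0 / (1.0 + np.exp(log_a) * w)
    return V @ (shrink * (V.T @ y))


def pi0_storey_smoother(
    values,
    lambda_grid=None,
    df: float = DEFAULT_SPLINE_DF,
) -> Pi0Estimate:
    """Storey's smoother estimate of pi0.

    Computes pi0(lambda) = #{p > lambda} / (n (1 - lambda)) on the grid
    (default 0.05, 0.10, ..., 0.95; ties p = lambda count as below), fits a
    cubic smoothing spline with ``df`` effective degrees of freedom, and
    reads off the fitted value at the largest lambda, clamped to [0, 1].
    """
    p = _clean(values)
    n = p.size
    if n < 100:
        raise ValueError("Storey smoother needs at least 100 finite p-values")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size < 4 or np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("lambda grid must have >= 4 points inside (0, 1)")
    grid = np.sort(grid)
    raw = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in grid])
    if np.all(raw == 0.0):
        warnings.warn("all p-values below the smallest lambda; pi0 estimated as 0")
        return Pi0Estimate(
            method="storey_smoother", value=0.0, n=n, lambda_grid=grid,
            warning="all p-values below min(lambda)",
            raw={"pi0_lambda": raw.tolist()},
        )
    fitted = smoothing_spline_fit(grid, raw, df=df)
    est = float(np.clip(fitted[-1], 0.0, 1.0))
    return Pi0Estimate(
        method="storey_smoother", value=est, n=n, lambda_grid=grid,
        raw={"pi0_lambda": raw.tolist(), "fitted": fitted.tolist()},
    )


@dataclass(frozen=True)
class Pi0Comparison:
    """Paired pi0 estimates from both methods over a collection of sets."""

    pairs: pd.DataFrame  # columns: lfdr, smoother
    mean_lfdr: float
    mean_smoother: float
    mean_difference: float


def compare_pi0_methods(sets) -> Pi0Comparison:
    """Estimate pi0 by both methods on each p-value set and summarize.

    Parameters
    ----------
    sets : iterable of array-like
        Qualifying (uniform or anti-conservative) p-value sets.
    """
    rows = []
    for s in sets:
        values = getattr(s, "values", s)
        rows.append(
            {"lfdr": pi0_lfdr(values).value,
             "smoother": pi0_storey_smoother(values).value}
        )
    if not rows:
        raise ValueError("need at least one p-value set")
    pairs = pd.DataFrame(rows)
    mean_lfdr = float(pairs["lfdr"].mean())
    mean_smoother = float(pairs["smoother"].mean())
    return Pi0Comparison(
        pairs=pairs,
        mean_lfdr=mean_lfdr,
        mean_smoother=mean_smoother,
        mean_difference=mean_lfdr - mean_smoother,
    )
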