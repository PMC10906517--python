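"""Statistical primitives shared by the significance pipelines.

Partial Pearson/Spearman correlations (least-squares residualization
with intercept), Benjamini-Hochberg and ForwardStop false-discovery
control, bootstrap sign p-values and bootstrap signal-to-noise ratios.

One-sided tests (r > 0) are the default throughout: preservation across
datasets requires *positive* score correlation, and the bootstrap sign
p-value is one-sided by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateResidualError",
    "TestResult",
    "residualize",
    "partial_pearson",
    "partial_spearman",
    "bh_fdr",
    "forward_stop",
    "bootstrap_sign_p",
    "snr",
]


class DegenerateResidualError(ValueError):
    """Raised when a residual has (numerically) zero variance."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    n_covariates: int
    sided: str  # "one" | "two"


def residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residual of v after least-squares regression on covariates + intercept."""
    v = np.asarray(v, dtype=float)
    if covariates is None or covariates.size == 0:
        return v - v.mean()
    C = np.column_stack([np.ones(len(v)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def _check_residual(r: np.ndarray, scale: float) -> None:
    if np.sqrt(np.mean(r**2)) <= 1e-12 * max(scale, 1.0):
        raise DegenerateResidualError("degenerate residual (zero variance)")


def partial_pearson(
    x,
    y,
    covariates=None,
    *,
    y_covariates=None,
    sided: str = "one",
) -> TestResult:
    """Partial Pearson correlation via residualization.

    ``x`` is residualized on ``covariates`` and ``y`` on
    ``y_covariates`` (defaulting to the same matrix), each by least
    squares with an intercept; the residuals are Pearson-correlated and
    the p-value comes from the t distribution with ``n - 2 - c`` degrees
    of freedom, where c is the number of covariate columns.  One-sided
    tests test r > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    cx = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cx is not None and cx.shape[0] != len(x):
        cx = cx.T
    if y_covariates is None:
        cy = cx
    else:
        cy = np.atleast_2d(np.asarray(y_covariates, float))
        if cy.shape[0] != len(y):
            cy = cy.T
    n_cov = 0
    for c in (cx, cy):
        if c is not None and c.size:
            n_cov = max(n_cov, c.shape[1])
    n = len(x)
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"too few observations (n={n}) for {n_cov} covariates")

    rx = residualize(x, cx)
    ry = residualize(y, cy)
    _check_residual(rx, float(np.abs(x).max(initial=0.0)))
    _check_residual(ry, float(np.abs(y).max(initial=0.0)))
    r = float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    if sided == "one":
        p = float(sps.t.sf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=r, p_value=min(p, 1.0), n=n,
                      n_covariates=n_cov, sided=sided)


def partial_spearman(
    x, y, covariates=None, *, y_covariates=None, sided: str = "one"
) -> TestResult:
    """Partial Spearman correlation: rank-transform everything (average
    ranks for ties), then apply :func:`partial_pearson` to the ranks."""

    def _rank(a):
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            return sps.rankdata(a)
        if a.shape[0] != len(np.asarray(x)):
            a = a.T
        return sps.rankdata(a, axis=0)

    return partial_pearson(
        _rank(x),
        _rank(y),
        None if covariates is None else _rank(covariates),
        y_covariates=None if y_covariates is None else _rank(y_covariates),
        sided=sided,
    )


def bh_fdr(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def forward_stop(p, alpha: float = 0.05) -> int:
    """ForwardStop sequential FDR rule.

    Given p-values ordered by the sequence under test, returns the
    largest k such that the running mean of -log(1 - p_i) over the first
    k values stays at or below alpha (0 if none).  p-values are clipped
    to 1 - 1e-12 before the log so that exact 1s (possible for bootstrap
    p-values) stay finite.
    """
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0 - 1e-12)
    if p.size == 0:
        return 0
    running = np.cumsum(-np.log1p(-p)) / np.arange(1, p.size + 1)
    passing = np.nonzero(running <= alpha)[0]
    return int(passing[-1] + 1) if passing.size else 0


def bootstrap_sign_p(draws, smoothed: bool = False) -> float:
    """One minus the fraction of bootstrap draws exceeding zero.

    With ``smoothed`` the add-one estimator ``(#{draws <= 0} + 1) /
    (B + 1)`` is used instead, which avoids exact zeros.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("need at least one bootstrap draw")
    n_pos = int(np.sum(draws > 0))
    if smoothed:
        return (draws.size - n_pos + 1) / (draws.size + 1)
    return 1.0 - n_pos / draws.size


def snr(point: float, draws) -> float:
    """Point estimate divided by the bootstrap standard deviation (ddof=1).

    A zero standard deviation (constant draws) yields +/- infinity,
    signalling a degenerate bootstrap rather than raising.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least two bootstrap draws")
    sd = float(draws.std(ddof=1))
    if sd == 0.0:
        return float(np.inf) if point >= 0 else float(-np.inf)
    return float(point) / sd
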