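"""Linear causal-effect estimation under different adjustment sets.

For a link ``X^i_{t-tau} -> X^j_t`` the average causal effect under a
linear model is the coefficient of the lagged driver in a regression of
the target on a valid adjustment set.  Four strategies are compared:

* ``ce_corr`` — univariate regression (no adjustment; on standardized
  data this is the lagged correlation, generally biased by indirect
  paths and common drivers);
* ``ce_full`` — adjustment on the whole past up to ``tau_max`` (valid but
  high-dimensional, hence high estimation variance);
* ``ce_pcmci`` — adjustment on the estimated parents of the target only
  (valid when the parent set is correct, with far fewer regressors);
* ``ce_true`` — adjustment on the generating parents (oracle reference).

Effects are reported on standardized variables; significance comes from a
nested-model F-test of dropping the driver term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import (
    ConfigurationError,
    LaggedVariable,
    ParentSet,
    TimeSeriesDataset,
    build_lagged_design,
)
from .synthetic import StructuralModel

__all__ = [
    "CausalEffectEstimate",
    "ce_corr",
    "ce_full",
    "ce_pcmci",
    "ce_true",
    "f_test_nested",
]


@dataclass(frozen=True)
class CausalEffectEstimate:
    method: str
    link: tuple[int, int, int]  # (i, tau, j)
    effect: float
    pvalue: float


def f_test_nested(rss_full: float, rss_reduced: float, df_extra: int, df_resid: int) -> float:
    """Right-tail p-value of the nested-model F-test
    ``F = ((RSS_reduced - RSS_full) / df_extra) / (RSS_full / df_resid)``.

    With ``df_extra = 1`` this equals the two-sided t-test on the dropped
    coefficient (t^2 = F).
    """
    if df_extra < 1 or df_resid < 1:
        raise ConfigurationError(f"invalid degrees of freedom ({df_extra}, {df_resid})")
    if rss_full <= 0 or rss_reduced < rss_full:
        raise ConfigurationError("need rss_reduced >= rss_full > 0")
    F = ((rss_reduced - rss_full) / df_extra) / (rss_full / df_resid)
    return float(stats.f.sf(F, df_extra, df_resid))


def _regress_effect(
    data: TimeSeriesDataset,
    i: int,
    tau: int,
    j: int,
    adjustment: list[LaggedVariable],
    window: int,
    method: str,
) -> CausalEffectEstimate:
    """Coefficient of (i, tau) in the OLS of X^j_t on {(i, tau)} + adjustment,
    with the drop-one-term F-test."""
    x = LaggedVariable(i, tau)
    regressors = [x] + [m for m in adjustment if m != x]
    y, Z = build_lagged_design(data, LaggedVariable(j, 0), regressors, window)
    n = len(y)
    X_full = np.column_stack([np.ones(n), Z])
    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    rss_full = float(resid @ resid)
    X_red = np.delete(X_full, 1, axis=1)
    beta_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    resid_r = y - X_red @ beta_r
    rss_red = float(resid_r @ resid_r)
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ConfigurationError(
            f"adjustment dimensionality {X_full.shape[1]} leaves no residual degrees of freedom at n={n}"
        )
    p = f_test_nested(rss_full, max(rss_red, rss_full), 1, df_resid)
    return CausalEffectEstimate(method=method, link=(i, tau, j), effect=float(beta[1]), pvalue=p)


def ce_corr(data: TimeSeriesDataset, i: int, tau: int, j: int) -> CausalEffectEstimate:
    """Univariate regression of the target on the lagged driver alone."""
    return _regress_effect(data, i, tau, j, [], tau, "ce_corr")


def ce_full(data: TimeSeriesDataset, i: int, tau: int, j: int, tau_max: int) -> CausalEffectEstimate:
    """Regression on all ``N * tau_max`` lagged terms of all variables."""
    n = data.T - tau_max
    if data.N * tau_max >= n - 2:
        raise ConfigurationError(
            f"whole-past adjustment needs N*tau_max < n-2 ({data.N * tau_max} vs {n - 2})"
        )
    adjustment = [
        LaggedVariable(v, lag) for lag in range(1, tau_max + 1) for v in range(data.N)
    ]
    return _regress_effect(data, i, tau, j, adjustment, tau_max, "ce_full")


def ce_pcmci(data: TimeSeriesDataset, i: int, tau: int, j: int, parents_j: ParentSet) -> CausalEffectEstimate:
    """Regression on the estimated parents of the target (the tested link
    is added to the regressors when not already a parent)."""
    window = max([tau] + [m.lag for m in parents_j.members]) if parents_j.members else tau
    return _regress_effect(data, i, tau, j, list(parents_j.members), window, "ce_pcmci")


def ce_true(data: TimeSeriesDataset, i: int, tau: int, j: int, model: StructuralModel) -> CausalEffectEstimate:
    """Oracle regression on the generating parents of the target."""
    parents = [link.parent for link in model.links[j]]
    window = max([tau] + [m.lag for m in parents]) if parents else tau
    est = _regress_effect(data, i, tau, j, parents, window, "ce_true")
    return est
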