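"""Core data containers and lag-aligned sample construction.

Every conditional-independence test and every regression in this package
operates on lag-aligned samples: given a multivariate series ``X_t`` of
length ``T`` and a maximum lag window ``tau_max``, the usable samples are
the ``T - tau_max`` time points ``t = tau_max, ..., T - 1`` at which every
requested lagged variable ``X^i_{t - tau}`` is observed.  This module owns
that alignment so all downstream statistics see an identical sample set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Invalid analysis configuration (bad lag, bad parameter bounds)."""


class DataError(ValueError):
    """Invalid input data (NaNs, ragged rows, degenerate columns)."""


class InsufficientSamplesError(DataError):
    """Too few aligned samples for the requested test or regression."""


@dataclass(frozen=True, order=True)
class LaggedVariable:
    """A variable at a time lag: ``(var, lag)`` addresses ``X^var_{t - lag}``.

    ``lag >= 1`` for causal links; ``lag == 0`` is reserved for targets.
    """

    var: int
    lag: int

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ConfigurationError(f"variable index must be >= 0, got {self.var}")
        if self.lag < 0:
            raise ConfigurationError(f"lag must be >= 0, got {self.lag}")

    def shifted(self, by: int) -> "LaggedVariable":
        """Return the same variable shifted ``by`` additional steps into the past."""
        return LaggedVariable(self.var, self.lag + by)


class TimeSeriesDataset:
    """A ``T x N`` real-valued multivariate time series with named columns.

    Parameters
    ----------
    values
        Array of shape ``(T, N)``; rows are time steps, columns variables.
    names
        Optional list of ``N`` unique variable labels. Defaults to
        ``["X0", "X1", ...]``.
    """

    def __init__(self, values: np.ndarray, names: Sequence[str] | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2:
            raise DataError(f"values must be 2-D, got shape {values.shape}")
        T, N = values.shape
        if T == 0 or N == 0:
            raise DataError("dataset must have at least one row and one column")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            raise DataError(
                f"non-finite entries at (row, col): {bad[:5].tolist()}"
                + (" ..." if len(bad) > 5 else "")
            )
        if names is None:
            names = [f"X{i}" for i in range(N)]
        names = list(map(str, names))
        if len(names) != N:
            raise DataError(f"expected {N} names, got {len(names)}")
        if len(set(names)) != N:
            raise DataError("variable names must be unique")
        self.values = values
        self.names = names

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "TimeSeriesDataset":
        """Return a copy with every column scaled to zero mean, unit variance."""
        return TimeSeriesDataset(standardize_columns(self.values, names=self.names), self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeSeriesDataset(T={self.T}, N={self.N}, names={self.names})"


@dataclass
class ParentSet:
    """Estimated (or preliminary) lagged parents of one target variable.

    ``members`` are kept sorted by descending ``|score|`` after every
    condition-selection iteration; the score is the absolute test statistic
    of the member's most recent conditional-independence test.
    """

    target: int
    members: list[LaggedVariable] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.scores):
            raise ConfigurationError("members and scores must have equal length")
        if len(set(self.members)) != len(self.members):
            raise ConfigurationError("parent members must be distinct")
        for m in self.members:
            if m.lag < 1:
                raise ConfigurationError(f"parent {m} must have lag >= 1")

    def sort(self) -> None:
        """Stable sort by (|score| desc, lag asc, var asc) — deterministic."""
        order = sorted(
            range(len(self.members)),
            key=lambda k: (-abs(self.scores[k]), self.members[k].lag, self.members[k].var),
        )
        self.members = [self.members[k] for k in order]
        self.scores = [self.scores[k] for k in order]

    def strongest(self, n: int | None) -> list[LaggedVariable]:
        """The ``n`` strongest members (all of them when ``n`` is None)."""
        if n is None:
            return list(self.members)
        return self.members[: max(n, 0)]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: LaggedVariable) -> bool:
        return item in self.members


PX_UNRESTRICTED = "unrestricted"
ALPHA_PC_AUTO = "auto"


@dataclass
class AnalysisConfig:
    """Settings of one discovery run.

    Parameters
    ----------
    tau_max
        Maximum causal time lag considered (>= 1). Application dependent;
        a common heuristic is the last lag with significant unconditional
        dependency.
    alpha_pc
        Significance threshold of the condition-selection stage; acts as a
        regularization parameter, not a test level. ``"auto"`` selects it
        per variable from ``{0.1, 0.2, 0.3, 0.4}`` by AIC (ParCorr only).
    alpha
        Significance level applied to the final (FDR-adjusted, if enabled)
        p-values when thresholding the graph.
    p_x
        Number of strongest parents of the lagged driver variable added as
        extra conditions in the MCI test; ``"unrestricted"`` uses all.
    q_max
        Maximum condition-set combinations tested per candidate and
        iteration during condition selection (1 = the fast PC1 variant).
    test
        Conditional-independence test: ``parcorr``, ``gpdc`` or ``cmi``.
    fdr
        ``"bh"`` applies false-discovery-rate q-values, ``"none"`` skips.
    seed
        Master seed; all stochastic elements (surrogates, null caches,
        tie-break noise) derive from it via independent substreams.
    """

    tau_max: int
    alpha_pc: float | str = 0.2
    alpha: float = 0.05
    p_x: int | str = PX_UNRESTRICTED
    q_max: int = 1
    test: Literal["parcorr", "gpdc", "cmi"] = "parcorr"
    fdr: Literal["none", "bh"] = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_max < 1:
            raise ConfigurationError(f"tau_max must be >= 1, got {self.tau_max}")
        if isinstance(self.alpha_pc, str):
            if self.alpha_pc != ALPHA_PC_AUTO:
                raise ConfigurationError(f"alpha_pc must be a float or 'auto', got {self.alpha_pc!r}")
            if self.test != "parcorr":
                raise ConfigurationError("alpha_pc='auto' (AIC selection) requires test='parcorr'")
        elif not 0.0 < self.alpha_pc <= 1.0:
            raise ConfigurationError(f"alpha_pc must be in (0, 1], got {self.alpha_pc}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if isinstance(self.p_x, str):
            if self.p_x != PX_UNRESTRICTED:
                raise ConfigurationError(f"p_x must be an int >= 0 or 'unrestricted', got {self.p_x!r}")
        elif self.p_x < 0:
            raise ConfigurationError(f"p_x must be >= 0, got {self.p_x}")
        if self.q_max < 1:
            raise ConfigurationError(f"q_max must be >= 1, got {self.q_max}")
        if self.test not in ("parcorr", "gpdc", "cmi"):
            raise ConfigurationError(f"unknown test {self.test!r}")
        if self.fdr not in ("none", "bh"):
            raise ConfigurationError(f"fdr must be 'none' or 'bh', got {self.fdr!r}")

    @property
    def p_x_limit(self) -> int | None:
        return None if self.p_x == PX_UNRESTRICTED else int(self.p_x)


def standardize_columns(matrix: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    """Scale each column to mean 0 and unit sample variance (ddof=1).

    Raises :class:`DataError` naming the offending column if any column has
    zero variance.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise DataError("expected a 2-D matrix")
    if matrix.shape[1] == 0:
        return matrix.copy()
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(matrix.shape[1])
    zero = np.flatnonzero(~(sd > 0))
    if zero.size:
        label = names[zero[0]] if names is not None else str(zero[0])
        raise DataError(f"column {label!r} has zero variance; cannot standardize")
    return (matrix - mean) / sd


def build_lagged_design(
    data: TimeSeriesDataset,
    target: LaggedVariable,
    regressors: Sequence[LaggedVariable],
    tau_max: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Align a response vector and a lagged design matrix on common rows.

    Row ``k`` corresponds to time ``t = tau_max + k``; the response is the
    target variable at lag 0 and column ``m`` of the design holds
    ``X^{var_m}_{t - lag_m}``. Uses only the ``T - tau_max`` fully observed
    windows (no padding or wraparound), so every test in an analysis sees
    the same sample set.

    Returns
    -------
    (y, Z)
        ``y`` of length ``n = T - tau_max`` and ``Z`` of shape
        ``(n, len(regressors))`` in regressor order.
    """
    if target.lag != 0:
        raise ConfigurationError(f"target must have lag 0, got {target.lag}")
    for r in regressors:
        if r.lag > tau_max:
            raise ConfigurationError(
                f"regressor {r} has lag {r.lag} > tau_max={tau_max}; "
                "widen the alignment window"
            )
    n = data.T - tau_max
    if n <= len(regressors) + 2:
        raise InsufficientSamplesError(
            f"n = T - tau_max = {n} samples for {len(regressors)} regressors; "
            "need n > #regressors + 2"
        )
    y = data.values[tau_max:, target.var].copy()
    Z = np.empty((n, len(regressors)))
    for m, r in enumerate(regressors):
        Z[:, m] = data.values[tau_max - r.lag : data.T - r.lag, r.var]
    return y, Z


def read_timeseries_csv(path) -> TimeSeriesDataset:
    """Read a delimited text time series (header row = variable names).

    The delimiter is auto-detected among comma, tab and semicolon; numeric
    parsing is strict (any non-numeric or missing cell is a data error).
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise DataError(f"could not parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path} contains no data rows")
    arr = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()].tolist()
        if bad:
            raise DataError(
                f"column {col!r} has non-numeric or missing values in rows {bad[:5]}"
            )
        arr[:, j] = numeric.to_numpy()
    return TimeSeriesDataset(arr, names=list(map(str, df.columns)))


def write_timeseries_csv(data: TimeSeriesDataset, path) -> None:
    data.to_frame().to_csv(path, index=False)
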