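"""Structural time-series models: worked examples, random benchmark
networks, simulation, and an exact linear-Gaussian population oracle.

A structural model specifies, for each variable ``X^j``, a list of lagged
parents with coefficients and link functions plus a noise scale:

    X^j_t = sum_links f( coeff * parent_value ) + noise_sd_j * eta^j_t

with mutually independent standard-normal dynamical noise ``eta``.  For
linear models the stationary joint distribution is Gaussian and fully
characterized by the stationary covariance of the companion-form VAR,
obtained here from a discrete Lyapunov solve; population partial
correlations — the effect sizes that determine detection power — then
follow from precision-matrix identities without any simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from ._rng import substream
from .data import ConfigurationError, LaggedVariable, TimeSeriesDataset

__all__ = [
    "Link",
    "StructuralModel",
    "PopulationQuery",
    "NonstationaryError",
    "w_system_model",
    "w_pair_model",
    "random_network_model",
    "simulate",
    "check_stationarity",
    "stationary_covariance",
    "population_parcorr",
    "motivating_z_extension",
]

LINK_FUNCS = {
    "linear": lambda u: u,
    "quadratic": lambda u: u**2,
    "tanh": np.tanh,
}


class NonstationaryError(ValueError):
    """The linear model has companion spectral radius >= 1 (or diverged)."""


@dataclass(frozen=True)
class Link:
    parent: LaggedVariable
    coefficient: float
    func: str = "linear"

    def __post_init__(self) -> None:
        if self.parent.lag < 1:
            raise ConfigurationError("structural links must have lag >= 1 (no contemporaneous effects)")
        if self.func not in LINK_FUNCS and self.func != "custom":
            raise ConfigurationError(f"unknown link function {self.func!r}")


@dataclass
class StructuralModel:
    """Per-variable lagged parents, coefficients, link functions and noise."""

    N: int
    links: list[list[Link]]
    noise_sd: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.links) != self.N:
            raise ConfigurationError(f"need {self.N} link lists, got {len(self.links)}")
        if not self.noise_sd:
            self.noise_sd = [1.0] * self.N
        if len(self.noise_sd) != self.N or any(s <= 0 for s in self.noise_sd):
            raise ConfigurationError("noise_sd must be N positive reals")
        for j, lst in enumerate(self.links):
            for link in lst:
                if not 0 <= link.parent.var < self.N:
                    raise ConfigurationError(f"link parent {link.parent} of X{j} out of range")

    @property
    def max_lag(self) -> int:
        lags = [link.parent.lag for lst in self.links for link in lst]
        return max(lags) if lags else 1

    @property
    def is_linear(self) -> bool:
        return all(link.func == "linear" for lst in self.links for link in lst)

    def true_links(self, cross_only: bool = False) -> list[tuple[int, int, int]]:
        """Generating links as (source var i, target var j, lag tau)."""
        out = []
        for j, lst in enumerate(self.links):
            for link in lst:
                if cross_only and link.parent.var == j:
                    continue
                out.append((link.parent.var, j, link.parent.lag))
        return out

    def autocoefficients(self) -> np.ndarray:
        """Lag-1 autodependency coefficient per variable (0 when absent)."""
        out = np.zeros(self.N)
        for j, lst in enumerate(self.links):
            for link in lst:
                if link.parent.var == j and link.parent.lag == 1 and link.func == "linear":
                    out[j] = link.coefficient
        return out

    def to_json(self) -> str:
        doc = {
            "schema": 1,
            "N": self.N,
            "noise_sd": list(self.noise_sd),
            "links": [
                [
                    {"parent_var": l.parent.var, "lag": l.parent.lag, "coefficient": l.coefficient, "func": l.func}
                    for l in lst
                ]
                for lst in self.links
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StructuralModel":
        doc = json.loads(text)
        links = [
            [
                Link(LaggedVariable(l["parent_var"], l["lag"]), l["coefficient"], l["func"])
                for l in lst
            ]
            for lst in doc["links"]
        ]
        return cls(N=doc["N"], links=links, noise_sd=list(doc["noise_sd"]))


@dataclass(frozen=True)
class PopulationQuery:
    """A population partial-correlation query rho(x, y | conditions).

    ``y`` addresses the present (lag 0); ``x`` and the conditions address
    lagged variables; ``x`` must not appear among the conditions.
    """

    x: LaggedVariable
    y: LaggedVariable
    conditions: tuple[LaggedVariable, ...] = ()

    def __post_init__(self) -> None:
        if self.y.lag != 0:
            raise ConfigurationError("query target y must have lag 0")
        if self.x in self.conditions:
            raise ConfigurationError("x must not appear among the conditions")


def w_system_model() -> StructuralModel:
    """The six-variable coupled-pairs example system.

    Three independent driver-target pairs with identical cross-coupling
    c = 0.15 at lag 2 but increasing autocorrelation: a = 0.1 for the
    first pair, 0.5 for the second and 0.9 for the third; unit-variance
    standard-normal noise throughout.  Odd-indexed variables (0, 2, 4 here)
    are pure AR(1) drivers; even-indexed ones additionally receive the
    lag-2 coupling from their driver.
    """
    c = 0.15
    autos = [0.1, 0.1, 0.5, 0.5, 0.9, 0.9]
    links: list[list[Link]] = []
    for j in range(6):
        lst = [Link(LaggedVariable(j, 1), autos[j])]
        if j % 2 == 1:  # coupled target: driver is the preceding variable
            lst.append(Link(LaggedVariable(j - 1, 2), c))
        links.append(lst)
    return StructuralModel(N=6, links=links)


def w_pair_model(a: float, c: float = 0.15, lag: int = 2) -> StructuralModel:
    """One driver-target pair: both AR(1) with coefficient ``a``, plus the
    cross-coupling ``c`` from variable 0 into variable 1 at ``lag``."""
    links = [
        [Link(LaggedVariable(0, 1), a)],
        [Link(LaggedVariable(1, 1), a), Link(LaggedVariable(0, lag), c)],
    ]
    return StructuralModel(N=2, links=links)


DEFAULT_AUTO_VALUES = tuple(round(0.1 * k, 1) for k in range(1, 10))


def random_network_model(
    N: int,
    L: int,
    coeff_abs: float,
    auto_values=DEFAULT_AUTO_VALUES,
    max_lag: int = 5,
    func: str = "linear",
    seed: int = 0,
) -> StructuralModel:
    """A random benchmark network: N variables, each with a lag-1
    autodependency drawn from ``auto_values``, plus L distinct cross-links
    drawn uniformly over (ordered pair, lag in [1, max_lag]) with
    coefficient +/- ``coeff_abs`` (random sign — every cross-link has the
    same absolute coupling strength, hence the same causal effect).

    Models are redrawn until the linear skeleton is stationary (at most
    100 attempts); fully determined by ``seed``.
    """
    if L > N * (N - 1):
        raise ConfigurationError(f"L={L} exceeds the {N * (N - 1)} ordered pairs")
    if coeff_abs <= 0:
        raise ConfigurationError("coeff_abs must be > 0")
    rng = substream(seed, "random-network", N, L)
    pairs = [(i, j) for i in range(N) for j in range(N) if i != j]
    for _ in range(100):
        links: list[list[Link]] = [
            [Link(LaggedVariable(j, 1), float(rng.choice(auto_values)))] for j in range(N)
        ]
        chosen = rng.choice(len(pairs), size=L, replace=False)
        for idx in chosen:
            i, j = pairs[idx]
            lag = int(rng.integers(1, max_lag + 1))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            links[j].append(Link(LaggedVariable(i, lag), sign * coeff_abs, func))
        model = StructuralModel(N=N, links=links)
        if check_stationarity(_linear_skeleton(model)):
            return model
    raise NonstationaryError(
        "no stationary network found in 100 attempts; reduce coeff_abs"
    )


def _linear_skeleton(model: StructuralModel) -> StructuralModel:
    """The model with every link treated as linear (stationarity check for
    bounded nonlinear links is conservative via their linear skeleton)."""
    if model.is_linear:
        return model
    links = [
        [Link(l.parent, l.coefficient, "linear") for l in lst] for lst in model.links
    ]
    return StructuralModel(N=model.N, links=links, noise_sd=list(model.noise_sd))


def _companion_matrix(model: StructuralModel, p: int) -> np.ndarray:
    """Companion transition for the stacked state (X_t, ..., X_{t-p+1})."""
    N = model.N
    A = np.zeros((N * p, N * p))
    for j, lst in enumerate(model.links):
        for link in lst:
            if link.func != "linear":
                raise ConfigurationError("companion form requires a linear model")
            A[j, (link.parent.lag - 1) * N + link.parent.var] += link.coefficient
    if p > 1:
        A[N:, : N * (p - 1)] = np.eye(N * (p - 1))
    return A


def check_stationarity(model: StructuralModel) -> bool:
    """True iff the companion-matrix spectral radius is < 1."""
    A = _companion_matrix(_linear_skeleton(model), model.max_lag)
    return bool(np.max(np.abs(np.linalg.eigvals(A))) < 1.0)


def simulate(
    model: StructuralModel,
    T: int,
    seed: int = 0,
    burn_in: int | None = None,
    names=None,
) -> TimeSeriesDataset:
    """Iterate the structural equations for ``T`` steps after a burn-in.

    Burn-in defaults to ``10 * max_lag + 100`` steps (geometric mixing is
    fast for all autocorrelations <= 0.9).  Raises
    :class:`NonstationaryError` if any value exceeds 1e8 in magnitude.
    """
    p = model.max_lag
    if burn_in is None:
        burn_in = 10 * p + 100
    rng = substream(seed, "simulate", model.N, T)
    total = T + burn_in + p
    X = np.zeros((total, model.N))
    noise = rng.standard_normal((total, model.N)) * np.asarray(model.noise_sd)
    X[:p] = noise[:p]
    funcs = [
        [(LINK_FUNCS[l.func], l.parent.var, l.parent.lag, l.coefficient) for l in lst]
        for lst in model.links
    ]
    for t in range(p, total):
        for j, lst in enumerate(funcs):
            acc = noise[t, j]
            for f, var, lag, coeff in lst:
                acc += f(coeff * X[t - lag, var])
            X[t, j] = acc
        if np.max(np.abs(X[t])) > 1e8:
            raise NonstationaryError(f"simulation diverged at step {t}")
    return TimeSeriesDataset(X[burn_in + p :], names=names)


def stationary_covariance(model: StructuralModel, window: int) -> np.ndarray:
    """Exact stationary covariance of the stacked vector
    ``(X_t, X_{t-1}, ..., X_{t-window})`` for a linear Gaussian model.

    Builds the companion form over ``window + 1`` lags and solves the
    discrete Lyapunov equation ``S = A S A' + Q``.  Entry block ``(h, k)``
    is ``Cov(X_{t-h}, X_{t-k})``.
    """
    if not model.is_linear:
        raise ConfigurationError("stationary covariance requires a linear model")
    p = max(model.max_lag, window + 1)
    A = _companion_matrix(model, p)
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        raise NonstationaryError("companion spectral radius >= 1")
    Q = np.zeros_like(A)
    Q[: model.N, : model.N] = np.diag(np.square(model.noise_sd))
    S = solve_discrete_lyapunov(A, Q)
    S = (S + S.T) / 2.0
    m = model.N * (window + 1)
    return S[:m, :m]


def _stack_index(v: LaggedVariable, N: int) -> int:
    return v.lag * N + v.var


def population_parcorr(model: StructuralModel, query: PopulationQuery) -> float:
    """Population partial correlation rho(x, y | conditions) of a linear
    Gaussian model, from the precision matrix of the exact stationary
    covariance (Schur-complement identity)."""
    window = max([query.x.lag, query.y.lag] + [c.lag for c in query.conditions] + [model.max_lag])
    S = stationary_covariance(model, window)
    sel = [_stack_index(query.x, model.N), _stack_index(query.y, model.N)] + [
        _stack_index(c, model.N) for c in query.conditions
    ]
    C = S[np.ix_(sel, sel)]
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("singular condition covariance in population query") from exc
    if np.linalg.cond(C) > 1e12:
        raise ConfigurationError("near-singular condition covariance in population query")
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def motivating_z_extension(
    base: TimeSeriesDataset, driver: int | str = 0, seed: int = 0, name: str = "Z"
) -> TimeSeriesDataset:
    """Append a derived column ``Z_t = 2 * driver_{t-1} + eta_t`` with
    independent standard-normal noise (the first value, whose parent is
    unobserved, uses a zero-initialized parent)."""
    if isinstance(driver, str):
        driver = base.names.index(driver)
    rng = substream(seed, "z-extension", base.T)
    d = np.concatenate([[0.0], base.values[:-1, driver]])
    z = 2.0 * d + rng.standard_normal(base.T)
    return TimeSeriesDataset(
        np.column_stack([base.values, z]), names=base.names + [name]
    )
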