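"""Conditional-independence tests: ParCorr, GPDC and CMI.

All three tests share one contract: given samples of scalars ``x``, ``y``
and a condition matrix ``z`` (``n x D``), return a statistic and a p-value
for the null hypothesis X independent of Y given Z.

* **ParCorr** — partial correlation via OLS residuals; assumes linear
  additive dependencies; analytic Student-t p-value.
* **GPDC** — Gaussian-process regression of x and y on z, then a distance
  correlation between the residuals; assumes additive (possibly nonlinear)
  dependencies; p-value from a cached null distribution of distance
  correlations between independent normals of the same sample size.
* **CMI** — k-nearest-neighbour conditional mutual information with a
  local-permutation surrogate test; model-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma

from ._rng import substream
from .data import InsufficientSamplesError

__all__ = [
    "CITestResult",
    "CMIParams",
    "parcorr_test",
    "gp_regress_residuals",
    "distance_correlation",
    "gpdc_test",
    "cmi_knn_estimate",
    "cmi_test",
    "get_ci_test",
]


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test.

    ``statistic`` is a partial correlation in [-1, 1] for ParCorr, a
    distance correlation in [0, 1] for GPDC, and an estimated CMI in nats
    (possibly slightly negative) for CMI.
    """

    statistic: float
    pvalue: float
    n: int
    dim_z: int


@dataclass(frozen=True)
class CMIParams:
    """Parameters of the CMI test (defaults k_cmi=60, k_perm=5)."""

    k_cmi: int = 60
    k_perm: int = 5
    n_surrogates: int = 500

    def __post_init__(self) -> None:
        if not 1 <= self.k_perm <= self.k_cmi:
            raise ValueError(f"need 1 <= k_perm <= k_cmi, got {self.k_perm}, {self.k_cmi}")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


def _as_condition_matrix(z, n: int) -> np.ndarray:
    if z is None:
        return np.empty((n, 0))
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != n:
        raise ValueError(f"condition matrix has {z.shape[0]} rows, expected {n}")
    return z


def _ols_residuals(target: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, int]:
    """Residuals of target on [1, z]; drops collinear columns.

    Returns (residuals, effective condition dimension).
    """
    n = target.shape[0]
    X = np.column_stack([np.ones(n), z])
    beta, _, rank, _ = np.linalg.lstsq(X, target, rcond=None)
    dim = z.shape[1]
    if rank < X.shape[1]:
        warnings.warn(
            f"condition matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            "collinear columns are effectively dropped",
            stacklevel=3,
        )
        dim = rank - 1
    return target - X @ beta, dim


def parcorr_test(x, y, z=None) -> CITestResult:
    """Linear partial correlation rho(X, Y | Z) with analytic p-value.

    Regresses x and y on z (with intercept) by OLS, correlates the
    residuals, and converts via ``t = r sqrt((n - D - 2) / (1 - r^2))``
    to a two-sided Student-t p-value with ``n - D - 2`` degrees of
    freedom.  With ``D = 0`` this is the plain Pearson correlation test.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    z = _as_condition_matrix(z, n)
    D = z.shape[1]
    if n <= D + 3:
        raise InsufficientSamplesError(f"n={n} too small for D={D} conditions")
    if D > 0:
        rx, dim = _ols_residuals(x, z)
        ry, _ = _ols_residuals(y, z)
    else:
        rx, ry, dim = x - x.mean(), y - y.mean(), 0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float((rx @ ry) / denom) if denom > 0 else 0.0
    r = min(1.0, max(-1.0, r))
    df = n - dim - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CITestResult(statistic=r, pvalue=p, n=n, dim_z=dim)


def gp_regress_residuals(target, z, seed: int = 0) -> np.ndarray:
    """Residuals of a Gaussian-process regression of ``target`` on ``z``.

    Radial-basis kernel plus white-noise term, hyperparameters by marginal
    likelihood maximization.  On optimizer failure falls back to a
    median-heuristic kernel width with fixed noise level (with a warning).
    ``z`` with zero columns returns the centred target.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    target = np.asarray(target, dtype=float).ravel()
    n = target.shape[0]
    z = _as_condition_matrix(z, n)
    if z.shape[1] == 0:
        return target - target.mean()
    if n <= 10:
        raise InsufficientSamplesError(f"n={n} too small for GP regression")
    # median-heuristic initial length scale; robust across condition scales
    sub = z[:: max(1, n // 200)]
    d = np.abs(sub[:, None, :] - sub[None, :, :]).max(axis=-1)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(med, (1e-2 * med, 1e2 * med)) + WhiteKernel(
        0.1, (1e-6, 1e1)
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=seed & 0x7FFFFFFF
            ).fit(z, target)
        pred = gp.predict(z)
    except Exception:
        warnings.warn("GP hyperparameter optimization failed; using median-heuristic fallback")
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * RBF(med) + WhiteKernel(0.1),
            optimizer=None,
            normalize_y=True,
        ).fit(z, target)
        pred = gp.predict(z)
    return target - pred


def distance_correlation(u, v) -> float:
    """Empirical distance correlation between two samples (0 iff independent
    in the population limit; 1 for univariate linear dependence).

    Uses the standard double-centred distance matrices; constant input
    returns 0 by convention.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    if v.ndim == 1:
        v = v[:, None]
    n = u.shape[0]
    if v.shape[0] != n:
        raise ValueError("u and v must have equal length")
    if n < 10:
        raise InsufficientSamplesError(f"n={n} too small for distance correlation")

    def centered(mat):
        d = np.sqrt(((mat[:, None, :] - mat[None, :, :]) ** 2).sum(-1))
        return d - d.mean(0, keepdims=True) - d.mean(1, keepdims=True) + d.mean()

    A, B = centered(u), centered(v)
    dcov2 = (A * B).mean()
    dvar_u = (A * A).mean()
    dvar_v = (B * B).mean()
    if dvar_u <= 0 or dvar_v <= 0:
        return 0.0
    val = dcov2 / np.sqrt(dvar_u * dvar_v)
    return float(np.sqrt(max(val, 0.0)))


_GPDC_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def gpdc_null_distribution(n: int, n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Null distance correlations between independent standard normals.

    Residuals of a correct GP fit are approximately independent normals
    under the null, so this cached distribution calibrates the GPDC
    p-value per sample size. Deterministic given (n, n_draws, seed).
    """
    key = (n, n_draws, seed)
    if key not in _GPDC_NULL_CACHE:
        rng = substream(seed, "gpdc-null", n, n_draws)
        draws = np.empty(n_draws)
        for i in range(n_draws):
            draws[i] = distance_correlation(rng.standard_normal(n), rng.standard_normal(n))
        _GPDC_NULL_CACHE[key] = np.sort(draws)
    return _GPDC_NULL_CACHE[key]


def gpdc_test(x, y, z=None, seed: int = 0, null_draws: int = 1000) -> CITestResult:
    """GPDC: distance correlation between GP-regression residuals.

    The p-value is the right-tail rank of the statistic within the cached
    null distribution for this sample size.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    z = _as_condition_matrix(z, n)
    if n < 50:
        warnings.warn(f"n={n} < 50: GP fits may be unstable; proceeding")
    rx = gp_regress_residuals(x, z, seed=seed)
    ry = gp_regress_residuals(y, z, seed=seed + 1)
    stat = distance_correlation(rx, ry)
    null = gpdc_null_distribution(n, null_draws, seed=seed)
    exceed = int(np.sum(null >= stat))
    p = (1 + exceed) / (1 + null.size)
    return CITestResult(statistic=stat, pvalue=float(p), n=n, dim_z=z.shape[1])


def _neighbor_counts(points: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """#points strictly within eps_i of point i (max norm), excluding self."""
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=eps - 1e-13, p=np.inf, return_length=True)
    return np.asarray(counts) - 1


def cmi_knn_estimate(x, y, z=None, k_cmi: int = 60, seed: int = 0) -> float:
    """Nearest-neighbour conditional mutual information I(X; Y | Z) in nats.

    Uses maximum-norm distances in the joint (x, y, z) space; ``eps_i`` is
    the distance to the ``k_cmi``-th neighbour of point ``i`` and
    ``I = psi(k) + < psi(n_z + 1) - psi(n_xz + 1) - psi(n_yz + 1) >``
    with neighbour counts within ``eps_i`` in each subspace.  With empty
    ``z`` this reduces to the corresponding mutual-information estimator
    (``n_z = n - 1`` identically).  Duplicate points are broken by seeded
    noise of amplitude 1e-10.
    """
    x = np.asarray(x, dtype=float).reshape(len(x), -1)
    y = np.asarray(y, dtype=float).reshape(len(y), -1)
    n = x.shape[0]
    z = _as_condition_matrix(z, n)
    if n <= k_cmi + 10:
        raise InsufficientSamplesError(f"n={n} too small for k_cmi={k_cmi}")
    rng = substream(seed, "cmi-ties", n)
    joint = np.column_stack([x, y, z])
    joint = joint + rng.uniform(-1e-10, 1e-10, size=joint.shape)
    dx, dy = x.shape[1], y.shape[1]
    xs = joint[:, :dx]
    ys = joint[:, dx : dx + dy]
    zs = joint[:, dx + dy :]

    tree = cKDTree(joint)
    eps = tree.query(joint, k=k_cmi + 1, p=np.inf)[0][:, -1]

    n_xz = _neighbor_counts(np.column_stack([xs, zs]), eps)
    n_yz = _neighbor_counts(np.column_stack([ys, zs]), eps)
    if zs.shape[1] > 0:
        n_z = _neighbor_counts(zs, eps)
    else:
        n_z = np.full(n, n - 1)
    val = digamma(k_cmi) + np.mean(digamma(n_z + 1) - digamma(n_xz + 1) - digamma(n_yz + 1))
    return float(val)


def _local_permutation(x: np.ndarray, z: np.ndarray, k_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffle x among each point's k_perm nearest neighbours in z-space.

    Preserves the x-z dependence while breaking x-y|z; with empty z this is
    a full permutation.
    """
    n = x.shape[0]
    if z.shape[1] == 0:
        return x[rng.permutation(n)]
    tree = cKDTree(z)
    neighbors = tree.query(z, k=k_perm, p=np.inf)[1]  # includes self
    order = rng.permutation(n)
    used = np.zeros(n, dtype=bool)
    out = np.empty_like(x)
    for i in order:
        cand = neighbors[i][rng.permutation(k_perm)]
        pick = cand[0]
        for j in cand:
            if not used[j]:
                pick = j
                break
        used[pick] = True
        out[i] = x[pick]
    return out


def cmi_test(x, y, z=None, params: CMIParams | None = None, seed: int = 0) -> CITestResult:
    """CMI test with local-permutation surrogates.

    ``p = (1 + #{surrogate >= statistic}) / (1 + n_surrogates)``; surrogate
    datasets permute x locally among ``k_perm`` nearest neighbours in
    z-space (full permutations when z is empty).
    """
    params = params or CMIParams()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    z = _as_condition_matrix(z, n)
    stat = cmi_knn_estimate(x, y, z, k_cmi=params.k_cmi, seed=seed)
    rng = substream(seed, "cmi-surrogates", n)
    exceed = 0
    for s in range(params.n_surrogates):
        x_surr = _local_permutation(x, z, params.k_perm, rng)
        if cmi_knn_estimate(x_surr, y, z, k_cmi=params.k_cmi, seed=seed) >= stat:
            exceed += 1
    p = (1 + exceed) / (1 + params.n_surrogates)
    return CITestResult(statistic=stat, pvalue=float(p), n=n, dim_z=z.shape[1])


def get_ci_test(name: str, seed: int = 0, cmi_params: CMIParams | None = None):
    """Callable ``test(x, y, z) -> CITestResult`` for a configured test name."""
    if name == "parcorr":
        return lambda x, y, z=None: parcorr_test(x, y, z)
    if name == "gpdc":
        return lambda x, y, z=None: gpdc_test(x, y, z, seed=seed)
    if name == "cmi":
        return lambda x, y, z=None: cmi_test(x, y, z, params=cmi_params, seed=seed)
    raise ValueError(f"unknown CI test {name!r}")
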