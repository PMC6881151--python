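"""Two-stage causal discovery for autocorrelated multivariate time series.

Stage 1 (PC1) prunes, for every variable, the full lag grid down to a
small set of relevant conditions by iterative conditional-independence
testing against the currently strongest candidates (a fast, q_max = 1
variant of the PC-stable skeleton search).  Stage 2 tests every ordered
lagged pair with the momentary conditional independence (MCI) test, which
conditions on the estimated parents of the target *and* the time-shifted
parents of the lagged driver; the latter conditioning is what keeps false
positives controlled under strong autocorrelation and makes the statistic
interpretable as a normalized causal strength.

The classical full-conditioning baseline (FullCI: condition on the entire
past of all variables, lag-specific Granger causality) is provided for
comparison and arises as the special case alpha_pc = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .citests import CITestResult, get_ci_test
from .data import (
    AnalysisConfig,
    ConfigurationError,
    LaggedVariable,
    ParentSet,
    TimeSeriesDataset,
    build_lagged_design,
)

__all__ = [
    "DiscoveryResult",
    "pc1_select",
    "select_alpha_pc",
    "mci_test_link",
    "run_pcmci",
    "run_fullci",
    "fdr_qvalues",
    "significant_links",
]

ALPHA_PC_GRID = (0.1, 0.2, 0.3, 0.4)

CITest = Callable[..., CITestResult]


@dataclass
class DiscoveryResult:
    """Estimated lagged causal graph.

    Array entry ``[i, j, tau - 1]`` refers to the link
    ``X^i_{t - tau} -> X^j_t``.  ``graph`` holds the thresholded links
    (q-values when FDR was applied, raw p-values otherwise).
    """

    stats: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray | None
    parents: list[ParentSet]
    alpha_pc_used: list[float]
    graph: np.ndarray
    names: list[str]
    config: AnalysisConfig

    @property
    def N(self) -> int:
        return self.stats.shape[0]

    @property
    def tau_max(self) -> int:
        return self.stats.shape[2]

    def edge_records(self) -> list[dict]:
        """All links as records (source, target, lag, statistic, pvalue, qvalue)."""
        out = []
        for i in range(self.N):
            for j in range(self.N):
                for t in range(self.tau_max):
                    out.append(
                        {
                            "source": self.names[i],
                            "target": self.names[j],
                            "lag": t + 1,
                            "statistic": float(self.stats[i, j, t]),
                            "pvalue": float(self.pvalues[i, j, t]),
                            "qvalue": float(self.qvalues[i, j, t]) if self.qvalues is not None else None,
                            "in_graph": bool(self.graph[i, j, t]),
                        }
                    )
        return out

    def to_json(self) -> str:
        doc = {
            "schema": 1,
            "names": self.names,
            "tau_max": self.tau_max,
            "alpha": self.config.alpha,
            "test": self.config.test,
            "fdr": self.config.fdr,
            "seed": self.config.seed,
            "alpha_pc_used": [float(a) for a in self.alpha_pc_used],
            "parents": [
                {
                    "target": ps.target,
                    "members": [[m.var, m.lag] for m in ps.members],
                    "scores": [float(s) for s in ps.scores],
                }
                for ps in self.parents
            ],
            "links": self.edge_records(),
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def _all_candidates(N: int, tau_max: int) -> list[LaggedVariable]:
    return [LaggedVariable(i, tau) for tau in range(1, tau_max + 1) for i in range(N)]


def _run_member_test(
    data: TimeSeriesDataset,
    j: int,
    member: LaggedVariable,
    conditions: Sequence[LaggedVariable],
    tau_max: int,
    test: CITest,
) -> CITestResult:
    y, M = build_lagged_design(
        data, LaggedVariable(j, 0), [member, *conditions], tau_max
    )
    return test(M[:, 0], y, M[:, 1:])


def pc1_select(
    data: TimeSeriesDataset,
    j: int,
    config: AnalysisConfig,
    test: CITest | None = None,
) -> ParentSet:
    """Iterative condition selection for variable ``j``.

    Starts from all ``N * tau_max`` lagged variables.  Iteration ``p = 0``
    removes candidates without unconditional dependency (p-value >=
    alpha_pc); each following iteration tests every remaining candidate
    against the ``p`` currently strongest other candidates and applies
    removals only at the end of the iteration (PC-stable behaviour).
    Candidates are re-sorted after every iteration by the absolute
    statistic of their most recent test.  With ``q_max > 1`` up to that
    many distinct condition subsets of size ``p`` are tried per candidate
    (in lexicographic order on the sorted candidates) and a candidate is
    removed as soon as any subset renders it independent; the recorded
    score is then the smallest absolute statistic observed.

    ``alpha_pc = 1`` removes nothing: all candidates are returned, scored
    by their unconditional statistic.
    """
    if test is None:
        test = get_ci_test(config.test, seed=config.seed)
    if isinstance(config.alpha_pc, str):
        raise ConfigurationError("alpha_pc must be numeric here; use select_alpha_pc for 'auto'")
    alpha_pc = float(config.alpha_pc)

    members = _all_candidates(data.N, config.tau_max)
    scores: dict[LaggedVariable, float] = {}

    # p = 0: unconditional screening
    survivors: list[LaggedVariable] = []
    for m in members:
        res = _run_member_test(data, j, m, [], config.tau_max, test)
        scores[m] = abs(res.statistic)
        if alpha_pc >= 1.0 or res.pvalue < alpha_pc:
            survivors.append(m)
    ps = ParentSet(target=j, members=survivors, scores=[scores[m] for m in survivors])
    ps.sort()
    if alpha_pc >= 1.0:
        # no removals are possible at any cardinality: whole grid selected
        ps = ParentSet(target=j, members=list(members), scores=[scores[m] for m in members])
        ps.sort()
        return ps

    from itertools import combinations, islice

    p = 1
    while len(ps) > 1:
        tested_any = False
        removed: set[LaggedVariable] = set()
        for m in list(ps.members):
            others = [o for o in ps.members if o != m]
            if len(others) < p:
                continue
            tested_any = True
            worst = np.inf
            for S in islice(combinations(others, p), config.q_max):
                res = _run_member_test(data, j, m, S, config.tau_max, test)
                worst = min(worst, abs(res.statistic))
                if res.pvalue >= alpha_pc:
                    removed.add(m)
                    break
            scores[m] = worst
        if not tested_any:
            break
        keep = [m for m in ps.members if m not in removed]
        ps = ParentSet(target=j, members=keep, scores=[scores[m] for m in keep])
        ps.sort()
        p += 1
    return ps


def _ols_rss(data: TimeSeriesDataset, j: int, members: Sequence[LaggedVariable], tau_max: int) -> tuple[float, int]:
    y, Z = build_lagged_design(data, LaggedVariable(j, 0), members, tau_max)
    X = np.column_stack([np.ones(len(y)), Z])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), len(y)


def select_alpha_pc(
    data: TimeSeriesDataset,
    j: int,
    config: AnalysisConfig,
    candidates: Sequence[float] = ALPHA_PC_GRID,
    test: CITest | None = None,
) -> tuple[float, ParentSet]:
    """Pick alpha_pc for variable ``j`` by an AIC score (ParCorr only).

    For each candidate level, runs condition selection, fits the target on
    the selected conditions by OLS and scores
    ``n log(RSS) + 2 |parent set|``; the smallest-scoring level wins, with
    ties resolved toward the smaller (sparser) level.
    """
    if config.test != "parcorr":
        raise ConfigurationError("AIC-based alpha_pc selection is defined for the parcorr test")
    best: tuple[float, float, ParentSet] | None = None
    from dataclasses import replace

    for a in sorted(candidates):
        cfg = replace(config, alpha_pc=float(a))
        ps = pc1_select(data, j, cfg, test=test)
        rss, n = _ols_rss(data, j, ps.members, config.tau_max)
        score = n * np.log(max(rss, 1e-300)) + 2 * len(ps)
        if best is None or score < best[0]:
            best = (score, float(a), ps)
    assert best is not None
    return best[1], best[2]


def mci_test_link(
    data: TimeSeriesDataset,
    i: int,
    tau: int,
    j: int,
    parents_j: ParentSet,
    parents_i: ParentSet,
    p_x: int | None,
    test: CITest,
    tau_max: int,
) -> CITestResult:
    """Momentary conditional independence test of ``X^i_{t-tau} -> X^j_t``.

    Conditions on the target's parents (minus the tested link) plus the
    ``p_x`` strongest parents of the driver, each shifted ``tau`` steps
    further into the past.  Shifted parents with lag beyond ``tau_max``
    are kept by widening the alignment window (no lag bound applies to
    the driver's parents).  When the target's parent set already covers
    the complete ``N * tau_max`` lag grid, the whole past separates the
    driver's parents from the target, so the (redundant) shifted
    conditions are omitted — the test then *is* the full-conditioning
    (FullCI) test.
    """
    x = LaggedVariable(i, tau)
    conditions = [m for m in parents_j.members if m != x]
    if len(parents_j) < data.N * tau_max:
        for m in parents_i.strongest(p_x):
            shifted = m.shifted(tau)
            if shifted != x and shifted not in conditions:
                conditions.append(shifted)
    window = max([tau_max, tau] + [c.lag for c in conditions])
    y, M = build_lagged_design(data, LaggedVariable(j, 0), [x, *conditions], window)
    return test(M[:, 0], y, M[:, 1:])


def _full_parent_sets(N: int, tau_max: int) -> list[ParentSet]:
    return [
        ParentSet(target=j, members=_all_candidates(N, tau_max), scores=[0.0] * (N * tau_max))
        for j in range(N)
    ]


def _mci_stage(
    data: TimeSeriesDataset,
    parents: list[ParentSet],
    config: AnalysisConfig,
    test: CITest,
) -> tuple[np.ndarray, np.ndarray]:
    N, tau_max = data.N, config.tau_max
    stats = np.zeros((N, N, tau_max))
    pvals = np.ones((N, N, tau_max))
    for j in range(N):
        for i in range(N):
            for tau in range(1, tau_max + 1):
                res = mci_test_link(
                    data, i, tau, j, parents[j], parents[i], config.p_x_limit, test, tau_max
                )
                stats[i, j, tau - 1] = res.statistic
                pvals[i, j, tau - 1] = res.pvalue
    return stats, pvals


def _finalize(
    data: TimeSeriesDataset,
    parents: list[ParentSet],
    alpha_pc_used: list[float],
    stats: np.ndarray,
    pvals: np.ndarray,
    config: AnalysisConfig,
) -> DiscoveryResult:
    qvals = None
    if config.fdr == "bh":
        qvals = np.asarray(fdr_qvalues(pvals.ravel().tolist())).reshape(pvals.shape)
    basis = qvals if qvals is not None else pvals
    graph = basis <= config.alpha
    return DiscoveryResult(
        stats=stats,
        pvalues=pvals,
        qvalues=qvals,
        parents=parents,
        alpha_pc_used=alpha_pc_used,
        graph=graph,
        names=list(data.names),
        config=config,
    )


def run_pcmci(
    data: TimeSeriesDataset,
    config: AnalysisConfig,
    test: CITest | None = None,
    standardize: bool = True,
) -> DiscoveryResult:
    """Full two-stage discovery: condition selection, then the MCI test
    over all ``N^2 tau_max`` ordered lagged pairs.

    Variables are standardized once up front so that ParCorr statistics
    live on the correlation scale (p-values are unaffected).  With
    ``alpha_pc = 'auto'`` the selection level is chosen per variable by
    AIC.  FDR q-values are attached when ``config.fdr == 'bh'``.
    """
    if data.T <= (config.tau_max + 1) * 5:
        raise ConfigurationError(
            f"T={data.T} too short for tau_max={config.tau_max}"
        )
    if test is None:
        test = get_ci_test(config.test, seed=config.seed)
    if standardize:
        data = data.standardized()
    parents: list[ParentSet] = []
    alpha_pc_used: list[float] = []
    from dataclasses import replace

    for j in range(data.N):
        if config.alpha_pc == "auto":
            a, ps = select_alpha_pc(data, j, config, test=test)
        else:
            a, ps = float(config.alpha_pc), pc1_select(data, j, config, test=test)
        parents.append(ps)
        alpha_pc_used.append(a)
    stats, pvals = _mci_stage(data, parents, config, test)
    return _finalize(data, parents, alpha_pc_used, stats, pvals, config)


def run_fullci(
    data: TimeSeriesDataset,
    config: AnalysisConfig,
    test: CITest | None = None,
    standardize: bool = True,
) -> DiscoveryResult:
    """Full-conditioning baseline: test each lagged pair given all other
    ``N tau_max - 1`` lagged variables (lag-specific Granger causality).

    Requires ``N * tau_max < T - tau_max``; beyond that the regression
    dimensionality exceeds the sample count and the method is undefined.
    """
    n = data.T - config.tau_max
    if data.N * config.tau_max >= n:
        raise ConfigurationError(
            f"FullCI dimensionality N*tau_max = {data.N * config.tau_max} "
            f"exceeds the {n} available samples"
        )
    if test is None:
        test = get_ci_test(config.test, seed=config.seed)
    if standardize:
        data = data.standardized()
    parents = _full_parent_sets(data.N, config.tau_max)
    stats, pvals = _mci_stage(data, parents, config, test)
    return _finalize(data, parents, [1.0] * data.N, stats, pvals, config)


def fdr_qvalues(pvalues: Sequence[float], monotone: bool = False) -> list[float]:
    """False-discovery-rate q-values: ``q = min(P * m / r, 1)`` with ``r``
    the ascending rank of ``P`` (ties share the lower rank) and ``m`` the
    number of p-values; input order is preserved.

    ``monotone=True`` additionally applies the standard step-up
    monotonicity correction (enforcing q non-decreasing in P) as a
    documented extension; off by default.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    ranks = rankdata(p, method="min")
    q = np.minimum(p * m / ranks, 1.0)
    if monotone:
        order = np.argsort(p, kind="stable")
        qs = q[order]
        qs = np.minimum.accumulate(qs[::-1])[::-1]
        q = np.empty_like(qs)
        q[order] = qs
    return q.tolist()


def significant_links(result: DiscoveryResult, alpha: float) -> list[tuple]:
    """Links significant at ``alpha`` (q-values when present, else
    p-values), sorted by descending absolute statistic so the strongest
    causal links rank first.

    Returns tuples ``(i, j, tau, statistic, pvalue, qvalue_or_None)``.
    """
    basis = result.qvalues if result.qvalues is not None else result.pvalues
    rows = []
    for i in range(result.N):
        for j in range(result.N):
            for t in range(result.tau_max):
                if basis[i, j, t] <= alpha:
                    rows.append(
                        (
                            i,
                            j,
                            t + 1,
                            float(result.stats[i, j, t]),
                            float(result.pvalues[i, j, t]),
                            float(result.qvalues[i, j, t]) if result.qvalues is not None else None,
                        )
                    )
    rows.sort(key=lambda r: (-abs(r[3]), r[2], r[0], r[1]))
    return rows
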