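"""Full and partial correlation association networks.

Networks are grown around seed metabolites by breadth-first expansion:
depth-1 edges connect seeds to features passing both an |r| and a
BH-q threshold; depth-2 edges connect those recruits to further
features. Partial-correlation networks recompute coefficients on the
recruited node set from a Schafer-Strimmer shrinkage estimate of the
correlation matrix, which guarantees a well-conditioned inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .tabular import FeatureTable, TargetQuery
from .features import match_features
from .mwas import (
    DEFAULT_MIN_PAIRS,
    _log10_missing_zeros,
    _pairwise_pearson_matrix,
    bh_adjust,
    correlation_pvalue,
)

DEFAULT_NODE_CAP = 500


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise-coefficient matrix over a feature subset.

    ``shrinkage`` is the Schafer-Strimmer intensity lambda in [0, 1]
    (0 = sample estimate, 1 = identity target), present only for
    shrunk estimates.
    """

    feature_ids: list[str]
    values: np.ndarray
    method: str = "pearson"
    shrinkage: Optional[float] = None
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.feature_ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape must match feature_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        if self.shrinkage is not None and not (0.0 <= self.shrinkage <= 1.0):
            raise ValueError("shrinkage intensity must lie in [0, 1]")


@dataclass
class AssociationNetwork:
    """Seed-centered association network.

    Node attributes: mz, rt, is_seed, depth (0 seed / 1 primary /
    2 secondary). Edge attributes: r (signed), q, depth of discovery.
    """

    graph: nx.Graph
    method: str = "full"          # full | partial
    corr: str = "spearman"        # pearson | spearman
    r_min: float = 0.3
    q_max: float = 0.05
    seeds: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}


# ---------------------------------------------------------------------------
# correlation estimators
# ---------------------------------------------------------------------------

def _complete_case_matrix(
    table: FeatureTable,
    subset: Sequence[int],
    log_transform: bool,
    impute_half_min: bool = False,
) -> np.ndarray:
    """Samples x features data over ``subset``; complete-case rows or
    half-minimum imputed, ready for a joint covariance estimate."""
    X = table.intensities[np.asarray(subset, dtype=int), :].T.astype(float)
    if impute_half_min:
        for j in range(X.shape[1]):
            col = X[:, j]
            bad = ~np.isfinite(col) | (col <= 0)
            if bad.all():
                raise ValueError(f"feature {subset[j]} has no observed values")
            col[bad] = np.nanmin(np.where(col > 0, col, np.nan)) / 2.0
            X[:, j] = col
    if log_transform:
        X = _log10_missing_zeros(X)
    rows = np.isfinite(X).all(axis=1)
    X = X[rows, :]
    if X.shape[0] < 3:
        raise ValueError("fewer than 3 complete observations over the subset")
    return X


def sample_correlation_matrix(
    table: FeatureTable,
    subset: Sequence[int],
    method: str = "pearson",
    log_transform: bool = True,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over a feature subset."""
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 features")
    X = table.intensities[np.asarray(subset, dtype=int), :].astype(float)
    if log_transform:
        X = _log10_missing_zeros(X)
    if method == "spearman":
        Xr = np.empty_like(X)
        for i in range(X.shape[0]):
            row = X[i, :]
            ranked = np.full_like(row, np.nan)
            ok = np.isfinite(row)
            ranked[ok] = stats.rankdata(row[ok])
            Xr[i, :] = ranked
        X = Xr
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    k = len(subset)
    R = np.eye(k)
    for i in range(k):
        r_row, n_row = _pairwise_pearson_matrix(X[i + 1:, :], X[i, :])
        if np.any(n_row < min_pairs):
            j = int(np.flatnonzero(n_row < min_pairs)[0]) + i + 1
            raise ValueError(
                f"pair ({subset[i]}, {subset[j]}) has fewer than "
                f"{min_pairs} complete observations"
            )
        R[i, i + 1:] = r_row
        R[i + 1:, i] = r_row
    return CorrelationMatrix(
        feature_ids=[table.feature_ids[i] for i in subset],
        values=R,
        method=method,
        n_samples=table.n_samples,
    )


def shrinkage_intensity(X: np.ndarray) -> float:
    """Schafer-Strimmer optimal shrinkage toward the identity target.

    X is samples x variables with complete data. lambda* =
    sum_{i!=j} Var-hat(r_ij) / sum_{i!=j} r_ij^2, clipped to [0, 1],
    where Var-hat is the unbiased empirical variance of the
    standardized cross-products. All off-diagonals exactly zero gives
    lambda = 1 by convention.
    """
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variable in shrinkage estimation")
    W = (X - X.mean(axis=0)) / sd          # standardized data
    R = W.T @ W / (n - 1)                  # sample correlations
    # w_kij = W_ki * W_kj; Var-hat(r_ij) = n/(n-1)^3 * sum_k (w_kij - mean)^2
    wbar = R * (n - 1) / n
    sum_sq = np.einsum("ki,kj->ij", W * W, W * W)  # sum_k w_kij^2
    var_r = (n / (n - 1.0) ** 3) * (sum_sq - n * wbar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    if denom == 0.0:
        return 1.0
    lam = float(var_r[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def shrink_correlation(
    table: FeatureTable,
    subset: Sequence[int],
    log_transform: bool = True,
    impute_half_min: bool = False,
    shrinkage: Optional[float] = None,
) -> CorrelationMatrix:
    """Shrinkage correlation estimate r*_ij = (1 - lambda) r_ij, unit diagonal.

    Complete data over the subset are required; rows with any missing
    value are dropped unless ``impute_half_min`` replaces missing/zero
    cells with half the feature minimum first. ``shrinkage`` overrides
    the estimated lambda (0 reproduces the sample matrix exactly).
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 features")
    X = _complete_case_matrix(table, subset, log_transform, impute_half_min)
    n = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature over complete cases")
    W = (X - X.mean(axis=0)) / sd
    R = W.T @ W / (n - 1)
    lam = shrinkage_intensity(X) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    Rs = (1.0 - lam) * R
    np.fill_diagonal(Rs, 1.0)
    return CorrelationMatrix(
        feature_ids=[table.feature_ids[i] for i in subset],
        values=Rs,
        method="pearson",
        shrinkage=lam,
        n_samples=n,
    )


def cor_to_pcor(R: CorrelationMatrix, pinv_fallback: bool = True) -> CorrelationMatrix:
    """Partial correlations from a correlation matrix.

    P_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega = R^-1;
    unit diagonal. Falls back to the Moore-Penrose pseudoinverse for a
    singular R when ``pinv_fallback``.
    """
    V = R.values
    try:
        omega = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        if not pinv_fallback:
            raise
        omega = np.linalg.pinv(V)
    d = np.sqrt(np.abs(np.diag(omega)))
    P = -omega / np.outer(d, d)
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 1.0)
    return CorrelationMatrix(
        feature_ids=list(R.feature_ids),
        values=P,
        method=R.method,
        shrinkage=R.shrinkage,
        n_samples=R.n_samples,
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _prepare_scan_matrix(table: FeatureTable, corr: str, log_transform: bool) -> np.ndarray:
    X = table.intensities.astype(float)
    if log_transform:
        X = _log10_missing_zeros(X)
    if corr == "spearman":
        Xr = np.empty_like(X)
        for i in range(X.shape[0]):
            row = X[i, :]
            ranked = np.full_like(row, np.nan)
            ok = np.isfinite(row)
            ranked[ok] = stats.rankdata(row[ok])
            Xr[i, :] = ranked
        X = Xr
    elif corr != "pearson":
        raise ValueError(f"unknown correlation method {corr!r}")
    return X


def _resolve_seeds(
    table: FeatureTable,
    seeds: Sequence[TargetQuery],
    ppm_tol: float,
    rt_tol: float,
) -> list[int]:
    idx: list[int] = []
    for q in seeds:
        hits = match_features(table, [q], ppm_tol=ppm_tol, rt_tol=rt_tol)
        if not hits:
            raise ValueError(f"seed {q.label!r} matches no table feature")
        if hits[0].feature_index not in idx:
            idx.append(hits[0].feature_index)
    return idx


def build_association_network(
    table: FeatureTable,
    seeds: Sequence[TargetQuery],
    r_min: float = 0.3,
    q_max: float = 0.05,
    depth_max: int = 2,
    method: str = "full",
    corr: str = "spearman",
    ppm_tol: float = 10.0,
    rt_tol: float = 30.0,
    log_transform: bool = True,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    node_cap: int = DEFAULT_NODE_CAP,
    pooled_adjust: bool = False,
) -> AssociationNetwork:
    """Grow a seed-centered association network by breadth-first expansion.

    Wave w correlates every frontier node against all features not yet
    recruited; p-values come from the t transform and are BH-adjusted
    within the wave (or pooled across waves with ``pooled_adjust``).
    An edge is kept when |r| > r_min and q < q_max. In partial mode the
    recruited node set is re-estimated with shrinkage + inversion and
    edges are re-derived from the partial coefficients.
    """
    if not 0.0 <= r_min < 1.0:
        raise ValueError("r_min must lie in [0, 1)")
    if not 0.0 < q_max <= 1.0:
        raise ValueError("q_max must lie in (0, 1]")
    if depth_max not in (1, 2):
        raise ValueError("depth_max must be 1 or 2")
    if method not in ("full", "partial"):
        raise ValueError(f"unknown network method {method!r}")

    X = _prepare_scan_matrix(table, corr, log_transform)
    seed_idx = _resolve_seeds(table, seeds, ppm_tol, rt_tol)

    g = nx.Graph()
    depth_of: dict[int, int] = {}
    for i in seed_idx:
        g.add_node(
            table.feature_ids[i],
            mz=float(table.mz[i]),
            rt=float(table.rt[i]),
            is_seed=True,
            depth=0,
        )
        depth_of[i] = 0

    recruited = set(seed_idx)
    frontier = list(seed_idx)
    pooled: list[tuple[int, int, float, int, float, int]] = []  # u, v, r, n, p, wave

    for wave in range(1, depth_max + 1):
        if not frontier:
            break
        tests: list[tuple[int, int, float, int, float]] = []
        others = np.array([j for j in range(table.n_features) if j not in recruited], dtype=int)
        if others.size == 0:
            break
        sub = X[others, :]
        for f in frontier:
            r_vec, n_vec = _pairwise_pearson_matrix(sub, X[f, :])
            r_vec = np.where(n_vec < min_pairs, np.nan, r_vec)
            for j_loc in np.flatnonzero(np.isfinite(r_vec)):
                j = int(others[j_loc])
                r = float(r_vec[j_loc])
                n = int(n_vec[j_loc])
                if n < 3:
                    continue
                p = correlation_pvalue(r, n, "pearson")
                tests.append((f, j, r, n, p))
        if not tests:
            break
        if pooled_adjust:
            pooled.extend((*t, wave) for t in tests)
            continue
        qvals = bh_adjust([t[4] for t in tests])
        _accept_wave(g, table, depth_of, recruited, tests, qvals, wave, r_min, q_max, node_cap)
        frontier = [i for i, d in depth_of.items() if d == wave]

    if pooled_adjust and pooled:
        qvals = bh_adjust([t[4] for t in pooled])
        for wave in sorted({t[5] for t in pooled}):
            wave_tests = [(t[:5], qv) for t, qv in zip(pooled, qvals) if t[5] == wave]
            _accept_wave(
                g, table, depth_of, recruited,
                [t for t, _ in wave_tests], np.array([qv for _, qv in wave_tests]),
                wave, r_min, q_max, node_cap,
            )

    net = AssociationNetwork(
        graph=g, method=method, corr=corr, r_min=r_min, q_max=q_max,
        seeds=[table.feature_ids[i] for i in seed_idx],
    )
    if method == "partial":
        _repartialize(net, table, depth_of, log_transform, r_min, q_max)
    return net


def _accept_wave(g, table, depth_of, recruited, tests, qvals, wave, r_min, q_max, node_cap):
    for (f, j, r, n, p), qv in zip(tests, qvals):
        if not np.isfinite(qv) or abs(r) <= r_min or qv >= q_max:
            continue
        jid = table.feature_ids[j]
        if j not in recruited:
            if len(recruited) >= node_cap:
                raise RuntimeError(
                    f"node recruitment exceeded the cap of {node_cap}; "
                    f"raise r_min or lower q_max"
                )
            recruited.add(j)
            depth_of[j] = wave
            g.add_node(
                jid,
                mz=float(table.mz[j]),
                rt=float(table.rt[j]),
                is_seed=False,
                depth=wave,
            )
        fid = table.feature_ids[f]
        if not g.has_edge(fid, jid):
            g.add_edge(fid, jid, r=float(r), q=float(qv), depth=wave)


def _repartialize(net, table, depth_of, log_transform, r_min, q_max):
    """Recompute edges as shrinkage partial correlations on the recruited set."""
    nodes = sorted(depth_of, key=lambda i: (depth_of[i], i))
    if len(nodes) < 2:
        return
    R = shrink_correlation(table, nodes, log_transform=log_transform)
    P = cor_to_pcor(R)
    n = R.n_samples or table.n_samples
    k = len(nodes)
    ids = [table.feature_ids[i] for i in nodes]
    df = n - k
    pairs, pvals = [], []
    for a in range(k):
        for b in range(a + 1, k):
            pr = float(P.values[a, b])
            if df >= 1 and abs(pr) < 1.0:
                t = pr * np.sqrt(df) / np.sqrt(1.0 - pr * pr)
                p = float(2.0 * stats.t.sf(abs(t), df))
            else:
                p = 0.0 if abs(pr) >= 1.0 else np.nan
            pairs.append((a, b, pr))
            pvals.append(p)
    qvals = bh_adjust(pvals)
    g = net.graph
    g.remove_edges_from(list(g.edges()))
    for (a, b, pr), qv in zip(pairs, qvals):
        if np.isfinite(qv) and abs(pr) > r_min and qv < q_max:
            depth = min(g.nodes[ids[a]]["depth"], g.nodes[ids[b]]["depth"]) + 1
            g.add_edge(ids[a], ids[b], r=pr, q=float(qv), depth=depth)
    # drop non-seed nodes left isolated by re-thresholding
    isolated = [v for v in g.nodes if g.degree(v) == 0 and not g.nodes[v]["is_seed"]]
    g.remove_nodes_from(isolated)


def stringency_sweep(
    table: FeatureTable,
    seeds: Sequence[TargetQuery],
    thresholds: Sequence[float] = (0.3, 0.5, 0.7),
    q_max: float = 0.05,
    depth_max: int = 2,
    method: str = "full",
    corr: str = "spearman",
    **kwargs,
) -> list[AssociationNetwork]:
    """One network per |r| threshold, nested by edge set.

    The base network is built at the lowest threshold; each higher
    threshold keeps only the edges exceeding it and prunes nodes no
    longer connected to a seed within depth_max, so the edge sets are
    nested by construction.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    base = build_association_network(
        table, seeds, r_min=thresholds[0], q_max=q_max,
        depth_max=depth_max, method=method, corr=corr, **kwargs,
    )
    nets = [base]
    for thr in thresholds[1:]:
        nets.append(_filter_network(base, thr, depth_max))
    return nets


def _filter_network(base: AssociationNetwork, r_min: float, depth_max: int) -> AssociationNetwork:
    g = nx.Graph()
    for v, d in base.graph.nodes(data=True):
        g.add_node(v, **d)
    for u, v, d in base.graph.edges(data=True):
        if abs(d["r"]) > r_min:
            g.add_edge(u, v, **d)
    seeds = set(base.seeds)
    dist = nx.multi_source_dijkstra_path_length(g, seeds, weight=None) if seeds else {}
    keep = {v for v, dd in dist.items() if dd <= depth_max}
    g.remove_nodes_from([v for v in list(g.nodes) if v not in keep])
    for v in g.nodes:
        g.nodes[v]["depth"] = int(dist[v])
    for u, v in g.edges:
        g.edges[u, v]["depth"] = min(dist[u], dist[v]) + 1
    return AssociationNetwork(
        graph=g, method=base.method, corr=base.corr,
        r_min=r_min, q_max=base.q_max, seeds=list(base.seeds),
    )


def pattern_similarity(
    corr_a: CorrelationMatrix,
    corr_b: CorrelationMatrix,
    alpha: float = 0.05,
) -> list[str]:
    """Features whose pairwise correlation patterns agree across two studies.

    For each matched feature, its off-diagonal row in A is
    Pearson-correlated with its row in B (k-1 paired values); the
    feature is selected when the test p-value is below ``alpha`` and
    the coefficient is positive.
    """
    if list(corr_a.feature_ids) != list(corr_b.feature_ids):
        raise ValueError("correlation matrices must share an identical feature index")
    k = len(corr_a.feature_ids)
    if k < 3:
        raise ValueError("need at least 3 matched features")
    selected = []
    for f in range(k):
        mask = np.ones(k, dtype=bool)
        mask[f] = False
        a = corr_a.values[f, mask]
        b = corr_b.values[f, mask]
        if a.std() == 0 or b.std() == 0:
            continue
        res = stats.pearsonr(a, b)
        if res.statistic > 0 and res.pvalue < alpha:
            selected.append(corr_a.feature_ids[f])
    return selected
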