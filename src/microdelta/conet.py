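"""Compositional co-occurrence networks and differential-module detection.

Pipeline: SparCC correlations on each arm's post-treatment samples →
three-method ensemble edge significance (SparCC + Pearson + Spearman, all
p <= threshold with agreeing signs) → comparison of the two networks either
by the differential-modularity objective (scoring modules whose edge density
in the perturbed network exceeds the expectation set by the baseline
network's degrees) or by Louvain partitioning of the subtracted
"differential network" whose edges are positive increases in |correlation|.

SparCC in brief: with log-ratio variances ``t_ij = Var(log(x_i / x_j))``
and assuming most pairs are uncorrelated, the per-taxon basis variances
``w_i^2`` solve the linear system ``sum_j t_ij = (D - 2) w_i^2 + sum_k
w_k^2``; correlations follow from ``rho_ij = (w_i^2 + w_j^2 - t_ij) /
(2 w_i w_j)``.  Strongly correlated pairs violate the sparsity assumption,
so the strongest pair above a threshold is iteratively excluded from the
system and the solve repeated.  Dirichlet resampling of the fractions
propagates count uncertainty; the reported rho is the median across
resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.base import BaseEstimator, ClusterMixin

from .core_io import FeatureTable

__all__ = [
    "CorrelationEstimate",
    "CoNetwork",
    "DiffModules",
    "SparCC",
    "sparcc",
    "edge_pvalues",
    "build_network",
    "DifferentialModularity",
    "differential_modularity",
    "differential_network",
    "LouvainPartition",
    "louvain_partition",
    "hub_ranking",
]


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

class SparCC(BaseEstimator):
    """Sparse compositional correlation estimator.

    Parameters
    ----------
    n_resample : int
        Dirichlet resamples of the per-sample fractions; the final
        correlation matrix is the elementwise median across resamples.
    exclusion_threshold : float
        |rho| above which the strongest pair is excluded from the sparsity
        system and the basis variances re-solved.
    max_exclude_iter : int
        Cap on exclusion rounds per resample.
    pseudocount : float
        Added to every count before forming fractions (Dirichlet prior).
    random_state : int or None
        Seed for the resampling draws.

    Attributes
    ----------
    rho_ : ndarray of shape (D, D)
        Median basis correlations, unit diagonal, clipped to [-1, 1].
    basis_variance_ : ndarray of shape (D,)
        Median inferred basis variances w_i^2.
    logratio_variance_ : ndarray of shape (D, D)
        Median log-ratio variance matrix t_ij (zero diagonal).
    """

    def __init__(
        self,
        n_resample: int = 20,
        exclusion_threshold: float = 0.1,
        max_exclude_iter: int = 10,
        pseudocount: float = 1.0,
        random_state: int | None = None,
    ):
        self.n_resample = n_resample
        self.exclusion_threshold = exclusion_threshold
        self.max_exclude_iter = max_exclude_iter
        self.pseudocount = pseudocount
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    @staticmethod
    def _logratio_variances(logf: np.ndarray) -> np.ndarray:
        cov = np.cov(logf, rowvar=False)
        v = np.diag(cov)
        t = v[:, None] + v[None, :] - 2.0 * cov
        np.fill_diagonal(t, 0.0)
        return np.clip(t, 0.0, None)

    @staticmethod
    def _solve_basis(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
        d = t.shape[0]
        m = np.ones((d, d))
        np.fill_diagonal(m, d - 1)
        tvec = t.sum(axis=1)
        for i, j in excluded:
            m[i, i] -= 1.0
            m[j, j] -= 1.0
            m[i, j] = m[j, i] = 0.0
            tvec[i] -= t[i, j]
            tvec[j] -= t[i, j]
        omega2 = np.linalg.solve(m, tvec)
        return np.clip(omega2, 1e-12, None)

    @classmethod
    def _rho_from(cls, t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
        w = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(w, w))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho

    def _estimate_once(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = t.shape[0]
        excluded: set[tuple[int, int]] = set()
        degree = np.full(d, d - 1)
        omega2 = self._solve_basis(t, excluded)
        for _ in range(self.max_exclude_iter):
            rho = self._rho_from(t, omega2)
            a = np.abs(rho)
            np.fill_diagonal(a, 0.0)
            for i, j in excluded:
                a[i, j] = a[j, i] = 0.0
            i, j = np.unravel_index(np.argmax(a), a.shape)
            if a[i, j] <= self.exclusion_threshold:
                break
            if degree[i] <= 2 or degree[j] <= 2:
                break  # keep the system well determined
            excluded.add((min(i, j), max(i, j)))
            degree[i] -= 1
            degree[j] -= 1
            omega2 = self._solve_basis(t, excluded)
        return self._rho_from(t, omega2), omega2

    def fit(self, X, y=None) -> "SparCC":
        """Estimate basis correlations from a samples x features count matrix."""
        X = np.asarray(X, float)
        n, d = X.shape
        if d < 4:
            raise ValueError("SparCC needs at least 4 features (system under-determined)")
        if self.n_resample == 0:
            # deterministic mode: plain pseudocounted fractions, no resampling
            frac = X + self.pseudocount
            frac = frac / frac.sum(axis=1, keepdims=True)
            t = self._logratio_variances(np.log(frac))
            rho, omega2 = self._estimate_once(t)
            self.rho_ = rho
            self.basis_variance_ = omega2
            self.logratio_variance_ = t
            self.n_features_in_ = d
            return self
        rng = np.random.default_rng(self.random_state)
        rhos = np.empty((self.n_resample, d, d))
        omegas = np.empty((self.n_resample, d))
        ts = np.empty((self.n_resample, d, d))
        for r in range(self.n_resample):
            gam = rng.standard_gamma(X + self.pseudocount)
            frac = gam / gam.sum(axis=1, keepdims=True)
            t = self._logratio_variances(np.log(frac))
            rho, omega2 = self._estimate_once(t)
            rhos[r], omegas[r], ts[r] = rho, omega2, t
        self.rho_ = np.median(rhos, axis=0)
        np.fill_diagonal(self.rho_, 1.0)
        self.basis_variance_ = np.median(omegas, axis=0)
        self.logratio_variance_ = np.median(ts, axis=0)
        self.n_features_in_ = d
        return self


@dataclass
class CorrelationEstimate:
    """SparCC correlations plus the ensemble companion statistics."""

    feature_ids: list[str]
    rho: np.ndarray                       # SparCC basis correlations
    basis_variances: np.ndarray
    logratio_variances: np.ndarray
    r_pearson: np.ndarray | None = None
    r_spearman: np.ndarray | None = None
    p_sparcc: np.ndarray | None = None
    p_pearson: np.ndarray | None = None
    p_spearman: np.ndarray | None = None
    n_perm: int | None = None

    def __post_init__(self):
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")


def sparcc(
    table: FeatureTable,
    n_resample: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclude_iter: int = 10,
    pseudocount: float = 1.0,
    seed: int | None = None,
) -> CorrelationEstimate:
    """Functional wrapper over :class:`SparCC` for a feature table."""
    est = SparCC(
        n_resample=n_resample,
        exclusion_threshold=exclusion_threshold,
        max_exclude_iter=max_exclude_iter,
        pseudocount=pseudocount,
        random_state=seed,
    ).fit(table.counts)
    return CorrelationEstimate(
        feature_ids=table.feature_ids,
        rho=est.rho_,
        basis_variances=est.basis_variance_,
        logratio_variances=est.logratio_variance_,
    )


def _corr_with_pvalues(x: np.ndarray, rank: bool) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson (or Spearman via ranks) r and two-sided t-dist p."""
    n = x.shape[0]
    if rank:
        x = np.apply_along_axis(sps.rankdata, 0, x)
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = np.nan
    r = (xc.T @ xc) / n / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(tstat), np.where(np.isnan(r), np.nan, 0.0), p)
    np.fill_diagonal(p, 0.0)
    return r, p


def edge_pvalues(
    table: FeatureTable,
    estimate: CorrelationEstimate,
    n_perm: int = 999,
    seed: int | None = None,
    sparcc_kwargs: dict | None = None,
) -> CorrelationEstimate:
    """Attach the three per-edge p-value matrices to a SparCC estimate.

    Pearson and Spearman correlations (with their standard t-distribution
    p-values) are computed on pseudocounted fractions.  The SparCC p-value
    is a two-sided permutation test: each feature is shuffled independently
    across samples, rho re-estimated, and ``p = (#{|rho*| >= |rho|} + 1) /
    (n_perm + 1)``.
    """
    kw = dict(n_resample=20, exclusion_threshold=0.1, max_exclude_iter=10,
              pseudocount=1.0)
    if sparcc_kwargs:
        kw.update(sparcc_kwargs)
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)
    frac = (counts + kw["pseudocount"])
    frac = frac / frac.sum(axis=1, keepdims=True)
    r_p, p_p = _corr_with_pvalues(frac, rank=False)
    r_s, p_s = _corr_with_pvalues(frac, rank=True)

    obs = np.abs(estimate.rho)
    exceed = np.zeros_like(obs)
    n, d = counts.shape
    for _ in range(n_perm):
        perm = counts.copy()
        for f in range(d):
            perm[:, f] = perm[rng.permutation(n), f]
        est = SparCC(random_state=int(rng.integers(2**31 - 1)), **kw).fit(perm)
        exceed += np.abs(est.rho_) >= obs
    p_sp = (exceed + 1.0) / (n_perm + 1.0)
    np.fill_diagonal(p_sp, 0.0)

    return CorrelationEstimate(
        feature_ids=estimate.feature_ids,
        rho=estimate.rho,
        basis_variances=estimate.basis_variances,
        logratio_variances=estimate.logratio_variances,
        r_pearson=r_p,
        r_spearman=r_s,
        p_sparcc=p_sp,
        p_pearson=p_p,
        p_spearman=p_s,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class CoNetwork:
    """Taxon co-occurrence network with per-edge ensemble annotations.

    ``edges`` holds one row per unordered node pair with the signed weight
    (SparCC rho, or a positive |rho| difference for a differential
    network), the three method p-values where available, and the
    ensemble-significance flag.
    """

    feature_ids: list[str]
    edges: pd.DataFrame

    def __post_init__(self):
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        bad = (self.edges["node_i"].map(pos) >= self.edges["node_j"].map(pos))
        if bad.any():
            raise ValueError("edges must be stored with node_i before node_j; no self-edges")

    @property
    def n_nodes(self) -> int:
        return len(self.feature_ids)

    def adjacency(self, absolute: bool = True, significant_only: bool = False) -> np.ndarray:
        """Dense symmetric weight matrix (|weight| by default), zero diagonal."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        edges = self.edges
        if significant_only and "significant" in edges:
            edges = edges[edges["significant"]]
        for ni, nj, w in zip(edges["node_i"], edges["node_j"], edges["weight"]):
            v = abs(w) if absolute else w
            a[pos[ni], pos[nj]] = a[pos[nj], pos[ni]] = v
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.feature_ids)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.node_i, row.node_j, **{
                k: getattr(row, k) for k in self.edges.columns
                if k not in ("node_i", "node_j")
            })
        return g


def build_network(
    estimate: CorrelationEstimate, p_threshold: float = 0.001
) -> CoNetwork:
    """Dense network from a SparCC estimate with ensemble significance flags.

    An edge is flagged significant iff all three p-values are <= the
    threshold AND the SparCC, Pearson and Spearman coefficients agree in
    sign.  Requires all three p matrices; errors if the permutation count
    cannot resolve the requested threshold.
    """
    for name in ("p_sparcc", "p_pearson", "p_spearman"):
        if getattr(estimate, name) is None:
            raise ValueError(f"estimate lacks {name}; run edge_pvalues first")
    if estimate.n_perm is not None and 1.0 / (estimate.n_perm + 1) > p_threshold:
        raise ValueError(
            f"n_perm={estimate.n_perm} cannot attain p <= {p_threshold}; "
            f"need at least {int(np.ceil(1 / p_threshold)) - 1} permutations"
        )
    ids = estimate.feature_ids
    rows = []
    d = len(ids)
    for i in range(d):
        for j in range(i + 1, d):
            ps = (estimate.p_sparcc[i, j], estimate.p_pearson[i, j],
                  estimate.p_spearman[i, j])
            signs = (np.sign(estimate.rho[i, j]),
                     np.sign(estimate.r_pearson[i, j]),
                     np.sign(estimate.r_spearman[i, j]))
            sig = all(p <= p_threshold for p in ps) and len(set(signs)) == 1 and signs[0] != 0
            rows.append(
                {"node_i": ids[i], "node_j": ids[j],
                 "weight": estimate.rho[i, j],
                 "p_sparcc": ps[0], "p_pearson": ps[1], "p_spearman": ps[2],
                 "significant": bool(sig)}
            )
    return CoNetwork(ids, pd.DataFrame(rows))


def differential_network(
    udca: CorrelationEstimate | CoNetwork,
    placebo: CorrelationEstimate | CoNetwork,
    mode: str = "abs",
) -> CoNetwork:
    """Subtracted network of correlation increases under treatment.

    ``mode='abs'`` (default): edge weight ``|rho_udca| - |rho_placebo|``
    kept when positive — each edge is an increase in correlation strength.
    ``mode='signed'``: plain difference ``rho_udca - rho_placebo`` kept when
    positive.  The sign of the underlying treated-arm correlation is kept
    for display.
    """
    def _rho(x):
        if isinstance(x, CorrelationEstimate):
            return x.feature_ids, x.rho
        return x.feature_ids, _network_rho_matrix(x)

    ids_u, rho_u = _rho(udca)
    ids_p, rho_p = _rho(placebo)
    if ids_u != ids_p:
        raise ValueError("node sets differ between the two estimates")
    if mode == "abs":
        diff = np.abs(rho_u) - np.abs(rho_p)
    elif mode == "signed":
        diff = rho_u - rho_p
    else:
        raise ValueError("mode must be 'abs' or 'signed'")
    rows = []
    d = len(ids_u)
    for i in range(d):
        for j in range(i + 1, d):
            if diff[i, j] > 0:
                rows.append(
                    {"node_i": ids_u[i], "node_j": ids_u[j],
                     "weight": diff[i, j],
                     "udca_sign": float(np.sign(rho_u[i, j]))}
                )
    edges = pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "udca_sign"])
    return CoNetwork(ids_u, edges)


def _network_rho_matrix(net: CoNetwork) -> np.ndarray:
    a = net.adjacency(absolute=False)
    return a


# ---------------------------------------------------------------------------
# Generalized Louvain on an arbitrary symmetric gain matrix
# ---------------------------------------------------------------------------

def _local_moves(b: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """Greedy node moves maximising the within-module B sum, to convergence.

    A node may also split off into a fresh singleton community (profitable
    whenever its affinity to its current module is negative).  Ties in gain
    are broken toward the smallest community label for determinism.
    Returns True if any move improved the objective.
    """
    n = b.shape[0]
    improved = False
    moved = True
    while moved:
        moved = False
        order = rng.permutation(n)
        for u in order:
            lu = labels[u]
            # affinity of u to every community (excluding u itself)
            row = b[u].copy()
            row[u] = 0.0
            comms = np.unique(labels)
            aff = {c: row[labels == c].sum() for c in comms}
            current = aff.get(lu, 0.0)
            best_c, best_gain = lu, 0.0
            for c in sorted(aff):
                if c == lu:
                    continue
                gain = aff[c] - current
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            if -current > best_gain + 1e-12 and (labels == lu).sum() > 1:
                # split off into a new singleton community
                best_c = labels.max() + 1
                best_gain = -current
            if best_c != lu:
                labels[u] = best_c
                improved = True
                moved = True
    return improved


def _louvain_matrix_once(
    b: np.ndarray, seed: int | None = None, init: np.ndarray | None = None
) -> np.ndarray:
    """One Louvain-style agglomeration pass maximising sum of B within modules.

    The diagonal of B is partition-independent and ignored during moves.
    ``init`` seeds the first level with a starting partition (restarts use
    random ones).  Returns integer labels (relabelled 0..k-1 by first
    appearance).
    """
    n = b.shape[0]
    rng = np.random.default_rng(seed)
    node_labels = np.arange(n)       # labels on original nodes
    cur = b.copy()
    np.fill_diagonal(cur, 0.0)
    cur0 = cur.copy()
    groups = [np.array([i]) for i in range(n)]   # original nodes per supernode
    first = True
    while True:
        if first and init is not None:
            labels = init.copy()
            first = False
        else:
            labels = np.arange(cur.shape[0])
        improved = _local_moves(cur, labels, rng)
        uniq, inv = np.unique(labels, return_inverse=True)
        if (not improved and init is None) or len(uniq) == cur.shape[0]:
            for s, lab in enumerate(inv):
                node_labels[groups[s]] = -(lab + 1)  # mark final
            break
        # aggregate supernodes
        k = len(uniq)
        agg = np.zeros((k, k))
        new_groups = [np.concatenate([groups[s] for s in np.where(inv == c)[0]])
                      for c in range(k)]
        for a in range(k):
            sa = np.where(inv == a)[0]
            for c in range(a, k):
                sc = np.where(inv == c)[0]
                agg[a, c] = agg[c, a] = cur[np.ix_(sa, sc)].sum()
        np.fill_diagonal(agg, 0.0)
        cur = agg
        groups = new_groups
        init = None
    # flat refinement: single-node moves on the original matrix (undoing
    # any locks introduced by aggregation), then community merges, iterated
    # to a joint fixed point
    final = -node_labels - 1
    while True:
        _local_moves(cur0, final, rng)
        if not _merge_communities(cur0, final):
            break
    _, out = np.unique(final, return_index=False, return_inverse=True)
    remap: dict[int, int] = {}
    labels_out = np.empty(n, int)
    nxt = 0
    for i in range(n):
        lab = final[i]
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        labels_out[i] = remap[lab]
    return labels_out


def _merge_communities(b: np.ndarray, labels: np.ndarray) -> bool:
    """Greedily merge community pairs while any merge raises the objective."""
    improved = False
    while True:
        comms = np.unique(labels)
        k = len(comms)
        if k < 2:
            return improved
        # between-community total weights (ordered-pair sum = 2 * block sum)
        best_gain, best_pair = 0.0, None
        for a in range(k):
            ma = labels == comms[a]
            for c in range(a + 1, k):
                mc = labels == comms[c]
                gain = 2.0 * b[np.ix_(ma, mc)].sum()
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (comms[a], comms[c])
        if best_pair is None:
            return improved
        labels[labels == best_pair[1]] = best_pair[0]
        improved = True


def _louvain_matrix(
    b: np.ndarray, seed: int | None = None, n_restarts: int | None = None
) -> np.ndarray:
    """Best of ``n_restarts`` greedy runs.

    The first restart starts from singletons (classic Louvain); later ones
    start from random partitions with random block counts, which pulls the
    greedy out of the local optima that a pure agglomerative pass can lock
    into.  Small instances have rugged landscapes relative to their cost,
    so they get more restarts by default.  Node orders and initial
    partitions all derive from ``seed``.
    """
    n = b.shape[0]
    if n_restarts is None:
        n_restarts = 40 if n <= 16 else 12
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, -np.inf
    for r in range(max(1, n_restarts)):
        init = None
        if r > 0:
            k = int(rng.integers(1, n + 1))
            init = rng.integers(0, k, size=n)
        labels = _louvain_matrix_once(b, int(rng.integers(2**31 - 1)), init=init)
        obj = _objective(b, labels)
        if obj > best_obj + 1e-15:
            best_labels, best_obj = labels, obj
    return best_labels


def _objective(b: np.ndarray, labels: np.ndarray) -> float:
    """Sum of B over ordered same-module pairs, diagonal included."""
    mask = labels[:, None] == labels[None, :]
    return float((b * mask).sum())


def _contributions(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """c_i = sum_{j in module(i)} B_ij; module sums equal the module's share."""
    mask = labels[:, None] == labels[None, :]
    return (b * mask).sum(axis=1)


@dataclass(frozen=True)
class DiffModules:
    """Node-to-module assignment with per-node objective contributions."""

    modules: pd.Series        # node id -> module label (int)
    contributions: pd.Series  # node id -> contribution to the objective
    objective: float
    objective_kind: str       # 'modularity' or 'differential_modularity'

    def ranking(self) -> pd.Series:
        """Nodes sorted by contribution, descending (ties lexicographic)."""
        df = self.contributions.rename("contribution").to_frame()
        df["node"] = df.index
        df = df.sort_values(["contribution", "node"], ascending=[False, True])
        return df["contribution"]

    def n_modules(self) -> int:
        return int(self.modules.nunique())


class LouvainPartition(BaseEstimator, ClusterMixin):
    """Weighted-modularity Louvain community detection.

    Maximises ``Q = sum_{ij same module} [A_ij / 2m - resolution * k_i k_j /
    (2m)^2]`` (ordered pairs, diagonal null term included) by greedy
    agglomeration on the modularity matrix.

    Attributes
    ----------
    labels_ : ndarray
        Module label per node.
    modularity_ : float
        Q at the final partition.
    contributions_ : ndarray
        Per-node contribution; within a module these sum to the module's
        share of Q.
    """

    def __init__(self, resolution: float = 1.0, random_state: int | None = None):
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, A, y=None) -> "LouvainPartition":
        a = np.asarray(A, float)
        if (a < 0).any():
            raise ValueError("adjacency weights must be non-negative")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        a = a.copy()
        np.fill_diagonal(a, 0.0)
        two_m = a.sum()
        n = a.shape[0]
        if two_m == 0:
            self.labels_ = np.arange(n)
            self.modularity_ = 0.0
            self.contributions_ = np.zeros(n)
            self.b_matrix_ = np.zeros_like(a)
            return self
        k = a.sum(axis=1)
        b = a / two_m - self.resolution * np.outer(k, k) / two_m**2
        self.labels_ = _louvain_matrix(b, self.random_state)
        self.b_matrix_ = b
        self.modularity_ = _objective(b, self.labels_)
        self.contributions_ = _contributions(b, self.labels_)
        return self

    def fit_predict(self, A, y=None) -> np.ndarray:
        return self.fit(A).labels_


class DifferentialModularity(BaseEstimator):
    """Modules denser in a perturbed network than a baseline predicts.

    The gain matrix is ``B_ij = A'_ij / 2m' - resolution * k_i k_j /
    (2m)^2`` with perturbed-network weights ``A'`` and the null term taken
    from the *baseline* network's degrees (``null='baseline'``, the
    default); ``null='perturbed'`` uses the perturbed network's own degrees
    instead.  The objective ``D = sum_{ij same module} B_ij`` (ordered
    pairs, diagonal included) reduces exactly to ordinary weighted
    modularity when the two networks coincide.  Optimised by the same
    greedy agglomeration as :class:`LouvainPartition`; nodes are ranked by
    their contribution ``c_i = sum_{j in module(i)} B_ij``.
    """

    def __init__(
        self,
        resolution: float = 1.0,
        null: str = "baseline",
        random_state: int | None = None,
    ):
        self.resolution = resolution
        self.null = null
        self.random_state = random_state

    def fit(self, A_baseline, A_perturbed=None, y=None) -> "DifferentialModularity":
        ab = np.asarray(A_baseline, float).copy()
        ap = np.asarray(A_perturbed, float).copy()
        if ab.shape != ap.shape:
            raise ValueError("baseline and perturbed networks must share nodes")
        np.fill_diagonal(ab, 0.0)
        np.fill_diagonal(ap, 0.0)
        if ab.sum() == 0 or ap.sum() == 0:
            raise ValueError("empty edge set")
        if self.null not in ("baseline", "perturbed"):
            raise ValueError("null must be 'baseline' or 'perturbed'")
        ref = ab if self.null == "baseline" else ap
        two_m_ref = ref.sum()
        k = ref.sum(axis=1)
        b = ap / ap.sum() - self.resolution * np.outer(k, k) / two_m_ref**2
        self.labels_ = _louvain_matrix(b, self.random_state)
        self.b_matrix_ = b
        self.objective_ = _objective(b, self.labels_)
        self.contributions_ = _contributions(b, self.labels_)
        return self


def louvain_partition(net: CoNetwork, seed: int | None = None,
                      resolution: float = 1.0) -> DiffModules:
    """Louvain modules of a non-negative network (e.g. the differential one)."""
    a = net.adjacency(absolute=False)
    if (a < 0).any():
        raise ValueError("louvain_partition expects non-negative edge weights")
    est = LouvainPartition(resolution=resolution, random_state=seed).fit(a)
    ids = net.feature_ids
    return DiffModules(
        modules=pd.Series(est.labels_, index=ids, name="module"),
        contributions=pd.Series(est.contributions_, index=ids, name="contribution"),
        objective=est.modularity_,
        objective_kind="modularity",
    )


def differential_modularity(
    baseline: CoNetwork,
    perturbed: CoNetwork,
    resolution: float = 1.0,
    seed: int | None = None,
    null: str = "baseline",
) -> DiffModules:
    """Differential modules of ``perturbed`` relative to ``baseline``.

    Both networks enter through the absolute values of their edge weights
    (|SparCC rho|), weighting positive and negative co-occurrence equally.
    """
    if baseline.feature_ids != perturbed.feature_ids:
        raise ValueError("node sets differ between baseline and perturbed networks")
    est = DifferentialModularity(
        resolution=resolution, null=null, random_state=seed
    ).fit(baseline.adjacency(absolute=True), perturbed.adjacency(absolute=True))
    ids = baseline.feature_ids
    return DiffModules(
        modules=pd.Series(est.labels_, index=ids, name="module"),
        contributions=pd.Series(est.contributions_, index=ids, name="contribution"),
        objective=est.objective_,
        objective_kind="differential_modularity",
    )


def hub_ranking(net: CoNetwork) -> pd.Series:
    """Nodes ordered by strength (sum of incident |weights|), ties lexicographic."""
    strength = dict.fromkeys(net.feature_ids, 0.0)
    for row in net.edges.itertuples(index=False):
        w = abs(row.weight)
        strength[row.node_i] += w
        strength[row.node_j] += w
    s = pd.Series(strength, name="strength")
    df = s.to_frame()
    df["node"] = df.index
    df = df.sort_values(["strength", "node"], ascending=[False, True])
    return df["strength"]
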