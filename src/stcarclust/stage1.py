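"""Stage 1: residual estimation and candidate cluster structures.

The neighbourhood matrix candidates are built from clusterings of the
estimated spatial residuals

    phi_tilde_it = ln(Y*_it / E_it) - x_it' beta_hat,

where beta_hat is the maximum-likelihood Poisson fit with offset ln(E)
assuming independence, and Y* applies a continuity correction to zero
counts so the log-ratio is defined.  Eight clustering methods are applied
without regard to spatial position — clusters represent distinct *risk
levels*, not spatially contiguous regions:

    1 k-means                  5 agglomerative, average linkage
    2 k-medoids (PAM)          6 agglomerative, Ward linkage
    3 agglomerative, centroid  7 divisive (DIANA)
    4 agglomerative, complete  8 Gaussian-mixture EM

Single linkage is deliberately absent (chaining).  Variant A clusters each
area's length-T residual profile once; variant B clusters the length-n
residual vector of each period separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .data import CountData

__all__ = [
    "METHODS",
    "ResidualSurface",
    "ClusteringRequest",
    "estimate_phi_tilde",
    "run_clustering",
    "build_partitions_A",
    "build_partitions_B",
]

#: Integer key -> clustering method name.
METHODS: Dict[int, str] = {
    1: "kmeans",
    2: "kmedoids",
    3: "agg_centroid",
    4: "agg_complete",
    5: "agg_average",
    6: "agg_ward",
    7: "div",
    8: "EM",
}
_NAME_TO_KEY = {v: k for k, v in METHODS.items()}
_LINKAGE = {"agg_centroid": "centroid", "agg_complete": "complete",
            "agg_average": "average", "agg_ward": "ward"}


@dataclass
class ResidualSurface:
    """Estimated spatial residuals ``phi_tilde`` (n x T) and stage-1 betas."""

    phi_tilde: np.ndarray
    beta_hat: np.ndarray

    def __post_init__(self) -> None:
        self.phi_tilde = np.asarray(self.phi_tilde, dtype=float)
        if not np.all(np.isfinite(self.phi_tilde)):
            raise ValueError("non-finite residuals")


@dataclass
class ClusteringRequest:
    method: Union[int, str]
    k: int
    data: np.ndarray
    seed: int = 0


def estimate_phi_tilde(data: CountData, zero_adjust: float = 0.5) -> ResidualSurface:
    """Spatial residuals from a working independence Poisson fit.

    The regression coefficients are the ML fit of ``Y ~ Poisson(E exp(x'b))``
    treating all cells as independent; for the intercept-only model this is
    ``b0 = ln(sum Y / sum E)`` in closed form.  Zero counts are replaced by
    ``zero_adjust`` (default 0.5) in the log-ratio only, never in the ML fit.
    """
    Y, E = data.Y, data.E
    if data.X is None:
        beta_hat = np.array([np.log(Y.sum() / E.sum())])
        xb = np.full(Y.shape, beta_hat[0])
    else:
        import statsmodels.api as sm

        Xf = np.column_stack(
            [np.ones(Y.size)] + [data.X[:, :, j].ravel() for j in range(data.p)]
        )
        fit = sm.GLM(
            Y.ravel(), Xf, family=sm.families.Poisson(), offset=np.log(E).ravel()
        ).fit()
        beta_hat = np.asarray(fit.params)
        xb = (Xf @ beta_hat).reshape(Y.shape)
    Ystar = np.where(Y == 0, zero_adjust, Y)
    phi_tilde = np.log(Ystar / E) - xb
    return ResidualSurface(phi_tilde=phi_tilde, beta_hat=beta_hat)


def _pam(X: np.ndarray, k: int, seed: int, max_iter: int = 50) -> np.ndarray:
    """Partitioning Around Medoids with Euclidean distance (BUILD + SWAP)."""
    n = X.shape[0]
    D = squareform(pdist(X))
    # BUILD: first medoid minimises total distance, then greedy gain
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest_d = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest_d[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest_d = np.minimum(nearest_d, D[:, m])
    medoids = np.array(medoids)
    for _ in range(max_iter):
        Dm = D[:, medoids]  # n x k
        order = np.argsort(Dm, axis=1)
        d1 = Dm[np.arange(n), order[:, 0]]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        nearest = order[:, 0]
        cost = d1.sum()
        best = (0.0, None, None)
        for mi in range(k):
            base = np.where(nearest == mi, d2, d1)
            swap_costs = np.minimum(base[:, None], D).sum(axis=0)  # cost for each h
            h = int(np.argmin(swap_costs))
            delta = swap_costs[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    Dm = D[:, medoids]
    return Dm.argmin(axis=1) + 1


def _diana(X: np.ndarray, k: int) -> np.ndarray:
    """DIANA-style divisive hierarchy cut at k clusters.

    Repeatedly splits the cluster with the largest diameter by seeding a
    splinter group with the most dissimilar member and migrating members
    whose mean dissimilarity favours the splinter.
    """
    n = X.shape[0]
    D = squareform(pdist(X))
    clusters = [list(range(n))]
    while len(clusters) < k:
        diameters = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        ci = int(np.argmax(diameters))
        if diameters[ci] <= 0.0:
            break  # nothing left to split (duplicate points)
        members = clusters[ci]
        sub = D[np.ix_(members, members)]
        m = len(members)
        in_spl = np.zeros(m, dtype=bool)
        in_spl[int(np.argmax(sub.mean(axis=1)))] = True
        row_tot = sub.sum(axis=1)
        while (~in_spl).sum() > 1:
            rest = np.flatnonzero(~in_spl)
            spl_sum = sub[:, in_spl].sum(axis=1)
            n_spl = int(in_spl.sum())
            d_spl = spl_sum[rest] / n_spl
            d_rest = (row_tot[rest] - spl_sum[rest]) / (m - n_spl - 1)
            diff = d_rest - d_spl
            j = int(np.argmax(diff))
            if diff[j] <= 0:
                break
            in_spl[rest[j]] = True
        clusters[ci] = [members[i] for i in np.flatnonzero(~in_spl)]
        clusters.append([members[i] for i in np.flatnonzero(in_spl)])
    labels = np.empty(n, dtype=np.int64)
    for li, c in enumerate(clusters, start=1):
        labels[c] = li
    return labels


def run_clustering(req: ClusteringRequest) -> "Partition":
    """Dispatch one clustering method; returns labels in ``1..k``.

    Methods operate on feature values only (never on adjacency).  If a
    method returns fewer than ``k`` non-empty clusters (e.g. EM component
    collapse on near-degenerate data) the partition is kept as-is.
    """
    from .graph import Partition

    X = np.atleast_2d(np.asarray(req.data, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    k = int(req.k)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for n={n}")
    name = req.method if isinstance(req.method, str) else METHODS[int(req.method)]
    if name not in _NAME_TO_KEY:
        raise ValueError(f"unknown clustering method {req.method!r}")
    if k == 1:
        return Partition(np.ones(n, dtype=np.int64), k=1)
    if np.allclose(X, X[0]):  # zero-variance features: a single effective cluster
        return Partition(np.ones(n, dtype=np.int64), k=k)

    if name == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=req.seed)
        labels = km.fit_predict(X) + 1
    elif name == "kmedoids":
        labels = _pam(X, k, req.seed)
    elif name in _LINKAGE:
        Z = linkage(X, method=_LINKAGE[name])
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif name == "div":
        labels = _diana(X, k)
    else:  # EM
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full" if X.shape[1] > 1 else "spherical",
                random_state=req.seed,
                reg_covar=1e-6,
                n_init=1,
            )
            labels = gm.fit_predict(X) + 1
        except ValueError:
            labels = np.ones(n, dtype=np.int64)
    return Partition(_canonical_labels(X, np.asarray(labels)), k=k)


def _canonical_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..g in increasing order of their mean feature level.

    Clustering algorithms assign arbitrary label identities; ordering them by
    the cluster mean (averaged over feature dimensions) makes labels
    semantically comparable — label 1 is always the lowest-risk level — so
    partitions from different methods or different time periods can be
    concatenated and compared directly.
    """
    uniq, inv = np.unique(labels, return_inverse=True)
    means = np.array([X[inv == g].mean() for g in range(uniq.size)])
    order = np.argsort(means, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(uniq.size)
    return (rank[inv] + 1).astype(np.int64)


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(seed)] + [int(x) for x in key])
    return int(ss.generate_state(1)[0] % (2**31))


def build_partitions_A(
    res: ResidualSurface, M: int = 8, K: int = 10, seed: int = 0
) -> Dict[Tuple[int, int], "Partition"]:
    """Variant-A partitions: cluster the areas' length-T residual profiles.

    Covers ``c = 1..M`` and ``k = 2..K`` — the ``(K-1) * M`` structures that,
    with the shared border-sharing matrix, form the variant-A candidate set.
    """
    out = {}
    for c in range(1, M + 1):
        for k in range(2, K + 1):
            req = ClusteringRequest(
                method=c, k=k, data=res.phi_tilde, seed=_child_seed(seed, c, k)
            )
            out[(c, k)] = run_clustering(req)
    return out


def build_partitions_B(
    res: ResidualSurface, M: int = 8, K: int = 10, seed: int = 0
) -> Dict[Tuple[int, int, int], "Partition"]:
    """Variant-B partitions: cluster each period's residual vector separately."""
    out = {}
    T = res.phi_tilde.shape[1]
    for t in range(1, T + 1):
        col = res.phi_tilde[:, t - 1 : t]
        for c in range(1, M + 1):
            for k in range(2, K + 1):
                req = ClusteringRequest(
                    method=c, k=k, data=col, seed=_child_seed(seed, c, k, t)
                )
                out[(c, k, t)] = run_clustering(req)
    return out
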