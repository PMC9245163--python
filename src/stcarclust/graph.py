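"""Areal adjacency structures and candidate neighbourhood matrices.

A study region of ``n`` non-overlapping areal units is represented by a
symmetric binary neighbourhood matrix ``W`` with zero diagonal, where
``w_ij = 1`` denotes that units ``(i, j)`` share a common border.  A cluster
partition of the units induces a *candidate* neighbourhood matrix by severing
every border between units assigned to different clusters, so that their
random effects become conditionally independent under a CAR prior.  The full
family of candidates produced by the stage-1 clustering methods is held in a
:class:`CandidateSet`, which also caches the eigenvalues of the graph
Laplacian ``diag(W1) - W`` of each candidate so that Leroux-precision
log-determinants can be evaluated in O(n) during MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AreaGraph",
    "Partition",
    "CandidateSet",
    "border_sharing_matrix",
    "candidate_from_partition",
    "assemble_candidate_set",
]


@dataclass(frozen=True)
class Partition:
    """A hard clustering of the ``n`` areal units into at most ``k`` groups.

    ``labels`` holds integer cluster ids in ``1..k``; the number of
    *distinct* labels may be smaller than ``k`` when a clustering method
    returns empty clusters (e.g. mixture-component collapse).
    """

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        if labels.size and (labels.min() < 1 or labels.max() > self.k):
            raise ValueError("labels must lie in 1..k")
        if np.unique(labels).size > self.k:
            raise ValueError("more than k distinct labels")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_effective(self) -> int:
        """Number of non-empty clusters actually present."""
        return int(np.unique(self.labels).size)


class AreaGraph:
    """Symmetric binary adjacency over ``n`` areal units.

    Internally areas are indexed ``0..n-1``; arbitrary input identifiers are
    mapped through ``ids`` and restored on output.  The graph may be
    disconnected (estuaries and rivers split real study regions), so no
    connectivity check is enforced.
    """

    def __init__(
        self,
        n: int,
        edges: Sequence[Tuple[int, int]],
        ids: Optional[Sequence[Hashable]] = None,
    ) -> None:
        if n < 1:
            raise ValueError("n must be positive")
        canon = set()
        for a, b in edges:
            a, b = int(a), int(b)
            if a == b:
                raise ValueError(f"self-adjacency for area index {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) out of range for n={n}")
            canon.add((min(a, b), max(a, b)))
        self.n = int(n)
        self.edges = frozenset(canon)
        self.ids = list(ids) if ids is not None else list(range(n))
        if len(self.ids) != n:
            raise ValueError("ids length must equal n")
        self._W = _edges_to_csr(self.n, self.edges)

    @property
    def W(self) -> sp.csr_matrix:
        """Sparse symmetric binary neighbourhood matrix (zero diagonal)."""
        return self._W

    @property
    def rowsums(self) -> np.ndarray:
        """Number of neighbours of each area, ``diag(W1)``."""
        return np.asarray(self._W.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self._W.toarray()

    @classmethod
    def from_matrix(cls, W, ids: Optional[Sequence[Hashable]] = None) -> "AreaGraph":
        W = np.asarray(sp.csr_matrix(W).toarray(), dtype=float)
        n = W.shape[0]
        if W.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(W, W.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("adjacency matrix must have zero diagonal")
        if not np.isin(W, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0/1")
        rows, cols = np.nonzero(np.triu(W, 1))
        return cls(n, list(zip(rows.tolist(), cols.tolist())), ids=ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AreaGraph)
            and self.n == other.n
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"AreaGraph(n={self.n}, n_edges={len(self.edges)})"


def _edges_to_csr(n: int, edges) -> sp.csr_matrix:
    if not edges:
        return sp.csr_matrix((n, n))
    rows, cols = [], []
    for a, b in edges:
        rows += [a, b]
        cols += [b, a]
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def border_sharing_matrix(
    edge_list: Sequence[Tuple[Hashable, Hashable]],
    n: Optional[int] = None,
    ids: Optional[Sequence[Hashable]] = None,
) -> AreaGraph:
    """Build the border-sharing :class:`AreaGraph` from a list of id pairs.

    ``ids`` fixes the area ordering; if omitted and ``n`` is given, ids are
    assumed to already be integer indices ``0..n-1``.
    """
    if ids is not None:
        lookup = {a: i for i, a in enumerate(ids)}
        if len(lookup) != len(ids):
            raise ValueError("duplicate area ids")
        try:
            edges = [(lookup[a], lookup[b]) for a, b in edge_list]
        except KeyError as exc:  # pragma: no cover - message only
            raise ValueError(f"unknown area id {exc.args[0]!r}") from exc
        return AreaGraph(len(ids), edges, ids=ids)
    if n is None:
        raise ValueError("either n or ids must be given")
    return AreaGraph(n, [(int(a), int(b)) for a, b in edge_list])


def candidate_from_partition(G: AreaGraph, p: Partition) -> sp.csr_matrix:
    """Candidate neighbourhood matrix retaining borders within clusters only.

    Entry ``(i, j)`` is 1 iff units ``i`` and ``j`` share a border *and* lie
    in the same cluster of ``p``; all cross-cluster borders are severed.  The
    result is always an entrywise subgraph of ``G.W``.
    """
    labels = np.asarray(p.labels)
    if labels.size != G.n:
        raise ValueError("partition length does not match graph size")
    W = G.W.tocoo()
    keep = labels[W.row] == labels[W.col]
    return sp.csr_matrix(
        (W.data[keep], (W.row[keep], W.col[keep])), shape=(G.n, G.n)
    )


@dataclass
class CandidateSet:
    """Indexed family of candidate neighbourhood matrices.

    Position 0 always holds the single border-sharing matrix; all ``k = 1``
    solutions of every clustering method collapse onto it so the discrete
    uniform prior gives the no-cluster structure the same weight as any other
    candidate.  ``index`` maps ``(c, k)`` labels (variant A) or ``(c, k, t)``
    labels (variant B) to matrix positions.  Eigenvalues of
    ``diag(W1) - W`` and the Laplacians themselves are cached per matrix.
    """

    matrices: List[sp.csr_matrix]
    index: Dict[Tuple[int, ...], int]
    partitions: List[np.ndarray]
    M: int
    K: int
    variant: str
    T: Optional[int] = None
    eigenvalues: List[np.ndarray] = field(default_factory=list)
    laplacians: List[sp.csr_matrix] = field(default_factory=list)
    rowsums: List[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        return self.matrices[0].shape[0]

    def position(self, label: Tuple[int, ...]) -> int:
        return self.index[tuple(label)]

    def logdet_Q(self, pos: int, rho: float) -> float:
        """``log det Q(rho, W)`` for candidate ``pos`` from cached eigenvalues."""
        lam = self.eigenvalues[pos]
        return float(np.log(rho * lam + (1.0 - rho)).sum())

    def quad_forms(self, pos: int, phi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Per-column pair ``(phi' L phi, phi' phi)`` for candidate ``pos``.

        ``phi`` may be a vector or an ``n x T`` matrix; the Leroux quadratic
        form is then ``rho * qL + (1 - rho) * qI`` for any ``rho``.
        """
        phi = np.atleast_2d(phi.T).T  # promote vectors to n x 1
        qL = np.einsum("ij,ij->j", phi, self.laplacians[pos] @ phi)
        qI = np.einsum("ij,ij->j", phi, phi)
        return qL, qI

    def labels_for(self, pos: int) -> np.ndarray:
        """Stage-1 cluster labels of the partition generating candidate ``pos``."""
        return self.partitions[pos]

    def k_of(self, label: Tuple[int, ...]) -> int:
        return int(label[1])


def assemble_candidate_set(
    G: AreaGraph,
    partitions: Mapping[Tuple[int, ...], Partition],
    variant: str = "A",
    T: Optional[int] = None,
) -> CandidateSet:
    """Assemble the discrete prior support for the neighbourhood matrix.

    ``partitions`` must cover ``c = 1..M`` and ``k = 2..K`` (and ``t = 1..T``
    for variant B); the ``k = 1`` solutions are implied and collapse to the
    border-sharing matrix, so variant A yields ``(K-1)*M + 1`` candidates and
    variant B ``(K-1)*M*T + 1``.  Distinct ``(c, k)`` labels that happen to
    produce identical matrices for ``k >= 2`` are retained as separate prior
    atoms, mirroring the construction of the prior (only the ``k = 1``
    duplicates are collapsed).
    """
    variant = variant.upper()
    if variant not in ("A", "B"):
        raise ValueError("variant must be 'A' or 'B'")
    keys = list(partitions.keys())
    if not keys:
        raise ValueError("no partitions supplied")
    klen = 3 if variant == "B" else 2
    if any(len(k) != klen for k in keys):
        raise ValueError(f"variant {variant} expects {klen}-tuples as keys")
    M = max(k[0] for k in keys)
    K = max(k[1] for k in keys)
    if variant == "B":
        T = T or max(k[2] for k in keys)

    expected = [
        (c, k) + ((t,) if variant == "B" else ())
        for c in range(1, M + 1)
        for k in range(2, K + 1)
        for t in (range(1, T + 1) if variant == "B" else [None])
    ]
    missing = [key for key in expected if key not in partitions]
    if missing:
        raise ValueError(f"missing partitions for {missing[:5]} ...")

    matrices: List[sp.csr_matrix] = [G.W.copy()]
    plabels: List[np.ndarray] = [np.ones(G.n, dtype=np.int64)]
    index: Dict[Tuple[int, ...], int] = {}
    # every method's k=1 solution is the shared border-sharing matrix
    for c in range(1, M + 1):
        for t in (range(1, T + 1) if variant == "B" else [None]):
            key = (c, 1) + ((t,) if variant == "B" else ())
            index[key] = 0
    for key in expected:
        p = partitions[key]
        index[key] = len(matrices)
        matrices.append(candidate_from_partition(G, p))
        plabels.append(np.asarray(p.labels, dtype=np.int64))

    eigenvalues, laplacians, rowsums = [], [], []
    for W in matrices:
        d = np.asarray(W.sum(axis=1)).ravel()
        L = sp.diags(d) - W
        laplacians.append(sp.csr_matrix(L))
        rowsums.append(d)
        eigenvalues.append(np.linalg.eigvalsh(L.toarray()))

    return CandidateSet(
        matrices=matrices,
        index=index,
        partitions=plabels,
        M=M,
        K=K,
        variant=variant,
        T=T,
        eigenvalues=eigenvalues,
        laplacians=laplacians,
        rowsums=rowsums,
    )
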