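"""Simulation-study data generation on a synthetic areal geography.

Emulates the study conditions of an urban disease-mapping panel: n = 257
areal units observed for T = 7 periods, expected counts between roughly 12.6
and 160 with median near 74, piecewise-constant cluster means in
{-Z, 0, Z} on the log-risk scale, Leroux-correlated spatial effects
(tau2 = 0.001) and an AR(1) temporal trend (alpha = 0.9, sigma2 = 0.1).
The geography is a near-square rook-adjacency lattice standing in for the
(unavailable) real polygon map, and the three-level cluster template is a
set of deterministic contiguous blobs grown on that lattice.

Scenarios vary the cluster magnitude Z in {0, 0.5, 1}, the expected-count
scale factor SF in {1, 2, 4} (larger SF = rarer disease), the spatial
dependence rho in {0, 0.3, 0.6, 0.9}, and whether clusters are static
(Case 1) or flip a small fraction of areas each period (Case 2); the full
grid comprises 30 sub-scenarios.  A model-free mode instead fixes the
risks at {exp(Z), 1, exp(-Z)} directly with no random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import truncnorm

from .car import leroux_precision
from .data import CountData
from .graph import AreaGraph

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "make_geography",
    "make_expected_counts",
    "make_cluster_means",
    "simulate_dataset",
    "simulate_model_free",
    "scenario_grid",
]

# expected-count calibration (per-area base values, constant over periods)
E_MEDIAN = 74.09
E_MIN = 12.61
E_MAX = 160.15
E_LOG_SIGMA = 0.5

ALPHA_TRUE = 0.9
SIGMA2_TRUE = 0.1
TAU2_TRUE = 0.001

#: fractions of areas in the elevated / reduced risk level of the template
HIGH_FRAC = 0.20
LOW_FRAC = 0.20


@dataclass
class SimulationScenario:
    """One cell of the simulation design."""

    case: Optional[int] = 1  # 1 static clusters, 2 evolving, None when Z = 0
    Z: float = 1.0
    SF: float = 1.0
    rho_true: float = 0.9
    alpha_true: float = ALPHA_TRUE
    sigma2_true: float = SIGMA2_TRUE
    tau2_true: float = TAU2_TRUE
    n_areas: int = 257
    T: int = 7
    seed: int = 0
    flip_frac: float = 0.03
    model_free: bool = False

    def __post_init__(self) -> None:
        if self.Z == 0:
            self.case = None
        elif self.case not in (1, 2):
            raise ValueError("case must be 1 or 2 when Z > 0")
        if not (0.0 <= self.rho_true < 1.0):
            raise ValueError("rho_true must lie in [0, 1)")


@dataclass
class SimulatedDataset:
    """Counts plus the generating truth for one simulation replicate."""

    data: CountData
    graph: AreaGraph
    risk: np.ndarray  # n x T true risks
    labels: np.ndarray  # n x T true level partition (1 low, 2 medium, 3 high)
    mu: np.ndarray  # n x T piecewise-constant means
    phi: np.ndarray  # n x T spatial effects (zero for model-free)
    theta: np.ndarray  # T temporal effects (zero for model-free)
    scenario: Optional[SimulationScenario] = None


def make_geography(n: int = 257) -> AreaGraph:
    """Near-square rook-adjacency lattice with ``n`` cells.

    Cells fill an ``m``-column grid row-major, with ``m = floor(sqrt(n))``,
    so n = 257 gives a 16 x 16 grid plus one appended cell.  Deterministic.
    """
    if n < 4:
        raise ValueError("need at least 4 areas")
    m = int(np.floor(np.sqrt(n)))
    edges = []
    for i in range(n):
        r, c = divmod(i, m)
        if c + 1 < m and i + 1 < n:
            edges.append((i, i + 1))
        if i + m < n:
            edges.append((i, i + m))
    return AreaGraph(n, edges)


def lattice_coords(n: int) -> np.ndarray:
    """(row, col) coordinates of the :func:`make_geography` lattice cells."""
    m = int(np.floor(np.sqrt(n)))
    idx = np.arange(n)
    return np.column_stack([idx // m, idx % m])


def make_expected_counts(
    n: int, T: int, SF: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Expected counts: truncated log-normal per area, constant over periods.

    At SF = 1 the draws have median near 74 and range roughly [12.6, 160];
    dividing by SF in {2, 4} emulates progressively rarer diseases.
    """
    rng = np.random.default_rng(seed)
    mu = np.log(E_MEDIAN)
    a = (np.log(E_MIN) - mu) / E_LOG_SIGMA
    b = (np.log(E_MAX) - mu) / E_LOG_SIGMA
    logE = truncnorm.rvs(a, b, loc=mu, scale=E_LOG_SIGMA, size=n, random_state=rng)
    E = np.exp(logE) / SF
    return np.tile(E[:, None], (1, T))


def _grow_blobs(G: AreaGraph, seeds: List[int], target: int, taken: np.ndarray) -> List[int]:
    """Grow contiguous regions by round-robin BFS from seed cells."""
    adj = [[] for _ in range(G.n)]
    for a, b in sorted(G.edges):
        adj[a].append(b)
        adj[b].append(a)
    chosen: List[int] = []
    frontiers = [[s] for s in seeds]
    visited = taken.copy()
    for s in seeds:
        if not visited[s]:
            visited[s] = True
            chosen.append(s)
    while len(chosen) < target and any(frontiers):
        for fi, frontier in enumerate(frontiers):
            if len(chosen) >= target or not frontier:
                continue
            node = frontier.pop(0)
            for nb in sorted(adj[node]):
                if not visited[nb]:
                    visited[nb] = True
                    chosen.append(nb)
                    frontier.append(nb)
                    if len(chosen) >= target:
                        break
        if all(not f for f in frontiers):
            break
    return chosen


def _template_levels(G: AreaGraph) -> np.ndarray:
    """Deterministic three-level template: contiguous high and low blobs."""
    n = G.n
    levels = np.zeros(n, dtype=np.int64)  # 0 = medium
    taken = np.zeros(n, dtype=bool)
    high_seeds = [int(0.10 * n), int(0.62 * n)]
    high = _grow_blobs(G, high_seeds, int(round(HIGH_FRAC * n)), taken)
    levels[high] = 1
    taken[high] = True
    low_seeds = [int(0.30 * n), int(0.86 * n)]
    low_seeds = [s if not taken[s] else int(np.flatnonzero(~taken)[0]) for s in low_seeds]
    low = _grow_blobs(G, low_seeds, int(round(LOW_FRAC * n)), taken)
    levels[low] = -1
    return levels


def make_cluster_means(
    geography: AreaGraph,
    case: Optional[int],
    Z: float,
    T: int,
    seed: int = 0,
    flip_frac: float = 0.03,
) -> np.ndarray:
    """Piecewise-constant means ``mu_it`` in ``{-Z, 0, Z}`` (n x T).

    Case 1 repeats the template every period; Case 2 reassigns a random
    ``flip_frac`` of areas to a different level at each successive period,
    cumulatively, so the clusters drift over time.  Z = 0 gives a flat
    (no-cluster) surface.
    """
    n = geography.n
    if Z == 0:
        return np.zeros((n, T))
    if case not in (1, 2):
        raise ValueError("case must be 1 or 2 when Z > 0")
    rng = np.random.default_rng(seed)
    levels = np.tile(_template_levels(geography)[:, None], (1, T))
    if case == 2 and flip_frac > 0:
        n_flip = max(1, int(round(flip_frac * n)))
        for t in range(1, T):
            levels[:, t] = levels[:, t - 1]
            flip = rng.choice(n, size=n_flip, replace=False)
            for i in flip:
                options = [lv for lv in (-1, 0, 1) if lv != levels[i, t]]
                levels[i, t] = options[rng.integers(2)]
    return Z * levels


def _sample_car(
    G: AreaGraph, rho: float, tau2: float, mu: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw phi_t ~ N(mu_t, tau2 Q(rho, W)^{-1}) for every column of mu."""
    Q = leroux_precision(rho, G.W)
    # upper Cholesky solve: if Q = C'C then C^{-1} z has covariance Q^{-1}
    C = np.linalg.cholesky(Q).T
    z = rng.standard_normal(mu.shape)
    from scipy.linalg import solve_triangular

    return mu + np.sqrt(tau2) * solve_triangular(C, z, lower=False)


def _levels_to_labels(mu: np.ndarray, Z: float) -> np.ndarray:
    if Z == 0:
        return np.ones(mu.shape, dtype=np.int64)
    return (np.sign(mu).astype(np.int64) + 2)  # -Z,0,Z -> 1,2,3


def simulate_dataset(sc: SimulationScenario) -> SimulatedDataset:
    """Generate one replicate of the simulation design.

    theta follows the AR(1) model (theta_1 ~ N(0, sigma2)); phi_t is drawn
    from the Leroux prior around the piecewise-constant cluster means; risks
    are R_it = exp(phi_it + theta_t) and Y_it ~ Poisson(E_it R_it).
    """
    if sc.model_free:
        G = make_geography(sc.n_areas)
        return simulate_model_free(G, sc.Z, sc.SF, sc.T, sc.seed)
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 2_000_001]))
    G = make_geography(sc.n_areas)
    E = make_expected_counts(sc.n_areas, sc.T, sc.SF, seed=sc.seed)
    mu = make_cluster_means(G, sc.case, sc.Z, sc.T, seed=sc.seed, flip_frac=sc.flip_frac)
    theta = np.empty(sc.T)
    theta[0] = rng.normal(0.0, np.sqrt(sc.sigma2_true))
    for t in range(1, sc.T):
        theta[t] = rng.normal(sc.alpha_true * theta[t - 1], np.sqrt(sc.sigma2_true))
    phi = _sample_car(G, sc.rho_true, sc.tau2_true, mu, rng)
    risk = np.exp(phi + theta[None, :])
    Y = rng.poisson(E * risk)
    data = CountData(Y=Y, E=E)
    return SimulatedDataset(
        data=data,
        graph=G,
        risk=risk,
        labels=_levels_to_labels(mu, sc.Z),
        mu=mu,
        phi=phi,
        theta=theta,
        scenario=sc,
    )


def simulate_model_free(
    geography: AreaGraph, Z: float, SF: float, T: int, seed: int = 0
) -> SimulatedDataset:
    """Model-free scenario: risks fixed at {exp(Z), 1, exp(-Z)} by level set."""
    if Z <= 0:
        raise ValueError("model-free scenario requires Z > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_002]))
    n = geography.n
    E = make_expected_counts(n, T, SF, seed=seed)
    mu = Z * np.tile(_template_levels(geography)[:, None], (1, T))
    risk = np.exp(mu)
    Y = rng.poisson(E * risk)
    return SimulatedDataset(
        data=CountData(Y=Y, E=E),
        graph=geography,
        risk=risk,
        labels=_levels_to_labels(mu, Z),
        mu=mu,
        phi=np.zeros((n, T)),
        theta=np.zeros(T),
        scenario=None,
    )


def scenario_grid() -> List[SimulationScenario]:
    """The 30 sub-scenarios of the simulation design."""
    out: List[SimulationScenario] = []
    for case in (1, 2):
        for Z in (1.0, 0.5):
            for SF in (1.0, 2.0, 4.0):
                out.append(SimulationScenario(case=case, Z=Z, SF=SF, rho_true=0.9))
    for SF in (1.0, 2.0, 4.0):
        out.append(SimulationScenario(case=None, Z=0.0, SF=SF, rho_true=0.9))
    for case in (1, 2):
        for Z in (1.0, 0.5):
            for rho in (0.6, 0.3, 0.0):
                out.append(SimulationScenario(case=case, Z=Z, SF=1.0, rho_true=rho))
    for rho in (0.6, 0.3, 0.0):
        out.append(SimulationScenario(case=None, Z=0.0, SF=1.0, rho_true=rho))
    return out
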