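"""Stage 2: Bayesian spatio-temporal model with an estimated neighbourhood matrix.

The data model is the Poisson log-linear specification

    Y_it | E_it, R_it ~ Poisson(E_it R_it)
    ln R_it = x_it' beta + phi_it + theta_t

with a region-wide AR(1) temporal trend theta and, for each period t, a
separate spatial surface phi_t ~ N(0, tau_t^2 Q(rho, W)^{-1}) under the
Leroux CAR prior.  The neighbourhood matrix W is itself a parameter with a
discrete uniform prior over the stage-1 candidates, updated by a bespoke
two-move Metropolis-Hastings step: move 1 proposes a different cluster
count k within a +/- s window of the same clustering method, move 2 a
different method at the same k.  Model variants:

    A  one matrix W~ shared by all periods, one rho
    B  a matrix W~_t and rho_t per period
    N  non-cluster reference: W fixed at border sharing (variant A with a
       single candidate)

Remaining updates are standard: random-walk MH for beta, phi (element wise)
and theta, conjugate Gibbs draws for tau_t^2 and sigma^2, a truncated
Gaussian Gibbs draw for alpha, and logit-scale MH for rho when it is
estimated rather than fixed at 0.99.  All random-effect sets are zero-mean
centred after each sweep with the removed means absorbed so the linear
predictor is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

from ._kernels import phi_site_sweep
from .data import CountData
from .graph import AreaGraph, CandidateSet, Partition, assemble_candidate_set
from .stage1 import build_partitions_A, build_partitions_B, estimate_phi_tilde

__all__ = [
    "ModelConfig",
    "ChainState",
    "Samples",
    "Sampler",
    "MODEL_PRESETS",
    "log_poisson_likelihood",
    "border_candidate_set",
    "run_chain",
    "fit_model",
]

#: Named models from the simulation-study comparison.
MODEL_PRESETS: Dict[str, Tuple[str, str]] = {
    "ST-A": ("A", "fixed"),
    "ST-A*": ("A", "estimated"),
    "ST-B": ("B", "fixed"),
    "ST-B*": ("B", "estimated"),
    "ST-N": ("N", "estimated"),
}


@dataclass
class ModelConfig:
    """Priors and MCMC controls.

    Defaults follow the weakly informative choices used throughout:
    ``beta ~ N(0, 1000)``, ``tau_t^2, sigma^2 ~ InvGamma(1, 0.01)`` (with
    ``(0.001, 0.001)`` and ``(0.5, 0.0005)`` as supported alternatives),
    ``alpha, rho ~ Uniform(0, 1)``, and a proposal window ``s = 2`` for the
    neighbourhood-matrix update.
    """

    variant: str = "A"
    rho_mode: str = "estimated"  # "estimated" | "fixed"
    rho_fixed: float = 0.99
    beta_prior_var: float = 1000.0
    tau2_prior: Tuple[float, float] = (1.0, 0.01)
    sigma2_prior: Tuple[float, float] = (1.0, 0.01)
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    n_chains: int = 1
    s_window: int = 2
    step_phi: float = 0.1
    step_theta: float = 0.05
    step_beta: float = 0.02
    step_rho: float = 1.0  # logit scale
    adapt_interval: int = 100
    target_accept: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        self.variant = self.variant.upper()
        if self.variant not in ("A", "B", "N"):
            raise ValueError("variant must be A, B or N")
        if self.rho_mode not in ("estimated", "fixed"):
            raise ValueError("rho_mode must be 'estimated' or 'fixed'")
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.s_window < 1:
            raise ValueError("proposal window s must be >= 1")


@dataclass
class ChainState:
    """All model unknowns at one MCMC iteration.

    ``w_label`` holds per-period ``(c, k)`` labels into the candidate set
    (all equal under variants A/N); a latent method label ``c`` is retained
    at ``k = 1`` so the within-method move stays defined from the shared
    border-sharing state.
    """

    beta: np.ndarray
    phi: np.ndarray  # n x T
    theta: np.ndarray  # T
    tau2: np.ndarray  # T
    sigma2: float
    alpha: float
    rho: np.ndarray  # T (shared value repeated under A/N)
    w_label: List[Tuple[int, int]]
    w_pos: np.ndarray  # T, positions into the CandidateSet

    def eta(self, data: CountData) -> np.ndarray:
        """Linear predictor ``x'beta + phi + theta`` (n x T)."""
        xb = self.beta[0]
        if data.X is not None:
            xb = xb + np.tensordot(data.X, self.beta[1:], axes=([2], [0]))
        return xb + self.phi + self.theta[None, :]


def log_poisson_likelihood(eta: np.ndarray, data: CountData) -> float:
    """Poisson log likelihood up to the ``Y!`` constant."""
    return float((data.Y * (np.log(data.E) + eta) - data.E * np.exp(eta)).sum())


def border_candidate_set(G: AreaGraph) -> CandidateSet:
    """Single-candidate set holding only the border-sharing matrix (model ST-N)."""
    p = {(1, 2): Partition(np.ones(G.n, dtype=np.int64), k=2)}
    cs = assemble_candidate_set(G, p, variant="A")
    # keep only the border matrix as prior support
    return CandidateSet(
        matrices=cs.matrices[:1],
        index={(1, 1): 0},
        partitions=cs.partitions[:1],
        M=1,
        K=1,
        variant="A",
        T=None,
        eigenvalues=cs.eigenvalues[:1],
        laplacians=cs.laplacians[:1],
        rowsums=cs.rowsums[:1],
    )


@dataclass
class Samples:
    """Thinned post-burn-in draws from one or more chains."""

    beta: np.ndarray  # S x (p+1)
    theta: np.ndarray  # S x T
    tau2: np.ndarray  # S x T
    sigma2: np.ndarray  # S
    alpha: np.ndarray  # S
    rho: np.ndarray  # S x T
    w_c: np.ndarray  # S x T  (method label)
    w_k: np.ndarray  # S x T  (cluster count)
    w_pos: np.ndarray  # S x T (candidate position)
    deviance: np.ndarray  # S
    log_risk: np.ndarray  # S x n x T (float32)
    chain: np.ndarray  # S, chain id
    acceptance: Dict[str, float] = field(default_factory=dict)
    config: Optional[ModelConfig] = None

    @property
    def n_samples(self) -> int:
        return self.deviance.size

    def risk_quantiles(self, q=(0.025, 0.5, 0.975)) -> np.ndarray:
        """Quantiles of the risk surface; returns ``len(q) x n x T``."""
        return np.quantile(np.exp(self.log_risk.astype(np.float64)), q, axis=0)


class Sampler:
    """Metropolis-within-Gibbs sampler for one Markov chain."""

    def __init__(
        self,
        data: CountData,
        cands: CandidateSet,
        config: ModelConfig,
        rng: np.random.Generator,
        state: Optional[ChainState] = None,
    ) -> None:
        self.data = data
        self.cands = cands
        self.config = config
        self.rng = rng
        n, T = data.n, data.T
        self.n, self.T = n, T
        self._logE = np.log(data.E)
        self._sumY = float(data.Y.sum())
        self._sumY_t = data.Y.sum(axis=0).astype(float)
        self._lgamma_const = float(gammaln(data.Y + 1).sum())
        self._sumYlogE = float((data.Y * self._logE).sum())
        self.state = state if state is not None else self._initial_state()
        self.accept_counts: Dict[str, List[float]] = {
            k: [0.0, 0.0] for k in ("beta", "phi", "theta", "rho", "w1", "w2")
        }
        # per-sweep cache of the CAR quadratic forms under the current W:
        # qL[t] = phi_t' (diag(W1)-W) phi_t, qI[t] = phi_t' phi_t
        self._qL = np.zeros(self.T)
        self._qI = np.zeros(self.T)
        self._refresh_quads()

    # ------------------------------------------------------------------ setup

    def _initial_state(self) -> ChainState:
        data, config = self.data, self.config
        n, T = self.n, self.T
        beta0 = np.log(max(float(data.Y.sum()), 0.5) / data.E.sum())
        logsir = np.log(np.where(data.Y == 0, 0.5, data.Y) / data.E)
        theta = logsir.mean(axis=0) - beta0
        theta -= theta.mean()
        phi = logsir - beta0 - theta[None, :]
        phi = phi - phi.mean(axis=0, keepdims=True)
        tau2 = np.maximum(phi.var(axis=0), 1e-4)
        rho0 = config.rho_fixed if config.rho_mode == "fixed" else 0.5
        p = data.p
        beta = np.zeros(p + 1)
        beta[0] = beta0
        return ChainState(
            beta=beta,
            phi=phi,
            theta=theta,
            tau2=tau2,
            sigma2=max(float(theta.var()), 0.01),
            alpha=0.5,
            rho=np.full(T, rho0),
            w_label=[(1, 1)] * T,
            w_pos=np.zeros(T, dtype=np.int64),
        )

    # ------------------------------------------------------------- likelihood

    def _eta(self) -> np.ndarray:
        return self.state.eta(self.data)

    def deviance(self) -> float:
        """Poisson deviance ``-2 log p(Y | .)`` including the ``Y!`` constant."""
        eta = self._eta()
        ll = (
            self._sumYlogE
            + float((self.data.Y * eta).sum())
            - float((self.data.E * np.exp(eta)).sum())
            - self._lgamma_const
        )
        return -2.0 * ll

    # ---------------------------------------------------------------- updates

    def update_beta(self) -> None:
        st, data = self.state, self.data
        step = self.config.step_beta
        pv = self.config.beta_prior_var
        if data.X is None:
            # intercept only: sufficient statistics make this a scalar update
            b = st.beta[0]
            bp = b + step * self.rng.standard_normal()
            C = float((data.E * np.exp(st.phi + st.theta[None, :])).sum())
            dl = self._sumY * (bp - b) - C * (np.exp(bp) - np.exp(b))
            dl += (b * b - bp * bp) / (2.0 * pv)
            if np.log(self.rng.uniform()) < dl:
                st.beta[0] = bp
                self._bump("beta", 1)
            else:
                self._bump("beta", 0)
            return
        beta_p = st.beta + step * self.rng.standard_normal(st.beta.size)
        eta_c = st.eta(data)
        cur = log_poisson_likelihood(eta_c, data) - float(st.beta @ st.beta) / (2 * pv)
        st_p = replace(st, beta=beta_p)
        prop = log_poisson_likelihood(st_p.eta(data), data) - float(
            beta_p @ beta_p
        ) / (2 * pv)
        if np.log(self.rng.uniform()) < prop - cur:
            st.beta = beta_p
            self._bump("beta", 1)
        else:
            self._bump("beta", 0)

    def update_phi(self) -> None:
        """Element-wise random-walk MH over every spatial random effect."""
        st, data = self.state, self.data
        step = self.config.step_phi
        xb = st.beta[0]
        if data.X is not None:
            xb = xb + np.tensordot(data.X, st.beta[1:], axes=([2], [0]))
        acc = 0
        zs = self.rng.standard_normal((self.n, self.T))
        us = self.rng.uniform(size=(self.n, self.T))
        for t in range(self.T):
            pos = int(st.w_pos[t])
            W = self.cands.matrices[pos]
            deg = self.cands.rowsums[pos]
            off = (xb[:, t] if data.X is not None else np.full(self.n, xb)) + st.theta[t]
            z = np.ascontiguousarray(zs[:, t])
            u = np.ascontiguousarray(us[:, t])
            acc += phi_site_sweep(
                st.phi[:, t],
                off,
                data.Y[:, t].astype(np.float64),
                data.E[:, t],
                W.indptr,
                W.indices,
                deg,
                float(st.rho[t]),
                float(st.tau2[t]),
                step,
                z,
                u,
            )
        self._bump("phi", acc / (self.n * self.T))

    def center_effects(self) -> None:
        """Zero-mean centre phi (per period) and theta, keeping eta invariant.

        Per-period phi means are absorbed into theta_t, and the theta mean
        into the intercept beta_0.
        """
        st = self.state
        mphi = st.phi.mean(axis=0)
        st.phi -= mphi[None, :]
        st.theta = st.theta + mphi
        mtheta = st.theta.mean()
        st.theta = st.theta - mtheta
        st.beta[0] += mtheta

    def update_theta(self) -> None:
        """Element-wise MH on the AR(1) temporal trend."""
        st, data = self.state, self.data
        step = self.config.step_theta
        xb = st.beta[0]
        if data.X is not None:
            xb = xb + np.tensordot(data.X, st.beta[1:], axes=([2], [0]))
        # sufficient statistics: sum_i Y_it and sum_i E_it exp(x'b + phi_it)
        Eexp = (data.E * np.exp(xb + st.phi)).sum(axis=0)
        a, s2 = st.alpha, st.sigma2
        th = st.theta
        acc = 0
        for t in range(self.T):
            cur, prop = th[t], th[t] + step * self.rng.standard_normal()
            dl = self._sumY_t[t] * (prop - cur) - Eexp[t] * (
                np.exp(prop) - np.exp(cur)
            )
            mean_t = a * th[t - 1] if t > 0 else 0.0
            dl -= ((prop - mean_t) ** 2 - (cur - mean_t) ** 2) / (2.0 * s2)
            if t + 1 < self.T:
                dl -= ((th[t + 1] - a * prop) ** 2 - (th[t + 1] - a * cur) ** 2) / (
                    2.0 * s2
                )
            if np.log(self.rng.uniform()) < dl:
                th[t] = prop
                acc += 1
        self._bump("theta", acc / self.T)

    def _refresh_quads(self) -> None:
        """Recompute the cached per-period quadratic forms under current W."""
        st = self.state
        if self.config.variant in ("A", "N"):
            qL, qI = self.cands.quad_forms(int(st.w_pos[0]), st.phi)
            self._qL, self._qI = qL, qI
            return
        for t in range(self.T):
            a, b = self.cands.quad_forms(int(st.w_pos[t]), st.phi[:, t])
            self._qL[t], self._qI[t] = a[0], b[0]

    def update_tau2(self) -> None:
        """Conjugate Gibbs draw ``tau_t^2 ~ IG(a + n/2, b + phi'Q phi / 2)``."""
        st = self.state
        a0, b0 = self.config.tau2_prior
        qL, qI = self._qL, self._qI
        quad = st.rho * qL + (1.0 - st.rho) * qI
        shape = a0 + 0.5 * self.n
        scale = b0 + 0.5 * quad
        st.tau2 = scale / self.rng.gamma(shape, 1.0, size=self.T)

    def update_sigma2_alpha(self) -> None:
        """Gibbs draws for the AR(1) variance and autoregressive parameter."""
        st = self.state
        a0, b0 = self.config.sigma2_prior
        th = st.theta
        resid = th[0] ** 2 + float(((th[1:] - st.alpha * th[:-1]) ** 2).sum())
        st.sigma2 = float(
            (b0 + 0.5 * resid) / self.rng.gamma(a0 + 0.5 * self.T, 1.0)
        )
        denom = float((th[:-1] ** 2).sum())
        if denom <= 0.0:
            st.alpha = float(self.rng.uniform())
            return
        mean = float((th[1:] * th[:-1]).sum()) / denom
        sd = np.sqrt(st.sigma2 / denom)
        # truncated Gaussian on [0, 1] by inverse-CDF sampling
        lo, hi = ndtr((0.0 - mean) / sd), ndtr((1.0 - mean) / sd)
        u = lo + (hi - lo) * self.rng.uniform()
        st.alpha = float(np.clip(mean + sd * ndtri(u), 0.0, 1.0))

    def update_rho(self) -> None:
        """Logit-scale MH for the spatial dependence parameter(s)."""
        if self.config.rho_mode != "estimated":
            return
        st = self.state
        step = self.config.step_rho
        qL, qI = self._qL, self._qI
        if self.config.variant in ("A", "N"):
            pos = int(st.w_pos[0])
            rho = float(st.rho[0])
            z = np.log(rho / (1.0 - rho)) + step * self.rng.standard_normal()
            rho_p = 1.0 / (1.0 + np.exp(-z))

            def logtarget(r: float) -> float:
                quads = (r * qL + (1.0 - r) * qI) / (2.0 * st.tau2)
                return (
                    0.5 * self.T * self.cands.logdet_Q(pos, r)
                    - float(quads.sum())
                    + np.log(r * (1.0 - r))
                )

            cur = logtarget(rho)
            prop = logtarget(rho_p)
            prop_vec = np.full(self.T, rho_p)
            if np.log(self.rng.uniform()) < prop - cur:
                st.rho = prop_vec
                self._bump("rho", 1)
            else:
                self._bump("rho", 0)
            return
        acc = 0
        for t in range(self.T):
            rho = float(st.rho[t])
            z = np.log(rho / (1.0 - rho)) + step * self.rng.standard_normal()
            rho_p = 1.0 / (1.0 + np.exp(-z))
            pos = int(st.w_pos[t])
            quad_c = rho * qL[t] + (1 - rho) * qI[t]
            quad_p = rho_p * qL[t] + (1 - rho_p) * qI[t]
            dl = 0.5 * (
                self.cands.logdet_Q(pos, rho_p) - self.cands.logdet_Q(pos, rho)
            )
            dl -= (quad_p - quad_c) / (2.0 * st.tau2[t])
            dl += np.log(rho_p * (1 - rho_p)) - np.log(rho * (1 - rho))
            if np.log(self.rng.uniform()) < dl:
                st.rho[t] = rho_p
                acc += 1
        self._bump("rho", acc / self.T)

    # ------------------------------------------------------- W two-move update

    def _window(self, k: int) -> List[int]:
        s, K = self.config.s_window, self.cands.K
        return [kk for kk in range(k - s, k + s + 1) if 1 <= kk <= K and kk != k]

    def propose_W(self, label: Tuple[int, int], move: int) -> Tuple[Tuple[int, int], float]:
        """One of the two discrete proposals for the neighbourhood matrix.

        Move 1 keeps the clustering method and proposes a cluster count
        uniformly within the +/- s window (truncated at the boundaries, with
        the asymmetric-window Hastings correction); move 2 keeps the cluster
        count and proposes a different method (symmetric).
        """
        c, k = label
        if move == 1:
            win = self._window(k)
            k_new = int(win[self.rng.integers(len(win))])
            log_h = np.log(len(win)) - np.log(len(self._window(k_new)))
            return (c, k_new), float(log_h)
        others = [h for h in range(1, self.cands.M + 1) if h != c]
        if not others:  # single clustering method: move 2 degenerates
            return (c, k), 0.0
        c_new = int(others[self.rng.integers(len(others))])
        return (c_new, k), 0.0

    def accept_W(
        self, proposed: Tuple[int, int], log_h: float, t: Optional[int] = None
    ) -> bool:
        """MH accept/reject for a proposed candidate label.

        The discrete-uniform prior and the Poisson likelihood cancel (W only
        enters the prior of phi), leaving the CAR log-density difference
        summed over all periods (variant A) or the single period t (B).
        """
        st = self.state
        variant = self.config.variant
        key = proposed if variant != "B" else proposed + (t + 1,)
        pos_p = self.cands.index[key]
        if variant != "B":
            pos_c = int(st.w_pos[0])
            if pos_p == pos_c:
                accept = np.log(self.rng.uniform()) < log_h
                if accept:
                    st.w_label = [proposed] * self.T
                return bool(accept)
            rho = float(st.rho[0])
            qLp, _ = self.cands.quad_forms(pos_p, st.phi)
            quad_c = rho * self._qL + (1.0 - rho) * self._qI
            quad_p = rho * qLp + (1.0 - rho) * self._qI
            dl = log_h + 0.5 * self.T * (
                self.cands.logdet_Q(pos_p, rho) - self.cands.logdet_Q(pos_c, rho)
            )
            dl -= float(((quad_p - quad_c) / (2.0 * st.tau2)).sum())
            if np.log(self.rng.uniform()) < dl:
                st.w_label = [proposed] * self.T
                st.w_pos[:] = pos_p
                self._qL = qLp
                return True
            return False
        pos_c = int(st.w_pos[t])
        dl = log_h
        qLp_t = self._qL[t]
        if pos_p != pos_c:
            phi_t = st.phi[:, t]
            rho = float(st.rho[t])
            qLp, _ = self.cands.quad_forms(pos_p, phi_t)
            qLp_t = qLp[0]
            quad_c = rho * self._qL[t] + (1 - rho) * self._qI[t]
            quad_p = rho * qLp_t + (1 - rho) * self._qI[t]
            dl += 0.5 * (
                self.cands.logdet_Q(pos_p, rho) - self.cands.logdet_Q(pos_c, rho)
            )
            dl -= (quad_p - quad_c) / (2.0 * st.tau2[t])
        if np.log(self.rng.uniform()) < dl:
            st.w_label[t] = proposed
            st.w_pos[t] = pos_p
            self._qL[t] = qLp_t
            return True
        return False

    def update_W(self) -> None:
        """Both discrete moves in sequence, each with its own accept/reject."""
        if len(self.cands) == 1:
            return
        st = self.state
        if self.config.variant in ("A", "N"):
            prop, log_h = self.propose_W(st.w_label[0], move=1)
            self._bump("w1", self.accept_W(prop, log_h))
            prop, log_h = self.propose_W(st.w_label[0], move=2)
            self._bump("w2", self.accept_W(prop, log_h))
            return
        acc1 = acc2 = 0
        for t in range(self.T):
            prop, log_h = self.propose_W(st.w_label[t], move=1)
            acc1 += self.accept_W(prop, log_h, t=t)
            prop, log_h = self.propose_W(st.w_label[t], move=2)
            acc2 += self.accept_W(prop, log_h, t=t)
        self._bump("w1", acc1 / self.T)
        self._bump("w2", acc2 / self.T)

    # ------------------------------------------------------------- orchestration

    def _bump(self, key: str, accepted: float) -> None:
        self.accept_counts[key][0] += accepted
        self.accept_counts[key][1] += 1.0

    def _adapt(self) -> None:
        cfg = self.config
        for key, attr in (
            ("beta", "step_beta"),
            ("phi", "step_phi"),
            ("theta", "step_theta"),
            ("rho", "step_rho"),
        ):
            acc, att = self.accept_counts[key]
            if att == 0:
                continue
            rate = acc / att
            step = getattr(cfg, attr) * float(
                np.exp(np.clip(rate - cfg.target_accept, -0.5, 0.5))
            )
            setattr(cfg, attr, float(np.clip(step, 1e-5, 20.0)))
            self.accept_counts[key] = [0.0, 0.0]

    def sweep(self) -> None:
        self.update_beta()
        self.update_phi()
        self.center_effects()
        self.update_theta()
        self.center_effects()
        self._refresh_quads()
        self.update_tau2()
        self.update_sigma2_alpha()
        self.update_rho()
        self.update_W()

    def run(self) -> Samples:
        cfg = self.config
        n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
        T, n = self.T, self.n
        out = Samples(
            beta=np.empty((n_keep, self.state.beta.size)),
            theta=np.empty((n_keep, T)),
            tau2=np.empty((n_keep, T)),
            sigma2=np.empty(n_keep),
            alpha=np.empty(n_keep),
            rho=np.empty((n_keep, T)),
            w_c=np.empty((n_keep, T), dtype=np.int64),
            w_k=np.empty((n_keep, T), dtype=np.int64),
            w_pos=np.empty((n_keep, T), dtype=np.int64),
            deviance=np.empty(n_keep),
            log_risk=np.empty((n_keep, n, T), dtype=np.float32),
            chain=np.zeros(n_keep, dtype=np.int64),
            config=cfg,
        )
        kept = 0
        for it in range(cfg.n_iter):
            self.sweep()
            if it < cfg.burn_in:
                if (it + 1) % cfg.adapt_interval == 0:
                    self._adapt()
                continue
            if (it - cfg.burn_in) % cfg.thin != cfg.thin - 1:
                continue
            st = self.state
            dev = self.deviance()
            if not np.isfinite(dev):
                raise RuntimeError(
                    f"non-finite log posterior at iteration {it}; "
                    f"state: beta={st.beta}, sigma2={st.sigma2}"
                )
            out.beta[kept] = st.beta
            out.theta[kept] = st.theta
            out.tau2[kept] = st.tau2
            out.sigma2[kept] = st.sigma2
            out.alpha[kept] = st.alpha
            out.rho[kept] = st.rho
            out.w_c[kept] = [lab[0] for lab in st.w_label]
            out.w_k[kept] = [lab[1] for lab in st.w_label]
            out.w_pos[kept] = st.w_pos
            out.deviance[kept] = dev
            out.log_risk[kept] = st.eta(self.data).astype(np.float32)
            kept += 1
        out.acceptance = {
            k: (v[0] / v[1] if v[1] else np.nan) for k, v in self.accept_counts.items()
        }
        return out


def _concat_samples(parts: List[Samples]) -> Samples:
    if len(parts) == 1:
        return parts[0]
    kw = {}
    for name in (
        "beta",
        "theta",
        "tau2",
        "sigma2",
        "alpha",
        "rho",
        "w_c",
        "w_k",
        "w_pos",
        "deviance",
        "log_risk",
    ):
        kw[name] = np.concatenate([getattr(p, name) for p in parts], axis=0)
    kw["chain"] = np.concatenate(
        [np.full(p.n_samples, i, dtype=np.int64) for i, p in enumerate(parts)]
    )
    kw["acceptance"] = parts[0].acceptance
    kw["config"] = parts[0].config
    return Samples(**kw)


def run_chain(
    data: CountData, cands: CandidateSet, config: ModelConfig
) -> Samples:
    """Run ``config.n_chains`` independent chains and pool their retained draws.

    Each chain applies its own burn-in and thinning; a fixed ``config.seed``
    makes the whole run bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    parts = []
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        cfg = replace(config)  # per-chain copy: step sizes adapt independently
        parts.append(Sampler(data, cands, cfg, rng).run())
    return _concat_samples(parts)


def fit_model(
    data: CountData,
    graph: AreaGraph,
    model: str = "ST-A*",
    config: Optional[ModelConfig] = None,
    M: int = 8,
    K: int = 10,
    stage1_seed: Optional[int] = None,
    zero_adjust: float = 0.5,
):
    """Full two-stage fit: residual clustering, candidate assembly, MCMC.

    ``model`` is one of ``ST-A``, ``ST-A*``, ``ST-B``, ``ST-B*``, ``ST-N``.
    Returns ``(samples, cands)``; posterior summarisation lives in
    :mod:`stcarclust.evaluation`.
    """
    if model not in MODEL_PRESETS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_PRESETS)}")
    variant, rho_mode = MODEL_PRESETS[model]
    config = replace(config) if config is not None else ModelConfig()
    config.variant = variant
    config.rho_mode = rho_mode
    if stage1_seed is None:
        stage1_seed = config.seed
    if variant == "N":
        cands = border_candidate_set(graph)
    else:
        res = estimate_phi_tilde(data, zero_adjust=zero_adjust)
        if variant == "A":
            parts = build_partitions_A(res, M=M, K=K, seed=stage1_seed)
            cands = assemble_candidate_set(graph, parts, variant="A")
        else:
            parts = build_partitions_B(res, M=M, K=K, seed=stage1_seed)
            cands = assemble_candidate_set(graph, parts, variant="B", T=data.T)
    samples = run_chain(data, cands, config)
    return samples, cands
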