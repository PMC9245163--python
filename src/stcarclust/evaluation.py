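"""Posterior summarisation, model fit and simulation metrics.

Covers risk medians with 95% equal-tailed credible intervals, the posterior
distribution and mode of the neighbourhood matrix (ties broken by the
smaller effective number of parameters), cluster-count credible intervals,
DIC / pd, Geweke convergence z-scores, and the simulation-study metrics:
root mean square error of the risk estimates, credible-interval coverage,
and the adjusted Rand index between true and estimated cluster partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .data import CountData
from .graph import CandidateSet
from .mcmc import Samples

__all__ = [
    "PosteriorSummary",
    "dic",
    "ari",
    "spatiotemporal_ari",
    "rmse_and_coverage",
    "posterior_mode_W",
    "cluster_count_summary",
    "geweke_z",
    "summarize",
    "modal_partition",
]


def dic(
    deviance_samples: np.ndarray, deviance_at_posterior_mean: float
) -> Tuple[float, float]:
    """Deviance information criterion and effective number of parameters.

    ``pd = mean(D) - D(posterior mean)`` and ``DIC = mean(D) + pd``; the
    plug-in deviance is evaluated at the posterior mean of the linear
    predictor, which stays well defined across neighbourhood-matrix values.
    """
    D = np.asarray(deviance_samples, dtype=float)
    if D.size == 0:
        raise ValueError("empty deviance trace")
    dbar = float(D.mean())
    pd_ = dbar - float(deviance_at_posterior_mean)
    return dbar + pd_, pd_


def _deviance_of_eta(eta: np.ndarray, data: CountData) -> float:
    ll = (
        data.Y * (np.log(data.E) + eta)
        - data.E * np.exp(eta)
        - gammaln(data.Y + 1)
    ).sum()
    return float(-2.0 * ll)


def ari(p1: Sequence[int], p2: Sequence[int]) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 means identical partitions (up to relabelling), values near 0 arise
    for independent random allocations.  For spatio-temporal comparisons the
    caller concatenates per-period labels into one vector per structure.
    """
    a = np.asarray(p1).ravel()
    b = np.asarray(p2).ravel()
    if a.size != b.size:
        raise ValueError("partitions must have equal length")
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


def spatiotemporal_ari(truth: np.ndarray, estimate: np.ndarray) -> float:
    """ARI between spatio-temporal cluster structures over all time periods.

    ``truth`` and ``estimate`` are ``n x T`` label matrices.  Cluster
    identities are only meaningful within a time period (a dynamic structure
    carries no cross-period identity), so the index is the mean over periods
    of the per-period ARI.  Identical structures score 1 and random
    allocations score near 0, and a static structure repeated over periods is
    compared on exactly the same scale as a dynamic one.
    """
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    if truth.shape != estimate.shape or truth.ndim != 2:
        raise ValueError("truth and estimate must be matching n x T matrices")
    return float(
        np.mean([ari(truth[:, t], estimate[:, t]) for t in range(truth.shape[1])])
    )


def rmse_and_coverage(
    risk_truth: np.ndarray,
    risk_median: np.ndarray,
    risk_lower: np.ndarray,
    risk_upper: np.ndarray,
) -> Tuple[float, float]:
    """RMSE of posterior-median risks and 95% credible-interval coverage."""
    truth = np.asarray(risk_truth, dtype=float)
    med = np.asarray(risk_median, dtype=float)
    if truth.shape != med.shape:
        raise ValueError("risk arrays must share a shape")
    rmse = float(np.sqrt(np.mean((med - truth) ** 2)))
    cover = float(np.mean((risk_lower <= truth) & (truth <= risk_upper)))
    return rmse, cover


def posterior_mode_W(
    w_trace: np.ndarray, pd_by_value: Optional[Dict[int, float]] = None
) -> int:
    """Most frequent candidate position in a pooled trace of W draws.

    With multiple modes, the one yielding the fewer effective number of
    parameters is chosen (model parsimony); lacking that information the
    smallest position wins.
    """
    trace = np.asarray(w_trace).ravel()
    if trace.size == 0:
        raise ValueError("empty W trace")
    values, counts = np.unique(trace, return_counts=True)
    tied = values[counts == counts.max()]
    if tied.size == 1 or pd_by_value is None:
        return int(tied.min())
    return int(min(tied, key=lambda v: (pd_by_value.get(int(v), np.inf), v)))


def cluster_count_summary(
    w_k_trace: np.ndarray,
) -> Tuple[int, Tuple[int, int]]:
    """Posterior mode and equal-tailed 95% interval of the cluster count."""
    ks = np.asarray(w_k_trace).ravel()
    values, counts = np.unique(ks, return_counts=True)
    mode = int(values[counts == counts.max()].min())
    lo, hi = np.quantile(ks, [0.025, 0.975])
    return mode, (int(np.floor(lo)), int(np.ceil(hi)))


def format_cluster_count(mode: int, cri: Tuple[int, int]) -> str:
    return f"{mode} ({cri[0]}, {cri[1]})"


def _spectral_var(x: np.ndarray) -> float:
    """Spectral density of a chain segment at frequency zero (Bartlett window)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    max_lag = min(n - 1, int(np.floor(10.0 * np.log10(n))) if n > 1 else 0)
    acov = np.array(
        [float(xc[: n - lag] @ xc[lag:]) / n for lag in range(max_lag + 1)]
    )
    weights = 1.0 - np.arange(1, max_lag + 1) / (max_lag + 1.0)
    return float(acov[0] + 2.0 * (weights * acov[1:]).sum())


def geweke_z(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence diagnostic.

    Compares the means of the first 10% and last 50% of the chain, with
    variances estimated by the spectral density at zero frequency.  Returns
    NaN for a (near-)constant trace, which has no meaningful z-score.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("trace too short for a Geweke diagnostic")
    a = x[: int(first * x.size)]
    b = x[int((1.0 - last) * x.size):]
    if np.var(x) == 0:
        return float("nan")
    va = _spectral_var(a) / a.size
    vb = _spectral_var(b) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / denom)


@dataclass
class PosteriorSummary:
    """Human- and machine-readable summary of a model fit."""

    risk_median: np.ndarray  # n x T
    risk_lower: np.ndarray
    risk_upper: np.ndarray
    w_probabilities: List[Dict[Tuple[int, int], float]]  # per period
    w_mode: List[int]  # candidate position per period
    w_mode_label: List[Tuple[int, int]]
    modal_partition: np.ndarray  # n x T labels
    cluster_counts: List[Tuple[int, Tuple[int, int]]]  # per period
    dic: float
    pd: float
    geweke: Dict[str, float]
    tau2_median: np.ndarray
    parameters: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dic": self.dic,
            "pd": self.pd,
            "w_mode": [list(lab) for lab in self.w_mode_label],
            "cluster_counts": [
                format_cluster_count(m, ci) for m, ci in self.cluster_counts
            ],
            "tau2_median": self.tau2_median.tolist(),
            "geweke": self.geweke,
            "parameters": self.parameters,
        }


def _pd_for_subset(samples: Samples, idx: np.ndarray, data: CountData) -> float:
    eta_mean = samples.log_risk[idx].astype(np.float64).mean(axis=0)
    _, pd_ = dic(samples.deviance[idx], _deviance_of_eta(eta_mean, data))
    return pd_


def modal_partition(cands: CandidateSet, w_mode: List[int], T: int) -> np.ndarray:
    """Stage-1 labels of the modal candidate(s), expanded to an n x T matrix."""
    cols = [cands.labels_for(pos) for pos in (w_mode if len(w_mode) == T else w_mode * T)]
    return np.column_stack(cols)


def summarize(samples: Samples, data: CountData, cands: CandidateSet) -> PosteriorSummary:
    """Posterior summary: risks, W posterior, cluster counts, DIC, diagnostics."""
    T = data.T
    variant = samples.config.variant if samples.config is not None else "A"
    q = samples.risk_quantiles((0.025, 0.5, 0.975))
    lower, median, upper = q[0], q[1], q[2]

    per_t = variant == "B"
    periods = range(T)
    w_probs: List[Dict[Tuple[int, int], float]] = []
    w_mode: List[int] = []
    w_mode_label: List[Tuple[int, int]] = []
    for t in periods:
        trace = samples.w_pos[:, t] if per_t else samples.w_pos[:, 0]
        values, counts = np.unique(trace, return_counts=True)
        tied = values[counts == counts.max()]
        pd_by = None
        if tied.size > 1:
            pd_by = {
                int(v): _pd_for_subset(samples, np.flatnonzero(trace == v), data)
                for v in tied
            }
        pos = posterior_mode_W(trace, pd_by)
        w_mode.append(pos)
        # label distribution on the (c, k) grid; k = 1 states collapse to pos 0
        cs = samples.w_c[:, t] if per_t else samples.w_c[:, 0]
        ks = samples.w_k[:, t] if per_t else samples.w_k[:, 0]
        probs: Dict[Tuple[int, int], float] = {}
        for c, k in zip(cs, ks):
            key = (1, 1) if k == 1 else (int(c), int(k))
            probs[key] = probs.get(key, 0.0) + 1.0
        total = sum(probs.values())
        w_probs.append({k: v / total for k, v in probs.items()})
        lab = min(
            (key for key, p in w_probs[-1].items()),
            key=lambda key: -w_probs[-1][key],
        )
        # report the label matching the modal position where possible
        matches = [
            key
            for key in w_probs[-1]
            if cands.index.get(key if not per_t else key + (t + 1,), -1) == pos
        ]
        w_mode_label.append(matches[0] if matches else lab)
        if not per_t:
            w_probs = w_probs * T
            w_mode = w_mode * T
            w_mode_label = w_mode_label * T
            break

    part = modal_partition(cands, w_mode, T)
    counts = [
        cluster_count_summary(samples.w_k[:, t] if per_t else samples.w_k[:, 0])
        for t in range(T)
    ]
    eta_mean = samples.log_risk.astype(np.float64).mean(axis=0)
    dic_, pd_ = dic(samples.deviance, _deviance_of_eta(eta_mean, data))

    geweke: Dict[str, float] = {}
    for name, trace in (
        ("beta0", samples.beta[:, 0]),
        ("deviance", samples.deviance),
        ("sigma2", samples.sigma2),
        ("alpha", samples.alpha),
        ("rho", samples.rho[:, 0]),
    ):
        try:
            geweke[name] = geweke_z(trace)
        except ValueError:
            geweke[name] = float("nan")

    params = {
        "beta0": float(np.median(samples.beta[:, 0])),
        "alpha": float(np.median(samples.alpha)),
        "sigma2": float(np.median(samples.sigma2)),
        "rho": float(np.median(samples.rho)),
    }
    return PosteriorSummary(
        risk_median=median,
        risk_lower=lower,
        risk_upper=upper,
        w_probabilities=w_probs,
        w_mode=w_mode,
        w_mode_label=w_mode_label,
        modal_partition=part,
        cluster_counts=counts,
        dic=dic_,
        pd=pd_,
        geweke=geweke,
        tau2_median=np.median(samples.tau2, axis=0),
        parameters=params,
    )
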