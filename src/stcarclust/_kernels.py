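"""Compiled inner loops for the MCMC sampler."""

import numpy as np
from numba import njit


@njit(cache=True)
def phi_site_sweep(phi, off, Y, E, indptr, indices, deg, rho, tau2, step, z, u):
    """Sequential single-site random-walk MH sweep over one spatial surface.

    For each area the target is the Poisson cell likelihood times the Leroux
    full-conditional prior given the current neighbours:
        mean = rho * sum_j w_ij phi_j / (rho d_i + 1 - rho)
        var  = tau2 / (rho d_i + 1 - rho).
    ``phi`` is updated in place; returns the number of accepted moves.
    ``off`` is the rest of the linear predictor (x'beta + theta_t), ``z`` and
    ``u`` are pre-drawn standard normals and uniforms.
    """
    n = phi.shape[0]
    acc = 0
    for i in range(n):
        s = 0.0
        for jj in range(indptr[i], indptr[i + 1]):
            s += phi[indices[jj]]
        denom = rho * deg[i] + 1.0 - rho
        m = rho * s / denom
        prec = denom / tau2
        cur = phi[i]
        prop = cur + step * z[i]
        ec = off[i] + cur
        ep = off[i] + prop
        dl = (
            Y[i] * (ep - ec)
            - E[i] * (np.exp(ep) - np.exp(ec))
            - 0.5 * prec * ((prop - m) ** 2 - (cur - m) ** 2)
        )
        if dl > 0.0 or u[i] < np.exp(dl):
            phi[i] = prop
            acc += 1
    return acc
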