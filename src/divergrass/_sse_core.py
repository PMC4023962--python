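"""Numerical core for binary-state speciation-extinction likelihoods.

The state vector along a branch is ``y = (E0, E1, D0, D1)``: the
probability that a lineage in state i leaves no sampled descendant, and
the density of the observed subtree given a lineage in state i.  Backward
in time (i != j):

    dE_i/dt = mu_i - (lambda_i + mu_i + q_ij) E_i + q_ij E_j + lambda_i E_i^2
    dD_i/dt = -(lambda_i + mu_i + q_ij) D_i + q_ij D_j + 2 lambda_i E_i D_i

Branches are integrated with an adaptive Dormand-Prince 5(4) scheme and
the post-order pruning pass renormalizes D whenever it underflows,
accumulating the discarded magnitude as a log-scale factor.
"""

import numpy as np
from numba import njit

UNDERFLOW = 1e-50
MAX_STEPS = 200_000


@njit(cache=True)
def _derivs(y, p, dy):
    l0, l1, m0, m1, q01, q10 = p[0], p[1], p[2], p[3], p[4], p[5]
    E0, E1, D0, D1 = y[0], y[1], y[2], y[3]
    dy[0] = m0 - (l0 + m0 + q01) * E0 + q01 * E1 + l0 * E0 * E0
    dy[1] = m1 - (l1 + m1 + q10) * E1 + q10 * E0 + l1 * E1 * E1
    dy[2] = -(l0 + m0 + q01) * D0 + q01 * D1 + 2.0 * l0 * E0 * D0
    dy[3] = -(l1 + m1 + q10) * D1 + q10 * D0 + 2.0 * l1 * E1 * D1


@njit(cache=True)
def integrate_branch(y0, p, duration, rtol, atol):
    """Integrate the 4-state system over ``duration`` (Dormand-Prince 5(4)).

    Returns the final state; on step-count exhaustion the state is filled
    with NaN so callers can flag solver failure.
    """
    y = y0.copy()
    if duration <= 0.0:
        return y
    t = 0.0
    rate_scale = max(
        p[0] + p[2] + p[4], p[1] + p[3] + p[5], 1e-8
    )
    h = min(duration, 0.1 / rate_scale)
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    k5 = np.empty(4)
    k6 = np.empty(4)
    k7 = np.empty(4)
    ytmp = np.empty(4)
    ynew = np.empty(4)
    _derivs(y, p, k1)
    steps = 0
    while t < duration:
        if steps > MAX_STEPS:
            for i in range(4):
                y[i] = np.nan
            return y
        steps += 1
        if t + h > duration:
            h = duration - t
        for i in range(4):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _derivs(ytmp, p, k2)
        for i in range(4):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _derivs(ytmp, p, k3)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i]
            )
        _derivs(ytmp, p, k4)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _derivs(ytmp, p, k5)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _derivs(ytmp, p, k6)
        for i in range(4):
            ynew[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _derivs(ynew, p, k7)
        errnorm = 0.0
        for i in range(4):
            err = h * (
                71.0 / 57600.0 * k1[i]
                - 71.0 / 16695.0 * k3[i]
                + 71.0 / 1920.0 * k4[i]
                - 17253.0 / 339200.0 * k5[i]
                + 22.0 / 525.0 * k6[i]
                - 1.0 / 40.0 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            errnorm += (err / sc) ** 2
        errnorm = np.sqrt(errnorm / 4.0)
        if errnorm <= 1.0:
            t += h
            for i in range(4):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            fac = 5.0 if errnorm == 0.0 else min(5.0, 0.9 * errnorm ** -0.2)
            h *= fac
        else:
            h *= max(0.2, 0.9 * errnorm ** -0.2)
    return y


@njit(cache=True)
def prune_loglik(order, left, right, elen, init, init_logw, p, rtol, atol):
    """Post-order pruning pass over a flattened bifurcating tree.

    ``order`` lists node ids in post-order (root last, edge length 0);
    tips carry initial conditions in ``init`` plus per-tip log weights.
    At each internal node children combine as
    ``D_i <- lambda_i * D_i(left) * D_i(right)``.

    Returns (root state, accumulated log scale, ok flag).
    """
    n = order.shape[0]
    Y = np.zeros((n, 4))
    logfac = 0.0
    for idx in range(n):
        nd = order[idx]
        if left[nd] < 0:
            y = init[nd].copy()
            logfac += init_logw[nd]
        else:
            yl = Y[left[nd]]
            yr = Y[right[nd]]
            y = np.empty(4)
            y[0] = 0.5 * (yl[0] + yr[0])
            y[1] = 0.5 * (yl[1] + yr[1])
            y[2] = p[0] * yl[2] * yr[2]
            y[3] = p[1] * yl[3] * yr[3]
        m = max(y[2], y[3])
        if m <= 0.0 or np.isnan(m):
            return Y[nd], logfac, False
        if m < UNDERFLOW:
            y[2] /= m
            y[3] /= m
            logfac += np.log(m)
        if elen[nd] > 0.0:
            y = integrate_branch(y, p, elen[nd], rtol, atol)
            if np.isnan(y[2]) or np.isnan(y[3]):
                return y, logfac, False
        Y[nd] = y
    return Y[order[n - 1]], logfac, True
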