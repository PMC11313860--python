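"""Compiled numerical kernels.

The CME steady state is re-implemented here as a banded Gaussian elimination
so that the Metropolis-Hastings loop and the stochastic simulator run at
compiled speed; ``burstkit.model.steady_state`` is the reference
implementation and the test suite asserts the two routes agree.

Promoter-state conventions match :mod:`burstkit.model`: count-major joint
index ``m * n_states + s``, the last state is the active one, switching
rates are ``(k_on, k_off)`` for two states and ``(f1, b1, f2, b2)`` for the
serial reversible three-state chain.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_FLOOR = 1e-300


@njit(cache=True)
def _switching_stationary(n_states, sr):
    pi = np.zeros(n_states)
    if n_states == 1:
        pi[0] = 1.0
    elif n_states == 2:
        tot = sr[0] + sr[1]
        if tot == 0.0:
            pi[0] = 0.5
            pi[1] = 0.5
        else:
            pi[0] = sr[1] / tot
            pi[1] = sr[0] / tot
    else:
        w0 = sr[1] * sr[3]
        w1 = sr[0] * sr[3]
        w2 = sr[0] * sr[2]
        tot = w0 + w1 + w2
        if tot == 0.0:
            pi[:] = 1.0 / 3.0
        else:
            pi[0] = w0 / tot
            pi[1] = w1 / tot
            pi[2] = w2 / tot
    return pi


@njit(cache=True, inline="always")
def _put(ab, rhs, b, k, i, j, v):
    """Add A[i, j] = v into the banded system with row/column k deleted."""
    if i == k:
        return
    ii = i if i < k else i - 1
    if j == k:
        rhs[ii] -= v
    else:
        jj = j if j < k else j - 1
        ab[b + ii - jj, jj] += v


@njit(cache=True)
def _steady_marginal_fixed(n_states, sr, k_eject, k_decay, N, k_pin):
    """Marginal stationary pmf over counts 0..N by banded elimination.

    Solves A p = 0 for the truncated generator with the well-scaled joint
    component ``k_pin`` (near the stationary mode) pinned to 1 and its
    redundant balance equation dropped; deleting a matching row/column pair
    keeps the bandwidth at ``n_states`` and the system column diagonally
    dominant.
    """
    n_s = n_states
    dim = n_s * (N + 1)
    n = dim - 1
    b = n_s
    k = k_pin
    ab = np.zeros((2 * b + 1, n))
    rhs = np.zeros(n)

    # promoter switching rates (serial chain: adjacent states only)
    up = np.zeros(n_s)    # s -> s+1
    down = np.zeros(n_s)  # s -> s-1
    if n_s == 2:
        up[0] = sr[0]
        down[1] = sr[1]
    elif n_s == 3:
        up[0] = sr[0]
        down[1] = sr[1]
        up[1] = sr[2]
        down[2] = sr[3]
    active = n_s - 1

    for m in range(N + 1):
        base = m * n_s
        for s in range(n_s):
            j = base + s
            out = 0.0
            if s + 1 < n_s and up[s] > 0.0:
                _put(ab, rhs, b, k, j + 1, j, up[s])
                out += up[s]
            if s > 0 and down[s] > 0.0:
                _put(ab, rhs, b, k, j - 1, j, down[s])
                out += down[s]
            # ejection (suppressed at the truncation boundary)
            if s == active and m < N and k_eject > 0.0:
                _put(ab, rhs, b, k, j + n_s, j, k_eject)
                out += k_eject
            if m > 0:
                d = m * k_decay
                _put(ab, rhs, b, k, j - n_s, j, d)
                out += d
            _put(ab, rhs, b, k, j, j, -out)

    # banded Gaussian elimination without pivoting
    for col in range(n):
        piv = ab[b, col]
        hi = col + b
        if hi > n - 1:
            hi = n - 1
        for i in range(col + 1, hi + 1):
            f = ab[b + i - col, col]
            if f == 0.0:
                continue
            f /= piv
            for j in range(col + 1, hi + 1):
                ab[b + i - j, j] -= f * ab[b + col - j, j]
            rhs[i] -= f * rhs[col]
    x = np.zeros(n)
    for i in range(n - 1, -1, -1):
        acc = rhs[i]
        hi = i + b
        if hi > n - 1:
            hi = n - 1
        for j in range(i + 1, hi + 1):
            acc -= ab[b + i - j, j] * x[j]
        x[i] = acc / ab[b, i]

    marg = np.zeros(N + 1)
    for m in range(N + 1):
        base = m * n_s
        acc = 0.0
        for s in range(n_s):
            jj = base + s
            if jj == k:
                v = 1.0
            elif jj < k:
                v = x[jj]
            else:
                v = x[jj - 1]
            if v > 0.0:
                acc += v
        marg[m] = acc
    total = marg.sum()
    return marg / total


@njit(cache=True)
def steady_marginal(n_states, sr, k_eject, k_decay, min_trunc, tail_tol, cap):
    """Adaptive-truncation stationary pmf; flag is False if the cap is hit."""
    pi = _switching_stationary(n_states, sr)
    p_on = pi[n_states - 1]
    nu = k_eject / k_decay
    mean = nu * p_on
    if n_states == 2:
        a = sr[0] / k_decay
        bb = sr[1] / k_decay
        var = mean * (1.0 + nu * bb / ((a + bb) * (1.0 + a + bb)))
    else:
        var = mean + nu * nu * p_on * (1.0 - p_on)
    N = int(4.0 * np.ceil(mean) + 10.0 * np.ceil(np.sqrt(var)))
    if N < min_trunc:
        N = min_trunc
    if N < 8:
        N = 8
    if N > cap:
        N = cap
    s_pin = 0
    for s in range(n_states):
        if pi[s] > pi[s_pin]:
            s_pin = s
    while True:
        m_pin = int(np.round(mean))
        if m_pin > N:
            m_pin = N
        k_pin = m_pin * n_states + s_pin
        marg = _steady_marginal_fixed(n_states, sr, k_eject, k_decay, N, k_pin)
        if marg[N] < tail_tol:
            return marg, True
        if N >= cap:
            return marg, False
        N = min(2 * N, cap)


@njit(cache=True)
def _loglik_hist(n_states, sr, k_eject, k_decay, hist, n_alleles, tail_tol, cap):
    """Log-likelihood of a count histogram under the multi-allele model."""
    max_count = hist.size - 1
    min_trunc = max_count // n_alleles + 2
    marg, ok = steady_marginal(n_states, sr, k_eject, k_decay, min_trunc, tail_tol, cap)
    if not ok:
        return -1e300
    p = marg
    for _ in range(n_alleles - 1):
        p = np.convolve(p, marg)
    ll = 0.0
    for m in range(hist.size):
        h = hist[m]
        if h > 0:
            pm = p[m] if m < p.size else 0.0
            if pm < _LOG_FLOOR:
                pm = _LOG_FLOOR
            ll += h * np.log(pm)
    return ll


@njit(cache=True)
def mh_chain(
    n_states,
    hist,
    k_decay,
    mu_log,
    sigma_log,
    n_samples,
    n_warmup,
    seed,
    init_log,
    n_alleles,
    init_scale,
    tail_tol,
    cap,
):
    """One adaptive random-walk Metropolis chain over log-rates.

    The sampled vector is ``[state_rates..., k_eject]`` in natural log.  The
    log-normal rate priors become Gaussians in log space.  Per-parameter
    proposal scales are adapted during warmup toward a 20-40% acceptance
    window and then frozen.  Returns (draws, logliks, acceptance_rate) with
    draws of shape (n_samples - n_warmup, n_free).
    """
    np.random.seed(seed)
    nf = mu_log.size
    x = init_log.copy()
    scale = init_scale  # global step multiplier, tuned toward 20-40% acceptance
    L = np.eye(nf)      # Cholesky factor of the proposal shape, adapted in warmup

    def _logprior(z):
        lp = 0.0
        for i in range(z.size):
            d = (z[i] - mu_log[i]) / sigma_log[i]
            lp += -0.5 * d * d - np.log(sigma_log[i])
        return lp

    sr = np.exp(x[: nf - 1])
    ll = _loglik_hist(n_states, sr, np.exp(x[nf - 1]), k_decay, hist, n_alleles, tail_tol, cap)
    lp = _logprior(x)

    n_keep = n_samples - n_warmup
    draws = np.empty((n_keep, nf))
    logliks = np.empty(n_keep)
    n_acc_total = 0
    n_acc_win = 0
    win = 0
    # warmup history for covariance adaptation (posterior ridges in log-rate
    # space, e.g. k_off vs k_eject, need correlated proposals to mix)
    hist_buf = np.empty((n_warmup, nf))
    shape_adapted = False

    for it in range(n_samples):
        step = L @ np.random.standard_normal(nf)
        prop = x + scale * step
        sr_p = np.exp(prop[: nf - 1])
        ll_p = _loglik_hist(
            n_states, sr_p, np.exp(prop[nf - 1]), k_decay, hist, n_alleles, tail_tol, cap
        )
        lp_p = _logprior(prop)
        if np.log(np.random.random()) < (ll_p + lp_p) - (ll + lp):
            x = prop
            ll = ll_p
            lp = lp_p
            n_acc_win += 1
            if it >= n_warmup:
                n_acc_total += 1
        win += 1
        if it < n_warmup:
            hist_buf[it] = x
            if win == 100:
                rate = n_acc_win / 100.0
                if rate < 0.20:
                    scale *= 0.7
                elif rate > 0.40:
                    scale *= 1.35
                n_acc_win = 0
                win = 0
            if it >= 400 and (it + 1) % 500 == 0:
                # Haario-style shape adaptation from the warmup history
                lo = (it + 1) // 2
                seg = hist_buf[lo : it + 1]
                mean = np.zeros(nf)
                for r in range(seg.shape[0]):
                    mean += seg[r]
                mean /= seg.shape[0]
                cov = np.zeros((nf, nf))
                for r in range(seg.shape[0]):
                    dv = seg[r] - mean
                    cov += np.outer(dv, dv)
                cov /= max(seg.shape[0] - 1, 1)
                for d in range(nf):
                    cov[d, d] += 1e-6
                ok_chol = True
                Lnew = np.zeros((nf, nf))
                for ci in range(nf):
                    for cj in range(ci + 1):
                        s = cov[ci, cj]
                        for ck in range(cj):
                            s -= Lnew[ci, ck] * Lnew[cj, ck]
                        if ci == cj:
                            if s <= 0.0:
                                ok_chol = False
                                break
                            Lnew[ci, ci] = np.sqrt(s)
                        else:
                            Lnew[ci, cj] = s / Lnew[cj, cj]
                    if not ok_chol:
                        break
                if ok_chol:
                    L = Lnew
                    if not shape_adapted:
                        scale = 2.38 / np.sqrt(nf)
                        shape_adapted = True
                    n_acc_win = 0
                    win = 0
        if it >= n_warmup:
            draws[it - n_warmup] = x
            logliks[it - n_warmup] = ll

    acc = n_acc_total / max(n_keep, 1)
    return draws, logliks, acc


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def gillespie_counts(n_states, sr, k_eject, k_decay, n_cells, t_burn, seed):
    """Exact SSA draws of the stationary mRNA count, one per cell.

    Each cell starts in a promoter state drawn from the switching-chain
    stationary law with the (rounded) stationary mean copy number, then
    evolves for ``t_burn`` minutes before its count is recorded.  Kept
    deliberately independent of the CME solver so the two routes
    cross-validate each other.
    """
    np.random.seed(seed)
    pi = _switching_stationary(n_states, sr)
    cdf = np.cumsum(pi)
    nu = k_eject / k_decay
    m0 = int(np.round(nu * pi[n_states - 1]))

    up = np.zeros(n_states)
    down = np.zeros(n_states)
    if n_states == 2:
        up[0] = sr[0]
        down[1] = sr[1]
    elif n_states == 3:
        up[0] = sr[0]
        down[1] = sr[1]
        up[1] = sr[2]
        down[2] = sr[3]
    active = n_states - 1

    out = np.empty(n_cells, dtype=np.int64)
    for c in range(n_cells):
        u = np.random.random()
        s = 0
        for k in range(n_states):
            if u <= cdf[k]:
                s = k
                break
        m = m0
        t = 0.0
        while True:
            r_up = up[s]
            r_down = down[s]
            r_ej = k_eject if s == active else 0.0
            r_dec = m * k_decay
            r_tot = r_up + r_down + r_ej + r_dec
            if r_tot <= 0.0:
                break
            t += -np.log(np.random.random()) / r_tot
            if t > t_burn:
                break
            u = np.random.random() * r_tot
            if u < r_up:
                s += 1
            elif u < r_up + r_down:
                s -= 1
            elif u < r_up + r_down + r_ej:
                m += 1
            else:
                m -= 1
        out[c] = m
    return out
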