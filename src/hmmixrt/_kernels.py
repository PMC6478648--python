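"""Compiled inner loops for the marginal likelihood and the E-step.

A single fused sweep runs, per person and per quadrature node, the scaled
forward (and optionally backward) recursion over items and accumulates the
aggregated sufficient statistics the M-step needs:

- ``Rstat[a, i, c, x]``: posterior-weighted response counts per theta node,
  item, state and response value;
- ``Tcat[q, i, c, t]``: posterior-weighted RT-category counts per (theta,
  tau) node, item and state;
- initial-state, transition and marginal state counts for the chain update;
- per-person posterior moments of (theta, tau) and per-item smoothed state
  posteriors for scoring.

Nodes with negligible posterior weight (< 1e-13) are skipped in the backward
pass.  Missing responses or RT categories (coded -1) contribute an emission
factor of 1 for the missing part only.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def sweep(x, t, Px, Pt, init, A, Wq, theta_q, tau_q, want_stats, want_scores):
    """Fused forward(-backward) sweep over persons and quadrature nodes.

    Parameters are pre-evaluated probability tables: ``Px[a, i, c]`` is the
    probability of a correct response at theta-node ``a`` (``a = q // Q``),
    ``Pt[q, i, c, t]`` the PCM category probability at node ``q``.
    """
    N, n = x.shape
    Q = Px.shape[0]
    Q2 = Pt.shape[0]
    T = Pt.shape[3]

    total = 0.0
    Lp = np.zeros(N)
    Rstat = np.zeros((Q, n, 2, 2))
    Tcat = np.zeros((Q2, n, 2, T))
    init_c = np.zeros(2)
    trans_c = np.zeros((2, 2))
    marg_c = np.zeros(2)
    Eth = np.zeros(N)
    Eth2 = np.zeros(N)
    Eta = np.zeros(N)
    Eta2 = np.zeros(N)
    if want_scores:
        gbar = np.zeros((N, n, 2))
    else:
        gbar = np.zeros((1, 1, 2))

    e = np.empty((Q2, n, 2))
    alphas = np.empty((Q2, n, 2))
    lognorm = np.empty(Q2)

    for p in range(N):
        # ---- pass 1: forward recursion at every node -------------------
        for q in range(Q2):
            a = q // Q
            ll = 0.0
            f0 = 0.0
            f1 = 0.0
            for i in range(n):
                xi = x[p, i]
                ti = t[p, i]
                for c in range(2):
                    g = 1.0
                    if xi >= 0:
                        pxc = Px[a, i, c]
                        g = pxc if xi == 1 else 1.0 - pxc
                    h = 1.0
                    if ti >= 0:
                        h = Pt[q, i, c, ti]
                    e[q, i, c] = g * h
                if i == 0:
                    f0 = init[0] * e[q, 0, 0]
                    f1 = init[1] * e[q, 0, 1]
                else:
                    pa0 = alphas[q, i - 1, 0]
                    pa1 = alphas[q, i - 1, 1]
                    f0 = (pa0 * A[0, 0] + pa1 * A[1, 0]) * e[q, i, 0]
                    f1 = (pa0 * A[0, 1] + pa1 * A[1, 1]) * e[q, i, 1]
                s = f0 + f1
                if s <= 0.0:
                    s = 1e-300
                alphas[q, i, 0] = f0 / s
                alphas[q, i, 1] = f1 / s
                ll += math.log(s)
            lognorm[q] = ll

        # ---- node posterior weights ------------------------------------
        m = lognorm[0]
        for q in range(1, Q2):
            if lognorm[q] > m:
                m = lognorm[q]
        Z = 0.0
        for q in range(Q2):
            Z += Wq[q] * math.exp(lognorm[q] - m)
        Lp[p] = m + math.log(Z)
        total += Lp[p]

        if not (want_stats or want_scores):
            continue

        # ---- pass 2: backward recursion and accumulation ---------------
        for q in range(Q2):
            w = Wq[q] * math.exp(lognorm[q] - m) / Z
            if w < 1e-13:
                continue
            if want_scores:
                Eth[p] += w * theta_q[q]
                Eth2[p] += w * theta_q[q] * theta_q[q]
                Eta[p] += w * tau_q[q]
                Eta2[p] += w * tau_q[q] * tau_q[q]
            a = q // Q
            b0 = 1.0
            b1 = 1.0
            for i in range(n - 1, -1, -1):
                g0 = alphas[q, i, 0] * b0
                g1 = alphas[q, i, 1] * b1
                sg = g0 + g1
                if sg <= 0.0:
                    sg = 1e-300
                g0 /= sg
                g1 /= sg
                if want_stats:
                    marg_c[0] += w * g0
                    marg_c[1] += w * g1
                    xi = x[p, i]
                    if xi >= 0:
                        Rstat[a, i, 0, xi] += w * g0
                        Rstat[a, i, 1, xi] += w * g1
                    ti = t[p, i]
                    if ti >= 0:
                        Tcat[q, i, 0, ti] += w * g0
                        Tcat[q, i, 1, ti] += w * g1
                if want_scores:
                    gbar[p, i, 0] += w * g0
                    gbar[p, i, 1] += w * g1
                if i > 0:
                    if want_stats:
                        j00 = alphas[q, i - 1, 0] * A[0, 0] * e[q, i, 0] * b0
                        j01 = alphas[q, i - 1, 0] * A[0, 1] * e[q, i, 1] * b1
                        j10 = alphas[q, i - 1, 1] * A[1, 0] * e[q, i, 0] * b0
                        j11 = alphas[q, i - 1, 1] * A[1, 1] * e[q, i, 1] * b1
                        sj = j00 + j01 + j10 + j11
                        if sj <= 0.0:
                            sj = 1e-300
                        trans_c[0, 0] += w * j00 / sj
                        trans_c[0, 1] += w * j01 / sj
                        trans_c[1, 0] += w * j10 / sj
                        trans_c[1, 1] += w * j11 / sj
                    nb0 = A[0, 0] * e[q, i, 0] * b0 + A[0, 1] * e[q, i, 1] * b1
                    nb1 = A[1, 0] * e[q, i, 0] * b0 + A[1, 1] * e[q, i, 1] * b1
                    sb = nb0 + nb1
                    if sb <= 0.0:
                        sb = 1e-300
                    b0 = nb0 / sb
                    b1 = nb1 / sb
                elif want_stats:
                    init_c[0] += w * g0
                    init_c[1] += w * g1

    return total, Lp, Rstat, Tcat, init_c, trans_c, marg_c, Eth, Eth2, Eta, Eta2, gbar


__all__ = ["sweep"]
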