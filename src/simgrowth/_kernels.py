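"""Compiled likelihood kernels for the mixed models.

Scalar-arithmetic ports of the vectorised profiled likelihoods in
:mod:`.mixed_models` (same parameterisation, same return values), jitted
with numba.  The pure-numpy versions remain the reference implementation;
agreement between the two paths is asserted in the test suite.  These
kernels exist because the non-parametric bootstrap refits the joint model
tens of thousands of times per run.

Each kernel returns ``(nll, grad, beta, M)`` where ``grad`` is the
gradient of the *negative* profiled log-likelihood with respect to the
log-Cholesky/log-sigma parameter vector, ``beta`` the profiled GLS fixed
effects and ``M = X'V^-1 X`` their information matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _solve2(a00, a01, a11, r0, r1):
    det = a00 * a11 - a01 * a01
    return (a11 * r0 - a01 * r1) / det, (a00 * r1 - a01 * r0) / det


@njit(cache=True)
def uni_nll_grad(theta, g00, g01, g11, zy0, zy1, yy, w, n_occ, want_grad):
    """Profiled negative log-likelihood of the univariate growth LMM.

    theta = (log l00, l10, log l11, log sigma_eh); per-individual
    sufficient statistics G = Z'Z (g00, g01, g11), Z'y (zy0, zy1), y'y.
    """
    J = g00.shape[0]
    l00 = np.exp(theta[0])
    l10 = theta[1]
    l11 = np.exp(theta[2])
    s2 = np.exp(2.0 * theta[3])
    # omega = L L'
    o00 = l00 * l00
    o01 = l00 * l10
    o11 = l10 * l10 + l11 * l11
    odet = o00 * o11 - o01 * o01
    oi00 = o11 / odet
    oi01 = -o01 / odet
    oi11 = o00 / odet

    A00 = np.empty(J); A01 = np.empty(J); A11 = np.empty(J)
    T0 = np.empty(J); T1 = np.empty(J)
    Sp00 = np.empty(J); Sp01 = np.empty(J); Sp11 = np.empty(J)
    M00 = 0.0; M01 = 0.0; M11 = 0.0
    r0 = 0.0; r1 = 0.0
    sum_logdet = 0.0
    sum_yVy = 0.0
    wsum = 0.0
    logs2 = np.log(s2)
    for j in range(J):
        wj = w[j]
        wsum += wj
        b00 = oi00 + g00[j] / s2
        b01 = oi01 + g01[j] / s2
        b11 = oi11 + g11[j] / s2
        bdet = b00 * b11 - b01 * b01
        sp00 = b11 / bdet
        sp01 = -b01 / bdet
        sp11 = b00 / bdet
        Sp00[j] = sp00; Sp01[j] = sp01; Sp11[j] = sp11
        # GSp = G @ Sp (non-symmetric)
        gs00 = g00[j] * sp00 + g01[j] * sp01
        gs01 = g00[j] * sp01 + g01[j] * sp11
        gs10 = g01[j] * sp00 + g11[j] * sp01
        gs11 = g01[j] * sp01 + g11[j] * sp11
        # A = (G - GSp G / s2) / s2  (symmetric)
        a00 = (g00[j] - (gs00 * g00[j] + gs01 * g01[j]) / s2) / s2
        a01 = (g01[j] - (gs00 * g01[j] + gs01 * g11[j]) / s2) / s2
        a11 = (g11[j] - (gs10 * g01[j] + gs11 * g11[j]) / s2) / s2
        A00[j] = a00; A01[j] = a01; A11[j] = a11
        # t = (Zy - GSp Zy / s2) / s2
        t0 = (zy0[j] - (gs00 * zy0[j] + gs01 * zy1[j]) / s2) / s2
        t1 = (zy1[j] - (gs10 * zy0[j] + gs11 * zy1[j]) / s2) / s2
        T0[j] = t0; T1[j] = t1
        # log|V| = I log s2 + log det(I + omega G / s2)
        m00 = 1.0 + (o00 * g00[j] + o01 * g01[j]) / s2
        m01 = (o00 * g01[j] + o01 * g11[j]) / s2
        m10 = (o01 * g00[j] + o11 * g01[j]) / s2
        m11 = 1.0 + (o01 * g01[j] + o11 * g11[j]) / s2
        detm = m00 * m11 - m01 * m10
        if detm <= 0.0:
            return np.inf, np.zeros(4), np.zeros(2), np.zeros((2, 2))
        sum_logdet += wj * (n_occ * logs2 + np.log(detm))
        # y'V^-1 y = yy/s2 - Zy' Sp Zy / s2^2
        spzy0 = sp00 * zy0[j] + sp01 * zy1[j]
        spzy1 = sp01 * zy0[j] + sp11 * zy1[j]
        sum_yVy += wj * (yy[j] / s2
                         - (zy0[j] * spzy0 + zy1[j] * spzy1) / (s2 * s2))
        M00 += wj * a00; M01 += wj * a01; M11 += wj * a11
        r0 += wj * t0; r1 += wj * t1

    beta0, beta1 = _solve2(M00, M01, M11, r0, r1)
    Q = (sum_yVy - 2.0 * (beta0 * r0 + beta1 * r1)
         + beta0 * (M00 * beta0 + M01 * beta1)
         + beta1 * (M01 * beta0 + M11 * beta1))
    nll = 0.5 * (wsum * n_occ * _LOG2PI + sum_logdet + Q)
    beta = np.array([beta0, beta1])
    M = np.array([[M00, M01], [M01, M11]])
    grad = np.zeros(4)
    if not want_grad:
        return nll, grad, beta, M

    S00 = 0.0; S01 = 0.0; S11 = 0.0
    dsig2 = 0.0
    for j in range(J):
        wj = w[j]
        a0 = T0[j] - (A00[j] * beta0 + A01[j] * beta1)
        a1 = T1[j] - (A01[j] * beta0 + A11[j] * beta1)
        S00 += wj * (a0 * a0 - A00[j])
        S01 += wj * (a0 * a1 - A01[j])
        S11 += wj * (a1 * a1 - A11[j])
        # d/dsig2 pieces
        q0 = zy0[j] - (g00[j] * beta0 + g01[j] * beta1)
        q1 = zy1[j] - (g01[j] * beta0 + g11[j] * beta1)
        sq0 = Sp00[j] * q0 + Sp01[j] * q1
        sq1 = Sp01[j] * q0 + Sp11[j] * q1
        gsq0 = g00[j] * sq0 + g01[j] * sq1
        gsq1 = g01[j] * sq0 + g11[j] * sq1
        rr = (yy[j] - 2.0 * (zy0[j] * beta0 + zy1[j] * beta1)
              + beta0 * (g00[j] * beta0 + g01[j] * beta1)
              + beta1 * (g01[j] * beta0 + g11[j] * beta1))
        rP2r = (rr - 2.0 * (q0 * sq0 + q1 * sq1) / s2
                + (gsq0 * sq0 + gsq1 * sq1) / (s2 * s2)) / (s2 * s2)
        trSpG = Sp00[j] * g00[j] + 2.0 * Sp01[j] * g01[j] + Sp11[j] * g11[j]
        trP = (n_occ - trSpG / s2) / s2
        dsig2 += wj * (rP2r - trP)
    S00 *= 0.5; S01 *= 0.5; S11 *= 0.5
    dsig2 *= 0.5
    # chain rule: dl/dL = 2 S L, diag entries * L_ii (log parameterised)
    dl00 = 2.0 * (S00 * l00 + S01 * l10)
    dl10 = 2.0 * (S01 * l00 + S11 * l10)
    dl11 = 2.0 * (S11 * l11)
    grad[0] = -dl00 * l00
    grad[1] = -dl10
    grad[2] = -dl11 * l11
    grad[3] = -dsig2 * 2.0 * s2
    return nll, grad, beta, M


@njit(cache=True)
def biv_nll_grad(theta, g00, g01, g11, zy0, zy1, yy, bp, w, n_occ, want_grad):
    """Profiled negative log-likelihood of the joint growth-outcome model.

    theta = (log l00, l10, log l11, l20, l21, log l22, log sigma_eh) for
    the 3x3 log-Cholesky of omega; the outcome row contributes through
    its scalar Schur complement s2_j = sigma_BP^2 - c'A_j c.
    """
    J = g00.shape[0]
    l00 = np.exp(theta[0]); l10 = theta[1]; l11 = np.exp(theta[2])
    l20 = theta[3]; l21 = theta[4]; l22 = np.exp(theta[5])
    s2 = np.exp(2.0 * theta[6])
    o00 = l00 * l00
    o01 = l00 * l10
    o11 = l10 * l10 + l11 * l11
    c0 = l00 * l20
    c1 = l10 * l20 + l11 * l21
    s2bp = l20 * l20 + l21 * l21 + l22 * l22
    odet = o00 * o11 - o01 * o01
    oi00 = o11 / odet; oi01 = -o01 / odet; oi11 = o00 / odet

    A00 = np.empty(J); A01 = np.empty(J); A11 = np.empty(J)
    T0 = np.empty(J); T1 = np.empty(J)
    Sp00 = np.empty(J); Sp01 = np.empty(J); Sp11 = np.empty(J)
    S2 = np.empty(J); YT = np.empty(J)
    # GLS accumulators over (beta0, beta1, beta2)
    N00 = 0.0; N01 = 0.0; N02 = 0.0; N11 = 0.0; N12 = 0.0; N22 = 0.0
    r0 = 0.0; r1 = 0.0; r2 = 0.0
    sum_logdet = 0.0
    sum_yVy = 0.0
    wsum = 0.0
    logs2 = np.log(s2)
    for j in range(J):
        wj = w[j]
        wsum += wj
        b00 = oi00 + g00[j] / s2
        b01 = oi01 + g01[j] / s2
        b11 = oi11 + g11[j] / s2
        bdet = b00 * b11 - b01 * b01
        sp00 = b11 / bdet; sp01 = -b01 / bdet; sp11 = b00 / bdet
        Sp00[j] = sp00; Sp01[j] = sp01; Sp11[j] = sp11
        gs00 = g00[j] * sp00 + g01[j] * sp01
        gs01 = g00[j] * sp01 + g01[j] * sp11
        gs10 = g01[j] * sp00 + g11[j] * sp01
        gs11 = g01[j] * sp01 + g11[j] * sp11
        a00 = (g00[j] - (gs00 * g00[j] + gs01 * g01[j]) / s2) / s2
        a01 = (g01[j] - (gs00 * g01[j] + gs01 * g11[j]) / s2) / s2
        a11 = (g11[j] - (gs10 * g01[j] + gs11 * g11[j]) / s2) / s2
        A00[j] = a00; A01[j] = a01; A11[j] = a11
        t0 = (zy0[j] - (gs00 * zy0[j] + gs01 * zy1[j]) / s2) / s2
        t1 = (zy1[j] - (gs10 * zy0[j] + gs11 * zy1[j]) / s2) / s2
        T0[j] = t0; T1[j] = t1
        m00 = 1.0 + (o00 * g00[j] + o01 * g01[j]) / s2
        m01 = (o00 * g01[j] + o01 * g11[j]) / s2
        m10 = (o01 * g00[j] + o11 * g01[j]) / s2
        m11 = 1.0 + (o01 * g01[j] + o11 * g11[j]) / s2
        detm = m00 * m11 - m01 * m10
        if detm <= 0.0:
            return np.inf, np.zeros(7), np.zeros(3), np.zeros((3, 3))
        sum_logdet += wj * (n_occ * logs2 + np.log(detm))
        spzy0 = sp00 * zy0[j] + sp01 * zy1[j]
        spzy1 = sp01 * zy0[j] + sp11 * zy1[j]
        sum_yVy += wj * (yy[j] / s2
                         - (zy0[j] * spzy0 + zy1[j] * spzy1) / (s2 * s2))
        # outcome row: Schur complement and working response
        ac0 = a00 * c0 + a01 * c1
        ac1 = a01 * c0 + a11 * c1
        s2j = s2bp - (c0 * ac0 + c1 * ac1)
        if s2j <= 0.0:
            return np.inf, np.zeros(7), np.zeros(3), np.zeros((3, 3))
        S2[j] = s2j
        yt = bp[j] - (t0 * c0 + t1 * c1)
        YT[j] = yt
        sum_logdet += wj * np.log(s2j)
        # xtil = (-ac0, -ac1, 1); accumulate X'V^-1X and X'V^-1y
        ws = wj / s2j
        N00 += wj * a00 + ws * ac0 * ac0
        N01 += wj * a01 + ws * ac0 * ac1
        N11 += wj * a11 + ws * ac1 * ac1
        N02 += -ws * ac0
        N12 += -ws * ac1
        N22 += ws
        r0 += wj * t0 - ws * yt * ac0
        r1 += wj * t1 - ws * yt * ac1
        r2 += ws * yt

    M = np.array([[N00, N01, N02], [N01, N11, N12], [N02, N12, N22]])
    rhs = np.array([r0, r1, r2])
    beta = np.linalg.solve(M, rhs)
    beta0 = beta[0]; beta1 = beta[1]; beta2 = beta[2]
    Q = sum_yVy
    for j in range(J):
        wj = w[j]
        ac0 = A00[j] * c0 + A01[j] * c1
        ac1 = A01[j] * c0 + A11[j] * c1
        m = YT[j] + ac0 * beta0 + ac1 * beta1 - beta2
        Q += wj * (-2.0 * (T0[j] * beta0 + T1[j] * beta1)
                   + beta0 * (A00[j] * beta0 + A01[j] * beta1)
                   + beta1 * (A01[j] * beta0 + A11[j] * beta1)
                   + m * m / S2[j])
    nll = 0.5 * (wsum * (n_occ + 1) * _LOG2PI + sum_logdet + Q)
    grad = np.zeros(7)
    if not want_grad:
        return nll, grad, beta, M

    # symmetric d loglik / d omega3 (S3) and d/d sig2
    S300 = 0.0; S301 = 0.0; S311 = 0.0
    S302 = 0.0; S312 = 0.0; S322 = 0.0
    dsig2 = 0.0
    for j in range(J):
        wj = w[j]
        a0 = T0[j] - (A00[j] * beta0 + A01[j] * beta1)
        a1 = T1[j] - (A01[j] * beta0 + A11[j] * beta1)
        ac0 = A00[j] * c0 + A01[j] * c1
        ac1 = A01[j] * c0 + A11[j] * c1
        m = YT[j] + ac0 * beta0 + ac1 * beta1 - beta2
        ms = m / S2[j]
        gt0 = a0 - ac0 * ms
        gt1 = a1 - ac1 * ms
        inv_s2j = 1.0 / S2[j]
        S300 += wj * (gt0 * gt0 - A00[j] - ac0 * ac0 * inv_s2j)
        S301 += wj * (gt0 * gt1 - A01[j] - ac0 * ac1 * inv_s2j)
        S311 += wj * (gt1 * gt1 - A11[j] - ac1 * ac1 * inv_s2j)
        S302 += wj * (gt0 * ms + ac0 * inv_s2j)
        S312 += wj * (gt1 * ms + ac1 * inv_s2j)
        S322 += wj * (ms * ms - inv_s2j)
        # sig2 derivative including the outcome row cross terms
        q0 = zy0[j] - (g00[j] * beta0 + g01[j] * beta1)
        q1 = zy1[j] - (g01[j] * beta0 + g11[j] * beta1)
        sq0 = Sp00[j] * q0 + Sp01[j] * q1
        sq1 = Sp01[j] * q0 + Sp11[j] * q1
        gsq0 = g00[j] * sq0 + g01[j] * sq1
        gsq1 = g01[j] * sq0 + g11[j] * sq1
        rr = (yy[j] - 2.0 * (zy0[j] * beta0 + zy1[j] * beta1)
              + beta0 * (g00[j] * beta0 + g01[j] * beta1)
              + beta1 * (g01[j] * beta0 + g11[j] * beta1))
        rP2r = (rr - 2.0 * (q0 * sq0 + q1 * sq1) / s2
                + (gsq0 * sq0 + gsq1 * sq1) / (s2 * s2)) / (s2 * s2)
        trSpG = Sp00[j] * g00[j] + 2.0 * Sp01[j] * g01[j] + Sp11[j] * g11[j]
        trP = (n_occ - trSpG / s2) / s2
        # Z'P^2 Z c and Z'P^2 r via GSp chains
        gs00 = g00[j] * Sp00[j] + g01[j] * Sp01[j]
        gs01 = g00[j] * Sp01[j] + g01[j] * Sp11[j]
        gs10 = g01[j] * Sp00[j] + g11[j] * Sp01[j]
        gs11 = g01[j] * Sp01[j] + g11[j] * Sp11[j]
        # K c where K = Z'P^2 Z: (Gc - 2 GSp Gc / s2 + GSp GSp Gc / s2^2)/s2^2
        gc0 = g00[j] * c0 + g01[j] * c1
        gc1 = g01[j] * c0 + g11[j] * c1
        gsgc0 = gs00 * gc0 + gs01 * gc1
        gsgc1 = gs10 * gc0 + gs11 * gc1
        gsgsgc0 = gs00 * gsgc0 + gs01 * gsgc1
        gsgsgc1 = gs10 * gsgc0 + gs11 * gsgc1
        kc0 = (gc0 - 2.0 * gsgc0 / s2 + gsgsgc0 / (s2 * s2)) / (s2 * s2)
        kc1 = (gc1 - 2.0 * gsgc1 / s2 + gsgsgc1 / (s2 * s2)) / (s2 * s2)
        cKc = c0 * kc0 + c1 * kc1
        gsgsq0 = gs00 * gsq0 + gs01 * gsq1
        gsgsq1 = gs10 * gsq0 + gs11 * gsq1
        zp2r0 = (q0 - 2.0 * gsq0 / s2 + gsgsq0 / (s2 * s2)) / (s2 * s2)
        zp2r1 = (q1 - 2.0 * gsq1 / s2 + gsgsq1 / (s2 * s2)) / (s2 * s2)
        cZP2r = c0 * zp2r0 + c1 * zp2r1
        norm_h = rP2r - 2.0 * ms * cZP2r + ms * ms * cKc
        tr_hh = trP + cKc * inv_s2j
        dsig2 += wj * (norm_h - tr_hh)
    S300 *= 0.5; S301 *= 0.5; S311 *= 0.5
    S302 *= 0.5; S312 *= 0.5; S322 *= 0.5
    dsig2 *= 0.5
    # dl/dL = 2 S L (L lower 3x3)
    dl00 = 2.0 * (S300 * l00 + S301 * l10 + S302 * l20)
    dl10 = 2.0 * (S301 * l00 + S311 * l10 + S312 * l20)
    dl11 = 2.0 * (S311 * l11 + S312 * l21)
    dl20 = 2.0 * (S302 * l00 + S312 * l10 + S322 * l20)
    dl21 = 2.0 * (S312 * l11 + S322 * l21)
    dl22 = 2.0 * (S322 * l22)
    grad[0] = -dl00 * l00
    grad[1] = -dl10
    grad[2] = -dl11 * l11
    grad[3] = -dl20
    grad[4] = -dl21
    grad[5] = -dl22 * l22
    grad[6] = -dsig2 * 2.0 * s2
    return nll, grad, beta, M
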