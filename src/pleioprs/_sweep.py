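"""Compiled inner loop of the blocked Gibbs sampler.

One call sweeps a single LD block: sequentially for each SNP it
computes the per-(class, component) collapsed marginals, samples the
assignment, redraws the bivariate effect from its conjugate conditional,
and updates the running residuals.  The kernel owns its RNG stream: the
caller passes one seed per (iteration, block), derived from the master
seed, so results are reproducible and blocks could in principle be swept
concurrently without changing the draw sequence.

All cross-SNP coupling enters through the residual vectors
``r_t = D A^{-1} beta_hat_t - H beta_t`` with ``H = D A^{-1} D``; the
SNP's own contribution is added back via the diagonal ``q_j = H_jj``
before its conditional is formed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_block_kernel(
    seed,
    H,        # (m, m) symmetric D A^{-1} D
    q,        # (m,) diagonal of H
    r1, r2,   # (m,) residuals, updated in place
    beta,     # (m, 2) effects, updated in place
    zc, zk,   # (m,) class / component labels, updated in place
    oi11, oi12, oi22,   # entries of Omega^{-1}
    lp0,      # scalar log p0
    lw1, lw2, lw3,      # (K,) log(p_c * pi_ck), -inf allowed
    s1sq, s2sq,         # (K,) trait-specific component variances
    S11, S12, S22,      # (K,) shared component covariances
):
    np.random.seed(seed)
    m = q.shape[0]
    K = lw1.shape[0]
    w1 = np.empty(K)
    w2 = np.empty(K)
    w3 = np.empty(K)

    for j in range(m):
        qj = q[j]
        v1 = r1[j] + qj * beta[j, 0]
        v2 = r2[j] + qj * beta[j, 1]
        b1 = oi11 * v1 + oi12 * v2
        b2 = oi12 * v1 + oi22 * v2
        P11 = qj * oi11
        P12 = qj * oi12
        P22 = qj * oi22

        mx = lp0
        for k in range(K):
            m1 = 1.0 + s1sq[k] * P11
            w1[k] = lw1[k] - 0.5 * np.log(m1) + 0.5 * b1 * b1 * s1sq[k] / m1
            m2 = 1.0 + s2sq[k] * P22
            w2[k] = lw2[k] - 0.5 * np.log(m2) + 0.5 * b2 * b2 * s2sq[k] / m2

            c11 = 1.0 + S11[k] * P11 + S12[k] * P12
            c12 = S11[k] * P12 + S12[k] * P22
            c21 = S12[k] * P11 + S22[k] * P12
            c22 = 1.0 + S12[k] * P12 + S22[k] * P22
            detC = c11 * c22 - c12 * c21
            g1 = S11[k] * b1 + S12[k] * b2
            g2 = S12[k] * b1 + S22[k] * b2
            x1 = (c22 * g1 - c12 * g2) / detC
            x2 = (-c21 * g1 + c11 * g2) / detC
            w3[k] = lw3[k] - 0.5 * np.log(detC) + 0.5 * (b1 * x1 + b2 * x2)

            if w1[k] > mx:
                mx = w1[k]
            if w2[k] > mx:
                mx = w2[k]
            if w3[k] > mx:
                mx = w3[k]

        total = np.exp(lp0 - mx)
        for k in range(K):
            total += np.exp(w1[k] - mx) + np.exp(w2[k] - mx) + np.exp(w3[k] - mx)

        u = np.random.random() * total
        cls = 3
        comp = K - 1
        acc = np.exp(lp0 - mx)
        if u < acc:
            cls = 0
            comp = 0
        else:
            done = False
            for k in range(K):
                acc += np.exp(w1[k] - mx)
                if u < acc:
                    cls = 1
                    comp = k
                    done = True
                    break
            if not done:
                for k in range(K):
                    acc += np.exp(w2[k] - mx)
                    if u < acc:
                        cls = 2
                        comp = k
                        done = True
                        break
            if not done:
                for k in range(K):
                    acc += np.exp(w3[k] - mx)
                    if u < acc:
                        cls = 3
                        comp = k
                        break

        # conjugate redraw of beta_j given the assignment
        if cls == 0:
            nb1 = 0.0
            nb2 = 0.0
        elif cls == 1:
            prec = P11 + 1.0 / s1sq[comp]
            nb1 = b1 / prec + np.random.normal() / np.sqrt(prec)
            nb2 = 0.0
        elif cls == 2:
            prec = P22 + 1.0 / s2sq[comp]
            nb1 = 0.0
            nb2 = b2 / prec + np.random.normal() / np.sqrt(prec)
        else:
            sdet = S11[comp] * S22[comp] - S12[comp] * S12[comp]
            si11 = S22[comp] / sdet
            si12 = -S12[comp] / sdet
            si22 = S11[comp] / sdet
            a11 = P11 + si11
            a12 = P12 + si12
            a22 = P22 + si22
            adet = a11 * a22 - a12 * a12
            cov11 = a22 / adet
            cov12 = -a12 / adet
            cov22 = a11 / adet
            mu1 = cov11 * b1 + cov12 * b2
            mu2 = cov12 * b1 + cov22 * b2
            l11 = np.sqrt(cov11)
            l21 = cov12 / l11
            t = cov22 - l21 * l21
            if t < 1e-300:
                t = 1e-300
            l22 = np.sqrt(t)
            g1 = np.random.normal()
            g2 = np.random.normal()
            nb1 = mu1 + l11 * g1
            nb2 = mu2 + l21 * g1 + l22 * g2

        d1 = nb1 - beta[j, 0]
        d2 = nb2 - beta[j, 1]
        if d1 != 0.0 or d2 != 0.0:
            Hj = H[j]
            for i in range(m):
                r1[i] -= Hj[i] * d1
                r2[i] -= Hj[i] * d2
        beta[j, 0] = nb1
        beta[j, 1] = nb2
        zc[j] = cls
        zk[j] = comp
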