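"""Numba inner loop of the collapsed Gibbs sampler.

The kernel mutates label and count arrays in place. Each token consumes
exactly one uniform variate (inverse-CDF draw over the flattened K×L
conditional table), so seeded runs are reproducible regardless of how the
surrounding code is vectorised.

Tokens whose pair count exceeds ``LOG_SLOT_THRESHOLD`` have their
conditional computed in log space to avoid underflow of long predictive
products; both paths implement the same ascending-factorial
Dirichlet-multinomial predictive.
"""

import numpy as np
from numba import njit

LOG_SLOT_THRESHOLD = 32  # pairs per token above which the log path is used


@njit(cache=True)
def sweep_kernel(
    order,
    uniforms,
    z,
    y,
    token_sample,
    sub_indptr,
    sub_comp,
    sub_rep,
    prod_indptr,
    prod_comp,
    prod_rep,
    count_nk,
    count_kl,
    count_k,
    dcount_lc,
    dcount_l,
    gcount_lc,
    gcount_l,
    a_th,
    a_ph,
    a_de,
    a_ga,
):
    K = count_kl.shape[0]
    L = count_kl.shape[1]
    C = dcount_lc.shape[1]
    f = np.empty(L, dtype=np.float64)
    w = np.empty((K, L), dtype=np.float64)

    for idx in range(order.shape[0]):
        t = order[idx]
        n = token_sample[t]
        k0 = z[t]
        l0 = y[t]
        s0 = sub_indptr[t]
        s1 = sub_indptr[t + 1]
        p0 = prod_indptr[t]
        p1 = prod_indptr[t + 1]

        # remove the token's entire contribution (exclude-self convention)
        count_nk[n, k0] -= 1
        count_kl[k0, l0] -= 1
        count_k[k0] -= 1
        for j in range(s0, s1):
            dcount_lc[l0, sub_comp[j]] -= 1
        dcount_l[l0] -= s1 - s0
        for j in range(p0, p1):
            gcount_lc[l0, prod_comp[j]] -= 1
        gcount_l[l0] -= p1 - p0
        if count_nk[n, k0] < 0 or count_kl[k0, l0] < 0 or dcount_l[l0] < 0 or gcount_l[l0] < 0:
            raise ValueError("negative count encountered: state is corrupt")

        use_log = (s1 - s0) > LOG_SLOT_THRESHOLD

        # per-subnetwork slot factor (independent of k)
        for l in range(L):
            if use_log:
                lf = 0.0
                for j in range(s0, s1):
                    lf += np.log(dcount_lc[l, sub_comp[j]] + a_de + sub_rep[j])
                    lf -= np.log(dcount_l[l] + C * a_de + (j - s0))
                for j in range(p0, p1):
                    lf += np.log(gcount_lc[l, prod_comp[j]] + a_ga + prod_rep[j])
                    lf -= np.log(gcount_l[l] + C * a_ga + (j - p0))
                f[l] = lf
            else:
                v = 1.0
                for j in range(s0, s1):
                    v *= (dcount_lc[l, sub_comp[j]] + a_de + sub_rep[j]) / (
                        dcount_l[l] + C * a_de + (j - s0)
                    )
                for j in range(p0, p1):
                    v *= (gcount_lc[l, prod_comp[j]] + a_ga + prod_rep[j]) / (
                        gcount_l[l] + C * a_ga + (j - p0)
                    )
                f[l] = v

        if use_log:
            mx = -1.0e308
            for k in range(K):
                lt = np.log(count_nk[n, k] + a_th)
                ld = np.log(count_k[k] + L * a_ph)
                for l in range(L):
                    v = lt + np.log(count_kl[k, l] + a_ph) - ld + f[l]
                    w[k, l] = v
                    if v > mx:
                        mx = v
            total = 0.0
            for k in range(K):
                for l in range(L):
                    w[k, l] = np.exp(w[k, l] - mx)
                    total += w[k, l]
        else:
            total = 0.0
            for k in range(K):
                tk = count_nk[n, k] + a_th
                denom = count_k[k] + L * a_ph
                for l in range(L):
                    v = tk * (count_kl[k, l] + a_ph) / denom * f[l]
                    w[k, l] = v
                    total += v

        # single inverse-CDF draw over the flattened table
        u = uniforms[idx] * total
        k1 = K - 1
        l1 = L - 1
        acc = 0.0
        done = False
        for k in range(K):
            for l in range(L):
                acc += w[k, l]
                if acc >= u:
                    k1 = k
                    l1 = l
                    done = True
                    break
            if done:
                break

        z[t] = k1
        y[t] = l1
        count_nk[n, k1] += 1
        count_kl[k1, l1] += 1
        count_k[k1] += 1
        for j in range(s0, s1):
            dcount_lc[l1, sub_comp[j]] += 1
        dcount_l[l1] += s1 - s0
        for j in range(p0, p1):
            gcount_lc[l1, prod_comp[j]] += 1
        gcount_l[l1] += p1 - p0
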