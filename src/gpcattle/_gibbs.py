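"""Single-site Gibbs kernels for the whole-genome regression samplers.

Compiled with numba; the samplers walk markers in fixed ascending order and
maintain the residual vector r = y - Xb - Z alpha, so one marker update is
two length-n passes.  All randomness comes from numba's np.random state,
seeded once per kernel call, which makes runs bit-reproducible.

Model codes: 0 = per-marker variances (BayesA), 1 = spike + per-marker
variances with fixed pi (BayesB), 2 = spike + common variance with sampled
pi (BayesC-pi).  BayesR has its own kernel.
"""

import numpy as np
from numba import njit

MODEL_A, MODEL_B, MODEL_CPI = 0, 1, 2


@njit(cache=True)
def _draw_scaled_inv_chi2(df, scale):
    # scaled-inverse-chi2(df, scale): df*scale / chi2_df
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _update_fixed(XT, xx, b, r, sigma_e2):
    p = XT.shape[0]
    for c in range(p):
        if xx[c] <= 0.0:
            continue
        rhs = np.dot(XT[c], r) + xx[c] * b[c]
        mean = rhs / xx[c]
        bn = mean + np.random.normal() * np.sqrt(sigma_e2 / xx[c])
        diff = b[c] - bn
        for i in range(XT.shape[1]):
            r[i] += XT[c, i] * diff
        b[c] = bn


@njit(cache=True)
def bayes_abc_kernel(y, XT, ZT, n_iter, burn_in, thin, seed, model,
                     pi_init, pi_is_fixed, v_df, sa2,
                     fix_sigma_e2, fix_marker_var):
    """Gibbs for BayesA / BayesB / BayesC-pi.

    ``fix_sigma_e2`` / ``fix_marker_var`` <= 0 mean "sample it"; positive
    values pin the corresponding variance (conjugate-test hooks).
    """
    np.random.seed(seed)
    m, n = ZT.shape
    p = XT.shape[0]

    xx = np.empty(p)
    for c in range(p):
        xx[c] = np.dot(XT[c], XT[c])
    zz = np.empty(m)
    for j in range(m):
        zz[j] = np.dot(ZT[j], ZT[j])

    b = np.zeros(p)
    alpha = np.zeros(m)
    r = y.copy()

    prior_var = sa2 * v_df / max(v_df - 2.0, 1e-3)
    sj2 = np.full(m, prior_var)          # per-marker variances (A, B)
    s_common = prior_var                 # common variance (C-pi)
    if fix_marker_var > 0.0:
        sj2[:] = fix_marker_var
        s_common = fix_marker_var
    sigma_e2 = np.var(y) / 2.0 if fix_sigma_e2 <= 0.0 else fix_sigma_e2
    pi = pi_init

    n_kept = n_iter - burn_in
    n_tr = (n_kept + thin - 1) // thin
    tr_se2 = np.zeros(n_tr)
    tr_pi = np.zeros(n_tr)
    tr_gv = np.zeros(n_tr)
    alpha_sum = np.zeros(m)
    b_sum = np.zeros(p)
    incl_sum = np.zeros(m)
    pi_sum = 0.0
    se2_sum = 0.0
    gv_sum = 0.0

    for it in range(n_iter):
        _update_fixed(XT, xx, b, r, sigma_e2)

        m1 = 0
        ss_incl = 0.0
        for j in range(m):
            if zz[j] <= 0.0:
                continue
            rhs = np.dot(ZT[j], r) + zz[j] * alpha[j]
            var_j = sj2[j] if model != MODEL_CPI else s_common

            include = True
            if model != MODEL_A and pi > 0.0:
                if pi >= 1.0:
                    include = False
                else:
                    v0 = sigma_e2 * zz[j]
                    v1 = v0 + zz[j] * zz[j] * var_j
                    log_bf = 0.5 * (np.log(v0) - np.log(v1)) \
                        + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
                    log_odds = np.log((1.0 - pi) / pi) + log_bf
                    if log_odds > 35.0:
                        include = True
                    elif log_odds < -35.0:
                        include = False
                    else:
                        include = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))

            if include:
                C = zz[j] + sigma_e2 / var_j
                mean = rhs / C
                an = mean + np.random.normal() * np.sqrt(sigma_e2 / C)
                m1 += 1
                ss_incl += an * an
                incl_ind = 1.0
            else:
                an = 0.0
                incl_ind = 0.0

            diff = alpha[j] - an
            if diff != 0.0:
                for i in range(n):
                    r[i] += ZT[j, i] * diff
            alpha[j] = an

            if fix_marker_var <= 0.0 and model != MODEL_CPI:
                if include:
                    sj2[j] = _draw_scaled_inv_chi2(
                        v_df + 1.0, (v_df * sa2 + an * an) / (v_df + 1.0))
                elif model == MODEL_B:
                    sj2[j] = _draw_scaled_inv_chi2(v_df, sa2)

            if it >= burn_in:
                incl_sum[j] += incl_ind

        if model == MODEL_CPI:
            if fix_marker_var <= 0.0:
                s_common = _draw_scaled_inv_chi2(
                    v_df + m1, (v_df * sa2 + ss_incl) / (v_df + m1))
            if not pi_is_fixed:
                pi = np.random.beta(m - m1 + 1.0, m1 + 1.0)

        if fix_sigma_e2 <= 0.0:
            rss = np.dot(r, r)
            sigma_e2 = rss / np.random.chisquare(n - 2.0)

        if it >= burn_in:
            alpha_sum += alpha
            b_sum += b
            pi_sum += pi
            se2_sum += sigma_e2
            xb = np.dot(b, XT)
            gv = 0.0
            mu = 0.0
            for i in range(n):
                mu += y[i] - r[i] - xb[i]
            mu /= n
            for i in range(n):
                gi = y[i] - r[i] - xb[i]
                gv += (gi - mu) ** 2
            gv /= n
            gv_sum += gv
            k = it - burn_in
            if k % thin == 0:
                tr_se2[k // thin] = sigma_e2
                tr_pi[k // thin] = pi
                tr_gv[k // thin] = gv

    return (alpha_sum / n_kept, b_sum / n_kept, incl_sum / n_kept,
            pi_sum / n_kept, se2_sum / n_kept, gv_sum / n_kept,
            tr_se2, tr_pi, tr_gv)


@njit(cache=True)
def bayes_r_kernel(y, XT, ZT, n_iter, burn_in, thin, seed, var_fracs,
                   sigma_g2_init, update_sigma_g2, fix_sigma_e2):
    """Gibbs for the four-component mixture model.

    ``var_fracs`` are the relative component variances (0, 1e-4, 1e-3,
    1e-2); component variances are var_fracs * sigma_g2.  Labels are
    sampled with the effect integrated out; mixture proportions get a
    Dirichlet(counts + 1) update (pseudo-counts of 1).
    """
    np.random.seed(seed)
    m, n = ZT.shape
    p = XT.shape[0]
    K = len(var_fracs)

    xx = np.empty(p)
    for c in range(p):
        xx[c] = np.dot(XT[c], XT[c])
    zz = np.empty(m)
    for j in range(m):
        zz[j] = np.dot(ZT[j], ZT[j])

    b = np.zeros(p)
    alpha = np.zeros(m)
    labels = np.zeros(m, dtype=np.int64)
    r = y.copy()
    props = np.full(K, 1.0 / K)
    sigma_g2 = sigma_g2_init
    sigma_e2 = np.var(y) / 2.0 if fix_sigma_e2 <= 0.0 else fix_sigma_e2

    n_kept = n_iter - burn_in
    n_tr = (n_kept + thin - 1) // thin
    tr_se2 = np.zeros(n_tr)
    tr_gv = np.zeros(n_tr)
    tr_sg2 = np.zeros(n_tr)
    alpha_sum = np.zeros(m)
    b_sum = np.zeros(p)
    comp_sum = np.zeros((m, K))
    props_sum = np.zeros(K)
    se2_sum = 0.0
    gv_sum = 0.0

    logw = np.empty(K)
    counts = np.empty(K)

    for it in range(n_iter):
        _update_fixed(XT, xx, b, r, sigma_e2)

        counts[:] = 0.0
        for j in range(m):
            if zz[j] <= 0.0:
                counts[0] += 1.0
                continue
            rhs = np.dot(ZT[j], r) + zz[j] * alpha[j]
            for k in range(K):
                vk = sigma_e2 * zz[j] + zz[j] * zz[j] * var_fracs[k] * sigma_g2
                logw[k] = np.log(props[k]) - 0.5 * np.log(vk) \
                    - 0.5 * rhs * rhs / vk
            mx = logw[0]
            for k in range(1, K):
                if logw[k] > mx:
                    mx = logw[k]
            tot = 0.0
            for k in range(K):
                logw[k] = np.exp(logw[k] - mx)
                tot += logw[k]
            u = np.random.random() * tot
            acc = 0.0
            kj = K - 1
            for k in range(K):
                acc += logw[k]
                if u <= acc:
                    kj = k
                    break
            labels[j] = kj

            vark = var_fracs[kj] * sigma_g2
            if vark > 0.0:
                C = zz[j] + sigma_e2 / vark
                an = rhs / C + np.random.normal() * np.sqrt(sigma_e2 / C)
            else:
                an = 0.0
            diff = alpha[j] - an
            if diff != 0.0:
                for i in range(n):
                    r[i] += ZT[j, i] * diff
            alpha[j] = an
            counts[kj] += 1.0

        # Dirichlet(counts + 1) via normalized gammas
        tot = 0.0
        for k in range(K):
            props[k] = np.random.gamma(counts[k] + 1.0, 1.0)
            tot += props[k]
        for k in range(K):
            props[k] /= tot

        if update_sigma_g2:
            ss = 0.0
            m_nz = 0
            for j in range(m):
                if var_fracs[labels[j]] > 0.0:
                    ss += alpha[j] * alpha[j] / var_fracs[labels[j]]
                    m_nz += 1
            if m_nz > 2:
                sigma_g2 = ss / np.random.chisquare(m_nz - 2.0)

        if fix_sigma_e2 <= 0.0:
            sigma_e2 = np.dot(r, r) / np.random.chisquare(n - 2.0)

        if it >= burn_in:
            alpha_sum += alpha
            b_sum += b
            for j in range(m):
                comp_sum[j, labels[j]] += 1.0
            props_sum += props
            se2_sum += sigma_e2
            xb = np.dot(b, XT)
            gv = 0.0
            mu = 0.0
            for i in range(n):
                mu += y[i] - r[i] - xb[i]
            mu /= n
            for i in range(n):
                gi = y[i] - r[i] - xb[i]
                gv += (gi - mu) ** 2
            gv /= n
            gv_sum += gv
            k = it - burn_in
            if k % thin == 0:
                tr_se2[k // thin] = sigma_e2
                tr_gv[k // thin] = gv
                tr_sg2[k // thin] = sigma_g2

    return (alpha_sum / n_kept, b_sum / n_kept, comp_sum / n_kept,
            props_sum / n_kept, se2_sum / n_kept, gv_sum / n_kept,
            tr_se2, tr_gv, tr_sg2)
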