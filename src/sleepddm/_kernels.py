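"""Numba kernels: WFPT density, Euler passage sampler, and the Gibbs sweep.

All functions assume unit diffusion coefficient. The first-passage density
follows the classic dual-series evaluation (small-time vs large-time
expansion, switched by a truncation-error criterion) for the density of
absorption at the *lower* boundary of a Wiener process with drift ``v``,
boundary separation ``a`` and relative start point ``w``.
"""

import numpy as np
from numba import njit

SQRT_2PI = np.sqrt(2.0 * np.pi)
LOG_ZERO = -1e300  # sentinel for log(0) that survives arithmetic


@njit(cache=True)
def wfpt_density_lower(tdec, v, a, w, err):
    """Density of hitting the lower boundary at decision time ``tdec``.

    ``tdec`` is time after the non-decision component; returns 0 for
    ``tdec <= 0``. ``err`` bounds the series truncation error.
    """
    if tdec <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return 0.0
    tt = tdec / (a * a)  # normalized time

    # number of terms needed by each expansion
    if np.pi * tt * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * err) / (np.pi * np.pi * tt))
        if kl < 1.0 / (np.pi * np.sqrt(tt)):
            kl = 1.0 / (np.pi * np.sqrt(tt))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tt))
    if 2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * np.sqrt(2.0 * np.pi * tt) * err))
        if ks < np.sqrt(tt) + 1.0:
            ks = np.sqrt(tt) + 1.0
    else:
        ks = 2.0

    if ks < kl:  # small-time expansion
        K = int(np.ceil(ks))
        p = 0.0
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1):
            arg = w + 2.0 * k
            p += arg * np.exp(-arg * arg / (2.0 * tt))
        p /= np.sqrt(2.0 * np.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(np.ceil(kl))
        p = 0.0
        for k in range(1, K + 1):
            p += k * np.exp(-k * k * np.pi * np.pi * tt / 2.0) * np.sin(k * np.pi * w)
        p *= np.pi

    if p < 0.0:
        p = 0.0
    # undo normalization and add the drift term
    return p * np.exp(-v * a * w - v * v * tdec / 2.0) / (a * a)


@njit(cache=True)
def wfpt_log_density(rt, upper, v, a, t0, z, err):
    """Log first-passage density of one observed trial.

    ``upper`` selects the absorbing boundary (1 = upper, 0 = lower).
    Invalid implied parameters or ``rt <= t0`` yield the log-zero sentinel.
    """
    if a <= 0.0 or t0 < 0.0 or z <= 0.0 or z >= 1.0:
        return LOG_ZERO
    tdec = rt - t0
    if tdec <= 0.0:
        return LOG_ZERO
    if upper:
        d = wfpt_density_lower(tdec, -v, a, 1.0 - z, err)
    else:
        d = wfpt_density_lower(tdec, v, a, z, err)
    if d <= 0.0:
        return LOG_ZERO
    return np.log(d)


@njit(cache=True)
def upper_probability(v, a, z):
    """Probability of absorption at the upper boundary (closed form)."""
    if abs(v) < 1e-12:
        return z
    x = -2.0 * v * a
    # guard overflow for large |v * a|
    if x > 700.0:
        return 0.0 if z < 1.0 else 1.0
    num = 1.0 - np.exp(x * z)
    den = 1.0 - np.exp(x)
    return num / den


@njit(cache=True)
def euler_passage(v, a, z, dt, horizon):
    """Simulate one first passage by Euler-Maruyama; returns (upper, tdec).

    ``upper`` is 1/0 for the absorbing boundary, -1 if the horizon was hit
    (the caller flags/truncates such trials).
    """
    x = z * a
    t = 0.0
    sq = np.sqrt(dt)
    while t < horizon:
        x += v * dt + sq * np.random.normal()
        t += dt
        if x >= a:
            return 1, t
        if x <= 0.0:
            return 0, t
    return -1, horizon


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def euler_passage_many(n, v, a, z, dt, horizon):
    ups = np.empty(n, dtype=np.int64)
    ts = np.empty(n)
    for i in range(n):
        u, t = euler_passage(v, a, z, dt, horizon)
        ups[i] = u
        ts[i] = t
    return ups, ts


# ---------------------------------------------------------------------------
# Hierarchical DDM regression sampler (adaptive Metropolis-within-Gibbs)
# ---------------------------------------------------------------------------
#
# Parameter layout per subject: beta[j, 0:P] concatenates the v, a and t
# regression coefficients (column index sets are passed in), plus z[j].
# Group level: mu[P], sigma[P], mu_z, sigma_z. Priors: mu_k ~ N(pm[k], ps[k]),
# sigma_k ~ HalfNormal(hs[k]); z_j ~ TruncNormal(mu_z, sigma_z, lo, hi),
# mu_z ~ N(0.5, 0.25) truncated to (lo, hi), sigma_z ~ HalfNormal(0.1).


@njit(cache=True)
def _subject_loglik(rt, up, lv, la, lt, z, err):
    total = 0.0
    for i in range(rt.shape[0]):
        ll = wfpt_log_density(rt[i], up[i], lv[i], la[i], lt[i], z, err)
        if ll <= LOG_ZERO:
            return LOG_ZERO
        total += ll
    return total


@njit(cache=True)
def _halfnormal_logpdf(x, s):
    if x <= 0.0:
        return LOG_ZERO
    return -x * x / (2.0 * s * s)


@njit(cache=True)
def hddm_gibbs_chain(
    rt, up, X, subj_start, subj_end,
    fam, col,                      # per concatenated coefficient: family id (0=v,1=a,2=t) and design column
    prior_mu_loc, prior_mu_scale, prior_sigma_scale,
    z_lo, z_hi,
    n_sweeps, burn_in, thin_subject,
    seed, err,
):
    """One MCMC chain; returns group draws, deviance trace, subject draws.

    Group node order in the returned array: mu[0:P], sigma[0:P], mu_z, sigma_z.
    """
    np.random.seed(seed)
    n_subj = subj_start.shape[0]
    P = fam.shape[0]

    # state
    beta = np.zeros((n_subj, P))
    mu = prior_mu_loc.copy()
    sigma = np.empty(P)
    for k in range(P):
        sigma[k] = 0.5 * prior_sigma_scale[k] + 0.05
    # modest starting values keep the likelihood finite: positive threshold,
    # small non-decision time, mid start point
    for k in range(P):
        if fam[k] == 1 and col_is_intercept(col, k):
            mu[k] = 1.5
        if fam[k] == 2 and col_is_intercept(col, k):
            mu[k] = 0.1
    for j in range(n_subj):
        for k in range(P):
            beta[j, k] = mu[k]
    z = np.full(n_subj, 0.5)
    mu_z = 0.5
    sigma_z = 0.05

    # cached linear predictors per trial
    n_trials = rt.shape[0]
    lv = np.zeros(n_trials)
    la = np.zeros(n_trials)
    lt = np.zeros(n_trials)
    for j in range(n_subj):
        for i in range(subj_start[j], subj_end[j]):
            for k in range(P):
                xb = X[i, col[k]] * beta[j, k]
                if fam[k] == 0:
                    lv[i] += xb
                elif fam[k] == 1:
                    la[i] += xb
                else:
                    lt[i] += xb

    subj_ll = np.empty(n_subj)
    for j in range(n_subj):
        s, e = subj_start[j], subj_end[j]
        subj_ll[j] = _subject_loglik(rt[s:e], up[s:e], lv[s:e], la[s:e], lt[s:e], z[j], err)

    # rescue invalid initial states by shrinking t and growing a
    for j in range(n_subj):
        tries = 0
        while subj_ll[j] <= LOG_ZERO and tries < 50:
            for k in range(P):
                if fam[k] == 2:
                    beta[j, k] *= 0.5
                if fam[k] == 1 and col_is_intercept(col, k):
                    beta[j, k] += 0.2
            s, e = subj_start[j], subj_end[j]
            for i in range(s, e):
                la[i] = 0.0
                lt[i] = 0.0
                for k in range(P):
                    if fam[k] == 1:
                        la[i] += X[i, col[k]] * beta[j, k]
                    elif fam[k] == 2:
                        lt[i] += X[i, col[k]] * beta[j, k]
            subj_ll[j] = _subject_loglik(rt[s:e], up[s:e], lv[s:e], la[s:e], lt[s:e], z[j], err)
            tries += 1

    # proposal scales + acceptance bookkeeping
    step_beta = np.full((n_subj, P), 0.15)
    step_z = np.full(n_subj, 0.05)
    step_logsig = np.full(P, 0.3)
    step_sigz = 0.3
    acc_beta = np.zeros((n_subj, P))
    try_beta = np.zeros((n_subj, P))
    acc_z = np.zeros(n_subj)
    try_z = np.zeros(n_subj)
    acc_ls = np.zeros(P)
    try_ls = np.zeros(P)
    step_shift = np.full(P, 0.1)
    acc_shift = np.zeros(P)
    try_shift = np.zeros(P)
    new_ll_all = np.empty(n_subj)

    # per-subject adaptive-covariance block proposals (Haario-style):
    # learn the joint covariance of (beta_j, z_j) during burn-in and propose
    # along it, so chains traverse the v/a/t trade-off ridges that
    # coordinate-wise updates cross only by diffusion
    d_blk = P + 1
    blk_mean = np.zeros((n_subj, d_blk))
    blk_outer = np.zeros((n_subj, d_blk, d_blk))
    blk_n = 0
    blk_chol = np.zeros((n_subj, d_blk, d_blk))
    have_chol = False
    blk_lam = np.full(n_subj, 1.0)
    acc_blk = np.zeros(n_subj)
    try_blk = np.zeros(n_subj)
    wv = np.empty(n_trials)
    wa = np.empty(n_trials)
    wt = np.empty(n_trials)
    xprop = np.empty(d_blk)

    n_keep = n_sweeps - burn_in
    n_group = 2 * P + 2
    group_draws = np.empty((n_keep, n_group))
    deviance = np.empty(n_keep)
    n_sub_keep = (n_keep + thin_subject - 1) // thin_subject
    subject_draws = np.empty((n_sub_keep, n_subj, P + 1))
    kept_sub = 0
    total_acc = 0.0
    total_try = 0.0

    work = np.empty(n_trials)  # scratch for proposed predictors

    for sweep in range(n_sweeps):
        # --- subject-level coefficients ---
        for j in range(n_subj):
            s, e = subj_start[j], subj_end[j]
            for k in range(P):
                old = beta[j, k]
                prop = old + step_beta[j, k] * np.random.normal()
                delta = prop - old
                c = col[k]
                f = fam[k]
                # proposed predictor for this family only
                if f == 0:
                    for i in range(s, e):
                        work[i] = lv[i] + X[i, c] * delta
                    new_ll = _subject_loglik(rt[s:e], up[s:e], work[s:e], la[s:e], lt[s:e], z[j], err)
                elif f == 1:
                    for i in range(s, e):
                        work[i] = la[i] + X[i, c] * delta
                    new_ll = _subject_loglik(rt[s:e], up[s:e], lv[s:e], work[s:e], lt[s:e], z[j], err)
                else:
                    for i in range(s, e):
                        work[i] = lt[i] + X[i, c] * delta
                    new_ll = _subject_loglik(rt[s:e], up[s:e], lv[s:e], la[s:e], work[s:e], z[j], err)
                lp_old = -(old - mu[k]) ** 2 / (2.0 * sigma[k] * sigma[k])
                lp_new = -(prop - mu[k]) ** 2 / (2.0 * sigma[k] * sigma[k])
                log_ratio = new_ll + lp_new - subj_ll[j] - lp_old
                try_beta[j, k] += 1.0
                if np.log(np.random.random()) < log_ratio:
                    beta[j, k] = prop
                    subj_ll[j] = new_ll
                    if f == 0:
                        for i in range(s, e):
                            lv[i] = work[i]
                    elif f == 1:
                        for i in range(s, e):
                            la[i] = work[i]
                    else:
                        for i in range(s, e):
                            lt[i] = work[i]
                    acc_beta[j, k] += 1.0

            # --- subject start point ---
            old = z[j]
            prop = old + step_z[j] * np.random.normal()
            try_z[j] += 1.0
            if z_lo < prop < z_hi:
                new_ll = _subject_loglik(rt[s:e], up[s:e], lv[s:e], la[s:e], lt[s:e], prop, err)
                lp_old = -(old - mu_z) ** 2 / (2.0 * sigma_z * sigma_z)
                lp_new = -(prop - mu_z) ** 2 / (2.0 * sigma_z * sigma_z)
                if np.log(np.random.random()) < new_ll + lp_new - subj_ll[j] - lp_old:
                    z[j] = prop
                    subj_ll[j] = new_ll
                    acc_z[j] += 1.0

            # --- joint block proposal along the learned covariance ---
            if have_chol:
                for _rep in range(4):
                    for kk in range(d_blk):
                        xprop[kk] = np.random.normal()
                    # alternate full-scale and fine-scale proposals; the
                    # fine scale keeps acceptance alive in the weakly
                    # identified low-drift cells
                    scale = blk_lam[j] * 2.38 / np.sqrt(d_blk)
                    if _rep >= 2:
                        scale *= 0.3
                    dx = scale * (blk_chol[j] @ xprop)
                    z_new = z[j] + dx[P]
                    try_blk[j] += 1.0
                    if not (z_lo < z_new < z_hi):
                        continue
                    for i in range(s, e):
                        wv[i] = lv[i]
                        wa[i] = la[i]
                        wt[i] = lt[i]
                    lp_old = -(z[j] - mu_z) ** 2 / (2.0 * sigma_z * sigma_z)
                    lp_new = -(z_new - mu_z) ** 2 / (2.0 * sigma_z * sigma_z)
                    for k in range(P):
                        c = col[k]
                        f = fam[k]
                        for i in range(s, e):
                            if f == 0:
                                wv[i] += X[i, c] * dx[k]
                            elif f == 1:
                                wa[i] += X[i, c] * dx[k]
                            else:
                                wt[i] += X[i, c] * dx[k]
                        old_b = beta[j, k]
                        new_b = old_b + dx[k]
                        lp_old += -(old_b - mu[k]) ** 2 / (2.0 * sigma[k] * sigma[k])
                        lp_new += -(new_b - mu[k]) ** 2 / (2.0 * sigma[k] * sigma[k])
                    new_ll = _subject_loglik(rt[s:e], up[s:e], wv[s:e], wa[s:e], wt[s:e], z_new, err)
                    if np.log(np.random.random()) < new_ll + lp_new - subj_ll[j] - lp_old:
                        for k in range(P):
                            beta[j, k] += dx[k]
                        z[j] = z_new
                        subj_ll[j] = new_ll
                        for i in range(s, e):
                            lv[i] = wv[i]
                            la[i] = wa[i]
                            lt[i] = wt[i]
                        acc_blk[j] += 1.0

        # accumulate subject-state statistics for the block covariance
        if sweep >= 50:
            for j in range(n_subj):
                for k in range(P):
                    blk_mean[j, k] += beta[j, k]
                blk_mean[j, P] += z[j]
                for k1 in range(d_blk):
                    x1 = beta[j, k1] if k1 < P else z[j]
                    for k2 in range(k1, d_blk):
                        x2 = beta[j, k2] if k2 < P else z[j]
                        blk_outer[j, k1, k2] += x1 * x2
            blk_n += 1
        if blk_n >= 100 and (sweep + 1) % 100 == 0 and sweep < burn_in:
            for j in range(n_subj):
                cov = np.empty((d_blk, d_blk))
                for k1 in range(d_blk):
                    m1 = blk_mean[j, k1] / blk_n
                    for k2 in range(k1, d_blk):
                        m2 = blk_mean[j, k2] / blk_n
                        cv = blk_outer[j, k1, k2] / blk_n - m1 * m2
                        cov[k1, k2] = cv
                        cov[k2, k1] = cv
                for k1 in range(d_blk):
                    cov[k1, k1] += 1e-8 + 1e-4 * cov[k1, k1]
                blk_chol[j] = np.linalg.cholesky(cov)
            have_chol = True

        # --- group means: conjugate normal update ---
        for k in range(P):
            sb = 0.0
            for j in range(n_subj):
                sb += beta[j, k]
            prec = n_subj / (sigma[k] * sigma[k]) + 1.0 / (prior_mu_scale[k] ** 2)
            mean = (sb / (sigma[k] * sigma[k]) + prior_mu_loc[k] / (prior_mu_scale[k] ** 2)) / prec
            mu[k] = mean + np.random.normal() / np.sqrt(prec)

        # --- joint shift moves: translate (mu_k, beta[:, k]) together ---
        # cures the slow random-walk drift of the common level in the
        # centered hierarchy when per-subject data are weak
        for k in range(P):
            delta = step_shift[k] * np.random.normal()
            c = col[k]
            f = fam[k]
            dll = 0.0
            ok = True
            for j in range(n_subj):
                s, e = subj_start[j], subj_end[j]
                if f == 0:
                    for i in range(s, e):
                        work[i] = lv[i] + X[i, c] * delta
                    nl = _subject_loglik(rt[s:e], up[s:e], work[s:e], la[s:e], lt[s:e], z[j], err)
                elif f == 1:
                    for i in range(s, e):
                        work[i] = la[i] + X[i, c] * delta
                    nl = _subject_loglik(rt[s:e], up[s:e], lv[s:e], work[s:e], lt[s:e], z[j], err)
                else:
                    for i in range(s, e):
                        work[i] = lt[i] + X[i, c] * delta
                    nl = _subject_loglik(rt[s:e], up[s:e], lv[s:e], la[s:e], work[s:e], z[j], err)
                if nl <= LOG_ZERO:
                    ok = False
                    break
                new_ll_all[j] = nl
                dll += nl - subj_ll[j]
            try_shift[k] += 1.0
            if ok:
                old_mu = mu[k]
                new_mu = old_mu + delta
                dll += ((old_mu - prior_mu_loc[k]) ** 2 - (new_mu - prior_mu_loc[k]) ** 2) / (
                    2.0 * prior_mu_scale[k] ** 2)
                if np.log(np.random.random()) < dll:
                    mu[k] = new_mu
                    for j in range(n_subj):
                        beta[j, k] += delta
                        subj_ll[j] = new_ll_all[j]
                        s, e = subj_start[j], subj_end[j]
                        if f == 0:
                            for i in range(s, e):
                                lv[i] += X[i, c] * delta
                        elif f == 1:
                            for i in range(s, e):
                                la[i] += X[i, c] * delta
                        else:
                            for i in range(s, e):
                                lt[i] += X[i, c] * delta
                    acc_shift[k] += 1.0

        # --- group spreads: MH on log scale, half-normal prior ---
        for k in range(P):
            old = sigma[k]
            prop = old * np.exp(step_logsig[k] * np.random.normal())
            ll_old = 0.0
            ll_new = 0.0
            for j in range(n_subj):
                d = beta[j, k] - mu[k]
                ll_old += -d * d / (2.0 * old * old)
                ll_new += -d * d / (2.0 * prop * prop)
            ll_old += -n_subj * np.log(old)
            ll_new += -n_subj * np.log(prop)
            lr = (ll_new + _halfnormal_logpdf(prop, prior_sigma_scale[k]) + np.log(prop)
                  - ll_old - _halfnormal_logpdf(old, prior_sigma_scale[k]) - np.log(old))
            try_ls[k] += 1.0
            if np.log(np.random.random()) < lr:
                sigma[k] = prop
                acc_ls[k] += 1.0

        # --- start-point hyperparameters ---
        old = mu_z
        prop = old + 0.05 * np.random.normal()
        if z_lo < prop < z_hi:
            ll_old = 0.0
            ll_new = 0.0
            for j in range(n_subj):
                ll_old += -(z[j] - old) ** 2 / (2.0 * sigma_z * sigma_z)
                ll_new += -(z[j] - prop) ** 2 / (2.0 * sigma_z * sigma_z)
            ll_old += -(old - 0.5) ** 2 / (2.0 * 0.25 * 0.25)
            ll_new += -(prop - 0.5) ** 2 / (2.0 * 0.25 * 0.25)
            if np.log(np.random.random()) < ll_new - ll_old:
                mu_z = prop
        old = sigma_z
        prop = old * np.exp(step_sigz * np.random.normal())
        ll_old = -n_subj * np.log(old)
        ll_new = -n_subj * np.log(prop)
        for j in range(n_subj):
            d = z[j] - mu_z
            ll_old += -d * d / (2.0 * old * old)
            ll_new += -d * d / (2.0 * prop * prop)
        lr = (ll_new + _halfnormal_logpdf(prop, 0.1) + np.log(prop)
              - ll_old - _halfnormal_logpdf(old, 0.1) - np.log(old))
        if np.log(np.random.random()) < lr:
            sigma_z = prop

        # --- adaptation during burn-in ---
        if sweep < burn_in and (sweep + 1) % 50 == 0:
            for j in range(n_subj):
                for k in range(P):
                    if try_beta[j, k] > 0:
                        r = acc_beta[j, k] / try_beta[j, k]
                        step_beta[j, k] *= np.exp(1.5 * (r - 0.44) * min(1.0, 50.0 / (sweep + 1.0)))
                        if step_beta[j, k] < 1e-4:
                            step_beta[j, k] = 1e-4
                if try_z[j] > 0:
                    r = acc_z[j] / try_z[j]
                    step_z[j] *= np.exp(1.5 * (r - 0.44) * min(1.0, 50.0 / (sweep + 1.0)))
                    if step_z[j] < 1e-4:
                        step_z[j] = 1e-4
                if try_blk[j] > 0:
                    r = acc_blk[j] / try_blk[j]
                    blk_lam[j] *= np.exp(1.5 * (r - 0.23) * min(1.0, 50.0 / (sweep + 1.0)))
                    if blk_lam[j] < 1e-3:
                        blk_lam[j] = 1e-3
                acc_blk[j] = 0.0
                try_blk[j] = 0.0
            for k in range(P):
                if try_ls[k] > 0:
                    r = acc_ls[k] / try_ls[k]
                    step_logsig[k] *= np.exp(1.5 * (r - 0.44) * min(1.0, 50.0 / (sweep + 1.0)))
                if try_shift[k] > 0:
                    r = acc_shift[k] / try_shift[k]
                    step_shift[k] *= np.exp(1.5 * (r - 0.25) * min(1.0, 50.0 / (sweep + 1.0)))
                    if step_shift[k] < 1e-4:
                        step_shift[k] = 1e-4
            acc_beta[:] = 0.0
            try_beta[:] = 0.0
            acc_z[:] = 0.0
            try_z[:] = 0.0
            acc_ls[:] = 0.0
            try_ls[:] = 0.0
            acc_shift[:] = 0.0
            try_shift[:] = 0.0

        # --- record ---
        if sweep >= burn_in:
            idx = sweep - burn_in
            for k in range(P):
                group_draws[idx, k] = mu[k]
                group_draws[idx, P + k] = sigma[k]
            group_draws[idx, 2 * P] = mu_z
            group_draws[idx, 2 * P + 1] = sigma_z
            dev = 0.0
            for j in range(n_subj):
                dev += subj_ll[j]
            deviance[idx] = -2.0 * dev
            if idx % thin_subject == 0:
                for j in range(n_subj):
                    for k in range(P):
                        subject_draws[kept_sub, j, k] = beta[j, k]
                    subject_draws[kept_sub, j, P] = z[j]
                kept_sub += 1

    for j in range(n_subj):
        for k in range(P):
            total_acc += acc_beta[j, k]
            total_try += try_beta[j, k]
    accept_rate = total_acc / total_try if total_try > 0 else 0.0
    return group_draws, deviance, subject_draws[:kept_sub], accept_rate


@njit(cache=True)
def col_is_intercept(col, k):
    return col[k] == 0


# ---------------------------------------------------------------------------
# Bayesian linear mixed models (Bernoulli-logit / shifted-lognormal)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _blmm_ll(y, eta, s, e, family, sigma_log, delta):
    """Log-likelihood of trials [s, e) given the linear predictor."""
    total = 0.0
    if family == 0:  # Bernoulli-logit, y in {0, 1}
        for i in range(s, e):
            x = eta[i]
            if x > 0.0:
                total += y[i] * x - x - np.log(1.0 + np.exp(-x))
            else:
                total += y[i] * x - np.log(1.0 + np.exp(x))
    else:  # shifted lognormal, y = rt
        for i in range(s, e):
            x = y[i] - delta
            if x <= 0.0:
                return LOG_ZERO
            lx = np.log(x)
            d = lx - eta[i]
            total += -lx - np.log(sigma_log) - d * d / (2.0 * sigma_log * sigma_log)
    return total


@njit(cache=True)
def blmm_chain(
    y, X, subj_start, subj_end, family,
    beta_prior_scale, n_sweeps, burn_in, seed,
):
    """One MCMC chain of the mixed model; returns draws and subject means.

    Draw layout per retained sweep: beta[0:p], sigma_u, sigma_log, delta
    (the last two are zero for the Bernoulli family).
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    n_subj = subj_start.shape[0]

    beta = np.zeros(p)
    u = np.zeros(n_subj)
    sigma_u = 0.3
    sigma_log = 0.5
    y_min = y.min()
    delta = 0.5 * y_min if family == 1 else 0.0
    if family == 1:
        # start the location near the marginal log mean above the shift
        m = 0.0
        for i in range(n):
            m += np.log(y[i] - delta)
        beta[0] = m / n

    eta = np.empty(n)
    subj_of = np.empty(n, dtype=np.int64)
    for j in range(n_subj):
        for i in range(subj_start[j], subj_end[j]):
            subj_of[i] = j
    for i in range(n):
        eta[i] = X[i] @ beta + u[subj_of[i]]

    ll_total = _blmm_ll(y, eta, 0, n, family, sigma_log, delta)

    step_beta = np.full(p, 0.2)
    step_u = np.full(n_subj, 0.2)
    step_sig = 0.3
    step_slog = 0.2
    step_delta = 0.1 * y_min if family == 1 else 0.0
    acc_b = np.zeros(p)
    try_b = np.zeros(p)
    acc_u = np.zeros(n_subj)
    try_u = np.zeros(n_subj)

    n_keep = n_sweeps - burn_in
    draws = np.empty((n_keep, p + 3))
    u_sum = np.zeros(n_subj)
    work = np.empty(n)

    # joint (intercept, sigma_log, delta) proposals for the lognormal family:
    # the shift trades off against the location along a ridge that
    # coordinate-wise updates traverse only slowly
    tri_mean = np.zeros(3)
    tri_outer = np.zeros((3, 3))
    tri_n = 0
    tri_chol = np.zeros((3, 3))
    tri_have = False
    tri_lam = 1.0
    acc_tri = 0.0
    try_tri = 0.0

    for sweep in range(n_sweeps):
        # fixed effects
        for k in range(p):
            d = step_beta[k] * np.random.normal()
            for i in range(n):
                work[i] = eta[i] + X[i, k] * d
            new_ll = _blmm_ll(y, work, 0, n, family, sigma_log, delta)
            old_b = beta[k]
            new_b = old_b + d
            lp = (old_b * old_b - new_b * new_b) / (2.0 * beta_prior_scale * beta_prior_scale)
            try_b[k] += 1.0
            if np.log(np.random.random()) < new_ll - ll_total + lp:
                beta[k] = new_b
                ll_total = new_ll
                for i in range(n):
                    eta[i] = work[i]
                acc_b[k] += 1.0

        # subject intercepts
        for j in range(n_subj):
            s, e = subj_start[j], subj_end[j]
            d = step_u[j] * np.random.normal()
            for i in range(s, e):
                work[i] = eta[i] + d
            ll_old = _blmm_ll(y, eta, s, e, family, sigma_log, delta)
            ll_new = _blmm_ll(y, work, s, e, family, sigma_log, delta)
            old_u = u[j]
            new_u = old_u + d
            lp = (old_u * old_u - new_u * new_u) / (2.0 * sigma_u * sigma_u)
            try_u[j] += 1.0
            if np.log(np.random.random()) < ll_new - ll_old + lp:
                u[j] = new_u
                ll_total += ll_new - ll_old
                for i in range(s, e):
                    eta[i] = work[i]
                acc_u[j] += 1.0

        # subject-intercept spread (half-normal prior, MH on log scale)
        old = sigma_u
        prop = old * np.exp(step_sig * np.random.normal())
        ll_old = -n_subj * np.log(old)
        ll_new = -n_subj * np.log(prop)
        for j in range(n_subj):
            ll_old += -u[j] * u[j] / (2.0 * old * old)
            ll_new += -u[j] * u[j] / (2.0 * prop * prop)
        lr = (ll_new + _halfnormal_logpdf(prop, 1.0) + np.log(prop)
              - ll_old - _halfnormal_logpdf(old, 1.0) - np.log(old))
        if np.log(np.random.random()) < lr:
            sigma_u = prop

        if family == 1:
            # residual scale on the log axis
            old = sigma_log
            prop = old * np.exp(step_slog * np.random.normal())
            ll_new = _blmm_ll(y, eta, 0, n, family, prop, delta)
            lr = (ll_new + _halfnormal_logpdf(prop, 1.0) + np.log(prop)
                  - ll_total - _halfnormal_logpdf(old, 1.0) - np.log(old))
            if np.log(np.random.random()) < lr:
                sigma_log = prop
                ll_total = ll_new
            # shift, uniform prior on [0, min rt)
            old = delta
            prop = old + step_delta * np.random.normal()
            if 0.0 <= prop < y_min:
                ll_new = _blmm_ll(y, eta, 0, n, family, sigma_log, prop)
                if np.log(np.random.random()) < ll_new - ll_total:
                    delta = prop
                    ll_total = ll_new

            # joint ridge move over (beta0, sigma_log, delta)
            if sweep >= 100:
                tri_mean[0] += beta[0]
                tri_mean[1] += sigma_log
                tri_mean[2] += delta
                x3 = np.array([beta[0], sigma_log, delta])
                for k1 in range(3):
                    for k2 in range(3):
                        tri_outer[k1, k2] += x3[k1] * x3[k2]
                tri_n += 1
            if tri_n >= 150 and (sweep + 1) % 150 == 0 and sweep < burn_in:
                cov3 = np.empty((3, 3))
                for k1 in range(3):
                    for k2 in range(3):
                        cov3[k1, k2] = (tri_outer[k1, k2] / tri_n
                                        - (tri_mean[k1] / tri_n) * (tri_mean[k2] / tri_n))
                for k1 in range(3):
                    cov3[k1, k1] += 1e-10 + 1e-4 * cov3[k1, k1]
                tri_chol[:] = np.linalg.cholesky(cov3)
                tri_have = True
            if tri_have:
                for _rep in range(2):
                    xi = np.empty(3)
                    for k1 in range(3):
                        xi[k1] = np.random.normal()
                    dx3 = tri_lam * 1.4 * (tri_chol @ xi)
                    b0n = beta[0] + dx3[0]
                    sln = sigma_log + dx3[1]
                    dln = delta + dx3[2]
                    try_tri += 1.0
                    if sln <= 0.0 or not (0.0 <= dln < y_min):
                        continue
                    for i in range(n):
                        work[i] = eta[i] + dx3[0]
                    ll_new = _blmm_ll(y, work, 0, n, family, sln, dln)
                    lp = ((beta[0] ** 2 - b0n ** 2) / (2.0 * beta_prior_scale ** 2)
                          + _halfnormal_logpdf(sln, 1.0) - _halfnormal_logpdf(sigma_log, 1.0))
                    if np.log(np.random.random()) < ll_new - ll_total + lp:
                        beta[0] = b0n
                        sigma_log = sln
                        delta = dln
                        ll_total = ll_new
                        for i in range(n):
                            eta[i] = work[i]
                        acc_tri += 1.0

        if sweep < burn_in and (sweep + 1) % 50 == 0:
            fac = min(1.0, 50.0 / (sweep + 1.0))
            if try_tri > 0:
                tri_lam *= np.exp(1.5 * (acc_tri / try_tri - 0.23) * fac)
                if tri_lam < 1e-3:
                    tri_lam = 1e-3
                acc_tri = 0.0
                try_tri = 0.0
            for k in range(p):
                if try_b[k] > 0:
                    step_beta[k] *= np.exp(1.5 * (acc_b[k] / try_b[k] - 0.44) * fac)
            for j in range(n_subj):
                if try_u[j] > 0:
                    step_u[j] *= np.exp(1.5 * (acc_u[j] / try_u[j] - 0.44) * fac)
            acc_b[:] = 0.0
            try_b[:] = 0.0
            acc_u[:] = 0.0
            try_u[:] = 0.0

        if sweep >= burn_in:
            idx = sweep - burn_in
            for k in range(p):
                draws[idx, k] = beta[k]
            draws[idx, p] = sigma_u
            draws[idx, p + 1] = sigma_log if family == 1 else 0.0
            draws[idx, p + 2] = delta
            for j in range(n_subj):
                u_sum[j] += u[j]

    acc_rate = 0.0
    tries = 0.0
    for k in range(p):
        acc_rate += acc_b[k]
        tries += try_b[k]
    rate = acc_rate / tries if tries > 0 else 0.0
    return draws, u_sum / n_keep, rate


@njit(cache=True)
def dataset_loglik(rt, up, lv, la, lt, zz, err):
    """Log-likelihood of a dataset given per-trial implied parameters."""
    total = 0.0
    for i in range(rt.shape[0]):
        ll = wfpt_log_density(rt[i], up[i], lv[i], la[i], lt[i], zz[i], err)
        if ll <= LOG_ZERO:
            return LOG_ZERO
        total += ll
    return total
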