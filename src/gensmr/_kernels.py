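"""Numba-jitted MCMC kernels.

The chain kernel performs one Metropolis-within-Gibbs sweep per iteration:

* activity-center random-walk updates for every individual (marked, and
  augmented with z=1; centers of z=0 slots are refreshed from the uniform
  prior so the inclusion update explores the state space);
* Gibbs inclusion updates z_i for the augmented slots;
* conjugate Gibbs draws for psi (Beta) and delta (Beta);
* log/logit-scale random-walk updates (with Jacobians) for lam0_mark,
  lam0_resight and sigma, with window-based scale adaptation during the
  warm-up phase only.

Two likelihood representations are supported by the same kernel:

* ``latent=False`` (default): the latent histories of marked-but-
  unidentified detections are marginalized out analytically (Poisson
  thinning), so nnid_jk ~ Poisson((1-delta) * sum_i alive_ik lambda_ij).
* ``latent=True``: the per-individual unidentified histories are imputed by
  their exact multinomial full conditional given the cell sums nnid_jk, and
  the conditional (unmarginalized) Poisson likelihood is used. This path
  exists as an independent cross-check of the marginalized sampler.

All helper functions are importable and are tested directly against the
pure-numpy joint density in :mod:`gensmr.likelihoods`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# small building blocks


@njit(cache=True)
def _sqdist_row(x, y, X):
    out = np.empty(X.shape[0])
    for j in range(X.shape[0]):
        dx = x - X[j, 0]
        dy = y - X[j, 1]
        out[j] = dx * dx + dy * dy
    return out


@njit(cache=True)
def _expfac(d2row, sigma):
    out = np.empty(d2row.shape[0])
    t = 1.0 / (2.0 * sigma * sigma)
    for j in range(d2row.shape[0]):
        out[j] = np.exp(-d2row[j] * t)
    return out


@njit(cache=True)
def _expmat(d2, sigma):
    n, p = d2.shape
    out = np.empty((n, p))
    t = 1.0 / (2.0 * sigma * sigma)
    for i in range(n):
        for j in range(p):
            out[i, j] = np.exp(-d2[i, j] * t)
    return out


@njit(cache=True)
def _ll_marking_row(et_row, cap_row, ktrap, lam0m, cloglog):
    """Bernoulli marking log-likelihood of one individual (capture counts
    per trap over the effort-on occasions)."""
    ll = 0.0
    for j in range(et_row.shape[0]):
        kj = ktrap[j]
        if kj <= 0.0:
            continue
        if cloglog:
            p = 1.0 - np.exp(-lam0m * et_row[j])
        else:
            p = lam0m * et_row[j]
        c = cap_row[j]
        if c > 0.0:
            if p <= 0.0:
                return -np.inf
            ll += c * np.log(p)
        if kj - c > 0.0:
            if p >= 1.0:
                return -np.inf
            ll += (kj - c) * np.log(1.0 - p)
    return ll


@njit(cache=True)
def _ll_marking_zero(et_row, ktrap, lam0m, cloglog):
    """Marking log-likelihood of an all-zero capture history."""
    ll = 0.0
    for j in range(et_row.shape[0]):
        kj = ktrap[j]
        if kj <= 0.0:
            continue
        if cloglog:
            p = 1.0 - np.exp(-lam0m * et_row[j])
        else:
            p = lam0m * et_row[j]
        if p >= 1.0:
            return -np.inf
        ll += kj * np.log(1.0 - p)
    return ll


@njit(cache=True)
def _ll_ident_row(ec_row, yid_row, keff_row, lam0r, delta):
    """Identified-resight Poisson terms of one marked individual, summed
    over cameras; mean per live/effort occasion is delta*lam0r*ec (y!
    constants dropped)."""
    ll = 0.0
    for j in range(ec_row.shape[0]):
        lam = delta * lam0r * ec_row[j]
        ll -= lam * keff_row[j]
        y = yid_row[j]
        if y > 0.0:
            if lam <= 0.0 or keff_row[j] <= 0.0:
                return -np.inf
            ll += y * np.log(lam)
    return ll


@njit(cache=True)
def _ll_full_row(ec_row, yfull_row, keff_row, lam0r):
    """Conditional Poisson terms of one marked individual's full (imputed)
    histories; mean per live/effort occasion is lam0r*ec."""
    ll = 0.0
    for j in range(ec_row.shape[0]):
        lam = lam0r * ec_row[j]
        ll -= lam * keff_row[j]
        y = yfull_row[j]
        if y > 0.0:
            if lam <= 0.0 or keff_row[j] <= 0.0:
                return -np.inf
            ll += y * np.log(lam)
    return ll


@njit(cache=True)
def _ll_unid(sa, nnid, effcam, lam0r, delta):
    """Marginal Poisson log-likelihood of the unidentified-marked counts.

    ``sa[j, k]`` holds sum_i alive_ik * exp-kernel_ij over marked
    individuals; the cell mean is (1-delta)*lam0r*sa on effort-on cells.
    """
    ll = 0.0
    c = (1.0 - delta) * lam0r
    Jc, K = sa.shape
    for j in range(Jc):
        for k in range(K):
            if effcam[j, k] <= 0.0:
                continue
            mu = c * sa[j, k]
            ll -= mu
            if nnid[j, k] > 0.0:
                if mu <= 0.0:
                    return -np.inf
                ll += nnid[j, k] * np.log(mu)
    return ll


@njit(cache=True)
def _ll_unmarked(g, nun, kcam, lam0r):
    """Poisson log-likelihood of occasion-aggregated unmarked counts;
    ``g[j]`` sums the exp-kernel over included augmented individuals."""
    ll = 0.0
    for j in range(g.shape[0]):
        mu = lam0r * g[j]
        ll -= mu * kcam[j]
        if nun[j] > 0.0:
            if mu <= 0.0 or kcam[j] <= 0.0:
                return -np.inf
            ll += nun[j] * np.log(mu)
    return ll


@njit(cache=True)
def _ll_tel_i(sx, sy, tn_i, tmx_i, tmy_i, tss_i, sigma):
    """Telemetry log-density of one individual from sufficient statistics
    (fix count, fix centroid, centered sum of squares); 2*pi constants
    dropped."""
    if tn_i <= 0.0:
        return 0.0
    dev = tss_i + tn_i * ((tmx_i - sx) ** 2 + (tmy_i - sy) ** 2)
    return -2.0 * tn_i * np.log(sigma) - dev / (2.0 * sigma * sigma)


@njit(cache=True)
def _build_sa(Ec, alive, m):
    Jc = Ec.shape[1]
    K = alive.shape[1]
    sa = np.zeros((Jc, K))
    for i in range(m):
        for j in range(Jc):
            e = Ec[i, j]
            for k in range(K):
                sa[j, k] += alive[i, k] * e
    return sa


@njit(cache=True)
def _build_g(Ec, z, m):
    M, Jc = Ec.shape
    g = np.zeros(Jc)
    for i in range(m, M):
        if z[i] == 1:
            for j in range(Jc):
                g[j] += Ec[i, j]
    return g


# ---------------------------------------------------------------------------
# update targets (the s_i-dependent or parameter-dependent part of the joint)


@njit(cache=True)
def marked_s_logtarget(
    sx,
    sy,
    cap_row,
    yid_row,
    keff_row,
    alive_row,
    sa_others,
    nnid,
    effcam,
    Xt,
    ktrap,
    Xc,
    lam0m,
    lam0r,
    sigma,
    delta,
    tn_i,
    tmx_i,
    tmy_i,
    tss_i,
    cloglog,
    latent,
    ymusum_row,
):
    """Log joint terms that depend on the activity center of marked
    individual i, evaluated at (sx, sy). ``sa_others`` excludes i's own
    contribution to the unidentified-marked means."""
    et = _expfac(_sqdist_row(sx, sy, Xt), sigma)
    ec = _expfac(_sqdist_row(sx, sy, Xc), sigma)
    ll = _ll_marking_row(et, cap_row, ktrap, lam0m, cloglog)
    Jc = Xc.shape[0]
    if latent:
        yfull = np.empty(Jc)
        for j in range(Jc):
            yfull[j] = yid_row[j] + ymusum_row[j]
        ll += _ll_full_row(ec, yfull, keff_row, lam0r)
    else:
        ll += _ll_ident_row(ec, yid_row, keff_row, lam0r, delta)
        K = effcam.shape[1]
        sa_new = np.empty((Jc, K))
        for j in range(Jc):
            for k in range(K):
                sa_new[j, k] = sa_others[j, k] + alive_row[k] * ec[j]
        ll += _ll_unid(sa_new, nnid, effcam, lam0r, delta)
    ll += _ll_tel_i(sx, sy, tn_i, tmx_i, tmy_i, tss_i, sigma)
    return ll


@njit(cache=True)
def aug_s_logtarget(
    sx, sy, g_others, nun, kcam, Xt, ktrap, Xc, lam0m, lam0r, sigma, cloglog
):
    """Log joint terms depending on the center of an included augmented
    individual at (sx, sy): its all-zero marking history plus the change to
    the unmarked-count means. ``g_others`` excludes its own kernel column."""
    et = _expfac(_sqdist_row(sx, sy, Xt), sigma)
    ec = _expfac(_sqdist_row(sx, sy, Xc), sigma)
    ll = _ll_marking_zero(et, ktrap, lam0m, cloglog)
    Jc = Xc.shape[0]
    gnew = np.empty(Jc)
    for j in range(Jc):
        gnew[j] = g_others[j] + ec[j]
    ll += _ll_unmarked(gnew, nun, kcam, lam0r)
    return ll


@njit(cache=True)
def full_loglik(
    s,
    z,
    Et,
    Ec,
    cap,
    ktrap,
    yid,
    keff,
    alive,
    nnid,
    effcam,
    nun,
    kcam,
    tn,
    tmx,
    tmy,
    tss,
    lam0m,
    lam0r,
    sigma,
    delta,
    m,
    cloglog,
    latent,
    ymusum,
):
    """Full data log-likelihood given kernel caches Et/Ec consistent with
    ``sigma`` (constants independent of all parameters are dropped)."""
    M = z.shape[0]
    ll = 0.0
    for i in range(m):
        ll += _ll_marking_row(Et[i], cap[i], ktrap, lam0m, cloglog)
        if latent:
            Jc = Ec.shape[1]
            yfull = np.empty(Jc)
            for j in range(Jc):
                yfull[j] = yid[i, j] + ymusum[i, j]
            ll += _ll_full_row(Ec[i], yfull, keff[i], lam0r)
        else:
            ll += _ll_ident_row(Ec[i], yid[i], keff[i], lam0r, delta)
        ll += _ll_tel_i(s[i, 0], s[i, 1], tn[i], tmx[i], tmy[i], tss[i], sigma)
        if not np.isfinite(ll):
            return -np.inf
    for i in range(m, M):
        if z[i] == 1:
            ll += _ll_marking_zero(Et[i], ktrap, lam0m, cloglog)
    if (not latent) and m > 0:
        sa = _build_sa(Ec, alive, m)
        ll += _ll_unid(sa, nnid, effcam, lam0r, delta)
    g = _build_g(Ec, z, m)
    ll += _ll_unmarked(g, nun, kcam, lam0r)
    if not np.isfinite(ll):
        return -np.inf
    return ll


# ---------------------------------------------------------------------------
# random draws


@njit(cache=True)
def _beta_draw(a, b):
    x = np.random.gamma(a, 1.0)
    y = np.random.gamma(b, 1.0)
    return x / (x + y)


@njit(cache=True)
def _impute_ymusum(ymusum, nnid, alive, Ec, m):
    """Exact Gibbs draw of the per-individual unidentified histories.

    For each camera-occasion cell the vector (y^mu_1jk ... y^mu_mjk) given
    its sum nnid_jk is Multinomial with probabilities proportional to
    alive_ik * lambda_ij; drawn by sequential binomials. Only the per-(i, j)
    sums over occasions are retained (sufficient for every other update).
    Returns 0 on success, 1 on impossible data (positive count, zero mean).
    """
    mm, Jc = ymusum.shape
    K = nnid.shape[1]
    for i in range(mm):
        for j in range(Jc):
            ymusum[i, j] = 0.0
    for j in range(Jc):
        for k in range(K):
            ntot = int(nnid[j, k])
            if ntot <= 0:
                continue
            wsum = 0.0
            for i in range(m):
                wsum += alive[i, k] * Ec[i, j]
            if wsum <= 0.0:
                return 1
            rem = ntot
            for i in range(m - 1):
                if rem == 0:
                    break
                w = alive[i, k] * Ec[i, j]
                p = w / wsum
                if p >= 1.0:
                    x = rem
                elif p <= 0.0:
                    x = 0
                else:
                    x = np.random.binomial(rem, p)
                ymusum[i, j] += x
                rem -= x
                wsum -= w
            if rem > 0:
                ymusum[m - 1, j] += rem
    return 0


# ---------------------------------------------------------------------------
# the chain


@njit(cache=True)
def run_chain(
    seed,
    n_sweeps,
    n_discard,
    thin,
    n_adapt,
    latent,
    # data
    Xt,
    ktrap,
    cap,
    Xc,
    kcam,
    effcam,
    yid,
    keff,
    alive,
    nnid,
    nun,
    tn,
    tmx,
    tmy,
    tss,
    # state space / priors
    xmin,
    xmax,
    ymin,
    ymax,
    lam0m_hi,
    lam0r_hi,
    sigma_hi,
    cloglog,
    # initial state (modified in place)
    s,
    z,
    lam0m,
    lam0r,
    sigma,
    delta,
    psi,
    m,
    # proposal scales
    ps_sm,
    ps_sa,
    ps_lam0m,
    ps_lam0r,
    ps_sigma,
    # outputs
    out,
    out_z,
    acc,
):
    """Run one MCMC chain; fills ``out`` (n_kept, 6: lam0_mark, lam0_resight,
    sigma, delta, psi, N), ``out_z`` (n_kept, M) and ``acc`` (5, 2 attempt/
    accept counts for marked-s, augmented-s, lam0_mark, lam0_resight,
    sigma). Returns 0 on success, 1 on a non-finite joint density."""
    np.random.seed(seed)
    M = z.shape[0]
    Jm = Xt.shape[0]
    Jc = Xc.shape[0]
    width = xmax - xmin
    height = ymax - ymin

    s_delta_tot = float(yid.sum())
    s_nnid_tot = float(nnid.sum())

    # distance and kernel caches
    d2t = np.empty((M, Jm))
    d2c = np.empty((M, Jc))
    for i in range(M):
        d2t[i] = _sqdist_row(s[i, 0], s[i, 1], Xt)
        d2c[i] = _sqdist_row(s[i, 0], s[i, 1], Xc)
    Et = _expmat(d2t, sigma)
    Ec = _expmat(d2c, sigma)

    ymusum = np.zeros((max(m, 1), Jc))

    # adaptation windows: attempts/accepts per block since last adjustment
    win = np.zeros((5, 2))
    scale_lo = 1e-7
    scale_hi_s = max(width, height)

    kept = 0
    for it in range(n_sweeps):
        if latent:
            status = _impute_ymusum(ymusum, nnid, alive, Ec, m)
            if status != 0:
                return 1

        sa = _build_sa(Ec, alive, m)
        g = _build_g(Ec, z, m)

        # ---- activity centers
        for i in range(M):
            if i < m:
                sa_oth = np.empty((Jc, alive.shape[1]))
                for j in range(Jc):
                    e = Ec[i, j]
                    for k in range(alive.shape[1]):
                        sa_oth[j, k] = sa[j, k] - alive[i, k] * e
                sx = s[i, 0] + ps_sm * np.random.normal()
                sy = s[i, 1] + ps_sm * np.random.normal()
                acc[0, 0] += 1.0
                win[0, 0] += 1.0
                if sx < xmin or sx > xmax or sy < ymin or sy > ymax:
                    continue
                ll_old = marked_s_logtarget(
                    s[i, 0], s[i, 1], cap[i], yid[i], keff[i], alive[i],
                    sa_oth, nnid, effcam, Xt, ktrap, Xc,
                    lam0m, lam0r, sigma, delta,
                    tn[i], tmx[i], tmy[i], tss[i], cloglog, latent, ymusum[i],
                )
                ll_new = marked_s_logtarget(
                    sx, sy, cap[i], yid[i], keff[i], alive[i],
                    sa_oth, nnid, effcam, Xt, ktrap, Xc,
                    lam0m, lam0r, sigma, delta,
                    tn[i], tmx[i], tmy[i], tss[i], cloglog, latent, ymusum[i],
                )
                dl = ll_new - ll_old
                if dl == dl and np.log(np.random.random()) < dl:
                    s[i, 0] = sx
                    s[i, 1] = sy
                    d2t[i] = _sqdist_row(sx, sy, Xt)
                    d2c[i] = _sqdist_row(sx, sy, Xc)
                    Et[i] = _expfac(d2t[i], sigma)
                    Ec[i] = _expfac(d2c[i], sigma)
                    for j in range(Jc):
                        e = Ec[i, j]
                        for k in range(alive.shape[1]):
                            sa[j, k] = sa_oth[j, k] + alive[i, k] * e
                    acc[0, 1] += 1.0
                    win[0, 1] += 1.0
            else:
                if z[i] == 0:
                    # refresh from the uniform prior (its full conditional)
                    s[i, 0] = xmin + width * np.random.random()
                    s[i, 1] = ymin + height * np.random.random()
                    d2t[i] = _sqdist_row(s[i, 0], s[i, 1], Xt)
                    d2c[i] = _sqdist_row(s[i, 0], s[i, 1], Xc)
                    Et[i] = _expfac(d2t[i], sigma)
                    Ec[i] = _expfac(d2c[i], sigma)
                    continue
                g_oth = np.empty(Jc)
                for j in range(Jc):
                    g_oth[j] = g[j] - Ec[i, j]
                    if g_oth[j] < 0.0:
                        g_oth[j] = 0.0
                sx = s[i, 0] + ps_sa * np.random.normal()
                sy = s[i, 1] + ps_sa * np.random.normal()
                acc[1, 0] += 1.0
                win[1, 0] += 1.0
                if sx < xmin or sx > xmax or sy < ymin or sy > ymax:
                    continue
                ll_old = aug_s_logtarget(
                    s[i, 0], s[i, 1], g_oth, nun, kcam, Xt, ktrap, Xc,
                    lam0m, lam0r, sigma, cloglog,
                )
                ll_new = aug_s_logtarget(
                    sx, sy, g_oth, nun, kcam, Xt, ktrap, Xc,
                    lam0m, lam0r, sigma, cloglog,
                )
                dl = ll_new - ll_old
                if dl == dl and np.log(np.random.random()) < dl:
                    s[i, 0] = sx
                    s[i, 1] = sy
                    d2t[i] = _sqdist_row(sx, sy, Xt)
                    d2c[i] = _sqdist_row(sx, sy, Xc)
                    Et[i] = _expfac(d2t[i], sigma)
                    Ec[i] = _expfac(d2c[i], sigma)
                    for j in range(Jc):
                        g[j] = g_oth[j] + Ec[i, j]
                    acc[1, 1] += 1.0
                    win[1, 1] += 1.0

        # ---- inclusion indicators (Gibbs)
        lpsi = np.log(psi)
        l1mpsi = np.log(1.0 - psi)
        for i in range(m, M):
            g_oth = np.empty(Jc)
            for j in range(Jc):
                if z[i] == 1:
                    g_oth[j] = g[j] - Ec[i, j]
                    if g_oth[j] < 0.0:
                        g_oth[j] = 0.0
                else:
                    g_oth[j] = g[j]
            ll0 = _ll_unmarked(g_oth, nun, kcam, lam0r)
            ll1 = aug_s_logtarget(
                s[i, 0], s[i, 1], g_oth, nun, kcam, Xt, ktrap, Xc,
                lam0m, lam0r, sigma, cloglog,
            )
            if ll1 == -np.inf and ll0 == -np.inf:
                return 1
            if ll0 == -np.inf:
                p1 = 1.0
            else:
                a = lpsi + ll1
                b = l1mpsi + ll0
                if a >= b:
                    p1 = 1.0 / (1.0 + np.exp(b - a))
                else:
                    e = np.exp(a - b)
                    p1 = e / (1.0 + e)
            znew = 1 if np.random.random() < p1 else 0
            if znew != z[i]:
                if znew == 1:
                    for j in range(Jc):
                        g[j] = g_oth[j] + Ec[i, j]
                else:
                    for j in range(Jc):
                        g[j] = g_oth[j]
                z[i] = znew

        # ---- psi (conjugate)
        nz = 0
        for i in range(M):
            nz += z[i]
        psi = _beta_draw(1.0 + nz, 1.0 + (M - nz))

        # ---- delta (conjugate; free of all other parameters)
        delta = _beta_draw(1.0 + s_delta_tot, 1.0 + s_nnid_tot)

        # ---- lam0_mark (logit-scale random walk on (0, lam0m_hi))
        acc[2, 0] += 1.0
        win[2, 0] += 1.0
        lo = np.log(lam0m / (lam0m_hi - lam0m))
        ln = lo + ps_lam0m * np.random.normal()
        lam0m_new = lam0m_hi / (1.0 + np.exp(-ln))
        if 0.0 < lam0m_new < lam0m_hi:
            ll_old = full_loglik(
                s, z, Et, Ec, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m, lam0r, sigma, delta, m, cloglog, latent, ymusum,
            )
            ll_new = full_loglik(
                s, z, Et, Ec, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m_new, lam0r, sigma, delta, m, cloglog, latent, ymusum,
            )
            jac = np.log(lam0m_new * (lam0m_hi - lam0m_new)) - np.log(
                lam0m * (lam0m_hi - lam0m)
            )
            dl = ll_new - ll_old + jac
            if dl == dl and np.log(np.random.random()) < dl:
                lam0m = lam0m_new
                acc[2, 1] += 1.0
                win[2, 1] += 1.0

        # ---- lam0_resight (log-scale random walk on (0, lam0r_hi))
        acc[3, 0] += 1.0
        win[3, 0] += 1.0
        lam0r_new = lam0r * np.exp(ps_lam0r * np.random.normal())
        if 0.0 < lam0r_new < lam0r_hi:
            ll_old = full_loglik(
                s, z, Et, Ec, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m, lam0r, sigma, delta, m, cloglog, latent, ymusum,
            )
            ll_new = full_loglik(
                s, z, Et, Ec, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m, lam0r_new, sigma, delta, m, cloglog, latent, ymusum,
            )
            dl = ll_new - ll_old + (np.log(lam0r_new) - np.log(lam0r))
            if dl == dl and np.log(np.random.random()) < dl:
                lam0r = lam0r_new
                acc[3, 1] += 1.0
                win[3, 1] += 1.0

        # ---- sigma (log-scale random walk on (0, sigma_hi))
        acc[4, 0] += 1.0
        win[4, 0] += 1.0
        sigma_new = sigma * np.exp(ps_sigma * np.random.normal())
        if 0.0 < sigma_new < sigma_hi:
            Et2 = _expmat(d2t, sigma_new)
            Ec2 = _expmat(d2c, sigma_new)
            ll_old = full_loglik(
                s, z, Et, Ec, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m, lam0r, sigma, delta, m, cloglog, latent, ymusum,
            )
            ll_new = full_loglik(
                s, z, Et2, Ec2, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m, lam0r, sigma_new, delta, m, cloglog, latent, ymusum,
            )
            dl = ll_new - ll_old + (np.log(sigma_new) - np.log(sigma))
            if dl == dl and np.log(np.random.random()) < dl:
                sigma = sigma_new
                Et = Et2
                Ec = Ec2
                acc[4, 1] += 1.0
                win[4, 1] += 1.0

        # ---- adaptation (warm-up only; frozen afterwards)
        if it < n_adapt and (it + 1) % 50 == 0:
            for b in range(5):
                if win[b, 0] < 1.0:
                    continue
                rate = win[b, 1] / win[b, 0]
                if b == 0:
                    if rate > 0.45:
                        ps_sm *= 1.2
                    elif rate < 0.30:
                        ps_sm /= 1.2
                    ps_sm = min(max(ps_sm, scale_lo), scale_hi_s)
                elif b == 1:
                    if rate > 0.45:
                        ps_sa *= 1.2
                    elif rate < 0.30:
                        ps_sa /= 1.2
                    ps_sa = min(max(ps_sa, scale_lo), scale_hi_s)
                elif b == 2:
                    if rate > 0.45:
                        ps_lam0m *= 1.2
                    elif rate < 0.30:
                        ps_lam0m /= 1.2
                    ps_lam0m = min(max(ps_lam0m, 1e-4), 10.0)
                elif b == 3:
                    if rate > 0.45:
                        ps_lam0r *= 1.2
                    elif rate < 0.30:
                        ps_lam0r /= 1.2
                    ps_lam0r = min(max(ps_lam0r, 1e-4), 10.0)
                else:
                    if rate > 0.45:
                        ps_sigma *= 1.2
                    elif rate < 0.30:
                        ps_sigma /= 1.2
                    ps_sigma = min(max(ps_sigma, 1e-4), 10.0)
                win[b, 0] = 0.0
                win[b, 1] = 0.0

        # ---- periodic sanity check on the joint density
        if it == 0 or (it + 1) % 250 == 0:
            ll = full_loglik(
                s, z, Et, Ec, cap, ktrap, yid, keff, alive, nnid, effcam,
                nun, kcam, tn, tmx, tmy, tss,
                lam0m, lam0r, sigma, delta, m, cloglog, latent, ymusum,
            )
            if not np.isfinite(ll):
                return 1

        # ---- record
        if it >= n_discard and (it - n_discard) % thin == 0:
            nz = 0
            for i in range(M):
                nz += z[i]
            out[kept, 0] = lam0m
            out[kept, 1] = lam0r
            out[kept, 2] = sigma
            out[kept, 3] = delta
            out[kept, 4] = psi
            out[kept, 5] = nz
            for i in range(M):
                out_z[kept, i] = z[i]
            kept += 1
    return 0
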