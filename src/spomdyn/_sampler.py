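"""Numba core of the Metropolis-within-Gibbs sampler.

Everything here operates on plain arrays; the friendly interface lives in
:mod:`spomdyn.inference`.  Layout conventions:

* years are 0-based ``t = 0..T-1``; transitions ``r = 0..R-1`` (R = T-1)
  carry the dynamics *into* year ``r+1`` (year-specific dispersal
  parameters are indexed by the destination-year transition ``r``);
* ``K[r]`` is the kernel ``exp(-alpha_r * d_ij)`` with a zeroed diagonal,
  so connectivity is the matrix-vector product ``K[r] @ (A * z[:, r])``;
* ``Cw``/``Cu`` hold the occupancy-weighted and structural (z = 1)
  connectivity sums; both are maintained incrementally under latent-state
  flips so the Gibbs-variable-selection indicator can switch weighting
  cheaply;
* random-effect deviates are log-scale: ``alpha_r = exp(la + ea[r]*I_D)``.

The latent-state update uses the exact full conditional: detection terms,
the patch's own past and future transition factors, and — for weighted
models — the cross-patch product over every other patch that was empty in
year ``t``, whose colonization probability into ``t+1`` depends on
``z[i, t]`` through connectivity.
"""

import numpy as np
from numba import njit

TINY = 1e-300

# proposal-scale slots for scalar parameters
SC_D0, SC_D1, SC_LA, SC_LB, SC_LSA, SC_LSB, SC_LSP = 0, 1, 2, 3, 4, 5, 6
N_SCAL = 7

# saved-draw column layout (before the per-year blocks)
COL_PSI1, COL_D0, COL_D1, COL_ALPHA, COL_BETA = 0, 1, 2, 3, 4
COL_SA, COL_SB, COL_MUP, COL_SP, COL_IZ, COL_ID, COL_LL = 5, 6, 7, 8, 9, 10, 11
N_FIXED_COLS = 12


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _log(x):
    return np.log(max(x, TINY))


@njit(cache=True)
def _kernel_into(D, alpha, out):
    n = D.shape[0]
    for i in range(n):
        for j in range(n):
            out[i, j] = np.exp(-alpha * D[i, j])
        out[i, i] = 0.0


@njit(cache=True)
def _kernels_into(D, alpha_tr, K):
    """Fill K[r] for every transition; reuse slice 0 when alphas coincide."""
    R = alpha_tr.shape[0]
    same = True
    for r in range(1, R):
        if alpha_tr[r] != alpha_tr[0]:
            same = False
            break
    _kernel_into(D, alpha_tr[0], K[0])
    for r in range(1, R):
        if same:
            K[r, :, :] = K[0]
        else:
            _kernel_into(D, alpha_tr[r], K[r])


@njit(cache=True)
def _connect_into(K, A, z, Cw, Cu):
    """Cw[r] = K[r] @ (A*z[:, r]);  Cu[r] = K[r] @ A (structural)."""
    R, n = Cw.shape
    for r in range(R):
        for i in range(n):
            sw = 0.0
            su = 0.0
            for j in range(n):
                aj = A[j] * K[r, i, j]
                su += aj
                if z[j, r] == 1:
                    sw += aj
            Cw[r, i] = sw
            Cu[r, i] = su


@njit(cache=True)
def _col_ll_r(z, r, Crow, beta_r):
    """Colonization log-likelihood of transition r (empty patches only)."""
    n = z.shape[0]
    ll = 0.0
    for i in range(n):
        if z[i, r] == 0:
            S = beta_r * Crow[i]
            if z[i, r + 1] == 1:
                ll += _log(-np.expm1(-S))
            else:
                ll += -S
    return ll


@njit(cache=True)
def _col_ll_total(z, C, beta_tr):
    R = C.shape[0]
    ll = 0.0
    for r in range(R):
        ll += _col_ll_r(z, r, C[r], beta_tr[r])
    return ll


@njit(cache=True)
def _ext_ll_total(z, eps):
    n, T = z.shape
    ll = 0.0
    for r in range(T - 1):
        for i in range(n):
            if z[i, r] == 1:
                if z[i, r + 1] == 1:
                    ll += np.log1p(-eps[i])
                else:
                    ll += _log(eps[i])
    return ll


@njit(cache=True)
def _det_ll_year(z, ysum, J, t, pt):
    n = z.shape[0]
    lp = _log(pt)
    l1p = np.log1p(-pt)
    ll = 0.0
    for i in range(n):
        if J[i, t] > 0 and z[i, t] == 1:
            ll += ysum[i, t] * lp + (J[i, t] - ysum[i, t]) * l1p
    return ll


@njit(cache=True)
def _det_ll_total(z, ysum, J, p):
    T = z.shape[1]
    ll = 0.0
    for t in range(T):
        ll += _det_ll_year(z, ysum, J, t, p[t])
    return ll


@njit(cache=True)
def _init_ll(z, psi1):
    n = z.shape[0]
    s = 0
    for i in range(n):
        s += z[i, 0]
    return s * _log(psi1) + (n - s) * np.log1p(-psi1)


@njit(cache=True)
def _z_sweep(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, weighted):
    """One Gibbs sweep over all free latent states; maintains Cw in place."""
    n, T = z.shape
    for t in range(T):
        r_out = t  # transition leaving year t (into t+1)
        for i in range(n):
            if forced[i, t] == 1:
                continue
            cur = z[i, t]
            w0 = 0.0
            w1 = 0.0
            if J[i, t] > 0:
                # ysum is 0 here (otherwise forced); z=1 pays the misses
                w1 += J[i, t] * np.log1p(-p[t])
            if t == 0:
                w1 += _log(psi1)
                w0 += np.log1p(-psi1)
            else:
                if z[i, t - 1] == 1:
                    w1 += np.log1p(-eps[i])
                    w0 += _log(eps[i])
                else:
                    Crow = Cw[t - 1] if weighted == 1 else Cu[t - 1]
                    S = beta_tr[t - 1] * Crow[i]
                    w1 += _log(-np.expm1(-S))
                    w0 += -S
            if t < T - 1:
                zn = z[i, t + 1]
                # own future given z[i,t]=1 (extinction branch)
                w1 += zn * np.log1p(-eps[i]) + (1 - zn) * _log(eps[i])
                # given z[i,t]=0 (colonization branch; S_i excludes j=i)
                Crow = Cw[r_out] if weighted == 1 else Cu[r_out]
                S = beta_tr[r_out] * Crow[i]
                if zn == 1:
                    w0 += _log(-np.expm1(-S))
                else:
                    w0 += -S
                if weighted == 1:
                    # cross-patch coupling: other empty patches' colonization
                    for k in range(n):
                        if k == i or z[k, t] == 1:
                            continue
                        dk = A[i] * K[r_out, k, i]
                        Cb = Cw[r_out, k] - cur * dk
                        S0 = beta_tr[r_out] * Cb
                        S1 = beta_tr[r_out] * (Cb + dk)
                        if z[k, t + 1] == 1:
                            w0 += _log(-np.expm1(-S0))
                            w1 += _log(-np.expm1(-S1))
                        else:
                            w0 += -S0
                            w1 += -S1
            p1 = 1.0 / (1.0 + np.exp(min(max(w0 - w1, -700.0), 700.0)))
            new = 1 if np.random.random() < p1 else 0
            if new != cur:
                z[i, t] = new
                if t < T - 1:
                    sgn = float(new - cur)
                    for k in range(n):
                        if k != i:
                            Cw[r_out, k] += sgn * A[i] * K[r_out, k, i]
    return None


@njit(cache=True)
def _row_flip_sweep(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, weighted):
    """MH move flipping a patch's whole trajectory z[i, :] -> 1 - z[i, :].

    Single-site Gibbs can stall in quasi-absorbing corners of the prior
    (e.g. extinction ~ 0 with an empty network: occupying year t is blocked
    unless year t+1 flips too).  The involution proposal is symmetric, so
    the acceptance ratio is the joint-density ratio of the terms touching
    patch i: its initial state, detection record, own transitions, and —
    for weighted models — every other empty patch's colonization factor.
    """
    n, T = z.shape
    R = T - 1
    for i in range(n):
        blocked = False
        for t in range(T):
            if forced[i, t] == 1:
                blocked = True
                break
        if blocked:
            continue
        dlp = 0.0
        # initial year and detection terms
        d_init = _log(psi1) - np.log1p(-psi1)
        dlp += (1 - 2.0 * z[i, 0]) * d_init
        for t in range(T):
            if J[i, t] > 0:
                dlp += (1 - 2.0 * z[i, t]) * J[i, t] * np.log1p(-p[t])
        # own transitions (S_i excludes the patch itself, so gamma_i is
        # unchanged by the flip)
        for r in range(R):
            Crow = Cw[r] if weighted == 1 else Cu[r]
            S = beta_tr[r] * Crow[i]
            lg1 = _log(-np.expm1(-S))
            zo, zn_ = z[i, r], 1 - z[i, r]
            wo, wn = z[i, r + 1], 1 - z[i, r + 1]
            if zo == 1:
                old = np.log1p(-eps[i]) if wo == 1 else _log(eps[i])
            else:
                old = lg1 if wo == 1 else -S
            if zn_ == 1:
                new = np.log1p(-eps[i]) if wn == 1 else _log(eps[i])
            else:
                new = lg1 if wn == 1 else -S
            dlp += new - old
        # cross-patch colonization factors
        if weighted == 1:
            for r in range(R):
                sgn = 1.0 - 2.0 * z[i, r]  # +A_i K if turning on
                for k in range(n):
                    if k == i or z[k, r] == 1:
                        continue
                    S0 = beta_tr[r] * Cw[r, k]
                    S1 = beta_tr[r] * (Cw[r, k] + sgn * A[i] * K[r, k, i])
                    if z[k, r + 1] == 1:
                        dlp += _log(-np.expm1(-S1)) - _log(-np.expm1(-S0))
                    else:
                        dlp += S0 - S1
        if np.log(np.random.random()) < dlp:
            for t in range(T):
                z[i, t] = 1 - z[i, t]
            for r in range(R):
                sgn = 2.0 * z[i, r] - 1.0  # new state already written
                for k in range(n):
                    if k != i:
                        Cw[r, k] += sgn * A[i] * K[r, k, i]
    return None


@njit(cache=True)
def _prior_refresh(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, weighted):
    """Independence MH move: propose a fresh trajectory from the process prior.

    The proposal forward-simulates the occupancy chain under the current
    parameters, so the process factors cancel and the acceptance ratio is
    the detection-likelihood ratio alone.  This bridges macroscopic basins
    (e.g. all-occupied vs all-empty networks in low-extinction corners)
    that no local move can cross; with informative data it is simply
    rejected most of the time.
    """
    n, T = z.shape
    R = T - 1
    znew = np.empty((n, T), dtype=np.int8)
    for i in range(n):
        znew[i, 0] = 1 if np.random.random() < psi1 else 0
    for r in range(R):
        for i in range(n):
            if znew[i, r] == 1:
                pr = 1.0 - eps[i]
            else:
                S = 0.0
                for j in range(n):
                    if j != i and (weighted == 0 or znew[j, r] == 1):
                        S += A[j] * K[r, i, j]
                pr = -np.expm1(-beta_tr[r] * S)
            znew[i, r + 1] = 1 if np.random.random() < pr else 0
    dlp = 0.0
    ok = True
    for i in range(n):
        for t in range(T):
            if forced[i, t] == 1 and znew[i, t] == 0:
                ok = False
                break
        if not ok:
            break
    if ok:
        for t in range(T):
            dlp += _det_ll_year(znew, ysum, J, t, p[t]) - _det_ll_year(
                z, ysum, J, t, p[t]
            )
        if np.log(np.random.random()) < dlp:
            z[:, :] = znew
            _connect_into(K, A, z, Cw, Cu)
    return None


@njit(cache=True)
def run_z_gibbs(
    A, D, ysum, J, forced, weighted, alpha_tr, beta_tr, eps, p, psi1, n_sweeps, seed
):
    """Gibbs sampling of z alone under fixed parameters.

    Returns the visited configuration index (bit-packed z, row-major) after
    every sweep — the raw material for comparing against an exhaustive
    enumeration of the latent posterior on tiny problems.
    """
    np.random.seed(seed)
    n, T = forced.shape
    R = T - 1
    z = np.ones((n, T), dtype=np.int8)
    K = np.empty((R, n, n))
    _kernels_into(D, alpha_tr, K)
    Cw = np.empty((R, n))
    Cu = np.empty((R, n))
    _connect_into(K, A, z, Cw, Cu)
    out = np.empty(n_sweeps, dtype=np.int64)
    for s in range(n_sweeps):
        _z_sweep(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, weighted)
        _row_flip_sweep(
            z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, weighted
        )
        _prior_refresh(
            z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, weighted
        )
        code = 0
        for i in range(n):
            for t in range(T):
                code = code * 2 + z[i, t]
        out[s] = code
    return out


@njit(cache=True)
def _norm_logpdf(x, m, s):
    return -0.5 * ((x - m) / s) ** 2 - np.log(s)


@njit(cache=True)
def _eff_rates(la, lb, ea, eb, ID, alpha_tr, beta_tr):
    R = ea.shape[0]
    for r in range(R):
        alpha_tr[r] = np.exp(la + ea[r] * ID)
        beta_tr[r] = np.exp(lb + eb[r] * ID)


@njit(cache=True)
def run_chain(
    A,
    D,
    ysum,
    J,
    forced,
    weighted,
    time_varying,
    gvs,
    pp_ea_m,
    pp_ea_s,
    pp_eb_m,
    pp_eb_s,
    pp_ls_m,
    pp_ls_s,
    rho_iz,
    priors,
    n_iter,
    n_burn,
    thin,
    seed,
):
    """One MCMC chain; returns (draws, z_draws, acceptance fractions).

    ``weighted``/``time_varying`` are the fixed indicator values when
    ``gvs == 0`` and the initial values when ``gvs == 1``.  ``priors`` is
    [delta_sd, alpha_hi, beta_hi, sigma_hi, mup_sd, sigp_hi].
    """
    np.random.seed(seed)
    n, T = forced.shape
    R = T - 1
    delta_sd, alpha_hi, beta_hi, sigma_hi, mup_sd, sigp_hi = (
        priors[0], priors[1], priors[2], priors[3], priors[4], priors[5],
    )

    # ---- state initialisation (z = 1 everywhere is always supported)
    z = np.ones((n, T), dtype=np.int8)
    psi1 = 0.5
    d0 = 0.0
    d1 = 0.0
    la = np.log(0.5)
    lb = np.log(0.1)
    lsa = np.log(0.3)
    lsb = np.log(0.3)
    mu_p = 1.0
    lsp = np.log(0.5)
    ea = np.zeros(R)
    eb = np.zeros(R)
    lp = np.full(T, mu_p)
    Iz = weighted
    ID = time_varying

    eps = np.empty(n)
    for i in range(n):
        eps[i] = _expit(d0 + d1 * A[i])
    p = np.empty(T)
    for t in range(T):
        p[t] = _expit(lp[t])
    alpha_tr = np.empty(R)
    beta_tr = np.empty(R)
    _eff_rates(la, lb, ea, eb, ID, alpha_tr, beta_tr)
    K = np.empty((R, n, n))
    _kernels_into(D, alpha_tr, K)
    Cw = np.empty((R, n))
    Cu = np.empty((R, n))
    _connect_into(K, A, z, Cw, Cu)
    # scratch for proposals
    Kp = np.empty((R, n, n))
    Cwp = np.empty((R, n))
    Cup = np.empty((R, n))
    atr_p = np.empty(R)
    btr_p = np.empty(R)
    eps_p = np.empty(n)

    # ---- adaptation bookkeeping
    scal = np.full(N_SCAL, 0.3)
    scal_lp = np.full(T, 0.5)
    scal_ea = np.full(R, 0.3)
    scal_eb = np.full(R, 0.3)
    win = 50
    acc_w = np.zeros(N_SCAL)
    acc_w_lp = np.zeros(T)
    acc_w_ea = np.zeros(R)
    acc_w_eb = np.zeros(R)
    acc_post = np.zeros(N_SCAL + 3)
    try_post = np.zeros(N_SCAL + 3)

    n_cols = N_FIXED_COLS + T + 2 * R
    n_save = (n_iter - n_burn) // thin
    draws = np.empty((n_save, n_cols))
    z_draws = np.empty((n_save, n, T), dtype=np.int8)
    saved = 0

    for it in range(n_iter):
        adapting = it < n_burn
        # ---- 1. latent states: single-site Gibbs plus trajectory-flip MH
        _z_sweep(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, Iz)
        _row_flip_sweep(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, Iz)
        _prior_refresh(z, forced, ysum, J, A, K, Cw, Cu, beta_tr, eps, p, psi1, Iz)
        C = Cw if Iz == 1 else Cu

        # ---- 2. psi1 (conjugate Beta under the uniform prior)
        s1 = 0.0
        for i in range(n):
            s1 += z[i, 0]
        psi1 = np.random.beta(1.0 + s1, 1.0 + n - s1)

        # ---- 3. extinction regression delta0, delta1
        for which in range(2):
            slot = SC_D0 + which
            if which == 0:
                d0p, d1p = d0 + scal[slot] * np.random.normal(), d1
            else:
                d0p, d1p = d0, d1 + scal[slot] * np.random.normal()
            for i in range(n):
                eps_p[i] = _expit(d0p + d1p * A[i])
            dlp = (
                _ext_ll_total(z, eps_p)
                - _ext_ll_total(z, eps)
                + _norm_logpdf(d0p, 0.0, delta_sd)
                - _norm_logpdf(d0, 0.0, delta_sd)
                + _norm_logpdf(d1p, 0.0, delta_sd)
                - _norm_logpdf(d1, 0.0, delta_sd)
            )
            acc = np.log(np.random.random()) < dlp
            if acc:
                d0, d1 = d0p, d1p
                eps[:] = eps_p
            if adapting:
                acc_w[slot] += 1.0 if acc else 0.0
            else:
                try_post[slot] += 1
                acc_post[slot] += 1.0 if acc else 0.0

        # ---- 4. kernel scale alpha (log scale, uniform natural-scale prior)
        lap = la + scal[SC_LA] * np.random.normal()
        if np.exp(lap) < alpha_hi:
            _eff_rates(lap, lb, ea, eb, ID, atr_p, btr_p)
            _kernels_into(D, atr_p, Kp)
            _connect_into(Kp, A, z, Cwp, Cup)
            Cp = Cwp if Iz == 1 else Cup
            dlp = (
                _col_ll_total(z, Cp, btr_p)
                - _col_ll_total(z, C, beta_tr)
                + (lap - la)  # Jacobian of the log transform
            )
            acc = np.log(np.random.random()) < dlp
            if acc:
                la = lap
                alpha_tr[:] = atr_p
                K[:] = Kp
                Cw[:] = Cwp
                Cu[:] = Cup
                C = Cw if Iz == 1 else Cu
        else:
            acc = False
        if adapting:
            acc_w[SC_LA] += 1.0 if acc else 0.0
        else:
            try_post[SC_LA] += 1
            acc_post[SC_LA] += 1.0 if acc else 0.0

        # ---- 5. dispersal rate beta (no kernel change)
        lbp = lb + scal[SC_LB] * np.random.normal()
        if np.exp(lbp) < beta_hi:
            _eff_rates(la, lbp, ea, eb, ID, atr_p, btr_p)
            dlp = (
                _col_ll_total(z, C, btr_p)
                - _col_ll_total(z, C, beta_tr)
                + (lbp - lb)
            )
            acc = np.log(np.random.random()) < dlp
            if acc:
                lb = lbp
                beta_tr[:] = btr_p
        else:
            acc = False
        if adapting:
            acc_w[SC_LB] += 1.0 if acc else 0.0
        else:
            try_post[SC_LB] += 1
            acc_post[SC_LB] += 1.0 if acc else 0.0

        # ---- 6. year-specific dispersal deviates
        if time_varying == 1 or gvs == 1:
            sa = np.exp(lsa)
            sb = np.exp(lsb)
            if ID == 1:
                for r in range(R):
                    # ea[r]: kernel of transition r changes
                    eap = ea[r] + scal_ea[r] * np.random.normal()
                    a_new = np.exp(la + eap)
                    _kernel_into(D, a_new, Kp[0])
                    for i in range(n):
                        sw = 0.0
                        su = 0.0
                        for j in range(n):
                            aj = A[j] * Kp[0, i, j]
                            su += aj
                            if z[j, r] == 1:
                                sw += aj
                        Cwp[0, i] = sw
                        Cup[0, i] = su
                    Crow_p = Cwp[0] if Iz == 1 else Cup[0]
                    dlp = (
                        _col_ll_r(z, r, Crow_p, beta_tr[r])
                        - _col_ll_r(z, r, C[r], beta_tr[r])
                        + _norm_logpdf(eap, 0.0, sa)
                        - _norm_logpdf(ea[r], 0.0, sa)
                    )
                    acc = np.log(np.random.random()) < dlp
                    if acc:
                        ea[r] = eap
                        alpha_tr[r] = a_new
                        K[r, :, :] = Kp[0]
                        Cw[r, :] = Cwp[0]
                        Cu[r, :] = Cup[0]
                    if adapting:
                        acc_w_ea[r] += 1.0 if acc else 0.0
                    else:
                        try_post[N_SCAL + 1] += 1
                        acc_post[N_SCAL + 1] += 1.0 if acc else 0.0
                    # eb[r]: only the rate changes
                    ebp = eb[r] + scal_eb[r] * np.random.normal()
                    b_new = np.exp(lb + ebp)
                    dlp = (
                        _col_ll_r(z, r, C[r], b_new)
                        - _col_ll_r(z, r, C[r], beta_tr[r])
                        + _norm_logpdf(ebp, 0.0, sb)
                        - _norm_logpdf(eb[r], 0.0, sb)
                    )
                    acc = np.log(np.random.random()) < dlp
                    if acc:
                        eb[r] = ebp
                        beta_tr[r] = b_new
                    if adapting:
                        acc_w_eb[r] += 1.0 if acc else 0.0
                    else:
                        try_post[N_SCAL + 2] += 1
                        acc_post[N_SCAL + 2] += 1.0 if acc else 0.0
            else:
                # deactivated block: Gibbs refresh from the pseudo-priors
                for r in range(R):
                    ea[r] = pp_ea_m[r] + pp_ea_s[r] * np.random.normal()
                    eb[r] = pp_eb_m[r] + pp_eb_s[r] * np.random.normal()

            # ---- 7. random-effect SDs (uniform priors on the natural scale);
            # deactivated under GVS they are refreshed from their pseudo-prior
            # so they cannot drift and jam the indicator
            if gvs == 1 and ID == 0:
                lsa = pp_ls_m[0] + pp_ls_s[0] * np.random.normal()
                lsb = pp_ls_m[1] + pp_ls_s[1] * np.random.normal()
            else:
                for which in range(2):
                    slot = SC_LSA + which
                    cur_ls = lsa if which == 0 else lsb
                    lsx = cur_ls + scal[slot] * np.random.normal()
                    if np.exp(lsx) < sigma_hi:
                        dlp = lsx - cur_ls
                        dev = ea if which == 0 else eb
                        s_old = np.exp(cur_ls)
                        s_new = np.exp(lsx)
                        for r in range(R):
                            dlp += _norm_logpdf(dev[r], 0.0, s_new) - _norm_logpdf(
                                dev[r], 0.0, s_old
                            )
                        acc = np.log(np.random.random()) < dlp
                        if acc:
                            if which == 0:
                                lsa = lsx
                            else:
                                lsb = lsx
                    else:
                        acc = False
                    if adapting:
                        acc_w[slot] += 1.0 if acc else 0.0
                    else:
                        try_post[slot] += 1
                        acc_post[slot] += 1.0 if acc else 0.0

        # ---- 8. detection: p_t, mu_p (conjugate), sigma_p
        sp = np.exp(lsp)
        for t in range(T):
            lpp = lp[t] + scal_lp[t] * np.random.normal()
            pnew = _expit(lpp)
            dlp = (
                _det_ll_year(z, ysum, J, t, pnew)
                - _det_ll_year(z, ysum, J, t, p[t])
                + _norm_logpdf(lpp, mu_p, sp)
                - _norm_logpdf(lp[t], mu_p, sp)
            )
            acc = np.log(np.random.random()) < dlp
            if acc:
                lp[t] = lpp
                p[t] = pnew
            if adapting:
                acc_w_lp[t] += 1.0 if acc else 0.0
            else:
                try_post[N_SCAL] += 1
                acc_post[N_SCAL] += 1.0 if acc else 0.0
        prec = 1.0 / mup_sd**2 + T / sp**2
        mean = (np.sum(lp) / sp**2) / prec
        mu_p = mean + np.random.normal() / np.sqrt(prec)
        lspp = lsp + scal[SC_LSP] * np.random.normal()
        if np.exp(lspp) < sigp_hi:
            sp_new = np.exp(lspp)
            dlp = lspp - lsp
            for t in range(T):
                dlp += _norm_logpdf(lp[t], mu_p, sp_new) - _norm_logpdf(
                    lp[t], mu_p, sp
                )
            acc = np.log(np.random.random()) < dlp
            if acc:
                lsp = lspp
        else:
            acc = False
        if adapting:
            acc_w[SC_LSP] += 1.0 if acc else 0.0
        else:
            try_post[SC_LSP] += 1
            acc_post[SC_LSP] += 1.0 if acc else 0.0

        # ---- 9. Gibbs variable selection indicators
        if gvs == 1:
            # I_z: joint proposal flipping the weighting branch while
            # rescaling beta by the occupancy fraction rho (weighted sums are
            # ~rho of the structural ones, so beta must change scale for the
            # other branch to be competitive); deterministic bijection on
            # log-beta, unit Jacobian there, reduces to a Gibbs likelihood-
            # ratio update when rho = 1
            lbp = lb + (np.log(rho_iz) if Iz == 1 else -np.log(rho_iz))
            if np.exp(lbp) < beta_hi:
                Cp = Cu if Iz == 1 else Cw
                _eff_rates(la, lbp, ea, eb, ID, atr_p, btr_p)
                d_iz = (
                    _col_ll_total(z, Cp, btr_p)
                    - _col_ll_total(z, C, beta_tr)
                    + (lbp - lb)
                )
                if np.log(np.random.random()) < d_iz:
                    Iz = 1 - Iz
                    lb = lbp
                    beta_tr[:] = btr_p
                    C = Cw if Iz == 1 else Cu

            # I_D: time-varying vs static dispersal; deactivated deviates sit
            # under the pseudo-prior, active ones under the hierarchical prior
            sa = np.exp(lsa)
            sb = np.exp(lsb)
            prior1 = 0.0
            prior0 = 0.0
            for r in range(R):
                prior1 += _norm_logpdf(ea[r], 0.0, sa) + _norm_logpdf(eb[r], 0.0, sb)
                prior0 += _norm_logpdf(ea[r], pp_ea_m[r], pp_ea_s[r])
                prior0 += _norm_logpdf(eb[r], pp_eb_m[r], pp_eb_s[r])
            if sa < sigma_hi and sb < sigma_hi:
                # SD priors: uniform natural scale (log-scale density e^ls/hi)
                prior1 += lsa + lsb - 2.0 * np.log(sigma_hi)
            else:
                prior1 += -np.inf
            prior0 += _norm_logpdf(lsa, pp_ls_m[0], pp_ls_s[0])
            prior0 += _norm_logpdf(lsb, pp_ls_m[1], pp_ls_s[1])
            if ID == 1:
                ll1 = _col_ll_total(z, C, beta_tr)
                # static branch: single kernel
                _kernel_into(D, np.exp(la), Kp[0])
                for r in range(R):
                    Kp[r, :, :] = Kp[0]
                _connect_into(Kp, A, z, Cwp, Cup)
                Cp = Cwp if Iz == 1 else Cup
                for r in range(R):
                    btr_p[r] = np.exp(lb)
                ll0 = _col_ll_total(z, Cp, btr_p)
            else:
                ll0 = _col_ll_total(z, C, beta_tr)
                _eff_rates(la, lb, ea, eb, 1, atr_p, btr_p)
                _kernels_into(D, atr_p, Kp)
                _connect_into(Kp, A, z, Cwp, Cup)
                Cp = Cwp if Iz == 1 else Cup
                ll1 = _col_ll_total(z, Cp, btr_p)
            d_id = (ll1 + prior1) - (ll0 + prior0)
            pr1 = 1.0 / (1.0 + np.exp(min(max(-d_id, -700.0), 700.0)))
            ID_new = 1 if np.random.random() < pr1 else 0
            if ID_new != ID:
                ID = ID_new
                K[:] = Kp
                Cw[:] = Cwp
                Cu[:] = Cup
                _eff_rates(la, lb, ea, eb, ID, alpha_tr, beta_tr)
                C = Cw if Iz == 1 else Cu

        # ---- adaptation (burn-in only)
        if adapting and (it + 1) % win == 0:
            step = min(0.1, 1.0 / np.sqrt((it + 1) / win))
            for s in range(N_SCAL):
                scal[s] *= np.exp(step if acc_w[s] / win > 0.44 else -step)
                acc_w[s] = 0.0
            for t in range(T):
                scal_lp[t] *= np.exp(step if acc_w_lp[t] / win > 0.44 else -step)
                acc_w_lp[t] = 0.0
            for r in range(R):
                scal_ea[r] *= np.exp(step if acc_w_ea[r] / win > 0.44 else -step)
                acc_w_ea[r] = 0.0
                scal_eb[r] *= np.exp(step if acc_w_eb[r] / win > 0.44 else -step)
                acc_w_eb[r] = 0.0

        # ---- save
        if it >= n_burn and (it - n_burn) % thin == 0:
            ll = (
                _init_ll(z, psi1)
                + _ext_ll_total(z, eps)
                + _col_ll_total(z, C, beta_tr)
                + _det_ll_total(z, ysum, J, p)
            )
            row = draws[saved]
            row[COL_PSI1] = psi1
            row[COL_D0] = d0
            row[COL_D1] = d1
            row[COL_ALPHA] = np.exp(la)
            row[COL_BETA] = np.exp(lb)
            row[COL_SA] = np.exp(lsa)
            row[COL_SB] = np.exp(lsb)
            row[COL_MUP] = mu_p
            row[COL_SP] = np.exp(lsp)
            row[COL_IZ] = Iz
            row[COL_ID] = ID
            row[COL_LL] = ll
            for t in range(T):
                row[N_FIXED_COLS + t] = p[t]
            for r in range(R):
                row[N_FIXED_COLS + T + r] = alpha_tr[r]
                row[N_FIXED_COLS + T + R + r] = beta_tr[r]
            z_draws[saved] = z
            saved += 1

    for s in range(N_SCAL + 3):
        if try_post[s] > 0:
            acc_post[s] /= try_post[s]
    return draws, z_draws, acc_post
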