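"""Numba-compiled hot loops of the Gibbs sampler.

All kernels mutate their array arguments in place and draw from numba's own
``np.random`` stream, which :func:`seed_kernels` seeds once per chain.  The
residual matrix ``E`` (kits x traits) is kept consistent incrementally: every
accepted scalar draw subtracts its change from the affected rows.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernels(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _std_trunc_lower(a):
    """Standard normal conditioned on z > a; Robert's exponential rejection
    for a > 0, plain rejection otherwise (acceptance >= 1/2 there)."""
    if a <= 0.0:
        while True:
            z = np.random.standard_normal()
            if z > a:
                return z
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a + np.random.exponential(1.0 / alpha)
        d = z - alpha
        if np.random.random() <= math.exp(-0.5 * d * d):
            return z


@njit(cache=True, inline="always")
def draw_gt0(mu, sd):
    """N(mu, sd^2) conditioned on being > 0."""
    return mu + sd * _std_trunc_lower(-mu / sd)


@njit(cache=True, inline="always")
def draw_le0(mu, sd):
    """N(mu, sd^2) conditioned on being <= 0."""
    return mu - sd * _std_trunc_lower(mu / sd)


@njit(cache=True, inline="always")
def _draw_interval(mu, sd, lo, hi):
    """Normal draw, optionally truncated to [lo, hi] (wide-bound use only)."""
    if lo == -np.inf and hi == np.inf:
        return mu + sd * np.random.standard_normal()
    for _ in range(64):
        z = mu + sd * np.random.standard_normal()
        if lo <= z <= hi:
            return z
    # bounds far in a tail: one-sided draw from the nearer bound
    if mu < lo:
        z = lo + sd * _std_trunc_lower(0.0)
    else:
        z = hi - sd * _std_trunc_lower(0.0)
    return min(max(z, lo), hi)


@njit(cache=True)
def pedigree_prior_draw(sire, dam, mend_var, lg, z):
    """Draw a ~ N(0, A (x) G0) down a sorted pedigree.

    ``mend_var`` holds each animal's Mendelian-sampling variance d_i (the
    diagonal of the generalized Cholesky of A), ``lg`` the Cholesky factor
    of G0, ``z`` iid standard normals of shape (n_animals, n_traits).
    """
    n, t = z.shape
    a = np.zeros((n, t))
    for i in range(n):
        dev = np.sqrt(mend_var[i])
        for r in range(t):
            acc = 0.0
            for s in range(r + 1):
                acc += lg[r, s] * z[i, s]
            a[i, r] = dev * acc
            if sire[i] >= 0:
                a[i, r] += 0.5 * a[sire[i], r]
            if dam[i] >= 0:
                a[i, r] += 0.5 * a[dam[i], r]
    return a


@njit(cache=True)
def sweep_liabilities(y, e, status, is_binary, lam):
    """Redraw augmented cells from their full conditionals.

    Binary cells are truncated at the (zero) threshold by their status code
    (2 alive -> positive, 1 dead -> non-positive, 0 missing -> untruncated);
    Gaussian cells are redrawn untruncated only when missing (status 0).
    The conditional regresses on the kit's other-trait residuals via the
    residual precision ``lam = inv(R0)``.
    """
    n, n_tr = y.shape
    for i in range(n):
        for t in range(n_tr):
            code = status[i, t]
            if not is_binary[t] and code == 3:
                continue
            vt = 1.0 / lam[t, t]
            corr = 0.0
            for s in range(n_tr):
                if s != t:
                    corr += lam[t, s] * e[i, s]
            fit = y[i, t] - e[i, t]
            mu = fit - vt * corr
            sd = math.sqrt(vt)
            if is_binary[t] and code == 2:
                z = draw_gt0(mu, sd)
            elif is_binary[t] and code == 1:
                z = draw_le0(mu, sd)
            else:
                z = mu + sd * np.random.standard_normal()
            y[i, t] = z
            e[i, t] = z - fit


@njit(cache=True)
def _sweep_group(e, u, lam, u0i, gp, gi):
    """Single-site draws for an iid random-effect block (maternal or litter):
    prior u_g ~ N(0, U0), likelihood through the kit rows listed in the
    CSC-style (gp, gi) group->kits mapping."""
    n_tr = e.shape[1]
    for g in range(u.shape[0]):
        for t in range(n_tr):
            ltt = lam[t, t]
            s1 = 0.0
            cnt = 0.0
            for k in range(gp[g], gp[g + 1]):
                i = gi[k]
                dot = 0.0
                for s in range(n_tr):
                    dot += lam[t, s] * e[i, s]
                s1 += dot
                cnt += 1.0
            rhs_prior = 0.0
            for s in range(n_tr):
                if s != t:
                    rhs_prior -= u0i[t, s] * u[g, s]
            old = u[g, t]
            prec = ltt * cnt + u0i[t, t]
            mu = (s1 + old * ltt * cnt + rhs_prior) / prec
            new = mu + np.random.standard_normal() / math.sqrt(prec)
            diff = new - old
            if diff != 0.0:
                for k in range(gp[g], gp[g + 1]):
                    e[gi[k], t] -= diff
            u[g, t] = new


@njit(cache=True)
def sweep_doe_blocks(e, m, c, lam, m0i, c0i,
                     dlp, dli,      # doe -> litters (CSC-style)
                     ckp, cki,      # litter -> kit rows
                     litter_doe):   # litter -> doe index
    """Joint redraw of each doe's maternal effect together with all her
    litters' effects from their exact multivariate Gaussian conditional.

    The maternal and litter variance components are near-exchangeable when
    litters-per-doe is small; scalar updates then mix the m/c split very
    slowly and can stick in a mis-attributed mode.  Does are conditionally
    independent given everything else, so this is an exact per-doe block of
    dimension (1 + L) x n_traits.
    """
    n_tr = e.shape[1]
    for d in range(m.shape[0]):
        n_lit = dlp[d + 1] - dlp[d]
        dim = n_tr * (1 + n_lit)
        prec = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        for t in range(n_tr):
            for s in range(n_tr):
                prec[t, s] = m0i[t, s]
        for j in range(n_lit):
            l = dli[dlp[d] + j]
            o = n_tr * (1 + j)
            nk = float(ckp[l + 1] - ckp[l])
            for t in range(n_tr):
                for s in range(n_tr):
                    prec[o + t, o + s] = c0i[t, s] + nk * lam[t, s]
                    prec[t, s] += nk * lam[t, s]
                    prec[t, o + s] += nk * lam[t, s]
                    prec[o + t, s] += nk * lam[t, s]
            for k in range(ckp[l], ckp[l + 1]):
                i = cki[k]
                for t in range(n_tr):
                    dot = 0.0
                    for s in range(n_tr):
                        dot += lam[t, s] * (e[i, s] + m[d, s] + c[l, s])
                    rhs[t] += dot
                    rhs[o + t] += dot
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        z = np.empty(dim)
        for k in range(dim):
            z[k] = np.random.standard_normal()
        # solve chol.T x = z for the fluctuation
        x = np.linalg.solve(chol.T, z)
        u = mean + x
        m_new = u[:n_tr]
        for j in range(n_lit):
            l = dli[dlp[d] + j]
            o = n_tr * (1 + j)
            for k in range(ckp[l], ckp[l + 1]):
                i = cki[k]
                for t in range(n_tr):
                    e[i, t] += (m[d, t] + c[l, t]) - (m_new[t] + u[o + t])
            for t in range(n_tr):
                c[l, t] = u[o + t]
        for t in range(n_tr):
            m[d, t] = m_new[t]


@njit(cache=True)
def sweep_locations(e, b, a, m, c, lam, g0i, m0i, c0i,
                    xp, xi, xv, xsq,
                    ap, ai, av, adiag,
                    akp, aki, mkp, mki, ckp, cki,
                    blo, bhi):
    """One Gauss-Seidel sweep over all location effects.

    Order: fixed effects (flat prior, optional bounds), additive genetic
    values for every pedigree animal (prior precision A^-1 (x) G0^-1, sparse
    CSR in ap/ai/av with cached diagonal adiag), then maternal and litter
    blocks.  (xp, xi, xv) is the CSC fixed design with column squared norms
    xsq; (akp, aki) maps animal -> kit rows.
    """
    n_tr = e.shape[1]
    # fixed effects
    for t in range(n_tr):
        ltt = lam[t, t]
        for j in range(b.shape[0]):
            if xsq[j] <= 0.0:
                continue
            s1 = 0.0
            for k in range(xp[j], xp[j + 1]):
                i = xi[k]
                dot = 0.0
                for s in range(n_tr):
                    dot += lam[t, s] * e[i, s]
                s1 += xv[k] * dot
            prec = ltt * xsq[j]
            old = b[j, t]
            mu = (s1 + old * prec) / prec
            sd = 1.0 / math.sqrt(prec)
            new = _draw_interval(mu, sd, blo, bhi)
            diff = new - old
            if diff != 0.0:
                for k in range(xp[j], xp[j + 1]):
                    e[xi[k], t] -= diff * xv[k]
            b[j, t] = new
    # additive genetic values (all pedigree animals, phenotyped or not)
    for k0 in range(a.shape[0]):
        for t in range(n_tr):
            ltt = lam[t, t]
            s1 = 0.0
            cnt = 0.0
            for k in range(akp[k0], akp[k0 + 1]):
                i = aki[k]
                dot = 0.0
                for s in range(n_tr):
                    dot += lam[t, s] * e[i, s]
                s1 += dot
                cnt += 1.0
            tsum = 0.0
            for k in range(ap[k0], ap[k0 + 1]):
                l = ai[k]
                dot = 0.0
                for s in range(n_tr):
                    dot += g0i[t, s] * a[l, s]
                tsum += av[k] * dot
            old = a[k0, t]
            dpre = adiag[k0] * g0i[t, t]
            prec = ltt * cnt + dpre
            mu = (s1 + old * ltt * cnt - (tsum - dpre * old)) / prec
            new = mu + np.random.standard_normal() / math.sqrt(prec)
            diff = new - old
            if diff != 0.0:
                for k in range(akp[k0], akp[k0 + 1]):
                    e[aki[k], t] -= diff
            a[k0, t] = new
    _sweep_group(e, m, lam, m0i, mkp, mki)
    _sweep_group(e, c, lam, c0i, ckp, cki)
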