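"""Compiled numerical kernels for the interference likelihood.

The model here is identical to :mod:`gammaxo.likelihood`; only the
numerics differ. Per parameter proposal the kernel tabulates log f* and
log S* = log(1 - F*) on a uniform grid and evaluates records by cubic
Hermite interpolation with exact derivatives; points in the short-distance
region (below ``_Y_EXACT`` Morgans), where log f* has a log-singularity,
are evaluated by the exact series instead. Zero-crossover probabilities
use the closed-form term-by-term integral of the series CDF.

scipy's incomplete-gamma functions are not callable from nopython code,
so regularized P(a, x)/Q(a, x) are implemented here (power series and
Lentz continued fraction); they are validated against scipy.special in
the test suite.
"""

import math

import numpy as np
from numba import njit

# Below this distance (Morgans) interpolation of log f* is replaced by the
# exact series: the (nu-1)*log y singularity makes polynomial panels
# inaccurate there, and such short distances are rare under interference.
_Y_EXACT = 0.02

_LOG_TINY = -745.0  # log of the smallest positive double, with margin


@njit(cache=True)
def _gammap(a, x):
    """Regularized lower incomplete gamma P(a, x)."""
    if x <= 0.0:
        return 0.0
    if x < a + 1.0:
        ap = a
        s = 1.0 / a
        delt = s
        for _ in range(1000):
            ap += 1.0
            delt *= x / ap
            s += delt
            if abs(delt) < abs(s) * 1e-16:
                break
        lg = -x + a * math.log(x) - math.lgamma(a)
        if lg < _LOG_TINY:
            return 0.0
        return s * math.exp(lg)
    return 1.0 - _gammaq_cf(a, x)


@njit(cache=True)
def _gammaq_cf(a, x):
    """Regularized upper incomplete gamma Q(a, x) for x >= a + 1
    (modified Lentz continued fraction)."""
    fpmin = 1e-300
    b = x + 1.0 - a
    c = 1.0 / fpmin
    d = 1.0 / b
    h = d
    for i in range(1, 1000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < fpmin:
            d = fpmin
        c = b + an / c
        if abs(c) < fpmin:
            c = fpmin
        d = 1.0 / d
        de = d * c
        h *= de
        if abs(de - 1.0) < 1e-16:
            break
    lg = -x + a * math.log(x) - math.lgamma(a)
    if lg < _LOG_TINY:
        return 0.0
    return math.exp(lg) * h


@njit(cache=True)
def _gammaq(a, x):
    if x <= 0.0:
        return 1.0
    if x < a + 1.0:
        return 1.0 - _gammap(a, x)
    return _gammaq_cf(a, x)


@njit(cache=True)
def _exact_point(nu, b, y):
    """Exact series evaluation at one distance y > 0.

    Returns (S*, log f*, dlog f*/dy). The survival series is closed with
    its geometric tail once Q(k nu, b y) saturates at 1.
    """
    x = b * y
    logy = math.log(y)
    logb = math.log(b)
    S = 0.0
    m = -1.0e308  # running max for the log-sum-exp of the density series
    sf = 0.0  # sum exp(lterm - m)
    sd = 0.0  # sum exp(lterm - m) * ((a-1)/y - b)
    w = 1.0
    k = 0
    while k < 500:
        k += 1
        w *= 0.5
        a = k * nu
        q = _gammaq(a, x)
        S += w * q
        lterm = -k * 0.6931471805599453 + a * logb - math.lgamma(a) + (a - 1.0) * logy - x
        if lterm > m:
            scale = math.exp(m - lterm)
            sf = sf * scale + 1.0
            sd = sd * scale + ((a - 1.0) / y - b)
            m = lterm
        else:
            t = math.exp(lterm - m)
            sf += t
            sd += t * ((a - 1.0) / y - b)
        if q >= 1.0 - 1e-14 and lterm < m + math.log(sf) - 36.0:
            S += w  # tail sum_{j>k} 2^{-j} with Q_j ~ 1
            break
    if S > 1.0:
        S = 1.0
    logf = m + math.log(sf) if sf > 0.0 else -1.0e308
    dlogf = sd / sf if sf > 0.0 else 0.0
    return S, logf, dlogf


@njit(cache=True)
def _log_p0(nu, lam, L):
    """log P(no observed crossover on [0, L]) for the gamma pathway:
    1 - lam*L + lam * sum_k 2^{-k} [L P(a_k, bL) - (a_k/b) P(a_k+1, bL)]."""
    b = 2.0 * nu * lam
    x = b * L
    s = 0.0
    w = 1.0
    k = 0
    while k < 500:
        k += 1
        w *= 0.5
        a = k * nu
        p1 = _gammap(a, x)
        s += w * (L * p1 - (a / b) * _gammap(a + 1.0, x))
        if a > x and w * L * p1 < 1e-16 * max(s, 1e-300):
            break
    p0 = 1.0 - lam * L + lam * s
    if p0 < 1e-300:
        p0 = 1e-300
    elif p0 > 1.0:
        p0 = 1.0
    return math.log(p0)


@njit(cache=True)
def _build_tables(nu, b, dy, M):
    """Tabulate log S*, dlogS*/dy, log f*, dlogf*/dy at y_i = i*dy."""
    logS = np.zeros(M + 1)
    dlogS = np.zeros(M + 1)
    logf = np.full(M + 1, -1.0e308)
    dlogf = np.zeros(M + 1)
    for i in range(1, M + 1):
        S, lf, dlf = _exact_point(nu, b, i * dy)
        lS = math.log(S) if S > 0.0 else -1.0e308
        logS[i] = lS
        dlogS[i] = -math.exp(lf - lS) if lf - lS > _LOG_TINY else 0.0
        logf[i] = lf
        dlogf[i] = dlf
    return logS, dlogS, logf, dlogf


@njit(cache=True, inline="always")
def _hermite(y, dy, i, v0, v1, m0, m1):
    t = y / dy - i
    t2 = t * t
    t3 = t2 * t
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + t
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    return h00 * v0 + h10 * dy * m0 + h01 * v1 + h11 * dy * m1


@njit(cache=True)
def _logS_at(y, nu, b, dy, M, logS, dlogS):
    if y <= 0.0:
        return 0.0
    if M == 0 or y < _Y_EXACT:
        S, _, _ = _exact_point(nu, b, y)
        return math.log(S) if S > 0.0 else -1.0e308
    i = int(y / dy)
    if i >= M:
        i = M - 1
    return _hermite(y, dy, i, logS[i], logS[i + 1], dlogS[i], dlogS[i + 1])


@njit(cache=True)
def _logf_at(y, nu, b, dy, M, logf, dlogf):
    if M == 0 or y < _Y_EXACT:
        _, lf, _ = _exact_point(nu, b, y)
        return lf
    i = int(y / dy)
    if i >= M:
        i = M - 1
    return _hermite(y, dy, i, logf[i], logf[i + 1], dlogf[i], dlogf[i + 1])


@njit(cache=True)
def _pathway_ll(sub, cnt, L, loglam, lp0, nu, b, dy, M, logS, dlogS, logf, dlogf):
    """Gamma-pathway log-likelihood of the first `cnt` entries of `sub`."""
    if cnt == 0:
        return lp0
    ll = loglam + _logS_at(sub[0], nu, b, dy, M, logS, dlogS)
    for i in range(1, cnt):
        ll += _logf_at(sub[i] - sub[i - 1], nu, b, dy, M, logf, dlogf)
    ll += _logS_at(L - sub[cnt - 1], nu, b, dy, M, logS, dlogS)
    return ll


@njit(cache=True)
def cell_loglik_kernel(nu, p, pos_flat, offsets, rec_Lidx, L_unique, counts_empty, M):
    """Total log-likelihood of one group cell's records under the
    gamma-sprinkling model with parameters (nu, p).

    pos_flat/offsets pack the non-empty records' positions (Morgans);
    rec_Lidx maps each non-empty record to its length in L_unique;
    counts_empty counts zero-crossover records per unique length.
    """
    lam = 1.0 - p
    b = 2.0 * nu * lam
    nL = L_unique.size
    logp0 = np.empty(nL)
    for u in range(nL):
        logp0[u] = _log_p0(nu, lam, L_unique[u])

    total = 0.0
    for u in range(nL):
        if counts_empty[u] > 0:
            ll0 = logp0[u]
            if p > 0.0:
                ll0 -= p * L_unique[u]
            total += counts_empty[u] * ll0

    nrec = rec_Lidx.size
    if nrec == 0:
        return total

    Lmax = L_unique[0]
    for u in range(1, nL):
        if L_unique[u] > Lmax:
            Lmax = L_unique[u]
    # building tables only pays off for enough evaluation points; small
    # cells are evaluated by the exact series directly (M = 0)
    if pos_flat.size < 128:
        M = 0
    if M > 0:
        dy = Lmax / M
        logS, dlogS, logf, dlogf = _build_tables(nu, b, dy, M)
    else:
        dy = Lmax
        logS = np.zeros(1)
        dlogS = np.zeros(1)
        logf = np.zeros(1)
        dlogf = np.zeros(1)
    loglam = math.log(lam)
    logp = math.log(p) if p > 0.0 else 0.0
    sub = np.empty(24)

    for r in range(nrec):
        s0 = offsets[r]
        s1 = offsets[r + 1]
        n = s1 - s0
        L = L_unique[rec_Lidx[r]]
        lp0 = logp0[rec_Lidx[r]]
        if p == 0.0:
            for i in range(n):
                sub[i] = pos_flat[s0 + i]
            total += _pathway_ll(sub, n, L, loglam, lp0, nu, b, dy, M, logS, dlogS, logf, dlogf)
            continue
        # exact sum over all 2^n pathway assignments, log-sum-exp online
        mmax = -1.0e308
        acc = 0.0
        for mask in range(1 << n):
            cnt = 0
            for i in range(n):
                if (mask >> i) & 1:
                    sub[cnt] = pos_flat[s0 + i]
                    cnt += 1
            llg = _pathway_ll(sub, cnt, L, loglam, lp0, nu, b, dy, M, logS, dlogS, logf, dlogf)
            term = llg + (n - cnt) * logp
            if term > mmax:
                acc = acc * math.exp(mmax - term) + 1.0
                mmax = term
            else:
                acc += math.exp(term - mmax)
        total += mmax + math.log(acc) - p * L
    return total
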