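"""Compiled numerical core shared by the reference stepper and the fast loop.

Everything in here is written so the pure-Python stepper in
:mod:`sociowalk.simulator` and the whole-run :func:`advance` loop perform
bit-identical arithmetic and consume the RNG stream in exactly the same
order, which lets the test-suite assert exact trajectory equivalence.

Conventions:
  * uniform integers are drawn as ``int(rng.random() * n)``;
  * polynomial fits are performed in sensor-centred coordinates scaled to
    [-1, 1] and returned in centred (unscaled) coordinates;
  * fit quality is gated on a 1-norm condition estimate of the scaled Gram
    matrix (threshold ``COND_LIMIT``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Condition threshold on the scaled Gram (normal) matrix.  The Gram matrix
# condition is the square of the design-matrix condition, so this corresponds
# to a design-matrix condition of ~1e8.
COND_LIMIT = 1e16
# Coefficients below this magnitude are treated as exactly zero when solving
# for the potential centre (flat parabola -> line, flat line -> degenerate).
COEF_EPS = 1e-12

W_UNIFORM = 0
W_TRICUBE = 1


@njit(cache=True)
def randint_below(rng, n):
    """Uniform draw from {0, ..., n-1} via a single rng.random() call."""
    v = int(rng.random() * n)
    if v >= n:  # guard the (measure-zero) edge rng.random() == 1.0-ulp
        v = n - 1
    return v


@njit(cache=True)
def round_half_away(v):
    if v >= 0.0:
        return np.int64(np.floor(v + 0.5))
    return np.int64(np.ceil(v - 0.5))


@njit(cache=True)
def wls_polyfit_scaled(u, y, w, order):
    """Weighted LS fit of a degree-`order` polynomial (order in {1, 2}).

    `u` must already be centred and scaled to O(1).  Returns
    ``(ok, c0, c1, c2)``; ``ok`` is False when the Gram matrix is singular or
    its 1-norm condition estimate exceeds COND_LIMIT.
    """
    s0 = 0.0; s1 = 0.0; s2 = 0.0; s3 = 0.0; s4 = 0.0
    t0 = 0.0; t1 = 0.0; t2 = 0.0
    for i in range(u.size):
        wi = w[i]
        ui = u[i]
        u2 = ui * ui
        s0 += wi
        s1 += wi * ui
        s2 += wi * u2
        s3 += wi * u2 * ui
        s4 += wi * u2 * u2
        t0 += wi * y[i]
        t1 += wi * ui * y[i]
        t2 += wi * u2 * y[i]
    if order == 1:
        det = s0 * s2 - s1 * s1
        if det == 0.0:
            return False, 0.0, 0.0, 0.0
        i00 = s2 / det
        i01 = -s1 / det
        i11 = s0 / det
        norm_g = max(s0 + abs(s1), abs(s1) + s2)
        norm_i = max(abs(i00) + abs(i01), abs(i01) + abs(i11))
        if norm_g * norm_i > COND_LIMIT:
            return False, 0.0, 0.0, 0.0
        c0 = i00 * t0 + i01 * t1
        c1 = i01 * t0 + i11 * t1
        return True, c0, c1, 0.0
    # order 2: symmetric 3x3 solve via the adjugate
    a00 = s2 * s4 - s3 * s3
    a01 = -(s1 * s4 - s3 * s2)
    a02 = s1 * s3 - s2 * s2
    a11 = s0 * s4 - s2 * s2
    a12 = -(s0 * s3 - s2 * s1)
    a22 = s0 * s2 - s1 * s1
    det = s0 * a00 + s1 * a01 + s2 * a02
    if det == 0.0:
        return False, 0.0, 0.0, 0.0
    i00 = a00 / det; i01 = a01 / det; i02 = a02 / det
    i11 = a11 / det; i12 = a12 / det; i22 = a22 / det
    norm_g = max(
        s0 + abs(s1) + s2,
        abs(s1) + s2 + abs(s3),
        s2 + abs(s3) + s4,
    )
    norm_i = max(
        abs(i00) + abs(i01) + abs(i02),
        abs(i01) + abs(i11) + abs(i12),
        abs(i02) + abs(i12) + abs(i22),
    )
    if norm_g * norm_i > COND_LIMIT:
        return False, 0.0, 0.0, 0.0
    c0 = i00 * t0 + i01 * t1 + i02 * t2
    c1 = i01 * t0 + i11 * t1 + i12 * t2
    c2 = i02 * t0 + i12 * t1 + i22 * t2
    return True, c0, c1, c2


@njit(cache=True)
def fit_sensed(us, ss, h, wmode):
    """Belief computation from sensed neighbour data.

    `us` are neighbour positions relative to the sensor, `ss` their ranks.
    Applies the sufficiency check (n >= 4 at >= 3 distinct positions for the
    order-2 fit), the tricube/uniform weighting, the beta2 > 0 fallback to
    order 1, and the model-fidelity score.

    Returns ``(ok, order, c0, c1, c2, phi)`` with coefficients in
    sensor-centred (unscaled) coordinates.  ``ok`` False means the belief
    must be reset to zero.  ``phi`` is 1 - SSres/SStot (unweighted); when the
    sensed ranks have zero variance it is 1.0 for a zero-residual fit and
    -inf otherwise.
    """
    n = us.size
    if n < 4:
        return False, 0, 0.0, 0.0, 0.0, np.nan
    srt = np.sort(us)
    distinct = 1
    for i in range(1, n):
        if srt[i] != srt[i - 1]:
            distinct += 1
    if distinct < 3:
        return False, 0, 0.0, 0.0, 0.0, np.nan

    scale = 1.0
    for i in range(n):
        a = abs(us[i])
        if a > scale:
            scale = a
    usc = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        usc[i] = us[i] / scale
        if wmode == W_TRICUBE:
            z = abs(us[i]) / h
            if z > 1.0:
                z = 1.0
            d = 1.0 - z * z * z
            w[i] = d * d * d
        else:
            w[i] = 1.0

    ok, c0s, c1s, c2s = wls_polyfit_scaled(usc, ss, w, 2)
    order = 2
    if ok and c2s > 0.0:
        ok, c0s, c1s, c2s = wls_polyfit_scaled(usc, ss, w, 1)
        order = 1
    if not ok:
        return False, 0, 0.0, 0.0, 0.0, np.nan

    c0 = c0s
    c1 = c1s / scale
    c2 = c2s / (scale * scale)

    sbar = 0.0
    for i in range(n):
        sbar += ss[i]
    sbar /= n
    sstot = 0.0
    ssres = 0.0
    for i in range(n):
        d = ss[i] - sbar
        sstot += d * d
        pred = c0 + c1 * us[i] + c2 * us[i] * us[i]
        e = ss[i] - pred
        ssres += e * e
    if sstot == 0.0:
        if ssres <= 1e-12 * (1.0 + sbar * sbar):
            phi = 1.0
        else:
            phi = -np.inf
    else:
        phi = 1.0 - ssres / sstot
    return True, order, c0, c1, c2, phi


@njit(cache=True)
def solve_center_centred(c0, c1, c2, order, s_k, x_k, rng):
    """Potential-centre solve in sensor-centred coordinates.

    Minimises |s_k - p(u)| over the lattice: for a concave quadratic either
    the root of p(u) = s_k nearer the agent (exact ties broken uniformly at
    random) or the vertex when s_k exceeds the maximum of p; for a line the
    exact inversion.  Returns ``(has_update, x_star)`` in absolute
    coordinates, rounded half away from zero.
    """
    if order == 2 and c2 < -COEF_EPS:
        v = -c1 / (2.0 * c2)
        smax = c0 + c1 * v + c2 * v * v
        if s_k > smax:
            u_star = v
        else:
            d = np.sqrt((s_k - smax) / c2)
            r1 = v - d
            r2 = v + d
            if abs(r1) < abs(r2):
                u_star = r1
            elif abs(r2) < abs(r1):
                u_star = r2
            else:
                u_star = r1 if rng.random() < 0.5 else r2
        return True, x_k + round_half_away(u_star)
    if abs(c1) > COEF_EPS:
        return True, x_k + round_half_away((s_k - c0) / c1)
    return False, np.int64(0)


@njit(cache=True)
def solve_center_windowed(c0, c1, c2, order, s_k, x_k, win, rng):
    """Potential-centre solve restricted to the sensed window [x_k-win, x_k+win].

    The belief is an extrapolating polynomial; restricting the argmin of
    |s_k - p(u)| to the communication region keeps centre updates local.
    p is piecewise monotone, so the constrained minimiser is one of: the
    clipped exact roots, the clipped vertex, or a window endpoint.  Ties on
    the objective are broken toward the agent, then uniformly at random.
    """
    has_any = (order == 2 and c2 < -COEF_EPS) or abs(c1) > COEF_EPS
    if not has_any:
        return False, np.int64(0)
    cands = np.empty(4)
    ncand = 0
    if order == 2 and c2 < -COEF_EPS:
        v = -c1 / (2.0 * c2)
        smax = c0 + c1 * v + c2 * v * v
        if s_k > smax:
            cands[ncand] = v
            ncand += 1
        else:
            d = np.sqrt((s_k - smax) / c2)
            cands[ncand] = v - d
            ncand += 1
            cands[ncand] = v + d
            ncand += 1
            cands[ncand] = v
            ncand += 1
    else:
        cands[ncand] = (s_k - c0) / c1
        ncand += 1
    best_u = 0.0
    best_obj = np.inf
    best_dist = np.inf
    w = float(win)
    for i in range(ncand):
        u = cands[i]
        if u > w:
            u = w
        elif u < -w:
            u = -w
        obj = abs(s_k - (c0 + c1 * u + c2 * u * u))
        dist = abs(u)
        if obj < best_obj or (obj == best_obj and dist < best_dist):
            best_obj = obj
            best_dist = dist
            best_u = u
            tie = False
        elif obj == best_obj and dist == best_dist and u != best_u:
            if rng.random() < 0.5:
                best_u = u
    return True, x_k + round_half_away(best_u)


@njit(cache=True)
def _interact_pair(j, k, S, dS_max, dplus, dminus, rng):
    """Gate, outcome and rank update for one co-located pair; 1 if realised."""
    if abs(S[j] - S[k]) >= dS_max:
        return 0
    if S[j] > S[k]:
        w, l = j, k
    elif S[k] > S[j]:
        w, l = k, j
    else:
        if rng.random() < 0.5:
            w, l = j, k
        else:
            w, l = k, j
    S[w] = S[w] + dplus
    lo = S[l] - dminus
    if lo < 0.0:
        lo = 0.0
    S[l] = lo
    return 1


CR_CLAMP = 0    # global argmin; stranded agent clamped into the new box
CR_WINDOW = 1   # argmin restricted to the sensed window [x_k - h, x_k + h]
CR_FROZEN = 2   # global argmin; stranded agent left outside (walk freezes)


@njit(cache=True)
def advance(x, S, border, b0, b1, b2, phi, xstar,
            h, L, dS_max, dplus, dminus, r, t_c, stay_prob,
            wmode, pair_all, center_rule, t_start, n_steps, rng):
    """Advance the population `n_steps` steps in place.

    Per step: (1) every agent proposes a +-1 move, rejected at the walls of
    its own box potential; (2) each multiply-occupied site resolves one
    uniformly chosen pair (or all pairs in random order when `pair_all`);
    (3) each agent senses with probability r, refits its belief and, subject
    to the two-stage t_c retention rule, re-solves its potential centre and
    is clamped inside the shifted box.

    Returns the number of realised interactions (for ledger checks).
    """
    N = x.size
    n_inter = 0
    for si in range(n_steps):
        t = t_start + si
        # -- move phase
        for k in range(N):
            if stay_prob > 0.0:
                if rng.random() < stay_prob:
                    continue
            d = 1 if rng.random() < 0.5 else -1
            nx = x[k] + d
            if abs(nx - xstar[k]) < L:
                x[k] = nx
        # -- interaction phase
        idx = np.argsort(x, kind="mergesort")
        i0 = 0
        while i0 < N:
            i1 = i0 + 1
            while i1 < N and x[idx[i1]] == x[idx[i0]]:
                i1 += 1
            c = i1 - i0
            if c >= 2:
                if pair_all:
                    npairs = c * (c - 1) // 2
                    pa = np.empty(npairs, np.int64)
                    pb = np.empty(npairs, np.int64)
                    q = 0
                    for a in range(c):
                        for b in range(a + 1, c):
                            pa[q] = idx[i0 + a]
                            pb[q] = idx[i0 + b]
                            q += 1
                    for q in range(npairs - 1, 0, -1):
                        j2 = randint_below(rng, q + 1)
                        pa[q], pa[j2] = pa[j2], pa[q]
                        pb[q], pb[j2] = pb[j2], pb[q]
                    for q in range(npairs):
                        n_inter += _interact_pair(
                            pa[q], pb[q], S, dS_max, dplus, dminus, rng
                        )
                else:
                    a = randint_below(rng, c)
                    b = randint_below(rng, c - 1)
                    if b >= a:
                        b += 1
                    n_inter += _interact_pair(
                        idx[i0 + a], idx[i0 + b], S, dS_max, dplus, dminus, rng
                    )
            i0 = i1
        # -- sensing phase
        for k in range(N):
            if rng.random() < r:
                cnt = 0
                for j in range(N):
                    if j != k and abs(x[j] - x[k]) <= h:
                        cnt += 1
                us = np.empty(cnt)
                ss = np.empty(cnt)
                q = 0
                for j in range(N):
                    if j != k and abs(x[j] - x[k]) <= h:
                        us[q] = x[j] - x[k]
                        ss[q] = S[j]
                        q += 1
                ok, bo, c0, c1, c2, ph = fit_sensed(us, ss, h, wmode)
                if not ok:
                    # insufficient quantity/quality: reset belief, keep x*
                    border[k] = 0
                    b0[k] = 0.0
                    b1[k] = 0.0
                    b2[k] = 0.0
                    phi[k] = np.nan
                elif t < t_c and ph < 0.0:
                    pass  # early low-fidelity measurement: not retained
                else:
                    xk = x[k]
                    border[k] = bo
                    b0[k] = c0 - c1 * xk + c2 * xk * xk
                    b1[k] = c1 - 2.0 * c2 * xk
                    b2[k] = c2
                    phi[k] = ph
                    if center_rule == CR_WINDOW:
                        has, xs = solve_center_windowed(
                            c0, c1, c2, bo, S[k], xk, h, rng
                        )
                    else:
                        has, xs = solve_center_centred(
                            c0, c1, c2, bo, S[k], xk, rng
                        )
                    if has:
                        xstar[k] = xs
                        if center_rule != CR_FROZEN and abs(x[k] - xs) >= L:
                            if x[k] < xs:
                                x[k] = xs - (L - 1)
                            else:
                                x[k] = xs + (L - 1)
    return n_inter
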