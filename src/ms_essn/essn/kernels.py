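"""Simulation kernels: SSA (Gillespie direct method) and tau-leaping.

The kernels are written against the flat-array net encoding of
:mod:`.compile` and are jit-compiled with numba when it is importable;
they run unmodified (slowly) as plain python otherwise.  All randomness
is drawn as uniforms from the numpy legacy global stream seeded inside
the kernel, so a given seed reproduces a trajectory bit-for-bit.
Poisson variates for tau-leaping are generated from uniforms (Knuth
product below mean 10, Hormann's PTRS transformed rejection above) to
keep the random stream identical between the jitted and plain builds.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ssa_kernel", "tau_kernel", "propensities_int", "propensities_real",
           "NUMBA"]

# status codes returned by the kernels
OK = 0
NEGATIVE_EVENT = 1
MAX_STEPS = 2

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _jit = numba.njit(cache=True)
    NUMBA = True
except Exception:  # pragma: no cover
    def _jit(f):
        return f

    NUMBA = False


@_jit
def _prop_fill(x, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult,
               discrete, a):
    n = kind.shape[0]
    for r in range(n):
        enabled = True
        for k in range(in_start[r], in_start[r + 1]):
            if x[in_idx[k]] < in_mult[k]:
                enabled = False
                break
        if discrete and not enabled:
            a[r] = 0.0
            continue
        if kind[r] == 0:  # mass action
            v = rate_c[r]
            for k in range(in_start[r], in_start[r + 1]):
                xv = x[in_idx[k]]
                if xv < 0.0:
                    xv = 0.0
                v *= xv ** in_mult[k]
            a[r] = v
        elif kind[r] == 1:  # hill
            xi = max(x[gi[r]], 0.0)
            xj = max(x[gj[r]], 0.0)
            a[r] = rate_c[r] * xi * xj / (khalf[r] + xj)
        elif kind[r] == 2:  # bilinear
            a[r] = rate_c[r] * max(x[gi[r]], 0.0) * max(x[gj[r]], 0.0)
        else:  # linear
            a[r] = rate_c[r] * max(x[gi[r]], 0.0)
    return a


def propensities_int(x, arrays):
    """Propensity vector on an integer state (enabling enforced)."""
    kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, _L = arrays
    a = np.zeros(kind.shape[0], dtype=np.float64)
    return _prop_fill(x.astype(np.float64), kind, rate_c, khalf, gi, gj,
                      in_start, in_idx, in_mult, True, a)


def propensities_real(x, arrays):
    """Propensity vector on a real-valued state (for the ODE field)."""
    kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, _L = arrays
    a = np.zeros(kind.shape[0], dtype=np.float64)
    return _prop_fill(np.asarray(x, dtype=np.float64), kind, rate_c, khalf,
                      gi, gj, in_start, in_idx, in_mult, False, a)


@_jit
def _poisson_u(lam):
    """Poisson variate from uniform draws only."""
    if lam <= 0.0:
        return 0
    if lam < 10.0:  # Knuth product method
        thresh = math.exp(-lam)
        k = 0
        p = 1.0
        while True:
            p *= np.random.random()
            if p <= thresh:
                return k
            k += 1
    # PTRS transformed rejection (Hormann 1993)
    b = 0.931 + 2.53 * math.sqrt(lam)
    a = -0.059 + 0.02483 * b
    inv_alpha = 1.1239 + 1.1328 / (b - 3.4)
    vr = 0.9277 - 3.6224 / (b - 2.0)
    while True:
        u = np.random.random() - 0.5
        v = np.random.random()
        us = 0.5 - abs(u)
        k = int(math.floor((2.0 * a / us + b) * u + lam + 0.43))
        if us >= 0.07 and v <= vr:
            return k
        if k < 0 or (us < 0.013 and v > us):
            continue
        if (math.log(v) + math.log(inv_alpha) - math.log(a / (us * us) + b)
                <= k * math.log(lam) - lam - math.lgamma(k + 1.0)):
            return k


@_jit
def ssa_kernel(x0, t0, t_end, grid, ev_times, ev_deltas,
               kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, L,
               seed, max_steps):
    """Gillespie direct method with deterministic timed events.

    Events are applied exactly at their times: if the next exponential
    jump would overshoot an event boundary, the clock advances to the
    boundary, the token deltas are applied, and propensities are
    recomputed (memorylessness makes redrawing the waiting time exact).
    Grid points are recorded with the state holding at that instant
    (right-continuous: a grid point at an event time sees the post-event
    state).
    """
    np.random.seed(seed)
    m = x0.shape[0]
    nr = kind.shape[0]
    ngrid = grid.shape[0]
    nev = ev_times.shape[0]
    x = x0.astype(np.float64).copy()
    out = np.zeros((ngrid, m), dtype=np.float64)
    a = np.zeros(nr, dtype=np.float64)
    t = t0
    gpos = 0
    epos = 0
    steps = 0
    status = OK
    while True:
        _prop_fill(x, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult,
                   True, a)
        a0 = 0.0
        for r in range(nr):
            a0 += a[r]
        if a0 > 0.0:
            t_next = t - math.log(1.0 - np.random.random()) / a0
        else:
            t_next = math.inf
        if epos < nev and ev_times[epos] <= t_end:
            bound = ev_times[epos]
            is_event = True
        else:
            bound = t_end
            is_event = False
        if t_next >= bound:
            while gpos < ngrid and grid[gpos] < bound:
                out[gpos] = x
                gpos += 1
            t = bound
            if is_event:
                for j in range(m):
                    x[j] += ev_deltas[epos, j]
                    if x[j] < 0.0:
                        status = NEGATIVE_EVENT
                epos += 1
                if status != OK:
                    break
            else:
                while gpos < ngrid:
                    out[gpos] = x
                    gpos += 1
                break
        else:
            while gpos < ngrid and grid[gpos] < t_next:
                out[gpos] = x
                gpos += 1
            u = np.random.random() * a0
            acc = 0.0
            chosen = nr - 1
            for r in range(nr):
                acc += a[r]
                if u < acc:
                    chosen = r
                    break
            for j in range(m):
                x[j] += L[chosen, j]
            t = t_next
            steps += 1
            if steps >= max_steps:
                status = MAX_STEPS
                break
    return out, status, steps


@_jit
def tau_kernel(x0, t0, t_end, grid, ev_times, ev_deltas,
               kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, L,
               seed, tau):
    """Fixed-step tau-leaping with Poisson firing counts.

    Each leap fires reaction ``r`` Poisson(a_r * h) times; leaps are
    truncated at event boundaries so timed token additions stay exact.
    If a leap would drive any count negative the step is halved and the
    counts redrawn (bounded retries; the step shrinks until every Poisson
    draw is 0, which is always accepted).
    """
    np.random.seed(seed)
    m = x0.shape[0]
    nr = kind.shape[0]
    ngrid = grid.shape[0]
    nev = ev_times.shape[0]
    x = x0.astype(np.float64).copy()
    cand = np.zeros(m, dtype=np.float64)
    out = np.zeros((ngrid, m), dtype=np.float64)
    a = np.zeros(nr, dtype=np.float64)
    t = t0
    gpos = 0
    epos = 0
    status = OK
    eps = 1e-12
    while t < t_end - eps:
        if epos < nev and ev_times[epos] <= t_end:
            bound = ev_times[epos]
            is_event = True
        else:
            bound = t_end
            is_event = False
        if bound <= t + eps and is_event:
            for j in range(m):
                x[j] += ev_deltas[epos, j]
                if x[j] < 0.0:
                    status = NEGATIVE_EVENT
            epos += 1
            if status != OK:
                break
            continue
        _prop_fill(x, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult,
                   True, a)
        a0 = 0.0
        for r in range(nr):
            a0 += a[r]
        if a0 <= 0.0:
            while gpos < ngrid and grid[gpos] < bound:
                out[gpos] = x
                gpos += 1
            t = bound
            if is_event:
                for j in range(m):
                    x[j] += ev_deltas[epos, j]
                    if x[j] < 0.0:
                        status = NEGATIVE_EVENT
                epos += 1
                if status != OK:
                    break
            continue
        h = tau
        if t + h > bound:
            h = bound - t
        ok = False
        for _try in range(64):
            for j in range(m):
                cand[j] = x[j]
            for r in range(nr):
                if a[r] > 0.0:
                    kfire = _poisson_u(a[r] * h)
                    if kfire > 0:
                        for j in range(m):
                            cand[j] += kfire * L[r, j]
            ok = True
            for j in range(m):
                if cand[j] < 0.0:
                    ok = False
                    break
            if ok:
                break
            h *= 0.5
        if not ok:
            # vanishing step: advance without firing (h > 0 keeps progress)
            for j in range(m):
                cand[j] = x[j]
        t_new = t + h
        while gpos < ngrid and grid[gpos] < t_new:
            out[gpos] = x
            gpos += 1
        for j in range(m):
            x[j] = cand[j]
        t = t_new
    while gpos < ngrid:
        out[gpos] = x
        gpos += 1
    return out, status


@_jit
def rk45_kernel(x0, t0, t_end, out_times, ev_times, ev_deltas,
                kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, L,
                rtol, atol, max_steps):
    """Adaptive Dormand-Prince RK45 integration of the fluid limit.

    Used where many fast repeated solves are needed (calibration);
    events are handled as exact state jumps at segment boundaries and
    states are clipped at zero after each accepted step.  Returns status
    1 if the step controller stalls (pathological parameter corners).
    """
    m = x0.shape[0]
    nr = kind.shape[0]
    x = x0.copy()
    nout = out_times.shape[0]
    out = np.zeros((nout, m), dtype=np.float64)
    k1 = np.zeros(nr); k2 = np.zeros(nr); k3 = np.zeros(nr)
    k4 = np.zeros(nr); k5 = np.zeros(nr); k6 = np.zeros(nr); k7 = np.zeros(nr)
    f1 = np.zeros(m); f2 = np.zeros(m); f3 = np.zeros(m)
    f4 = np.zeros(m); f5 = np.zeros(m); f6 = np.zeros(m); f7 = np.zeros(m)
    y = np.zeros(m); y5 = np.zeros(m); y4 = np.zeros(m)
    t = t0
    opos = 0
    epos = 0
    # skip events scheduled before the start
    while epos < ev_times.shape[0] and ev_times[epos] < t0:
        epos += 1
    h = (t_end - t0) / 100.0
    steps = 0
    while t < t_end - 1e-12:
        # next boundary: event or end
        if epos < ev_times.shape[0] and ev_times[epos] <= t_end:
            bound = ev_times[epos]
            is_event = True
        else:
            bound = t_end
            is_event = False
        if bound <= t + 1e-12 and is_event:
            for j in range(m):
                x[j] += ev_deltas[epos, j]
                if x[j] < 0.0:
                    x[j] = 0.0
            epos += 1
            continue
        if t + h > bound:
            hs = bound - t
        else:
            hs = h
        # Dormand-Prince tableau
        _prop_fill(x, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k1)
        for j in range(m):
            f1[j] = 0.0
        for r in range(nr):
            if k1[r] != 0.0:
                for j in range(m):
                    f1[j] += L[r, j] * k1[r]
        for j in range(m):
            y[j] = x[j] + hs * 0.2 * f1[j]
        _prop_fill(y, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k2)
        for j in range(m):
            f2[j] = 0.0
        for r in range(nr):
            if k2[r] != 0.0:
                for j in range(m):
                    f2[j] += L[r, j] * k2[r]
        for j in range(m):
            y[j] = x[j] + hs * (0.075 * f1[j] + 0.225 * f2[j])
        _prop_fill(y, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k3)
        for j in range(m):
            f3[j] = 0.0
        for r in range(nr):
            if k3[r] != 0.0:
                for j in range(m):
                    f3[j] += L[r, j] * k3[r]
        for j in range(m):
            y[j] = x[j] + hs * (44.0 / 45.0 * f1[j] - 56.0 / 15.0 * f2[j]
                                + 32.0 / 9.0 * f3[j])
        _prop_fill(y, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k4)
        for j in range(m):
            f4[j] = 0.0
        for r in range(nr):
            if k4[r] != 0.0:
                for j in range(m):
                    f4[j] += L[r, j] * k4[r]
        for j in range(m):
            y[j] = x[j] + hs * (19372.0 / 6561.0 * f1[j]
                                - 25360.0 / 2187.0 * f2[j]
                                + 64448.0 / 6561.0 * f3[j]
                                - 212.0 / 729.0 * f4[j])
        _prop_fill(y, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k5)
        for j in range(m):
            f5[j] = 0.0
        for r in range(nr):
            if k5[r] != 0.0:
                for j in range(m):
                    f5[j] += L[r, j] * k5[r]
        for j in range(m):
            y[j] = x[j] + hs * (9017.0 / 3168.0 * f1[j] - 355.0 / 33.0 * f2[j]
                                + 46732.0 / 5247.0 * f3[j]
                                + 49.0 / 176.0 * f4[j]
                                - 5103.0 / 18656.0 * f5[j])
        _prop_fill(y, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k6)
        for j in range(m):
            f6[j] = 0.0
        for r in range(nr):
            if k6[r] != 0.0:
                for j in range(m):
                    f6[j] += L[r, j] * k6[r]
        for j in range(m):
            y5[j] = x[j] + hs * (35.0 / 384.0 * f1[j]
                                 + 500.0 / 1113.0 * f3[j]
                                 + 125.0 / 192.0 * f4[j]
                                 - 2187.0 / 6784.0 * f5[j]
                                 + 11.0 / 84.0 * f6[j])
        _prop_fill(y5, kind, rate_c, khalf, gi, gj, in_start, in_idx, in_mult, False, k7)
        for j in range(m):
            f7[j] = 0.0
        for r in range(nr):
            if k7[r] != 0.0:
                for j in range(m):
                    f7[j] += L[r, j] * k7[r]
        # 4th-order solution for the error estimate
        err = 0.0
        for j in range(m):
            y4[j] = x[j] + hs * (5179.0 / 57600.0 * f1[j]
                                 + 7571.0 / 16695.0 * f3[j]
                                 + 393.0 / 640.0 * f4[j]
                                 - 92097.0 / 339200.0 * f5[j]
                                 + 187.0 / 2100.0 * f6[j]
                                 + 1.0 / 40.0 * f7[j])
            sc = atol + rtol * max(abs(x[j]), abs(y5[j]))
            e = (y5[j] - y4[j]) / sc
            err += e * e
        err = math.sqrt(err / m)
        if err <= 1.0:
            # record outputs strictly inside this step; a grid point that
            # coincides with an event boundary is recorded after the event
            # fires (right-continuous, like the stochastic backends)
            t_new = t + hs
            while opos < nout and out_times[opos] < t_new - 1e-12:
                # linear interpolation within the accepted step
                if hs > 0.0 and out_times[opos] > t:
                    w = (out_times[opos] - t) / hs
                else:
                    w = 0.0
                for j in range(m):
                    v = x[j] + w * (y5[j] - x[j])
                    if v < 0.0:
                        v = 0.0
                    out[opos, j] = v
                opos += 1
            for j in range(m):
                x[j] = y5[j]
                if x[j] < 0.0:
                    x[j] = 0.0
            t = t_new
        if err == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * err ** -0.2
            if fac > 5.0:
                fac = 5.0
            elif fac < 0.2:
                fac = 0.2
        h = hs * fac
        if h < 1e-10:
            return out, 1
        steps += 1
        if steps >= max_steps:
            return out, 1
    while opos < nout:
        for j in range(m):
            out[opos, j] = x[j]
        opos += 1
    return out, 0
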