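"""Numba kernels: voxel photon transport and per-detector pair sums.

All kernel-side lengths are in micrometers and optical coefficients in
um^-1.  Photon streams use a counter-based splitmix64 generator keyed by
(seed, photon id), so results are independent of execution order and
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, uint64

_GOLDEN = uint64(0x9E3779B97F4A7C15)


@njit(cache=True, inline="always")
def _mix64(z):
    z = uint64(z)
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(cache=True, inline="always")
def _stream_init(seed, pid):
    # decorrelated per-photon stream origin
    return _mix64(uint64(seed) * uint64(0xD1342543DE82EF95) ^ (uint64(pid) + uint64(1)) * _GOLDEN)


@njit(cache=True, inline="always")
def _next_u01(state):
    state = uint64(state + _GOLDEN)
    z = _mix64(state)
    return state, (z >> uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _sample_hg(state, g):
    """Henyey-Greenstein cosine of the scattering polar angle."""
    state, u = _next_u01(state)
    if abs(g) < 1e-6:
        return state, 1.0 - 2.0 * u
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return state, ct


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    """Rotate direction (ux,uy,uz) by polar angle acos(ct), azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    # renormalize against drift
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def transport_chunk(
    cls_grid,  # (nx,ny,nz) uint8: 0 extravascular, 1 capillary, 2 noncapillary
    gidx,  # (nx,ny,nz) int32: flow-group index, -1 outside vessels
    vdir,  # (nx,ny,nz,3) float32 unit centerline tangents
    occ,  # (bx,by,bz) uint8 coarse blocks: 1 if any vessel voxel inside
    occ_dist,  # (bx,by,bz) int16 chessboard distance to nearest occupied block
    block,  # voxels per coarse block side
    mu_a,  # (3,) um^-1 per class
    mu_s,  # (3,) um^-1 per class
    g_hg,  # (3,) anisotropy per class
    pitch,
    src_x,
    src_y,
    beam_radius,
    n_chunk,
    pid_offset,
    seed,
    rr_threshold,
    rr_survive,
    max_events,
    out_det,  # (n_chunk,) uint8
    out_x,
    out_y,
    out_w,  # (n_chunk,) float64
    out_q,  # (n_chunk, G) float32
    out_nscat,  # (n_chunk,) int32
):
    nx, ny, nz = cls_grid.shape
    lx = nx * pitch
    ly = ny * pitch
    lz = nz * pitch
    inv_pitch = 1.0 / pitch
    bpitch = block * pitch
    inv_bpitch = 1.0 / bpitch
    eps = 1e-6 * pitch
    mus0 = mu_s[0]
    mua0 = mu_a[0]
    for p in range(n_chunk):
        state = _stream_init(seed, pid_offset + p)
        # uniform point in the collimated beam disk
        state, u1 = _next_u01(state)
        state, u2 = _next_u01(state)
        r = beam_radius * math.sqrt(u1)
        ang = 2.0 * math.pi * u2
        x = src_x + r * math.cos(ang)
        y = src_y + r * math.sin(ang)
        z = eps
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w_od = 0.0  # accumulated absorption optical depth
        rrw = 1.0  # Russian-roulette boost factor
        nscat = 0
        alive = True
        detected = False
        while alive:
            state, u = _next_u01(state)
            tau = -math.log(u + 1e-300)
            # --- propagate until the scattering optical depth is consumed ---
            scatter_here = False
            while True:
                ix = int(x * inv_pitch)
                iy = int(y * inv_pitch)
                iz = int(z * inv_pitch)
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                    alive = False
                    break
                if occ[ix // block, iy // block, iz // block] == 0:
                    # vessel-free coarse block: step to its boundary in one go
                    bx = ix // block
                    by = iy // block
                    bz = iz // block
                    if ux > 0.0:
                        tx = ((bx + 1) * bpitch - x) / ux
                    elif ux < 0.0:
                        tx = (bx * bpitch - x) / ux
                    else:
                        tx = 1e30
                    if uy > 0.0:
                        ty = ((by + 1) * bpitch - y) / uy
                    elif uy < 0.0:
                        ty = (by * bpitch - y) / uy
                    else:
                        ty = 1e30
                    if uz > 0.0:
                        tz = ((bz + 1) * bpitch - z) / uz
                    elif uz < 0.0:
                        tz = (bz * bpitch - z) / uz
                    else:
                        tz = 1e30
                    tb = tx
                    if ty < tb:
                        tb = ty
                    if tz < tb:
                        tb = tz
                    if tb < 0.0:
                        tb = 0.0
                    # with the nearest vessel block d blocks away (chessboard),
                    # a straight hop of (d-1) block pitches stays vessel-free;
                    # cap it at the domain boundary so surface exits are never
                    # overshot by a scattering site outside the medium
                    d = occ_dist[bx, by, bz]
                    if d > 1:
                        hop = (d - 1) * bpitch
                        if hop > tb:
                            tb = hop
                        if ux > 0.0:
                            t_dom = (lx - x) / ux
                        elif ux < 0.0:
                            t_dom = -x / ux
                        else:
                            t_dom = 1e30
                        if uy > 0.0:
                            t2 = (ly - y) / uy
                        elif uy < 0.0:
                            t2 = -y / uy
                        else:
                            t2 = 1e30
                        if t2 < t_dom:
                            t_dom = t2
                        if uz > 0.0:
                            t2 = (lz - z) / uz
                        elif uz < 0.0:
                            t2 = -z / uz
                        else:
                            t2 = 1e30
                        if t2 < t_dom:
                            t_dom = t2
                        if t_dom < tb:
                            tb = t_dom
                        if tb < 0.0:
                            tb = 0.0
                    ts = tau / mus0
                    if ts <= tb:
                        x += ux * ts
                        y += uy * ts
                        z += uz * ts
                        w_od += mua0 * ts
                        scatter_here = True
                        break
                    x += ux * (tb + eps)
                    y += uy * (tb + eps)
                    z += uz * (tb + eps)
                    w_od += mua0 * tb
                    tau -= mus0 * tb
                else:
                    c = cls_grid[ix, iy, iz]
                    mus = mu_s[c]
                    mua = mu_a[c]
                    # distance to the next voxel boundary along the direction
                    if ux > 0.0:
                        tx = ((ix + 1) * pitch - x) / ux
                    elif ux < 0.0:
                        tx = (ix * pitch - x) / ux
                    else:
                        tx = 1e30
                    if uy > 0.0:
                        ty = ((iy + 1) * pitch - y) / uy
                    elif uy < 0.0:
                        ty = (iy * pitch - y) / uy
                    else:
                        ty = 1e30
                    if uz > 0.0:
                        tz = ((iz + 1) * pitch - z) / uz
                    elif uz < 0.0:
                        tz = (iz * pitch - z) / uz
                    else:
                        tz = 1e30
                    tb = tx
                    if ty < tb:
                        tb = ty
                    if tz < tb:
                        tb = tz
                    if tb < 0.0:
                        tb = 0.0
                    ts = tau / mus
                    if ts <= tb:
                        x += ux * ts
                        y += uy * ts
                        z += uz * ts
                        w_od += mua * ts
                        scatter_here = True
                        break
                    x += ux * (tb + eps)
                    y += uy * (tb + eps)
                    z += uz * (tb + eps)
                    w_od += mua * tb
                    tau -= mus * tb
                if z < 0.0:
                    # crossed the top surface: back up to the z=0 plane
                    f = z / uz
                    out_x[p] = x - ux * f
                    out_y[p] = y - uy * f
                    detected = True
                    alive = False
                    break
                if x < 0.0 or x >= lx or y < 0.0 or y >= ly or z >= lz:
                    alive = False
                    break
            if not alive:
                break
            if not scatter_here:
                continue
            # --- scattering event ---
            c = cls_grid[ix, iy, iz]
            state, ct = _sample_hg(state, g_hg[c])
            state, u = _next_u01(state)
            phi = 2.0 * math.pi * u
            nux, nuy, nuz = _spin(ux, uy, uz, ct, phi)
            gi = gidx[ix, iy, iz]
            if gi >= 0:
                dvx = vdir[ix, iy, iz, 0]
                dvy = vdir[ix, iy, iz, 1]
                dvz = vdir[ix, iy, iz, 2]
                out_q[p, gi] += (nux - ux) * dvx + (nuy - uy) * dvy + (nuz - uz) * dvz
            ux = nux
            uy = nuy
            uz = nuz
            nscat += 1
            if nscat >= max_events:
                alive = False
                break
            w = math.exp(-w_od) * rrw
            if w < rr_threshold:
                state, u = _next_u01(state)
                if u < rr_survive:
                    rrw /= rr_survive
                else:
                    alive = False
        out_nscat[p] = nscat
        if detected:
            out_det[p] = 1
            out_w[p] = math.exp(-w_od) * rrw


_INV_PIO2 = 6.36619772367581382433e-01
_PIO2_1 = 1.57079632673412561417e+00  # first 33 bits of pi/2
_PIO2_1T = 6.07710050650619224932e-11  # pi/2 - _PIO2_1


@njit(cache=True, inline="always")
def _sincos(x):
    """sin(x) and cos(x) by Cody-Waite reduction + minimax polynomials.

    Accurate to ~1e-15 relative for |x| < ~1e5 (the momentum-transfer
    phases here stay below a few thousand); one shared implementation keeps
    the contrast and gradient kernels bit-consistent.
    """
    n = int(round(x * _INV_PIO2))
    r = (x - n * _PIO2_1) - n * _PIO2_1T
    z = r * r
    # sin(r), |r| <= pi/4
    s = r + r * z * (
        -1.66666666666666324348e-01
        + z * (8.33333333332248946124e-03
               + z * (-1.98412698298579493134e-04
                      + z * (2.75573137070700676789e-06
                             + z * (-2.50507602534068634195e-08
                                    + z * 1.58969099521155010221e-10))))
    )
    # cos(r)
    c = 1.0 - 0.5 * z + z * z * (
        4.16666666666666019037e-02
        + z * (-1.38888888888741095749e-03
               + z * (2.48015872894767294178e-05
                      + z * (-2.75573143513906633035e-07
                             + z * (2.08757232129817482790e-09
                                    + z * -1.13596475577881948265e-11))))
    )
    q = n % 4
    if q == 0:
        return s, c
    if q == 1:
        return c, -s
    if q == 2:
        return -s, -c
    return -c, s


@njit(cache=True, inline="always")
def _sinc_sq(x):
    """sin^2(x)/x^2 with a series guard near 0."""
    if abs(x) < 1e-4:
        x2 = x * x
        return 1.0 - x2 / 3.0 + 2.0 * x2 * x2 / 45.0
    s, _ = _sincos(x)
    return s * s / (x * x)


@njit(cache=True, inline="always")
def _dsinc_sq(x):
    """d/dx of sin^2(x)/x^2 = 2 sin(x)(x cos(x) - sin(x))/x^3."""
    if abs(x) < 1e-3:
        return -2.0 * x / 3.0 + 8.0 * x * x * x / 45.0
    s, c = _sincos(x)
    return 2.0 * s * (x * c - s) / (x * x * x)


@njit(cache=True)
def pair_contrast(P, Y, s0, sum_ps2, k0t, beta):
    """Closed-form speckle contrast K from the photon-pair sum.

    P, Y cover the *dynamic* photons only; s0 and sum_ps2 are the total
    weight and summed squared weight of the static photons (Y = 0), whose
    pair terms are accumulated analytically.
    """
    m = P.shape[0]
    diag = sum_ps2
    cross = 0.5 * (s0 * s0 - sum_ps2)
    for n in range(m):
        diag += P[n] * P[n]
        cross += s0 * P[n] * _sinc_sq(k0t * Y[n])
        yn = Y[n]
        pn = P[n]
        # arithmetic mirrors the analytic-gradient kernel term for term so
        # that model and measured contrasts from identical ensembles agree
        # bitwise (the inversion's fixed point relies on it)
        for mm in range(n + 1, m):
            x = k0t * (yn - Y[mm])
            pp = pn * P[mm]
            if abs(x) < 1e-3:
                x2 = x * x
                s2 = 1.0 - x2 / 3.0 + 2.0 * x2 * x2 / 45.0
            else:
                s, _ = _sincos(x)
                inv_x2 = 1.0 / (x * x)
                s2 = s * s * inv_x2
            cross += pp * s2
    ksq = beta * (0.5 * diag + cross)
    if ksq < 0.0:
        ksq = 0.0
    return math.sqrt(ksq)


@njit(cache=True)
def pair_residual_grad_analytic(P, Y, Qd, s0, sum_ps2, k0t, beta, k_meas):
    """Residual (K_meas - Khat)^2 and its analytic gradient w.r.t. group flows.

    Qd is the dense (G, m_dyn) momentum-transfer coefficient block for the
    detector's dynamic photons; the returned gradient is per um/s of group
    speed (callers rescale to mm/s).
    """
    m = P.shape[0]
    G = Qd.shape[0]
    # The Khat accumulation mirrors pair_contrast term for term; both
    # kernels are compiled under strict IEEE semantics (no fastmath), so a
    # model evaluated on the trajectories behind the measurement reproduces
    # the measured contrast bitwise and the residual vanishes exactly.
    diag = sum_ps2
    cross = 0.5 * (s0 * s0 - sum_ps2)
    c = np.zeros(m)
    for n in range(m):
        diag += P[n] * P[n]
        xn = k0t * Y[n]
        cross += s0 * P[n] * _sinc_sq(xn)
        c[n] += s0 * P[n] * _dsinc_sq(xn)
        yn = Y[n]
        pn = P[n]
        cn = c[n]
        for mm in range(n + 1, m):
            x = k0t * (yn - Y[mm])
            pp = pn * P[mm]
            if abs(x) < 1e-3:
                x2 = x * x
                s2 = 1.0 - x2 / 3.0 + 2.0 * x2 * x2 / 45.0
                dd = -2.0 * x / 3.0 + 8.0 * x * x2 / 45.0
            else:
                s, co = _sincos(x)
                inv_x2 = 1.0 / (x * x)
                s2 = s * s * inv_x2
                dd = 2.0 * s * (x * co - s) * inv_x2 / x
            cross += pp * s2
            w = pp * dd
            cn += w
            c[mm] -= w
        c[n] = cn
    ksq = beta * (0.5 * diag + cross)
    if ksq < 0.0:
        ksq = 0.0
    khat = math.sqrt(ksq)
    grad = np.zeros(G)
    if khat > 0.0:
        pref = -(k_meas - khat) / khat * beta * k0t
        for i in range(G):
            acc = 0.0
            for n in range(m):
                acc += Qd[i, n] * c[n]
            grad[i] = pref * acc
    res = (k_meas - khat) * (k_meas - khat)
    return khat, res, grad


@njit(cache=True)
def pair_residual_grad_fd(P, Y, Qd, s0, sum_ps2, k0t, beta, k_meas, eps_um):
    """Same residual, gradient by vectorized one-sided finite differences.

    One unperturbed evaluation plus one per flow group, each reusing the
    stored trajectories (the perturbation only shifts the per-photon
    momentum transfer Y by eps * q_i).
    """
    m = P.shape[0]
    G = Qd.shape[0]
    khat = pair_contrast(P, Y, s0, sum_ps2, k0t, beta)
    grad = np.zeros(G)
    yp = np.empty(m)
    for i in range(G):
        for n in range(m):
            yp[n] = Y[n] + eps_um * Qd[i, n]
        ki = pair_contrast(P, yp, s0, sum_ps2, k0t, beta)
        grad[i] = -2.0 * (k_meas - khat) * (ki - khat) / eps_um
    res = (k_meas - khat) * (k_meas - khat)
    return khat, res, grad


@njit(cache=True)
def tv1d_denoise(y, lam):
    """Exact 1D total-variation proximal operator (direct, non-iterative).

    Returns argmin_x 0.5*||x - y||^2 + lam * sum |x_{i+1} - x_i| by the
    derivative-tracking single-pass method with backtracking segment
    flushes.
    """
    n = y.shape[0]
    x = np.empty_like(y)
    if n == 0:
        return x
    if lam <= 0.0 or n == 1:
        for i in range(n):
            x[i] = y[i]
        return x
    k = 0
    k0 = 0
    km = 0
    kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:
                # the minorant is violated: flush the segment at vmin
                for i in range(k0, km + 1):
                    x[i] = vmin
                km += 1
                k = km
                k0 = km
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
            elif umax > 0.0:
                for i in range(k0, kp + 1):
                    x[i] = vmax
                kp += 1
                k = kp
                k0 = kp
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
            else:
                v = vmin + umin / (k - k0 + 1)
                for i in range(k0, n):
                    x[i] = v
                return x
            continue
        if y[k + 1] + umin < vmin - lam:
            # negative jump is certain
            for i in range(k0, km + 1):
                x[i] = vmin
            km += 1
            k = km
            k0 = km
            kp = km
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:
            # positive jump is certain
            for i in range(k0, kp + 1):
                x[i] = vmax
            kp += 1
            k = kp
            k0 = kp
            km = kp
            vmax = y[k]
            vmin = y[k] - 2.0 * lam
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k
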