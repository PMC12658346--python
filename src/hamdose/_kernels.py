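"""Numba kernels for photon transport and track-length KERMA scoring.

Transport is photon-only: Woodcock (delta) tracking against a global majorant,
with free-electron Klein-Nishina Compton scattering, photoelectric absorption
as the residual of the tabulated total attenuation, and an optional
form-factor-free Thomson "Rayleigh" channel.  Dose to water is scored as
collisional KERMA with a track-length estimator: every traversal of length l
through a scored voxel at energy E and weight w contributes
w * E * l * (mu_en/rho)_water(E); division by voxel volume happens outside the
kernel.

The source capsule and drive cable are handled as first-flight attenuation at
emission (analytic ray chords through the iridium core, the steel shell, and a
polyline-of-cylinders cable); metal is not part of the Woodcock geometry.

Randomness is a counter-based splitmix64 stream seeded per history, which makes
runs bit-reproducible and lets paired runs share identical decay samples
(common random numbers).
"""
import math

import numpy as np
from numba import njit

from .geometry import project_to_parabola_impl

U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0

_project = njit(cache=True, inline="always")(project_to_parabola_impl)


@njit(cache=True, inline="always")
def _sm64(state):
    state = state + U64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    z = z ^ (z >> U64(31))
    return state, z


@njit(cache=True, inline="always")
def _u01(state):
    state, z = _sm64(state)
    return state, float(z >> U64(11)) * _INV53


@njit(cache=True, inline="always")
def _init_state(seed, uid):
    s = (U64(seed) + U64(0x9E3779B97F4A7C15)) * U64(0xFF51AFD7ED558CCD)
    s = s ^ ((U64(uid) + U64(1)) * U64(0xC2B2AE3D27D4EB4F))
    s, _ = _sm64(s)
    s, _ = _sm64(s)
    return s


@njit(cache=True, inline="always")
def _interp_e(E, logE0, invdlog, tab):
    f = (math.log(E) - logE0) * invdlog
    if f <= 0.0:
        return tab[0]
    i = int(f)
    if i >= tab.shape[0] - 1:
        return tab[tab.shape[0] - 1]
    w = f - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True, inline="always")
def kn_total_cross_section(E_keV):
    """Klein-Nishina total cross-section per electron (cm^2)."""
    a = E_keV / 511.0
    re2 = 7.940787e-26
    l = math.log(1.0 + 2.0 * a)
    t1 = (1.0 + a) / (a * a) * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - l / a)
    t2 = l / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / ((1.0 + 2.0 * a) ** 2)
    return 2.0 * math.pi * re2 * (t1 + t2 - t3)


@njit(cache=True, inline="always")
def _sample_compton(state, E):
    """Klein-Nishina (E', cos theta) by rejection on x = E'/E."""
    alpha = E / 511.0
    xmin = 1.0 / (1.0 + 2.0 * alpha)
    M = xmin + 1.0 / xmin
    if M < 2.0:
        M = 2.0
    while True:
        state, u1 = _u01(state)
        state, u2 = _u01(state)
        x = xmin + (1.0 - xmin) * u1
        ct = 1.0 - (1.0 - x) / (alpha * x)
        f = x + 1.0 / x - (1.0 - ct * ct)
        if u2 * M <= f:
            return state, x, ct


@njit(cache=True, inline="always")
def _sample_thomson(state):
    while True:
        state, u1 = _u01(state)
        state, u2 = _u01(state)
        ct = 2.0 * u1 - 1.0
        if 2.0 * u2 <= 1.0 + ct * ct:
            return state, ct


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, ct, phi):
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(dz) < 0.999999:
        s = math.sqrt(1.0 - dz * dz)
        nx = (dx * dz * cp - dy * sp) * st / s + dx * ct
        ny = (dy * dz * cp + dx * sp) * st / s + dy * ct
        nz = -s * cp * st + dz * ct
    else:
        sign = 1.0 if dz > 0.0 else -1.0
        nx = st * cp
        ny = sign * st * sp
        nz = sign * ct
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


# ----------------------------------------------------------------- geometry

@njit(cache=True, inline="always")
def _material_at(x, y, z, scene_i, scene_f, cath_x):
    """Resolve a point to a transport material id (0 water, 1 air, 2 silicone, 3 HDPE)."""
    phantom = scene_i[0]
    bend = scene_i[1]
    water_only = scene_i[2]
    ncath = scene_i[3]
    a = scene_f[0]
    hx = scene_f[1]
    hz = scene_f[2]
    ytop = scene_f[3]
    yup = scene_f[4]
    rout = scene_f[5]
    rlum = scene_f[6]
    if bend == 0:
        xf = x
        yf = y
        zf = z
    else:
        if bend == 1:
            u = x
            v = z
        else:
            u = z
            v = x
        t = _project(a, u, y)
        q = 2.0 * a * t
        sn = math.sqrt(1.0 + q * q)
        yf = ((u - t) * q + (y + a * t * t)) / sn
        s = 0.5 * (t * sn + math.asinh(q) / (2.0 * a))
        if bend == 1:
            xf = s
            zf = v
        else:
            xf = v
            zf = s
    if phantom == 1 and yf < -yup:
        return 1  # air upstream of the (possibly bent) boundary surface
    if water_only == 1:
        return 0
    if -yup <= yf <= ytop and -hx <= xf <= hx and -hz <= zf <= hz:
        for c in range(ncath):
            dxc = xf - cath_x[c]
            rr = dxc * dxc + yf * yf
            if rr < rlum * rlum:
                return 1
            if rr < rout * rout:
                return 3
        return 2
    return 0


@njit(cache=True, inline="always")
def _cyl_chord(px, py, pz, dx, dy, dz, cx, cy, cz, ax, ay, az, R, hl):
    """Forward chord length of ray (p, d) through a finite cylinder."""
    rx = px - cx
    ry = py - cy
    rz = pz - cz
    pa = rx * ax + ry * ay + rz * az
    da = dx * ax + dy * ay + dz * az
    prx = rx - pa * ax
    pry = ry - pa * ay
    prz = rz - pa * az
    drx = dx - da * ax
    dry = dy - da * ay
    drz = dz - da * az
    A = drx * drx + dry * dry + drz * drz
    B = 2.0 * (prx * drx + pry * dry + prz * drz)
    C = prx * prx + pry * pry + prz * prz - R * R
    if A < 1e-14:
        if C > 0.0:
            return 0.0
        t0r = -1e30
        t1r = 1e30
    else:
        disc = B * B - 4.0 * A * C
        if disc <= 0.0:
            return 0.0
        sq = math.sqrt(disc)
        t0r = (-B - sq) / (2.0 * A)
        t1r = (-B + sq) / (2.0 * A)
    if abs(da) < 1e-14:
        if abs(pa) > hl:
            return 0.0
        t0a = -1e30
        t1a = 1e30
    else:
        t0a = (-hl - pa) / da
        t1a = (hl - pa) / da
        if t0a > t1a:
            t0a, t1a = t1a, t0a
    lo = max(max(t0r, t0a), 0.0)
    hi = min(t1r, t1a)
    return max(0.0, hi - lo)


@njit(cache=True)
def _metal_attenuation(px, py, pz, dx, dy, dz, cx, cy, cz, ax, ay, az,
                       src, cable_pts, mu_ir, mu_steel):
    """exp(-sum mu*l) through core, capsule shell, and cable polyline."""
    r_act = src[0]
    hl_act = src[1]
    r_cap = src[2]
    hl_cap = src[3]
    r_cab = src[4]
    l_core = _cyl_chord(px, py, pz, dx, dy, dz, cx, cy, cz, ax, ay, az, r_act, hl_act)
    l_cap = _cyl_chord(px, py, pz, dx, dy, dz, cx, cy, cz, ax, ay, az, r_cap, hl_cap)
    l_steel = max(0.0, l_cap - l_core)
    ncp = cable_pts.shape[0]
    for k in range(ncp - 1):
        qx = cable_pts[k, 0]
        qy = cable_pts[k, 1]
        qz = cable_pts[k, 2]
        wx = cable_pts[k + 1, 0] - qx
        wy = cable_pts[k + 1, 1] - qy
        wz = cable_pts[k + 1, 2] - qz
        ln = math.sqrt(wx * wx + wy * wy + wz * wz)
        if ln < 1e-12:
            continue
        l_steel += _cyl_chord(px, py, pz, dx, dy, dz,
                              qx + 0.5 * wx, qy + 0.5 * wy, qz + 0.5 * wz,
                              wx / ln, wy / ln, wz / ln, r_cab, 0.5 * ln)
    arg = mu_ir * l_core + mu_steel * l_steel
    if arg <= 0.0:
        return 1.0
    return math.exp(-arg)


# ------------------------------------------------------------------- scorers

@njit(cache=True, inline="always")
def _clip_box(px, py, pz, dx, dy, dz, L, lo0, lo1, lo2, hi0, hi1, hi2):
    t0 = 0.0
    t1 = L
    for axis in range(3):
        if axis == 0:
            p = px
            d = dx
            lo = lo0
            hi = hi0
        elif axis == 1:
            p = py
            d = dy
            lo = lo1
            hi = hi1
        else:
            p = pz
            d = dz
            lo = lo2
            hi = hi2
        if abs(d) < 1e-14:
            if p < lo or p > hi:
                return 1.0, 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True)
def _score_grid(px, py, pz, dx, dy, dz, L, fac,
                ox, oy, oz, sx, sy, sz, nx, ny, nz, acc):
    """Exact voxel traversal (Amanatides-Woo) over an axis-aligned grid."""
    t0, t1 = _clip_box(px, py, pz, dx, dy, dz, L,
                       ox, oy, oz, ox + nx * sx, oy + ny * sy, oz + nz * sz)
    if t0 >= t1:
        return
    eps = 1e-10
    t = t0 + eps
    x = px + t * dx
    y = py + t * dy
    z = pz + t * dz
    ix = int((x - ox) / sx)
    iy = int((y - oy) / sy)
    iz = int((z - oz) / sz)
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz >= nz:
        iz = nz - 1
    stepx = 1 if dx > 0 else -1
    stepy = 1 if dy > 0 else -1
    stepz = 1 if dz > 0 else -1
    big = 1e30
    if abs(dx) > 1e-14:
        tmx = ((ox + (ix + (1 if dx > 0 else 0)) * sx) - px) / dx
        tdx = abs(sx / dx)
    else:
        tmx = big
        tdx = big
    if abs(dy) > 1e-14:
        tmy = ((oy + (iy + (1 if dy > 0 else 0)) * sy) - py) / dy
        tdy = abs(sy / dy)
    else:
        tmy = big
        tdy = big
    if abs(dz) > 1e-14:
        tmz = ((oz + (iz + (1 if dz > 0 else 0)) * sz) - pz) / dz
        tdz = abs(sz / dz)
    else:
        tmz = big
        tdz = big
    t = t0
    while t < t1 - 1e-12:
        tn = tmx
        if tmy < tn:
            tn = tmy
        if tmz < tn:
            tn = tmz
        if tn > t1:
            tn = t1
        acc[ix, iy, iz] += (tn - t) * fac
        t = tn
        if t >= t1 - 1e-12:
            break
        if tmx <= tmy and tmx <= tmz:
            ix += stepx
            tmx += tdx
            if ix < 0 or ix >= nx:
                break
        elif tmy <= tmz:
            iy += stepy
            tmy += tdy
            if iy < 0 or iy >= ny:
                break
        else:
            iz += stepz
            tmz += tdz
            if iz < 0 or iz >= nz:
                break


@njit(cache=True)
def _score_deformed(px, py, pz, dx, dy, dz, L, fac, a, bend_axis, sub,
                    lo0, lo1, lo2, hi0, hi1, hi2,
                    ox, oy, oz, sx, sy, sz, nx, ny, nz, acc):
    """Sub-stepped scoring into a flat-frame grid mapped onto the bent geometry.

    Each substep midpoint is projected onto the bent surface; its (arc length,
    transverse, normal-distance) coordinates index the flat grid, and the local
    volume Jacobian 1 + d*kappa reweights the contribution.
    """
    t0, t1 = _clip_box(px, py, pz, dx, dy, dz, L, lo0, lo1, lo2, hi0, hi1, hi2)
    if t0 >= t1:
        return
    n = int((t1 - t0) / sub) + 1
    dt = (t1 - t0) / n
    for i in range(n):
        tm = t0 + (i + 0.5) * dt
        x = px + tm * dx
        y = py + tm * dy
        z = pz + tm * dz
        if bend_axis == 1:
            u = x
            v = z
        else:
            u = z
            v = x
        tp = _project(a, u, y)
        q = 2.0 * a * tp
        sn = math.sqrt(1.0 + q * q)
        dsg = ((u - tp) * q + (y + a * tp * tp)) / sn
        s = 0.5 * (tp * sn + math.asinh(q) / (2.0 * a))
        if bend_axis == 1:
            xf = s
            zf = v
        else:
            xf = v
            zf = s
        kappa = 2.0 * a / (sn * sn * sn)
        jac = 1.0 + dsg * kappa
        if jac <= 1e-9:
            continue
        ix = int(math.floor((xf - ox) / sx))
        if ix < 0 or ix >= nx:
            continue
        iy = int(math.floor((dsg - oy) / sy))
        if iy < 0 or iy >= ny:
            continue
        iz = int(math.floor((zf - oz) / sz))
        if iz < 0 or iz >= nz:
            continue
        acc[ix, iy, iz] += dt * fac / jac


@njit(cache=True)
def _score_polar(px, py, pz, dx, dy, dz, L, fac,
                 r_edges, th_edges, acc, sub_min, sub_frac):
    """Score a segment into (r, theta) bins about the origin, axis = z.

    Radial assignment is exact: the segment is split at every shell-edge
    crossing (r(t)^2 is quadratic in t), so each sub-interval lies in one
    shell.  Within a sub-interval the polar angle is assigned at midpoints of
    short angular substeps; angular misassignment averages out over isotropic
    directions.
    """
    nr = acc.shape[0]
    nt = acc.shape[1]
    rmax = r_edges[nr]
    b = px * dx + py * dy + pz * dz
    a0 = px * px + py * py + pz * pz
    disc = b * b - (a0 - rmax * rmax)
    if disc <= 0.0:
        return
    sq = math.sqrt(disc)
    t0 = max(0.0, -b - sq)
    t1 = min(L, -b + sq)
    if t0 >= t1:
        return
    cross = np.empty(2 * nr + 4)
    nc = 0
    cross[nc] = t0
    nc += 1
    cross[nc] = t1
    nc += 1
    for ie in range(nr + 1):
        re_ = r_edges[ie]
        dd = b * b - (a0 - re_ * re_)
        if dd > 0.0:
            sd = math.sqrt(dd)
            tm_ = -b - sd
            if t0 < tm_ < t1:
                cross[nc] = tm_
                nc += 1
            tp_ = -b + sd
            if t0 < tp_ < t1:
                cross[nc] = tp_
                nc += 1
    for i in range(1, nc):
        key = cross[i]
        j = i - 1
        while j >= 0 and cross[j] > key:
            cross[j + 1] = cross[j]
            j -= 1
        cross[j + 1] = key
    for k in range(nc - 1):
        ta = cross[k]
        tb = cross[k + 1]
        seg = tb - ta
        if seg <= 1e-14:
            continue
        tm = 0.5 * (ta + tb)
        rm2 = tm * tm + 2.0 * b * tm + a0
        if rm2 <= 1e-24:
            continue
        rm = math.sqrt(rm2)
        ir = np.searchsorted(r_edges, rm) - 1
        if ir < 0 or ir >= nr:
            continue
        nsub = int(seg / (0.25 * rm)) + 1
        dts = seg / nsub
        for s_ in range(nsub):
            ts = ta + (s_ + 0.5) * dts
            zm = pz + ts * dz
            rr2 = ts * ts + 2.0 * b * ts + a0
            rr = math.sqrt(max(rr2, 1e-24))
            cz = zm / rr
            if cz > 1.0:
                cz = 1.0
            elif cz < -1.0:
                cz = -1.0
            th = math.acos(cz)
            it = np.searchsorted(th_edges, th) - 1
            if it < 0:
                it = 0
            elif it >= nt:
                it = nt - 1
            acc[ir, it] += dts * fac


# ---------------------------------------------------------------- main kernel

@njit(cache=True)
def run_batch(seed, uid0, nh,
              dpos, dax, de1, de2, src, cable_pts,
              spec_E, spec_cdf,
              logE0, invdlog, mu_t, mu_maj, mu_en, ne_cm3, mu_metal,
              coh_frac,
              scene_i, scene_f, cath_x,
              cutoff, rayleigh, primary_only, metal_on,
              smode,
              g1o, g1sp, g1n, acc1, aabb1,
              g2o, g2sp, g2n, acc2, aabb2,
              deformed, substep,
              r_edges, th_edges, accp, psub_min, psub_frac,
              emission_mode, pencil):
    """Transport one batch of histories and accumulate raw track-length scores.

    Scores are w*E*l*(mu_en/rho)_w sums; divide by voxel volume outside.
    """
    world = scene_f[7]
    a_bend = scene_f[0]
    bend_axis = scene_i[1]
    ndw = dpos.shape[0]
    use_g1 = g1n[0] > 0
    use_g2 = g2n[0] > 0
    for dw in range(ndw):
        cx = dpos[dw, 0]
        cy = dpos[dw, 1]
        cz = dpos[dw, 2]
        ax = dax[dw, 0]
        ay = dax[dw, 1]
        az = dax[dw, 2]
        for h in range(nh[dw]):
            state = _init_state(seed, uid0[dw] + h)
            # --- emission
            if emission_mode == 0:
                state, u = _u01(state)
                rr = src[0] * math.sqrt(u)
                state, u = _u01(state)
                phi = 6.283185307179586 * u
                state, u = _u01(state)
                along = src[1] * (2.0 * u - 1.0)
                crx = rr * math.cos(phi)
                cry = rr * math.sin(phi)
                px = cx + along * ax + crx * de1[dw, 0] + cry * de2[dw, 0]
                py = cy + along * ay + crx * de1[dw, 1] + cry * de2[dw, 1]
                pz = cz + along * az + crx * de1[dw, 2] + cry * de2[dw, 2]
                state, u = _u01(state)
                ct = 2.0 * u - 1.0
                st = math.sqrt(max(0.0, 1.0 - ct * ct))
                state, u = _u01(state)
                psi = 6.283185307179586 * u
                dx = st * math.cos(psi)
                dy = st * math.sin(psi)
                dz = ct
                state, u = _u01(state)
                il = np.searchsorted(spec_cdf, u)
                if il >= spec_E.shape[0]:
                    il = spec_E.shape[0] - 1
                E = spec_E[il]
                w = 1.0
                if metal_on == 1:
                    mu_ir = _interp_e(E, logE0, invdlog, mu_metal[0])
                    mu_st = _interp_e(E, logE0, invdlog, mu_metal[1])
                    w = _metal_attenuation(px, py, pz, dx, dy, dz,
                                           cx, cy, cz, ax, ay, az,
                                           src, cable_pts[dw], mu_ir, mu_st)
            else:
                px = pencil[0]
                py = pencil[1]
                pz = pencil[2]
                dx = pencil[3]
                dy = pencil[4]
                dz = pencil[5]
                E = pencil[6]
                w = 1.0
            # --- transport
            fac = w * E * _interp_e(E, logE0, invdlog, mu_en)
            mum = _interp_e(E, logE0, invdlog, mu_maj)
            if mum < 1e-30:
                mum = 1e-30
            alive = True
            while alive:
                state, u = _u01(state)
                step = -math.log(u) / mum
                # score the flight segment
                if smode == 1:
                    _score_polar(px, py, pz, dx, dy, dz, step, fac,
                                 r_edges, th_edges, accp, psub_min, psub_frac)
                else:
                    if use_g1:
                        if deformed == 1:
                            _score_deformed(px, py, pz, dx, dy, dz, step, fac,
                                            a_bend, bend_axis, substep,
                                            aabb1[0], aabb1[1], aabb1[2],
                                            aabb1[3], aabb1[4], aabb1[5],
                                            g1o[0], g1o[1], g1o[2],
                                            g1sp[0], g1sp[1], g1sp[2],
                                            g1n[0], g1n[1], g1n[2], acc1)
                        else:
                            _score_grid(px, py, pz, dx, dy, dz, step, fac,
                                        g1o[0], g1o[1], g1o[2],
                                        g1sp[0], g1sp[1], g1sp[2],
                                        g1n[0], g1n[1], g1n[2], acc1)
                    if use_g2:
                        if deformed == 1:
                            _score_deformed(px, py, pz, dx, dy, dz, step, fac,
                                            a_bend, bend_axis, substep,
                                            aabb2[0], aabb2[1], aabb2[2],
                                            aabb2[3], aabb2[4], aabb2[5],
                                            g2o[0], g2o[1], g2o[2],
                                            g2sp[0], g2sp[1], g2sp[2],
                                            g2n[0], g2n[1], g2n[2], acc2)
                        else:
                            _score_grid(px, py, pz, dx, dy, dz, step, fac,
                                        g2o[0], g2o[1], g2o[2],
                                        g2sp[0], g2sp[1], g2sp[2],
                                        g2n[0], g2n[1], g2n[2], acc2)
                px += step * dx
                py += step * dy
                pz += step * dz
                if abs(px) > world or abs(py) > world or abs(pz) > world:
                    break
                m = _material_at(px, py, pz, scene_i, scene_f, cath_x)
                mut = _interp_e(E, logE0, invdlog, mu_t[m])
                state, u = _u01(state)
                if u * mum > mut:
                    continue  # null collision
                if primary_only == 1:
                    break
                p_inc = kn_total_cross_section(E) * ne_cm3[m] / mut
                if p_inc > 1.0:
                    p_inc = 1.0
                state, u = _u01(state)
                if u < p_inc:
                    state, xr, ctx = _sample_compton(state, E)
                    E = E * xr
                    if E < cutoff:
                        break
                    state, uu = _u01(state)
                    dx, dy, dz = _rotate(dx, dy, dz, ctx, 6.283185307179586 * uu)
                    fac = w * E * _interp_e(E, logE0, invdlog, mu_en)
                    mum = _interp_e(E, logE0, invdlog, mu_maj)
                    if mum < 1e-30:
                        mum = 1e-30
                elif rayleigh == 1:
                    pc = coh_frac[0] if coh_frac.shape[0] == 1 else _interp_e(
                        E, logE0, invdlog, coh_frac)
                    if pc > 1.0 - p_inc:
                        pc = 1.0 - p_inc
                    if u < p_inc + pc:
                        state, ctr = _sample_thomson(state)
                        state, uu = _u01(state)
                        dx, dy, dz = _rotate(dx, dy, dz, ctr, 6.283185307179586 * uu)
                    else:
                        break  # photoelectric
                else:
                    break  # photoelectric
    return 0


@njit(cache=True)
def sample_compton_batch(seed, E, n, out_x, out_ct):
    """Draw n Klein-Nishina samples at fixed energy (test/inspection helper)."""
    state = _init_state(seed, 0)
    for i in range(n):
        state, x, ct = _sample_compton(state, E)
        out_x[i] = x
        out_ct[i] = ct
    return 0
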