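"""Numba kernels: pair/bonded/wall forces, the step loop, and a Langevin sampler.

All kernels work in reduced DPD units (r_c = k_B T = m = 1, tau the derived
time unit).  Randomness is counter-based: every Gaussian draw is a pure hash
of (seed, step, i, j) so that per-pair draws are symmetric by construction
and trajectories are bit-reproducible under any pair iteration order.
"""

import math

import numpy as np
from numba import njit

U64 = np.uint64

_SM_M1 = U64(0xBF58476D1CE4E5B9)
_SM_M2 = U64(0x94D049BB133111EB)
_C_STEP = U64(0xD6E8FEB86659FD93)
_C_I = U64(0xA24BAED4963EE407)
_C_J = U64(0x9FB21C651E98DF25)
_C_ALT = U64(0x9E3779B97F4A7C15)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53
_TWO_PI = 2.0 * math.pi

ROLE_FREE = 0
ROLE_TETHERED = 1
ROLE_DRIVEN = 2


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * _SM_M1
    z = (z ^ (z >> U64(27))) * _SM_M2
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _inv_norm_cdf(p):
    """Acklam's rational approximation of the standard normal quantile
    (relative error ~1e-9); transcendental-free in the central region."""
    if p < 0.02425:
        q = math.sqrt(-2.0 * math.log(p))
        return (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                   - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                 + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q
             + 1.0)
    if p > 1.0 - 0.02425:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        return -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                    - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
                  + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q
             + 1.0)
    q = p - 0.5
    r = q * q
    return (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
               - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
             - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
        (((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
            - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
          - 1.328068155288572e+01) * r + 1.0)


@njit(cache=True, inline="always")
def _counter_gauss(seed, step, i, j):
    """One standard normal keyed by (seed, step, i, j); symmetric if i < j fed."""
    h = _mix64(U64(seed) ^ (U64(step) * _C_STEP))
    h = _mix64(h ^ (U64(i) * _C_I))
    h = _mix64(h ^ (U64(j) * _C_J))
    u = (np.float64(h >> U64(11)) + 0.5) * _INV53  # (0, 1)
    return _inv_norm_cdf(u)


@njit(cache=True, inline="always")
def _min_image(d, L, per):
    if per:
        d -= L * math.floor(d / L + 0.5)
    return d


@njit(cache=True, inline="always")
def _in_excl(excl_keys, key):
    lo = 0
    hi = excl_keys.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if excl_keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < excl_keys.shape[0] and excl_keys[lo] == key


@njit(cache=True, inline="always")
def _pair_kernel(i, j, pos, vel, species, a, beta, rc, kBT, dt,
                 L, per, step, seed, f_out, sf_out, track_solvent, excl_keys):
    """Accumulate the C+D+R force of one candidate pair.  Returns 1 if degenerate."""
    n = pos.shape[0]
    dx = _min_image(pos[i, 0] - pos[j, 0], L[0], per[0])
    dy = _min_image(pos[i, 1] - pos[j, 1], L[1], per[1])
    dz = _min_image(pos[i, 2] - pos[j, 2], L[2], per[2])
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc:
        return 0
    if r2 < 1e-24:
        return 1
    if excl_keys.shape[0] > 0:
        ii, jj = (i, j) if i < j else (j, i)
        if _in_excl(excl_keys, np.int64(ii) * np.int64(n) + np.int64(jj)):
            return 0
    r = math.sqrt(r2)
    w = 1.0 - r / rc
    ex = dx / r
    ey = dy / r
    ez = dz / r
    si = species[i]
    sj = species[j]
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    ev = ex * vx + ey * vy + ez * vz
    b = beta[si, sj]
    sigma = math.sqrt(2.0 * b * kBT / dt)
    ii = i if i < j else j
    jj = j if i < j else i
    alpha = _counter_gauss(seed, step, ii, jj)
    fmag = a[si, sj] * w - b * w * w * ev + sigma * w * alpha
    fx = fmag * ex
    fy = fmag * ey
    fz = fmag * ez
    f_out[i, 0] += fx
    f_out[i, 1] += fy
    f_out[i, 2] += fz
    f_out[j, 0] -= fx
    f_out[j, 1] -= fy
    f_out[j, 2] -= fz
    if track_solvent:
        if sj == 0 and si != 0:
            sf_out[i, 0] += fx
            sf_out[i, 1] += fy
            sf_out[i, 2] += fz
        if si == 0 and sj != 0:
            sf_out[j, 0] -= fx
            sf_out[j, 1] -= fy
            sf_out[j, 2] -= fz
    return 0


@njit(cache=True)
def pair_forces_brute(pos, vel, species, a, beta, rc, kBT, dt, L, per,
                      step, seed, f_out, sf_out, track_solvent, excl_keys):
    """O(N^2) pair loop; used for tiny systems and boxes < 3 r_c across."""
    n = pos.shape[0]
    ndegen = 0
    for i in range(n):
        for j in range(i + 1, n):
            ndegen += _pair_kernel(i, j, pos, vel, species, a, beta, rc, kBT,
                                   dt, L, per, step, seed, f_out, sf_out,
                                   track_solvent, excl_keys)
    return ndegen


#: forward half-stencil of neighbor-cell offsets (13 of 26)
_HALF_STENCIL = np.array(
    [(ox, oy, oz)
     for ox in (-1, 0, 1) for oy in (-1, 0, 1) for oz in (-1, 0, 1)
     if (ox > 0) or (ox == 0 and oy > 0) or (ox == 0 and oy == 0 and oz > 0)],
    dtype=np.int64)


@njit(cache=True, fastmath=True)
def pair_forces_cells(pos, vel, species, a, beta, rc, kBT, dt, L, per,
                      step, seed, f_out, sf_out, track_solvent, excl_keys):
    """Cell-list pair loop (cell edge >= r_c, rebuilt on every call).

    Particles are gathered in cell-sorted order for cache locality; the
    forward half stencil visits each cell pair once, with the periodic image
    shift applied per neighbor cell.  Requires >= 3 cells along every
    periodic axis (the engine falls back to the brute-force loop otherwise).
    """
    n = pos.shape[0]
    ncx = max(1, int(L[0] // rc))
    ncy = max(1, int(L[1] // rc))
    ncz = max(1, int(L[2] // rc))
    ncell = ncx * ncy * ncz
    rc2 = rc * rc
    has_excl = excl_keys.shape[0] > 0
    nsp = a.shape[0]
    sigma = np.empty((nsp, nsp))
    for s1 in range(nsp):
        for s2 in range(nsp):
            sigma[s1, s2] = math.sqrt(2.0 * beta[s1, s2] * kBT / dt)

    # counting sort of particles into cells
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for p in range(n):
        cx = int(pos[p, 0] / L[0] * ncx)
        cy = int(pos[p, 1] / L[1] * ncy)
        cz = int(pos[p, 2] / L[2] * ncz)
        if cx < 0:
            cx = 0
        elif cx >= ncx:
            cx = ncx - 1
        if cy < 0:
            cy = 0
        elif cy >= ncy:
            cy = ncy - 1
        if cz < 0:
            cz = 0
        elif cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[p] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    start = count  # start[c]..start[c+1] slices the sorted arrays
    cursor = start[:-1].copy()
    gid = np.empty(n, dtype=np.int64)
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    vxs = np.empty(n)
    vys = np.empty(n)
    vzs = np.empty(n)
    sp = np.empty(n, dtype=np.int64)
    for p in range(n):
        k = cursor[cell_of[p]]
        cursor[cell_of[p]] += 1
        gid[k] = p
        xs[k] = pos[p, 0]
        ys[k] = pos[p, 1]
        zs[k] = pos[p, 2]
        vxs[k] = vel[p, 0]
        vys[k] = vel[p, 1]
        vzs[k] = vel[p, 2]
        sp[k] = species[p]
    fxs = np.zeros(n)
    fys = np.zeros(n)
    fzs = np.zeros(n)
    sfx = np.zeros(n) if track_solvent else np.zeros(0)
    sfy = np.zeros(n) if track_solvent else np.zeros(0)
    sfz = np.zeros(n) if track_solvent else np.zeros(0)

    ndegen = 0
    nstencil = _HALF_STENCIL.shape[0]
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0 = start[c]
                a1 = start[c + 1]
                # self cell plus 13 forward neighbors (ns = -1 marks self)
                for ns in range(-1, nstencil):
                    if ns < 0:
                        b0i = a0
                        b1i = a1
                        shx = 0.0
                        shy = 0.0
                        shz = 0.0
                    else:
                        nx = cx + _HALF_STENCIL[ns, 0]
                        ny = cy + _HALF_STENCIL[ns, 1]
                        nz = cz + _HALF_STENCIL[ns, 2]
                        shx = 0.0
                        shy = 0.0
                        shz = 0.0
                        if nx < 0:
                            if not per[0]:
                                continue
                            nx += ncx
                            shx = -L[0]
                        elif nx >= ncx:
                            if not per[0]:
                                continue
                            nx -= ncx
                            shx = L[0]
                        if ny < 0:
                            if not per[1]:
                                continue
                            ny += ncy
                            shy = -L[1]
                        elif ny >= ncy:
                            if not per[1]:
                                continue
                            ny -= ncy
                            shy = L[1]
                        if nz < 0:
                            if not per[2]:
                                continue
                            nz += ncz
                            shz = -L[2]
                        elif nz >= ncz:
                            if not per[2]:
                                continue
                            nz -= ncz
                            shz = L[2]
                        nc = (nx * ncy + ny) * ncz + nz
                        b0i = start[nc]
                        b1i = start[nc + 1]
                    for ka in range(a0, a1):
                        xi = xs[ka]
                        yi = ys[ka]
                        zi = zs[ka]
                        kb0 = ka + 1 if ns < 0 else b0i
                        for kb in range(kb0, b1i):
                            dx = xi - xs[kb] - shx
                            dy = yi - ys[kb] - shy
                            dz = zi - zs[kb] - shz
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= rc2:
                                continue
                            if r2 < 1e-24:
                                ndegen += 1
                                continue
                            gi = gid[ka]
                            gj = gid[kb]
                            if has_excl:
                                lo, hi = (gi, gj) if gi < gj else (gj, gi)
                                if _in_excl(excl_keys,
                                            np.int64(lo) * np.int64(n)
                                            + np.int64(hi)):
                                    continue
                            r = math.sqrt(r2)
                            w = 1.0 - r / rc
                            inv_r = 1.0 / r
                            ex = dx * inv_r
                            ey = dy * inv_r
                            ez = dz * inv_r
                            si = sp[ka]
                            sj = sp[kb]
                            ev = (ex * (vxs[ka] - vxs[kb])
                                  + ey * (vys[ka] - vys[kb])
                                  + ez * (vzs[ka] - vzs[kb]))
                            lo, hi = (gi, gj) if gi < gj else (gj, gi)
                            alpha = _counter_gauss(seed, step, lo, hi)
                            fmag = (a[si, sj] * w
                                    - beta[si, sj] * w * w * ev
                                    + sigma[si, sj] * w * alpha)
                            fx = fmag * ex
                            fy = fmag * ey
                            fz = fmag * ez
                            fxs[ka] += fx
                            fys[ka] += fy
                            fzs[ka] += fz
                            fxs[kb] -= fx
                            fys[kb] -= fy
                            fzs[kb] -= fz
                            if track_solvent:
                                if sj == 0 and si != 0:
                                    sfx[ka] += fx
                                    sfy[ka] += fy
                                    sfz[ka] += fz
                                if si == 0 and sj != 0:
                                    sfx[kb] -= fx
                                    sfy[kb] -= fy
                                    sfz[kb] -= fz
    # scatter back to particle order
    for k in range(n):
        p = gid[k]
        f_out[p, 0] += fxs[k]
        f_out[p, 1] += fys[k]
        f_out[p, 2] += fzs[k]
        if track_solvent:
            sf_out[p, 0] += sfx[k]
            sf_out[p, 1] += sfy[k]
            sf_out[p, 2] += sfz[k]
    return ndegen


@njit(cache=True)
def bond_forces(pos, bonds, ks, b0, L, per, f_out):
    """Harmonic bonds E = k_s (r - b0)^2.  Returns (energy, n_degenerate)."""
    e = 0.0
    ndegen = 0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], L[0], per[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], L[1], per[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], L[2], per[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            ndegen += 1
            continue
        dr = r - b0[b]
        e += ks[b] * dr * dr
        fmag = -2.0 * ks[b] * dr / r
        f_out[i, 0] += fmag * dx
        f_out[i, 1] += fmag * dy
        f_out[i, 2] += fmag * dz
        f_out[j, 0] -= fmag * dx
        f_out[j, 1] -= fmag * dy
        f_out[j, 2] -= fmag * dz
    return e, ndegen


@njit(cache=True)
def angle_forces(pos, angles, kE, phi0, L, per, f_out):
    """Harmonic bending E = (k_E/2)(phi - phi0)^2 on consecutive triples.

    Returns (energy, n_degenerate).  phi in [0, pi] from the arm vectors at the
    central bead; the (phi - phi0)/sin(phi) factor is finite at phi -> pi.
    """
    e = 0.0
    ndegen = 0
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]  # central bead
        k = angles[t, 2]
        ax = _min_image(pos[i, 0] - pos[j, 0], L[0], per[0])
        ay = _min_image(pos[i, 1] - pos[j, 1], L[1], per[1])
        az = _min_image(pos[i, 2] - pos[j, 2], L[2], per[2])
        bx = _min_image(pos[k, 0] - pos[j, 0], L[0], per[0])
        by = _min_image(pos[k, 1] - pos[j, 1], L[1], per[1])
        bz = _min_image(pos[k, 2] - pos[j, 2], L[2], per[2])
        ra = math.sqrt(ax * ax + ay * ay + az * az)
        rb = math.sqrt(bx * bx + by * by + bz * bz)
        if ra < 1e-12 or rb < 1e-12:
            ndegen += 1
            continue
        c = (ax * bx + ay * by + az * bz) / (ra * rb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = math.acos(c)
        dphi = phi - phi0[t]
        e += 0.5 * kE[t] * dphi * dphi
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = kE[t] * dphi / s
        # d(cos phi)/d r_i and /d r_k
        dcix = bx / (ra * rb) - c * ax / (ra * ra)
        dciy = by / (ra * rb) - c * ay / (ra * ra)
        dciz = bz / (ra * rb) - c * az / (ra * ra)
        dckx = ax / (ra * rb) - c * bx / (rb * rb)
        dcky = ay / (ra * rb) - c * by / (rb * rb)
        dckz = az / (ra * rb) - c * bz / (rb * rb)
        fix = coef * dcix
        fiy = coef * dciy
        fiz = coef * dciz
        fkx = coef * dckx
        fky = coef * dcky
        fkz = coef * dckz
        f_out[i, 0] += fix
        f_out[i, 1] += fiy
        f_out[i, 2] += fiz
        f_out[k, 0] += fkx
        f_out[k, 1] += fky
        f_out[k, 2] += fkz
        f_out[j, 0] -= fix + fkx
        f_out[j, 1] -= fiy + fky
        f_out[j, 2] -= fiz + fkz
    return e, ndegen


@njit(cache=True)
def wall_forces(pos, Ly, a_wall, rc, f_out):
    """Soft repulsion a_wall (1 - y/r_c) perpendicular to the y = 0 and y = Ly walls."""
    for p in range(pos.shape[0]):
        y = pos[p, 1]
        if y < rc:
            f_out[p, 1] += a_wall * (1.0 - y / rc)
        if y > Ly - rc:
            f_out[p, 1] -= a_wall * (1.0 - (Ly - y) / rc)


@njit(cache=True)
def total_forces(pos, vel, species, role, a, beta, rc, kBT, dt, L, per,
                 walled, a_wall, bonds, bond_ks, bond_b0,
                 angles, angle_kE, angle_phi0, body_force, pois_fx,
                 step, seed, f_out, sf_out, track_solvent, excl_keys,
                 use_cells):
    f_out[:] = 0.0
    if track_solvent:
        sf_out[:] = 0.0
    if use_cells:
        nd = pair_forces_cells(pos, vel, species, a, beta, rc, kBT, dt, L, per,
                               step, seed, f_out, sf_out, track_solvent,
                               excl_keys)
    else:
        nd = pair_forces_brute(pos, vel, species, a, beta, rc, kBT, dt, L, per,
                               step, seed, f_out, sf_out, track_solvent,
                               excl_keys)
    eb, ndb = bond_forces(pos, bonds, bond_ks, bond_b0, L, per, f_out)
    ea, nda = angle_forces(pos, angles, angle_kE, angle_phi0, L, per, f_out)
    if walled:
        wall_forces(pos, L[1], a_wall, rc, f_out)
    half_z = 0.5 * L[2]
    for p in range(pos.shape[0]):
        s = species[p]
        f_out[p, 0] += body_force[s, 0]
        f_out[p, 1] += body_force[s, 1]
        f_out[p, 2] += body_force[s, 2]
        if pois_fx != 0.0:
            # counter-flowing x body force by z half (viscosity calibration)
            if pos[p, 2] < half_z:
                f_out[p, 0] += pois_fx
            else:
                f_out[p, 0] -= pois_fx
    return nd + ndb + nda


@njit(cache=True)
def run_nsteps(pos, vel, frc, species, role, mass, drive,
               a, beta, rc, kBT, dt, lam, L, per, walled, a_wall,
               bonds, bond_ks, bond_b0, angles, angle_kE, angle_phi0,
               body_force, pois_fx, excl_keys, seed, step0, nsteps,
               track_solvent, sf_out, use_cells, vpred, fnew):
    """Advance nsteps of the modified velocity-Verlet (Groot-Warren) scheme.

    frc must hold the forces of the current configuration on entry and holds
    the forces of the final configuration on exit.  Free particles integrate;
    tethered particles stay put; driven particles advance kinematically.
    Returns (n_degenerate_pairs, finite_ok).
    """
    n = pos.shape[0]
    ndegen = 0
    for s in range(step0, step0 + nsteps):
        # position update + boundary handling
        for p in range(n):
            if role[p] == ROLE_FREE:
                im = 1.0 / mass[p]
                pos[p, 0] += dt * vel[p, 0] + 0.5 * dt * dt * frc[p, 0] * im
                pos[p, 1] += dt * vel[p, 1] + 0.5 * dt * dt * frc[p, 1] * im
                pos[p, 2] += dt * vel[p, 2] + 0.5 * dt * dt * frc[p, 2] * im
            elif role[p] == ROLE_DRIVEN:
                pos[p, 0] += dt * drive[p, 0]
                pos[p, 1] += dt * drive[p, 1]
                pos[p, 2] += dt * drive[p, 2]
            for d in range(3):
                if per[d]:
                    if pos[p, d] < 0.0:
                        pos[p, d] += L[d]
                    elif pos[p, d] >= L[d]:
                        pos[p, d] -= L[d]
                else:
                    # reflective containment at the walls
                    if pos[p, d] < 0.0:
                        pos[p, d] = -pos[p, d]
                        vel[p, d] = -vel[p, d]
                    elif pos[p, d] > L[d]:
                        pos[p, d] = 2.0 * L[d] - pos[p, d]
                        vel[p, d] = -vel[p, d]
        # predicted velocities for the dissipative force
        for p in range(n):
            if role[p] == ROLE_FREE:
                im = 1.0 / mass[p]
                vpred[p, 0] = vel[p, 0] + lam * dt * frc[p, 0] * im
                vpred[p, 1] = vel[p, 1] + lam * dt * frc[p, 1] * im
                vpred[p, 2] = vel[p, 2] + lam * dt * frc[p, 2] * im
            elif role[p] == ROLE_DRIVEN:
                vpred[p, 0] = drive[p, 0]
                vpred[p, 1] = drive[p, 1]
                vpred[p, 2] = drive[p, 2]
            else:
                vpred[p, 0] = 0.0
                vpred[p, 1] = 0.0
                vpred[p, 2] = 0.0
        ndegen += total_forces(pos, vpred, species, role, a, beta, rc, kBT, dt,
                               L, per, walled, a_wall, bonds, bond_ks, bond_b0,
                               angles, angle_kE, angle_phi0, body_force,
                               pois_fx, s, seed, fnew, sf_out, track_solvent,
                               excl_keys, use_cells)
        # corrector
        for p in range(n):
            if role[p] == ROLE_FREE:
                im = 1.0 / mass[p]
                vel[p, 0] += 0.5 * dt * (frc[p, 0] + fnew[p, 0]) * im
                vel[p, 1] += 0.5 * dt * (frc[p, 1] + fnew[p, 1]) * im
                vel[p, 2] += 0.5 * dt * (frc[p, 2] + fnew[p, 2]) * im
            elif role[p] == ROLE_DRIVEN:
                vel[p, 0] = drive[p, 0]
                vel[p, 1] = drive[p, 1]
                vel[p, 2] = drive[p, 2]
            else:
                vel[p, 0] = 0.0
                vel[p, 1] = 0.0
                vel[p, 2] = 0.0
            frc[p, 0] = fnew[p, 0]
            frc[p, 1] = fnew[p, 1]
            frc[p, 2] = fnew[p, 2]
    ok = True
    for p in range(n):
        for d in range(3):
            if not math.isfinite(pos[p, d]) or not math.isfinite(vel[p, d]):
                ok = False
    return ndegen, ok


@njit(cache=True)
def langevin_sample(pos, vel, mass, bonds, bond_ks, bond_b0,
                    angles, angle_kE, angle_phi0, kBT, gamma, dt,
                    nsteps, sample_every, seed, freeze_z, out_pos):
    """BAOAB Langevin sampler for isolated bonded molecules (no pair forces).

    Used for equilibrium fluctuation diagnostics of the bond and bending
    potentials.  freeze_z restricts the dynamics to the x-y plane.
    Snapshots every sample_every steps go to out_pos; returns count stored.
    """
    n = pos.shape[0]
    big = np.array([1e12, 1e12, 1e12])
    noper = np.array([False, False, False])
    f = np.zeros((n, 3))
    bond_forces(pos, bonds, bond_ks, bond_b0, big, noper, f)
    angle_forces(pos, angles, angle_kE, angle_phi0, big, noper, f)
    c1 = math.exp(-gamma * dt)
    nsamp = 0
    for s in range(nsteps):
        for p in range(n):
            im = 1.0 / mass[p]
            ndim = 2 if freeze_z else 3
            for d in range(ndim):
                vel[p, d] += 0.5 * dt * f[p, d] * im
                pos[p, d] += 0.5 * dt * vel[p, d]
                c2 = math.sqrt(kBT * (1.0 - c1 * c1) * im)
                xi = _counter_gauss(seed, s, p, d)
                vel[p, d] = c1 * vel[p, d] + c2 * xi
                pos[p, d] += 0.5 * dt * vel[p, d]
        f[:] = 0.0
        bond_forces(pos, bonds, bond_ks, bond_b0, big, noper, f)
        angle_forces(pos, angles, angle_kE, angle_phi0, big, noper, f)
        for p in range(n):
            im = 1.0 / mass[p]
            ndim = 2 if freeze_z else 3
            for d in range(ndim):
                vel[p, d] += 0.5 * dt * f[p, d] * im
        if (s + 1) % sample_every == 0 and nsamp < out_pos.shape[0]:
            for p in range(n):
                for d in range(3):
                    out_pos[nsamp, p, d] = pos[p, d]
            nsamp += 1
    return nsamp
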