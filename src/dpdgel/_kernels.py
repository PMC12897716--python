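"""Numba kernels: neighbour lists, force loops, and integrator drivers.

Everything here operates on plain arrays in reduced units.  Pair iteration
order is fixed by the (deterministic) neighbour-list build, and all noise is
drawn from an in-kernel xorshift64* stream seeded from (seed, step-block),
so trajectories are bit-reproducible for a given seed.

Integrator: velocity Verlet with a single force evaluation per step; the
dissipative force uses the mid-step velocities (the standard DPD-VV
scheme).  The random pair force carries the 1/sqrt(dt) time-step scaling
required for a time-step-independent temperature.
"""

import numpy as np
from numba import njit

# thermostat modes
MODE_DPD = 0
MODE_LANGEVIN = 1

_U64 = np.uint64
_SQRT3 = np.sqrt(3.0)


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = _U64(x) + _U64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _next_u64(state):
    s = state[0]
    s ^= s >> _U64(12)
    s ^= s << _U64(25)
    s ^= s >> _U64(27)
    state[0] = s
    return s * _U64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _uniform(state):
    """Uniform in [0, 1)."""
    return (_next_u64(state) >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _theta(state):
    """Zero-mean unit-variance uniform variate on [-sqrt(3), sqrt(3))."""
    return (2.0 * _uniform(state) - 1.0) * _SQRT3


@njit(cache=True, inline="always")
def _gauss(state):
    """Standard normal via Box-Muller (one of the pair, for simplicity)."""
    u1 = _uniform(state)
    u2 = _uniform(state)
    if u1 < 1e-300:
        u1 = 1e-300
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


@njit(cache=True)
def count_pairs(pos, box, rcut):
    """Number of minimum-image pairs with r < rcut (brute force)."""
    n = pos.shape[0]
    c = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            r2 = 0.0
            for k in range(3):
                d = pos[i, k] - pos[j, k]
                if d > 0.5 * box:
                    d -= box
                elif d < -0.5 * box:
                    d += box
                r2 += d * d
            if r2 < rcut * rcut:
                c += 1
    return c


@njit(cache=True)
def build_pairs(pos, box, rcut):
    """Deterministic neighbour list of minimum-image pairs with r < rcut.

    Uses a linked-cell grid when the box accommodates >= 3 cells per side,
    otherwise falls back to an all-pairs sweep.  Returns (pi, pj) index
    arrays with pi < pj in a fixed traversal order.
    """
    n = pos.shape[0]
    ncell = int(box / rcut)
    r2cut = rcut * rcut
    if ncell < 3:
        m = count_pairs(pos, box, rcut)
        pi = np.empty(m, dtype=np.int64)
        pj = np.empty(m, dtype=np.int64)
        c = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                r2 = 0.0
                for k in range(3):
                    d = pos[i, k] - pos[j, k]
                    if d > 0.5 * box:
                        d -= box
                    elif d < -0.5 * box:
                        d += box
                    r2 += d * d
                if r2 < r2cut:
                    pi[c] = i
                    pj[c] = j
                    c += 1
        return pi, pj

    cell_size = box / ncell
    ncell3 = ncell * ncell * ncell
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell3 + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_size) % ncell
        cy = int(pos[i, 1] / cell_size) % ncell
        cz = int(pos[i, 2] / cell_size) % ncell
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell3):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # half stencil: self + 13 neighbour cells
    stencil = np.empty((14, 3), dtype=np.int64)
    idx = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                key = (dx * 9) + (dy * 3) + dz
                if key > 0 or (dx == 0 and dy == 0 and dz == 0):
                    stencil[idx, 0] = dx
                    stencil[idx, 1] = dy
                    stencil[idx, 2] = dz
                    idx += 1

    # two passes: count then fill
    total = 0
    pi = np.empty(0, dtype=np.int64)
    pj = np.empty(0, dtype=np.int64)
    for phase in range(2):
        c_out = 0
        if phase == 1:
            pi = np.empty(total, dtype=np.int64)
            pj = np.empty(total, dtype=np.int64)
        for cx in range(ncell):
            for cy in range(ncell):
                for cz in range(ncell):
                    c1 = (cx * ncell + cy) * ncell + cz
                    for s in range(14):
                        nx = (cx + stencil[s, 0]) % ncell
                        ny = (cy + stencil[s, 1]) % ncell
                        nz = (cz + stencil[s, 2]) % ncell
                        c2 = (nx * ncell + ny) * ncell + nz
                        same = c1 == c2
                        for a in range(counts[c1], counts[c1 + 1]):
                            i = order[a]
                            b0 = a + 1 if same else counts[c2]
                            for b in range(b0, counts[c2 + 1]):
                                j = order[b]
                                r2 = 0.0
                                for k in range(3):
                                    d = pos[i, k] - pos[j, k]
                                    if d > 0.5 * box:
                                        d -= box
                                    elif d < -0.5 * box:
                                        d += box
                                    r2 += d * d
                                if r2 < r2cut:
                                    if phase == 1:
                                        if i < j:
                                            pi[c_out] = i
                                            pj[c_out] = j
                                        else:
                                            pi[c_out] = j
                                            pj[c_out] = i
                                    c_out += 1
        if phase == 0:
            total = c_out
    return pi, pj


@njit(cache=True)
def _bond_and_bath(pos, vel, box, bonds, kbond, r0, f, rng, mode, lgamma,
                   ldt_noise, mass):
    """Harmonic bond forces plus (in Langevin mode) the per-particle bath."""
    half = 0.5 * box
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -kbond * (r - r0) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    if mode == MODE_LANGEVIN:
        n = pos.shape[0]
        for i in range(n):
            m = mass[i]
            amp = np.sqrt(2.0 * lgamma * m) * ldt_noise
            f[i, 0] += -lgamma * m * vel[i, 0] + amp * _gauss(rng)
            f[i, 1] += -lgamma * m * vel[i, 1] + amp * _gauss(rng)
            f[i, 2] += -lgamma * m * vel[i, 2] + amp * _gauss(rng)


@njit(cache=True)
def dpd_forces_cells(pos, vel, typ, box, fmax, gamma, sigma_dt,
                     bonds, kbond, r0, f, rng, mode, lgamma, ldt_noise,
                     mass, counts, order, ncell, stencil,
                     pos_s, vel_s, typ_s, fs):
    """All DPD forces via direct linked-cell traversal (no pair list).

    Cell data (counts/order) must be freshly built for ``pos``.  Bead data
    are copied into cell-sorted scratch arrays (pos_s/vel_s/typ_s/fs) so the
    inner loops touch contiguous memory.  Traversal order is deterministic,
    fixing the per-pair noise stream.
    """
    n = pos.shape[0]
    for a in range(n):
        i = order[a]
        pos_s[a, 0] = pos[i, 0]
        pos_s[a, 1] = pos[i, 1]
        pos_s[a, 2] = pos[i, 2]
        vel_s[a, 0] = vel[i, 0]
        vel_s[a, 1] = vel[i, 1]
        vel_s[a, 2] = vel[i, 2]
        typ_s[a] = typ[i]
        fs[a, 0] = 0.0
        fs[a, 1] = 0.0
        fs[a, 2] = 0.0
    half = 0.5 * box
    dpd = mode == MODE_DPD
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c1 = (cx * ncell + cy) * ncell + cz
                a_lo = counts[c1]
                a_hi = counts[c1 + 1]
                if a_lo == a_hi:
                    continue
                interior = (0 < cx < ncell - 1 and 0 < cy < ncell - 1
                            and 0 < cz < ncell - 1)
                for s in range(14):
                    if interior:
                        nx = cx + stencil[s, 0]
                        ny = cy + stencil[s, 1]
                        nz = cz + stencil[s, 2]
                    else:
                        nx = cx + stencil[s, 0]
                        if nx < 0:
                            nx += ncell
                        elif nx >= ncell:
                            nx -= ncell
                        ny = cy + stencil[s, 1]
                        if ny < 0:
                            ny += ncell
                        elif ny >= ncell:
                            ny -= ncell
                        nz = cz + stencil[s, 2]
                        if nz < 0:
                            nz += ncell
                        elif nz >= ncell:
                            nz -= ncell
                    c2 = (nx * ncell + ny) * ncell + nz
                    same = c1 == c2
                    for a in range(a_lo, a_hi):
                        xi = pos_s[a, 0]
                        yi = pos_s[a, 1]
                        zi = pos_s[a, 2]
                        vxi = vel_s[a, 0]
                        vyi = vel_s[a, 1]
                        vzi = vel_s[a, 2]
                        ti = typ_s[a]
                        b0 = a + 1 if same else counts[c2]
                        if interior:
                            for b in range(b0, counts[c2 + 1]):
                                dx = xi - pos_s[b, 0]
                                dy = yi - pos_s[b, 1]
                                dz = zi - pos_s[b, 2]
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 >= 1.0 or r2 < 1e-24:
                                    continue
                                r = np.sqrt(r2)
                                inv = 1.0 / r
                                fmag = fmax[ti, typ_s[b]] * (1.0 - r)
                                if dpd:
                                    vdotr = ((vxi - vel_s[b, 0]) * dx
                                             + (vyi - vel_s[b, 1]) * dy
                                             + (vzi - vel_s[b, 2]) * dz) * inv
                                    fmag += (-gamma * vdotr
                                             + sigma_dt * _theta(rng))
                                fmag *= inv
                                fs[a, 0] += fmag * dx
                                fs[a, 1] += fmag * dy
                                fs[a, 2] += fmag * dz
                                fs[b, 0] -= fmag * dx
                                fs[b, 1] -= fmag * dy
                                fs[b, 2] -= fmag * dz
                        else:
                            for b in range(b0, counts[c2 + 1]):
                                dx = xi - pos_s[b, 0]
                                dy = yi - pos_s[b, 1]
                                dz = zi - pos_s[b, 2]
                                if dx > half:
                                    dx -= box
                                elif dx < -half:
                                    dx += box
                                if dy > half:
                                    dy -= box
                                elif dy < -half:
                                    dy += box
                                if dz > half:
                                    dz -= box
                                elif dz < -half:
                                    dz += box
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 >= 1.0 or r2 < 1e-24:
                                    continue
                                r = np.sqrt(r2)
                                inv = 1.0 / r
                                fmag = fmax[ti, typ_s[b]] * (1.0 - r)
                                if dpd:
                                    vdotr = ((vxi - vel_s[b, 0]) * dx
                                             + (vyi - vel_s[b, 1]) * dy
                                             + (vzi - vel_s[b, 2]) * dz) * inv
                                    fmag += (-gamma * vdotr
                                             + sigma_dt * _theta(rng))
                                fmag *= inv
                                fs[a, 0] += fmag * dx
                                fs[a, 1] += fmag * dy
                                fs[a, 2] += fmag * dz
                                fs[b, 0] -= fmag * dx
                                fs[b, 1] -= fmag * dy
                                fs[b, 2] -= fmag * dz
    for a in range(n):
        i = order[a]
        f[i, 0] = fs[a, 0]
        f[i, 1] = fs[a, 1]
        f[i, 2] = fs[a, 2]
    _bond_and_bath(pos, vel, box, bonds, kbond, r0, f, rng, mode, lgamma,
                   ldt_noise, mass)


@njit(cache=True, fastmath=True)
def _assign_cells(pos, box, ncell, cell_of, counts, order):
    """Counting sort of beads into cells; fills cell_of/counts/order."""
    n = pos.shape[0]
    cell_size = box / ncell
    ncell3 = ncell * ncell * ncell
    for c in range(ncell3 + 1):
        counts[c] = 0
    for i in range(n):
        cx = int(pos[i, 0] / cell_size)
        cy = int(pos[i, 1] / cell_size)
        cz = int(pos[i, 2] / cell_size)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell3):
        counts[c + 1] += counts[c]
    fill = counts[:ncell3].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1


@njit(cache=True)
def dpd_forces(pos, vel, typ, box, fmax, gamma, sigma_dt, pi, pj,
               bonds, kbond, r0, f, rng, mode, lgamma, ldt_noise, mass):
    """All forces in place into f; returns nothing.

    mode == MODE_DPD: conservative + dissipative + random pair forces.
    mode == MODE_LANGEVIN: conservative pair forces + per-particle Langevin
    friction and noise (used for pre-thermalization).
    Harmonic bonds are always applied.
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        half = 0.5 * box
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 1.0 or r2 < 1e-24:
            continue
        r = np.sqrt(r2)
        inv = 1.0 / r
        ex = dx * inv
        ey = dy * inv
        ez = dz * inv
        fmag = fmax[typ[i], typ[j]] * (1.0 - r)
        if mode == MODE_DPD:
            vdotr = ((vel[i, 0] - vel[j, 0]) * ex
                     + (vel[i, 1] - vel[j, 1]) * ey
                     + (vel[i, 2] - vel[j, 2]) * ez)
            fmag += -gamma * vdotr + sigma_dt * _theta(rng)
        f[i, 0] += fmag * ex
        f[i, 1] += fmag * ey
        f[i, 2] += fmag * ez
        f[j, 0] -= fmag * ex
        f[j, 1] -= fmag * ey
        f[j, 2] -= fmag * ez
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        half = 0.5 * box
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -kbond * (r - r0) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    if mode == MODE_LANGEVIN:
        for i in range(n):
            m = mass[i]
            amp = np.sqrt(2.0 * lgamma * m) * ldt_noise
            f[i, 0] += -lgamma * m * vel[i, 0] + amp * _gauss(rng)
            f[i, 1] += -lgamma * m * vel[i, 1] + amp * _gauss(rng)
            f[i, 2] += -lgamma * m * vel[i, 2] + amp * _gauss(rng)


@njit(cache=True, fastmath=True)
def run_dpd_block(pos, img, vel, typ, mass, box, fmax, gamma, sigma,
                  bonds, kbond, r0, dt, nsteps, step0, seed, mode,
                  lgamma, skin):
    """Advance nsteps of DPD (or Langevin-thermostatted) dynamics in place.

    Returns -1 on success or the absolute step index at which the
    integrator blew up (per-step displacement exceeding box/2).
    """
    n = pos.shape[0]
    rng = np.empty(1, dtype=np.uint64)
    rng[0] = _splitmix64(_U64(seed) * _U64(0x9E3779B1) + _U64(step0))
    if rng[0] == _U64(0):
        rng[0] = _U64(0x853C49E6748FEA9B)

    sigma_dt = sigma / np.sqrt(dt)
    ldt_noise = 1.0 / np.sqrt(dt)

    ncell = int(box / 1.0)
    use_cells = ncell >= 3
    ncell3 = ncell * ncell * ncell if use_cells else 1
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncell3 + 1, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    stencil = np.empty((14, 3), dtype=np.int64)
    idx = 0
    for sx in range(-1, 2):
        for sy in range(-1, 2):
            for sz in range(-1, 2):
                key = (sx * 9) + (sy * 3) + sz
                if key > 0 or (sx == 0 and sy == 0 and sz == 0):
                    stencil[idx, 0] = sx
                    stencil[idx, 1] = sy
                    stencil[idx, 2] = sz
                    idx += 1
    pi = np.empty(0, dtype=np.int64)
    pj = np.empty(0, dtype=np.int64)
    pos_s = np.empty((n, 3))
    vel_s = np.empty((n, 3))
    typ_s = np.empty(n, dtype=np.int64)
    fs = np.empty((n, 3))

    f = np.zeros((n, 3))
    if use_cells:
        _assign_cells(pos, box, ncell, cell_of, counts, order)
        dpd_forces_cells(pos, vel, typ, box, fmax, gamma, sigma_dt,
                         bonds, kbond, r0, f, rng, mode, lgamma, ldt_noise,
                         mass, counts, order, ncell, stencil,
                         pos_s, vel_s, typ_s, fs)
    else:
        pi, pj = build_pairs(pos, box, 1.0)
        dpd_forces(pos, vel, typ, box, fmax, gamma, sigma_dt, pi, pj,
                   bonds, kbond, r0, f, rng, mode, lgamma, ldt_noise, mass)
    half_box = 0.5 * box
    for s in range(nsteps):
        # half kick + drift
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] * inv_m
                step_d = dt * vel[i, k]
                if step_d > half_box or step_d < -half_box:
                    return step0 + s
                x = pos[i, k] + step_d
                if x >= box:
                    x -= box
                    img[i, k] += 1
                elif x < 0.0:
                    x += box
                    img[i, k] -= 1
                pos[i, k] = x
        if use_cells:
            _assign_cells(pos, box, ncell, cell_of, counts, order)
            dpd_forces_cells(pos, vel, typ, box, fmax, gamma, sigma_dt,
                             bonds, kbond, r0, f, rng, mode, lgamma,
                             ldt_noise, mass, counts, order, ncell, stencil,
                             pos_s, vel_s, typ_s, fs)
        else:
            pi, pj = build_pairs(pos, box, 1.0)
            dpd_forces(pos, vel, typ, box, fmax, gamma, sigma_dt, pi, pj,
                       bonds, kbond, r0, f, rng, mode, lgamma, ldt_noise,
                       mass)
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] * inv_m
    return -1


@njit(cache=True, fastmath=True)
def polymer_forces(pos, vel, box, eps, sig, eps_h, r1, r2h, fcap,
                   bonds, kbond, r0, f, rng, lgamma, ldt_noise, mass,
                   pi, pj):
    """WCA + hydrophobic well + bonds + Langevin bath for the polymer-only
    model.  Returns the number of capped WCA evaluations."""
    n = pos.shape[0]
    ncap = 0
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rwca = 1.122462048309373 * sig
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        half = 0.5 * box
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-24:
            continue
        r = np.sqrt(r2)
        fmag = 0.0
        if r < rwca:
            s6 = (sig / r) ** 6
            fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / r
            if fmag > fcap:
                fmag = fcap
                ncap += 1
        if eps_h > 0.0 and r1 < r < r2h:
            u = 0.5 * np.pi * (r - r1) / (r2h - r1)
            fmag -= eps_h * np.pi * np.cos(u) * np.sin(u) / (r2h - r1)
        if fmag != 0.0:
            inv = 1.0 / r
            f[i, 0] += fmag * dx * inv
            f[i, 1] += fmag * dy * inv
            f[i, 2] += fmag * dz * inv
            f[j, 0] -= fmag * dx * inv
            f[j, 1] -= fmag * dy * inv
            f[j, 2] -= fmag * dz * inv
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        half = 0.5 * box
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -kbond * (r - r0) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    if lgamma > 0.0:
        for i in range(n):
            m = mass[i]
            amp = np.sqrt(2.0 * lgamma * m) * ldt_noise
            f[i, 0] += -lgamma * m * vel[i, 0] + amp * _gauss(rng)
            f[i, 1] += -lgamma * m * vel[i, 1] + amp * _gauss(rng)
            f[i, 2] += -lgamma * m * vel[i, 2] + amp * _gauss(rng)
    return ncap


@njit(cache=True, fastmath=True)
def run_polymer_block(pos, img, vel, mass, box, eps, sig, eps_h, r1, r2h,
                      fcap, bonds, kbond, r0, dt, nsteps, step0, seed,
                      lgamma, skin):
    """Advance nsteps of polymer-only Langevin dynamics in place.

    Returns (-1, ncapped) on success or (blowup step, ncapped)."""
    n = pos.shape[0]
    rng = np.empty(1, dtype=np.uint64)
    rng[0] = _splitmix64(_U64(seed) * _U64(0x9E3779B1) + _U64(step0))
    if rng[0] == _U64(0):
        rng[0] = _U64(0x853C49E6748FEA9B)
    ldt_noise = 1.0 / np.sqrt(dt)
    rcut = max(1.122462048309373 * sig, r2h)
    rlist = rcut + skin
    pi, pj = build_pairs(pos, box, rlist)
    ref = pos.copy()
    f = np.zeros((n, 3))
    ncap = polymer_forces(pos, vel, box, eps, sig, eps_h, r1, r2h, fcap,
                          bonds, kbond, r0, f, rng, lgamma, ldt_noise,
                          mass, pi, pj)
    half_box = 0.5 * box
    for s in range(nsteps):
        maxdisp2 = 0.0
        for i in range(n):
            inv_m = 1.0 / mass[i]
            d2 = 0.0
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] * inv_m
                step_d = dt * vel[i, k]
                if step_d > half_box or step_d < -half_box:
                    return step0 + s, ncap
                x = pos[i, k] + step_d
                if x >= box:
                    x -= box
                    img[i, k] += 1
                elif x < 0.0:
                    x += box
                    img[i, k] -= 1
                pos[i, k] = x
                dd = x - ref[i, k]
                if dd > half_box:
                    dd -= box
                elif dd < -half_box:
                    dd += box
                d2 += dd * dd
            if d2 > maxdisp2:
                maxdisp2 = d2
        if maxdisp2 > 0.25 * skin * skin:
            pi, pj = build_pairs(pos, box, rlist)
            ref = pos.copy()
        ncap += polymer_forces(pos, vel, box, eps, sig, eps_h, r1, r2h,
                               fcap, bonds, kbond, r0, f, rng, lgamma,
                               ldt_noise, mass, pi, pj)
        for i in range(n):
            inv_m = 1.0 / mass[i]
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] * inv_m
    return -1, ncap
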