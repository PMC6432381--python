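"""Numba-compiled inner loops for the BD simulator.

These kernels are the production path for propagating the bead-spring chain;
they are validated in the test suite against the pure-numpy reference
implementation in :mod:`nanodozer.forcefield` (finite-difference force
checks, all-pairs neighbor oracles) and against closed-form statistical
results (Einstein relation, equipartition).

Error codes returned by the propagators:
    0  ok
    1  FENE bond overstretch (r >= R0)
    2  bead at/through a wall or the gasket plane
    3  cell-list capacity exceeded (caller reallocates and resumes)
    4  non-finite coordinate encountered
"""

from __future__ import annotations

import numpy as np
from numba import njit

CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)

SCHEME_GVB = 0
SCHEME_BAOAB = 1


@njit(cache=True)
def _forces(pos, F, eps, sigb, kf, R0, kappa, D, walls_on, gasket_on,
            gasket_x, fext, head, nxt, stamp, stepid, cell):
    """Fill F with total forces; returns an error code (0 = ok).

    ``stamp`` lazily invalidates the persistent cell-list ``head`` array: a
    cell is treated as empty unless ``stamp[c] == stepid``, so the grid
    never needs wholesale clearing between steps.
    """
    n = pos.shape[0]
    rc = CUTOFF_FACTOR * sigb
    rc2 = rc * rc
    ncap = head.shape[0]

    for i in range(n):
        F[i, 0] = fext
        F[i, 1] = 0.0
        F[i, 2] = 0.0

    # --- bounding box and cell grid -------------------------------------
    xmin = pos[0, 0]
    xmax = pos[0, 0]
    ymin = pos[0, 1]
    ymax = pos[0, 1]
    zmin = pos[0, 2]
    zmax = pos[0, 2]
    for i in range(n):
        if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                and np.isfinite(pos[i, 2])):
            return 4
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        if pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        if pos[i, 1] > ymax:
            ymax = pos[i, 1]
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        if pos[i, 2] > zmax:
            zmax = pos[i, 2]
    nx = int((xmax - xmin) / cell) + 1
    ny = int((ymax - ymin) / cell) + 1
    nz = int((zmax - zmin) / cell) + 1
    ncells = nx * ny * nz
    if ncells > ncap:
        return 3

    for i in range(n):
        cx = int((pos[i, 0] - xmin) / cell)
        cy = int((pos[i, 1] - ymin) / cell)
        cz = int((pos[i, 2] - zmin) / cell)
        c = (cx * ny + cy) * nz + cz
        if stamp[c] != stepid:
            stamp[c] = stepid
            head[c] = -1
        nxt[i] = head[c]
        head[c] = i

    # --- WCA between all pairs within cutoff ----------------------------
    sig2 = sigb * sigb
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / cell)
        cy = int((pos[i, 1] - ymin) / cell)
        cz = int((pos[i, 2] - zmin) / cell)
        for ax in range(max(0, cx - 1), min(nx, cx + 2)):
            for ay in range(max(0, cy - 1), min(ny, cy + 2)):
                for az in range(max(0, cz - 1), min(nz, cz + 2)):
                    cc = (ax * ny + ay) * nz + az
                    j = head[cc] if stamp[cc] == stepid else -1
                    while j != -1:
                        if j > i:
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            dz = pos[j, 2] - pos[i, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2:
                                sr2 = sig2 / r2
                                sr6 = sr2 * sr2 * sr2
                                g = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                                F[j, 0] += g * dx
                                F[j, 1] += g * dy
                                F[j, 2] += g * dz
                                F[i, 0] -= g * dx
                                F[i, 1] -= g * dy
                                F[i, 2] -= g * dz
                        j = nxt[j]

    # --- FENE bonds -----------------------------------------------------
    R02 = R0 * R0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            return 1
        g = -kf / (1.0 - r2 / R02)  # force on bead i+1 along bond vector
        F[i + 1, 0] += g * dx
        F[i + 1, 1] += g * dy
        F[i + 1, 2] += g * dz
        F[i, 0] -= g * dx
        F[i, 1] -= g * dy
        F[i, 2] -= g * dz

    # --- bending --------------------------------------------------------
    if kappa > 0.0:
        for i in range(1, n - 1):
            b1x = pos[i, 0] - pos[i - 1, 0]
            b1y = pos[i, 1] - pos[i - 1, 1]
            b1z = pos[i, 2] - pos[i - 1, 2]
            b2x = pos[i + 1, 0] - pos[i, 0]
            b2y = pos[i + 1, 1] - pos[i, 1]
            b2z = pos[i + 1, 2] - pos[i, 2]
            l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            l2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            e1x, e1y, e1z = b1x / l1, b1y / l1, b1z / l1
            e2x, e2y, e2z = b2x / l2, b2y / l2, b2z / l2
            c = e1x * e2x + e1y * e2y + e1z * e2z
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            # dU/db1 = -kappa (e2 - c e1)/l1 ; dU/db2 = -kappa (e1 - c e2)/l2
            g1x = -kappa * (e2x - c * e1x) / l1
            g1y = -kappa * (e2y - c * e1y) / l1
            g1z = -kappa * (e2z - c * e1z) / l1
            g2x = -kappa * (e1x - c * e2x) / l2
            g2y = -kappa * (e1y - c * e2y) / l2
            g2z = -kappa * (e1z - c * e2z) / l2
            F[i - 1, 0] += g1x
            F[i - 1, 1] += g1y
            F[i - 1, 2] += g1z
            F[i, 0] += -g1x + g2x
            F[i, 1] += -g1y + g2y
            F[i, 2] += -g1z + g2z
            F[i + 1, 0] += -g2x
            F[i + 1, 1] += -g2y
            F[i + 1, 2] += -g2z

    # --- confining walls (analytic planes at y,z = 0 and D) --------------
    if walls_on:
        for i in range(n):
            for axis in range(1, 3):
                d = pos[i, axis]
                if d < rc:
                    if d <= 1e-9:
                        return 2
                    sr2 = sig2 / (d * d)
                    sr6 = sr2 * sr2 * sr2
                    F[i, axis] += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d
                d = D - pos[i, axis]
                if d < rc:
                    if d <= 1e-9:
                        return 2
                    sr2 = sig2 / (d * d)
                    sr6 = sr2 * sr2 * sr2
                    F[i, axis] -= 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d

    # --- gasket plane ----------------------------------------------------
    if gasket_on:
        for i in range(n):
            d = gasket_x - pos[i, 0]
            if d < rc:
                if d <= 1e-9:
                    return 2
                sr2 = sig2 / (d * d)
                sr6 = sr2 * sr2 * sr2
                F[i, 0] -= 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d
    return 0


@njit(cache=True)
def run_chain(pos, vel, n_steps, eps, sigb, kf, R0, kappa, m, gamma, kT, dt,
              D, walls_on, gasket_on, gasket_x0, gasket_v, fext, scheme,
              noise, head, nxt, stamp):
    """Advance the chain ``n_steps`` Langevin steps in place.

    ``noise`` is a pre-drawn standard-normal array of shape
    (n_steps, n, 3, 2); the second slot is unused by BAOAB.  The gasket
    plane moves ballistically: ``x_g = gasket_x0 + gasket_v * t`` measured
    from the start of this segment.  Returns ``(code, steps_done)``.
    """
    n = pos.shape[0]
    F = np.empty((n, 3))
    cell = CUTOFF_FACTOR * sigb

    beta = gamma / m
    half = 0.5 * dt
    c_full = np.exp(-beta * dt)
    sd_full = np.sqrt(kT / m * (1.0 - c_full * c_full))
    c_half = np.exp(-beta * half)
    sd_half = np.sqrt(kT / m * (1.0 - c_half * c_half))

    code = _forces(pos, F, eps, sigb, kf, R0, kappa, D, walls_on,
                   gasket_on, gasket_x0, fext, head, nxt, stamp, 0, cell)
    if code != 0:
        return code, 0

    for step in range(n_steps):
        gx = gasket_x0 + gasket_v * (step + 1) * dt
        if scheme == SCHEME_GVB:
            # O(dt/2) B(dt/2) A(dt) [force] B(dt/2) O(dt/2)
            for i in range(n):
                for k in range(3):
                    v = c_half * vel[i, k] + sd_half * noise[step, i, k, 0]
                    v += F[i, k] * half / m
                    vel[i, k] = v
                    pos[i, k] += v * dt
            code = _forces(pos, F, eps, sigb, kf, R0, kappa, D, walls_on,
                           gasket_on, gx, fext, head, nxt, stamp, step + 1,
                           cell)
            if code != 0:
                return code, step
            for i in range(n):
                for k in range(3):
                    v = vel[i, k] + F[i, k] * half / m
                    vel[i, k] = c_half * v + sd_half * noise[step, i, k, 1]
        else:  # BAOAB: B(dt/2) A(dt/2) O(dt) A(dt/2) [force] B(dt/2)
            for i in range(n):
                for k in range(3):
                    v = vel[i, k] + F[i, k] * half / m
                    x = pos[i, k] + v * half
                    v = c_full * v + sd_full * noise[step, i, k, 0]
                    pos[i, k] = x + v * half
                    vel[i, k] = v
            code = _forces(pos, F, eps, sigb, kf, R0, kappa, D, walls_on,
                           gasket_on, gx, fext, head, nxt, stamp, step + 1,
                           cell)
            if code != 0:
                return code, step
            for i in range(n):
                for k in range(3):
                    vel[i, k] += F[i, k] * half / m
    return 0, n_steps


@njit(cache=True)
def run_free_particles(pos, vel, n_steps, k_trap, m, gamma, kT, dt, scheme,
                       seed, sample_every, pos_out, vel_out):
    """Propagate independent particles in an optional harmonic trap.

    Used for the integrator's statistical contract (Einstein relation,
    equipartition, trap variance).  Samples positions/velocities every
    ``sample_every`` steps into the provided output arrays.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    beta = gamma / m
    half = 0.5 * dt
    c_full = np.exp(-beta * dt)
    sd_full = np.sqrt(kT / m * (1.0 - c_full * c_full))
    c_half = np.exp(-beta * half)
    sd_half = np.sqrt(kT / m * (1.0 - c_half * c_half))

    ns = 0
    for step in range(n_steps):
        if scheme == SCHEME_GVB:
            for i in range(n):
                for k in range(3):
                    v = c_half * vel[i, k] + sd_half * \
                        np.random.standard_normal()
                    v += -k_trap * pos[i, k] * half / m
                    pos[i, k] += v * dt
                    v += -k_trap * pos[i, k] * half / m
                    vel[i, k] = c_half * v + sd_half * \
                        np.random.standard_normal()
        else:
            for i in range(n):
                for k in range(3):
                    vel[i, k] += -k_trap * pos[i, k] * half / m
                    pos[i, k] += vel[i, k] * half
                    vel[i, k] = c_full * vel[i, k] + sd_full * \
                        np.random.standard_normal()
                    pos[i, k] += vel[i, k] * half
                    vel[i, k] += -k_trap * pos[i, k] * half / m
        if (step + 1) % sample_every == 0 and ns < pos_out.shape[0]:
            for i in range(n):
                for k in range(3):
                    pos_out[ns, i, k] = pos[i, k]
                    vel_out[ns, i, k] = vel[i, k]
            ns += 1
    return ns


@njit(cache=True)
def bin_bonds(pos, edge0, width, nbins, out):
    """Apportion each bond's length to x-bins by x-projection overlap.

    ``out`` (size nbins) accumulates contour length per bin; returns the
    contour length that fell outside [edge0, edge0 + nbins*width].
    """
    lost = 0.0
    for i in range(pos.shape[0] - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        ell = np.sqrt(dx * dx + dy * dy + dz * dz)
        xa = pos[i, 0]
        xb = pos[i + 1, 0]
        if xb < xa:
            xa, xb = xb, xa
        if xb - xa < 1e-12:
            j = int((0.5 * (xa + xb) - edge0) / width)
            if 0 <= j < nbins:
                out[j] += ell
            else:
                lost += ell
            continue
        inv_span = 1.0 / (xb - xa)
        j0 = int(np.floor((xa - edge0) / width))
        j1 = int(np.floor((xb - edge0) / width))
        for j in range(j0, j1 + 1):
            lo = edge0 + j * width
            hi = lo + width
            olo = xa if xa > lo else lo
            ohi = xb if xb < hi else hi
            if ohi > olo:
                frac = (ohi - olo) * inv_span
                if 0 <= j < nbins:
                    out[j] += ell * frac
                else:
                    lost += ell * frac
    return lost
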