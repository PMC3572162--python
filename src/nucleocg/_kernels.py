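"""Numba kernels for bonded/non-bonded energies, forces and neighbour search.

All kernels take a cubic box edge ``box``; ``box <= 0`` means non-periodic
(no minimum-image convention applied). Forces are accumulated in kT/Å.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_SIXTH = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _min_image(d, box):
    if box > 0.0:
        d -= box * round(d / box)
    return d


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def bond_ef(pos, bi, bj, kb, r0, box, forces):
    e = 0.0
    for n in range(bi.shape[0]):
        i = bi[n]
        j = bj[n]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += 0.5 * kb[n] * dr * dr
        if r > 0.0:
            f = -kb[n] * dr / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    return e


@njit(cache=True, fastmath=True)
def angle_ef(pos, ai, aj, ak, ka, phi0, box, forces):
    e = 0.0
    for n in range(ai.shape[0]):
        i = ai[n]
        j = aj[n]
        k = ak[n]
        ax = _min_image(pos[i, 0] - pos[j, 0], box)
        ay = _min_image(pos[i, 1] - pos[j, 1], box)
        az = _min_image(pos[i, 2] - pos[j, 2], box)
        bx = _min_image(pos[k, 0] - pos[j, 0], box)
        by = _min_image(pos[k, 1] - pos[j, 1], box)
        bz = _min_image(pos[k, 2] - pos[j, 2], box)
        ra2 = ax * ax + ay * ay + az * az
        rb2 = bx * bx + by * by + bz * bz
        ra = math.sqrt(ra2)
        rb = math.sqrt(rb2)
        dot = ax * bx + ay * by + az * bz
        c = dot / (ra * rb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = math.acos(c)
        dphi = phi - phi0[n]
        e += 0.5 * ka[n] * dphi * dphi
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = -ka[n] * dphi / s  # dU/dcos(phi) chain factor
        # gradients of cos(phi)
        fia = coef * (bx / (ra * rb) - c * ax / ra2)
        fib = coef * (by / (ra * rb) - c * ay / ra2)
        fic = coef * (bz / (ra * rb) - c * az / ra2)
        fka = coef * (ax / (ra * rb) - c * bx / rb2)
        fkb = coef * (ay / (ra * rb) - c * by / rb2)
        fkc = coef * (az / (ra * rb) - c * bz / rb2)
        forces[i, 0] -= fia
        forces[i, 1] -= fib
        forces[i, 2] -= fic
        forces[k, 0] -= fka
        forces[k, 1] -= fkb
        forces[k, 2] -= fkc
        forces[j, 0] += fia + fka
        forces[j, 1] += fib + fkb
        forces[j, 2] += fic + fkc
    return e


# ---------------------------------------------------------------------------
# WCA repulsion on the hard-core-shifted distance x = r - (R_i + R_j)
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def wca_pairs_ef(pos, pi, pj, radii, box, sigma, eps, ucap, forces):
    """Purely repulsive truncated-shifted LJ over an explicit pair list.

    Inside x <= x_cap (where U reaches ``ucap``) the potential continues
    linearly with constant inward force so overlapping beads, including
    full hard-core overlap (x <= 0), never produce non-finite forces.
    Returns (energy, number of hard-core overlaps seen).
    """
    xcut = TWO_SIXTH * sigma
    ycap = (1.0 + math.sqrt(ucap)) / 2.0      # (sigma/x_cap)^6
    xcap = sigma * ycap ** (-1.0 / 6.0)
    fcap = 4.0 * eps * (12.0 * ycap * ycap - 6.0 * ycap) / xcap
    e = 0.0
    n_overlap = 0
    for n in range(pi.shape[0]):
        i = pi[n]
        j = pj[n]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        rij = radii[i] + radii[j]
        x = r - rij
        if x >= xcut:
            continue
        if x <= 0.0:
            n_overlap += 1
        if x <= xcap:
            e += ucap * eps + fcap * (xcap - x)
            fmag = fcap
        else:
            s6 = (sigma / x) ** 6
            e += 4.0 * eps * (s6 * s6 - s6) + eps
            fmag = 4.0 * eps * (12.0 * s6 * s6 - 6.0 * s6) / x
        if r > 1e-10:
            fr = fmag / r
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        else:
            # exactly coincident beads: push apart along x
            forces[i, 0] += fmag
            forces[j, 0] -= fmag
    return e, n_overlap


# ---------------------------------------------------------------------------
# Coulomb: direct minimum-image sum over a charged subset
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def coulomb_direct_ef(pos, q, lb, box, forces):
    """U = l_B q_i q_j / r over all pairs of the given subset arrays."""
    n = pos.shape[0]
    e = 0.0
    periodic = box > 0.0
    ibox = 1.0 / box if periodic else 0.0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        qi = lb * q[i]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if periodic:
                dx -= box * math.floor(dx * ibox + 0.5)
                dy -= box * math.floor(dy * ibox + 0.5)
                dz -= box * math.floor(dz * ibox + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            inv_r = 1.0 / math.sqrt(r2)
            u = qi * q[j] * inv_r
            e += u
            fr = u * inv_r * inv_r
            fx += fr * dx
            fy += fr * dy
            fz += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
    return e


@njit(cache=True, fastmath=True)
def coulomb_pairs_ef(pos, pi, pj, q, lb, box, sign, forces):
    """Coulomb over an explicit pair list (used for bonded exclusions)."""
    e = 0.0
    for n in range(pi.shape[0]):
        i = pi[n]
        j = pj[n]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        u = sign * lb * q[i] * q[j] / r
        e += u
        fr = u / (r * r)
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    return e


# ---------------------------------------------------------------------------
# Ewald summation (classic, structure-factor reciprocal part)
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def ewald_real_ef(pos, q, lb, box, alpha, rcut, forces):
    n = pos.shape[0]
    e = 0.0
    rc2 = rcut * rcut
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box)
            dy = _min_image(pos[i, 1] - pos[j, 1], box)
            dz = _min_image(pos[i, 2] - pos[j, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc2:
                continue
            r = math.sqrt(r2)
            qq = lb * q[i] * q[j]
            erfc_ar = math.erfc(alpha * r)
            e += qq * erfc_ar / r
            fr = qq * (
                erfc_ar / r
                + 2.0 * alpha / math.sqrt(math.pi) * math.exp(-alpha * alpha * r2)
            ) / r2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    return e


@njit(cache=True, fastmath=True)
def ewald_recip_ef(pos, q, lb, box, alpha, kvecs, forces):
    n = pos.shape[0]
    vol = box * box * box
    e = 0.0
    for m in range(kvecs.shape[0]):
        kx = kvecs[m, 0]
        ky = kvecs[m, 1]
        kz = kvecs[m, 2]
        k2 = kx * kx + ky * ky + kz * kz
        a = math.exp(-k2 / (4.0 * alpha * alpha)) / k2
        sre = 0.0
        sim = 0.0
        for i in range(n):
            ph = kx * pos[i, 0] + ky * pos[i, 1] + kz * pos[i, 2]
            sre += q[i] * math.cos(ph)
            sim += q[i] * math.sin(ph)
        pref = 2.0 * math.pi * lb / vol * a
        e += pref * (sre * sre + sim * sim)
        for i in range(n):
            ph = kx * pos[i, 0] + ky * pos[i, 1] + kz * pos[i, 2]
            gi = 2.0 * pref * q[i] * (math.sin(ph) * sre - math.cos(ph) * sim)
            forces[i, 0] += gi * kx
            forces[i, 1] += gi * ky
            forces[i, 2] += gi * kz
    return e


# ---------------------------------------------------------------------------
# neighbour list: cell-list construction of a Verlet pair list
# ---------------------------------------------------------------------------
@njit(cache=True)
def build_pair_list(pos, box, rlist, excl_keys):
    """Pairs (i<j) with minimum-image distance < rlist, skipping exclusions.

    ``excl_keys`` is a sorted int64 array of i * n + j keys (i < j).
    Returns two int32 arrays.
    """
    n = pos.shape[0]
    if box > 0.0:
        ncell = int(box // rlist)
        # cap the grid near the particle count: empty cells cost memory
        cap_cells = int(math.ceil((4.0 * n) ** (1.0 / 3.0)))
        if ncell > cap_cells:
            ncell = cap_cells
        if ncell < 3:
            ncell = 1
    else:
        ncell = 1
    if ncell == 1:
        return _pairs_bruteforce(pos, box, rlist, excl_keys)
    cell_edge = box / ncell
    # assign beads to cells (wrap positions into [0, box))
    ncells = ncell * ncell * ncell
    cell_of = np.empty(n, dtype=np.int64)
    cx_of = np.empty(n, dtype=np.int64)
    cy_of = np.empty(n, dtype=np.int64)
    cz_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] % box) / cell_edge) % ncell
        cy = int((pos[i, 1] % box) / cell_edge) % ncell
        cz = int((pos[i, 2] % box) / cell_edge) % ncell
        cx_of[i] = cx
        cy_of[i] = cy
        cz_of[i] = cz
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        count[c + 1] += 1
    start = count
    for c in range(ncells):
        start[c + 1] += start[c]
    members = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        members[fill[c]] = i
        fill[c] += 1
    cap = 1024
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    cnt = 0
    r2max = rlist * rlist
    # per-bead sweep over the 27 neighbouring cells (cheap in sparse boxes)
    for i in range(n):
        cx = cx_of[i]
        cy = cy_of[i]
        cz = cz_of[i]
        for dxc in range(-1, 2):
            ox = (cx + dxc) % ncell
            for dyc in range(-1, 2):
                oy = (cy + dyc) % ncell
                for dzc in range(-1, 2):
                    oz = (cz + dzc) % ncell
                    c2 = (ox * ncell + oy) * ncell + oz
                    for b in range(start[c2], start[c2 + 1]):
                        j = members[b]
                        if j <= i:
                            continue
                        dx = _min_image(pos[i, 0] - pos[j, 0], box)
                        dy = _min_image(pos[i, 1] - pos[j, 1], box)
                        dz = _min_image(pos[i, 2] - pos[j, 2], box)
                        if dx * dx + dy * dy + dz * dz >= r2max:
                            continue
                        key = i * n + j
                        if _in_sorted(excl_keys, key):
                            continue
                        if cnt == cap:
                            cap *= 2
                            pi2 = np.empty(cap, dtype=np.int32)
                            pj2 = np.empty(cap, dtype=np.int32)
                            pi2[:cnt] = pi[:cnt]
                            pj2[:cnt] = pj[:cnt]
                            pi = pi2
                            pj = pj2
                        pi[cnt] = i
                        pj[cnt] = j
                        cnt += 1
    return pi[:cnt].copy(), pj[:cnt].copy()


@njit(cache=True)
def _pairs_bruteforce(pos, box, rlist, excl_keys):
    n = pos.shape[0]
    r2max = rlist * rlist
    cap = 64
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box)
            dy = _min_image(pos[i, 1] - pos[j, 1], box)
            dz = _min_image(pos[i, 2] - pos[j, 2], box)
            if dx * dx + dy * dy + dz * dz >= r2max:
                continue
            key = i * n + j
            if _in_sorted(excl_keys, key):
                continue
            if cnt == cap:
                cap *= 2
                pi2 = np.empty(cap, dtype=np.int32)
                pj2 = np.empty(cap, dtype=np.int32)
                pi2[:cnt] = pi[:cnt]
                pj2[:cnt] = pj[:cnt]
                pi = pi2
                pj = pj2
            pi[cnt] = i
            pj[cnt] = j
            cnt += 1
    return pi[:cnt].copy(), pj[:cnt].copy()


@njit(cache=True, inline="always")
def _in_sorted(keys, key):
    lo = 0
    hi = keys.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < keys.shape[0] and keys[lo] == key


# ---------------------------------------------------------------------------
# pair-distance histogram (used by P(r) on large selections)
# ---------------------------------------------------------------------------
@njit(cache=True, fastmath=True)
def pair_distance_hist(pos, bin_width, nbins):
    n = pos.shape[0]
    hist = np.zeros(nbins, dtype=np.int64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            b = int(r / bin_width)
            if b < nbins:
                hist[b] += 1
    return hist
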