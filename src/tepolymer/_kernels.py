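"""Numba kernels for the Monte Carlo engine.

Conventions shared by every kernel here:

* coordinates are ``(N, 3)`` float64 arrays in bead-diameter units (sigma = 1);
* energies are in units of the thermal energy kT;
* ``bend_k`` is padded to length N: ``bend_k[b]`` is the bending stiffness of
  the Kratky-Porod angle centred at bead ``b`` (entries 0 and N-1 are unused
  and must be 0, because no angle exists at the chain ends);
* non-bonded interactions act between all pairs ``|i - j| >= 2`` (only the
  directly bonded 1-2 pair is excluded);
* randomness comes from numba's global RNG, seeded once per kernel call chain
  through ``np.random.seed`` so that every trajectory is reproducible from a
  single integer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# squared WCA cutoff for ev_sigma = 1 (r_c = 2^(1/6))
_WCA_CUT2 = 2.0 ** (1.0 / 3.0)
_R_MIN = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def pair_ev(r2, ev_sigma):
    """Purely repulsive truncated-shifted Lennard-Jones (WCA) energy."""
    if ev_sigma <= 0.0:
        return 0.0
    s2 = ev_sigma * ev_sigma
    if r2 >= _WCA_CUT2 * s2:
        return 0.0
    if r2 < 1e-12:
        return 1e12
    x6 = (s2 / r2) ** 3
    return 4.0 * (x6 * x6 - x6) + 1.0


@njit(cache=True)
def pair_attr(r2, ev_sigma, eps, attr_rc):
    """Short-range attractive well: -eps inside the WCA minimum, cos^2 taper
    to zero at attr_rc. Returns a negative energy (or 0)."""
    if eps <= 0.0 or ev_sigma <= 0.0:
        return 0.0
    if r2 >= attr_rc * attr_rc:
        return 0.0
    rmin = _R_MIN * ev_sigma
    r = np.sqrt(r2)
    if r < rmin:
        return -eps
    c = np.cos(0.5 * np.pi * (r - rmin) / (attr_rc - rmin))
    return -eps * c * c


@njit(cache=True)
def pair_nb(r2, ev_sigma, eps, attr_rc):
    return pair_ev(r2, ev_sigma) + pair_attr(r2, ev_sigma, eps, attr_rc)


@njit(cache=True)
def _dist2(coords, i, j):
    dx = coords[i, 0] - coords[j, 0]
    dy = coords[i, 1] - coords[j, 1]
    dz = coords[i, 2] - coords[j, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def one_minus_cos(coords, a, b, c):
    """1 - cos(theta) for the bending angle centred at bead b."""
    ux = coords[b, 0] - coords[a, 0]
    uy = coords[b, 1] - coords[a, 1]
    uz = coords[b, 2] - coords[a, 2]
    vx = coords[c, 0] - coords[b, 0]
    vy = coords[c, 1] - coords[b, 1]
    vz = coords[c, 2] - coords[b, 2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 1e12
    return 1.0 - (ux * vx + uy * vy + uz * vz) / (nu * nv)


@njit(cache=True)
def total_components(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc):
    """(E_bond, E_bend, E_ev, E_attr) of a linear chain."""
    n = coords.shape[0]
    e_bond = 0.0
    for i in range(n - 1):
        d = np.sqrt(_dist2(coords, i, i + 1))
        e_bond += kb * (d - r0) * (d - r0)
    e_bend = 0.0
    for b in range(1, n - 1):
        e_bend += bend_k[b] * one_minus_cos(coords, b - 1, b, b + 1)
    e_ev = 0.0
    e_attr = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            r2 = _dist2(coords, i, j)
            e_ev += pair_ev(r2, ev_sigma)
            e_attr += pair_attr(r2, ev_sigma, eps, attr_rc)
    return e_bond, e_bend, e_ev, e_attr


@njit(cache=True)
def _bead_env(coords, m, bend_k, kb, r0, ev_sigma, eps, attr_rc):
    """Energy of every term that involves bead m (used for displacement
    moves: evaluate before/after moving bead m in place)."""
    n = coords.shape[0]
    e = 0.0
    if m > 0:
        d = np.sqrt(_dist2(coords, m - 1, m))
        e += kb * (d - r0) * (d - r0)
    if m < n - 1:
        d = np.sqrt(_dist2(coords, m, m + 1))
        e += kb * (d - r0) * (d - r0)
    for b in range(m - 1, m + 2):
        if 1 <= b <= n - 2:
            e += bend_k[b] * one_minus_cos(coords, b - 1, b, b + 1)
    for j in range(n):
        if j < m - 1 or j > m + 1:
            e += pair_nb(_dist2(coords, m, j), ev_sigma, eps, attr_rc)
    return e


@njit(cache=True)
def _segment_env(coords, i, j, bend_k, kb, r0, ev_sigma, eps, attr_rc):
    """Energy terms that change when beads i+1..j-1 rotate rigidly about the
    axis through beads i and j (crankshaft): the two anchor angles plus
    non-bonded pairs between moved beads and beads outside [i, j]."""
    n = coords.shape[0]
    e = 0.0
    if 1 <= i <= n - 2:
        e += bend_k[i] * one_minus_cos(coords, i - 1, i, i + 1)
    if 1 <= j <= n - 2:
        e += bend_k[j] * one_minus_cos(coords, j - 1, j, j + 1)
    for m in range(i + 1, j):
        for t in range(n):
            if i <= t <= j:
                continue
            e += pair_nb(_dist2(coords, m, t), ev_sigma, eps, attr_rc)
    return e


@njit(cache=True)
def _tail_env(coords, p, bend_k, kb, r0, ev_sigma, eps, attr_rc):
    """Energy terms that change when beads p+1..N-1 rotate rigidly about a
    point at bead p (pivot): the angle at p plus tail-head non-bonded pairs."""
    n = coords.shape[0]
    e = 0.0
    if 1 <= p <= n - 2:
        e += bend_k[p] * one_minus_cos(coords, p - 1, p, p + 1)
    for m in range(p + 1, n):
        for t in range(p):
            e += pair_nb(_dist2(coords, m, t), ev_sigma, eps, attr_rc)
    return e


@njit(cache=True)
def _rotate_range(coords, lo, hi, ox, oy, oz, ax, ay, az, angle):
    """Rodrigues rotation of beads lo..hi-1 about the unit axis (ax,ay,az)
    through origin (ox,oy,oz), in place."""
    c = np.cos(angle)
    s = np.sin(angle)
    for m in range(lo, hi):
        px = coords[m, 0] - ox
        py = coords[m, 1] - oy
        pz = coords[m, 2] - oz
        dot = ax * px + ay * py + az * pz
        cx = ay * pz - az * py
        cy = az * px - ax * pz
        cz = ax * py - ay * px
        coords[m, 0] = ox + px * c + cx * s + ax * dot * (1.0 - c)
        coords[m, 1] = oy + py * c + cy * s + ay * dot * (1.0 - c)
        coords[m, 2] = oz + pz * c + cz * s + az * dot * (1.0 - c)


@njit(cache=True)
def _metropolis(d_e):
    if d_e <= 0.0:
        return True
    if d_e > 700.0:
        return False
    return np.random.random() < np.exp(-d_e)


@njit(cache=True)
def one_sweep(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
              max_disp, crank_max, n_pivot, pivot_max, zero_temp):
    """One MC sweep: N single-bead displacements, N/2 crankshafts and
    optionally n_pivot pivot moves. Returns the number of accepted moves.

    ``zero_temp`` switches to the greedy limit (accept only dE <= 0)."""
    n = coords.shape[0]
    acc = 0
    old = np.empty(3)
    for _ in range(n):
        m = int(np.random.random() * n)
        if m >= n:
            m = n - 1
        e_old = _bead_env(coords, m, bend_k, kb, r0, ev_sigma, eps, attr_rc)
        old[0] = coords[m, 0]
        old[1] = coords[m, 1]
        old[2] = coords[m, 2]
        coords[m, 0] += (2.0 * np.random.random() - 1.0) * max_disp
        coords[m, 1] += (2.0 * np.random.random() - 1.0) * max_disp
        coords[m, 2] += (2.0 * np.random.random() - 1.0) * max_disp
        d_e = _bead_env(coords, m, bend_k, kb, r0, ev_sigma, eps, attr_rc) - e_old
        ok = (d_e <= 0.0) if zero_temp else _metropolis(d_e)
        if ok:
            acc += 1
        else:
            coords[m, 0] = old[0]
            coords[m, 1] = old[1]
            coords[m, 2] = old[2]
    n_crank = n // 2
    saved = np.empty((4, 3))
    for _ in range(n_crank):
        g = 2 + int(np.random.random() * 3)  # anchor gap 2..4
        if n - g - 1 < 0:
            continue
        i = int(np.random.random() * (n - g))
        j = i + g
        a2 = _dist2(coords, i, j)
        if a2 < 1e-12:
            continue
        inv = 1.0 / np.sqrt(a2)
        ax = (coords[j, 0] - coords[i, 0]) * inv
        ay = (coords[j, 1] - coords[i, 1]) * inv
        az = (coords[j, 2] - coords[i, 2]) * inv
        e_old = _segment_env(coords, i, j, bend_k, kb, r0, ev_sigma, eps, attr_rc)
        for m in range(i + 1, j):
            saved[m - i - 1, 0] = coords[m, 0]
            saved[m - i - 1, 1] = coords[m, 1]
            saved[m - i - 1, 2] = coords[m, 2]
        angle = (2.0 * np.random.random() - 1.0) * crank_max
        _rotate_range(coords, i + 1, j, coords[i, 0], coords[i, 1], coords[i, 2],
                      ax, ay, az, angle)
        d_e = _segment_env(coords, i, j, bend_k, kb, r0, ev_sigma, eps, attr_rc) - e_old
        ok = (d_e <= 0.0) if zero_temp else _metropolis(d_e)
        if ok:
            acc += 1
        else:
            for m in range(i + 1, j):
                coords[m, 0] = saved[m - i - 1, 0]
                coords[m, 1] = saved[m - i - 1, 1]
                coords[m, 2] = saved[m - i - 1, 2]
    for _ in range(n_pivot):
        p = 1 + int(np.random.random() * (n - 2))
        # uniform random axis
        while True:
            ux = 2.0 * np.random.random() - 1.0
            uy = 2.0 * np.random.random() - 1.0
            uz = 2.0 * np.random.random() - 1.0
            q = ux * ux + uy * uy + uz * uz
            if 1e-6 < q <= 1.0:
                break
        inv = 1.0 / np.sqrt(q)
        ux *= inv
        uy *= inv
        uz *= inv
        e_old = _tail_env(coords, p, bend_k, kb, r0, ev_sigma, eps, attr_rc)
        tail = coords[p + 1:].copy()
        angle = (2.0 * np.random.random() - 1.0) * pivot_max
        _rotate_range(coords, p + 1, n, coords[p, 0], coords[p, 1], coords[p, 2],
                      ux, uy, uz, angle)
        d_e = _tail_env(coords, p, bend_k, kb, r0, ev_sigma, eps, attr_rc) - e_old
        ok = (d_e <= 0.0) if zero_temp else _metropolis(d_e)
        if ok:
            acc += 1
        else:
            coords[p + 1:] = tail
    return acc


@njit(cache=True)
def run_sweeps(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
               max_disp, crank_max, n_pivot, pivot_max, n_sweeps, seed,
               zero_temp):
    """Run n_sweeps sweeps in place; returns total accepted moves."""
    np.random.seed(seed)
    acc = 0
    for _ in range(n_sweeps):
        acc += one_sweep(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                         max_disp, crank_max, n_pivot, pivot_max, zero_temp)
    return acc


@njit(cache=True)
def sample_frames(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                  max_disp, crank_max, n_pivot, pivot_max,
                  equil_sweeps, stride, out, seed):
    """Equilibrate, then store a frame into ``out`` every ``stride`` sweeps."""
    np.random.seed(seed)
    for _ in range(equil_sweeps):
        one_sweep(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                  max_disp, crank_max, n_pivot, pivot_max, False)
    for f in range(out.shape[0]):
        for _ in range(stride):
            one_sweep(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                      max_disp, crank_max, n_pivot, pivot_max, False)
        out[f] = coords


@njit(cache=True)
def insertion_delta(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                    locus, kink, psi, phi, out_junctions):
    """Energy change of rewiring host bond ``locus`` through the invading
    element's two junction beads.

    The bond (l, l+1) is opened; junction beads e1 (bonded to l) and e2
    (bonded to l+1) splay by the kink angle from the old bond axis, with
    their out-of-axis directions separated by the azimuthal opening ``psi``
    around the mean azimuth ``phi``. The element interior is implicit: its
    internal energy is identical before and after reconnection and cancels,
    and its end tangents relax onto the junction bonds, so only host-side
    terms plus junction-bead sterics contribute. Junction positions are
    written to ``out_junctions`` (2 x 3).
    """
    n = coords.shape[0]
    dx = coords[locus + 1, 0] - coords[locus, 0]
    dy = coords[locus + 1, 1] - coords[locus, 1]
    dz = coords[locus + 1, 2] - coords[locus, 2]
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    if d < 1e-9:
        return 1e12
    dxh = dx / d
    dyh = dy / d
    dzh = dz / d
    # orthonormal frame (d_hat, n1, n2)
    if abs(dzh) < 0.9:
        rx, ry, rz = 0.0, 0.0, 1.0
    else:
        rx, ry, rz = 1.0, 0.0, 0.0
    n1x = dyh * rz - dzh * ry
    n1y = dzh * rx - dxh * rz
    n1z = dxh * ry - dyh * rx
    nn = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    n1x /= nn
    n1y /= nn
    n1z /= nn
    n2x = dyh * n1z - dzh * n1y
    n2y = dzh * n1x - dxh * n1z
    n2z = dxh * n1y - dyh * n1x
    ck = np.cos(kink)
    sk = np.sin(kink)
    a1 = phi + 0.5 * psi
    a2 = phi - 0.5 * psi
    u1x = np.cos(a1) * n1x + np.sin(a1) * n2x
    u1y = np.cos(a1) * n1y + np.sin(a1) * n2y
    u1z = np.cos(a1) * n1z + np.sin(a1) * n2z
    u2x = np.cos(a2) * n1x + np.sin(a2) * n2x
    u2y = np.cos(a2) * n1y + np.sin(a2) * n2y
    u2z = np.cos(a2) * n1z + np.sin(a2) * n2z
    # junction bead bonded to l, splayed +kink off the bond axis
    e1x = coords[locus, 0] + r0 * (ck * dxh + sk * u1x)
    e1y = coords[locus, 1] + r0 * (ck * dyh + sk * u1y)
    e1z = coords[locus, 2] + r0 * (ck * dzh + sk * u1z)
    # junction bead bonded to l+1, splayed -kink (pointing back over the bond)
    e2x = coords[locus + 1, 0] + r0 * (-ck * dxh + sk * u2x)
    e2y = coords[locus + 1, 1] + r0 * (-ck * dyh + sk * u2y)
    e2z = coords[locus + 1, 2] + r0 * (-ck * dzh + sk * u2z)
    out_junctions[0, 0] = e1x
    out_junctions[0, 1] = e1y
    out_junctions[0, 2] = e1z
    out_junctions[1, 0] = e2x
    out_junctions[1, 1] = e2y
    out_junctions[1, 2] = e2z

    d_e = 0.0
    # bonds: two new junction bonds (rest length by construction) minus the
    # old host bond
    d_e += kb * (r0 - r0) ** 2 * 2.0
    d_e -= kb * (d - r0) * (d - r0)
    # host bending at the two joints flanking the opened bond
    if locus >= 1:
        a = locus - 1
        bx = coords[locus, 0] - coords[a, 0]
        by = coords[locus, 1] - coords[a, 1]
        bz = coords[locus, 2] - coords[a, 2]
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        vx = e1x - coords[locus, 0]
        vy = e1y - coords[locus, 1]
        vz = e1z - coords[locus, 2]
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        new = 1.0 - (bx * vx + by * vy + bz * vz) / (nb * nv)
        old = one_minus_cos(coords, a, locus, locus + 1)
        d_e += bend_k[locus] * (new - old)
    if locus + 1 <= n - 2:
        c = locus + 2
        bx = coords[c, 0] - coords[locus + 1, 0]
        by = coords[c, 1] - coords[locus + 1, 1]
        bz = coords[c, 2] - coords[locus + 1, 2]
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        vx = coords[locus + 1, 0] - e2x
        vy = coords[locus + 1, 1] - e2y
        vz = coords[locus + 1, 2] - e2z
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        new = 1.0 - (bx * vx + by * vy + bz * vz) / (nb * nv)
        old = one_minus_cos(coords, locus, locus + 1, c)
        d_e += bend_k[locus + 1] * (new - old)
    # non-bonded terms: each junction bead against every host bead except its
    # own bond partner; the junction pair itself; and the old bond partners,
    # now topologically distant, interact sterically
    for j in range(n):
        if j != locus:
            ddx = e1x - coords[j, 0]
            ddy = e1y - coords[j, 1]
            ddz = e1z - coords[j, 2]
            d_e += pair_nb(ddx * ddx + ddy * ddy + ddz * ddz, ev_sigma, eps, attr_rc)
        if j != locus + 1:
            ddx = e2x - coords[j, 0]
            ddy = e2y - coords[j, 1]
            ddz = e2z - coords[j, 2]
            d_e += pair_nb(ddx * ddx + ddy * ddy + ddz * ddz, ev_sigma, eps, attr_rc)
    ddx = e1x - e2x
    ddy = e1y - e2y
    ddz = e1z - e2z
    d_e += pair_nb(ddx * ddx + ddy * ddy + ddz * ddz, ev_sigma, eps, attr_rc)
    d_e += pair_nb(d * d, ev_sigma, eps, attr_rc)
    return d_e


@njit(cache=True)
def best_insertion(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                   locus, kink, psi, phis, out_junctions):
    """Minimum insertion_delta over the trial azimuths ``phis`` (the relaxed
    trial placement of the junction beads)."""
    best = 1e30
    tmp = np.empty((2, 3))
    for t in range(phis.shape[0]):
        d_e = insertion_delta(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                              locus, kink, psi, phis[t], tmp)
        if d_e < best:
            best = d_e
            out_junctions[0] = tmp[0]
            out_junctions[1] = tmp[1]
    return best


@njit(cache=True)
def run_replicate(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                  max_disp, crank_max, equil_sweeps, attempts_per_sweep,
                  max_attempts, kink, psi, n_trials, seed):
    """Equilibrate the host, then alternate one MC sweep with uniform-random
    integration attempts until the first Metropolis acceptance.

    Returns (locus, delta_E, sweep, attempts); locus = -1 if the attempt cap
    was reached. Attempts target interior bonds 1..N-3 so that every
    candidate locus has both flanking joints.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    for _ in range(equil_sweeps):
        one_sweep(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                  max_disp, crank_max, 0, 0.0, False)
    attempts = 0
    sweep = 0
    phis = np.empty(n_trials)
    junc = np.empty((2, 3))
    while attempts < max_attempts:
        one_sweep(coords, bend_k, kb, r0, ev_sigma, eps, attr_rc,
                  max_disp, crank_max, 0, 0.0, False)
        sweep += 1
        for _ in range(attempts_per_sweep):
            attempts += 1
            locus = 1 + int(np.random.random() * (n - 3))
            if locus > n - 3:
                locus = n - 3
            for t in range(n_trials):
                phis[t] = np.random.random() * 2.0 * np.pi
            d_e = best_insertion(coords, bend_k, kb, r0, ev_sigma, eps,
                                 attr_rc, locus, kink, psi, phis, junc)
            if _metropolis(d_e):
                return locus, d_e, sweep, attempts
            if attempts >= max_attempts:
                break
    return -1, np.nan, sweep, attempts
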