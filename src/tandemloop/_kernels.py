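"""Numba kernels for the 3D polymer dynamics and contact analysis.

All kernels work in reduced units inside a periodic cubic box under the
minimum-image convention. The repulsive pair term is truncated at
``r = REPsigma`` where both the potential and the radial force vanish, and the
pair force magnitude is capped to survive overlaps from the lattice start.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "forces_and_energy",
    "run_md_block",
    "accumulate_contact_map",
    "pair_contact_matrix",
]


@njit(cache=True, inline="always")
def _min_image(d, box):
    return d - box * np.rint(d / box)


@njit(cache=True)
def _repulsive_forces(pos, box, rep_e, rep_rmin, rep_sigma, rep_emin, f_cap, f, pe):
    """Truncated repulsive excluded-volume forces via a cell linked list."""
    n = pos.shape[0]
    cutoff = rep_sigma
    ncell = min(int(box / cutoff), 64)
    scale = rep_rmin / rep_sigma
    pref = rep_e / rep_emin
    if ncell < 3:
        # box too small for a cell list: brute-force pairs
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box)
                dy = _min_image(pos[i, 1] - pos[j, 1], box)
                dz = _min_image(pos[i, 2] - pos[j, 2], box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cutoff * cutoff and r2 > 0.0:
                    r = np.sqrt(r2)
                    x = r * scale
                    x2 = x * x
                    x11 = x2 * x2 * x2 * x2 * x2 * x
                    # dU/dr = pref * scale * (14 x^13 - 12 x^11)
                    dudr = pref * scale * (14.0 * x11 * x2 - 12.0 * x11)
                    fmag = -dudr
                    if fmag > f_cap:
                        fmag = f_cap
                    elif fmag < -f_cap:
                        fmag = -f_cap
                    fx = fmag * dx / r
                    fy = fmag * dy / r
                    fz = fmag * dz / r
                    f[i, 0] += fx
                    f[i, 1] += fy
                    f[i, 2] += fz
                    f[j, 0] -= fx
                    f[j, 1] -= fy
                    f[j, 2] -= fz
                    pe[0] += rep_e * (1.0 + x11 * x * (x2 - 1.0) / rep_emin)
        return
    cell_w = box / ncell
    ncell3 = ncell * ncell * ncell
    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cells = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_w) % ncell
        cy = int(pos[i, 1] / cell_w) % ncell
        cz = int(pos[i, 2] / cell_w) % ncell
        c = (cx * ncell + cy) * ncell + cz
        cells[i] = c
        nxt[i] = head[c]
        head[c] = i
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                i = head[c]
                while i >= 0:
                    # same cell: pairs with j after i in the list
                    j = nxt[i]
                    while j >= 0:
                        _pair_accum(pos, box, i, j, scale, pref, rep_e,
                                    rep_emin, cutoff, f_cap, f, pe)
                        j = nxt[j]
                    # half of the 26 neighbour cells
                    for off in range(13):
                        nx_ = (cx + _NEIGHBOR_OFFSETS[off, 0]) % ncell
                        ny_ = (cy + _NEIGHBOR_OFFSETS[off, 1]) % ncell
                        nz_ = (cz + _NEIGHBOR_OFFSETS[off, 2]) % ncell
                        nc = (nx_ * ncell + ny_) * ncell + nz_
                        j = head[nc]
                        while j >= 0:
                            _pair_accum(pos, box, i, j, scale, pref, rep_e,
                                        rep_emin, cutoff, f_cap, f, pe)
                            j = nxt[j]
                    i = nxt[i]


_NEIGHBOR_OFFSETS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


@njit(cache=True, inline="always")
def _pair_accum(pos, box, i, j, scale, pref, rep_e, rep_emin, cutoff, f_cap, f, pe):
    dx = _min_image(pos[i, 0] - pos[j, 0], box)
    dy = _min_image(pos[i, 1] - pos[j, 1], box)
    dz = _min_image(pos[i, 2] - pos[j, 2], box)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 < cutoff * cutoff and r2 > 0.0:
        r = np.sqrt(r2)
        x = r * scale
        x2 = x * x
        x11 = x2 * x2 * x2 * x2 * x2 * x
        dudr = pref * scale * (14.0 * x11 * x2 - 12.0 * x11)
        fmag = -dudr
        if fmag > f_cap:
            fmag = f_cap
        elif fmag < -f_cap:
            fmag = -f_cap
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz
        pe[0] += rep_e * (1.0 + x11 * x * (x2 - 1.0) / rep_emin)


@njit(cache=True)
def _bond_forces(pos, box, bonds, k, d, f, pe):
    """Harmonic bonds U = k (r - d)^2 over an (m, 2) index array."""
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        fmag = -2.0 * k * (r - d)
        f[i, 0] += fmag * dx / r
        f[i, 1] += fmag * dy / r
        f[i, 2] += fmag * dz / r
        f[j, 0] -= fmag * dx / r
        f[j, 1] -= fmag * dy / r
        f[j, 2] -= fmag * dz / r
        pe[0] += k * (r - d) * (r - d)


@njit(cache=True)
def _angle_forces(pos, box, amplitude, f, pe):
    """Bending stiffness U = amplitude * (1 - cos(theta)) per backbone triplet.

    theta is the angle between consecutive bond vectors (0 for a straight
    chain). Chain ends carry no angle term.
    """
    n = pos.shape[0]
    for i in range(1, n - 1):
        ax = _min_image(pos[i, 0] - pos[i - 1, 0], box)
        ay = _min_image(pos[i, 1] - pos[i - 1, 1], box)
        az = _min_image(pos[i, 2] - pos[i - 1, 2], box)
        bx = _min_image(pos[i + 1, 0] - pos[i, 0], box)
        by = _min_image(pos[i + 1, 1] - pos[i, 1], box)
        bz = _min_image(pos[i + 1, 2] - pos[i, 2], box)
        la2 = ax * ax + ay * ay + az * az
        lb2 = bx * bx + by * by + bz * bz
        if la2 == 0.0 or lb2 == 0.0:
            continue
        la = np.sqrt(la2)
        lb = np.sqrt(lb2)
        dot = ax * bx + ay * by + az * bz
        cth = dot / (la * lb)
        pe[0] += amplitude * (1.0 - cth)
        # grad of cos(theta); force = +amplitude * grad(cos theta)
        inv = 1.0 / (la * lb)
        # d cth / d a = b*inv - cth * a / la2 ; d cth / d b = a*inv - cth * b / lb2
        gax = bx * inv - cth * ax / la2
        gay = by * inv - cth * ay / la2
        gaz = bz * inv - cth * az / la2
        gbx = ax * inv - cth * bx / lb2
        gby = ay * inv - cth * by / lb2
        gbz = az * inv - cth * bz / lb2
        # a depends on r_{i-1} (-) and r_i (+); b on r_i (-) and r_{i+1} (+)
        f[i - 1, 0] -= amplitude * gax
        f[i - 1, 1] -= amplitude * gay
        f[i - 1, 2] -= amplitude * gaz
        f[i, 0] += amplitude * (gax - gbx)
        f[i, 1] += amplitude * (gay - gby)
        f[i, 2] += amplitude * (gaz - gbz)
        f[i + 1, 0] += amplitude * gbx
        f[i + 1, 1] += amplitude * gby
        f[i + 1, 2] += amplitude * gbz


@njit(cache=True)
def forces_and_energy(pos, box, coh_bonds, rep_e, rep_rmin, rep_sigma, rep_emin,
                      bb_k, bb_d, coh_k, coh_d, sti_amp, f_cap):
    """Total force field: repulsion + backbone + cohesin bonds + bending."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    pe = np.zeros(1)
    _repulsive_forces(pos, box, rep_e, rep_rmin, rep_sigma, rep_emin, f_cap, f, pe)
    backbone = np.empty((n - 1, 2), dtype=np.int64)
    for i in range(n - 1):
        backbone[i, 0] = i
        backbone[i, 1] = i + 1
    _bond_forces(pos, box, backbone, bb_k, bb_d, f, pe)
    if coh_bonds.shape[0] > 0:
        _bond_forces(pos, box, coh_bonds, coh_k, coh_d, f, pe)
    _angle_forces(pos, box, sti_amp, f, pe)
    return f, pe[0]


@njit(cache=True)
def run_md_block(pos, vel, f, box, coh_bonds, noise1, noise2, dt, ag,
                 rep_e, rep_rmin, rep_sigma, rep_emin,
                 bb_k, bb_d, coh_k, coh_d, sti_amp, f_cap):
    """Integrate ``nsteps`` of the Langevin velocity-Verlet scheme in place.

    noise1/noise2 are (nsteps, n, 3) standard Gaussian draws for the two
    stochastic kicks of each step. Returns the force array valid for the final
    positions.
    """
    nsteps = noise1.shape[0]
    n = pos.shape[0]
    a = (2.0 - ag * dt) / (2.0 + ag * dt)
    # two independent kicks of variance ag*dt per step satisfy
    # fluctuation-dissipation at unit reduced temperature: <v^2> = 1 + O(dt^2)
    b = np.sqrt(ag * dt)
    c = 2.0 * dt / (2.0 + ag * dt)
    for s in range(nsteps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += 0.5 * dt * f[i, k] + b * noise1[s, i, k]
                pos[i, k] += c * vel[i, k]
                pos[i, k] -= box * np.floor(pos[i, k] / box)
        f_new, _ = forces_and_energy(pos, box, coh_bonds, rep_e, rep_rmin,
                                     rep_sigma, rep_emin, bb_k, bb_d,
                                     coh_k, coh_d, sti_amp, f_cap)
        for i in range(n):
            for k in range(3):
                f[i, k] = f_new[i, k]
                vel[i, k] = a * vel[i, k] + b * noise2[s, i, k] + 0.5 * dt * f[i, k]
    return f


@njit(cache=True)
def accumulate_contact_map(positions, box, radius, weights, out):
    """Weighted fraction of conformations with min-image distance <= radius."""
    n_conf = positions.shape[0]
    n = positions.shape[1]
    r2max = radius * radius
    for c in range(n_conf):
        w = weights[c]
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image(positions[c, i, 0] - positions[c, j, 0], box)
                dy = _min_image(positions[c, i, 1] - positions[c, j, 1], box)
                dz = _min_image(positions[c, i, 2] - positions[c, j, 2], box)
                if dx * dx + dy * dy + dz * dz <= r2max:
                    out[i, j] += w
                    out[j, i] += w


@njit(cache=True)
def pair_contact_matrix(positions, box, radius, pairs):
    """0/1 contact indicators c_ij(q_n) for a list of constrained pairs."""
    n_conf = positions.shape[0]
    m = pairs.shape[0]
    out = np.zeros((n_conf, m), dtype=np.int8)
    r2max = radius * radius
    for c in range(n_conf):
        for p in range(m):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = _min_image(positions[c, i, 0] - positions[c, j, 0], box)
            dy = _min_image(positions[c, i, 1] - positions[c, j, 1], box)
            dz = _min_image(positions[c, i, 2] - positions[c, j, 2], box)
            if dx * dx + dy * dy + dz * dz <= r2max:
                out[c, p] = 1
    return out
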