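"""Independent scalar (triple-loop) implementation of one automaton step.

Used as an oracle against the vectorized implementation on tiny lattices.
Everything here is written with explicit per-voxel loops and plain Python
floats, following the documented update rules, in the same neighbour order
(+x, -x, +y, -y, +z, -z) so results agree with the array code bit-for-bit.
"""

import math

import numpy as np

DIRS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def flux_response(m, params):
    if m <= params.ecm_crit:
        return m / params.ecm_crit
    return math.exp(-params.decay_k * (m - params.ecm_crit))


def in_slab(k, params):
    mid = (params.nz - 1) // 2
    return abs(k - mid) <= params.cleft_half_thickness


def scalar_step(cells, ecm, params):
    """proliferation -> degradation -> migration, one step, pure loops."""
    nx, ny, nz = cells.shape
    c = cells.astype(float).copy()
    m = ecm.astype(float).copy()

    def inside(i, j, k):
        return 0 <= i < nx and 0 <= j < ny and 0 <= k < nz

    # proliferation
    growth = 2.0 ** (params.dt / params.t_d)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c[i, j, k] = min(1.0, c[i, j, k] * growth)

    # degradation
    m_new = m.copy()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                nbr = 0.0
                count = 0.0
                for ax in range(3):
                    pair = 0.0
                    for di, dj, dk in (DIRS[2 * ax], DIRS[2 * ax + 1]):
                        if inside(i + di, j + dj, k + dk):
                            pair += c[i + di, j + dj, k + dk]
                            count += 1.0
                    nbr += pair
                load = (c[i, j, k] + nbr) / (1.0 + count)
                m_new[i, j, k] = max(0.0, m[i, j, k] * (1.0 - params.delta * load))
    m = m_new

    # migration: desired fluxes from the pre-step field
    f = np.zeros_like(c)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                f[i, j, k] = flux_response(m[i, j, k], params)

    def gfac(i, j, k, d):
        # in-plane neighbour inside the cleft slab
        if DIRS[d][2] == 0 and in_slab(k, params):
            return params.guidance_g
        return 1.0

    J = np.zeros((6, nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                wsum = 0.0
                for ax in range(3):
                    pair = 0.0
                    for d in (2 * ax, 2 * ax + 1):
                        di, dj, dk = DIRS[d]
                        if inside(i + di, j + dj, k + dk):
                            pair += f[i + di, j + dj, k + dk] * gfac(i, j, k, d)
                    wsum += pair
                Z = max(1.0, wsum)
                for d, (di, dj, dk) in enumerate(DIRS):
                    if inside(i + di, j + dj, k + dk):
                        J[d, i, j, k] = (
                            params.mu
                            * c[i, j, k]
                            * f[i + di, j + dj, k + dk]
                            * (1.0 - c[i + di, j + dj, k + dk])
                            * gfac(i, j, k, d)
                            / Z
                        )

    inflow = np.zeros_like(c)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                for ax in range(3):
                    pair = 0.0
                    for d in (2 * ax, 2 * ax + 1):
                        di, dj, dk = DIRS[d]
                        if inside(i - di, j - dj, k - dk):
                            pair += J[d, i - di, j - dj, k - dk]
                    acc += pair
                inflow[i, j, k] = acc

    s = np.ones_like(c)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                avail = 1.0 - c[i, j, k]
                if inflow[i, j, k] > avail:
                    s[i, j, k] = avail / inflow[i, j, k]

    c_new = c.copy()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out = 0.0
                for ax in range(3):
                    pair = 0.0
                    for d in (2 * ax, 2 * ax + 1):
                        di, dj, dk = DIRS[d]
                        if inside(i + di, j + dj, k + dk):
                            pair += J[d, i, j, k] * s[i + di, j + dj, k + dk]
                    out += pair
                c_new[i, j, k] = min(
                    1.0, max(0.0, c[i, j, k] - out + s[i, j, k] * inflow[i, j, k])
                )
    return c_new, m
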