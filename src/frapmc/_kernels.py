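"""Numba kernels for the particle-based FRAP simulation.

These are the hot loops behind :func:`frapmc.frap_sim.simulate_frap`.
Design notes:

* Kinetic transitions are generated by sampling geometric dwell-time
  countdowns (number of substeps until the next event), which is
  distributionally identical to per-substep Bernoulli trials but avoids
  drawing one uniform per particle per substep.
* Gaussian displacement increments are pre-drawn in bulk by the caller
  with numpy's ziggurat sampler (much faster than per-element draws
  inside the kernel) and consumed positionally; event-related uniforms
  use numba's internal RNG, seeded explicitly per replicate.
"""

import numpy as np
from numba import njit

# countdown value meaning "never" (no event on any realistic timescale)
_NEVER = np.int64(2**62)


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (used for event and bleach uniforms)."""
    np.random.seed(seed)


@njit(cache=True)
def _geometric(p):
    """Substeps until an event with per-substep probability p (support 1,2,...)."""
    if p <= 0.0:
        return _NEVER
    if p >= 1.0:
        return np.int64(1)
    u = np.random.random()
    k = np.int64(np.ceil(np.log(u) / np.log1p(-p)))
    if k < 1:
        k = np.int64(1)
    return k


@njit(cache=True)
def _reflect(x, y, z, dx, dy, dz, a, b, c):
    """Move (x,y,z) by (dx,dy,dz) with specular reflection at the ellipsoid.

    Reflection is applied at the exact boundary crossing, about the local
    surface normal, iterated up to 10 times; if the point is still outside
    (pathological step) the move is rejected and the origin point returned.
    """
    ox, oy, oz = x, y, z
    nx = x + dx
    ny = y + dy
    nz = z + dz
    for _ in range(10):
        if (nx / a) ** 2 + (ny / b) ** 2 + (nz / c) ** 2 <= 1.0:
            return nx, ny, nz
        ux = x / a
        uy = y / b
        uz = z / c
        vx = dx / a
        vy = dy / b
        vz = dz / c
        A = vx * vx + vy * vy + vz * vz
        if A <= 0.0:
            break
        B = 2.0 * (ux * vx + uy * vy + uz * vz)
        C = ux * ux + uy * uy + uz * uz - 1.0
        if C > 0.0:
            C = 0.0  # start numerically on/outside the surface
        disc = B * B - 4.0 * A * C
        if disc < 0.0:
            disc = 0.0
        t = (-B + np.sqrt(disc)) / (2.0 * A)
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        qx = x + t * dx
        qy = y + t * dy
        qz = z + t * dz
        nxs = qx / (a * a)
        nys = qy / (b * b)
        nzs = qz / (c * c)
        nn = np.sqrt(nxs * nxs + nys * nys + nzs * nzs)
        if nn <= 0.0:
            break
        nxs /= nn
        nys /= nn
        nzs /= nn
        rx = (1.0 - t) * dx
        ry = (1.0 - t) * dy
        rz = (1.0 - t) * dz
        dot = rx * nxs + ry * nys + rz * nzs
        rx -= 2.0 * dot * nxs
        ry -= 2.0 * dot * nys
        rz -= 2.0 * dot * nzs
        # nudge the boundary point inward so the next inclusion test is stable
        x = qx * (1.0 - 1e-12)
        y = qy * (1.0 - 1e-12)
        z = qz * (1.0 - 1e-12)
        dx, dy, dz = rx, ry, rz
        nx = x + dx
        ny = y + dy
        nz = z + dz
    return ox, oy, oz


@njit(cache=True)
def apply_displacements(pos, disp, mobile, a, b, c):
    """Apply per-particle displacements with reflective boundaries (in place)."""
    for i in range(pos.shape[0]):
        if mobile[i]:
            x, y, z = _reflect(
                pos[i, 0], pos[i, 1], pos[i, 2],
                disp[i, 0], disp[i, 1], disp[i, 2],
                a, b, c,
            )
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z


@njit(cache=True)
def _strip_intensity(x, half_w, lat_sigma):
    d = np.abs(x) - half_w
    if d <= 0.0:
        return 1.0
    return np.exp(-d * d / (2.0 * lat_sigma * lat_sigma))


@njit(cache=True)
def bleach_round(pos, fluor, dose, half_w, lat_sigma):
    """One bleach iteration: stochastic survival under the beam profile."""
    for i in range(pos.shape[0]):
        if fluor[i]:
            inten = _strip_intensity(pos[i, 0], half_w, lat_sigma)
            if np.random.random() >= np.exp(-dose * inten):
                fluor[i] = False


@njit(cache=True)
def bleach_round_weighted(pos, weight, dose, half_w, lat_sigma):
    """One bleach iteration on continuous fluorescence weights.

    Rao-Blackwellized form of :func:`bleach_round`: each particle keeps
    its expected surviving fluorescence ``w *= exp(-dose*I)`` instead of
    a Bernoulli outcome. The mean ROI signal is identical; the variance
    contributed by bleach survival randomness (dominated by the few
    immobile particles resident in the strip) vanishes.
    """
    for i in range(pos.shape[0]):
        if weight[i] > 0.0:
            inten = _strip_intensity(pos[i, 0], half_w, lat_sigma)
            weight[i] *= np.exp(-dose * inten)


@njit(cache=True)
def advance_block(pos, state, countdown, fluor, normals, nsub,
                  a, b, c, sigma_step, p_on1, p_on2, p_off1, p_off2,
                  half_w, counts_out):
    """Advance a block of scan intervals, recording the ROI count per scan.

    ``counts_out`` has one slot per scan in the block; each scan is
    ``nsub`` substeps. ``fluor`` holds per-particle fluorescence weights
    summed by the ROI measurement after each scan. ``normals`` is an
    (m, 3) float32 buffer of unit normals, pre-drawn by the caller and
    consumed sequentially by free particles; if it runs out (free count
    fluctuated upward) the kernel falls back to its own RNG. Event
    uniforms use numba's RNG, so :func:`seed_rng` must be called first.
    """
    p_on = p_on1 + p_on2
    branch1 = p_on1 / p_on if p_on > 0.0 else 1.0
    n = pos.shape[0]
    ia = 1.0 / a
    ib = 1.0 / b
    ic = 1.0 / c
    m = normals.shape[0]
    cur = 0
    for sc in range(counts_out.shape[0]):
        for _ in range(nsub):
            for i in range(n):
                if state[i] == 0:
                    if sigma_step > 0.0:
                        if cur < m:
                            dx = sigma_step * normals[cur, 0]
                            dy = sigma_step * normals[cur, 1]
                            dz = sigma_step * normals[cur, 2]
                            cur += 1
                        else:
                            dx = sigma_step * np.random.standard_normal()
                            dy = sigma_step * np.random.standard_normal()
                            dz = sigma_step * np.random.standard_normal()
                        nx = pos[i, 0] + dx
                        ny = pos[i, 1] + dy
                        nz = pos[i, 2] + dz
                        if (nx * ia) ** 2 + (ny * ib) ** 2 + (nz * ic) ** 2 <= 1.0:
                            pos[i, 0] = nx
                            pos[i, 1] = ny
                            pos[i, 2] = nz
                        else:
                            x, y, z = _reflect(
                                pos[i, 0], pos[i, 1], pos[i, 2],
                                dx, dy, dz, a, b, c,
                            )
                            pos[i, 0] = x
                            pos[i, 1] = y
                            pos[i, 2] = z
                    countdown[i] -= 1
                    if countdown[i] <= 0:
                        if np.random.random() < branch1:
                            state[i] = 1
                            countdown[i] = _geometric(p_off1)
                        else:
                            state[i] = 2
                            countdown[i] = _geometric(p_off2)
                else:
                    countdown[i] -= 1
                    if countdown[i] <= 0:
                        state[i] = 0
                        countdown[i] = _geometric(p_on)
        cnt = 0.0
        for i in range(n):
            if -half_w <= pos[i, 0] <= half_w:
                cnt += fluor[i]
        counts_out[sc] = cnt

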