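"""Numba-JIT inner loops for the Brownian-dynamics integrator.

The hot path advances all nuclei with the Euler-Maruyama scheme

    dx_i = F_i * dt + sqrt(2 * D * dt) * xi_i

where ``F_i`` sums pair forces (harmonic core repulsion, quadratic adhesive
well of depth S over the shell ``(1, 1+R)``) and harmonic wall repulsion
from the flat lower membrane, the spline-interpolated upper membrane and
the two end walls.  Pair search exploits the quasi-1D geometry: nuclei are
sorted by x each step and the inner loop breaks once the x-gap exceeds the
interaction radius, giving O(n log n) work per step.

The upper-membrane height is evaluated from the cubic-spline coefficient
array produced by ``scipy.interpolate.CubicSpline`` (uniform breakpoints),
so the kernel never calls back into Python.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _spline_height(x, bx0, bdx, bc):
    """Evaluate the piecewise cubic at x given uniform breakpoints."""
    m = bc.shape[1]
    i = int((x - bx0) / bdx)
    if i < 0:
        i = 0
    elif i >= m:
        i = m - 1
    t = x - (bx0 + i * bdx)
    return ((bc[0, i] * t + bc[1, i]) * t + bc[2, i]) * t + bc[3, i]


@njit(cache=True)
def advance(pos, n_steps, dt, D, S, k_rep, R, L, T, has_profile, bx0, bdx, bc, rng):
    """Advance ``pos`` (modified in place) by ``n_steps`` Euler-Maruyama steps.

    Returns (step_index, nucleus_index) of the first non-finite position, or
    (-1, -1) on success.  ``k_rep == 0`` disables both pair repulsion and all
    walls; together with ``S == 0`` this is free diffusion.
    """
    n = pos.shape[0]
    rcut = 1.0 + R
    rcut2 = rcut * rcut
    noise = np.sqrt(2.0 * D * dt)
    free = (S == 0.0) and (k_rep == 0.0)
    fx = np.empty(n)
    fy = np.empty(n)
    for step in range(n_steps):
        if not free:
            for i in range(n):
                fx[i] = 0.0
                fy[i] = 0.0
            order = np.argsort(pos[:, 0])
            for a in range(n):
                i = order[a]
                xi = pos[i, 0]
                yi = pos[i, 1]
                for b in range(a + 1, n):
                    j = order[b]
                    dxp = pos[j, 0] - xi
                    if dxp > rcut:
                        break
                    dyp = pos[j, 1] - yi
                    r2 = dxp * dxp + dyp * dyp
                    if r2 > rcut2 or r2 == 0.0:
                        continue
                    r = np.sqrt(r2)
                    if r < 1.0:
                        fmag = 2.0 * k_rep * (1.0 - r)
                    else:
                        fmag = -(2.0 * S / R) * (1.0 - (r - 1.0) / R)
                    # fmag > 0 pushes i and j apart along the centre line
                    fxij = fmag * dxp / r
                    fyij = fmag * dyp / r
                    fx[i] -= fxij
                    fy[i] -= fyij
                    fx[j] += fxij
                    fy[j] += fyij
                if k_rep > 0.0:
                    if yi < 0.5:
                        fy[i] += k_rep * (0.5 - yi)
                    if has_profile:
                        upper = T + _spline_height(xi, bx0, bdx, bc)
                    else:
                        upper = T
                    if upper - yi < 0.5:
                        fy[i] -= k_rep * (0.5 - (upper - yi))
                    if xi < 0.5:
                        fx[i] += k_rep * (0.5 - xi)
                    if L - xi < 0.5:
                        fx[i] -= k_rep * (0.5 - (L - xi))
        for i in range(n):
            if free:
                pos[i, 0] += noise * rng.standard_normal()
                pos[i, 1] += noise * rng.standard_normal()
            else:
                pos[i, 0] += fx[i] * dt + noise * rng.standard_normal()
                pos[i, 1] += fy[i] * dt + noise * rng.standard_normal()
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                return step, i
    return -1, -1
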