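"""Compiled inner loops for the force engine (numba), with numpy fallbacks.

The kernels take precomputed Verlet pair lists and accumulate forces in
place; z is the only periodic direction.  Each returns the potential energy
of its term (the FENE kernel also returns the maximum bond length so the
caller can detect blow-up without branching inside the loop).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def wca_kernel(pos, pairs, Lz, eps, sigma, rcut, cap, f_out):
    e = 0.0
    rc2 = rcut * rcut
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dz -= Lz * round(dz / Lz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            sr2 = sigma * sigma / r2
            sr6 = sr2 * sr2 * sr2
            r = np.sqrt(r2)
            fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
            if cap > 0.0 and fmag > cap:
                fmag = cap
            e += 4.0 * eps * (sr6 * sr6 - sr6) + eps
            fr = fmag / r
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            f_out[i, 0] += fx
            f_out[i, 1] += fy
            f_out[i, 2] += fz
            f_out[j, 0] -= fx
            f_out[j, 1] -= fy
            f_out[j, 2] -= fz
    return e


@njit(cache=True)
def coulomb_kernel(pos, pairs, q, Lz, pref, rc, f_out):
    e = 0.0
    rc2 = rc * rc
    inv_rc = 1.0 / rc
    inv_rc2 = inv_rc * inv_rc
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dz -= Lz * round(dz / Lz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            r = np.sqrt(r2)
            qq = pref * q[i] * q[j]
            fmag = qq * (1.0 / r2 - inv_rc2)
            e += qq * (1.0 / r - inv_rc + (r - rc) * inv_rc2)
            fr = fmag / r
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            f_out[i, 0] += fx
            f_out[i, 1] += fy
            f_out[i, 2] += fz
            f_out[j, 0] -= fx
            f_out[j, 1] -= fy
            f_out[j, 2] -= fz
    return e


@njit(cache=True)
def fene_kernel(pos, bonds, Lz, kf, R0, f_out):
    e = 0.0
    rmax = 0.0
    R02 = R0 * R0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dz -= Lz * round(dz / Lz)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r > rmax:
            rmax = r
        if r >= R0:
            continue  # caller raises using rmax
        x2 = r2 / R02
        e += -0.5 * kf * R02 * np.log(1.0 - x2)
        fr = -kf / (1.0 - x2)  # attractive: force along -d
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        f_out[i, 0] += fx
        f_out[i, 1] += fy
        f_out[i, 2] += fz
        f_out[j, 0] -= fx
        f_out[j, 1] -= fy
        f_out[j, 2] -= fz
    return e, rmax
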