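"""Numba kernel: exact per-voxel ray tracing (Siddon-style parametric walk).

The kernel accumulates sum_j a_ij * f_j for a batch of rays sharing one
source position, where a_ij is the exact intersection length of ray i with
voxel j.  Kept free of Python objects so it compiles once per session.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = 1e300
_EPS = 1e-12


@njit(cache=False, fastmath=False, boundscheck=False)
def siddon_integrals(values, bx0, by0, bz0, sx, sy, sz,
                     srcx, srcy, srcz, dst, out):  # pragma: no cover - jit
    nx, ny, nz = values.shape
    n = dst.shape[0]
    bx1 = bx0 + nx * sx
    by1 = by0 + ny * sy
    bz1 = bz0 + nz * sz
    for i in range(n):
        dx = dst[i, 0] - srcx
        dy = dst[i, 1] - srcy
        dz = dst[i, 2] - srcz
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        tmin = 0.0
        tmax = 1.0
        miss = False
        # slab clipping per axis
        for a in range(3):
            if a == 0:
                d, p, b0, b1 = dx, srcx, bx0, bx1
            elif a == 1:
                d, p, b0, b1 = dy, srcy, by0, by1
            else:
                d, p, b0, b1 = dz, srcz, bz0, bz1
            if d != 0.0:
                t0 = (b0 - p) / d
                t1 = (b1 - p) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > tmin:
                    tmin = t0
                if t1 < tmax:
                    tmax = t1
            elif p <= b0 or p >= b1:
                miss = True
        if miss or tmax <= tmin:
            out[i] = 0.0
            continue
        t = tmin
        px = srcx + t * dx
        py = srcy + t * dy
        pz = srcz + t * dz
        ix = int(np.floor((px - bx0) / sx))
        iy = int(np.floor((py - by0) / sy))
        iz = int(np.floor((pz - bz0) / sz))
        if ix < 0:
            ix = 0
        elif ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy > ny - 1:
            iy = ny - 1
        if iz < 0:
            iz = 0
        elif iz > nz - 1:
            iz = nz - 1
        # next crossing parameter and step per axis
        if dx > 0.0:
            stepx = 1
            tx = (bx0 + (ix + 1) * sx - srcx) / dx
            dtx = sx / dx
        elif dx < 0.0:
            stepx = -1
            tx = (bx0 + ix * sx - srcx) / dx
            dtx = -sx / dx
        else:
            stepx = 0
            tx = _INF
            dtx = _INF
        if dy > 0.0:
            stepy = 1
            ty = (by0 + (iy + 1) * sy - srcy) / dy
            dty = sy / dy
        elif dy < 0.0:
            stepy = -1
            ty = (by0 + iy * sy - srcy) / dy
            dty = -sy / dy
        else:
            stepy = 0
            ty = _INF
            dty = _INF
        if dz > 0.0:
            stepz = 1
            tz = (bz0 + (iz + 1) * sz - srcz) / dz
            dtz = sz / dz
        elif dz < 0.0:
            stepz = -1
            tz = (bz0 + iz * sz - srcz) / dz
            dtz = -sz / dz
        else:
            stepz = 0
            tz = _INF
            dtz = _INF
        acc = 0.0
        while t < tmax - _EPS:
            tnext = tx
            if ty < tnext:
                tnext = ty
            if tz < tnext:
                tnext = tz
            if tnext > tmax:
                tnext = tmax
            if tnext > t:
                acc += (tnext - t) * values[ix, iy, iz]
                t = tnext
            else:
                t = t + _EPS  # defensive: should not happen
            done = False
            if tx <= t + _EPS:
                ix += stepx
                tx += dtx
                if ix < 0 or ix >= nx:
                    done = True
            if ty <= t + _EPS:
                iy += stepy
                ty += dty
                if iy < 0 or iy >= ny:
                    done = True
            if tz <= t + _EPS:
                iz += stepz
                tz += dtz
                if iz < 0 or iz >= nz:
                    done = True
            if done:
                break
        out[i] = acc * length
    return out
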