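"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own integration routines: mass
properties come from counting voxel centres inside the surface (z-column
ray parity), and rotation compositions are built directly from the
elementary matrices.
"""

from __future__ import annotations

import numpy as np


def voxel_mass_properties(mesh, n: int = 200, density: float = 1.0):
    """Voxel-counting mass, volume, and COM of a closed mesh.

    An n×n grid of vertical columns covers the bounding box; each column
    collects its surface crossings (triangle/ray intersections) and
    integrates the inside intervals between entry/exit pairs exactly along
    z (the cross-section stays discretized at the n-grid).  Returns a dict
    with ``volume``, ``mass``, ``com``.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    lo = v.min(axis=0) - 1e-9
    hi = v.max(axis=0) + 1e-9
    pad = 0.5 * (hi - lo) / n
    lo, hi = lo - pad, hi + pad
    step = (hi - lo) / n
    xc = lo[0] + (np.arange(n) + 0.5) * step[0]
    yc = lo[1] + (np.arange(n) + 0.5) * step[1]
    zc = lo[2] + (np.arange(n) + 0.5) * step[2]

    cols_all, z_all = [], []
    tri = v[f]  # (m, 3, 3)
    for a, b, c in tri:
        xmin, xmax = min(a[0], b[0], c[0]), max(a[0], b[0], c[0])
        ymin, ymax = min(a[1], b[1], c[1]), max(a[1], b[1], c[1])
        i0 = np.searchsorted(xc, xmin, "left")
        i1 = np.searchsorted(xc, xmax, "right")
        j0 = np.searchsorted(yc, ymin, "left")
        j1 = np.searchsorted(yc, ymax, "right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xc[i0:i1], yc[j0:j1], indexing="ij")
        p = np.stack([gx.ravel(), gy.ravel()], axis=1)
        # barycentric in the xy-projection
        d = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        if abs(d) < 1e-15:
            continue  # vertical triangle: no z-crossing contribution
        w1 = ((p[:, 0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[:, 1] - a[1])) / d
        w2 = ((b[0] - a[0]) * (p[:, 1] - a[1]) - (p[:, 0] - a[0]) * (b[1] - a[1])) / d
        w0 = 1.0 - w1 - w2
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        zhit = (w0 * a[2] + w1 * b[2] + w2 * c[2])[inside]
        ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
        cols = (ii.ravel() * n + jj.ravel())[inside]
        cols_all.append(cols)
        z_all.append(zhit)

    cols_all = np.concatenate(cols_all)
    z_all = np.concatenate(z_all)
    order = np.lexsort((z_all, cols_all))
    cols_all, z_all = cols_all[order], z_all[order]
    uniq, starts = np.unique(cols_all, return_index=True)
    starts = np.append(starts, len(cols_all))

    total_len = 0.0
    sx = sy = sz = 0.0
    for u, s0, s1 in zip(uniq, starts[:-1], starts[1:]):
        zs = z_all[s0:s1]
        if len(zs) % 2:  # grazing column; skip
            continue
        i, j = divmod(u, n)
        for z_in, z_out in zip(zs[0::2], zs[1::2]):
            length = z_out - z_in
            if length <= 0:
                continue
            total_len += length
            sx += length * xc[i]
            sy += length * yc[j]
            sz += length * 0.5 * (z_in + z_out)

    cell_xy = float(step[0] * step[1])
    volume = total_len * cell_xy
    com = np.array([sx, sy, sz]) / max(total_len, 1e-300)
    return {"volume": volume, "mass": density * volume, "com": com}


def rotation_product_oracle(theta_x, theta_y, theta_z):
    """Explicit Rx·Ry·Rz product (radians), built independently."""
    def rx(t):
        return np.array([[1, 0, 0],
                         [0, np.cos(t), -np.sin(t)],
                         [0, np.sin(t), np.cos(t)]])

    def ry(t):
        return np.array([[np.cos(t), 0, np.sin(t)],
                         [0, 1, 0],
                         [-np.sin(t), 0, np.cos(t)]])

    def rz(t):
        return np.array([[np.cos(t), -np.sin(t), 0],
                         [np.sin(t), np.cos(t), 0],
                         [0, 0, 1]])

    return rx(theta_x) @ ry(theta_y) @ rz(theta_z)


def seeded_blob(seed: int, subdivisions: int = 3):
    """Watertight star-shaped mesh: an icosphere with smoothly varying radii."""
    import trimesh

    rng = np.random.default_rng(seed)
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = mesh.vertices.copy()
    # smooth radial modulation from a few random spherical harmonics-like terms
    freq = rng.uniform(1.0, 3.0, size=(3, 3))
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.uniform(0.05, 0.15, size=3)
    r = np.ones(len(v))
    for k in range(3):
        r += amp[k] * np.sin(v @ freq[k] + phase[k])
    mesh.vertices = v * r[:, None]
    return mesh


def tangent_wrap_oracle(P, Q, R):
    """Planar tangent-line wrap length around a circle at the origin.

    Constructs the two tangent points explicitly for each wrap side and
    returns the shorter tangent–arc–tangent length.
    """
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    dP, dQ = np.linalg.norm(P), np.linalg.norm(Q)
    lP = np.sqrt(dP ** 2 - R ** 2)
    lQ = np.sqrt(dQ ** 2 - R ** 2)
    aP, aQ = np.arctan2(P[1], P[0]), np.arctan2(Q[1], Q[0])
    bP, bQ = np.arccos(R / dP), np.arccos(R / dQ)
    best = None
    for s in (1, -1):
        tP = aP + s * bP
        tQ = aQ - s * bQ
        arc = (s * (tQ - tP)) % (2 * np.pi)
        # verify the tangency construction: the tangent points must lie on
        # the circle and the tangent lines must have length lP, lQ
        TP = R * np.array([np.cos(tP), np.sin(tP)])
        TQ = R * np.array([np.cos(tQ), np.sin(tQ)])
        assert abs(np.linalg.norm(P - TP) - lP) < 1e-9
        assert abs(np.linalg.norm(Q - TQ) - lQ) < 1e-9
        cand = lP + R * arc + lQ
        best = cand if best is None or cand < best else best
    return best
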