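"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: point-in-mesh via the
generalized winding number (solid-angle sum) instead of ray parity, and
hull membership via convex-combination linear-programming feasibility
instead of facet half-spaces.
"""

import numpy as np
from scipy.optimize import linprog


def winding_inside(points, mesh, thresh=0.5, batch=512):
    """Generalized winding number >= ~1 marks interior points.

    Solid angle of each triangle at each query point via the
    van Oosterom-Strackee formula, summed and divided by 4*pi.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    tris = mesh.vertices[mesh.faces]
    out = np.zeros(len(pts), dtype=bool)
    for s in range(0, len(pts), batch):
        p = pts[s:s + batch]
        a = tris[None, :, 0] - p[:, None]
        b = tris[None, :, 1] - p[:, None]
        c = tris[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("ptk,ptk->pt", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ptk,ptk->pt", a, b) * lc
               + np.einsum("ptk,ptk->pt", a, c) * lb
               + np.einsum("ptk,ptk->pt", b, c) * la)
        omega = 2.0 * np.arctan2(num, den)
        out[s:s + batch] = np.abs(omega.sum(axis=1)) / (4 * np.pi) > thresh
    return out


def in_hull_lp(point, generators, tol=1e-9):
    """Is ``point`` a convex combination of ``generators``? (LP feasibility)."""
    gen = np.asarray(generators, float)
    n = len(gen)
    a_eq = np.vstack([gen.T, np.ones(n)])
    b_eq = np.append(np.asarray(point, float), 1.0)
    res = linprog(np.zeros(n), A_eq=a_eq, b_eq=b_eq,
                  bounds=[(0, None)] * n, method="highs")
    return res.status == 0 and res.success


def in_hull_lp_mask(points, generators, tol=1e-9):
    return np.array([in_hull_lp(p, generators, tol) for p in points])


def in_cone_lp(point, generators):
    """Is ``point`` a *conic* (nonnegative) combination of ``generators``?

    The focal cone from the origin over the hull of the generators is
    exactly their conic hull, so this is the brute-force oracle for the
    carried-through-cone removal test.
    """
    gen = np.asarray(generators, float)
    res = linprog(np.zeros(len(gen)), A_eq=gen.T,
                  b_eq=np.asarray(point, float),
                  bounds=[(0, None)] * len(gen), method="highs")
    return res.status == 0 and res.success


def in_cone_lp_mask(points, generators):
    return np.array([in_cone_lp(p, generators) for p in points])
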