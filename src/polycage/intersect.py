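"""Face-face interpenetration tests.

Optimized cages can end up with faces passing through each other (mostly
prism-derived cages); such geometries must be discarded.  Faces are
triangulated into their facelets (centre + two consecutive vertices) and
facelet pairs from distinct faces are tested with Moller's interval-overlap
triangle-triangle test, robust to coplanar pairs.  Facelet pairs sharing a
cage node are skipped: contact along a shared edge is structural, not
interpenetration.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-9


class DegenerateTriangleError(ValueError):
    pass


def _project_interval(verts, d, line_dir, line_pt):
    """Scalar interval covered by a triangle on the intersection line.

    ``d`` are signed distances of the triangle's vertices to the other
    plane; the triangle crosses the line between vertices of opposite sign.
    """
    t = verts @ line_dir - line_pt @ line_dir
    lo, hi = np.inf, -np.inf
    for i in range(3):
        if abs(d[i]) <= EPS:        # vertex on the line's plane
            lo, hi = min(lo, t[i]), max(hi, t[i])
        for j in range(i + 1, 3):
            di, dj = d[i], d[j]
            if di > EPS and dj < -EPS or di < -EPS and dj > EPS:
                s = di / (di - dj)
                v = t[i] + s * (t[j] - t[i])
                lo, hi = min(lo, v), max(hi, v)
    return lo, hi


def _coplanar_overlap(t1, t2, normal):
    """2-D overlap test for coplanar triangles (closed triangles)."""
    axis = int(np.argmax(np.abs(normal)))
    keep = [k for k in range(3) if k != axis]
    a = t1[:, keep]
    b = t2[:, keep]

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    def seg_intersect(p, q, r, s):
        d1 = cross2(q - p, r - p)
        d2 = cross2(q - p, s - p)
        d3 = cross2(s - r, p - r)
        d4 = cross2(s - r, q - r)
        if ((d1 > EPS) != (d2 > EPS)) and ((d3 > EPS) != (d4 > EPS)) \
                and abs(d1 - d2) > EPS and abs(d3 - d4) > EPS:
            return True
        for u, (v, w) in ((p, (r, s)), (q, (r, s)), (r, (p, q)), (s, (p, q))):
            if _on_segment(u, v, w):
                return True
        return False

    def _on_segment(u, v, w):
        if abs(cross2(w - v, u - v)) > EPS:
            return False
        return (min(v[0], w[0]) - EPS <= u[0] <= max(v[0], w[0]) + EPS
                and min(v[1], w[1]) - EPS <= u[1] <= max(v[1], w[1]) + EPS)

    def inside(pt, tri):
        s = 0
        for k in range(3):
            c = cross2(tri[(k + 1) % 3] - tri[k], pt - tri[k])
            if abs(c) <= EPS:
                continue
            sg = 1 if c > 0 else -1
            if s == 0:
                s = sg
            elif s != sg:
                return False
        return True

    for i in range(3):
        for j in range(3):
            if seg_intersect(a[i], a[(i + 1) % 3], b[j], b[(j + 1) % 3]):
                return True
    return inside(a[0], b) or inside(b[0], a)


def triangles_intersect(t1, t2):
    """True iff the closed triangles share at least one point."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    if np.linalg.norm(n1) < 1e-14 or np.linalg.norm(n2) < 1e-14:
        raise DegenerateTriangleError("degenerate input triangle")

    d2 = (t1 - t2[0]) @ n2          # distances of t1 vertices to plane 2
    if np.all(d2 > EPS) or np.all(d2 < -EPS):
        return False
    d1 = (t2 - t1[0]) @ n1
    if np.all(d1 > EPS) or np.all(d1 < -EPS):
        return False

    if np.all(np.abs(d2) <= EPS):   # coplanar
        return bool(_coplanar_overlap(t1, t2, n2))

    line = np.cross(n1, n2)
    line = line / np.linalg.norm(line)
    lo1, hi1 = _project_interval(t1, d2, line, t1[0] * 0.0)
    lo2, hi2 = _project_interval(t2, d1, line, t1[0] * 0.0)
    return bool(lo1 <= hi2 + EPS and lo2 <= hi1 + EPS)


# ---------------------------------------------------------------------------
# cage-level test
# ---------------------------------------------------------------------------

def _facelets(geometry):
    """Per face: list of (triangle (3,3), frozenset of touched node ids)."""
    topo = geometry.topology
    C = geometry.face_centres()
    x = geometry.face_nodes
    out = []
    for f in range(topo.N):
        tris = []
        for i in range(topo.P):
            j = (i + 1) % topo.P
            tri = np.stack([C[f], x[f, i], x[f, j]])
            tris.append((tri, frozenset((int(topo.faces[f, i]),
                                         int(topo.faces[f, j])))))
        out.append(tris)
    return out


def cage_self_intersects(geometry, max_pairs=None):
    """Detect interpenetrating faces; returns (flag, offending face pairs).

    All facelet pairs from distinct faces are tested except those sharing a
    cage node (the structural contact along shared edges).  A bounding-
    sphere prefilter skips far-apart face pairs.
    """
    topo = geometry.topology
    fl = _facelets(geometry)
    C = geometry.face_centres()
    radii = np.linalg.norm(geometry.face_nodes - C[:, None, :], axis=2).max(axis=1)
    offending = []
    for f in range(topo.N):
        for g in range(f + 1, topo.N):
            if np.linalg.norm(C[f] - C[g]) > radii[f] + radii[g] + 1e-9:
                continue
            hit = False
            for tri1, nodes1 in fl[f]:
                for tri2, nodes2 in fl[g]:
                    if nodes1 & nodes2:
                        continue
                    if triangles_intersect(tri1, tri2):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                offending.append((f, g))
                if max_pairs is not None and len(offending) >= max_pairs:
                    return True, offending
    return bool(offending), offending
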