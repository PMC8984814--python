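"""Three-dimensional embedding of a p-cage and its face geometry.

Node coordinates are dimensionless with the reference edge length L_f = 1.
The derived quantities follow the standard cage bookkeeping: edge vectors
s_{f,i} between consecutive face nodes (anticlockwise seen from outside),
corner angles, the cage centre O (mean over distinct nodes), face centres
C_f, facelet normals w_{f,i} = (nu_{f,i} x nu_{f,i+1})/2 spanned by
consecutive spokes nu from the face centre, and the face area vector
W_f = sum_i w_{f,i} with unit normal W_f/|W_f|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solids import build_solid
from .topology import build_topology


class DegenerateEdgeError(ValueError):
    pass


class EmbeddingError(RuntimeError):
    pass


@dataclass
class PCageGeometry:
    """A p-cage topology together with node coordinates.

    Shared nodes are stored once; faces address them through the topology's
    (N, P) index table, so coincidence of shared nodes is structural.
    """

    topology: object
    nodes: np.ndarray           # (NN, 3)

    def copy(self):
        return PCageGeometry(self.topology, self.nodes.copy())

    # ------------------------------------------------------------------
    @property
    def face_nodes(self):
        """(N, P, 3) coordinates per face slot."""
        return self.nodes[self.topology.faces]

    def edge_vectors(self):
        """s_{f,i} = n_{f,i+1} - n_{f,i}, shape (N, P, 3)."""
        x = self.face_nodes
        return np.roll(x, -1, axis=1) - x

    def edge_lengths(self):
        return np.linalg.norm(self.edge_vectors(), axis=2)

    def face_angles(self):
        """Corner angles alpha in (0, pi); the value computed from edges i
        and i+1 is stored at node (i+1) % P."""
        s = self.edge_vectors()
        ln = np.linalg.norm(s, axis=2)
        if np.any(ln < 1e-14):
            raise DegenerateEdgeError("zero-length edge")
        nxt = np.roll(s, -1, axis=1)
        cosv = -(s * nxt).sum(axis=2) / (ln * np.roll(ln, -1, axis=1))
        ang = np.arccos(np.clip(cosv, -1.0, 1.0))
        return np.roll(ang, 1, axis=1)

    def cage_centre(self):
        return self.nodes.mean(axis=0)

    def face_centres(self):
        return self.face_nodes.mean(axis=1)

    def facelet_normals(self):
        """w_{f,i}, shape (N, P, 3)."""
        nu = self.face_nodes - self.face_centres()[:, None, :]
        return 0.5 * np.cross(nu, np.roll(nu, -1, axis=1))

    def face_area_vectors(self):
        return self.facelet_normals().sum(axis=1)

    def face_unit_normals(self):
        W = self.face_area_vectors()
        n = np.linalg.norm(W, axis=1, keepdims=True)
        if np.any(n < 1e-14):
            raise DegenerateEdgeError("degenerate face (zero area vector)")
        return W / n

    def edge_midpoints(self):
        x = self.face_nodes
        return 0.5 * (x + np.roll(x, -1, axis=1))

    def midpoint_offsets(self):
        """d_{f,i} = M_{f,i} - C_f."""
        return self.edge_midpoints() - self.face_centres()[:, None, :]

    def transformed(self, rotation=None, translation=None):
        out = self.nodes
        if rotation is not None:
            out = out @ np.asarray(rotation).T
        if translation is not None:
            out = out + np.asarray(translation)
        return PCageGeometry(self.topology, out)


# ---------------------------------------------------------------------------
# initial embedding
# ---------------------------------------------------------------------------

def _regular_polygon(P):
    """Unit-edge regular P-gon in the xy-plane, anticlockwise, centred at 0."""
    rho = 0.5 / np.sin(np.pi / P)
    ang = 2.0 * np.pi * (np.arange(P) + 0.5) / P
    return np.stack([rho * np.cos(ang), rho * np.sin(ang),
                     np.zeros(P)], axis=1)


def _tangent_basis(normal):
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2, n


def initial_embedding(topology, max_iter=2000, tol=1e-9):
    """Assemble the cage from rigid regular faces and merge shared nodes.

    Each face starts as a regular unit-edge P-gon placed on its
    hole-polyhedron vertex (normal radial, in-plane rotation chosen so the
    shared-edge midpoints point towards the face's neighbours), at a radius
    where neighbouring face centres sit roughly a face diameter apart.  The
    assembly is then relaxed by alternating two steps that mimic zero-rest-
    length springs between the two copies of every shared-edge node: set
    each shared node's target to the mean of its copies, then rigidly re-fit
    every face to its targets (Kabsch).  When the copy gaps stop shrinking
    (or fall below ``tol``) the copies are merged at their midpoints.

    The result is deterministic; no randomness is involved.
    """
    labeling = topology.labeling
    solid = build_solid(labeling.solid_symbol)
    P, N = topology.P, topology.N
    poly = _regular_polygon(P)
    rho = 0.5 / np.sin(np.pi / P)

    # radius: nearest hole-polyhedron vertex distance ~ face diameter
    verts = solid.vertices
    dmin = min(np.linalg.norm(verts[u] - verts[v])
               for u, v in solid.edges)
    R = 2.0 * rho / dmin

    # per-face placement
    placements = np.empty((N, P, 3))
    for f in range(N):
        e1, e2, n = _tangent_basis(verts[f])
        # expected in-plane angles of shared-edge midpoints vs neighbours
        offsets = []
        corners = solid.corners_of_vertex(f)
        pos = 0
        for c in corners:
            u = solid.darts[c][1]
            d = verts[u] - verts[f]
            target = np.arctan2(d @ e2, d @ e1)
            slot_mid = 2.0 * np.pi * (pos + 0.5) / P    # midpoint angle at theta=0
            offsets.append(target - slot_mid)
            pos += 1 + labeling.labels[c]
        theta = np.angle(np.mean(np.exp(1j * np.array(offsets))))
        ca, sa = np.cos(theta), np.sin(theta)
        frame = np.stack([ca * e1 + sa * e2, -sa * e1 + ca * e2, n])
        placements[f] = poly @ frame + R * verts[f]

    # shared-node copy groups: (f, slot index) pairs sharing a node id
    groups = {}
    for f in range(N):
        for i in range(P):
            groups.setdefault(topology.faces[f, i], []).append((f, i))
    shared_groups = [g for g in groups.values() if len(g) > 1]

    def max_gap():
        return max(np.linalg.norm(placements[a][i] - placements[b][j])
                   for (a, i), (b, j) in
                   ((g[0], g[1]) for g in shared_groups))

    last = np.inf
    for _ in range(max_iter):
        targets = np.array(placements)  # copy; only shared slots get targets
        for g in shared_groups:
            mean = np.mean([placements[f][i] for f, i in g], axis=0)
            for f, i in g:
                targets[f][i] = mean
        for f in range(N):
            placements[f] = _kabsch_fit(poly, targets[f])
        gap = max_gap()
        if gap < tol or gap > last * (1.0 - 1e-6):
            break
        last = gap

    nodes = np.zeros((topology.NN, 3))
    for node, g in groups.items():
        nodes[node] = np.mean([placements[f][i] for f, i in g], axis=0)
    return PCageGeometry(topology, nodes)


def _kabsch_fit(template, targets):
    """Best rigid placement (rotation + translation) of ``template`` onto
    ``targets`` in the least-squares sense."""
    mt = template.mean(axis=0)
    mg = targets.mean(axis=0)
    H = (template - mt).T @ (targets - mg)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    Rm = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (template - mt) @ Rm.T + mg


def embed_labeling(labeling, **kwargs):
    """Convenience: topology + initial embedding in one call."""
    return initial_embedding(build_topology(labeling), **kwargs)
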