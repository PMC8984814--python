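"""Incidence structure of a p-cage built from a corner labeling.

Every hole-polyhedron vertex carries one P-gonal cage face.  Walking
anticlockwise around the vertex, the face's edges alternate between a
*shared* edge (one per incident hole-polyhedron edge) and a run of a_i
*hole* edges contributed to the hole sitting on the face between two
consecutive neighbours.  Identifying the endpoint node slots of each shared
edge across the two faces produces the cage graph: NN = N*P - 2*E nodes,
one hole boundary cycle per hole-polyhedron face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solids import build_solid


@dataclass
class PCageTopology:
    """Node/face/hole incidence structure of a homogeneous p-cage."""

    labeling: object                 # CornerLabeling
    N: int                           # number of faces
    P: int                           # edges per face
    faces: np.ndarray                # (N, P) node ids, anticlockwise from outside
    shared_edges: list               # pairs ((f, i), (f2, i2)) of identified edge slots
    shared_slots: set = field(repr=False, default=None)   # {(f, i)} of shared edges
    holes: list = None               # node-id cycles, one per hole-polyhedron face
    hole_faces: list = None          # hole-polyhedron face id per hole

    @property
    def NN(self):
        return int(self.faces.max()) + 1

    @property
    def n_holes(self):
        return len(self.holes)

    def edge_is_shared(self, f, i):
        return (f, i) in self.shared_slots

    def face_neighbours(self, f):
        out = set()
        for (a, i), (b, j) in self.shared_edges:
            if a == f:
                out.add(b)
            elif b == f:
                out.add(a)
        return out


def build_topology(labeling):
    """Assemble the p-cage incidence structure for a labeling.

    Nodes are numbered by union-find over the N*P face-edge slots: the slot
    node (f, i) is the tail of face f's i-th edge; the two endpoint slots of
    a shared edge are identified crosswise with the partner face (the faces
    traverse the common edge in opposite directions).
    """
    labeling.validate()
    solid = build_solid(labeling.solid_symbol)
    P = labeling.P
    N = solid.n_vertices
    Eh = solid.Eh

    # slot layout per face: for neighbour j (ccw), a shared edge at position
    # pos[j], followed by labels[corner j] hole edges
    shared_pos = {}      # (vertex, neighbour) -> edge position in the P-gon
    corner_runs = {}     # (vertex, ccw corner index) -> (start, count) of hole edges
    for v in range(N):
        corners = solid.corners_of_vertex(v)       # out-darts, ccw
        pos = 0
        for j, c in enumerate(corners):
            u = solid.darts[c][1]
            shared_pos[(v, u)] = pos
            corner_runs[(v, j)] = (pos + 1, labeling.labels[c])
            pos += 1 + labeling.labels[c]
        assert pos == P

    # union-find over slots
    parent = list(range(N * P))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def slot(f, i):
        return f * P + i % P

    shared_edges = []
    for (v, u) in {tuple(sorted(d)) for d in solid.darts}:
        i, i2 = shared_pos[(v, u)], shared_pos[(u, v)]
        # face v runs the edge i -> i+1; face u runs it i2 -> i2+1 reversed
        union(slot(v, i), slot(u, i2 + 1))
        union(slot(v, i + 1), slot(u, i2))
        shared_edges.append(((v, i), (u, i2)))

    roots = {}
    faces = np.empty((N, P), dtype=int)
    for f in range(N):
        for i in range(P):
            r = find(slot(f, i))
            if r not in roots:
                roots[r] = len(roots)
            faces[f, i] = roots[r]

    topo = PCageTopology(labeling=labeling, N=N, P=P, faces=faces,
                         shared_edges=shared_edges,
                         shared_slots={s for pair in shared_edges for s in pair})
    _trace_holes(topo, solid, corner_runs)
    _check_invariants(topo, solid)
    return topo


def _trace_holes(topo, solid, corner_runs):
    """Hole boundary cycles, one per hole-polyhedron face.

    The hole on face F collects, from every corner (v, F) around it, the run
    of hole edges that corner contributes; runs join at shared-edge
    endpoints, so walking the face cycle of F concatenates them into one
    node cycle.
    """
    holes, hole_faces = [], []
    P = topo.P
    for fi, face in enumerate(solid.faces):
        cycle = []
        for v in face:
            corners = solid.corners_of_vertex(v)
            j = next(j for j, c in enumerate(corners)
                     if solid.corner_face(c) == fi)
            start, count = corner_runs[(v, j)]
            # hole edges of face v from slot start to start+count-1; the hole is
            # traversed opposite to the face orientation, so prepend reversed
            run = [topo.faces[v, (start + k) % P] for k in range(count + 1)]
            cycle.extend(reversed(run[1:]))
        # consecutive runs share their junction node; drop duplicates
        out = []
        for n in cycle:
            if not out or (n != out[-1] and n != out[0]):
                out.append(n)
        holes.append(out)
        hole_faces.append(fi)
    topo.holes = holes
    topo.hole_faces = hole_faces


def _check_invariants(topo, solid):
    N, P = topo.N, topo.P
    E = solid.n_edges
    if topo.NN != N * P - 2 * E:
        raise AssertionError("node count must satisfy NN = N*P - 2*E")
    if topo.n_holes != solid.n_faces:
        raise AssertionError("one hole per hole-polyhedron face")
    expected = {fi: sum(topo.labeling.hole_q(fi)) for fi in range(solid.n_faces)}
    for hole, fi in zip(topo.holes, topo.hole_faces):
        if len(hole) != expected[fi]:
            raise AssertionError(
                f"hole {fi}: boundary length {len(hole)} != {expected[fi]}")
    # every node sits on 1 or 2 faces and each face has >= 3 neighbours
    counts = np.zeros(topo.NN, dtype=int)
    for f in range(N):
        for i in range(P):
            counts[topo.faces[f, i]] += 1
    if not np.all((counts == 1) | (counts == 2)):
        raise AssertionError("nodes must belong to one or two faces")
    for f in range(N):
        if len(topo.face_neighbours(f)) < 3:
            raise AssertionError("each face needs at least three neighbours")


def hole_size_census(topo):
    """Multiset {boundary length: count} over the cage's holes."""
    out = {}
    for h in topo.holes:
        out[len(h)] = out.get(len(h), 0) + 1
    return out
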