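"""Cage incidence structure and embedding geometry."""

import numpy as np
import pytest

from conftest import random_rigid_motion
from polycage.geometry import PCageGeometry, embed_labeling, initial_embedding
from polycage.labelings import labeling_from_name, named_distributions
from polycage.solids import build_solid, rotation_group
from polycage.topology import build_topology, hole_size_census


@pytest.mark.parametrize("name,N,NN,holes,census", [
    ("Asc_P11_2_1_1_1_1", 24, 144, 38, {3: 32, 8: 6}),
    ("Pic_P10_1_1_1_1_1", 12, 60, 20, {3: 20}),
    ("Arcd_P12_1_2_3_2", 60, 480, 62, {3: 20, 8: 30, 15: 12}),
])
def test_topology_worked_examples(name, N, NN, holes, census):
    topo = build_topology(labeling_from_name(name))
    assert topo.N == N
    assert topo.NN == NN
    assert topo.n_holes == holes
    assert hole_size_census(topo) == census


@pytest.mark.parametrize("symbol,P", [("tp", 8), ("Poc", 10), ("Aid", 10)])
def test_counting_identities_hold_for_all_enumerated_labelings(symbol, P):
    solid = build_solid(symbol)
    for name, lab in named_distributions(symbol, P).items():
        topo = build_topology(lab)
        assert topo.NN == topo.N * topo.P - 2 * solid.n_edges
        assert topo.n_holes == solid.n_faces
        for hole, fi in zip(topo.holes, topo.hole_faces):
            assert len(hole) == sum(lab.hole_q(fi))


def test_every_face_edge_shared_with_face_or_hole():
    topo = build_topology(labeling_from_name("Asc_P11_2_1_1_1_1"))
    hole_edges = set()
    for hole in topo.holes:
        n = len(hole)
        for k in range(n):
            hole_edges.add(frozenset((hole[k], hole[(k + 1) % n])))
    for f in range(topo.N):
        shared_count = 0
        prev_shared = None
        for i in range(topo.P):
            e = frozenset((topo.faces[f, i], topo.faces[f, (i + 1) % topo.P]))
            is_shared = topo.edge_is_shared(f, i)
            if is_shared:
                shared_count += 1
                # of two adjacent edges at least one borders a hole
                assert prev_shared is not True
            else:
                assert e in hole_edges
            prev_shared = is_shared
        assert shared_count == 5  # Eh of the snub cube


def test_embedding_merges_shared_nodes_exactly():
    geo = embed_labeling(labeling_from_name("7p_P9_2_2_2"))
    # shared nodes are stored once: rebuilding per-face coordinates through
    # the index table is the only access path, so copies cannot diverge
    x = geo.face_nodes
    topo = geo.topology
    for (f, i), (f2, i2) in topo.shared_edges:
        a0, a1 = x[f, i], x[f, (i + 1) % topo.P]
        b0, b1 = x[f2, i2], x[f2, (i2 + 1) % topo.P]
        assert np.allclose(a0, b1) and np.allclose(a1, b0)


def test_embedding_of_regular_cage_is_icosahedrally_symmetric(pic_geometry):
    # map the node set onto itself under a rotation induced by the solid
    geo = pic_geometry
    solid = build_solid("Pic")
    g = next(el for el in rotation_group("Pic").elements
             if el.vertex_perm != tuple(range(12)))
    # face centres follow the vertex permutation
    C = geo.face_centres()
    perm = np.array(g.vertex_perm)
    # find the orthogonal matrix aligning C to C[perm]
    U, _, Vt = np.linalg.svd(C.T @ C[perm])
    R = (U @ Vt).T
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
    assert np.allclose(C[perm], C @ R.T, atol=1e-6)


def test_face_angles_of_regular_embedding(pic_geometry):
    a = pic_geometry.face_angles()
    assert np.allclose(a, np.pi * (1 - 2 / 10), atol=1e-9)
    l = pic_geometry.edge_lengths()
    assert np.allclose(l, 1.0, atol=1e-9)


def test_planar_face_normals(pic_geometry):
    w = pic_geometry.facelet_normals()
    What = pic_geometry.face_unit_normals()
    # all facelet normals parallel to the face normal, |W| = face area
    cross = np.cross(w, What[:, None, :])
    assert np.abs(cross).max() < 1e-9
    area = np.linalg.norm(pic_geometry.face_area_vectors(), axis=1)
    P = 10
    expected = P / (4 * np.tan(np.pi / P))   # unit-edge regular P-gon
    assert np.allclose(area, expected, atol=1e-8)


def test_outward_orientation_convention(pic_geometry):
    # anticlockwise from outside means face normals point away from centre
    What = pic_geometry.face_unit_normals()
    F = pic_geometry.face_centres() - pic_geometry.cage_centre()
    assert np.all((What * F).sum(axis=1) > 0)


def test_geometry_quantities_equivariant_under_rigid_motion(pic_geometry):
    Q, t = random_rigid_motion(3)
    moved = pic_geometry.transformed(rotation=Q, translation=t)
    assert np.allclose(moved.edge_lengths(), pic_geometry.edge_lengths(),
                       atol=1e-12)
    assert np.allclose(moved.face_angles(), pic_geometry.face_angles(),
                       atol=1e-12)
    assert np.allclose(moved.face_centres(),
                       pic_geometry.face_centres() @ Q.T + t, atol=1e-12)
    assert np.allclose(moved.facelet_normals(),
                       pic_geometry.facelet_normals() @ Q.T, atol=1e-12)


def test_degenerate_edge_raises():
    from polycage.geometry import DegenerateEdgeError
    geo = embed_labeling(labeling_from_name("Pdo_P9_2_2_2")).copy()
    f0 = geo.topology.faces[0]
    geo.nodes[f0[1]] = geo.nodes[f0[0]]
    with pytest.raises(DegenerateEdgeError):
        geo.face_angles()
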