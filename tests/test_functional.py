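"""Deformation functional terms and metrics."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from conftest import random_rigid_motion
from polycage.functional import (
    FunctionalWeights,
    deformation,
    face_similarity,
    q_angle,
    q_conv_cage,
    q_conv_face,
    q_length,
    q_planar,
    total_q,
)
from polycage.geometry import PCageGeometry


def single_face_geometry(points):
    """Wrap explicit polygons as a geometry (no shared edges)."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 2:
        points = points[None]
    N, P, _ = points.shape
    topo = SimpleNamespace(P=P, N=N,
                           faces=np.arange(N * P).reshape(N, P),
                           shared_edges=[], holes=[])
    return PCageGeometry(topo, points.reshape(-1, 3))


def brute_force_terms(geometry):
    """Independent loop-based evaluation of the smooth functional terms."""
    topo = geometry.topology
    P = topo.P
    a0 = math.pi * (1 - 2 / P)
    ql = qa = qp = 0.0
    for f in range(topo.N):
        x = [geometry.nodes[topo.faces[f][i]] for i in range(P)]
        C = np.mean(x, axis=0)
        s = [x[(i + 1) % P] - x[i] for i in range(P)]
        w = [0.5 * np.cross(x[i] - C, x[(i + 1) % P] - C) for i in range(P)]
        W = np.sum(w, axis=0)
        What = W / np.linalg.norm(W)
        for i in range(P):
            ql += (np.linalg.norm(s[i]) - 1.0) ** 2
            cosv = -np.dot(s[i], s[(i + 1) % P]) / (
                np.linalg.norm(s[i]) * np.linalg.norm(s[(i + 1) % P]))
            qa += (math.acos(max(-1.0, min(1.0, cosv))) - a0) ** 2
            qp += np.dot(w[i], w[i]) - np.dot(w[i], What) ** 2
    return ql, qa, qp


def test_all_terms_vanish_on_regular_cage(pic_geometry):
    qb = total_q(pic_geometry)
    assert qb.q_length < 1e-14
    assert qb.q_angle < 1e-14
    assert qb.q_planar < 1e-12
    assert qb.q_conv_face == 0
    assert qb.q_conv_cage == 0
    assert qb.total < 1e-9


def test_terms_match_brute_force_oracle(noisy_pic):
    ql, qa, qp = brute_force_terms(noisy_pic)
    assert q_length(noisy_pic) == pytest.approx(ql, rel=1e-10)
    assert q_angle(noisy_pic) == pytest.approx(qa, rel=1e-10)
    assert q_planar(noisy_pic) == pytest.approx(qp, rel=1e-8)


def test_q_length_scaling(pic_geometry):
    doubled = pic_geometry.copy()
    doubled.nodes = 2.0 * doubled.nodes
    n_edges = pic_geometry.topology.N * pic_geometry.topology.P
    assert q_length(doubled) == pytest.approx(n_edges * 1.0, rel=1e-9)


def test_q_angle_square_example():
    """100/80-degree parallelogram-like quad: 4 corners 10 degrees off."""
    d = math.radians(10.0)
    a, b = math.radians(100.0), math.radians(80.0)
    # planar quadrilateral with interior angles 100, 80, 100, 80
    pts = [np.zeros(3)]
    heading = 0.0
    for ang in (b, a, b):
        heading += math.pi - ang
        pts.append(pts[-1] + np.array([math.cos(heading), math.sin(heading), 0.0]))
    geo = single_face_geometry(np.array(pts))
    assert q_angle(geo) == pytest.approx(4 * d * d, rel=1e-9)
    assert deformation(geo)[1] == pytest.approx(d / (math.pi / 2), rel=1e-9)


def test_q_planar_lifted_square():
    flat = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    geo = single_face_geometry(flat)
    assert q_planar(geo) < 1e-16
    lifted = flat.copy()
    lifted[2, 2] = 0.1
    geo2 = single_face_geometry(lifted)
    ql, qa, qp = brute_force_terms(geo2)
    assert q_planar(geo2) == pytest.approx(qp, rel=1e-10)
    assert q_planar(geo2) > 0


def test_unit_square_normal_orientation():
    square = single_face_geometry(
        np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float))
    What = square.face_unit_normals()
    assert np.allclose(What[0], [0, 0, 1], atol=1e-12)


def test_q_conv_face_counts_reflex_corners(pic_geometry):
    assert q_conv_face(pic_geometry) == 0
    # pull one node past the face centre -> dart-shaped (reflex) corner
    geo = pic_geometry.copy()
    f0 = geo.topology.faces[0]
    C = geo.face_centres()[0]
    geo.nodes[f0[0]] = C + 0.2 * (C - geo.nodes[f0[0]])
    assert q_conv_face(geo) >= 1


def test_q_conv_cage_flags_inward_fold(pic_geometry):
    assert q_conv_cage(pic_geometry, "edge-midpoint") == 0
    assert q_conv_cage(pic_geometry, "normal-tip") == 0
    # fold one face about a shared edge into the cage: the pair becomes
    # reflex seen from outside and both variants flag it
    topo = pic_geometry.topology
    (f, i), (f2, i2) = topo.shared_edges[0]
    geo = pic_geometry.copy()
    P = topo.P
    a = geo.nodes[topo.faces[f2, i2]]
    b = geo.nodes[topo.faces[f2, (i2 + 1) % P]]
    axis = (b - a) / np.linalg.norm(b - a)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    ang = 2.0
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    shared = {topo.faces[f2, i2], topo.faces[f2, (i2 + 1) % P]}
    for node in topo.faces[f2]:
        if node not in shared:
            geo.nodes[node] = a + R @ (geo.nodes[node] - a)
    assert q_conv_cage(geo, "edge-midpoint") >= 1
    assert q_conv_cage(geo, "normal-tip") >= 1


def test_total_q_is_weighted_sum(noisy_pic):
    w = FunctionalWeights(c_l=2.0, c_a=0.5, c_p=10.0, c_cf=3.0, c_cp=7.0)
    qb = total_q(noisy_pic, w)
    expected = (2.0 * qb.q_length + 0.5 * qb.q_angle + 10.0 * qb.q_planar
                + 3.0 * qb.q_conv_face + 7.0 * qb.q_conv_cage)
    assert qb.total == pytest.approx(expected, rel=1e-12)
    only_planar = FunctionalWeights(c_l=0, c_a=0, c_p=5.0, c_cf=0, c_cp=0)
    assert total_q(noisy_pic, only_planar).total == pytest.approx(
        5.0 * qb.q_planar, rel=1e-12)


def test_default_weights_match_protocol():
    w = FunctionalWeights()
    assert (w.c_l, w.c_a, w.c_p, w.c_cf, w.c_cp) == (1.0, 1.0, 1000.0, 100.0, 100.0)
    assert w.L_f == 1.0


def test_metrics_invariant_under_rigid_motion(noisy_pic):
    Q, t = random_rigid_motion(11)
    moved = noisy_pic.transformed(rotation=Q, translation=t)
    for f in (q_length, q_angle, q_planar):
        assert f(moved) == pytest.approx(f(noisy_pic), abs=1e-11)
    assert q_conv_face(moved) == q_conv_face(noisy_pic)
    assert q_conv_cage(moved) == q_conv_cage(noisy_pic)
    d0, d1 = deformation(noisy_pic), deformation(moved)
    assert d0 == pytest.approx(d1, abs=1e-12)


def test_deformation_examples(pic_geometry):
    assert deformation(pic_geometry) == pytest.approx((0.0, 0.0), abs=1e-9)
    geo = pic_geometry.copy()
    geo.nodes = geo.nodes * 1.02          # edges in [1.02], delta_l = 0.02
    dl, da = deformation(geo)
    assert dl == pytest.approx(0.02, abs=1e-6)
    assert da < 1e-9


def test_face_similarity_zero_for_congruent_faces(pic_geometry):
    wl, wa = face_similarity(pic_geometry)
    assert wl < 1e-12 and wa < 1e-12


def test_face_similarity_cyclic_alignment_and_quantity():
    """Shifted congruent faces align at some delta; rectangles of different
    aspect mismatch by 2|b - c|/P under the best cyclic alignment."""
    a, b, c = 2.0, 1.0, 1.4
    rect = lambda u, v: np.array([[0, 0, 0], [u, 0, 0], [u, v, 0], [0, v, 0]],
                                 dtype=float)
    r1, r2 = rect(a, b), rect(a, c) + np.array([0, 0, 5.0])
    geo = single_face_geometry(np.stack([r1, r2]))
    wl, _ = face_similarity(geo)
    assert wl == pytest.approx(2 * abs(b - c) / 4, rel=1e-12)
    # a cyclically re-indexed copy of the same face matches exactly
    r3 = np.roll(r1, 2, axis=0) + np.array([0, 0, 9.0])
    geo2 = single_face_geometry(np.stack([r1, r3]))
    wl2, wa2 = face_similarity(geo2)
    assert wl2 < 1e-12 and wa2 < 1e-12


def test_iso_weight_calibration_right_triangle():
    """Elongating the hypotenuse via an edge or via the right angle gives
    (delta_l)^2 / l^2 = (delta_theta)^2 to first order."""
    l = 1.0
    for eps in (1e-3, 1e-4):
        L_edge = math.sqrt(l ** 2 + (l * (1 + eps)) ** 2)
        # opening angle of the unit isosceles pair reaching the same span:
        # L^2 = 2 l^2 (1 - cos(theta))
        theta = math.acos(1.0 - L_edge ** 2 / (2 * l * l))
        delta = theta - math.pi / 2
        assert abs(delta / (eps * l) - 1.0) < 10 * eps
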