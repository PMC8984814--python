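"""Deformation quality functional and cage metrics.

The functional scores how far a cage is from an assembly of regular,
planar, convex P-gons forming a locally convex cage:

* ``q_length``  -- sum of squared relative edge-length deviations from L_f;
* ``q_angle``   -- sum of squared corner-angle deviations (radians) from the
  regular P-gon angle pi(1 - 2/P);
* ``q_planar``  -- squared lengths of the facelet normals projected onto the
  face plane (zero iff every face is planar);
* ``q_conv_face`` -- count of face corners violating local convexity;
* ``q_conv_cage`` -- count of adjacent-face pairs bent away from the centre
  (edge-midpoint variant) or whose normal tips diverge (normal-tip variant).

Both convexity counters count *violations* so that minimization drives
them to zero, with H(0) = 0: boundary cases (straight corners, coplanar
neighbouring faces) are not penalized.  For the face counter the reversed
cross product makes the stated argument negative at convex corners, so
violations are its positive values; for the cage counter the bent-towards-
the-centre condition is positive on convex pairs, so violations are the
negative values.

The scalar metrics are the maximum deformations
``delta_l = max |l - L_f|`` and ``delta_a = max |alpha - alpha_0|/alpha_0``
and the pairwise face-dissimilarity maxima (omega_l, omega_a) computed
under the best cyclic relabeling of one face against the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WEIGHTS = dict(c_l=1.0, c_a=1.0, c_p=1000.0, c_cf=100.0, c_cp=100.0)


@dataclass(frozen=True)
class FunctionalWeights:
    c_l: float = 1.0
    c_a: float = 1.0
    c_p: float = 1000.0
    c_cf: float = 100.0
    c_cp: float = 100.0
    L_f: float = 1.0
    cage_convexity_variant: str = "edge-midpoint"   # or "normal-tip"

    def __post_init__(self):
        if min(self.c_l, self.c_a, self.c_p, self.c_cf, self.c_cp) < 0:
            raise ValueError("weights must be non-negative")
        if self.cage_convexity_variant not in ("edge-midpoint", "normal-tip"):
            raise ValueError("unknown cage convexity variant")


@dataclass
class QualityBreakdown:
    q_length: float
    q_angle: float
    q_planar: float
    q_conv_face: float
    q_conv_cage: float
    weights: FunctionalWeights

    @property
    def total(self):
        w = self.weights
        return (w.c_l * self.q_length + w.c_a * self.q_angle
                + w.c_p * self.q_planar + w.c_cf * self.q_conv_face
                + w.c_cp * self.q_conv_cage)


@dataclass
class DeformationReport:
    delta_l: float
    delta_a: float
    omega_l: float = float("nan")
    omega_a: float = float("nan")

    @property
    def max_deformation(self):
        return max(self.delta_l, self.delta_a)


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def q_length(geometry, L_f=1.0):
    l = geometry.edge_lengths()
    return float((((l - L_f) / L_f) ** 2).sum())


def q_angle(geometry):
    a0 = np.pi * (1.0 - 2.0 / geometry.topology.P)
    return float(((geometry.face_angles() - a0) ** 2).sum())


def q_planar(geometry):
    w = geometry.facelet_normals()
    What = geometry.face_unit_normals()
    proj = (w * What[:, None, :]).sum(axis=2)
    return float((w ** 2).sum() - (proj ** 2).sum())


def q_conv_face(geometry):
    """Number of face corners where the edge pair turns the wrong way.

    For an anticlockwise face seen from outside, s_i x s_{i+1} points
    outward, so the reversed product (s_{i+1} x s_i) . F_f is negative at
    convex corners (F_f being the face centre relative to the cage centre);
    corners with a positive product are reflex and counted.  H(0) = 0:
    straight corners are not penalized.
    """
    s = geometry.edge_vectors()
    F = geometry.face_centres() - geometry.cage_centre()
    x = (np.cross(np.roll(s, -1, axis=1), s) * F[:, None, :]).sum(axis=2)
    return float(np.count_nonzero(x > 0.0))


def q_conv_cage(geometry, variant="edge-midpoint"):
    topo = geometry.topology
    if variant == "edge-midpoint":
        d = geometry.midpoint_offsets()
        dhat = d / np.linalg.norm(d, axis=2, keepdims=True)
        M = geometry.edge_midpoints()
        O = geometry.cage_centre()
        n = 0
        for (f, i), (f2, i2) in topo.shared_edges:
            x = (dhat[f, i] + dhat[f2, i2]) @ (M[f, i] - O)
            if x < 0.0:
                n += 1
        return float(n)
    if variant == "normal-tip":
        C = geometry.face_centres()
        What = geometry.face_unit_normals()
        seen = set()
        n = 0
        for (f, _), (f2, _) in topo.shared_edges:
            key = (min(f, f2), max(f, f2))
            if key in seen:
                continue
            seen.add(key)
            base = np.linalg.norm(C[f] - C[f2])
            if base < 1e-14:
                raise ValueError("degenerate pair: coincident face centres")
            tip = np.linalg.norm(C[f] + What[f] - C[f2] - What[f2])
            if base - tip > 0.0:
                n += 1
        return float(n)
    raise ValueError("unknown cage convexity variant")


def total_q(geometry, weights=None):
    w = weights or FunctionalWeights()
    return QualityBreakdown(
        q_length=q_length(geometry, w.L_f),
        q_angle=q_angle(geometry),
        q_planar=q_planar(geometry),
        q_conv_face=q_conv_face(geometry),
        q_conv_cage=q_conv_cage(geometry, w.cage_convexity_variant),
        weights=w,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def deformation(geometry, L_f=1.0):
    """(delta_l, delta_a): maximum edge-length and relative angle deformation."""
    l = geometry.edge_lengths()
    a = geometry.face_angles()
    a0 = np.pi * (1.0 - 2.0 / geometry.topology.P)
    return float(np.abs(l - L_f).max()), float(np.abs(a - a0).max() / a0)


def face_similarity(geometry):
    """(omega_l, omega_a): worst pairwise face dissimilarity.

    For each unordered face pair the edge-length (and angle) sequences are
    compared under every cyclic shift delta = 1..P-1 of one face, keeping
    the smallest mean absolute difference; omega is the maximum over pairs.
    Angles are normalized by the regular angle pi(1 - 2/P).
    """
    l = geometry.edge_lengths()
    a = geometry.face_angles()
    P = geometry.topology.P
    a0 = np.pi * (1.0 - 2.0 / P)
    shifts = [np.roll(l, -d, axis=1) for d in range(1, P)]
    ashifts = [np.roll(a, -d, axis=1) for d in range(1, P)]
    N = l.shape[0]
    wl = wa = 0.0
    for f in range(N):
        for g in range(f + 1, N):
            dl = min(np.abs(l[f] - s[g]).sum() for s in shifts) / P
            da = min(np.abs(a[f] - s[g]).sum() for s in ashifts) / (P * a0)
            wl = max(wl, dl)
            wa = max(wa, da)
    return wl, wa


def deformation_report(geometry, L_f=1.0, similarity=True):
    dl, da = deformation(geometry, L_f)
    if similarity:
        wl, wa = face_similarity(geometry)
    else:
        wl = wa = float("nan")
    return DeformationReport(delta_l=dl, delta_a=da, omega_l=wl, omega_a=wa)
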