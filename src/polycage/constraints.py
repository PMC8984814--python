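"""Geometric pruning constraints on hole-edge distributions.

Two necessary conditions weed out distributions that cannot be realized as a
convex cage with face deformations below a threshold ``kappa_t``:

* an angle-sum bound: flattening the ring of sub-faces around a hole must
  open it up, so the projected corner angles around a Q-gonal hole must sum
  to at least the inner-angle sum of a planar Q-gon, which bounds P from
  above in terms of the q_i and the tolerated angle deformation;

* a polygon inequality on the hole chords: the chord subtended by a face's
  run of q_k hole edges (computed for a regular P-gon, with every angle
  uniformly stretched or contracted by the threshold factor) must not
  exceed the stretched sum of the other chords around the same hole.

Both tests are evaluated per hole of a labeling; failing either rules the
configuration out before any optimization is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: default threshold deformation factor (10% of the regular-polygon values)
DEFAULT_KAPPA = 0.1


class DegenerateHoleError(ValueError):
    pass


@dataclass(frozen=True)
class HoleSpec:
    """A hole with Q surrounding faces contributing q_i edges each."""

    Q: int
    q: tuple
    P: int
    kappa_t: float = DEFAULT_KAPPA

    def __post_init__(self):
        if self.Q < 3:
            raise DegenerateHoleError("a hole needs at least three faces")
        if len(self.q) != self.Q:
            raise ValueError("q must list one contribution per face")
        if any(qi < 1 for qi in self.q):
            raise ValueError("each face must contribute at least one edge")

    @property
    def beta0(self):
        return 2.0 * math.pi / self.P

    @property
    def alpha0(self):
        return math.pi * (1.0 - 2.0 / self.P)

    def gamma0(self, i):
        return math.pi * (self.q[i] - 1) / self.P


def angle_constraint_ok(hole):
    """Projected angle-sum bound on P for one hole.

    True iff ``P <= 2*sum(q_i+1)/(Q-2) * (1 + kappa_t*(P-2)/2)``.
    """
    bound = (2.0 * sum(qi + 1 for qi in hole.q) / (hole.Q - 2)
             * (1.0 + hole.kappa_t * (hole.P - 2) / 2.0))
    return hole.P <= bound + 1e-12


def subface_hole_edge_length(qk, P, K):
    """Chord length (in units of the face edge length) subtended by a run of
    ``qk`` hole edges of a regular P-gon whose angles are uniformly scaled
    by the factor ``K``.
    """
    if K <= 0:
        raise ValueError("angle scale factor K must be positive")
    if qk < 1 or P <= qk:
        raise ValueError("need 1 <= qk < P")
    if qk % 2 == 0:
        return 2.0 * sum(math.cos(math.pi * K * (qk - 1 - 2 * i) / P)
                         for i in range(qk // 2))
    return 1.0 + 2.0 * sum(math.cos(math.pi * K * (qk - 1 - 2 * i) / P)
                           for i in range((qk - 1) // 2))


def length_constraint_ok(hole):
    """Polygon inequality on the hole chords at threshold deformation.

    Each chord in turn is taken as the long side, contracted via
    ``K = 1/(1+kappa_t)``, and compared against the stretched remaining
    chords (``K = 1+kappa_t``) scaled by ``(1+kappa_t)/(1-kappa_t)``.
    """
    kt = hole.kappa_t
    short = [subface_hole_edge_length(qi, hole.P, 1.0 / (1.0 + kt)) for qi in hole.q]
    long_ = [subface_hole_edge_length(qi, hole.P, 1.0 + kt) for qi in hole.q]
    stretch = (1.0 + kt) / (1.0 - kt)
    total_long = sum(long_)
    for j in range(hole.Q):
        if short[j] > stretch * (total_long - long_[j]) + 1e-12:
            return False
    return True


@dataclass
class PruneReport:
    """Per-hole verdicts for a labeling."""

    name: str
    holes: list = field(default_factory=list)  # (face id, HoleSpec, angle_ok, length_ok)

    @property
    def ok(self):
        return all(a and l for _, _, a, l in self.holes)

    @property
    def length_ok(self):
        return all(l for _, _, _, l in self.holes)

    @property
    def angle_ok(self):
        return all(a for _, _, a, _ in self.holes)

    @property
    def limiting_hole(self):
        for fi, spec, a, l in self.holes:
            if not (a and l):
                return fi
        return None


def hole_specs(labeling, kappa_t=DEFAULT_KAPPA):
    """The :class:`HoleSpec` of every hole-polyhedron face of a labeling."""
    solid = labeling.solid()
    return [(fi, HoleSpec(Q=len(solid.faces[fi]), q=tuple(labeling.hole_q(fi)),
                          P=labeling.P, kappa_t=kappa_t))
            for fi in range(solid.n_faces)]


def prune_configuration(labeling, kappa_t=DEFAULT_KAPPA, use_angle=False):
    """Evaluate the pruning constraints on every hole of a labeling.

    The chord (length) inequality is always applied; the angle-sum bound is
    optional (off by default) so the survivor count can be reported for the
    chord test alone.  Returns a :class:`PruneReport`; its ``ok`` reflects
    the tests actually applied.
    """
    report = PruneReport(name=labeling.name)
    for fi, spec in hole_specs(labeling, kappa_t):
        a_ok = angle_constraint_ok(spec) if use_angle else True
        l_ok = length_constraint_ok(spec)
        report.holes.append((fi, spec, a_ok, l_ok))
    return report
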