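"""Convex uniform solids used as hole-polyhedra.

A polyhedral cage (p-cage) is an assembly of P-gonal faces separated by
holes.  Joining the centres of edge-sharing faces yields the cage's dual,
the *hole-polyhedron*: its vertices, edges and faces correspond to the
cage's faces, shared edges and holes.  For homogeneous connectivity-
invariant cages the hole-polyhedron must be a vertex-transitive convex
polyhedron, i.e. a Platonic or Archimedean solid, a uniform prism or a
uniform antiprism (Maschke's classification).  Two Archimedean solids --
the truncated cuboctahedron and the truncated icosidodecahedron -- are
vertex-transitive only through reflections and are excluded, because
cage connectivity invariance via reflections is not considered.

This module constructs every supported solid as an *oriented* combinatorial
polyhedron (faces anticlockwise seen from outside) with unit-circumsphere
coordinates, and computes its combinatorial automorphisms, split into
rotations (orientation-preserving) and reflections (orientation-reversing).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import ConvexHull

PHI = (1.0 + math.sqrt(5.0)) / 2.0

#: uniform prisms by base size (the square prism is the cube "Pcu")
PRISMS = {"tp": 3, "pp": 5, "hp": 6, "7p": 7, "8p": 8, "9p": 9, "10p": 10}
#: uniform antiprisms by base size (the triangular antiprism shares the
#: octahedron graph but keeps its own 2n-element prismatic rotation group)
ANTIPRISMS = {"ta": 3, "sa": 4, "pa": 5, "ha": 6, "7a": 7, "8a": 8, "9a": 9, "10a": 10}
PLATONIC = ("Pte", "Pcu", "Poc", "Pdo", "Pic")
ARCHIMEDEAN = ("Att", "Atc", "Ato", "Atd", "Ati", "Aco", "Aid", "Arco", "Arcd", "Asc", "Asd")

#: symbols of the two reflection-only Archimedean solids (not constructible)
REFLECTION_ONLY = {"Atco": "truncated cuboctahedron", "Atid": "truncated icosidodecahedron"}

ALL_SYMBOLS = tuple(PRISMS) + tuple(ANTIPRISMS) + PLATONIC + ARCHIMEDEAN

# expected face-size multisets, used as construction self-checks
_FACE_VECTORS = {
    "Pte": {3: 4}, "Pcu": {4: 6}, "Poc": {3: 8}, "Pdo": {5: 12}, "Pic": {3: 20},
    "Att": {3: 4, 6: 4}, "Atc": {3: 8, 8: 6}, "Ato": {4: 6, 6: 8},
    "Atd": {3: 20, 10: 12}, "Ati": {5: 12, 6: 20}, "Aco": {3: 8, 4: 6},
    "Aid": {3: 20, 5: 12}, "Arco": {3: 8, 4: 18}, "Arcd": {3: 20, 4: 30, 5: 12},
    "Asc": {3: 32, 4: 6}, "Asd": {3: 80, 5: 12},
}


class UnsupportedSolidError(ValueError):
    """Raised for symbols outside the supported table."""


class ReflectionOnlySolidError(ValueError):
    """Raised for the two solids whose vertex transitivity needs reflections."""


# ---------------------------------------------------------------------------
# coordinate generators
# ---------------------------------------------------------------------------

def _signs(template, parities=None):
    """All sign combinations of the nonzero entries of ``template``.

    ``parities`` restricts the number of minus signs modulo 2 (0=even, 1=odd).
    """
    out = []
    idx = [i for i, t in enumerate(template) if t != 0]
    for signs in itertools.product((1.0, -1.0), repeat=len(idx)):
        if parities is not None and sum(s < 0 for s in signs) % 2 != parities:
            continue
        v = list(template)
        for i, s in zip(idx, signs):
            v[i] = s * v[i]
        out.append(v)
    return out


def _cyclic(points):
    out = []
    for p in points:
        x, y, z = p
        out.extend([(x, y, z), (y, z, x), (z, x, y)])
    return out


def _dedup(points, tol=1e-9):
    uniq = []
    for p in points:
        if not any(max(abs(p[k] - q[k]) for k in range(3)) < tol for q in uniq):
            uniq.append(tuple(p))
    return np.array(uniq, dtype=float)


def _prism_coords(n):
    s = 2.0 * math.sin(math.pi / n)            # base edge for unit base circumradius
    h = s / 2.0
    pts = []
    for k in range(n):
        a = 2.0 * math.pi * k / n
        pts.append((math.cos(a), math.sin(a), h))
        pts.append((math.cos(a), math.sin(a), -h))
    return np.array(pts)


def _antiprism_coords(n):
    s2 = 4.0 * math.sin(math.pi / n) ** 2
    h2 = s2 - 4.0 * math.sin(math.pi / (2 * n)) ** 2   # uniform (equal-edge) height
    h = math.sqrt(h2) / 2.0
    pts = []
    for k in range(n):
        a = 2.0 * math.pi * k / n
        pts.append((math.cos(a), math.sin(a), h))
        b = a + math.pi / n
        pts.append((math.cos(b), math.sin(b), -h))
    return np.array(pts)


def _rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


@lru_cache(maxsize=None)
def _icosahedral_rotations():
    """The 60 rotation matrices of the standard icosahedral frame."""
    gens = [
        np.array([[0.0, 0, 1], [1, 0, 0], [0, 1, 0]]),    # coordinate 3-cycle
        np.diag([-1.0, -1.0, 1.0]),
        _rotation_matrix((0.0, 1.0, PHI), 2.0 * math.pi / 5.0),
    ]
    group = {}
    frontier = [np.eye(3)]
    while frontier:
        new = []
        for m in frontier:
            key = tuple(np.round(m, 9).ravel())
            if key in group:
                continue
            group[key] = m
            for g in gens:
                new.append(g @ m)
        frontier = new
    mats = list(group.values())
    assert len(mats) == 60
    return tuple(mats)


def _snub_cube_coords():
    t = 1.8392867552141612  # tribonacci constant, t^3 = t^2 + t + 1
    base = (1.0, 1.0 / t, t)
    pts = []
    for perm in itertools.permutations(range(3)):
        parity = 0 if perm in ((0, 1, 2), (1, 2, 0), (2, 0, 1)) else 1
        tpl = tuple(base[p] for p in perm)
        pts.extend(_signs(tpl, parities=parity))
    return _dedup(pts)


def _snub_dodecahedron_coords():
    # seed vertex from the standard construction: xi^3 - 2 xi = phi
    xi = np.roots([1.0, 0.0, -2.0, -PHI])
    xi = float(np.real(xi[np.isreal(xi) & (np.real(xi) > 0)][0]))
    alpha = xi - 1.0 / xi
    beta = xi * PHI + PHI ** 2 + PHI / xi
    seed = np.array([2.0 * alpha, 2.0, 2.0 * beta])
    pts = [m @ seed for m in _icosahedral_rotations()]
    return _dedup(pts)


def _coordinates(symbol):
    if symbol in PRISMS:
        return _prism_coords(PRISMS[symbol])
    if symbol in ANTIPRISMS:
        return _antiprism_coords(ANTIPRISMS[symbol])
    f = PHI
    if symbol == "Pte":
        return np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float)
    if symbol == "Pcu":
        return _dedup(_signs((1.0, 1.0, 1.0)))
    if symbol == "Poc":
        return _dedup(_cyclic(_signs((1.0, 0.0, 0.0))))
    if symbol == "Pdo":
        return _dedup(_signs((1.0, 1.0, 1.0)) + _cyclic(_signs((0.0, 1.0 / f, f))))
    if symbol == "Pic":
        return _dedup(_cyclic(_signs((0.0, 1.0, f))))
    if symbol == "Att":
        pts = []
        for perm in itertools.permutations((1.0, 1.0, 3.0)):
            pts.extend(_signs(perm, parities=0))
        return _dedup(pts)
    if symbol == "Atc":
        x = math.sqrt(2.0) - 1.0
        pts = []
        for perm in set(itertools.permutations((x, 1.0, 1.0))):
            pts.extend(_signs(perm))
        return _dedup(pts)
    if symbol == "Ato":
        pts = []
        for perm in set(itertools.permutations((0.0, 1.0, 2.0))):
            pts.extend(_signs(perm))
        return _dedup(pts)
    if symbol == "Atd":
        return _dedup(_cyclic(
            _signs((0.0, 1.0 / f, 2.0 + f)) + _signs((1.0 / f, f, 2.0 * f))
            + _signs((f, 2.0, f + 1.0))))
    if symbol == "Ati":
        return _dedup(_cyclic(
            _signs((0.0, 1.0, 3.0 * f)) + _signs((1.0, 2.0 + f, 2.0 * f))
            + _signs((f, 2.0, 2.0 * f + 1.0))))
    if symbol == "Aco":
        pts = []
        for perm in set(itertools.permutations((0.0, 1.0, 1.0))):
            pts.extend(_signs(perm))
        return _dedup(pts)
    if symbol == "Aid":
        return _dedup(_cyclic(_signs((0.0, 0.0, f))
                              + _signs((0.5, f / 2.0, f ** 2 / 2.0))))
    if symbol == "Arco":
        pts = []
        for perm in set(itertools.permutations((1.0, 1.0, 1.0 + math.sqrt(2.0)))):
            pts.extend(_signs(perm))
        return _dedup(pts)
    if symbol == "Arcd":
        return _dedup(_cyclic(
            _signs((1.0, 1.0, f ** 3)) + _signs((f ** 2, f, 2.0 * f))
            + _signs((2.0 + f, 0.0, f ** 2))))
    if symbol == "Asc":
        return _snub_cube_coords()
    if symbol == "Asd":
        return _snub_dodecahedron_coords()
    raise UnsupportedSolidError(f"unsupported solid symbol: {symbol!r}")


# ---------------------------------------------------------------------------
# combinatorial structure
# ---------------------------------------------------------------------------

def _faces_from_hull(vertices):
    """Faces of the convex hull as vertex cycles, anticlockwise from outside."""
    hull = ConvexHull(vertices)
    groups = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq, 6))
        groups.setdefault(key, [set(), None])[0].update(simplex)
        groups[key][1] = eq
    # merge keys describing the same plane but differing by rounding jitter
    merged = {}
    for key, (vs, eq) in groups.items():
        placed = False
        for mk in list(merged):
            if np.allclose(np.array(mk), np.array(key), atol=1e-5):
                merged[mk][0].update(vs)
                placed = True
                break
        if not placed:
            merged[key] = [set(vs), eq]
    faces = []
    for vs, eq in merged.values():
        normal = eq[:3] / np.linalg.norm(eq[:3])
        ids = sorted(vs)
        pts = vertices[ids]
        centre = pts.mean(axis=0)
        # in-plane basis with e1 x e2 = outward normal
        e1 = pts[0] - centre
        e1 = e1 - np.dot(e1, normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        ang = np.arctan2((pts - centre) @ e2, (pts - centre) @ e1)
        order = np.argsort(ang)
        faces.append(tuple(ids[k] for k in order))
    return faces


def _vertex_cycles(vertices, faces):
    """For each vertex, incident faces and neighbours anticlockwise from outside."""
    nv = len(vertices)
    incident = [[] for _ in range(nv)]
    for fi, face in enumerate(faces):
        for v in face:
            incident[v].append(fi)
    neighbour_cycles = []
    face_cycles = []
    for v in range(nv):
        out = vertices[v] / np.linalg.norm(vertices[v])
        nbrs = set()
        for fi in incident[v]:
            face = faces[fi]
            k = face.index(v)
            nbrs.add(face[(k + 1) % len(face)])
            nbrs.add(face[(k - 1) % len(face)])
        nbrs = sorted(nbrs)
        e1 = vertices[nbrs[0]] - vertices[v]
        e1 = e1 - np.dot(e1, out) * out
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(out, e1)
        def angle_of(p):
            d = p - vertices[v]
            return math.atan2(np.dot(d, e2), np.dot(d, e1))
        nbrs_sorted = sorted(nbrs, key=lambda u: angle_of(vertices[u]))
        neighbour_cycles.append(tuple(nbrs_sorted))
        # faces ordered anticlockwise too (by centroid angle)
        fcs = sorted(incident[v],
                     key=lambda fi: angle_of(vertices[list(faces[fi])].mean(axis=0)))
        face_cycles.append(tuple(fcs))
    return neighbour_cycles, face_cycles


@dataclass(frozen=True)
class HolePolyhedron:
    """Oriented combinatorial model of a uniform solid.

    Faces are vertex cycles anticlockwise seen from outside; ``vertex_cycles``
    lists the faces around each vertex, also anticlockwise from outside.
    Darts (directed edges) carry the orientation bookkeeping: dart ``(v, u)``
    belongs to the unique face in which ``u`` follows ``v``, and the pair
    ``(v, face)`` -- a *corner* -- is in bijection with the darts out of ``v``.
    """

    symbol: str
    vertices: np.ndarray                 # (V, 3), unit circumsphere
    faces: tuple                         # tuples of vertex ids, ccw from outside
    vertex_cycles: tuple                 # per vertex: incident face ids, ccw
    neighbour_cycles: tuple              # per vertex: neighbour vertex ids, ccw
    base_faces: tuple = ()               # the two base faces of a (anti)prism

    # --- dart machinery (filled in __post_init__) ---
    darts: tuple = field(default=None, repr=False)
    dart_index: dict = field(default=None, repr=False)
    dart_face: np.ndarray = field(default=None, repr=False)
    sigma: np.ndarray = field(default=None, repr=False)   # ccw rotation at tail
    alpha: np.ndarray = field(default=None, repr=False)   # reversal
    corner_lookup: dict = field(default=None, repr=False)  # (vertex, face) -> dart

    def __post_init__(self):
        darts = []
        dart_face = []
        for fi, face in enumerate(self.faces):
            n = len(face)
            for k in range(n):
                darts.append((face[k], face[(k + 1) % n]))
                dart_face.append(fi)
        index = {d: i for i, d in enumerate(darts)}
        nd = len(darts)
        alpha = np.empty(nd, dtype=int)
        sigma = np.empty(nd, dtype=int)
        for i, (u, v) in enumerate(darts):
            alpha[i] = index[(v, u)]
            cyc = self.neighbour_cycles[u]
            j = cyc.index(v)
            sigma[i] = index[(u, cyc[(j + 1) % len(cyc)])]
        corner_lookup = {(darts[i][0], dart_face[i]): i for i in range(nd)}
        object.__setattr__(self, "darts", tuple(darts))
        object.__setattr__(self, "dart_index", index)
        object.__setattr__(self, "dart_face", np.array(dart_face))
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "corner_lookup", corner_lookup)

    # ------------------------------------------------------------------
    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_faces(self):
        return len(self.faces)

    @property
    def edges(self):
        return tuple(sorted({tuple(sorted(d)) for d in self.darts}))

    @property
    def n_edges(self):
        return len(self.darts) // 2

    @property
    def Eh(self):
        degs = {len(c) for c in self.neighbour_cycles}
        assert len(degs) == 1
        return degs.pop()

    def corners_of_vertex(self, v):
        """Out-dart ids of ``v`` in anticlockwise order (corner ids)."""
        cyc = self.neighbour_cycles[v]
        return [self.dart_index[(v, u)] for u in cyc]

    def corner_face(self, dart_id):
        return int(self.dart_face[dart_id])

    def corners_of_face(self, fi):
        """Corner (dart) ids of face ``fi`` in face cyclic order."""
        face = self.faces[fi]
        n = len(face)
        return [self.dart_index[(face[k], face[(k + 1) % n])] for k in range(n)]

    def face_sizes(self):
        sizes = {}
        for f in self.faces:
            sizes[len(f)] = sizes.get(len(f), 0) + 1
        return sizes

    def export_off(self, path):
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.n_vertices} {self.n_faces} {self.n_edges}\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.15g} {v[1]:.15g} {v[2]:.15g}\n")
            for face in self.faces:
                fh.write(" ".join([str(len(face))] + [str(v) for v in face]) + "\n")


# ---------------------------------------------------------------------------
# automorphisms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Automorphism:
    """Combinatorial automorphism, acting on vertices, faces and corners.

    ``corner_perm`` sends the corner (v, f), indexed by its out-dart, to the
    corner (g(v), g(f)).  For orientation-preserving elements it coincides
    with ``dart_perm``; for reversing ones the image dart of a corner's dart
    lies in the neighbouring face, so the two permutations differ.
    """

    vertex_perm: tuple
    face_perm: tuple
    dart_perm: tuple
    corner_perm: tuple
    reverses_orientation: bool

    def __mul__(self, other):
        vp = tuple(self.vertex_perm[i] for i in other.vertex_perm)
        fp = tuple(self.face_perm[i] for i in other.face_perm)
        dp = tuple(self.dart_perm[i] for i in other.dart_perm)
        cp = tuple(self.corner_perm[i] for i in other.corner_perm)
        return Automorphism(vp, fp, dp, cp,
                           self.reverses_orientation != other.reverses_orientation)


@dataclass(frozen=True)
class RotationGroup:
    """A group of combinatorial automorphisms of a hole-polyhedron."""

    solid_symbol: str
    elements: tuple

    @property
    def order(self):
        return len(self.elements)

    def rotations(self):
        return [g for g in self.elements if not g.reverses_orientation]

    def is_vertex_transitive(self, n_vertices):
        orbit = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for g in self.elements:
                w = g.vertex_perm[v]
                if w not in orbit:
                    orbit.add(w)
                    frontier.append(w)
        return len(orbit) == n_vertices


def _propagate(solid, d0_image, reverse):
    nd = len(solid.darts)
    sigma, al = solid.sigma, solid.alpha
    sigma_inv = np.empty(nd, dtype=int)
    sigma_inv[sigma] = np.arange(nd)
    phi = np.full(nd, -1, dtype=int)
    phi[0] = d0_image
    stack = [0]
    img_sigma = sigma_inv if reverse else sigma
    while stack:
        x = stack.pop()
        for gen, img in ((sigma, img_sigma), (al, al)):
            y = gen[x]
            target = img[phi[x]]
            if phi[y] == -1:
                phi[y] = target
                stack.append(y)
            elif phi[y] != target:
                return None
    if len(set(phi.tolist())) != nd:
        return None
    # induced vertex and face permutations must be well defined
    vperm = [-1] * solid.n_vertices
    fperm = [-1] * solid.n_faces
    for i in range(nd):
        u = solid.darts[i][0]
        iu = solid.darts[phi[i]][0]
        if vperm[u] == -1:
            vperm[u] = iu
        elif vperm[u] != iu:
            return None
        f = solid.dart_face[i]
        imf = solid.dart_face[phi[i]] if not reverse else solid.dart_face[solid.alpha[phi[i]]]
        if fperm[f] == -1:
            fperm[f] = imf
        elif fperm[f] != imf:
            return None
    cperm = tuple(
        solid.corner_lookup[(vperm[solid.darts[i][0]], fperm[solid.dart_face[i]])]
        for i in range(nd))
    return Automorphism(tuple(vperm), tuple(fperm), tuple(phi.tolist()), cperm, reverse)


def _all_automorphisms(solid, include_reflections):
    out = []
    base_set = set(solid.base_faces)
    for reverse in ((False, True) if include_reflections else (False,)):
        for d in range(len(solid.darts)):
            g = _propagate(solid, d, reverse)
            if g is None:
                continue
            if base_set and {g.face_perm[f] for f in base_set} != base_set:
                continue   # prismatic symbols keep their designated base pair
            out.append(g)
    return out


@lru_cache(maxsize=None)
def build_solid(symbol):
    """Construct the hole-polyhedron for a Table-style solid symbol.

    Raises :class:`ReflectionOnlySolidError` for the truncated cuboctahedron
    and truncated icosidodecahedron, and :class:`UnsupportedSolidError`
    otherwise for unknown symbols.
    """
    if symbol in REFLECTION_ONLY:
        raise ReflectionOnlySolidError(
            f"{REFLECTION_ONLY[symbol]} is vertex transitive only via reflections")
    if symbol not in ALL_SYMBOLS:
        raise UnsupportedSolidError(f"unsupported solid symbol: {symbol!r}")
    coords = _coordinates(symbol)
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    faces = _faces_from_hull(coords)
    neighbour_cycles, face_cycles = _vertex_cycles(coords, faces)
    base = ()
    if symbol in PRISMS or symbol in ANTIPRISMS:
        zs = [np.ptp(coords[list(f)][:, 2]) for f in faces]
        flat = [fi for fi, dz in enumerate(zs) if dz < 1e-9]
        assert len(flat) == 2, "prismatic solid must have two horizontal bases"
        base = tuple(flat)
    solid = HolePolyhedron(symbol=symbol, vertices=coords, faces=tuple(faces),
                           vertex_cycles=tuple(face_cycles),
                           neighbour_cycles=tuple(neighbour_cycles),
                           base_faces=base)
    _validate(solid)
    return solid


def _validate(solid):
    V, E, F = solid.n_vertices, solid.n_edges, solid.n_faces
    if V - E + F != 2:
        raise AssertionError(f"{solid.symbol}: Euler relation violated")
    expected = _FACE_VECTORS.get(solid.symbol)
    if solid.symbol in PRISMS:
        n = PRISMS[solid.symbol]
        expected = {n: 2, 4: n} if n != 4 else {4: 6}
    elif solid.symbol in ANTIPRISMS:
        n = ANTIPRISMS[solid.symbol]
        expected = {n: 2 + (2 * n if n == 3 else 0)} if n == 3 else {n: 2, 3: 2 * n}
    if expected is not None and solid.face_sizes() != expected:
        raise AssertionError(
            f"{solid.symbol}: face sizes {solid.face_sizes()} != {expected}")


@lru_cache(maxsize=None)
def rotation_group(symbol):
    """Orientation-preserving combinatorial automorphism group.

    For prisms and antiprisms the group is restricted to automorphisms
    preserving the designated pair of base faces, which yields the 2n-element
    prismatic rotation group even when the abstract polyhedron has more
    symmetry (the triangular antiprism / octahedron graph).
    """
    solid = build_solid(symbol)
    els = _all_automorphisms(solid, include_reflections=False)
    group = RotationGroup(symbol, tuple(els))
    if not group.is_vertex_transitive(solid.n_vertices):
        raise AssertionError(f"{symbol}: rotation group not vertex transitive")
    return group


@lru_cache(maxsize=None)
def full_automorphisms(symbol):
    """All combinatorial automorphisms, orientation-reversing ones flagged."""
    solid = build_solid(symbol)
    els = _all_automorphisms(solid, include_reflections=True)
    return RotationGroup(symbol, tuple(els))
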