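"""Connectivity-invariant distributions of hole edges over face corners.

A homogeneous p-cage with P-gonal faces is encoded on its hole-polyhedron by
assigning to every corner (vertex, incident face) a positive integer a_i:
the number of edges the cage face sitting on that vertex contributes to the
hole sitting on that face.  At every vertex the counts must satisfy

    P = Eh + sum_i a_i,

Eh being the vertex degree.  The assembly is *connectivity invariant* when
the subgroup of (orientation-preserving) automorphisms preserving the
assignment acts transitively on the vertices: every face of the cage can
then be mapped onto every other while preserving shared and hole edges.

Enumeration exploits the equivalent characterization: an assignment is
connectivity invariant iff it is constant on the corner orbits of some
vertex-transitive subgroup H of the rotation group.  Enumerating the
vertex-transitive subgroups and the positive assignments on their corner
orbits therefore yields every valid distribution without searching the full
composition space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .solids import (
    ANTIPRISMS,
    PLATONIC,
    PRISMS,
    build_solid,
    full_automorphisms,
    rotation_group,
)


class InvalidLabelingError(ValueError):
    pass


@dataclass(frozen=True)
class CornerLabeling:
    """Assignment of hole-edge counts to every corner of a hole-polyhedron.

    ``labels`` is indexed by corner id (the dart out of the vertex along the
    face; see :class:`polycage.solids.HolePolyhedron`).
    """

    solid_symbol: str
    P: int
    labels: tuple

    @property
    def name(self):
        return canonical_name(self)

    def solid(self):
        return build_solid(self.solid_symbol)

    def vertex_labels(self, v):
        """Corner values around vertex ``v``, anticlockwise."""
        solid = self.solid()
        return [self.labels[c] for c in solid.corners_of_vertex(v)]

    def hole_q(self, fi):
        """Edge contributions q_i around hole ``fi`` (a solid face), in order."""
        solid = self.solid()
        return [self.labels[c] for c in solid.corners_of_face(fi)]

    def validate(self):
        solid = self.solid()
        if len(self.labels) != len(solid.darts):
            raise InvalidLabelingError("labeling must cover every corner")
        if any(a < 1 for a in self.labels):
            raise InvalidLabelingError("corner labels must be >= 1")
        need = self.P - solid.Eh
        for v in range(solid.n_vertices):
            if sum(self.vertex_labels(v)) != need:
                raise InvalidLabelingError(
                    f"vertex {v}: labels must sum to P - Eh = {need}")


# ---------------------------------------------------------------------------
# connectivity invariance
# ---------------------------------------------------------------------------

def _apply(labels, g):
    """Labels pushed forward through automorphism ``g``."""
    out = [0] * len(labels)
    for d, a in enumerate(labels):
        out[g.corner_perm[d]] = a
    return tuple(out)


def is_connectivity_invariant(labeling, group=None):
    """True iff the label-preserving subgroup is transitive on vertices."""
    labeling.validate()
    if group is None:
        group = rotation_group(labeling.solid_symbol)
    solid = labeling.solid()
    stab = [g for g in group.elements if _apply(labeling.labels, g) == labeling.labels]
    seen = {0}
    for g in stab:
        seen.add(g.vertex_perm[0])
    # the stabilizer is a group, so the orbit of vertex 0 is its image set
    return len(seen) == solid.n_vertices


# ---------------------------------------------------------------------------
# subgroup enumeration
# ---------------------------------------------------------------------------

def _closure_table(table, gens):
    """Subgroup generated by ``gens``, elements as indices into a mult table."""
    group = set(gens) | {0}
    frontier = list(group)
    while frontier:
        g = frontier.pop()
        row = table[g]
        for h in list(group):
            for prod in (row[h], table[h][g]):
                if prod not in group:
                    group.add(prod)
                    frontier.append(prod)
    return frozenset(group)


@lru_cache(maxsize=None)
def _vertex_transitive_subgroups(symbol):
    """Minimal vertex-transitive subgroups of the rotation group.

    Returns, per subgroup, the partition of corners into orbits.  Only
    minimal transitive subgroups matter: a bigger group's orbit partition is
    coarser, so its constant assignments are a subset of the smaller
    group's.  When the rotation group acts regularly (|G| equals the vertex
    count, true for most supported solids) the whole group is the only
    transitive subgroup and no lattice search is needed.
    """
    solid = build_solid(symbol)
    group = rotation_group(symbol)
    els = list(group.elements)
    # element 0 must be the identity for _closure_table
    ident = tuple(range(len(solid.darts)))
    els.sort(key=lambda g: g.dart_perm != ident)
    nv = solid.n_vertices
    n = len(els)
    if n == nv:     # regular action: the only transitive subgroup is G itself
        transitive = [frozenset(range(n))]
    else:
        index = {g.dart_perm: i for i, g in enumerate(els)}
        table = [[index[tuple(a.dart_perm[k] for k in b.dart_perm)] for b in els]
                 for a in els]
        subgroups = {frozenset([0])}
        transitive = []
        frontier = [frozenset([0])]
        while frontier:
            s = frontier.pop()
            for g in range(1, n):
                if g in s:
                    continue
                t = _closure_table(table, set(s) | {g})
                if t in subgroups:
                    continue
                subgroups.add(t)
                if len({els[i].vertex_perm[0] for i in t}) == nv:
                    transitive.append(t)
                else:
                    # minimal transitive subgroups are reached through chains
                    # of non-transitive ones, so transitive sets need no growth
                    frontier.append(t)
    minimal = [s for s in transitive
               if not any(t < s for t in transitive if t is not s)]
    out = []
    for s in minimal:
        perms = [els[i].corner_perm for i in s]
        out.append(_corner_orbits(len(solid.darts), perms))
    return tuple(out)


def _corner_orbits(nd, perms):
    orbit_of = [-1] * nd
    nxt = 0
    for d in range(nd):
        if orbit_of[d] != -1:
            continue
        stack = [d]
        orbit_of[d] = nxt
        while stack:
            x = stack.pop()
            for p in perms:
                y = p[x]
                if orbit_of[y] == -1:
                    orbit_of[y] = nxt
                    stack.append(y)
        nxt += 1
    return tuple(orbit_of)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _compositions(weights, total):
    """Positive integer solutions x of sum(w_j x_j) = total."""
    if total < sum(weights):
        return
    if len(weights) == 1:
        w = weights[0]
        if total % w == 0 and total // w >= 1:
            yield (total // w,)
        return
    w = weights[0]
    rest = weights[1:]
    x = 1
    while w * x + sum(rest) <= total:
        for tail in _compositions(rest, total - w * x):
            yield (x,) + tail
        x += 1


def enumerate_distributions(symbol, P):
    """All connectivity-invariant corner labelings for a solid and face size P.

    The result is complete and duplicate free (labelings reachable from
    several transitive subgroups are merged by exact corner equality); chiral
    twins are *not* merged here -- see :func:`dedup_chiral`.
    """
    solid = build_solid(symbol)
    Eh = solid.Eh
    if P <= Eh:
        return []
    rem = P - Eh
    found = {}
    corners0 = solid.corners_of_vertex(0)
    for orbit_of in _vertex_transitive_subgroups(symbol):
        classes = []
        for c in corners0:
            o = orbit_of[c]
            if o not in classes:
                classes.append(o)
        weights = [sum(1 for c in corners0 if orbit_of[c] == o) for o in classes]
        for xs in _compositions(weights, rem):
            value = dict(zip(classes, xs))
            labels = tuple(value[orbit_of[d]] for d in range(len(orbit_of)))
            if labels not in found:
                found[labels] = CornerLabeling(symbol, P, labels)
    return sorted(found.values(), key=lambda l: l.labels)


# ---------------------------------------------------------------------------
# naming and deduplication
# ---------------------------------------------------------------------------

def _designated_faces(solid):
    """Faces that may carry the label 'a' at a vertex.

    Base polygon for prisms and antiprisms; smallest face for Archimedean
    solids except the snub cube (square) and snub dodecahedron (pentagon);
    any face for the Platonic solids.
    """
    sym = solid.symbol
    if sym in PRISMS or sym in ANTIPRISMS:
        return set(solid.base_faces)
    if sym in PLATONIC:
        return set(range(solid.n_faces))
    if sym == "Asc":
        want = 4
    elif sym == "Asd":
        want = 5
    else:
        want = min(len(f) for f in solid.faces)
    return {fi for fi, f in enumerate(solid.faces) if len(f) == want}


def canonical_name(labeling):
    """Canonical ``SYM_P<P>_a_b_...`` name of a labeling.

    The label sequence is read anticlockwise around a vertex starting from a
    corner on a designated face; among all admissible starting corners the
    lexicographically smallest sequence is used.
    """
    solid = labeling.solid()
    allowed = _designated_faces(solid)
    best = None
    for v in range(solid.n_vertices):
        cs = solid.corners_of_vertex(v)
        k = len(cs)
        for i, c in enumerate(cs):
            if solid.corner_face(c) not in allowed:
                continue
            seq = tuple(labeling.labels[cs[(i + j) % k]] for j in range(k))
            if best is None or seq < best:
                best = seq
    assert best is not None
    sym = labeling.solid_symbol
    if sym == "Poc":
        sym = _octahedron_family(labeling)
    return f"{sym}_P{labeling.P}_" + "_".join(map(str, best))


def _octahedron_family(labeling):
    """The two octahedron diagram families.

    ``Poc2``: every face monochrome, adjacent faces alternating between two
    values; ``Poc1``: one opposite pair of monochrome faces, the remaining
    labels distributed around them (the all-equal labeling is filed under
    ``Poc1``).
    """
    solid = labeling.solid()
    per_face = [set(labeling.hole_q(fi)) for fi in range(solid.n_faces)]
    if all(len(s) == 1 for s in per_face) and \
            len({next(iter(s)) for s in per_face}) > 1:
        return "Poc2"
    return "Poc1"


def named_distributions(symbol, P):
    """Canonically named, symmetry-deduplicated labelings, name -> labeling.

    Distinct configurations that happen to read identically at a vertex
    (possible on the cube, where the distinguished monochrome face pair is
    not recoverable from a single vertex) receive a ``_v2``, ``_v3`` ...
    suffix so catalog names stay unique per (symbol, P).
    """
    labs = dedup_symmetry(enumerate_distributions(symbol, P))
    out = {}
    for lab in sorted(labs, key=lambda l: (canonical_name(l), l.labels)):
        base = canonical_name(lab)
        name, k = base, 1
        while name in out:
            k += 1
            name = f"{base}_v{k}"
        out[name] = lab
    return out


def labeling_from_name(name):
    """Parse ``SYM_P<P>_a_b_...`` back into a labeling (inverse of naming)."""
    parts = name.split("_")
    symbol = parts[0]
    if symbol in ("Poc1", "Poc2"):
        symbol = "Poc"
    P = int(parts[1][1:])
    for nm, lab in named_distributions(symbol, P).items():
        if nm == name:
            return lab
    raise InvalidLabelingError(f"no connectivity-invariant labeling named {name}")


def dedup_symmetry(labelings, chiral=True):
    """One representative per orbit under the full automorphism group.

    Rotated copies of the same diagram are always merged; with ``chiral``
    (the default) mirror-image diagrams are merged as well, keeping the
    lexicographically smallest canonical name.  On chiral solids (snub cube,
    snub dodecahedron) there are no orientation-reversing automorphisms and
    mirror twins never co-occur in the enumeration.
    """
    if not labelings:
        return []
    symbol = labelings[0].solid_symbol
    group = full_automorphisms(symbol)
    els = [g for g in group.elements if chiral or not g.reverses_orientation]
    pool = {l.labels: l for l in labelings}
    out = []
    seen = set()
    for lab in sorted(pool.values(), key=lambda l: (canonical_name(l), l.labels)):
        if lab.labels in seen:
            continue
        orbit = {_apply(lab.labels, g) for g in els}
        seen.update(orbit)
        out.append(lab)
    return out


def dedup_chiral(labelings):
    """Merge chiral twins (and rotated copies) of labelings."""
    return dedup_symmetry(labelings, chiral=True)


# ---------------------------------------------------------------------------
# diagram-level enumeration
# ---------------------------------------------------------------------------

def _partition_key(orbit_of):
    blocks = {}
    for c, o in enumerate(orbit_of):
        blocks.setdefault(o, []).append(c)
    return frozenset(frozenset(v) for v in blocks.values())


def _map_partition(key, g):
    return frozenset(frozenset(g.corner_perm[c] for c in blk) for blk in key)


@lru_cache(maxsize=None)
def _diagram_families(symbol):
    """One label diagram per conjugacy class of minimal transitive subgroups.

    Each family is returned as (slot classes at vertex 0, slot weights,
    mirror slot involution or None).  Conjugate subgroups describe the same
    printed diagram looked at through a rotated solid, so only one
    representative per class is kept; the mirror involution is the slot
    permutation induced by one orientation-reversing automorphism that
    preserves the family's corner partition (None on chiral solids).
    """
    solid = build_solid(symbol)
    fg = full_automorphisms(symbol)
    fams = _vertex_transitive_subgroups(symbol)
    keys = [_partition_key(f) for f in fams]
    reps, used = [], set()
    for i, k in enumerate(keys):
        if i in used:
            continue
        reps.append(fams[i])
        for j in range(i + 1, len(keys)):
            if j not in used and any(_map_partition(k, g) == keys[j]
                                     for g in fg.elements):
                used.add(j)
    corners0 = solid.corners_of_vertex(0)
    out = []
    for orbit_of in reps:
        classes = []
        for c in corners0:
            if orbit_of[c] not in classes:
                classes.append(orbit_of[c])
        weights = tuple(sum(1 for c in corners0 if orbit_of[c] == o)
                        for o in classes)
        key = _partition_key(orbit_of)
        tau = None
        for g in fg.elements:
            if g.reverses_orientation and _map_partition(key, g) == key:
                tau = tuple(
                    classes.index(orbit_of[g.corner_perm[next(
                        c for c in range(len(orbit_of)) if orbit_of[c] == o)]])
                    for o in classes)
                break
        out.append((orbit_of, classes, weights, tau))
    return tuple(out)


def diagram_assignments(symbol, P):
    """Labelings enumerated the way the printed diagrams are filled in.

    One value assignment per diagram slot, with mirror-image assignments
    merged (one kept per chiral pair).  Unlike :func:`named_distributions`
    this does *not* merge assignments related by a rotation that happens to
    permute the slots of a single diagram (possible on the tetrahedron and
    the cuboctahedron), and the all-equal octahedron labeling appears once
    per diagram family; it reproduces the cage-census counting convention
    of the source catalogue.
    """
    solid = build_solid(symbol)
    Eh = solid.Eh
    if P <= Eh:
        return []
    out = []
    for orbit_of, classes, weights, tau in _diagram_families(symbol):
        seen = set()
        for xs in _compositions(list(weights), P - Eh):
            if xs in seen:
                continue
            if tau is not None:
                inv = tuple(xs[tau.index(j)] for j in range(len(xs)))
                seen.add(inv)
            seen.add(xs)
            value = dict(zip(classes, xs))
            labels = tuple(value[orbit_of[d]] for d in range(len(orbit_of)))
            out.append(CornerLabeling(symbol, P, labels))
    return out
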