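"""Enumeration of connectivity-invariant hole-edge distributions."""

import itertools

import pytest

from polycage.labelings import (
    CornerLabeling,
    InvalidLabelingError,
    canonical_name,
    dedup_chiral,
    diagram_assignments,
    enumerate_distributions,
    is_connectivity_invariant,
    labeling_from_name,
    named_distributions,
)
from polycage.solids import build_solid, rotation_group


def compositions(total, k):
    if k == 1:
        if total >= 1:
            yield (total,)
        return
    for x in range(1, total - k + 2):
        for rest in compositions(total - x, k - 1):
            yield (x,) + rest


def brute_force(symbol, P):
    """Independent oracle: filter ALL per-vertex composition combinations
    through the connectivity-invariance test."""
    solid = build_solid(symbol)
    group = rotation_group(symbol)
    Eh = solid.Eh
    if P <= Eh:
        return set()
    pervert = [solid.corners_of_vertex(v) for v in range(solid.n_vertices)]
    comps = list(compositions(P - Eh, Eh))
    out = set()
    for combo in itertools.product(comps, repeat=solid.n_vertices):
        labels = [0] * len(solid.darts)
        for v, cvals in enumerate(combo):
            for c, a in zip(pervert[v], cvals):
                labels[c] = a
        lab = CornerLabeling(symbol, P, tuple(labels))
        if is_connectivity_invariant(lab, group):
            out.add(lab.labels)
    return out


@pytest.mark.parametrize("symbol,P", [
    ("Pte", 7), ("Pte", 8), ("Pte", 10),
    ("tp", 7), ("tp", 8),
    ("Pcu", 7), ("Poc", 9), ("ta", 9),
])
def test_enumeration_equals_brute_force(symbol, P):
    expected = brute_force(symbol, P)
    got = {l.labels for l in enumerate_distributions(symbol, P)}
    assert got == expected


@pytest.mark.parametrize("symbol,P", [("Pte", 9), ("tp", 9), ("Poc", 10)])
def test_enumerated_labelings_are_connectivity_invariant(symbol, P):
    for lab in enumerate_distributions(symbol, P):
        assert is_connectivity_invariant(lab)


def test_dodecahedron_single_distribution():
    named = named_distributions("Pdo", 9)
    assert list(named) == ["Pdo_P9_2_2_2"]
    assert enumerate_distributions("Pdo", 10) == []


def test_icosahedron_all_ones():
    names = set(named_distributions("Pic", 10))
    assert "Pic_P10_1_1_1_1_1" in names


def test_snub_cube_trap_distribution():
    named = named_distributions("Asc", 11)
    assert "Asc_P11_2_1_1_1_1" in named
    # the leading label sits on the square by convention
    lab = named["Asc_P11_2_1_1_1_1"]
    solid = lab.solid()
    for v in range(solid.n_vertices):
        for c in solid.corners_of_vertex(v):
            size = len(solid.faces[solid.corner_face(c)])
            assert lab.labels[c] == (2 if size == 4 else 1)


def test_p_not_above_eh_gives_empty():
    assert enumerate_distributions("Pic", 5) == []
    assert enumerate_distributions("Pic", 4) == []


def test_connectivity_invariance_examples_on_tetrahedron():
    """All-equal corners and orbit-consistent distinct corners pass; breaking
    the orbit structure at one vertex destroys the invariance."""
    solid = build_solid("Pte")
    group = rotation_group("Pte")
    P = 9
    all_equal = CornerLabeling("Pte", P, tuple([2] * len(solid.darts)))
    assert is_connectivity_invariant(all_equal, group)
    distinct = next(l for l in enumerate_distributions("Pte", P)
                    if sorted(set(l.labels)) == [1, 2, 3])
    assert is_connectivity_invariant(distinct, group)
    # swap two different labels at one vertex only -> no longer invariant
    labels = list(distinct.labels)
    c0, c1, c2 = solid.corners_of_vertex(0)
    labels[c0], labels[c1] = labels[c1], labels[c0]
    broken = CornerLabeling("Pte", P, tuple(labels))
    assert not is_connectivity_invariant(broken, group)


def test_octahedron_two_diagram_families():
    # at P=12 both families are populated: Poc1 (opposite pair of all-equal
    # faces) and Poc2 (two alternating monochrome values)
    names = set(named_distributions("Poc", 12))
    assert any(n.startswith("Poc1_") for n in names)
    assert any(n.startswith("Poc2_") for n in names)
    lab = labeling_from_name("Poc2_P12_1_3_1_3")
    solid = lab.solid()
    per_face = [set(lab.hole_q(f)) for f in range(solid.n_faces)]
    assert all(len(s) == 1 for s in per_face)
    values = sorted(next(iter(s)) for s in per_face)
    assert values == [1] * 4 + [3] * 4


def test_icosidodecahedron_forces_alternating_pattern():
    # triangles all take one value, pentagons the other
    for name, lab in named_distributions("Aid", 12).items():
        solid = lab.solid()
        for f in range(solid.n_faces):
            assert len(set(lab.hole_q(f))) == 1


def test_cube_square_corner_rule():
    # Eh=3 squares: all corners equal, or diagonal pairs equal
    for name, lab in named_distributions("Pcu", 10).items():
        solid = lab.solid()
        for f in range(solid.n_faces):
            q = lab.hole_q(f)
            assert q[0] == q[2] and q[1] == q[3]


def test_vertex_sum_rule():
    for sym, P in (("Asc", 11), ("7p", 10)):
        solid = build_solid(sym)
        for lab in enumerate_distributions(sym, P):
            for v in range(solid.n_vertices):
                assert solid.Eh + sum(lab.vertex_labels(v)) == P


def test_invalid_labelings_rejected():
    solid = build_solid("Pte")
    nd = len(solid.darts)
    with pytest.raises(InvalidLabelingError):
        CornerLabeling("Pte", 9, tuple([0] * nd)).validate()
    with pytest.raises(InvalidLabelingError):
        CornerLabeling("Pte", 9, tuple([1] * nd)).validate()  # wrong sum


def test_chiral_dedup_merges_mirror_pairs():
    labs = enumerate_distributions("Pte", 9)       # contains 1-2-3 and 1-3-2
    dd = dedup_chiral(labs)
    assert len(dd) < len(labs)
    # all-equal labeling is achiral and always retained
    assert any(set(l.labels) == {2} for l in dd)
    # representative has the lexicographically smallest name in its orbit
    names = [canonical_name(l) for l in dd]
    assert len(names) == len(set(names))


def test_canonical_names_round_trip():
    for name in ("Pdo_P9_2_2_2", "Asc_P11_2_1_1_1_1", "Aid_P10_1_2_1_2",
                 "tp_P8_1_1_3", "Pcu_P16_3_5_5"):
        lab = labeling_from_name(name)
        assert canonical_name(lab) == name


def test_prism_name_starts_on_base():
    named = named_distributions("9p", 12)
    assert "9p_P12_5_1_3" in named
    lab = named["9p_P12_5_1_3"]
    solid = lab.solid()
    base = set(solid.base_faces)
    # base corners carry the leading label 5
    for v in range(solid.n_vertices):
        for c in solid.corners_of_vertex(v):
            if solid.corner_face(c) in base:
                assert lab.labels[c] == 5


def test_diagram_counting_is_superset_of_orbit_counting():
    for sym, P in (("Pte", 10), ("Aco", 12), ("7p", 11)):
        n_orbit = len(named_distributions(sym, P))
        n_diag = len(diagram_assignments(sym, P))
        assert n_diag >= n_orbit
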