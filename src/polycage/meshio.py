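"""OFF / OBJ import and export for cage and solid geometries.

Faces are written as polygons (holes are implicit); round-trips preserve
coordinates to double precision and face cycles exactly.  The OFF flavour
is the plain ASCII one (counts line, vertex lines, face lines); OBJ uses
``v``/``f`` records with 1-based indices.
"""

from __future__ import annotations

import os

import numpy as np


class MeshParseError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


def export_geometry(geometry, path):
    """Write a PCageGeometry (or any nodes+faces pair) as OFF or OBJ."""
    ext = os.path.splitext(path)[1].lower()
    nodes = geometry.nodes
    faces = [list(map(int, row)) for row in geometry.topology.faces]
    if ext == ".off":
        _write_off(nodes, faces, path)
    elif ext == ".obj":
        _write_obj(nodes, faces, path)
    else:
        raise ValueError(f"unknown geometry format: {ext!r} (use .off or .obj)")


def _write_off(nodes, faces, path):
    n_edges = sum(len(f) for f in faces) // 2
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(nodes)} {len(faces)} {n_edges}\n")
        for v in nodes:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in faces:
            fh.write(" ".join([str(len(f))] + [str(i) for i in f]) + "\n")


def _write_obj(nodes, faces, path):
    with open(path, "w") as fh:
        for v in nodes:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in faces:
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def import_mesh(path):
    """Read an OFF or OBJ polygon mesh; returns (nodes (n,3), faces list)."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".off":
        return _read_off(path)
    if ext == ".obj":
        return _read_obj(path)
    raise ValueError(f"unknown geometry format: {ext!r} (use .off or .obj)")


def _read_off(path):
    with open(path) as fh:
        lines = fh.readlines()
    rows = [(i + 1, l.strip()) for i, l in enumerate(lines)
            if l.strip() and not l.strip().startswith("#")]
    if not rows or rows[0][1] != "OFF":
        raise MeshParseError(path, rows[0][0] if rows else 1, "missing OFF header")
    try:
        nv, nf, _ = map(int, rows[1][1].split())
    except Exception:
        raise MeshParseError(path, rows[1][0], "malformed counts line")
    verts, faces = [], []
    for lineno, text in rows[2:2 + nv]:
        parts = text.split()
        if len(parts) < 3:
            raise MeshParseError(path, lineno, "vertex needs three coordinates")
        verts.append([float(x) for x in parts[:3]])
    for lineno, text in rows[2 + nv:2 + nv + nf]:
        parts = text.split()
        try:
            k = int(parts[0])
            face = [int(x) for x in parts[1:1 + k]]
        except Exception:
            raise MeshParseError(path, lineno, "malformed face line")
        if len(face) != k:
            raise MeshParseError(path, lineno, "face vertex count mismatch")
        faces.append(face)
    if len(verts) != nv or len(faces) != nf:
        raise MeshParseError(path, rows[1][0], "truncated OFF body")
    return np.array(verts), faces


def _read_obj(path):
    verts, faces = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshParseError(path, lineno, "vertex needs three coordinates")
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                try:
                    faces.append([int(tok.split("/")[0]) - 1 for tok in parts[1:]])
                except Exception:
                    raise MeshParseError(path, lineno, "malformed face line")
    return np.array(verts), faces


def import_geometry(path, topology):
    """Load node coordinates for an existing topology from OFF/OBJ.

    The file's face cycles must match the topology's exactly.
    """
    from .geometry import PCageGeometry

    nodes, faces = import_mesh(path)
    expected = [list(map(int, row)) for row in topology.faces]
    if faces != expected:
        raise ValueError("face cycles in file do not match the topology")
    if len(nodes) != topology.NN:
        raise ValueError("node count in file does not match the topology")
    return PCageGeometry(topology, np.asarray(nodes, dtype=float))


def export_permutations(group, path):
    """Write a group's vertex permutations as CSV (one row per element)."""
    with open(path, "w") as fh:
        n = len(group.elements[0].vertex_perm)
        fh.write("reverses," + ",".join(f"v{i}" for i in range(n)) + "\n")
        for g in group.elements:
            fh.write(("1" if g.reverses_orientation else "0") + ","
                     + ",".join(map(str, g.vertex_perm)) + "\n")
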