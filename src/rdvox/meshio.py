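"""Tetrahedral mesh import: TetGen, Gmsh MSH ASCII 2.2 and Abaqus formats.

All importers funnel element data through :class:`ElementProxy` objects,
which assign contiguous 0-based internal indices in insertion order while
recording the bijective mapping between the file's own ("import") indices
and the internal ones.  The maps stay attached to the returned
:class:`~rdvox.geometry.Tetmesh` (``mesh.import_maps``) and are accessible
during later simulation, e.g. to address tets by the indices a mesh
generator reported.

Node coordinates are multiplied by a caller-supplied ``scale`` factor to
convert to meters (pass 1e-6 for meshes authored in micrometers; default 1.0).
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .geometry import Tetmesh

__all__ = [
    "ElementProxy", "MeshFormatError", "import_mesh",
    "import_tetgen", "import_gmsh", "import_abaqus", "write_tetgen",
]


class MeshFormatError(ValueError):
    """A mesh file failed to parse; the message names file and line."""


class ElementProxy:
    """Ordered store of raw mesh elements with import/internal index maps.

    ``kind`` is one of ``node``/``tet``/``tri``.  Internal indices are
    assigned in insertion order starting at 0; the import->internal map is
    a bijection over the inserted elements.
    """

    def __init__(self, kind: str):
        self.kind = kind
        self.data: list = []
        self._to_internal: dict[int, int] = {}
        self._to_import: list[int] = []
        self.groups: dict[int, str | int] = {}  # internal index -> label

    def insert(self, import_index: int, record, group=None) -> int:
        if import_index in self._to_internal:
            raise MeshFormatError(f"duplicate {self.kind} index {import_index}")
        internal = len(self.data)
        self.data.append(record)
        self._to_internal[import_index] = internal
        self._to_import.append(import_index)
        if group is not None:
            self.groups[internal] = group
        return internal

    def __len__(self) -> int:
        return len(self.data)

    def to_internal(self, import_index: int) -> int:
        try:
            return self._to_internal[import_index]
        except KeyError:
            raise KeyError(f"{self.kind} import index {import_index} not present") from None

    def to_import(self, internal_index: int) -> int:
        try:
            return self._to_import[internal_index]
        except IndexError:
            raise KeyError(f"{self.kind} internal index {internal_index} not present") from None

    def internal_of_group(self, label) -> list[int]:
        """Internal indices of all elements tagged with ``label``."""
        return [i for i, g in self.groups.items() if g == label]


def _build_mesh(nodes: ElementProxy, tets: ElementProxy, tris: ElementProxy,
                scale: float) -> Tetmesh:
    vertices = np.asarray(nodes.data, dtype=float) * scale
    tet_arr = [[nodes.to_internal(v) for v in rec] for rec in tets.data]
    mesh = Tetmesh(vertices, tet_arr,
                   import_maps={"node": nodes, "tet": tets, "tri": tris})
    return mesh


# ---------------------------------------------------------------------------
# TetGen (.node / .ele / .face)
# ---------------------------------------------------------------------------

def _tetgen_lines(path: Path):
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield ln, line.split()


def import_tetgen(basename, scale: float = 1.0):
    """Import TetGen ``.node``/``.ele`` (and ``.face`` if present).

    ``basename`` is the path without extension.  TetGen files may be 0- or
    1-based; the base is auto-detected from the first element index.
    """
    base = Path(basename)
    node_path = base.with_suffix(".node")
    ele_path = base.with_suffix(".ele")
    face_path = base.with_suffix(".face")
    nodes = ElementProxy("node")
    tets = ElementProxy("tet")
    tris = ElementProxy("tri")

    lines = list(_tetgen_lines(node_path))
    if not lines:
        raise MeshFormatError(f"{node_path}: empty .node file")
    ln, header = lines[0]
    try:
        n_nodes, dim = int(header[0]), int(header[1])
    except (ValueError, IndexError):
        raise MeshFormatError(f"{node_path}:{ln}: malformed header") from None
    if dim != 3:
        raise MeshFormatError(f"{node_path}:{ln}: only 3D .node files supported")
    if len(lines) - 1 != n_nodes:
        raise MeshFormatError(f"{node_path}: header says {n_nodes} nodes, "
                              f"found {len(lines) - 1}")
    for ln, tok in lines[1:]:
        try:
            nodes.insert(int(tok[0]), [float(tok[1]), float(tok[2]), float(tok[3])])
        except (ValueError, IndexError):
            raise MeshFormatError(f"{node_path}:{ln}: malformed node line") from None

    lines = list(_tetgen_lines(ele_path))
    if not lines:
        raise MeshFormatError(f"{ele_path}: empty .ele file")
    ln, header = lines[0]
    try:
        n_tets = int(header[0])
    except ValueError:
        raise MeshFormatError(f"{ele_path}:{ln}: malformed header") from None
    if len(lines) - 1 != n_tets:
        raise MeshFormatError(f"{ele_path}: header says {n_tets} tets, "
                              f"found {len(lines) - 1}")
    for ln, tok in lines[1:]:
        try:
            verts = [int(v) for v in tok[1:5]]
            region = int(tok[5]) if len(tok) > 5 else None
        except (ValueError, IndexError):
            raise MeshFormatError(f"{ele_path}:{ln}: malformed tet line") from None
        for v in verts:
            if v not in nodes._to_internal:
                raise MeshFormatError(f"{ele_path}:{ln}: unknown node {v}")
        tets.insert(int(tok[0]), verts, region)

    if face_path.exists():
        lines = list(_tetgen_lines(face_path))
        ln, header = lines[0]
        for ln, tok in lines[1:]:
            try:
                verts = [int(v) for v in tok[1:4]]
                marker = int(tok[4]) if len(tok) > 4 else None
            except (ValueError, IndexError):
                raise MeshFormatError(f"{face_path}:{ln}: malformed face line") from None
            for v in verts:
                if v not in nodes._to_internal:
                    raise MeshFormatError(f"{face_path}:{ln}: unknown node {v}")
            tris.insert(int(tok[0]), verts, marker)

    return _build_mesh(nodes, tets, tris, scale), {"node": nodes, "tet": tets, "tri": tris}


def write_tetgen(mesh: Tetmesh, basename, scale: float = 1.0) -> None:
    """Write a mesh in the TetGen dialect (1-based), for round-trip tests.

    Coordinates are divided by ``scale`` (the inverse of import scaling).
    """
    base = Path(basename)
    with open(base.with_suffix(".node"), "w") as fh:
        fh.write(f"{mesh.n_vertices} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.vertices / scale, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    with open(base.with_suffix(".ele"), "w") as fh:
        fh.write(f"{mesh.n_tets} 4 0\n")
        for i, verts in enumerate(mesh.tets, start=1):
            fh.write(f"{i} " + " ".join(str(v + 1) for v in verts) + "\n")
    boundary = np.flatnonzero(mesh.tri_boundary)
    with open(base.with_suffix(".face"), "w") as fh:
        fh.write(f"{len(boundary)} 0\n")
        for i, fi in enumerate(boundary, start=1):
            fh.write(f"{i} " + " ".join(str(v + 1) for v in mesh.tris[fi]) + "\n")


# ---------------------------------------------------------------------------
# Gmsh MSH ASCII v2.2
# ---------------------------------------------------------------------------

def import_gmsh(path, scale: float = 1.0):
    """Import a Gmsh MSH ASCII v2.2 file.

    Element type 4 (4-node tetrahedra) become voxels; type 2 (3-node
    triangles) are retained as candidate patch triangles; any other element
    type is ignored with a warning.  The first (physical) tag becomes the
    group label.
    """
    path = Path(path)
    nodes = ElementProxy("node")
    tets = ElementProxy("tet")
    tris = ElementProxy("tri")
    lines = path.read_text().splitlines()
    i = 0

    def expect(tag):
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or lines[i].strip() != tag:
            raise MeshFormatError(f"{path}:{i + 1}: expected {tag}")
        i += 1

    expect("$MeshFormat")
    fmt = lines[i].split()
    if not fmt or not fmt[0].startswith("2."):
        raise MeshFormatError(f"{path}:{i + 1}: only MSH ASCII v2.x supported")
    if len(fmt) > 1 and fmt[1] != "0":
        raise MeshFormatError(f"{path}:{i + 1}: binary MSH not supported")
    i += 1
    expect("$EndMeshFormat")
    # skip optional sections until $Nodes
    while i < len(lines) and lines[i].strip() != "$Nodes":
        i += 1
    expect("$Nodes")
    try:
        n_nodes = int(lines[i])
    except ValueError:
        raise MeshFormatError(f"{path}:{i + 1}: malformed node count") from None
    i += 1
    for _ in range(n_nodes):
        tok = lines[i].split()
        try:
            nodes.insert(int(tok[0]), [float(tok[1]), float(tok[2]), float(tok[3])])
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}:{i + 1}: malformed node line") from None
        i += 1
    expect("$EndNodes")
    expect("$Elements")
    try:
        n_elems = int(lines[i])
    except ValueError:
        raise MeshFormatError(f"{path}:{i + 1}: malformed element count") from None
    i += 1
    skipped: set[int] = set()
    for _ in range(n_elems):
        tok = lines[i].split()
        try:
            eid, etype, ntags = int(tok[0]), int(tok[1]), int(tok[2])
            tags = [int(t) for t in tok[3:3 + ntags]]
            verts = [int(v) for v in tok[3 + ntags:]]
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}:{i + 1}: malformed element line") from None
        group = tags[0] if tags else None
        for v in verts:
            if v not in nodes._to_internal:
                raise MeshFormatError(f"{path}:{i + 1}: unknown node {v}")
        if etype == 4:
            if len(verts) != 4:
                raise MeshFormatError(f"{path}:{i + 1}: tet needs 4 nodes")
            tets.insert(eid, verts, group)
        elif etype == 2:
            tris.insert(eid, verts, group)
        else:
            skipped.add(etype)
        i += 1
    expect("$EndElements")
    if skipped:
        warnings.warn(f"{path}: ignored unsupported MSH element types {sorted(skipped)}",
                      stacklevel=2)
    return _build_mesh(nodes, tets, tris, scale), {"node": nodes, "tet": tets, "tri": tris}


# ---------------------------------------------------------------------------
# Abaqus (*NODE, *ELEMENT TYPE=C3D4)
# ---------------------------------------------------------------------------

def import_abaqus(path, scale: float = 1.0):
    """Import an Abaqus ``.inp`` file (as exportable by CUBIT).

    Supports ``*NODE`` and ``*ELEMENT, TYPE=C3D4`` blocks; the ``ELSET``
    name becomes the group label of its tets.  Other element types are
    ignored with a warning.
    """
    path = Path(path)
    nodes = ElementProxy("node")
    tets = ElementProxy("tet")
    tris = ElementProxy("tri")
    mode = None  # None | "node" | "tet" | "skip"
    elset = None
    skipped: set[str] = set()
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            key = line.split(",", 1)[0].strip().upper()
            if key == "*NODE":
                mode = "node"
            elif key == "*ELEMENT":
                m = re.search(r"TYPE\s*=\s*([\w-]+)", line, re.IGNORECASE)
                etype = m.group(1).upper() if m else ""
                if etype == "C3D4":
                    mode = "tet"
                    m = re.search(r"ELSET\s*=\s*([\w.-]+)", line, re.IGNORECASE)
                    elset = m.group(1) if m else None
                else:
                    mode = "skip"
                    skipped.add(etype or "?")
            else:
                mode = None
            continue
        tok = [t for t in line.replace(",", " ").split() if t]
        if mode == "node":
            try:
                nodes.insert(int(tok[0]), [float(tok[1]), float(tok[2]), float(tok[3])])
            except (ValueError, IndexError):
                raise MeshFormatError(f"{path}:{ln}: malformed node line") from None
        elif mode == "tet":
            try:
                verts = [int(v) for v in tok[1:5]]
            except (ValueError, IndexError):
                raise MeshFormatError(f"{path}:{ln}: malformed element line") from None
            for v in verts:
                if v not in nodes._to_internal:
                    raise MeshFormatError(f"{path}:{ln}: unknown node {v}")
            tets.insert(int(tok[0]), verts, elset)
    if skipped:
        warnings.warn(f"{path}: ignored unsupported Abaqus element types {sorted(skipped)}",
                      stacklevel=2)
    if not len(tets):
        raise MeshFormatError(f"{path}: no C3D4 elements found")
    return _build_mesh(nodes, tets, tris, scale), {"node": nodes, "tet": tets, "tri": tris}


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_IMPORTERS = {"tetgen": import_tetgen, "gmsh": import_gmsh, "abaqus": import_abaqus}


def import_mesh(path, fmt: str, scale: float = 1.0):
    """One-step import; ``fmt`` is ``tetgen`` (path = basename), ``gmsh`` or
    ``abaqus``.  Returns ``(Tetmesh, {kind: ElementProxy})``."""
    try:
        importer = _IMPORTERS[fmt]
    except KeyError:
        raise ValueError(f"unknown mesh format {fmt!r}; "
                         f"choose from {sorted(_IMPORTERS)}") from None
    return importer(path, scale=scale)
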