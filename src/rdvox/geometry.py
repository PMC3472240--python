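"""Geometry containers and tetrahedral-mesh primitives.

Two kinds of geometry can host a chemical model: well-mixed compartments and
patches (defined only by volume / area), and tetrahedral meshes in which each
tetrahedron is treated as an internally well-mixed voxel.  Compartments are
3D regions with reflective boundaries; patches are 2D surfaces connected to
one or two compartments.

All lengths are in meters, volumes in m^3, areas in m^2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateTetError",
    "NonManifoldMeshError",
    "WellMixedCompartment",
    "WellMixedPatch",
    "WellMixedGeometry",
    "Tetmesh",
    "tet_geometry",
    "quality_metrics",
    "build_connectivity",
    "generate_box_tetmesh",
]

#: ratio of degenerate-volume tolerance to bounding-box volume
DEGENERACY_REL_TOL = 1e-18

#: radius-edge ratio of the regular tetrahedron, sqrt(6)/4 -- the minimum
#: attainable value, reported as ~0.61 by mesh generators.
REGULAR_RADIUS_EDGE = np.sqrt(6.0) / 4.0


class DegenerateTetError(ValueError):
    """Raised for tetrahedra with (near-)zero volume."""


class NonManifoldMeshError(ValueError):
    """Raised when a triangular face is shared by more than two tetrahedra."""


# ---------------------------------------------------------------------------
# well-mixed geometry
# ---------------------------------------------------------------------------

@dataclass
class WellMixedCompartment:
    """A well-mixed 3D reaction container, defined only by its volume."""

    id: str
    volume: float  # m^3
    volume_systems: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"compartment {self.id!r}: volume must be > 0")
        self.volume_systems = tuple(self.volume_systems)


@dataclass
class WellMixedPatch:
    """A well-mixed 2D surface between one or two compartments."""

    id: str
    area: float  # m^2
    inner: str
    outer: str | None = None
    surface_systems: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"patch {self.id!r}: area must be > 0")
        self.surface_systems = tuple(self.surface_systems)


@dataclass
class WellMixedGeometry:
    """A collection of well-mixed compartments and patches."""

    compartments: dict[str, WellMixedCompartment] = field(default_factory=dict)
    patches: dict[str, WellMixedPatch] = field(default_factory=dict)

    def add_compartment(self, comp: WellMixedCompartment) -> WellMixedCompartment:
        if comp.id in self.compartments:
            raise ValueError(f"duplicate compartment id {comp.id!r}")
        self.compartments[comp.id] = comp
        return comp

    def add_patch(self, patch: WellMixedPatch) -> WellMixedPatch:
        if patch.id in self.patches:
            raise ValueError(f"duplicate patch id {patch.id!r}")
        if patch.inner not in self.compartments:
            raise ValueError(f"patch {patch.id!r}: unknown inner compartment {patch.inner!r}")
        if patch.outer is not None and patch.outer not in self.compartments:
            raise ValueError(f"patch {patch.id!r}: unknown outer compartment {patch.outer!r}")
        self.patches[patch.id] = patch
        return patch


# ---------------------------------------------------------------------------
# tetrahedron primitives
# ---------------------------------------------------------------------------

def tet_geometry(points) -> dict:
    """Volume, barycenter and face areas of a single tetrahedron.

    Parameters
    ----------
    points : (4, 3) array-like
        Vertex coordinates.

    Returns
    -------
    dict with keys ``volume`` (m^3), ``barycenter`` ((3,) array) and
    ``face_areas`` ((4,) array; entry j is the face opposite vertex j).

    Raises
    ------
    DegenerateTetError
        If the four points are coplanar (volume below tolerance).
    """
    p = np.asarray(points, dtype=float)
    if p.shape != (4, 3):
        raise ValueError("tet_geometry expects four 3D points")
    e = p[1:] - p[0]
    volume = abs(np.linalg.det(e)) / 6.0
    extent = p.max(axis=0) - p.min(axis=0)
    bbox = float(np.prod(np.where(extent > 0, extent, 1.0)))
    if volume <= DEGENERACY_REL_TOL * bbox or volume == 0.0:
        raise DegenerateTetError("degenerate tetrahedron (coplanar or duplicated vertices)")
    areas = np.empty(4)
    for j in range(4):
        a, b, c = p[[k for k in range(4) if k != j]]
        areas[j] = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
    return {"volume": volume, "barycenter": p.mean(axis=0), "face_areas": areas}


def _circumsphere(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the sphere through four non-coplanar points."""
    a = 2.0 * (p[1:] - p[0])
    b = np.einsum("ij,ij->i", p[1:], p[1:]) - p[0] @ p[0]
    center = np.linalg.solve(a, b)
    return center, float(np.linalg.norm(center - p[0]))


def quality_metrics(points) -> dict:
    """Shape-quality metrics of a tetrahedron.

    ``radius_edge_ratio`` is the circumsphere radius divided by the shortest
    edge length (>= sqrt(6)/4 ~ 0.612, the regular-tet value; TetGen's default
    quality bound is 2.0).  ``aspect_ratio_beta`` is the circumsphere radius
    divided by 3x the inscribed-sphere radius (1 for a regular tet, with
    values up to ~3 generally considered acceptable).
    """
    p = np.asarray(points, dtype=float)
    geo = tet_geometry(p)  # raises on degenerate input
    circum_r = _circumsphere(p)[1]
    edges = [np.linalg.norm(p[i] - p[j]) for i, j in itertools.combinations(range(4), 2)]
    # insphere radius from r = 3V / (total face area)
    in_r = 3.0 * geo["volume"] / geo["face_areas"].sum()
    return {
        "radius_edge_ratio": circum_r / min(edges),
        "aspect_ratio_beta": circum_r / (3.0 * in_r),
    }


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def build_connectivity(tets) -> dict:
    """Face-sharing neighbor relation of a tetrahedron list.

    Two tets are neighbors iff they share exactly three vertices (one face);
    each tet therefore has at most 4 neighbors, fewer at boundaries.

    Returns a dict with:

    ``neighbors`` : (n_tet, 4) int array; entry ``[t, j]`` is the tet across
        the face opposite local vertex j, or -1 for a boundary face.
    ``faces`` : (n_face, 3) int array of unique faces (sorted vertex triples).
    ``face_tets`` : (n_face, 2) int array; the one or two tets adjacent to
        each face (-1 in the second slot for boundary faces).
    ``boundary`` : boolean mask over faces.

    Raises
    ------
    NonManifoldMeshError
        If any face is shared by more than two tets.
    """
    tets = np.asarray(tets, dtype=np.int64)
    n = len(tets)
    face_map: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    for t in range(n):
        verts = tets[t]
        for j in range(4):
            face = tuple(sorted(int(v) for k, v in enumerate(verts) if k != j))
            face_map.setdefault(face, []).append((t, j))
    neighbors = np.full((n, 4), -1, dtype=np.int64)
    faces = np.empty((len(face_map), 3), dtype=np.int64)
    face_tets = np.full((len(face_map), 2), -1, dtype=np.int64)
    boundary = np.zeros(len(face_map), dtype=bool)
    for i, (face, owners) in enumerate(sorted(face_map.items())):
        if len(owners) > 2:
            raise NonManifoldMeshError(f"face {face} shared by {len(owners)} tets")
        faces[i] = face
        face_tets[i, : len(owners)] = [t for t, _ in owners]
        boundary[i] = len(owners) == 1
        if len(owners) == 2:
            (t1, j1), (t2, j2) = owners
            neighbors[t1, j1] = t2
            neighbors[t2, j2] = t1
    return {
        "neighbors": neighbors,
        "faces": faces,
        "face_tets": face_tets,
        "boundary": boundary,
    }


# ---------------------------------------------------------------------------
# tetrahedral mesh container
# ---------------------------------------------------------------------------

@dataclass
class TetCompartment:
    id: str
    tets: np.ndarray  # internal tet indices
    volume_systems: tuple[str, ...] = ()

    @property
    def n_tets(self) -> int:
        return len(self.tets)


@dataclass
class TetPatch:
    id: str
    tris: np.ndarray  # internal triangle (face) indices
    inner: str
    outer: str | None = None
    surface_systems: tuple[str, ...] = ()


class Tetmesh:
    """A tetrahedral mesh with connectivity, annotation and geometric data.

    Vertices are 0-based and in meters; ``tets`` holds 4 vertex indices per
    tetrahedron.  On construction the full connectivity (neighbor relation,
    unique triangular faces, boundary flags) and the per-element geometric
    quantities used by the diffusion rates -- tet volumes V_k, barycenters
    (for barycenter-to-barycenter distances dx) and face areas S -- are
    computed and cached.
    """

    def __init__(self, vertices, tets, import_maps: dict | None = None):
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(tets, dtype=np.int64).reshape(-1, 4)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.vertices)):
            raise ValueError("tet vertex index out of range")
        if len(self.tets) == 0:
            raise ValueError("mesh contains no tetrahedra")
        #: import-index <-> internal-index maps from mesh_io (may be empty)
        self.import_maps = import_maps or {}

        p = self.vertices[self.tets]  # (n, 4, 3)
        e = p[:, 1:, :] - p[:, :1, :]
        vol = np.abs(np.linalg.det(e)) / 6.0
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        bbox = float(np.prod(np.where(extent > 0, extent, 1.0)))
        if np.any(vol <= DEGENERACY_REL_TOL * bbox):
            bad = int(np.argmin(vol))
            raise DegenerateTetError(f"tet {bad} is degenerate (volume {vol[bad]:g} m^3)")
        self.tet_volumes = vol
        self.tet_barycenters = p.mean(axis=1)

        conn = build_connectivity(self.tets)
        self.tet_neighbors = conn["neighbors"]
        self.tris = conn["faces"]
        self.tri_tets = conn["face_tets"]
        self.tri_boundary = conn["boundary"]
        q = self.vertices[self.tris]
        self.tri_areas = 0.5 * np.linalg.norm(
            np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]), axis=1
        )
        self.tri_barycenters = q.mean(axis=1)
        self._face_index = {tuple(f): i for i, f in enumerate(map(tuple, self.tris))}
        # area of the face opposite local vertex j of each tet
        self.tet_face_areas = np.empty((len(self.tets), 4))
        self.tet_face_tris = np.empty((len(self.tets), 4), dtype=np.int64)
        for t in range(len(self.tets)):
            verts = self.tets[t]
            for j in range(4):
                face = tuple(sorted(int(v) for k, v in enumerate(verts) if k != j))
                fi = self._face_index[face]
                self.tet_face_tris[t, j] = fi
                self.tet_face_areas[t, j] = self.tri_areas[fi]

        self.compartments: dict[str, TetCompartment] = {}
        self.patches: dict[str, TetPatch] = {}
        #: compartment id per tet ('' = unassigned)
        self.tet_compartment = np.full(len(self.tets), -1, dtype=np.int64)
        self._comp_order: list[str] = []

    # -- basic properties ---------------------------------------------------

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_volume(self) -> float:
        return float(self.tet_volumes.sum())

    def barycenter_distance(self, k: int, l: int) -> float:
        """dx_{k,l}: barycenter-to-barycenter distance (symmetric by construction)."""
        return float(np.linalg.norm(self.tet_barycenters[k] - self.tet_barycenters[l]))

    def find_tet(self, point) -> int:
        """Index of the tet containing ``point`` (barycentric test); -1 if none."""
        pt = np.asarray(point, dtype=float)
        for t in range(self.n_tets):
            p = self.vertices[self.tets[t]]
            try:
                lam = np.linalg.solve((p[1:] - p[0]).T, pt - p[0])
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate guarded earlier
                continue
            if lam.min() >= -1e-12 and lam.sum() <= 1 + 1e-12:
                return t
        return -1

    # -- annotation ---------------------------------------------------------

    def add_compartment(self, cid: str, tet_indices, volume_systems=()) -> TetCompartment:
        """Declare a compartment as a set of tets; compartments must be disjoint."""
        idx = np.unique(np.asarray(tet_indices, dtype=np.int64))
        if cid in self.compartments:
            raise ValueError(f"duplicate compartment id {cid!r}")
        if idx.size == 0:
            raise ValueError(f"compartment {cid!r} has no tets")
        if idx.min() < 0 or idx.max() >= self.n_tets:
            raise ValueError(f"compartment {cid!r}: tet index out of range")
        if np.any(self.tet_compartment[idx] >= 0):
            raise ValueError(f"compartment {cid!r} overlaps an existing compartment")
        comp = TetCompartment(cid, idx, tuple(volume_systems))
        self.compartments[cid] = comp
        self.tet_compartment[idx] = len(self._comp_order)
        self._comp_order.append(cid)
        return comp

    def add_patch(self, pid: str, tri_indices, inner: str, outer: str | None = None,
                  surface_systems=()) -> TetPatch:
        """Declare a patch as a set of mesh faces between inner/outer compartments."""
        idx = np.unique(np.asarray(tri_indices, dtype=np.int64))
        if pid in self.patches:
            raise ValueError(f"duplicate patch id {pid!r}")
        if inner not in self.compartments:
            raise ValueError(f"patch {pid!r}: unknown inner compartment {inner!r}")
        if outer is not None and outer not in self.compartments:
            raise ValueError(f"patch {pid!r}: unknown outer compartment {outer!r}")
        inner_ix = self._comp_order.index(inner)
        outer_ix = self._comp_order.index(outer) if outer is not None else -1
        for fi in idx:
            owners = set(self.tri_tets[fi][self.tri_tets[fi] >= 0])
            comps = {int(self.tet_compartment[t]) for t in owners}
            if inner_ix not in comps:
                raise ValueError(
                    f"patch {pid!r}: triangle {fi} is not a face of compartment {inner!r}")
            if outer is not None and outer_ix not in comps:
                raise ValueError(
                    f"patch {pid!r}: triangle {fi} is not a face of compartment {outer!r}")
        patch = TetPatch(pid, idx, inner, outer, tuple(surface_systems))
        self.patches[pid] = patch
        return patch

    def patch_tri_tets(self, pid: str) -> tuple[np.ndarray, np.ndarray]:
        """Per patch triangle: (inner tet index, outer tet index or -1)."""
        patch = self.patches[pid]
        inner_ix = self._comp_order.index(patch.inner)
        inner = np.empty(len(patch.tris), dtype=np.int64)
        outer = np.full(len(patch.tris), -1, dtype=np.int64)
        for i, fi in enumerate(patch.tris):
            owners = [int(t) for t in self.tri_tets[fi] if t >= 0]
            inn = [t for t in owners if self.tet_compartment[t] == inner_ix]
            inner[i] = inn[0]
            rest = [t for t in owners if t != inn[0]]
            if rest:
                outer[i] = rest[0]
        return inner, outer

    # -- quality ------------------------------------------------------------

    def quality_report(self) -> pd.DataFrame:
        """Per-tet shape metrics (radius-edge ratio, Aspect Ratio Beta, volume).

        Quality is report-only: a simulation will run on a poor-quality mesh,
        the decision is left to the user.
        """
        rows = []
        for t in range(self.n_tets):
            m = quality_metrics(self.vertices[self.tets[t]])
            rows.append((t, m["radius_edge_ratio"], m["aspect_ratio_beta"],
                         self.tet_volumes[t]))
        return pd.DataFrame(rows, columns=["tet", "radius_edge_ratio",
                                           "aspect_ratio_beta", "volume"])

    def quality_summary(self) -> dict:
        rep = self.quality_report()
        return {
            "n_tets": self.n_tets,
            "radius_edge_ratio_max": float(rep.radius_edge_ratio.max()),
            "aspect_ratio_beta_max": float(rep.aspect_ratio_beta.max()),
            "volume_min": float(rep.volume.min()),
            "volume_max": float(rep.volume.max()),
            "volume_mean": float(rep.volume.mean()),
            "volume_sd": float(rep.volume.std(ddof=0)),
            "total_volume": self.total_volume,
        }


# ---------------------------------------------------------------------------
# structured box mesh (fixture generator)
# ---------------------------------------------------------------------------

# Kuhn subdivision: six tets per cube, all sharing the main diagonal
# (0,0,0)-(1,1,1); translation-invariant, hence face-conforming across cubes.
_KUHN_PERMS = list(itertools.permutations(range(3)))


def generate_box_tetmesh(lengths, divisions) -> Tetmesh:
    """Axis-aligned box split into cubes, each cube into 6 tetrahedra.

    Parameters
    ----------
    lengths : float or (3,) sequence
        Box edge lengths in meters.
    divisions : int or (3,) sequence
        Number of cells per axis (>= 1).

    The decomposition is exact: the tet volumes sum to the box volume, and
    the result always passes :func:`build_connectivity`.
    """
    lengths = np.broadcast_to(np.asarray(lengths, dtype=float), (3,)).copy()
    divisions = np.broadcast_to(np.asarray(divisions, dtype=np.int64), (3,)).copy()
    if np.any(lengths <= 0):
        raise ValueError("box lengths must be positive")
    if np.any(divisions < 1):
        raise ValueError("divisions must be >= 1")
    nx, ny, nz = (int(d) for d in divisions)
    xs = [np.linspace(0.0, lengths[i], divisions[i] + 1) for i in range(3)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = np.array([i, j, k])
                for perm in _KUHN_PERMS:
                    path = [corner.copy()]
                    c = corner.copy()
                    for axis in perm:
                        c = c.copy()
                        c[axis] += 1
                        path.append(c)
                    tets.append([vid(*v) for v in path])
    return Tetmesh(vertices, tets)
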