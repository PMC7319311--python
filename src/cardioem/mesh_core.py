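"""Tetrahedral mesh data model, file I/O, quality metrics, refinement and surfaces.

The mesh carrier used by every stage of the toolkit is :class:`TetMesh`: linear
tetrahedra with integer region tags, per-element fibre/sheet vectors and named
per-node / per-element scalar fields.  Coordinates are millimetres throughout;
the toolkit works in a consistent mm / ms / kPa unit system (so a conduction
velocity of 0.6 m/s is stored as 0.6 mm/ms and pressures in kPa pair with mm
and kPa·mm² forces).

Two on-disk dialects are supported:

* CARP-style text: ``<prefix>.pts`` (count line, then ``x y z``),
  ``<prefix>.elem`` (count line, then ``Tt i j k l tag``, 0-based indices) and
  ``<prefix>.lon`` (header ``1`` or ``2``, then 3 or 6 reals per element for
  fibre, or fibre followed by sheet).  Named node fields are sidecar
  ``<prefix>.<name>.dat`` files (one value per line) and element fields
  ``<prefix>.<name>.edat``.
* VTK legacy unstructured grid (ASCII write; ASCII and big-endian binary read)
  with tags/fibres/sheets as cell data and node fields as point data.

Non-ventricular elements carry the conventional default orientation vectors
fibre ``[1, 0, 0]`` and sheet ``[0, 1, 0]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_FIBRE",
    "DEFAULT_SHEET",
    "UVC_SENTINEL",
    "MeshFormatError",
    "MeshValidationError",
    "SurfaceExtractionError",
    "LabelSchema",
    "TetMesh",
    "SurfaceSet",
    "read_mesh",
    "write_mesh",
    "scaled_jacobian",
    "edge_length_stats",
    "uniform_refine",
    "extract_surfaces",
    "boundary_faces",
    "tet_volumes",
    "triangle_areas",
    "triangle_normals",
    "unique_edges",
]

DEFAULT_FIBRE = np.array([1.0, 0.0, 0.0])
DEFAULT_SHEET = np.array([0.0, 1.0, 0.0])
#: Value assigned to ventricular-coordinate fields outside the ventricles.
UVC_SENTINEL = -100.0


class MeshFormatError(ValueError):
    """Raised for malformed or unsupported mesh files."""


class MeshValidationError(ValueError):
    """Raised when a mesh violates the TetMesh invariants."""


class SurfaceExtractionError(RuntimeError):
    """Raised when labelled surfaces cannot be extracted unambiguously."""


# ---------------------------------------------------------------------------
# Label schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelSchema:
    """Mapping of element tags to anatomical roles.

    The four-chamber schema has 24 regions: 4 myocardial chambers, 2 vessel
    walls, 7 rings at the cropped veins/appendage, 4 valve planes and 7 planes
    closing the cut veins.  Geometries where the left pulmonary veins branch
    off-image carry only 22 of these tags; they validate against the same
    schema with two tags absent.
    """

    tags: dict[int, str]
    ventricular: frozenset[int]
    rings: frozenset[int]
    valve_planes: dict[str, int]
    vein_planes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.tags.values())) != len(self.tags):
            raise MeshValidationError("label schema role names must be unique")

    @property
    def lv(self) -> int:
        return next(t for t, r in self.tags.items() if r == "lv_myocardium")

    @property
    def rv(self) -> int | None:
        for t, r in self.tags.items():
            if r == "rv_myocardium":
                return t
        return None

    def role(self, tag: int) -> str:
        return self.tags[tag]

    def validate_tags(self, present: np.ndarray) -> None:
        unknown = sorted(set(int(t) for t in np.unique(present)) - set(self.tags))
        if unknown:
            raise MeshValidationError(f"element tags {unknown} not in label schema")

    @classmethod
    def four_chamber(cls) -> "LabelSchema":
        """The published 24-tag four-chamber numbering.

        1–4 LV/RV/LA/RA myocardium, 5–6 aorta/pulmonary-artery wall,
        7 appendage ring, 8–11 pulmonary-vein rings, 12–13 caval rings,
        14–17 mitral/tricuspid/aortic/pulmonary valve planes, 18–24 planes at
        the cut veins in ring order.
        """
        tags = {
            1: "lv_myocardium",
            2: "rv_myocardium",
            3: "la_myocardium",
            4: "ra_myocardium",
            5: "aorta_wall",
            6: "pa_wall",
            7: "laa_ring",
            8: "lspv_ring",
            9: "lipv_ring",
            10: "rspv_ring",
            11: "ripv_ring",
            12: "svc_ring",
            13: "ivc_ring",
            14: "mitral_plane",
            15: "tricuspid_plane",
            16: "aortic_plane",
            17: "pulmonary_plane",
            18: "laa_plane",
            19: "lspv_plane",
            20: "lipv_plane",
            21: "rspv_plane",
            22: "ripv_plane",
            23: "svc_plane",
            24: "ivc_plane",
        }
        return cls(
            tags=tags,
            ventricular=frozenset({1, 2}),
            rings=frozenset(range(7, 14)),
            valve_planes={"mitral": 14, "tricuspid": 15, "aortic": 16, "pulmonary": 17},
            vein_planes=frozenset(range(18, 25)),
        )

    @classmethod
    def lv_only(cls) -> "LabelSchema":
        """Synthetic single-ventricle schema: LV myocardium + mitral cap."""
        return cls(
            tags={1: "lv_myocardium", 14: "mitral_plane"},
            ventricular=frozenset({1}),
            rings=frozenset(),
            valve_planes={"mitral": 14},
        )

    @classmethod
    def biventricular(cls) -> "LabelSchema":
        return cls(
            tags={1: "lv_myocardium", 2: "rv_myocardium", 14: "mitral_plane", 15: "tricuspid_plane"},
            ventricular=frozenset({1, 2}),
            rings=frozenset(),
            valve_planes={"mitral": 14, "tricuspid": 15},
        )


# ---------------------------------------------------------------------------
# TetMesh
# ---------------------------------------------------------------------------


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes, positive for canonically oriented elements."""
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with tags, fibre/sheet frames and named fields."""

    nodes: np.ndarray
    tets: np.ndarray
    elem_tags: np.ndarray
    fibres: np.ndarray | None = None
    sheets: np.ndarray | None = None
    node_fields: dict[str, np.ndarray] = field(default_factory=dict)
    elem_fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.elem_tags = np.ascontiguousarray(self.elem_tags, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshValidationError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshValidationError("tets must be (m, 4)")
        if self.elem_tags.shape != (self.n_elems,):
            raise MeshValidationError("elem_tags must have one entry per tet")
        if self.n_elems and (self.tets.min() < 0 or self.tets.max() >= self.n_nodes):
            raise MeshValidationError("tet node indices out of range")
        self._orient()
        if self.fibres is not None:
            self.fibres = np.ascontiguousarray(self.fibres, dtype=np.float64)
        if self.sheets is not None:
            self.sheets = np.ascontiguousarray(self.sheets, dtype=np.float64)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.tets.shape[0]

    def _orient(self) -> None:
        """Reorient inverted elements (swap two indices) with a warning."""
        vol = tet_volumes(self.nodes, self.tets)
        bad = vol < 0
        if bad.any():
            warnings.warn(
                f"reoriented {int(bad.sum())} inverted tetrahedra", stacklevel=3
            )
            self.tets[bad] = self.tets[bad][:, [0, 2, 1, 3]]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def elem_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def default_frames(self) -> None:
        """Assign the default fibre/sheet vectors to every element."""
        self.fibres = np.tile(DEFAULT_FIBRE, (self.n_elems, 1))
        self.sheets = np.tile(DEFAULT_SHEET, (self.n_elems, 1))

    def validate(self, schema: LabelSchema | None = None, tol: float = 1e-6) -> None:
        """Check the TetMesh invariants; raise :class:`MeshValidationError`."""
        if (self.volumes() <= 0).any():
            raise MeshValidationError("non-positive element volumes after orientation")
        if schema is not None:
            schema.validate_tags(self.elem_tags)
            if self.fibres is not None and self.sheets is not None:
                vent = np.isin(self.elem_tags, list(schema.ventricular))
                for name, vec in (("fibre", self.fibres), ("sheet", self.sheets)):
                    norms = np.linalg.norm(vec[vent], axis=1)
                    if norms.size and np.abs(norms - 1.0).max() > tol:
                        raise MeshValidationError(f"ventricular {name} vectors not unit norm")
                dots = np.abs(np.einsum("ij,ij->i", self.fibres[vent], self.sheets[vent]))
                if dots.size and dots.max() > tol:
                    raise MeshValidationError("ventricular fibre/sheet vectors not orthogonal")

    def copy(self) -> "TetMesh":
        return TetMesh(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            elem_tags=self.elem_tags.copy(),
            fibres=None if self.fibres is None else self.fibres.copy(),
            sheets=None if self.sheets is None else self.sheets.copy(),
            node_fields={k: v.copy() for k, v in self.node_fields.items()},
            elem_fields={k: v.copy() for k, v in self.elem_fields.items()},
        )


# ---------------------------------------------------------------------------
# Surface utilities
# ---------------------------------------------------------------------------

# Outward-oriented local faces of a positively oriented tet (a, b, c, d).
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


def boundary_faces(
    mesh: TetMesh, elem_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Outward-oriented boundary triangles of (a subset of) the mesh.

    Returns ``(faces, owners)`` where each boundary face belongs to exactly
    one tetrahedron of the selected subset.
    """
    tets = self_tets = mesh.tets if elem_mask is None else mesh.tets[elem_mask]
    owners_all = (
        np.arange(mesh.n_elems)
        if elem_mask is None
        else np.flatnonzero(elem_mask)
    )
    faces = self_tets[:, _TET_FACES].reshape(-1, 3)
    owners = np.repeat(owners_all, 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_sorted = key[order]
    dup_prev = np.zeros(len(key), dtype=bool)
    same = (key_sorted[1:] == key_sorted[:-1]).all(axis=1)
    dup_prev[1:] = same
    dup_next = np.zeros(len(key), dtype=bool)
    dup_next[:-1] = same
    unique = ~(dup_prev | dup_next)
    sel = order[unique]
    return faces[sel], owners[sel]


def triangle_normals(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Unit normals following the triangle winding."""
    p0, p1, p2 = (nodes[tris[:, i]] for i in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    return n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p0, p1, p2 = (nodes[tris[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)


def _face_components(faces: np.ndarray) -> np.ndarray:
    """Connected-component label per face, faces linked by shared edges."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    nf = len(faces)
    edges = faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    face_id = np.repeat(np.arange(nf), 3)
    # group faces sharing an identical undirected edge
    key = edges[:, 0].astype(np.int64) * (edges.max() + 1 if edges.size else 1) + edges[:, 1]
    order = np.argsort(key, kind="stable")
    key_s, fid_s = key[order], face_id[order]
    starts = np.flatnonzero(np.r_[True, key_s[1:] != key_s[:-1]])
    ends = np.r_[starts[1:], len(key_s)]
    rows, cols = [], []
    for s, e in zip(starts, ends):
        grp = fid_s[s:e]
        if len(grp) > 1:
            rows.append(np.repeat(grp[0], len(grp) - 1))
            cols.append(grp[1:])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    adj = coo_matrix((np.ones(len(r)), (r, c)), shape=(nf, nf))
    _, labels = connected_components(adj, directed=False)
    return labels


@dataclass
class SurfaceSet:
    """Named, outward-oriented triangle surfaces referencing a parent mesh."""

    mesh: TetMesh
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    owners: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def nodes_of(self, name: str) -> np.ndarray:
        """Unique node indices of a named surface."""
        return np.unique(self.surfaces[name])

    def area(self, name: str) -> float:
        return float(triangle_areas(self.mesh.nodes, self.surfaces[name]).sum())

    def __contains__(self, name: str) -> bool:
        return name in self.surfaces or name in self.node_sets


def extract_surfaces(mesh: TetMesh, schema: LabelSchema) -> SurfaceSet:
    """Extract endocardial/epicardial/base/valve/ring surfaces by tag topology.

    The ventricular base is the set of surface nodes shared between the
    ventricular myocardium and the mitral/tricuspid valve-plane labels.
    Removing those nodes splits the remaining ventricular boundary into
    endocardial and epicardial sheets; endocardium is identified by its
    outward normals pointing back toward the myocardial centroid (into a
    cavity), epicardium by normals pointing away.
    """
    schema.validate_tags(mesh.elem_tags)
    vent_tags = sorted(schema.ventricular & set(np.unique(mesh.elem_tags)))
    if not vent_tags:
        raise SurfaceExtractionError("mesh has no ventricular elements")
    vent_mask = np.isin(mesh.elem_tags, vent_tags)
    faces, owners = boundary_faces(mesh, vent_mask)

    # base nodes: ventricular surface nodes shared with MV/TV plane elements
    av_tags = [t for r, t in schema.valve_planes.items() if r in ("mitral", "tricuspid")]
    av_mask = np.isin(mesh.elem_tags, av_tags)
    plane_nodes = np.unique(mesh.tets[av_mask]) if av_mask.any() else np.empty(0, int)
    base_nodes = np.intersect1d(np.unique(faces), plane_nodes)

    on_base = np.isin(faces, base_nodes).any(axis=1)
    free = ~on_base
    labels = np.full(len(faces), -1)
    labels[free] = _face_components(faces[free])
    comp_ids = np.unique(labels[free]) if free.any() else np.empty(0, int)

    centroids = mesh.elem_centroids()[vent_mask]
    vols = mesh.volumes()[vent_mask]
    region_centroid = (centroids * vols[:, None]).sum(axis=0) / vols.sum()

    endo_comps, epi_comps = [], []
    for cid in comp_ids:
        sel = labels == cid
        tri = faces[sel]
        n = triangle_normals(mesh.nodes, tri)
        a = triangle_areas(mesh.nodes, tri)
        ctr = mesh.nodes[tri].mean(axis=1)
        sense = float((a * np.einsum("ij,ij->i", n, ctr - region_centroid)).sum() / a.sum())
        (endo_comps if sense < 0 else epi_comps).append((cid, sel))

    if len(epi_comps) != 1:
        raise SurfaceExtractionError(
            f"expected one epicardial component, found {len(epi_comps)} "
            f"(component ids {[c for c, _ in epi_comps]})"
        )
    if not 1 <= len(endo_comps) <= len(vent_tags):
        raise SurfaceExtractionError(
            f"found {len(endo_comps)} endocardial components for "
            f"{len(vent_tags)} ventricle(s): ids {[c for c, _ in endo_comps]}"
        )

    out = SurfaceSet(mesh=mesh)
    epi_sel = epi_comps[0][1]
    out.surfaces["epicardium"] = faces[epi_sel]
    out.owners["epicardium"] = owners[epi_sel]

    rv_tag = schema.rv
    if len(endo_comps) == 1:
        sel = endo_comps[0][1]
        out.surfaces["lv_endo"] = faces[sel]
        out.owners["lv_endo"] = owners[sel]
    else:
        # rv cavity lining carries the larger fraction of RV-owned faces
        def rv_fraction(sel: np.ndarray) -> float:
            a = triangle_areas(mesh.nodes, faces[sel])
            is_rv = mesh.elem_tags[owners[sel]] == rv_tag
            return float(a[is_rv].sum() / a.sum())

        scored = sorted(((rv_fraction(sel), cid, sel) for cid, sel in endo_comps))
        (_, _, lv_sel), (_, _, rv_sel) = scored[0], scored[-1]
        out.surfaces["lv_endo"] = faces[lv_sel]
        out.owners["lv_endo"] = owners[lv_sel]
        out.surfaces["rv_endo"] = faces[rv_sel]
        out.owners["rv_endo"] = owners[rv_sel]
        # split the RV lining into free wall (RV-owned) and septum (LV-owned)
        is_rv_owned = mesh.elem_tags[owners[rv_sel]] == rv_tag
        out.surfaces["rv_endo_freewall"] = faces[rv_sel][is_rv_owned]
        out.owners["rv_endo_freewall"] = owners[rv_sel][is_rv_owned]
        out.surfaces["septum_rv_side"] = faces[rv_sel][~is_rv_owned]
        out.owners["septum_rv_side"] = owners[rv_sel][~is_rv_owned]

    out.node_sets["base"] = base_nodes

    # per-valve-plane and per-ring surface sheets from whole-mesh boundary
    all_faces, all_owners = boundary_faces(mesh)
    owner_tags = mesh.elem_tags[all_owners]
    for role, tag in schema.valve_planes.items():
        sel = owner_tags == tag
        if sel.any():
            out.surfaces[f"{role}_plane"] = all_faces[sel]
            out.owners[f"{role}_plane"] = all_owners[sel]
    for tag in sorted(schema.rings):
        sel = owner_tags == tag
        if sel.any():
            name = schema.role(tag)
            out.surfaces[name] = all_faces[sel]
            out.owners[name] = all_owners[sel]
    return out


# ---------------------------------------------------------------------------
# Quality metrics
# ---------------------------------------------------------------------------


def scaled_jacobian(
    mesh: TetMesh, exclude_inverted: bool = True
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-element scaled Jacobian and a (mean, sd) summary.

    At each vertex the Jacobian determinant of the three incident edge vectors
    is normalised by the product of their lengths; the element value is the
    minimum over the four vertices, scaled by √2 so a regular tetrahedron
    scores exactly 1.  Degenerate elements approach 0 and inverted elements
    are negative (flagged, and excluded from the summary unless configured
    otherwise).
    """
    pts = mesh.nodes[mesh.tets]
    det6v = 6.0 * tet_volumes(mesh.nodes, mesh.tets)
    # product of incident edge lengths at each vertex
    prods = np.empty((mesh.n_elems, 4))
    for v in range(4):
        others = [i for i in range(4) if i != v]
        e = pts[:, others, :] - pts[:, [v], :]
        prods[:, v] = np.prod(np.linalg.norm(e, axis=2), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sj = np.sqrt(2.0) * det6v / prods.max(axis=1)
    n_inv = int((sj < 0).sum())
    if n_inv:
        warnings.warn(f"{n_inv} inverted elements have negative scaled Jacobian")
    vals = sj[sj >= 0] if exclude_inverted else sj
    summary = {
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "min": float(sj.min()),
        "n_inverted": n_inv,
    }
    return sj, summary


def unique_edges(tets: np.ndarray) -> np.ndarray:
    """Undirected unique edges (k, 2) of a tet connectivity array."""
    pairs = tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]].reshape(-1, 2)
    return np.unique(np.sort(pairs, axis=1), axis=0)


def edge_length_stats(
    mesh: TetMesh, bins: int = 50
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, sd and histogram of unique edge lengths (mm)."""
    edges = unique_edges(mesh.tets)
    lengths = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1)
    if lengths.max() - lengths.min() < 1e-12:  # constant edge length
        bins = 1
    hist = np.histogram(lengths, bins=bins)
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    return float(lengths.mean()), sd, hist


# ---------------------------------------------------------------------------
# Uniform refinement
# ---------------------------------------------------------------------------

# Red refinement: 4 corner children plus the interior octahedron, split
# along the shortest of its three diagonals (quality-preserving choice).
# Indices 0–3 are parent vertices, 4..9 the edge midpoints
# m01, m02, m03, m12, m13, m23.
_REFINE_CORNERS = [[0, 4, 5, 6], [4, 1, 7, 8], [5, 7, 2, 9], [6, 8, 9, 3]]
_REFINE_DIAGONALS = [(4, 9), (5, 8), (6, 7)]
_REFINE_OCTA = {
    (4, 9): [[4, 5, 6, 9], [4, 6, 8, 9], [4, 5, 9, 7], [4, 7, 9, 8]],
    (5, 8): [[5, 4, 6, 8], [5, 6, 9, 8], [5, 4, 8, 7], [5, 7, 8, 9]],
    (6, 7): [[6, 4, 5, 7], [6, 5, 9, 7], [6, 4, 7, 8], [6, 8, 7, 9]],
}
_REFINE_CHILD_SETS = [
    np.array(_REFINE_CORNERS + _REFINE_OCTA[d]) for d in _REFINE_DIAGONALS
]
_EDGE_LOCAL = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def uniform_refine(mesh: TetMesh, rounds: int = 1) -> TetMesh:
    """Split every tetrahedron 1→8 via edge midpoints, ``rounds`` times.

    Tags, fibres, sheets and element fields are inherited by the children;
    node fields are interpolated linearly (midpoint averages).  Total volume
    is preserved exactly and the mean edge length roughly halves per round.
    """
    if rounds < 0:
        raise ValueError("rounds must be non-negative")
    out = mesh.copy()
    for _ in range(rounds):
        edges = unique_edges(out.tets)
        n0 = out.n_nodes
        mid = 0.5 * (out.nodes[edges[:, 0]] + out.nodes[edges[:, 1]])
        nodes = np.vstack([out.nodes, mid])
        # edge -> midpoint node id lookup
        key = edges[:, 0] * n0 + edges[:, 1]
        order = np.argsort(key)
        sorted_key = key[order]
        mid_ids = n0 + np.arange(len(edges))

        elem_edges = np.sort(out.tets[:, _EDGE_LOCAL], axis=2)
        ek = elem_edges[:, :, 0] * n0 + elem_edges[:, :, 1]
        pos = np.searchsorted(sorted_key, ek)
        mid_of_elem = mid_ids[order[pos]]  # (m, 6)

        verts = np.concatenate([out.tets, mid_of_elem], axis=1)  # (m, 10)
        diag_len = np.stack(
            [
                np.linalg.norm(nodes[verts[:, a]] - nodes[verts[:, b]], axis=1)
                for a, b in _REFINE_DIAGONALS
            ],
            axis=1,
        )
        choice = np.argmin(diag_len, axis=1)
        children = np.empty((out.n_elems, 8, 4), dtype=np.int64)
        for c, child_set in enumerate(_REFINE_CHILD_SETS):
            sel = choice == c
            children[sel] = verts[sel][:, child_set]
        children = children.reshape(-1, 4)

        # orient children before constructing (some diagonal choices flip)
        cvol = tet_volumes(nodes, children)
        neg = cvol < 0
        children[neg] = children[neg][:, [0, 2, 1, 3]]

        node_fields = {}
        for name, f in out.node_fields.items():
            node_fields[name] = np.concatenate(
                [f, 0.5 * (f[edges[:, 0]] + f[edges[:, 1]])]
            )
        out = TetMesh(
            nodes=nodes,
            tets=children,
            elem_tags=np.repeat(out.elem_tags, 8),
            fibres=None if out.fibres is None else np.repeat(out.fibres, 8, axis=0),
            sheets=None if out.sheets is None else np.repeat(out.sheets, 8, axis=0),
            node_fields=node_fields,
            elem_fields={k: np.repeat(v, 8) for k, v in out.elem_fields.items()},
        )
    return out


# ---------------------------------------------------------------------------
# CARP text I/O
# ---------------------------------------------------------------------------


def _read_count_header(path: Path) -> tuple[int, list[str]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise MeshFormatError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path}: malformed header line 1: {lines[0]!r}") from exc
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != count:
        raise MeshFormatError(
            f"{path}: header declares {count} records, body has {len(body)}"
        )
    return count, body


def _read_carp(prefix: Path) -> TetMesh:
    pts_path = Path(str(prefix) + ".pts")
    elem_path = Path(str(prefix) + ".elem")
    n_pts, pts_body = _read_count_header(pts_path)
    nodes = np.loadtxt(pts_path, skiprows=1, ndmin=2, dtype=np.float64)
    if nodes.shape != (n_pts, 3):
        raise MeshFormatError(f"{pts_path}: expected {n_pts} xyz rows")

    n_el, body = _read_count_header(elem_path)
    tets = np.empty((n_el, 4), dtype=np.int64)
    tags = np.empty(n_el, dtype=np.int64)
    for i, ln in enumerate(body):
        parts = ln.split()
        if parts[0] != "Tt":
            raise MeshFormatError(
                f"{elem_path}: line {i + 2}: unsupported element type {parts[0]!r} "
                "(only tetrahedra 'Tt' are supported)"
            )
        if len(parts) != 6:
            raise MeshFormatError(f"{elem_path}: line {i + 2}: expected 'Tt i j k l tag'")
        tets[i] = [int(p) for p in parts[1:5]]
        tags[i] = int(parts[5])

    fibres = sheets = None
    lon_path = Path(str(prefix) + ".lon")
    if lon_path.exists():
        lon_lines = lon_path.read_text().split("\n")
        try:
            n_vec = int(lon_lines[0].split()[0])
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{lon_path}: malformed header line 1") from exc
        data = np.loadtxt(lon_path, skiprows=1, ndmin=2)
        if data.shape[0] != n_el or data.shape[1] not in (3, 6):
            raise MeshFormatError(
                f"{lon_path}: expected {n_el} rows of 3 or 6 reals, got {data.shape}"
            )
        fibres = data[:, :3]
        if n_vec == 2:
            if data.shape[1] != 6:
                raise MeshFormatError(f"{lon_path}: header '2' but only 3 columns")
            sheets = data[:, 3:6]

    node_fields, elem_fields = {}, {}
    stem = prefix.name
    for p in sorted(prefix.parent.glob(f"{stem}.*.dat")):
        name = p.name[len(stem) + 1 : -4]
        vals = np.loadtxt(p, ndmin=1)
        if len(vals) == n_pts:
            node_fields[name] = vals
    for p in sorted(prefix.parent.glob(f"{stem}.*.edat")):
        name = p.name[len(stem) + 1 : -5]
        vals = np.loadtxt(p, ndmin=1)
        if len(vals) == n_el:
            elem_fields[name] = vals

    return TetMesh(nodes, tets, tags, fibres, sheets, node_fields, elem_fields)


def _write_carp(mesh: TetMesh, prefix: Path, write_lon: bool = True) -> list[Path]:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    pts_path = Path(str(prefix) + ".pts")
    with pts_path.open("w") as fh:
        fh.write(f"{mesh.n_nodes}\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
    written.append(pts_path)

    elem_path = Path(str(prefix) + ".elem")
    with elem_path.open("w") as fh:
        fh.write(f"{mesh.n_elems}\n")
        for (i, j, k, l), t in zip(mesh.tets, mesh.elem_tags):
            fh.write(f"Tt {i} {j} {k} {l} {t}\n")
    written.append(elem_path)

    if write_lon:
        if mesh.fibres is None:
            raise MeshFormatError(".lon requested but mesh has no fibre vectors")
        lon_path = Path(str(prefix) + ".lon")
        with lon_path.open("w") as fh:
            if mesh.sheets is not None:
                fh.write("2\n")
                np.savetxt(fh, np.hstack([mesh.fibres, mesh.sheets]), fmt="%.10g")
            else:
                fh.write("1\n")
                np.savetxt(fh, mesh.fibres, fmt="%.10g")
        written.append(lon_path)

    for name, vals in mesh.node_fields.items():
        p = prefix.parent / f"{prefix.name}.{name}.dat"
        np.savetxt(p, np.asarray(vals), fmt="%.10g")
        written.append(p)
    for name, vals in mesh.elem_fields.items():
        p = prefix.parent / f"{prefix.name}.{name}.edat"
        np.savetxt(p, np.asarray(vals), fmt="%.10g")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# VTK legacy unstructured grid I/O
# ---------------------------------------------------------------------------


def _write_vtk(mesh: TetMesh, path: Path) -> list[Path]:
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("cardioem mesh (mm)\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        fh.write(f"CELLS {mesh.n_elems} {5 * mesh.n_elems}\n")
        cells = np.hstack(
            [np.full((mesh.n_elems, 1), 4, dtype=np.int64), mesh.tets]
        )
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_elems}\n")
        np.savetxt(fh, np.full(mesh.n_elems, 10, dtype=np.int64), fmt="%d")

        n_cell_arrays = 1 + (mesh.fibres is not None) + (mesh.sheets is not None) + len(
            mesh.elem_fields
        )
        fh.write(f"CELL_DATA {mesh.n_elems}\n")
        fh.write(f"FIELD celldata {n_cell_arrays}\n")
        fh.write(f"elem_tags 1 {mesh.n_elems} int\n")
        np.savetxt(fh, mesh.elem_tags, fmt="%d")
        if mesh.fibres is not None:
            fh.write(f"fibres 3 {mesh.n_elems} double\n")
            np.savetxt(fh, mesh.fibres, fmt="%.10g")
        if mesh.sheets is not None:
            fh.write(f"sheets 3 {mesh.n_elems} double\n")
            np.savetxt(fh, mesh.sheets, fmt="%.10g")
        for name, vals in mesh.elem_fields.items():
            fh.write(f"{name} 1 {mesh.n_elems} double\n")
            np.savetxt(fh, np.asarray(vals), fmt="%.10g")

        if mesh.node_fields:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            fh.write(f"FIELD pointdata {len(mesh.node_fields)}\n")
            for name, vals in mesh.node_fields.items():
                fh.write(f"{name} 1 {mesh.n_nodes} double\n")
                np.savetxt(fh, np.asarray(vals), fmt="%.10g")
    return [path]


_VTK_DTYPES = {
    "double": (">f8", np.float64),
    "float": (">f4", np.float64),
    "int": (">i4", np.int64),
    "long": (">i8", np.int64),
    "unsigned_int": (">u4", np.int64),
    "char": (">i1", np.int64),
    "unsigned_char": (">u1", np.int64),
    "short": (">i2", np.int64),
}


class _VtkScanner:
    """Token/byte scanner over a legacy VTK file (ASCII or big-endian binary)."""

    def __init__(self, raw: bytes, binary: bool):
        self.raw = raw
        self.binary = binary
        self.pos = 0

    def readline(self) -> str:
        nl = self.raw.find(b"\n", self.pos)
        if nl < 0:
            line = self.raw[self.pos :]
            self.pos = len(self.raw)
        else:
            line = self.raw[self.pos : nl]
            self.pos = nl + 1
        return line.decode("ascii", errors="replace").strip()

    def next_nonempty_line(self) -> str | None:
        while self.pos < len(self.raw):
            line = self.readline()
            if line:
                return line
        return None

    def read_values(self, count: int, vtk_type: str) -> np.ndarray:
        bin_dtype, out_dtype = _VTK_DTYPES[vtk_type.lower()]
        if self.binary:
            nbytes = count * np.dtype(bin_dtype).itemsize
            chunk = self.raw[self.pos : self.pos + nbytes]
            if len(chunk) < nbytes:
                raise MeshFormatError("vtk: unexpected end of binary data")
            self.pos += nbytes
            return np.frombuffer(chunk, dtype=bin_dtype).astype(out_dtype)
        vals = np.empty(count, dtype=np.float64)
        got = 0
        while got < count:
            line = self.next_nonempty_line()
            if line is None:
                raise MeshFormatError("vtk: unexpected end of ASCII data")
            parts = line.split()
            vals[got : got + len(parts)] = [float(p) for p in parts]
            got += len(parts)
        return vals.astype(out_dtype)


def _read_vtk(path: Path) -> TetMesh:
    raw = path.read_bytes()
    sc = _VtkScanner(raw, binary=False)
    header = sc.readline()
    if not header.startswith("# vtk"):
        raise MeshFormatError(f"{path}: line 1: not a legacy VTK file")
    sc.readline()  # title
    mode = sc.next_nonempty_line()
    if mode is None or mode.upper() not in ("ASCII", "BINARY"):
        raise MeshFormatError(f"{path}: expected ASCII or BINARY, got {mode!r}")
    sc.binary = mode.upper() == "BINARY"
    dataset = sc.next_nonempty_line()
    if dataset is None or "UNSTRUCTURED_GRID" not in dataset.upper():
        raise MeshFormatError(f"{path}: only UNSTRUCTURED_GRID is supported")

    nodes = cells = cell_types = None
    cell_data: dict[str, np.ndarray] = {}
    point_data: dict[str, np.ndarray] = {}
    n_points = n_cells = 0
    section = None  # current attribute section: 'cell' or 'point'

    def read_attributes(target: dict, n: int, first: str | None) -> str | None:
        line = first
        while line is not None:
            kw = line.split()[0].upper()
            if kw == "SCALARS":
                parts = line.split()
                name, vtk_type = parts[1], parts[2]
                ncomp = int(parts[3]) if len(parts) > 3 else 1
                lookup = sc.next_nonempty_line()  # LOOKUP_TABLE line
                if lookup is None or not lookup.upper().startswith("LOOKUP_TABLE"):
                    raise MeshFormatError(f"{path}: SCALARS {name} missing LOOKUP_TABLE")
                vals = sc.read_values(n * ncomp, vtk_type)
                target[name] = vals if ncomp == 1 else vals.reshape(n, ncomp)
            elif kw == "VECTORS":
                parts = line.split()
                name, vtk_type = parts[1], parts[2]
                target[name] = sc.read_values(n * 3, vtk_type).reshape(n, 3)
            elif kw == "FIELD":
                n_arrays = int(line.split()[-1])
                for _ in range(n_arrays):
                    hdr = sc.next_nonempty_line()
                    parts = hdr.split()
                    name, ncomp, ntup, vtk_type = (
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        parts[3],
                    )
                    vals = sc.read_values(ncomp * ntup, vtk_type)
                    target[name] = vals if ncomp == 1 else vals.reshape(ntup, ncomp)
            elif kw == "LOOKUP_TABLE":
                parts = line.split()
                sc.read_values(int(parts[2]) * 4, "float")
            else:
                return line
            line = sc.next_nonempty_line()
        return None

    line = sc.next_nonempty_line()
    while line is not None:
        kw = line.split()[0].upper()
        if kw == "POINTS":
            _, count, vtk_type = line.split()
            n_points = int(count)
            nodes = sc.read_values(3 * n_points, vtk_type).reshape(n_points, 3)
            line = sc.next_nonempty_line()
        elif kw == "CELLS":
            _, count, total = line.split()
            n_cells = int(count)
            cells = sc.read_values(int(total), "int")
            line = sc.next_nonempty_line()
        elif kw == "CELL_TYPES":
            n = int(line.split()[1])
            cell_types = sc.read_values(n, "int")
            line = sc.next_nonempty_line()
        elif kw == "CELL_DATA":
            line = read_attributes(cell_data, n_cells, sc.next_nonempty_line())
        elif kw == "POINT_DATA":
            line = read_attributes(point_data, n_points, sc.next_nonempty_line())
        else:
            line = sc.next_nonempty_line()

    if nodes is None or cells is None or cell_types is None:
        raise MeshFormatError(f"{path}: missing POINTS/CELLS/CELL_TYPES sections")
    if not np.all(cell_types == 10):
        bad = sorted(set(int(t) for t in cell_types) - {10})
        raise MeshFormatError(
            f"{path}: unsupported non-tetrahedral VTK cell types {bad}"
        )
    cells = cells.reshape(n_cells, 5)
    if not np.all(cells[:, 0] == 4):
        raise MeshFormatError(f"{path}: tetrahedral cells must list 4 points")
    tets = cells[:, 1:].astype(np.int64)

    tags = cell_data.pop("elem_tags", None)
    if tags is None:
        # common alternative names
        for alias in ("tags", "cell_scalars", "material"):
            if alias in cell_data:
                tags = cell_data.pop(alias)
                break
    if tags is None:
        tags = np.ones(n_cells, dtype=np.int64)
    fibres = cell_data.pop("fibres", cell_data.pop("fiber", None))
    sheets = cell_data.pop("sheets", cell_data.pop("sheet", None))
    elem_fields = {k: v for k, v in cell_data.items() if np.ndim(v) == 1}

    return TetMesh(
        nodes=nodes.astype(np.float64),
        tets=tets,
        elem_tags=np.asarray(tags, dtype=np.int64),
        fibres=fibres,
        sheets=sheets,
        node_fields={k: np.asarray(v, float) for k, v in point_data.items() if np.ndim(v) == 1},
        elem_fields=elem_fields,
    )


# ---------------------------------------------------------------------------
# Public I/O entry points
# ---------------------------------------------------------------------------


def _vtk_path(path_prefix: str | Path) -> Path:
    p = Path(path_prefix)
    return p if p.suffix == ".vtk" else p.with_suffix(".vtk")


def read_mesh(path_prefix: str | Path, format: str = "carp_txt") -> TetMesh:
    """Read a mesh in CARP text (``<prefix>.pts/.elem[.lon]``) or VTK format."""
    if format == "carp_txt":
        return _read_carp(Path(path_prefix))
    if format == "vtk":
        return _read_vtk(_vtk_path(path_prefix))
    raise ValueError(f"unknown mesh format {format!r}")


def write_mesh(
    mesh: TetMesh,
    path_prefix: str | Path,
    format: str = "carp_txt",
    write_lon: bool | None = None,
) -> list[Path]:
    """Write a mesh; returns the list of files created.

    For ``carp_txt`` a ``.lon`` file is written whenever fibres are present
    (pass ``write_lon=True`` to force, raising if fibres are missing).
    """
    if format == "carp_txt":
        if write_lon is None:
            write_lon = mesh.fibres is not None
        return _write_carp(mesh, Path(path_prefix), write_lon=write_lon)
    if format == "vtk":
        return _write_vtk(mesh, _vtk_path(path_prefix))
    raise ValueError(f"unknown mesh format {format!r}")
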