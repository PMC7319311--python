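"""Parametric synthetic anatomies for exercising the pipeline at desk scale.

The generators produce tagged tetrahedral meshes with the structure the
processing stages assume — a ventricular wall bounded by endocardium,
epicardium and a base, closed by a valve-plane cap, with an identifiable
apex — without requiring any patient geometry:

* :func:`generate_slab` — structured box split into 6 tetrahedra per cell
  (Kuhn triangulation), uniform fibres; the conduction-velocity verification
  fixture.
* :func:`generate_lv_ellipsoid` — thick-walled truncated half-ellipsoid LV
  meshed on a prolate-style structured grid, capped by a mitral-plane plug
  so the cavity is watertight.  The default geometry is a dilated
  heart-failure-scale LV (end-diastolic cavity volume ≈ 190 mL, 9 mm wall).
* :func:`generate_biventricular` — the LV with an RV free-wall shell
  (default 3.5 mm wall) wrapped around a sector of the LV epicardium, sharing
  the septal wall, plus a tricuspid-plane cap over the RV cavity opening.
* :func:`place_electrode` — endocardial stimulus node label (default naming
  follows the published cohort, ``electrode_endo_rv``; radius 5 mm).

Generation is fully deterministic: the mesh is a pure function of the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import (
    LabelSchema,
    SurfaceSet,
    TetMesh,
    extract_surfaces,
    tet_volumes,
)

__all__ = [
    "SlabSpec",
    "EllipsoidSpec",
    "generate_slab",
    "generate_lv_ellipsoid",
    "generate_biventricular",
    "place_electrode",
]


# ---------------------------------------------------------------------------
# Kuhn triangulation of structured hexahedral blocks
# ---------------------------------------------------------------------------

# corner id = dx + 2*dy + 4*dz
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
_KUHN_TETS = []
for _p in _KUHN_PERMS:
    _v = [0]
    _mask = 0
    for _axis in _p:
        _mask |= 1 << _axis
        _v.append(_mask)
    _KUHN_TETS.append(_v)
_KUHN_TETS = np.array(_KUHN_TETS)  # (6, 4) corner ids


def _grid_to_tets(grid: np.ndarray) -> np.ndarray:
    """Tetrahedralize a structured block of node ids with the Kuhn split.

    ``grid`` has shape (ni+1, nj+1, nk+1); repeated ids encode degenerate
    (collapsed) cell corners, e.g. at poles or seams — the resulting
    zero-volume tetrahedra are removed by the caller via :func:`_clean_tets`.
    The split uses consistent cell diagonals, so neighbouring blocks sharing
    a grid plane of identical node ids mesh conformally.
    """
    c = [
        grid[:-1, :-1, :-1],
        grid[1:, :-1, :-1],
        grid[:-1, 1:, :-1],
        grid[1:, 1:, :-1],
        grid[:-1, :-1, 1:],
        grid[1:, :-1, 1:],
        grid[:-1, 1:, 1:],
        grid[1:, 1:, 1:],
    ]
    corners = np.stack(c, axis=-1).reshape(-1, 8)
    tets = corners[:, _KUHN_TETS]  # (ncell, 6, 4)
    return tets.reshape(-1, 4)


def _clean_tets(nodes: np.ndarray, tets: np.ndarray, tol: float = 1e-9):
    """Drop degenerate tets, orient the rest positively; returns (tets, keep)."""
    distinct = (
        (tets[:, 0] != tets[:, 1])
        & (tets[:, 0] != tets[:, 2])
        & (tets[:, 0] != tets[:, 3])
        & (tets[:, 1] != tets[:, 2])
        & (tets[:, 1] != tets[:, 3])
        & (tets[:, 2] != tets[:, 3])
    )
    tets = tets[distinct]
    vol = tet_volumes(nodes, tets)
    scale = np.abs(vol).max() if len(vol) else 1.0
    keep_vol = np.abs(vol) > tol * scale
    tets = tets[keep_vol]
    vol = vol[keep_vol]
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    keep = distinct.copy()
    keep[distinct] = keep_vol
    return tets, keep


def _compact(nodes: np.ndarray, tets: np.ndarray):
    """Drop unused nodes; returns (nodes, tets, old->new map)."""
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[tets], remap


# ---------------------------------------------------------------------------
# Slab
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlabSpec:
    """Rectangular tissue slab: extents in mm, target edge length, fibre axis."""

    extents: tuple[float, float, float] = (60.0, 20.0, 20.0)
    edge_length: float = 1.0
    fibre: tuple[float, float, float] = (1.0, 0.0, 0.0)
    #: optional boundary face tagged as a one-element-deep fast layer:
    #: one of "x-", "x+", "y-", "y+", "z-", "z+"
    fast_layer_face: str | None = None
    tag: int = 1

    def __post_init__(self) -> None:
        if min(self.extents) <= 0:
            raise ValueError("slab extents must be positive")
        if self.edge_length <= 0:
            raise ValueError("edge length must be positive")
        if self.edge_length > min(self.extents):
            raise ValueError("edge length exceeds the smallest slab extent")


def generate_slab(spec: SlabSpec) -> TetMesh:
    """Structured slab mesh with uniform fibres (6 tets per grid cell)."""
    sx, sy, sz = spec.extents
    h = spec.edge_length
    nx, ny, nz = (max(1, round(s / h)) for s in spec.extents)
    x = np.linspace(0.0, sx, nx + 1)
    y = np.linspace(0.0, sy, ny + 1)
    z = np.linspace(0.0, sz, nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    grid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    tets = _grid_to_tets(grid)
    tets, _ = _clean_tets(nodes, tets)

    f = np.asarray(spec.fibre, dtype=float)
    f = f / np.linalg.norm(f)
    # any unit vector orthogonal to the fibre serves as the sheet direction
    trial = np.array([0.0, 1.0, 0.0]) if abs(f[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    s = trial - np.dot(trial, f) * f
    s /= np.linalg.norm(s)

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        elem_tags=np.full(len(tets), spec.tag, dtype=np.int64),
        fibres=np.tile(f, (len(tets), 1)),
        sheets=np.tile(s, (len(tets), 1)),
    )
    if spec.fast_layer_face is not None:
        axis = {"x": 0, "y": 1, "z": 2}[spec.fast_layer_face[0]]
        value = 0.0 if spec.fast_layer_face[1] == "-" else spec.extents[axis]
        on_face = np.abs(mesh.nodes[:, axis] - value) < 1e-9 * max(spec.extents)
        fast = on_face[mesh.tets].any(axis=1)
        mesh.elem_fields["fast_layer"] = fast.astype(float)
    return mesh


# ---------------------------------------------------------------------------
# Truncated-ellipsoid LV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipsoidSpec:
    """Truncated thick-walled half-ellipsoid ventricle.

    The endocardial surface is the ellipsoid with semi-axes
    ``(a_endo, b_endo, c_endo)`` centred at the origin with the apex at
    ``z = -c``; the wall is offset outward by ``wall_thickness`` on each
    semi-axis, and both shells are truncated by the base plane at
    ``z = truncation_fraction * c_endo``.  Defaults give a dilated LV of
    heart-failure scale (cavity ≈ 190 mL, 9 mm wall).
    """

    a_endo: float = 30.0
    b_endo: float = 30.0
    c_endo: float = 75.0
    wall_thickness: float = 9.0
    truncation_fraction: float = 0.25
    edge_length: float = 1.5
    cap_thickness: float = 2.0
    #: lower bound on transmural element layers (bending fidelity of the wall)
    min_transmural_layers: int = 2
    myocardium_tag: int = 1
    cap_tag: int = 14

    def __post_init__(self) -> None:
        if min(self.a_endo, self.b_endo, self.c_endo) <= 0:
            raise ValueError("endocardial semi-axes must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("epicardial semi-axes must exceed endocardial ones")
        if self.wall_thickness >= min(self.a_endo, self.b_endo, self.c_endo):
            raise ValueError("wall thicker than the endocardial semi-axes (self-intersection)")
        if not -1.0 < self.truncation_fraction < 1.0:
            raise ValueError("truncation plane must intersect both shells")
        if self.edge_length <= 0:
            raise ValueError("target edge length must be positive")

    @property
    def z_cut(self) -> float:
        return self.truncation_fraction * self.c_endo

    def axes(self, t: float | np.ndarray):
        """Semi-axes of the shell at transmural fraction t (0 endo, 1 epi)."""
        th = self.wall_thickness
        return self.a_endo + t * th, self.b_endo + t * th, self.c_endo + t * th

    def analytic_cavity_volume(self) -> float:
        """Exact volume (mm³) of the ellipsoid below the truncation plane."""
        zf = self.truncation_fraction
        return float(
            np.pi * self.a_endo * self.b_endo * self.c_endo * ((zf - zf**3 / 3.0) + 2.0 / 3.0)
        )


def _meridian_arc(a: float, c: float, u0: float, u1: float, n: int = 400) -> float:
    u = np.linspace(u0, u1, n)
    dx = -a * np.sin(u)
    dz = c * np.cos(u)
    ds = np.hypot(dx, dz)
    return float(np.trapezoid(ds, u))


def _shell_grid(spec: EllipsoidSpec):
    """Structured prolate-style node grid of the truncated shell.

    Returns (nodes, grid) where grid[s, v, t] indexes nodes; v wraps
    periodically (grid[:, -1, :] == grid[:, 0, :]) and the apex pole rows
    (s = 0) collapse to one node per transmural layer.
    """
    h = spec.edge_length
    th = spec.wall_thickness
    a_m, b_m, c_m = spec.axes(0.5)
    u_max_endo = float(np.arcsin(np.clip(spec.z_cut / spec.c_endo, -1, 1)))
    arc = _meridian_arc(0.5 * (a_m + b_m), c_m, -np.pi / 2, u_max_endo)
    nu = max(4, int(round(arc / h)))
    circ = 2 * np.pi * np.sqrt(0.5 * (a_m**2 + b_m**2))
    nv = max(8, int(round(circ / h)))
    nt = max(spec.min_transmural_layers, int(round(th / h)))

    s_frac = np.linspace(0.0, 1.0, nu + 1)  # 0 apex .. 1 base
    v = 2 * np.pi * np.arange(nv) / nv
    t = np.linspace(0.0, 1.0, nt + 1)

    a_t, b_t, c_t = spec.axes(t)  # (nt+1,)
    u_max_t = np.arcsin(np.clip(spec.z_cut / c_t, -1, 1))  # (nt+1,)
    # u(s, t): apex (-pi/2) to the truncation latitude of each shell
    U = -np.pi / 2 + s_frac[:, None] * (u_max_t[None, :] + np.pi / 2)  # (nu+1, nt+1)

    cosU, sinU = np.cos(U), np.sin(U)
    x = a_t[None, None, :] * cosU[:, None, :] * np.cos(v)[None, :, None]
    y = b_t[None, None, :] * cosU[:, None, :] * np.sin(v)[None, :, None]
    z = np.broadcast_to((c_t[None, :] * sinU)[:, None, :], x.shape).copy()

    nodes = []
    grid = np.empty((nu + 1, nv + 1, nt + 1), dtype=np.int64)
    next_id = 0
    for k in range(nt + 1):
        # apex pole: one node per layer
        nodes.append([0.0, 0.0, -c_t[k]])
        grid[0, :, k] = next_id
        next_id += 1
        layer = np.column_stack(
            [x[1:, :, k].ravel(), y[1:, :, k].ravel(), z[1:, :, k].ravel()]
        )
        ids = np.arange(next_id, next_id + layer.shape[0]).reshape(nu, nv)
        nodes.append(layer)
        grid[1:, :-1, k] = ids
        grid[1:, -1, k] = ids[:, 0]
        next_id += layer.shape[0]
    nodes = np.vstack([np.atleast_2d(n) for n in nodes])
    return nodes, grid


def _cap_grid(spec: EllipsoidSpec, nodes: np.ndarray, shell_grid: np.ndarray):
    """Valve-plane cap node grid R[r, v, k] covering the full truncation disc.

    Radially: centre pole, interior disc rings, then the shell's top rim
    nodes (shared ids) across the wall; one extruded layer of thickness
    ``cap_thickness`` on top.
    """
    nu1, nv1, nt1 = shell_grid.shape
    nv, nt = nv1 - 1, nt1 - 1
    rim = shell_grid[nu1 - 1, :, :]  # (nv+1, nt+1) ids at z = z_cut
    z0 = spec.z_cut
    ra = spec.a_endo * np.cos(np.arcsin(np.clip(z0 / spec.c_endo, -1, 1)))
    rb = spec.b_endo * np.cos(np.arcsin(np.clip(z0 / spec.c_endo, -1, 1)))
    n_r = max(2, int(round(min(ra, rb) / spec.edge_length)))
    v = 2 * np.pi * np.arange(nv) / nv

    pts = [nodes]
    next_id = nodes.shape[0]
    n_rad = n_r + nt  # radial cell count
    R = np.empty((n_rad + 1, nv + 1, 2), dtype=np.int64)

    # bottom layer (z = z_cut)
    R[0, :, 0] = next_id  # centre pole
    pts.append(np.array([[0.0, 0.0, z0]]))
    next_id += 1
    for j in range(1, n_r):
        q = j / n_r
        ring = np.column_stack([q * ra * np.cos(v), q * rb * np.sin(v), np.full(nv, z0)])
        ids = np.arange(next_id, next_id + nv)
        pts.append(ring)
        R[j, :-1, 0] = ids
        R[j, -1, 0] = ids[0]
        next_id += nv
    for t_i in range(nt + 1):
        R[n_r + t_i, :, 0] = rim[:, t_i]

    # top layer (z = z_cut + cap thickness): all new nodes
    all_bottom = np.vstack([np.atleast_2d(p) for p in pts])
    z_top = z0 + spec.cap_thickness
    top_ids = np.empty_like(R[:, :, 0])
    # centre
    top_ids[0, :] = next_id
    pts.append(np.array([[0.0, 0.0, z_top]]))
    next_id += 1
    for j in range(1, n_rad + 1):
        base_ids = R[j, :-1, 0]
        ring = all_bottom[base_ids].copy()
        ring[:, 2] = z_top
        ids = np.arange(next_id, next_id + nv)
        pts.append(ring)
        top_ids[j, :-1] = ids
        top_ids[j, -1] = ids[0]
        next_id += nv
    R[:, :, 1] = top_ids
    return np.vstack([np.atleast_2d(p) for p in pts]), R


def generate_lv_ellipsoid(spec: EllipsoidSpec) -> tuple[TetMesh, SurfaceSet]:
    """Truncated thick-walled LV with a mitral-plane cap closing the base.

    Returns the mesh (myocardium + cap tags) and its extracted surfaces; the
    epicardial apex node id is exposed as ``node_sets['apex']``.
    """
    nodes, grid = _shell_grid(spec)
    shell_tets = _grid_to_tets(grid)
    nodes, cap = _cap_grid(spec, nodes, grid)
    cap_tets = _grid_to_tets(cap)

    tets = np.vstack([shell_tets, cap_tets])
    tags = np.concatenate(
        [
            np.full(len(shell_tets), spec.myocardium_tag, dtype=np.int64),
            np.full(len(cap_tets), spec.cap_tag, dtype=np.int64),
        ]
    )
    tets, keep = _clean_tets(nodes, tets)
    tags = tags[keep]
    apex_old = grid[0, 0, grid.shape[2] - 1]  # epicardial pole
    nodes, tets, remap = _compact(nodes, tets)

    mesh = TetMesh(nodes=nodes, tets=tets, elem_tags=tags)
    mesh.default_frames()
    schema = LabelSchema.lv_only() if spec.myocardium_tag == 1 else None
    surfaces = extract_surfaces(mesh, schema or LabelSchema.lv_only())
    surfaces.node_sets["apex"] = np.array([remap[apex_old]])
    return mesh, surfaces


# ---------------------------------------------------------------------------
# Biventricular fixture
# ---------------------------------------------------------------------------


def _weld(nodes: np.ndarray, tets: np.ndarray, decimals: int = 6):
    """Merge coincident nodes (coordinates equal after rounding)."""
    key = np.round(nodes, decimals)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_nodes = nodes[first[order]]
    remap = rank[inverse]
    return new_nodes, remap[tets], remap


def generate_biventricular(
    spec_lv: EllipsoidSpec,
    rv_scale: float = 1.55,
    rv_wall_thickness: float = 3.5,
    rv_sector: tuple[float, float] = (0.5 * np.pi, 1.5 * np.pi),
    rv_apex_fraction: float = 0.3,
) -> tuple[TetMesh, SurfaceSet]:
    """LV plus an RV free-wall shell wrapped around a sector of the LV.

    The RV cavity is the crescent between the LV epicardium (the shared
    septal wall) and an RV free-wall shell of thickness ``rv_wall_thickness``
    (default 3.5 mm, the conventional dilation used to recover an RV wall
    from its blood pool).  The free wall merges onto the LV epicardium at the
    sector seams and towards the apex; a tricuspid-plane cap closes the RV
    cavity at the base.  The RV cavity boundary ellipsoid has semi-axes
    ``rv_scale`` times the LV epicardial a/b axes (c is kept at the LV
    epicardial value so the RV stays above the LV apex).
    """
    spec = spec_lv
    nodes, grid = _shell_grid(spec)
    nu1, nv1, nt1 = grid.shape
    nu, nv, nt = nu1 - 1, nv1 - 1, nt1 - 1
    shell_tets = _grid_to_tets(grid)
    nodes, cap = _cap_grid(spec, nodes, grid)
    mv_tets = _grid_to_tets(cap)

    a_epi, b_epi, c_epi = spec.axes(1.0)
    a_rv, b_rv, c_rv = rv_scale * a_epi, rv_scale * b_epi, 1.02 * c_epi
    if min(a_rv - a_epi, b_rv - b_epi) <= 0:
        raise ValueError("RV shell does not clear the LV epicardium (non-overlapping shells)")

    v = 2 * np.pi * np.arange(nv) / nv
    j_sec = np.flatnonzero((v >= rv_sector[0] - 1e-9) & (v <= rv_sector[1] + 1e-9))
    if len(j_sec) < 4:
        raise ValueError("RV sector too narrow for the mesh resolution")
    s0 = int(round(rv_apex_fraction * nu))

    epi_ids = grid[s0:, :, nt]  # (ns+1, nv+1) LV epicardial patch in sector rows
    ns = epi_ids.shape[0] - 1
    nt_rv = max(2, int(round(rv_wall_thickness / spec.edge_length)))

    p_epi = nodes[epi_ids[:, j_sec]]  # (ns+1, njs, 3)
    njs = len(j_sec)
    r_xy = np.linalg.norm(p_epi[:, :, :2], axis=2)
    d = np.zeros_like(p_epi)
    d[:, :, 0] = p_epi[:, :, 0] / np.maximum(r_xy, 1e-12)
    d[:, :, 1] = p_epi[:, :, 1] / np.maximum(r_xy, 1e-12)

    # horizontal-ray intersection with the RV cavity ellipsoid
    A = (d[:, :, 0] / a_rv) ** 2 + (d[:, :, 1] / b_rv) ** 2
    B = 2 * (p_epi[:, :, 0] * d[:, :, 0] / a_rv**2 + p_epi[:, :, 1] * d[:, :, 1] / b_rv**2)
    C = (
        (p_epi[:, :, 0] / a_rv) ** 2
        + (p_epi[:, :, 1] / b_rv) ** 2
        + (p_epi[:, :, 2] / c_rv) ** 2
        - 1.0
    )
    disc = B**2 - 4 * A * C
    tau = np.where(
        (C < 0) & (disc > 0) & (A > 0), (-B + np.sqrt(np.maximum(disc, 0.0))) / (2 * np.maximum(A, 1e-300)), 0.0
    )
    if tau.max() <= spec.edge_length:
        raise ValueError("RV cavity has no clearance from the LV (non-overlapping shells)")

    # Two blends: the cavity gap closes strictly inside the sector so the RV
    # wall attaches to the LV epicardium over a solid band (welded later),
    # keeping the cavity lining disconnected from the outer epicardium; the
    # wall itself only pinches to zero thickness at the very seam columns.
    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return x * x * (3 - 2 * x)

    xi = (v[j_sec] - rv_sector[0]) / (rv_sector[1] - rv_sector[0])  # 0..1 across sector
    margin = 0.12
    wv_gap = smoothstep((xi - margin) / margin) * smoothstep((1 - xi - margin) / margin)
    wv_wall = np.sqrt(np.clip(np.sin(np.pi * xi), 0.0, 1.0))
    s_lin = np.linspace(0, 1, ns + 1)
    ws_gap = smoothstep((s_lin - 0.25) / 0.25)
    ws_wall = smoothstep(s_lin / 0.2)
    W_gap = ws_gap[:, None] * wv_gap[None, :]
    W_wall = ws_wall[:, None] * wv_wall[None, :]
    for W in (W_gap, W_wall):
        W[0, :] = 0.0
        W[:, 0] = 0.0
        W[:, -1] = 0.0

    t_rv = np.linspace(0.0, 1.0, nt_rv + 1)
    offset = (
        W_gap[:, :, None] * tau[:, :, None]
        + W_wall[:, :, None] * t_rv[None, None, :] * rv_wall_thickness
    )
    pos = p_epi[:, :, None, :] + offset[:, :, :, None] * d[:, :, None, :]  # (ns+1, njs, nt_rv+1, 3)

    rv_grid = np.empty((ns + 1, njs, nt_rv + 1), dtype=np.int64)
    next_id = nodes.shape[0]
    new_pts = []
    zero_off = np.abs(offset) < 1e-12
    for si in range(ns + 1):
        for jj in range(njs):
            for ti in range(nt_rv + 1):
                if zero_off[si, jj, ti]:
                    rv_grid[si, jj, ti] = epi_ids[si, j_sec[jj]]
                else:
                    rv_grid[si, jj, ti] = next_id
                    new_pts.append(pos[si, jj, ti])
                    next_id += 1
    nodes = np.vstack([nodes, np.array(new_pts).reshape(-1, 3)])
    rv_tets = _grid_to_tets(rv_grid)

    # tricuspid cap: crescent from the LV epicardial rim over the RV opening
    rim_lv = epi_ids[ns, j_sec]  # LV epi rim ids in sector (z = z_cut)
    rim_rv = rv_grid[ns, :, :]  # (njs, nt_rv+1)
    gap = W_gap[ns, :] * tau[ns, :]
    n_gap = max(2, int(round(np.median(gap[gap > 0]) / spec.edge_length))) if (gap > 0).any() else 2
    z0 = spec.z_cut
    n_rad = n_gap + nt_rv
    TV = np.empty((n_rad + 1, njs, 2), dtype=np.int64)
    TV[0, :, 0] = rim_lv
    p_lv = nodes[rim_lv]
    p_rv0 = nodes[rim_rv[:, 0]]
    new_pts = []
    for j in range(1, n_gap):
        q = j / n_gap
        ring = (1 - q) * p_lv + q * p_rv0
        ring[:, 2] = z0
        same = rim_rv[:, 0] == rim_lv  # collapsed seam columns
        ids = np.empty(njs, dtype=np.int64)
        for jj in range(njs):
            if same[jj]:
                ids[jj] = rim_lv[jj]
            else:
                ids[jj] = next_id
                new_pts.append(ring[jj])
                next_id += 1
        TV[j, :, 0] = ids
    for ti in range(nt_rv + 1):
        TV[n_gap + ti, :, 0] = rim_rv[:, ti]
    # extruded top layer
    if new_pts:
        nodes = np.vstack([nodes, np.array(new_pts)])
    z_top = z0 + spec.cap_thickness
    new_pts = []
    for j in range(n_rad + 1):
        base_ids = TV[j, :, 0]
        ring = nodes[base_ids].copy()
        ring[:, 2] = z_top
        ids = np.arange(next_id, next_id + njs)
        new_pts.append(ring)
        TV[j, :, 1] = ids
        next_id += njs
    nodes = np.vstack([nodes, np.vstack(new_pts)])
    tv_tets = _grid_to_tets(TV)

    tets = np.vstack([shell_tets, mv_tets, rv_tets, tv_tets])
    tags = np.concatenate(
        [
            np.full(len(shell_tets), 1, dtype=np.int64),
            np.full(len(mv_tets), 14, dtype=np.int64),
            np.full(len(rv_tets), 2, dtype=np.int64),
            np.full(len(tv_tets), 15, dtype=np.int64),
        ]
    )
    tets, keep = _clean_tets(nodes, tets)
    tags = tags[keep]
    apex_old = grid[0, 0, nt]
    nodes, tets, remap = _compact(nodes, tets)
    nodes, tets, remap2 = _weld(nodes, tets)

    mesh = TetMesh(nodes=nodes, tets=tets, elem_tags=tags)
    mesh.default_frames()
    surfaces = extract_surfaces(mesh, LabelSchema.biventricular())
    surfaces.node_sets["apex"] = np.array([remap2[remap[apex_old]]])
    return mesh, surfaces


# ---------------------------------------------------------------------------
# Stimulus electrode
# ---------------------------------------------------------------------------


def place_electrode(
    mesh: TetMesh,
    surfaces: SurfaceSet,
    center: np.ndarray,
    radius: float = 5.0,
    surface: str | None = None,
    label: str = "electrode_endo_rv",
) -> np.ndarray:
    """Mark endocardial nodes within ``radius`` mm of ``center`` as stimulated.

    Writes (and returns) a 0/1 node field named ``label`` on the mesh.  With
    ``radius == 0`` the single nearest endocardial node is selected.
    """
    if surface is None:
        surface = "rv_endo" if "rv_endo" in surfaces.surfaces else "lv_endo"
    endo_nodes = surfaces.nodes_of(surface)
    center = np.asarray(center, dtype=float)
    dist = np.linalg.norm(mesh.nodes[endo_nodes] - center, axis=1)
    if radius <= 0:
        chosen = endo_nodes[[int(np.argmin(dist))]]
    else:
        chosen = endo_nodes[dist <= radius]
    if chosen.size == 0:
        raise ValueError(
            f"no {surface} nodes within {radius} mm of {center.tolist()} "
            f"(nearest at {dist.min():.2f} mm)"
        )
    fld = np.zeros(mesh.n_nodes)
    fld[chosen] = 1.0
    mesh.node_fields[label] = fld
    return fld
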