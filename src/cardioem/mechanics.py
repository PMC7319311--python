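"""Quasi-static active-stress finite elasticity on linear tetrahedra.

Total-Lagrangian finite elasticity with single-point quadrature on linear
tetrahedra (exact for constant strain), solved quasi-statically with Newton's
method at each step of the contraction schedule.  The ventricles follow the
transversely isotropic Guccione law

    Ψ(E) = C/2 (e^Q − 1) + κ/2 ln²J,
    Q = b_ff E_ff² + 2 b_fs (E_fs² + E_fn²) + b_ss (E_ss² + E_nn² + 2 E_sn²),

with strains expressed in the fibre/sheet/normal frame; non-ventricular
tissue uses the isochoric neo-Hookean form Ψ = c (Ī₁ − 3) + κ/2 ln²J with
Ī₁ = J^(−2/3) tr C (stress-free at the reference configuration).
Near-incompressibility is enforced by the volumetric penalty with bulk
modulus κ = 1 MPa by default.  Active contraction adds a fibre-direction
second Piola–Kirchhoff stress Ta(t) f₀⊗f₀ with the phenomenological twitch

    Ta = T_peak tanh²(ts/τ_r) tanh²((t_dur − ts)/τ_d),  0 < ts < t_dur,
    ts = t − t_act − t_emd,

driven by the eikonal activation time of each element.  Default parameters
(ventricles): C = 3.0 kPa, b_ff = 19.25, b_fs = 8.75, b_ss = 7.0,
T_peak = 125 kPa, t_emd = 20 ms, t_dur = 550 ms, τ_r = 130 ms, τ_d = 100 ms.

Boundary conditions are omni-directional springs on labelled node sets
(10 kPa/mm at the cropped-vein rings in the four-chamber setting; the base
ring for the lone synthetic LV) and a pericardial penalty on epicardial
displacement normal to the reference surface, scaled by a per-node map in
[0, 1] (an apex-to-base analytic profile by default).  Contraction is free:
zero cavity pressure, zero resistance, and passive atria/vessels.

Units are mm / ms / kPa throughout; nodal forces are kPa·mm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .eikonal_ep import ActivationMap
from .fibres_uvc import cavity_volume, p1_gradients
from .mesh_core import SurfaceSet, TetMesh, triangle_areas, triangle_normals

__all__ = [
    "GuccioneParams",
    "NeoHookeanParams",
    "ActiveTensionParams",
    "MaterialConfig",
    "BoundaryConditions",
    "ContractionSchedule",
    "KinematicsState",
    "MotionTrace",
    "MechanicsProblem",
    "active_tension",
    "passive_stress",
    "run_contraction",
    "ef_sv",
    "default_lv_bcs",
    "NonAdmissibleState",
]


class NonAdmissibleState(RuntimeError):
    """Raised when a deformation state has non-positive Jacobian."""


# ---------------------------------------------------------------------------
# Material parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuccioneParams:
    """Transversely isotropic exponential law; defaults are the heart-failure
    ventricular values (C in kPa, exponents dimensionless, κ in kPa)."""

    C: float = 3.0
    b_ff: float = 19.25
    b_fs: float = 8.75
    b_ss: float = 7.0
    kappa: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.C, self.b_ff, self.b_fs, self.b_ss, self.kappa) <= 0:
            raise ValueError("Guccione parameters must be positive")

    @classmethod
    def healthy(cls) -> "GuccioneParams":
        """Healthy-myocardium stiffness variant."""
        return cls(C=1.7, b_ff=8.0, b_fs=4.0, b_ss=3.0)


@dataclass(frozen=True)
class NeoHookeanParams:
    """Isochoric neo-Hookean law, Ψ = c (Ī₁ − 3) + κ/2 ln²J (kPa)."""

    c: float
    kappa: float = 1000.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.kappa <= 0:
            raise ValueError("neo-Hookean parameters must be positive")


#: Reference per-region neo-Hookean stiffnesses (kPa).
NEO_HOOKEAN_DEFAULTS = {
    "atria": 7.45,
    "aorta": 26.66,
    "pulmonary_artery": 3.7,
    "valve_planes": 1000.0,
    "veins_rings": 7.45,
}


@dataclass(frozen=True)
class ActiveTensionParams:
    """Phenomenological twitch parameters (kPa / ms)."""

    T_peak: float = 125.0
    t_emd: float = 20.0
    t_dur: float = 550.0
    tau_r: float = 130.0
    tau_d: float = 100.0

    def __post_init__(self) -> None:
        if min(self.T_peak, self.t_emd, self.t_dur, self.tau_r, self.tau_d) <= 0:
            raise ValueError("active-tension parameters must be positive")


def active_tension(t, t_act, p: ActiveTensionParams = ActiveTensionParams()):
    """Active tension Ta(t) in kPa; total function, zero outside (0, t_dur).

    ``t`` and ``t_act`` broadcast; ts = t − t_act − t_emd.
    """
    t = np.asarray(t, dtype=float)
    t_act = np.asarray(t_act, dtype=float)
    ts = t - t_act - p.t_emd
    with np.errstate(invalid="ignore"):
        ta = (
            p.T_peak
            * np.tanh(ts / p.tau_r) ** 2
            * np.tanh((p.t_dur - ts) / p.tau_d) ** 2
        )
    out = np.where((ts > 0) & (ts < p.t_dur) & np.isfinite(ts), ta, 0.0)
    return out if out.ndim else float(out)


@dataclass
class MaterialConfig:
    """Per-tag passive laws and active-tension parameters.

    ``passive`` maps element tag → Guccione or neo-Hookean parameters;
    ``active`` maps tag → twitch parameters (only contracting regions —
    the ventricles — appear here; everything else stays passive).
    """

    passive: dict[int, GuccioneParams | NeoHookeanParams]
    active: dict[int, ActiveTensionParams] = field(default_factory=dict)

    @classmethod
    def four_chamber_defaults(cls) -> "MaterialConfig":
        g = GuccioneParams()
        a = ActiveTensionParams()
        nh = NEO_HOOKEAN_DEFAULTS
        passive: dict[int, GuccioneParams | NeoHookeanParams] = {1: g, 2: g}
        for tag in (3, 4):
            passive[tag] = NeoHookeanParams(c=nh["atria"])
        passive[5] = NeoHookeanParams(c=nh["aorta"])
        passive[6] = NeoHookeanParams(c=nh["pulmonary_artery"])
        for tag in range(7, 14):
            passive[tag] = NeoHookeanParams(c=nh["veins_rings"])
        for tag in range(14, 25):
            passive[tag] = NeoHookeanParams(c=nh["valve_planes"])
        return cls(passive=passive, active={1: a, 2: a})

    @classmethod
    def lv_defaults(cls) -> "MaterialConfig":
        return cls(
            passive={1: GuccioneParams(), 14: NeoHookeanParams(c=NEO_HOOKEAN_DEFAULTS["valve_planes"])},
            active={1: ActiveTensionParams()},
        )

    @classmethod
    def biventricular_defaults(cls) -> "MaterialConfig":
        g = GuccioneParams()
        nh = NeoHookeanParams(c=NEO_HOOKEAN_DEFAULTS["valve_planes"])
        a = ActiveTensionParams()
        return cls(passive={1: g, 2: g, 14: nh, 15: nh}, active={1: a, 2: a})


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------


@dataclass
class BoundaryConditions:
    """Spring and pericardial penalties anchored to the reference (ED) state.

    ``springs``: list of (node indices, stiffness kPa/mm, nodal areas mm²) —
    omni-directional restraints.  ``pericardium``: (node indices, reference
    outward normals, penalty map in [0,1], stiffness kPa/mm, nodal areas) —
    penalises displacement normal to the epicardial surface.
    """

    springs: list[tuple[np.ndarray, float, np.ndarray]] = field(default_factory=list)
    pericardium: tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for nodes, k, areas in self.springs:
            if k < 0:
                raise ValueError("spring stiffness must be non-negative")
        if self.pericardium is not None:
            _, _, pmap, k, _ = self.pericardium
            if k < 0:
                raise ValueError("pericardial stiffness must be non-negative")
            if (pmap < -1e-12).any() or (pmap > 1 + 1e-12).any():
                raise ValueError("pericardial penalty map must lie in [0, 1]")


def _nodal_areas(mesh: TetMesh, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lumped nodal areas and area-weighted outward normals of a surface."""
    a = triangle_areas(mesh.nodes, tris)
    n = triangle_normals(mesh.nodes, tris)
    nodes = np.unique(tris)
    idx = np.searchsorted(nodes, tris)
    areas = np.zeros(len(nodes))
    normals = np.zeros((len(nodes), 3))
    for i in range(3):
        np.add.at(areas, idx[:, i], a / 3.0)
        np.add.at(normals, idx[:, i], (a / 3.0)[:, None] * n)
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    return nodes, areas, normals


def default_lv_bcs(
    mesh: TetMesh,
    surfaces: SurfaceSet,
    k_spring: float = 10.0,
    k_peri: float = 1.0,
) -> BoundaryConditions:
    """Boundary conditions for the lone synthetic LV.

    Omni-directional springs (10 kPa/mm) on the base node set stand in for
    the vein-ring anchors of the four-chamber setting; the epicardium gets a
    normal-direction pericardial penalty scaled by an analytic apex-to-base
    profile (1 at the apex, 0 at the base).
    """
    all_tris = np.vstack([surfaces.surfaces[n] for n in surfaces.surfaces])
    bnodes, bareas, _ = _nodal_areas(mesh, all_tris)
    base = surfaces.node_sets["base"]
    base_areas = bareas[np.searchsorted(bnodes, base)]
    springs = [(base, k_spring, base_areas)]

    pericardium = None
    if k_peri > 0 and "epicardium" in surfaces.surfaces:
        enodes, eareas, enormals = _nodal_areas(mesh, surfaces.surfaces["epicardium"])
        z = mesh.nodes[enodes][:, 2]
        zmin, zmax = z.min(), z.max()
        pmap = np.clip((zmax - z) / max(zmax - zmin, 1e-12), 0.0, 1.0)
        pericardium = (enodes, enormals, pmap, k_peri, eareas)
    return BoundaryConditions(springs=springs, pericardium=pericardium)


# ---------------------------------------------------------------------------
# Kinematics and stress
# ---------------------------------------------------------------------------


@dataclass
class KinematicsState:
    """Per-element deformation state at one configuration."""

    u: np.ndarray  # (n, 3) nodal displacements (mm)
    F: np.ndarray  # (m, 3, 3) deformation gradient
    J: np.ndarray  # (m,) det F
    E: np.ndarray  # (m, 3, 3) Green–Lagrange strain

    def fibre_strains(self, rotations: np.ndarray) -> dict[str, np.ndarray]:
        """Strain components in the fibre frame (E_ff, E_fs, E_fn, E_ss, E_sn, E_nn)."""
        E_loc = np.einsum("ekI,ekl,elJ->eIJ", rotations, self.E, rotations)
        return {
            "E_ff": E_loc[:, 0, 0],
            "E_fs": E_loc[:, 0, 1],
            "E_fn": E_loc[:, 0, 2],
            "E_ss": E_loc[:, 1, 1],
            "E_sn": E_loc[:, 1, 2],
            "E_nn": E_loc[:, 2, 2],
        }


_I4S = 0.5 * (
    np.einsum("ik,jl->ijkl", np.eye(3), np.eye(3))
    + np.einsum("il,jk->ijkl", np.eye(3), np.eye(3))
)


class MechanicsProblem:
    """Assembled quasi-static elasticity problem on a tagged mesh.

    Precomputes shape-function gradients, fibre-frame rotations and per-tag
    material arrays; exposes residual/tangent assembly, energy evaluation and
    the Newton solve used by :func:`run_contraction`.
    """

    def __init__(
        self,
        mesh: TetMesh,
        materials: MaterialConfig,
        bcs: BoundaryConditions | None = None,
    ):
        if mesh.fibres is None or mesh.sheets is None:
            raise ValueError("mechanics requires fibre and sheet vectors")
        self.mesh = mesh
        self.materials = materials
        self.bcs = bcs or BoundaryConditions()
        self.gradN, self.vol = p1_gradients(mesh)
        if (self.vol <= 0).any():
            raise ValueError("mesh has non-positive element volumes")

        f = mesh.fibres
        s = mesh.sheets
        n = np.cross(f, s)
        self.R = np.stack([f, s, n], axis=2)  # columns f, s, n

        tags = np.unique(mesh.elem_tags)
        missing = [int(t) for t in tags if int(t) not in materials.passive]
        if missing:
            raise ValueError(f"no passive material for tags {missing}")
        m = mesh.n_elems
        self.is_guccione = np.zeros(m, dtype=bool)
        self.gC = np.zeros(m)
        self.gW = np.zeros((m, 3, 3))  # exponent weight matrix per element
        self.nh_c = np.zeros(m)
        self.kappa = np.zeros(m)
        for tag in tags:
            sel = mesh.elem_tags == tag
            p = materials.passive[int(tag)]
            if isinstance(p, GuccioneParams):
                self.is_guccione[sel] = True
                self.gC[sel] = p.C
                W = np.array(
                    [
                        [p.b_ff, p.b_fs, p.b_fs],
                        [p.b_fs, p.b_ss, p.b_ss],
                        [p.b_fs, p.b_ss, p.b_ss],
                    ]
                )
                self.gW[sel] = W
                self.kappa[sel] = p.kappa
            else:
                self.nh_c[sel] = p.c
                self.kappa[sel] = p.kappa

        self.active_mask = np.isin(mesh.elem_tags, list(materials.active))
        self.f0 = f
        self.ff0 = np.einsum("ei,ej->eij", f, f)

        # sparse assembly pattern: dof index per (element, vertex, component)
        dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 12)
        self._rows = np.repeat(dof, 12, axis=1).ravel()
        self._cols = np.tile(dof, (1, 12)).ravel()
        self._dof = dof
        self.n_dof = 3 * mesh.n_nodes

    # -- kinematics --------------------------------------------------------

    def kinematics(self, u: np.ndarray) -> KinematicsState:
        u = np.asarray(u, dtype=float).reshape(self.mesh.n_nodes, 3)
        F = np.eye(3)[None] + np.einsum("eai,eaJ->eiJ", u[self.mesh.tets], self.gradN)
        J = np.linalg.det(F)
        E = 0.5 * (np.einsum("ekI,ekJ->eIJ", F, F) - np.eye(3)[None])
        return KinematicsState(u=u, F=F, J=J, E=E)

    # -- constitutive law --------------------------------------------------

    def stress(
        self,
        state: KinematicsState,
        ta_elem: np.ndarray | None = None,
        tangent: bool = False,
    ):
        """Second Piola–Kirchhoff stress, energy density and (optionally) the
        material tangent ∂S/∂E per element.  Raises on J ≤ 0."""
        if (state.J <= 0).any():
            raise NonAdmissibleState(
                f"{int((state.J <= 0).sum())} elements with non-positive Jacobian"
            )
        m = self.mesh.n_elems
        S = np.zeros((m, 3, 3))
        W = np.zeros(m)
        CC = np.zeros((m, 3, 3, 3, 3)) if tangent else None

        # Guccione isochoric part (in the fibre frame, rotated back)
        g = self.is_guccione
        if g.any():
            R = self.R[g]
            E_loc = np.einsum("ekI,ekl,elJ->eIJ", R, state.E[g], R)
            Wm = self.gW[g]
            Q = np.einsum("eIJ,eIJ->e", Wm, E_loc**2)
            Q = np.minimum(Q, 200.0)  # overflow guard; caller cuts the step
            B = Wm * E_loc
            expQ = np.exp(Q)
            S_loc = self.gC[g, None, None] * expQ[:, None, None] * B
            S[g] += np.einsum("eiI,eIJ,ejJ->eij", R, S_loc, R)
            W[g] += 0.5 * self.gC[g] * (expQ - 1.0)
            if tangent:
                CC_loc = self.gC[g, None, None, None, None] * expQ[:, None, None, None, None] * (
                    Wm[:, :, :, None, None] * _I4S[None]
                    + 2.0 * np.einsum("eIJ,eKL->eIJKL", B, B)
                )
                t1 = np.einsum("eiI,eIJKL->eiJKL", R, CC_loc)
                t2 = np.einsum("ejJ,eiJKL->eijKL", R, t1)
                t3 = np.einsum("ekK,eijKL->eijkL", R, t2)
                CC[g] += np.einsum("elL,eijkL->eijkl", R, t3)

        # neo-Hookean isochoric part, Ψ = c (Ī₁ − 3) with Ī₁ = J^(-2/3) tr C
        # (stress-free at the reference configuration)
        nh = ~g
        if nh.any():
            Cn = np.einsum("ekI,ekJ->eIJ", state.F[nh], state.F[nh])
            Cni = np.linalg.inv(Cn)
            I1 = np.einsum("eII->e", Cn)
            a = state.J[nh] ** (-2.0 / 3.0)
            c = self.nh_c[nh]
            S[nh] += (
                2.0
                * (c * a)[:, None, None]
                * (np.eye(3)[None] - (I1 / 3.0)[:, None, None] * Cni)
            )
            W[nh] += c * (a * I1 - 3.0)
            if tangent:
                ca = 4.0 * c * a
                dd = np.eye(3)[None] * np.ones(len(c))[:, None, None]
                CC[nh] += ca[:, None, None, None, None] * (
                    -(1.0 / 3.0)
                    * (
                        np.einsum("eKL,eIJ->eIJKL", Cni, dd)
                        + np.einsum("eKL,eIJ->eIJKL", dd, Cni)
                    )
                    + (I1 / 9.0)[:, None, None, None, None]
                    * np.einsum("eIJ,eKL->eIJKL", Cni, Cni)
                    + (I1 / 6.0)[:, None, None, None, None]
                    * (
                        np.einsum("eIK,eJL->eIJKL", Cni, Cni)
                        + np.einsum("eIL,eJK->eIJKL", Cni, Cni)
                    )
                )

        # volumetric penalty (all elements)
        Cm = np.einsum("ekI,ekJ->eIJ", state.F, state.F)
        Cinv = np.linalg.inv(Cm)
        lnJ = np.log(state.J)
        S += self.kappa[:, None, None] * lnJ[:, None, None] * Cinv
        W += 0.5 * self.kappa * lnJ**2
        if tangent:
            CC += self.kappa[:, None, None, None, None] * np.einsum(
                "eIJ,eKL->eIJKL", Cinv, Cinv
            )
            CC -= (self.kappa * lnJ)[:, None, None, None, None] * (
                np.einsum("eIK,eJL->eIJKL", Cinv, Cinv)
                + np.einsum("eIL,eJK->eIJKL", Cinv, Cinv)
            )

        # active stress along the reference fibre direction
        if ta_elem is not None:
            ta = np.where(self.active_mask, ta_elem, 0.0)
            S += ta[:, None, None] * self.ff0
            E_ff = np.einsum("eij,eij->e", state.E, self.ff0)
            W += ta * E_ff

        return (S, W, CC) if tangent else (S, W)

    # -- energy / residual / tangent --------------------------------------

    def energy(self, u: np.ndarray, ta_elem: np.ndarray | None = None, include_bcs: bool = True) -> float:
        state = self.kinematics(u)
        _, W = self.stress(state, ta_elem)
        total = float((W * self.vol).sum())
        if include_bcs:
            total += self._bc_energy(state.u)
        return total

    def _bc_energy(self, u: np.ndarray) -> float:
        total = 0.0
        for nodes, k, areas in self.bcs.springs:
            total += 0.5 * k * float((areas * (u[nodes] ** 2).sum(axis=1)).sum())
        if self.bcs.pericardium is not None:
            nodes, normals, pmap, k, areas = self.bcs.pericardium
            un = np.einsum("ij,ij->i", u[nodes], normals)
            total += 0.5 * k * float((areas * pmap * un**2).sum())
        return total

    def assemble(self, u: np.ndarray, ta_elem: np.ndarray | None = None, tangent: bool = True):
        """Residual (internal force, n_dof) and consistent tangent (sparse)."""
        state = self.kinematics(u)
        if tangent:
            S, _, CC = self.stress(state, ta_elem, tangent=True)
        else:
            S, _ = self.stress(state, ta_elem)
        P = np.einsum("eiI,eIJ->eiJ", state.F, S)
        fe = np.einsum("eiJ,eaJ,e->eai", P, self.gradN, self.vol)  # (m, 4, 3)
        r = np.zeros(self.n_dof)
        np.add.at(r, self._dof.ravel(), fe.reshape(self.mesh.n_elems, 12).ravel())

        K = None
        if tangent:
            H = np.einsum("eaK,eiI->eaiIK", self.gradN, state.F)
            T = np.einsum("eIKML,ebjML->eIKbj", CC, H)
            Kmat = np.einsum("eaiIK,eIKbj->eaibj", H, T)
            Kgeo = np.einsum("eaI,eIJ,ebJ->eab", self.gradN, S, self.gradN)
            Ke = Kmat + Kgeo[:, :, None, :, None] * np.eye(3)[None, None, :, None, :]
            Ke = Ke.reshape(self.mesh.n_elems, 12, 12) * self.vol[:, None, None]
            K = coo_matrix(
                (Ke.ravel(), (self._rows, self._cols)), shape=(self.n_dof, self.n_dof)
            ).tocsc()

        r, K = self._bc_contributions(state.u, r, K, tangent)
        return (r, K) if tangent else r

    def _bc_contributions(self, u, r, K, tangent):
        rows, cols, vals = [], [], []
        for nodes, k, areas in self.bcs.springs:
            coef = k * areas
            r[(3 * nodes[:, None] + np.arange(3)).ravel()] += (
                coef[:, None] * u[nodes]
            ).ravel()
            if tangent:
                dof = (3 * nodes[:, None] + np.arange(3)).ravel()
                rows.append(dof)
                cols.append(dof)
                vals.append(np.repeat(coef, 3))
        if self.bcs.pericardium is not None:
            nodes, normals, pmap, k, areas = self.bcs.pericardium
            coef = k * areas * pmap
            un = np.einsum("ij,ij->i", u[nodes], normals)
            force = coef[:, None] * un[:, None] * normals
            r[(3 * nodes[:, None] + np.arange(3)).ravel()] += force.ravel()
            if tangent:
                blk = coef[:, None, None] * np.einsum("ij,ik->ijk", normals, normals)
                dof = 3 * nodes[:, None] + np.arange(3)
                rows.append(np.repeat(dof, 3, axis=1).ravel())
                cols.append(np.tile(dof, (1, 3)).ravel())
                vals.append(blk.ravel())
        if tangent and rows:
            K = K + coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.n_dof, self.n_dof),
            ).tocsc()
        return r, K

    # -- Newton solve ------------------------------------------------------

    def newton_solve(
        self,
        u0: np.ndarray,
        ta_elem: np.ndarray | None,
        tol: float = 1e-6,
        max_iter: int = 20,
        abs_tol: float = 1e-9,
    ) -> tuple[np.ndarray, bool, int]:
        """Solve the quasi-static equilibrium from the initial guess ``u0``.

        Convergence: ||r|| ≤ tol · max(||r_initial||, abs_tol-scale).  A
        backtracking line search keeps the state admissible (J > 0).
        Returns (u, converged, iterations).
        """
        u = u0.reshape(-1).copy()
        r, K = self.assemble(u, ta_elem)
        r0 = np.linalg.norm(r)
        scale = max(r0, abs_tol)
        if r0 <= abs_tol:
            return u, True, 0
        for it in range(1, max_iter + 1):
            du = splu(K, permc_spec="MMD_AT_PLUS_A").solve(-r)
            # backtracking: keep the state admissible and the residual decreasing
            alpha = 1.0
            accepted = None
            r_norm = np.linalg.norm(r)
            for _ in range(14):
                try:
                    r_new, K_new = self.assemble(u + alpha * du, ta_elem)
                except NonAdmissibleState:
                    alpha *= 0.5
                    continue
                if np.linalg.norm(r_new) <= (1.0 - 1e-4 * alpha) * r_norm or alpha <= 1e-3:
                    accepted = (r_new, K_new, alpha)
                    break
                alpha *= 0.5
            if accepted is None:
                return u, False, it
            r, K, alpha = accepted
            u = u + alpha * du
            if np.linalg.norm(r) <= tol * scale:
                return u, True, it
        return u, False, max_iter


# ---------------------------------------------------------------------------
# Contraction driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContractionSchedule:
    """Time discretisation of the single-beat free contraction.

    The mechanics marches quasi-statically with ``dt`` (ms) steps over
    ``t_end``; on Newton failure the step is halved down to ``dt_min`` before
    aborting.  Defaults cover the full twitch (t_emd + t_dur + margin).
    """

    dt: float = 5.0
    t_end: float = 700.0
    dt_min: float = 0.3125
    newton_tol: float = 1e-6
    max_newton: int = 20
    snapshot_every: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0 or self.dt_min <= 0:
            raise ValueError("schedule times must be positive")


@dataclass
class MotionTrace:
    """Displacement snapshots and chamber-volume series from a contraction."""

    times: np.ndarray
    volumes: dict[str, np.ndarray]
    snapshots: list[tuple[float, np.ndarray]]
    j_frac_within_5pct: np.ndarray  # fraction of elements with |J-1| <= 0.05
    peak_time: float
    peak_u: np.ndarray


def elem_activation_times(mesh: TetMesh, amap: ActivationMap) -> np.ndarray:
    """Element activation time: mean of the finite nodal arrival times."""
    t = amap.t_act[mesh.tets]
    fin = np.isfinite(t)
    cnt = fin.sum(axis=1)
    sums = np.where(fin, t, 0.0).sum(axis=1)
    return np.where(cnt > 0, sums / np.maximum(cnt, 1), np.inf)


def run_contraction(
    mesh: TetMesh,
    surfaces: SurfaceSet,
    materials: MaterialConfig,
    bcs: BoundaryConditions,
    activation: ActivationMap,
    schedule: ContractionSchedule = ContractionSchedule(),
    chambers: tuple[str, ...] = ("lv",),
) -> MotionTrace:
    """Free active contraction of one beat (zero pressure / zero resistance).

    The reference configuration is the input end-diastolic geometry.  At each
    step the active tension per element follows the twitch evaluated at the
    element activation time, and the quasi-static equilibrium is re-solved
    starting from the previous displacement.  Returns chamber-volume series,
    the incompressibility record and displacement snapshots.
    """
    prob = MechanicsProblem(mesh, materials, bcs)
    act_params = {t: p for t, p in materials.active.items()}
    if not act_params:
        raise ValueError("no active regions configured")
    t_act = elem_activation_times(mesh, activation)
    vent = prob.active_mask
    if not np.isfinite(t_act[vent]).all():
        raise ValueError("activation map is not finite on the contracting region")

    def ta_at(t: float) -> np.ndarray:
        ta = np.zeros(mesh.n_elems)
        for tag, p in act_params.items():
            sel = mesh.elem_tags == tag
            ta[sel] = active_tension(t, t_act[sel], p)
        return ta

    times = [0.0]
    vols = {ch: [cavity_volume(surfaces, ch)] for ch in chambers}
    jfrac = [1.0]
    snapshots = [(0.0, np.zeros((mesh.n_nodes, 3)))]
    u = np.zeros(prob.n_dof)
    min_vol = vols[chambers[0]][0]
    peak_time, peak_u = 0.0, np.zeros((mesh.n_nodes, 3))

    t = 0.0
    step = 0
    dt = schedule.dt
    while t < schedule.t_end - 1e-9:
        t_next = min(t + dt, schedule.t_end)
        ta = ta_at(t_next)
        u_new, ok, _ = prob.newton_solve(
            u, ta, tol=schedule.newton_tol, max_iter=schedule.max_newton
        )
        if not ok:
            if dt / 2 >= schedule.dt_min:
                dt /= 2
                continue
            raise RuntimeError(
                f"Newton failed at t={t_next:.1f} ms below the minimum step; "
                f"state: |u|_max={np.abs(u).max():.3g} mm"
            )
        u = u_new
        t = t_next
        step += 1
        dt = min(dt * 2, schedule.dt) if dt < schedule.dt else schedule.dt
        disp = u.reshape(-1, 3)
        times.append(t)
        for ch in chambers:
            vols[ch].append(cavity_volume(surfaces, ch, displacement=disp))
        state = prob.kinematics(u)
        jfrac.append(float((np.abs(state.J[vent] - 1.0) <= 0.05).mean()))
        if vols[chambers[0]][-1] < min_vol:
            min_vol = vols[chambers[0]][-1]
            peak_time = t
            peak_u = disp.copy()
        if step % schedule.snapshot_every == 0:
            snapshots.append((t, disp.copy()))

    return MotionTrace(
        times=np.array(times),
        volumes={ch: np.array(v) for ch, v in vols.items()},
        snapshots=snapshots,
        j_frac_within_5pct=np.array(jfrac),
        peak_time=peak_time,
        peak_u=peak_u,
    )


def ef_sv(trace: MotionTrace) -> dict[str, dict[str, float]]:
    """Ejection fraction (%) and stroke volume (mL) per chamber.

    SV = EDV − min volume over the beat; EF = 100 · SV / EDV.
    """
    out = {}
    for ch, v in trace.volumes.items():
        edv = float(v[0])
        if edv <= 0:
            raise ValueError(f"zero end-diastolic volume for chamber {ch!r}")
        sv = edv - float(v.min())
        out[ch] = {"EDV_mL": edv, "SV_mL": sv, "EF_pct": 100.0 * sv / edv}
    return out


# ---------------------------------------------------------------------------
# Spec-level convenience wrappers
# ---------------------------------------------------------------------------


def passive_stress(
    mesh: TetMesh,
    materials: MaterialConfig,
    u: np.ndarray,
):
    """Per-element passive PK2 stress and strain energy at displacement u."""
    prob = MechanicsProblem(mesh, materials)
    state = prob.kinematics(u)
    S, W = prob.stress(state)
    return S, W * prob.vol
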