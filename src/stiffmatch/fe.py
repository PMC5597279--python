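"""Small-strain finite elements on regular voxel grids.

Trilinear 8-node hexahedra on an axis-aligned voxel grid (anisotropic voxel
spacing allowed), 2x2x2 Gauss quadrature, assembled into scipy sparse CSR.
Dirichlet conditions are imposed by elimination; the linear solver is
conjugate gradients with diagonal (Jacobi) preconditioning, switching to a
sparse direct factorization for small systems.  Superelastic materials are
handled by an incremental Newton scheme with a numerically consistent tangent
evaluated at every Gauss point.  Units: N, mm, MPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .materials import LinearElastic, SMAParams, sma_update

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelMesh",
    "LoadCase",
    "FieldResult",
    "Interface",
    "hex_B",
    "assemble_and_solve_linear",
    "solve_incremental_sma",
    "tie_and_contact_interface",
    "von_mises",
]

_GP = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float,
) / np.sqrt(3.0)
_NODE_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def _dN_dxi(xi: np.ndarray) -> np.ndarray:
    """Shape-function gradients (8 nodes x 3) at local coordinates ``xi``."""
    g = np.empty((8, 3))
    for a in range(8):
        sa = _NODE_XI[a]
        g[a, 0] = 0.125 * sa[0] * (1 + sa[1] * xi[1]) * (1 + sa[2] * xi[2])
        g[a, 1] = 0.125 * sa[1] * (1 + sa[0] * xi[0]) * (1 + sa[2] * xi[2])
        g[a, 2] = 0.125 * sa[2] * (1 + sa[0] * xi[0]) * (1 + sa[1] * xi[1])
    return g


def _B_at(xi: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Strain-displacement matrix (6 x 24), engineering Voigt, at ``xi``."""
    dN = _dN_dxi(xi) * (2.0 / np.asarray(spacing))  # physical gradients
    B = np.zeros((6, 24))
    for a in range(8):
        ax, ay, az = dN[a]
        c = 3 * a
        B[0, c] = ax
        B[1, c + 1] = ay
        B[2, c + 2] = az
        B[3, c + 1] = az
        B[3, c + 2] = ay
        B[4, c] = az
        B[4, c + 2] = ax
        B[5, c] = ay
        B[5, c + 1] = ax
    return B


def hex_B(spacing: Sequence[float]) -> tuple[np.ndarray, np.ndarray, float]:
    """(B at the 8 Gauss points (8,6,24), B at the centroid (6,24), Gauss
    weight = detJ) for a voxel of the given spacing."""
    Bg = np.stack([_B_at(xi, spacing) for xi in _GP])
    Bc = _B_at(np.zeros(3), spacing)
    w = np.prod(spacing) / 8.0
    return Bg, Bc, float(w)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises stress of Voigt stress arrays (..., 6)."""
    s = np.asarray(stress)
    d = (
        0.5
        * (
            (s[..., 0] - s[..., 1]) ** 2
            + (s[..., 1] - s[..., 2]) ** 2
            + (s[..., 2] - s[..., 0]) ** 2
        )
        + 3.0 * (s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2)
    )
    return np.sqrt(np.maximum(d, 0.0))


class VoxelMesh:
    """Regular hexahedral mesh of a voxel indicator field.

    ``mat`` is an (nx, ny, nz) integer array of material tags; -1 marks void.
    Nodes are created only where solid voxels need them.  ``spacing`` is the
    voxel edge length per axis (mm).
    """

    def __init__(
        self,
        mat: np.ndarray,
        spacing: Sequence[float] | float = 1.0,
        check_connectivity: bool = True,
        scale: np.ndarray | None = None,
    ):
        mat = np.asarray(mat)
        if mat.ndim != 3:
            raise ValueError("mat must be a 3D array of material tags")
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        self.mat = mat.astype(np.int32)
        self.spacing = tuple(float(s) for s in spacing)
        self.shape = mat.shape
        solid = mat >= 0
        if not solid.any():
            raise ValueError("mesh has no solid voxels")
        if check_connectivity:
            _, ncomp = ndimage.label(solid, ndimage.generate_binary_structure(3, 1))
            if ncomp > 1:
                raise ValueError(
                    f"solid region has {ncomp} disconnected face-connected "
                    "components; the stiffness matrix would be singular"
                )

        nx, ny, nz = self.shape
        ii, jj, kk = np.nonzero(solid)
        self.elem_voxel = np.stack([ii, jj, kk], axis=1)
        self.elem_mat = mat[ii, jj, kk]
        # optional per-voxel stiffness scale (composite-voxel discretization)
        self.elem_scale = None if scale is None else np.asarray(scale)[ii, jj, kk].astype(float)
        # grid node index -> compressed node id
        off = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
             [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]]
        )
        corner = self.elem_voxel[:, None, :] + off[None, :, :]  # (ne, 8, 3)
        flat = np.ravel_multi_index(
            (corner[..., 0], corner[..., 1], corner[..., 2]),
            (nx + 1, ny + 1, nz + 1),
        )
        used, conn = np.unique(flat, return_inverse=True)
        self.conn = conn.reshape(-1, 8).astype(np.int64)
        gx, gy, gz = np.unravel_index(used, (nx + 1, ny + 1, nz + 1))
        self.coords = np.stack(
            [gx * self.spacing[0], gy * self.spacing[1], gz * self.spacing[2]], axis=1
        ).astype(float)
        self._grid_to_node = dict(zip(used.tolist(), range(len(used))))
        self.n_nodes = len(used)
        self.n_elems = len(self.conn)

    # -- geometry queries ----------------------------------------------------
    @property
    def ndof(self) -> int:
        return 3 * self.n_nodes

    @property
    def solid_volume(self) -> float:
        return self.n_elems * float(np.prod(self.spacing))

    def nodes_where(self, predicate) -> np.ndarray:
        """Node ids whose coordinates satisfy ``predicate(x, y, z)``."""
        m = predicate(self.coords[:, 0], self.coords[:, 1], self.coords[:, 2])
        return np.nonzero(m)[0]

    def face_nodes(self, axis: int, side: int, tol: float = 1e-9) -> np.ndarray:
        """Nodes on a bounding face (side 0 = min, 1 = max of ``axis``)."""
        lo = self.coords[:, axis].min()
        hi = self.coords[:, axis].max()
        target = hi if side else lo
        return np.nonzero(np.abs(self.coords[:, axis] - target) < tol)[0]

    def elems_where(self, predicate) -> np.ndarray:
        """Element ids whose voxel centres satisfy ``predicate(x, y, z)``."""
        c = (self.elem_voxel + 0.5) * np.asarray(self.spacing)
        return np.nonzero(predicate(c[:, 0], c[:, 1], c[:, 2]))[0]

    def split_plane(
        self,
        axis: int,
        plane: int,
        column_mask: np.ndarray | None = None,
        keep_side: str = "both",
    ):
        """Duplicate the grid-node plane between voxel layers ``plane-1`` and
        ``plane`` along ``axis`` so the two sides can move independently.

        ``column_mask`` (2D bool over the remaining two voxel axes) restricts
        the split to a sub-region.  Nodes shared with voxels outside the mask
        stay merged; ``keep_side`` chooses which side's out-of-mask voxels
        veto the split ('both', 'plus', or 'minus').  Elements on the + side
        are rewired to fresh node ids.  Returns an (npairs, 2) array of
        (minus-side id, plus-side id).
        """
        ax = axis
        vox = self.elem_voxel
        others = [i for i in range(3) if i != ax]
        if column_mask is None:
            column_mask = np.ones(
                (self.shape[others[0]], self.shape[others[1]]), dtype=bool
            )
        # nodes strictly interior to the split region: a grid node on the plane
        # is split when every voxel column touching it is in the mask
        nplus = np.zeros(self.n_nodes, dtype=bool)
        plus_elems = np.nonzero(
            (vox[:, ax] >= plane)
            & (vox[:, ax] == plane)  # only the layer touching the plane matters
            & column_mask[vox[:, others[0]], vox[:, others[1]]]
        )[0]
        minus_elems = np.nonzero(
            (vox[:, ax] == plane - 1)
            & column_mask[vox[:, others[0]], vox[:, others[1]]]
        )[0]
        h = self.spacing[ax]
        plane_coord = plane * h
        on_plane = np.abs(self.coords[:, ax] - plane_coord) < 1e-9 * max(1.0, plane_coord)

        # candidate nodes: on the plane AND touched by masked voxels on both sides
        touch_plus = np.zeros(self.n_nodes, dtype=bool)
        touch_minus = np.zeros(self.n_nodes, dtype=bool)
        touch_plus[self.conn[plus_elems].ravel()] = True
        touch_minus[self.conn[minus_elems].ravel()] = True
        # exclude nodes shared with unmasked columns (they stay merged = tied)
        out_plus = np.nonzero(
            (vox[:, ax] == plane)
            & ~column_mask[vox[:, others[0]], vox[:, others[1]]]
        )[0]
        out_minus = np.nonzero(
            (vox[:, ax] == plane - 1)
            & ~column_mask[vox[:, others[0]], vox[:, others[1]]]
        )[0]
        keep = np.zeros(self.n_nodes, dtype=bool)
        if keep_side in ("both", "plus"):
            keep[self.conn[out_plus].ravel()] = True
        if keep_side in ("both", "minus"):
            keep[self.conn[out_minus].ravel()] = True

        split_nodes = np.nonzero(on_plane & touch_plus & touch_minus & ~keep)[0]
        if len(split_nodes) == 0:
            return np.empty((0, 2), dtype=np.int64)

        new_ids = np.arange(self.n_nodes, self.n_nodes + len(split_nodes))
        remap = -np.ones(self.n_nodes, dtype=np.int64)
        remap[split_nodes] = new_ids
        self.coords = np.vstack([self.coords, self.coords[split_nodes]])
        self.n_nodes += len(split_nodes)

        # rewire all elements on the + side of the plane (not only the touching
        # layer) that reference a split node
        all_plus = np.nonzero(vox[:, ax] >= plane)[0]
        c = self.conn[all_plus]
        m = remap[c] >= 0
        c[m] = remap[c][m]
        self.conn[all_plus] = c
        return np.stack([split_nodes, new_ids], axis=1)


@dataclass
class Interface:
    """Penalty coupling between paired nodes across a planar interface.

    ``mode='tie'`` bonds all components; ``mode='contact'`` transmits
    compression only along ``axis`` (frictionless tangentially) — the
    friction-0 endpoint; ``mode='bonded'`` is an alias for tie (friction-1).
    """

    pairs: np.ndarray  # (n, 2) node ids, (minus side, plus side)
    axis: int
    mode: str = "contact"
    stiffness: float | None = None  # N/mm per pair; default set at solve time

    def default_stiffness(self, mesh: VoxelMesh, e_max: float, factor: float = 100.0) -> float:
        others = [i for i in range(3) if i != self.axis]
        area = mesh.spacing[others[0]] * mesh.spacing[others[1]]
        return factor * e_max * area / mesh.spacing[self.axis]


@dataclass
class LoadCase:
    """Boundary conditions and loads.

    ``dirichlet``: (node ids, component, value mm); ``forces``: (node ids,
    component, total force N distributed evenly over the set);
    ``eigenstrain``: optional per-element initial strain (n_elems, 6) used for
    plate pretension.  ``n_increments`` controls incremental (superelastic)
    solves.
    """

    dirichlet: list = field(default_factory=list)
    forces: list = field(default_factory=list)
    eigenstrain: np.ndarray | None = None
    n_increments: int = 10
    cg_rtol: float = 1e-8
    newton_rtol: float = 1e-6
    max_newton: int = 25
    max_cuts: int = 4


@dataclass
class FieldResult:
    """Solution fields and derived quantities of one solve/increment."""

    u: np.ndarray  # (n_nodes, 3) mm
    strain: np.ndarray  # (n_elems, 6) centroid engineering strain
    stress: np.ndarray  # (n_elems, 6) centroid stress MPa
    vm: np.ndarray  # (n_elems,) element-centroid von Mises MPa
    reactions: list  # resultant reaction (N) per dirichlet set
    external_work: float
    strain_energy: float
    xi: np.ndarray | None = None  # per-element mean martensite fraction
    interface_tractions: list = field(default_factory=list)  # mean normal traction per interface (MPa, +=compression)
    increments: list = field(default_factory=list)  # per-increment summaries for incremental solves


# ----------------------------------------------------------------------------
# assembly helpers
# ----------------------------------------------------------------------------


def _dof_matrix(conn: np.ndarray) -> np.ndarray:
    return (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), 24)


def _assemble_csr(mesh: VoxelMesh, ke: np.ndarray, springs=None) -> sp.csr_matrix:
    """Assemble a global CSR matrix from per-element 24x24 blocks.

    ``ke`` is (n_elems, 24, 24) or (24, 24) shared by all elements.
    ``springs`` is a list of (i_dof, j_dof, k) scalar couplings (adds
    k on (i,i),(j,j) and -k on (i,j),(j,i)).
    """
    dof = _dof_matrix(mesh.conn)
    if ke.ndim == 2:
        data = np.broadcast_to(ke, (mesh.n_elems, 24, 24))
    else:
        data = ke
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    vals = np.ascontiguousarray(data).ravel()
    if springs:
        si = np.array([s[0] for s in springs])
        sj = np.array([s[1] for s in springs])
        sk = np.array([s[2] for s in springs], dtype=float)
        rows = np.concatenate([rows, si, sj, si, sj])
        cols = np.concatenate([cols, si, sj, sj, si])
        vals = np.concatenate([vals, sk, sk, -sk, -sk])
    K = sp.coo_matrix((vals, (rows, cols)), shape=(mesh.ndof, mesh.ndof)).tocsr()
    return K


def _collect_dirichlet(load: LoadCase):
    dofs, vals = [], []
    for nodes, comp, value in load.dirichlet:
        nodes = np.asarray(nodes, dtype=np.int64)
        dofs.append(3 * nodes + comp)
        vals.append(np.full(len(nodes), float(value)))
    if not dofs:
        raise ValueError("no Dirichlet constraints: rigid-body motion is unconstrained")
    dofs = np.concatenate(dofs)
    vals = np.concatenate(vals)
    # keep the first specification of duplicated dofs
    _, first = np.unique(dofs, return_index=True)
    dofs, vals = dofs[first], vals[first]
    if len(dofs) < 6:
        raise ValueError("fewer than 6 constrained dofs: system is under-constrained")
    return dofs, vals


def _force_vector(mesh: VoxelMesh, load: LoadCase, scale: float = 1.0) -> np.ndarray:
    f = np.zeros(mesh.ndof)
    for nodes, comp, total in load.forces:
        nodes = np.asarray(nodes, dtype=np.int64)
        f[3 * nodes + comp] += scale * float(total) / len(nodes)
    return f


def _eigen_force(mesh: VoxelMesh, Bg, w, D_of_elem, eps_star, scale=1.0) -> np.ndarray:
    """Equivalent nodal forces of an initial strain field."""
    f = np.zeros(mesh.ndof)
    sig = np.einsum("eij,ej->ei", D_of_elem, eps_star) * scale  # (ne, 6)
    fe = np.einsum("gij,ei->ej", Bg, sig) * w  # (ne, 24)
    np.add.at(f, _dof_matrix(mesh.conn).ravel(), fe.ravel())
    return f


def _solve_system(
    K: sp.csr_matrix,
    f: np.ndarray,
    fixed: np.ndarray,
    fixed_vals: np.ndarray,
    rtol: float,
    x0: np.ndarray | None = None,
    direct_max_dof: int = 15000,
):
    """Eliminate Dirichlet dofs and solve; returns the full dof vector."""
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    u = np.zeros(n)
    u[fixed] = fixed_vals
    Kff = K[free][:, free]
    rhs = f[free] - K[free][:, fixed] @ fixed_vals
    diag = Kff.diagonal()
    if np.any(diag <= 0):
        raise ValueError("non-positive-definite system (bad material or free dof)")
    if len(free) <= direct_max_dof:
        u[free] = spla.spsolve(Kff.tocsc(), rhs)
        return u
    M = sp.diags(1.0 / diag)
    x0f = None if x0 is None else x0[free]
    sol, info = spla.cg(Kff, rhs, x0=x0f, M=M, rtol=rtol, atol=0.0, maxiter=40000)
    if info != 0:
        raise RuntimeError(
            f"conjugate-gradient solver failed (info={info}); the system may be "
            "under-constrained or badly scaled"
        )
    u[free] = sol
    return u


def _contact_springs(interfaces, active_sets, mesh, e_max):
    springs = []
    for itf, act in zip(interfaces, active_sets):
        k = itf.stiffness or itf.default_stiffness(mesh, e_max)
        if itf.mode in ("tie", "bonded"):
            for c in range(3):
                i = 3 * itf.pairs[:, 0] + c
                j = 3 * itf.pairs[:, 1] + c
                springs.extend(zip(i.tolist(), j.tolist(), [k] * len(i)))
        else:
            p = itf.pairs[act]
            i = 3 * p[:, 0] + itf.axis
            j = 3 * p[:, 1] + itf.axis
            springs.extend(zip(i.tolist(), j.tolist(), [k] * len(i)))
    return springs


def _interface_report(interfaces, active_sets, mesh, u, e_max):
    out = []
    for itf, act in zip(interfaces, active_sets):
        k = itf.stiffness or itf.default_stiffness(mesh, e_max)
        others = [i for i in range(3) if i != itf.axis]
        area = mesh.spacing[others[0]] * mesh.spacing[others[1]]
        opening = (
            u[itf.pairs[:, 1], itf.axis] - u[itf.pairs[:, 0], itf.axis]
        )
        force = np.where(
            act if itf.mode == "contact" else np.ones(len(itf.pairs), bool),
            -k * opening,
            0.0,
        )  # + = compression
        out.append(float(force.sum() / (len(itf.pairs) * area)))
    return out


# ----------------------------------------------------------------------------
# linear solve
# ----------------------------------------------------------------------------


def assemble_and_solve_linear(
    mesh: VoxelMesh,
    materials: dict,
    load: LoadCase,
    interfaces: list[Interface] | None = None,
    x0: np.ndarray | None = None,
) -> FieldResult:
    """Linear elastic solve.

    ``materials`` maps material tags to :class:`LinearElastic` (a
    :class:`SMAParams` is accepted and linearized at its austenite modulus).
    Contact-mode interfaces trigger an active-set iteration of linear solves.
    """
    interfaces = interfaces or []
    Bg, Bc, w = hex_B(mesh.spacing)
    tags = np.unique(mesh.elem_mat)
    D_by_tag, ke_by_tag, e_by_tag = {}, {}, {}
    for t in tags:
        m = materials[int(t)]
        if isinstance(m, SMAParams):
            m = LinearElastic(E=m.E_A_mpa, nu=m.nu, sigma_y=m.sigma_y, name=m.name)
        D = m.D()
        D_by_tag[int(t)] = D
        ke_by_tag[int(t)] = np.einsum("gia,ij,gjb->ab", Bg, D, Bg) * w
        e_by_tag[int(t)] = m.E
    e_max = max(e_by_tag.values())

    if len(tags) == 1 and mesh.elem_scale is None:
        ke = ke_by_tag[int(tags[0])]
    else:
        ke = np.empty((mesh.n_elems, 24, 24))
        for t in tags:
            ke[mesh.elem_mat == t] = ke_by_tag[int(t)]
        if mesh.elem_scale is not None:
            ke *= mesh.elem_scale[:, None, None]

    D_of_elem = np.empty((mesh.n_elems, 6, 6))
    for t in tags:
        D_of_elem[mesh.elem_mat == t] = D_by_tag[int(t)]
    if mesh.elem_scale is not None:
        # composite voxels: element stress/energy consistent with scaled stiffness
        D_of_elem *= mesh.elem_scale[:, None, None]

    fixed, fixed_vals = _collect_dirichlet(load)
    f = _force_vector(mesh, load)
    eps_star = load.eigenstrain
    if eps_star is not None:
        f = f + _eigen_force(mesh, Bg, w, D_of_elem, eps_star)

    active_sets = [np.ones(len(i.pairs), dtype=bool) for i in interfaces]
    u = None
    for _ in range(30):
        springs = _contact_springs(interfaces, active_sets, mesh, e_max)
        K = _assemble_csr(mesh, ke, springs)
        u_flat = _solve_system(K, f, fixed, fixed_vals, load.cg_rtol, x0=x0)
        x0 = u_flat
        changed = False
        for itf, act in zip(interfaces, active_sets):
            if itf.mode != "contact":
                continue
            opening = (
                u_flat[3 * itf.pairs[:, 1] + itf.axis]
                - u_flat[3 * itf.pairs[:, 0] + itf.axis]
            )
            new_act = opening < 1e-12
            if not np.array_equal(new_act, act):
                changed = True
            act[:] = new_act
        u = u_flat
        if not changed:
            break
    else:
        raise RuntimeError("contact active-set iteration did not settle in 30 cycles")

    dof = _dof_matrix(mesh.conn)
    ue = u[dof]
    strain = np.einsum("ij,ej->ei", Bc, ue)
    eps_el = strain if eps_star is None else strain - eps_star
    stress = np.einsum("eij,ej->ei", D_of_elem, eps_el)
    vm = von_mises(stress)

    r = K @ u - f
    reactions = [float(r[3 * np.asarray(nodes) + comp].sum()) for nodes, comp, _ in load.dirichlet]
    w_ext = 0.5 * float(f @ u + r[fixed] @ u[fixed])
    # strain energy from Gauss-point strains (exact for the discrete system)
    eps_g = np.einsum("gij,ej->egi", Bg, ue)
    if eps_star is not None:
        eps_g = eps_g - eps_star[:, None, :]
    sig_g = np.einsum("eij,egj->egi", D_of_elem, eps_g)
    w_int = 0.5 * float((sig_g * eps_g).sum() * w)

    return FieldResult(
        u=u.reshape(-1, 3),
        strain=strain,
        stress=stress,
        vm=vm,
        reactions=reactions,
        external_work=w_ext,
        strain_energy=w_int,
        interface_tractions=_interface_report(interfaces, active_sets, mesh, u.reshape(-1, 3), e_max),
    )


def tie_and_contact_interface(
    mesh: VoxelMesh, axis: int, plane: int, mode: str = "contact",
    column_mask: np.ndarray | None = None, stiffness: float | None = None,
) -> Interface:
    """Split the mesh along a voxel plane and return the coupling interface.

    With ``mode='tie'`` the two sides remain rigidly bonded (penalty on all
    components); ``mode='contact'`` transmits compression only along the plane
    normal and nothing in tension (frictionless).  The voxel grids on both
    sides are matched by construction; a mismatched plane raises.
    """
    if not 0 < plane < mesh.shape[axis]:
        raise ValueError("interface plane must be interior to the grid")
    pairs = mesh.split_plane(axis, plane, column_mask)
    if len(pairs) == 0:
        raise ValueError("interface plane does not intersect the solid region")
    return Interface(pairs=pairs, axis=axis, mode=mode, stiffness=stiffness)


# ----------------------------------------------------------------------------
# incremental superelastic solve
# ----------------------------------------------------------------------------


def _sma_tangents(params: SMAParams, eps, eps_t, xi, h=1e-7):
    """Consistent tangents (n, 6, 6) for Gauss-point arrays.

    Elastic-branch points get the exact isotropic tangent at their current
    martensite fraction; transforming points get a symmetrized central-
    difference tangent of the return mapping.
    """
    n = len(eps)
    D = np.empty((n, 6, 6))
    _, xi_new, _ = sma_update(params, eps, eps_t, xi)
    active = np.abs(xi_new - xi) > 1e-12
    inel = ~active
    if inel.any():
        E = params.modulus_mpa(xi[inel])
        lam = E * params.nu / ((1 + params.nu) * (1 - 2 * params.nu))
        mu = E / (2 * (1 + params.nu))
        Del = np.zeros((inel.sum(), 6, 6))
        Del[:, :3, :3] = lam[:, None, None]
        idx = np.arange(3)
        Del[:, idx, idx] += (2 * mu)[:, None]
        idx = np.arange(3, 6)
        Del[:, idx, idx] = mu[:, None]
        D[inel] = Del
    if active.any():
        ea, eta, xa = eps[active], eps_t[active], xi[active]
        Da = np.empty((active.sum(), 6, 6))
        for k in range(6):
            ep = ea.copy()
            em = ea.copy()
            ep[:, k] += h
            em[:, k] -= h
            sp_, _, _ = sma_update(params, ep, eta, xa)
            sm_, _, _ = sma_update(params, em, eta, xa)
            Da[:, :, k] = (sp_ - sm_) / (2 * h)
        D[active] = 0.5 * (Da + np.transpose(Da, (0, 2, 1)))
    return D


def solve_incremental_sma(
    mesh: VoxelMesh,
    materials: dict,
    load: LoadCase,
    interfaces: list[Interface] | None = None,
    schedule: Sequence[float] | None = None,
) -> FieldResult:
    """Incremental Newton solve with superelastic material points.

    ``materials`` maps tags to :class:`SMAParams` or :class:`LinearElastic`;
    loads and prescribed displacements are ramped proportionally over
    ``load.n_increments`` steps, or along an explicit ``schedule`` of load
    factors (e.g. ``[0.25, 0.5, ..., 1.0, 0.75, ..., 0.0]`` for a
    load/unload loop).  On Newton failure a ramped increment is halved up to
    ``load.max_cuts`` times; scheduled increments are bisected the same way.
    Returns the final state with per-increment summaries in
    ``result.increments``.
    """
    if interfaces and any(i.mode == "contact" for i in interfaces):
        raise NotImplementedError("contact interfaces are supported in linear solves only")
    if mesh.elem_scale is not None:
        raise NotImplementedError(
            "composite-voxel meshes are for linear stiffness probes; "
            "superelastic solves use binary meshes"
        )
    interfaces = interfaces or []
    Bg, Bc, w = hex_B(mesh.spacing)
    tags = np.unique(mesh.elem_mat)
    sma_tags = [int(t) for t in tags if isinstance(materials[int(t)], SMAParams)]
    lin_tags = [int(t) for t in tags if int(t) not in sma_tags]
    if not sma_tags:
        raise ValueError("no superelastic material in the mesh; use the linear solver")

    sma_elems = {t: np.nonzero(mesh.elem_mat == t)[0] for t in sma_tags}
    lin_mask = np.isin(mesh.elem_mat, lin_tags)
    D_lin = np.zeros((mesh.n_elems, 6, 6))
    ke_lin = {}
    e_moduli = []
    for t in lin_tags:
        m = materials[t]
        D_lin[mesh.elem_mat == t] = m.D()
        ke_lin[t] = np.einsum("gia,ij,gjb->ab", Bg, m.D(), Bg) * w
        e_moduli.append(m.E)
    for t in sma_tags:
        e_moduli.append(materials[t].E_A_mpa)
    e_max = max(e_moduli)

    # committed Gauss-point state per SMA tag
    state = {
        t: {
            "eps_t": np.zeros((len(sma_elems[t]), 8, 6)),
            "xi": np.zeros((len(sma_elems[t]), 8)),
        }
        for t in sma_tags
    }

    fixed, fixed_vals1 = _collect_dirichlet(load)
    dof = _dof_matrix(mesh.conn)
    springs = _contact_springs(interfaces, [np.ones(len(i.pairs), bool) for i in interfaces], mesh, e_max)

    u = np.zeros(mesh.ndof)
    increments = []

    def internal_force_and_stress(u_vec, scale, committed):
        """f_int, per-GP stress, trial xi/eps_t (not committed)."""
        ue = u_vec[dof]
        eps_g = np.einsum("gij,ej->egi", Bg, ue)  # (ne, 8, 6)
        if load.eigenstrain is not None:
            eps_g = eps_g - scale * load.eigenstrain[:, None, :]
        sig_g = np.zeros_like(eps_g)
        if lin_mask.any():
            sig_g[lin_mask] = np.einsum(
                "eij,egj->egi", D_lin[lin_mask], eps_g[lin_mask]
            )
        trial = {}
        for t in sma_tags:
            idx = sma_elems[t]
            e = eps_g[idx].reshape(-1, 6)
            s, xi_n, et_n = sma_update(
                materials[t], e, committed[t]["eps_t"].reshape(-1, 6),
                committed[t]["xi"].ravel(),
            )
            sig_g[idx] = s.reshape(-1, 8, 6)
            trial[t] = {"eps_t": et_n.reshape(-1, 8, 6), "xi": xi_n.reshape(-1, 8)}
        fe = np.einsum("gij,egi->ej", Bg, sig_g) * w
        f_int = np.zeros(mesh.ndof)
        np.add.at(f_int, dof.ravel(), fe.ravel())
        if springs:
            for i, j, k in springs:
                d = u_vec[i] - u_vec[j]
                f_int[i] += k * d
                f_int[j] -= k * d
        return f_int, sig_g, eps_g, trial

    def tangent_matrix(eps_g, committed):
        ke = np.zeros((mesh.n_elems, 24, 24))
        for t in lin_tags:
            ke[mesh.elem_mat == t] = ke_lin[t]
        for t in sma_tags:
            idx = sma_elems[t]
            Dg = _sma_tangents(
                materials[t], eps_g[idx].reshape(-1, 6),
                committed[t]["eps_t"].reshape(-1, 6), committed[t]["xi"].ravel(),
            ).reshape(-1, 8, 6, 6)
            ke[idx] = np.einsum("gia,egij,gjb->eab", Bg, Dg, Bg) * w
        return _assemble_csr(mesh, ke, springs)

    if schedule is None:
        targets = list(np.linspace(1.0 / load.n_increments, 1.0, load.n_increments))
    else:
        targets = [float(t) for t in schedule]
    t_done = 0.0
    i_target = 0
    cuts = 0
    total_cuts = 0
    work_ext = 0.0
    prev_reactions = np.zeros(len(load.dirichlet))
    free = np.setdiff1d(np.arange(mesh.ndof), fixed)

    while i_target < len(targets):
        t_goal = targets[i_target]
        t_try = t_done + (t_goal - t_done) * 0.5**cuts
        u_try = u.copy()
        u_try[fixed] = t_try * fixed_vals1
        f_ext = _force_vector(mesh, load, scale=t_try)
        converged = False
        f_int, sig_g, eps_g, trial = internal_force_and_stress(u_try, t_try, state)
        n_iter = 0
        for it in range(load.max_newton):
            res = f_ext - f_int
            rnorm = np.linalg.norm(res[free])
            ref = max(np.linalg.norm(f_ext), np.linalg.norm(f_int), 1e-12)
            logger.debug("t=%.4f newton %d: |r|=%.3e (ref %.3e)", t_try, it, rnorm, ref)
            if rnorm <= load.newton_rtol * ref:
                converged = True
                n_iter = it
                break
            K = tangent_matrix(eps_g, state)
            du = _solve_system(
                K, res + K @ u_try, fixed, u_try[fixed], load.cg_rtol
            ) - u_try
            # backtracking line search: branch switches make the residual
            # non-smooth and the full step can cycle
            alpha = 1.0
            for ls in range(6):
                u_new = u_try + alpha * du
                f_i, s_g, e_g, tr = internal_force_and_stress(u_new, t_try, state)
                rn = np.linalg.norm((f_ext - f_i)[free])
                if rn < (1.0 - 1e-4 * alpha) * rnorm or ls == 5:
                    break
                alpha *= 0.5
            u_try, f_int, sig_g, eps_g, trial = u_new, f_i, s_g, e_g, tr
        if not converged:
            cuts += 1
            total_cuts += 1
            if cuts > load.max_cuts:
                raise RuntimeError(
                    f"superelastic increment failed to converge after {load.max_cuts} "
                    f"cuts (t={t_try:.3f}, residual {rnorm:.3e})"
                )
            logger.info("increment cut %d at t=%.4f", cuts, t_try)
            continue

        # commit
        for t in sma_tags:
            state[t] = trial[t]
        r = -(f_ext - f_int)
        reactions = np.array(
            [float(r[3 * np.asarray(n) + c].sum()) for n, c, _ in load.dirichlet]
        )
        # external work: trapezoid on reactions x prescribed displacement
        work_ext += float(
            0.5
            * (
                (prev_reactions + reactions)
                @ np.array([v * (t_try - t_done) for _, _, v in load.dirichlet])
            )
        ) if load.dirichlet else 0.0
        prev_reactions = reactions
        u = u_try
        t_done = t_try
        if abs(t_done - t_goal) < 1e-12:
            i_target += 1
            cuts = 0
        else:
            cuts = max(0, cuts - 1)
        sig_c = sig_g.mean(axis=1)
        vm_g = von_mises(sig_c)
        increments.append(
            {
                "t": t_done,
                "reactions": reactions.tolist(),
                "max_vm": float(vm_g.max()),
                "xi_max": max(float(state[t]["xi"].max()) for t in sma_tags),
            }
        )

    ue = u[dof]
    strain = np.einsum("ij,ej->ei", Bc, ue)
    f_int, sig_g, eps_g, _ = internal_force_and_stress(u, t_done, state)
    stress = sig_g.mean(axis=1)
    vm = von_mises(stress)
    xi_elem = np.zeros(mesh.n_elems)
    for t in sma_tags:
        xi_elem[sma_elems[t]] = state[t]["xi"].mean(axis=1)
    r = f_int - _force_vector(mesh, load, t_done)
    reactions = [float(r[3 * np.asarray(n) + c].sum()) for n, c, _ in load.dirichlet]
    w_int = float(0.5 * (sig_g * eps_g).sum() * w)  # upper bound ignores dissipation split

    return FieldResult(
        u=u.reshape(-1, 3),
        strain=strain,
        stress=stress,
        vm=vm,
        reactions=reactions,
        external_work=work_ext,
        strain_energy=w_int,
        xi=xi_elem,
        increments=increments,
    )
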