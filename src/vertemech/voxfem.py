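"""Voxel hexahedral micro-FE for vertebral compression.

Each retained coarse cell becomes one 8-node trilinear hexahedral element
(2x2x2 Gauss quadrature, isotropic linear elasticity).  Boundary conditions
reproduce a compression test between a fixed base and a rigid loading plate:

* the lowest-z face of the base cement cap is fully fixed;
* the top-surface nodes are kinematically coupled to a single 6-DOF rigid
  body whose reference sits at the load point, so the plate translates and
  tilts freely about the loading ball while an axial point load acts through
  the reference (force and moment balance about the load point);
* bone-cement interfaces are tied by construction (shared lattice nodes).

Units: lengths mm, moduli GPa, forces kN (1 GPa * mm^2 = 1 kN), so assembled
stiffness is kN/mm and reported specimen stiffness is directly kN/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, spsolve

from .bvtv_map import LABEL_BONE, LABEL_CEMENT
from .material_map import MaterialField

__all__ = [
    "FEModel",
    "SolutionField",
    "StiffnessResult",
    "hex_element_stiffness",
    "build_model",
    "apply_rigid_plate_load",
    "solve",
    "stiffness_from_solution",
]

# local corner offsets (i, j, k) in the standard C3D8 ordering: bottom face
# counter-clockwise then top face
_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=np.int64)


def hex_element_stiffness(E: float, nu: float, edges) -> np.ndarray:
    """24x24 stiffness matrix of an 8-node trilinear brick.

    Isotropic linear elasticity, full 2x2x2 Gauss integration, DOF order
    node-major (u1x, u1y, u1z, u2x, ...).  ``edges`` are the element edge
    lengths (mm) along x, y, z.
    """
    if not E > 0:
        raise ValueError("E must be > 0")
    if not (0 <= nu < 0.5):
        raise ValueError(f"need 0 <= nu < 0.5, got {nu}")
    a, b, c = (float(e) for e in np.broadcast_to(np.asarray(edges, float), (3,)))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)

    # natural coordinates of corners in (-1, 1)^3
    xi_n = 2.0 * _CORNERS - 1.0
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    detJ = (a / 2) * (b / 2) * (c / 2)
    inv_h = np.array([2 / a, 2 / b, 2 / c])
    for p in (-g, g):
        for q in (-g, g):
            for r in (-g, g):
                # shape function gradients w.r.t. natural coords
                dN = np.empty((8, 3))
                for n in range(8):
                    sx, sy, sz = xi_n[n]
                    dN[n, 0] = sx * (1 + sy * q) * (1 + sz * r) / 8
                    dN[n, 1] = (1 + sx * p) * sy * (1 + sz * r) / 8
                    dN[n, 2] = (1 + sx * p) * (1 + sy * q) * sz / 8
                dNdx = dN * inv_h  # rectangular element: diagonal Jacobian
                B = np.zeros((6, 24))
                for n in range(8):
                    bx, by, bz = dNdx[n]
                    col = 3 * n
                    B[0, col] = bx
                    B[1, col + 1] = by
                    B[2, col + 2] = bz
                    B[3, col] = by
                    B[3, col + 1] = bx
                    B[4, col + 1] = bz
                    B[4, col + 2] = by
                    B[5, col] = bz
                    B[5, col + 2] = bx
                K += B.T @ D @ B * detJ
    return K


@dataclass
class FEModel:
    """Assembled-geometry voxel FE model (elements, nodes, constraints, load)."""

    element_cells: np.ndarray        # (n_el, 3) coarse-grid cell indices
    element_modulus: np.ndarray      # (n_el,) GPa
    element_nu: np.ndarray           # (n_el,)
    element_label: np.ndarray        # (n_el,) region label
    connectivity: np.ndarray         # (n_el, 8) node indices
    node_coords: np.ndarray          # (n_nodes, 3) mm
    spacing: np.ndarray              # element edge lengths, mm
    fixed_nodes: np.ndarray          # node indices with all DOFs fixed
    plate_nodes: np.ndarray          # node indices coupled to the rigid plate
    load_point: np.ndarray | None = None   # (3,) mm
    load_N: float = 1000.0           # axial load magnitude, N (applied -z)
    n_dropped: int = 0               # disconnected/void elements dropped

    @property
    def n_elements(self) -> int:
        return len(self.element_modulus)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def assemble(self) -> sparse.csr_matrix:
        """Global stiffness (kN/mm units) as CSR.

        All elements share edge lengths and Poisson's ratio, so the element
        matrix is computed once at unit modulus and scaled per element.
        """
        nus = np.unique(self.element_nu)
        dofs = self.connectivity[:, :, None] * 3 + np.arange(3)[None, None, :]
        edof = dofs.reshape(self.n_elements, 24)
        rows = np.repeat(edof, 24, axis=1).ravel()
        cols = np.tile(edof, (1, 24)).ravel()
        data = np.empty((self.n_elements, 576))
        for nu in nus:
            m = self.element_nu == nu
            K1 = hex_element_stiffness(1.0, float(nu), self.spacing).ravel()
            data[m] = self.element_modulus[m, None] * K1[None, :]
        K = sparse.coo_matrix((data.ravel(), (rows, cols)),
                              shape=(3 * self.n_nodes, 3 * self.n_nodes))
        return K.tocsr()

    def with_modulus(self, element_modulus: np.ndarray) -> "FEModel":
        """Same mesh and constraints with a new per-element modulus."""
        element_modulus = np.asarray(element_modulus, dtype=float)
        if element_modulus.shape != self.element_modulus.shape:
            raise ValueError("modulus array must match element count")
        return replace(self, element_modulus=element_modulus)


def build_model(materials: MaterialField, load_N: float = 1000.0,
                require_cement: bool = True) -> FEModel:
    """Mesh the material field into a voxel FE model with experiment BCs.

    Void elements and bone elements below the modulus floor are dropped; only
    the largest face-connected component is retained (the count of dropped
    elements is recorded).  The base is the lowest-z face of the retained
    mesh (the bottom cement cap when cement is present); the plate couples
    the highest-z face.  With ``require_cement=False`` plain blocks (no
    cement) can be meshed for verification problems.
    """
    E = materials.modulus
    labels = materials.labels.data
    keep = (labels == LABEL_CEMENT) | ((labels == LABEL_BONE)
                                       & (E >= materials.params.E_floor - 1e-300))
    if require_cement and not (labels == LABEL_CEMENT).any():
        raise ValueError("no cement region; pass require_cement=False for bare blocks")
    if not keep.any():
        raise ValueError("no elements to mesh")
    # face connectivity: corner-linked elements would hinge, not transmit load
    lab, n = ndimage.label(keep, structure=ndimage.generate_binary_structure(3, 1))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    main = lab == (1 + int(np.argmax(sizes)))
    n_dropped = int(keep.sum() - main.sum())

    cells = np.argwhere(main)
    nx, ny, nz = labels.shape
    # lattice node ids for the 8 corners of each retained cell
    corner_idx = cells[:, None, :] + _CORNERS[None, :, :]
    lattice = (corner_idx[..., 0] * (ny + 1) + corner_idx[..., 1]) * (nz + 1) \
        + corner_idx[..., 2]
    used, connectivity = np.unique(lattice, return_inverse=True)
    connectivity = connectivity.reshape(-1, 8)
    kz = used % (nz + 1)
    rem = used // (nz + 1)
    jy = rem % (ny + 1)
    ix = rem // (ny + 1)
    spacing = materials.spacing.astype(float)
    origin = materials.origin.astype(float)
    node_coords = np.stack([ix, jy, kz], axis=1) * spacing + origin

    z_lo, z_hi = node_coords[:, 2].min(), node_coords[:, 2].max()
    fixed = np.nonzero(np.isclose(node_coords[:, 2], z_lo))[0]
    plate = np.nonzero(np.isclose(node_coords[:, 2], z_hi))[0]
    if np.intersect1d(fixed, plate).size:
        raise ValueError("base and plate share nodes; model too thin to load")

    cell_idx = tuple(cells.T)
    model = FEModel(
        element_cells=cells,
        element_modulus=E[cell_idx].astype(float),
        element_nu=materials.nu[cell_idx].astype(float),
        element_label=labels[cell_idx].astype(np.uint8),
        connectivity=connectivity.astype(np.int64),
        node_coords=node_coords,
        spacing=spacing,
        fixed_nodes=fixed,
        plate_nodes=plate,
        load_N=float(load_N),
        n_dropped=n_dropped,
    )
    return model


def plate_footprint(model: FEModel) -> tuple[np.ndarray, np.ndarray]:
    """(min, max) x/y bounds (mm) of the rigid-plate node set."""
    xy = model.node_coords[model.plate_nodes, :2]
    return xy.min(axis=0), xy.max(axis=0)


def apply_rigid_plate_load(model: FEModel, load_point, load_N: float | None = None
                           ) -> FEModel:
    """Place the axial point load (on the plate plane) at ``load_point``.

    ``load_point`` may be (x, y) or (x, y, z); z is snapped to the plate
    plane.  The point must lie within the plate footprint.
    """
    lp = np.asarray(load_point, dtype=float)
    z_top = model.node_coords[model.plate_nodes, 2].max()
    if lp.size == 2:
        lp = np.array([lp[0], lp[1], z_top])
    else:
        lp = lp.copy()
        lp[2] = z_top
    lo, hi = plate_footprint(model)
    if np.any(lp[:2] < lo - 1e-9) or np.any(lp[:2] > hi + 1e-9):
        raise ValueError(
            f"load point {lp[:2]} outside plate footprint [{lo}, {hi}]"
        )
    return replace(model, load_point=lp,
                   load_N=model.load_N if load_N is None else float(load_N))


@dataclass
class SolutionField:
    """Nodal displacements plus the plate's rigid-body motion."""

    displacement: np.ndarray       # (n_nodes, 3) mm
    plate_translation: np.ndarray  # (3,) mm, at the load point
    plate_rotation: np.ndarray     # (3,) rad
    iterations: int
    residual: float
    converged: bool


def _constraint_transform(model: FEModel):
    """Sparse map T from reduced DOFs (free nodal DOFs + 6 plate DOFs) to the
    full nodal DOF vector; fixed DOFs map to zero.

    Plate nodes move rigidly: u = U + theta x (x - x_ref), small rotations.
    """
    if model.load_point is None:
        raise ValueError("no load point set; call apply_rigid_plate_load first")
    n = model.n_nodes
    is_fixed = np.zeros(n, dtype=bool)
    is_fixed[model.fixed_nodes] = True
    is_plate = np.zeros(n, dtype=bool)
    is_plate[model.plate_nodes] = True
    if np.any(is_fixed & is_plate):
        raise ValueError("a node is both fixed and on the plate")
    free = np.nonzero(~is_fixed & ~is_plate)[0]
    n_red = 3 * len(free) + 6

    rows, cols, vals = [], [], []
    # free nodes: identity
    fdof = (free[:, None] * 3 + np.arange(3)).ravel()
    rows.append(fdof)
    cols.append(np.arange(3 * len(free)))
    vals.append(np.ones(3 * len(free)))
    # plate nodes: rigid-body map; reduced plate DOFs are the last six
    # [Ux, Uy, Uz, thx, thy, thz]
    base = 3 * len(free)
    r = model.node_coords[model.plate_nodes] - model.load_point[None, :]
    npl = len(model.plate_nodes)
    pdof = model.plate_nodes[:, None] * 3 + np.arange(3)
    # u_x = Ux + thy * rz - thz * ry
    rows.append(np.repeat(pdof[:, 0], 3))
    cols.append(np.tile([base + 0, base + 4, base + 5], npl))
    vals.append(np.stack([np.ones(npl), r[:, 2], -r[:, 1]], axis=1).ravel())
    # u_y = Uy + thz * rx - thx * rz
    rows.append(np.repeat(pdof[:, 1], 3))
    cols.append(np.tile([base + 1, base + 5, base + 3], npl))
    vals.append(np.stack([np.ones(npl), r[:, 0], -r[:, 2]], axis=1).ravel())
    # u_z = Uz + thx * ry - thy * rx
    rows.append(np.repeat(pdof[:, 2], 3))
    cols.append(np.tile([base + 2, base + 3, base + 4], npl))
    vals.append(np.stack([np.ones(npl), r[:, 1], -r[:, 0]], axis=1).ravel())

    T = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, n_red),
    ).tocsr()
    return T, free


def solve(model: FEModel, tol: float = 1e-8, max_iter: int = 20000,
          x0: np.ndarray | None = None, method: str = "cg") -> SolutionField:
    """Solve the constrained linear system for the applied plate load.

    The rigid plate is condensed into 6 master DOFs via a kinematic
    transformation; the reduced SPD system is solved with Jacobi-
    preconditioned conjugate gradients to relative residual ``tol``
    (``method='direct'`` uses a sparse LU factorization instead, for small
    verification meshes).  ``x0`` warm-starts the iteration.
    """
    K = model.assemble()
    T, free = _constraint_transform(model)
    Kr = (T.T @ K @ T).tocsr()
    F = np.zeros(Kr.shape[0])
    F[-4] = -model.load_N / 1000.0  # axial force, kN, through the load point

    if method == "direct":
        u_red = spsolve(Kr.tocsc(), F)
        iterations, converged = 1, True
        residual = float(np.linalg.norm(Kr @ u_red - F) / np.linalg.norm(F))
    else:
        d = Kr.diagonal()
        if np.any(d <= 0):
            raise ValueError("singular reduced system (zero diagonal); "
                             "check connectivity and modulus floor")
        M = sparse.diags(1.0 / d)
        info_holder = {"it": 0}

        def cb(xk):
            info_holder["it"] += 1

        u_red, info = cg(Kr, F, x0=x0, rtol=tol, atol=0.0, maxiter=max_iter,
                         M=M, callback=cb)
        iterations = info_holder["it"]
        residual = float(np.linalg.norm(Kr @ u_red - F) / np.linalg.norm(F))
        converged = info == 0
        if not converged:
            raise RuntimeError(
                f"CG failed to converge in {max_iter} iterations "
                f"(relative residual {residual:.3e})"
            )

    u_full = np.asarray(T @ u_red).reshape(-1, 3)
    sol = SolutionField(
        displacement=u_full,
        plate_translation=u_red[-6:-3].copy(),
        plate_rotation=u_red[-3:].copy(),
        iterations=iterations,
        residual=residual,
        converged=converged,
    )
    sol._reduced = u_red  # stashed for warm starts
    return sol


@dataclass(frozen=True)
class StiffnessResult:
    stiffness_kN_per_mm: float
    apparent_modulus_MPa: float | None
    load_point: np.ndarray | None
    model_id: str = ""


def stiffness_from_solution(model: FEModel, solution: SolutionField,
                            height_mm: float | None = None,
                            area_mm2: float | None = None,
                            model_id: str = "") -> StiffnessResult:
    """Stiffness = load / axial displacement at the load point (kN/mm);
    apparent modulus = stiffness * height / area (MPa) when morphometrics
    are given."""
    if not solution.converged:
        raise ValueError("solution did not converge")
    w = abs(float(solution.plate_translation[2]))
    if w == 0:
        raise ZeroDivisionError("zero plate displacement at the load point")
    S = (model.load_N / 1000.0) / w  # kN/mm
    app = None
    if height_mm is not None and area_mm2 is not None:
        app = S * height_mm / area_mm2 * 1000.0  # kN/mm * mm / mm^2 = GPa -> MPa
    return StiffnessResult(stiffness_kN_per_mm=S, apparent_modulus_MPa=app,
                           load_point=model.load_point, model_id=model_id)
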