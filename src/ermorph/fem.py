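"""Small plane-stress finite-element kernel on quadrilateral meshes.

Elements are 4-node quadrilaterals enhanced with incompatible bending modes
(QM6): four internal degrees of freedom per element, condensed out at
assembly, with the volume-averaged correction that restores the patch test
on distorted meshes.  This keeps thin structures (ER tubules, the cortex
band) from shear-locking while the mesh stays a simple mapped grid.

Loads: nodal forces, constant tractions on boundary segments, and
elementwise eigenstress (used for contractile active stress).  The reported
strain energy density is the elastic one, U = (1/V) (1/2) \\int (C eps) : eps dV,
evaluated by 2x2 Gaussian quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_XI_N = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def plane_stress_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """(E_el,) -> (E_el, 3, 3) plane-stress constitutive matrices."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    f = E / (1.0 - nu**2)
    D = np.zeros(E.shape + (3, 3))
    D[..., 0, 0] = D[..., 1, 1] = f
    D[..., 0, 1] = D[..., 1, 0] = f * nu
    D[..., 2, 2] = f * (1.0 - nu) / 2.0
    return D


def _shape_derivs(xi: float, eta: float) -> np.ndarray:
    """(2, 4) derivatives of the Q4 shape functions wrt (xi, eta)."""
    d = np.empty((2, 4))
    d[0] = 0.25 * _XI_N[:, 0] * (1.0 + _XI_N[:, 1] * eta)
    d[1] = 0.25 * _XI_N[:, 1] * (1.0 + _XI_N[:, 0] * xi)
    return d


@dataclass
class FEResult:
    u: np.ndarray                 # (n_nodes, 2) displacements
    strain: np.ndarray            # (n_el, 4, 3) at Gauss points
    stress: np.ndarray            # (n_el, 4, 3) elastic stress C:eps
    element_energy: np.ndarray    # (n_el,) strain energy per element
    element_volume: np.ndarray    # (n_el,)
    U: float                      # (1/V)(1/2) \int sigma:eps dV
    V: float
    residual: float


def _element_matrices(coords: np.ndarray, D: np.ndarray, thickness: float):
    """Batched QM6 element matrices.

    coords: (E, 4, 2); D: (E, 3, 3).
    Returns Kcc (E,8,8), Kca (E,8,4), Kaa (E,4,4),
    plus per-gp (Bc, Ba, wdet) for strain recovery / eigenstress loads.
    """
    nel = coords.shape[0]
    # centre Jacobian for the incompatible modes
    d0 = _shape_derivs(0.0, 0.0)
    J0 = np.einsum("in,enj->eij", d0, coords)
    detJ0 = np.linalg.det(J0)
    invJ0 = np.linalg.inv(J0)

    Bc_g = np.zeros((4, nel, 3, 8))
    Ba_g = np.zeros((4, nel, 3, 4))
    wdet = np.zeros((4, nel))
    for g, (xi, eta) in enumerate(_GP):
        d = _shape_derivs(xi, eta)
        J = np.einsum("in,enj->eij", d, coords)
        detJ = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        dN = np.einsum("eij,jn->ein", invJ, d)     # (E, 2, 4) d/dx, d/dy
        B = np.zeros((nel, 3, 8))
        B[:, 0, 0::2] = dN[:, 0]
        B[:, 1, 1::2] = dN[:, 1]
        B[:, 2, 0::2] = dN[:, 1]
        B[:, 2, 1::2] = dN[:, 0]
        Bc_g[g] = B
        # incompatible modes mapped with the centre Jacobian, scaled so the
        # stiffness stays consistent on non-parallelogram elements
        dP = np.array([[-2.0 * xi, 0.0], [0.0, -2.0 * eta]])  # (mode, 2)
        dPx = np.einsum("eij,mj->emi", invJ0, dP) * (detJ0 / detJ)[:, None, None]
        Ba = np.zeros((nel, 3, 4))
        for m in range(2):
            Ba[:, 0, 2 * m] = dPx[:, m, 0]
            Ba[:, 1, 2 * m + 1] = dPx[:, m, 1]
            Ba[:, 2, 2 * m] = dPx[:, m, 1]
            Ba[:, 2, 2 * m + 1] = dPx[:, m, 0]
        Ba_g[g] = Ba
        wdet[g] = detJ * thickness
    # patch-test correction: subtract the volume average of Ba
    vol = wdet.sum(axis=0)
    Ba_mean = np.einsum("ge,geij->eij", wdet, Ba_g) / vol[:, None, None]
    Ba_g = Ba_g - Ba_mean[None]

    Kcc = np.zeros((nel, 8, 8))
    Kca = np.zeros((nel, 8, 4))
    Kaa = np.zeros((nel, 4, 4))
    for g in range(4):
        DB_c = np.einsum("eij,ejk->eik", D, Bc_g[g])
        DB_a = np.einsum("eij,ejk->eik", D, Ba_g[g])
        w = wdet[g][:, None, None]
        Kcc += w * np.einsum("eji,ejk->eik", Bc_g[g], DB_c)
        Kca += w * np.einsum("eji,ejk->eik", Bc_g[g], DB_a)
        Kaa += w * np.einsum("eji,ejk->eik", Ba_g[g], DB_a)
    return Kcc, Kca, Kaa, Bc_g, Ba_g, wdet


def fe_solve(nodes: np.ndarray, elems: np.ndarray,
             E_el: np.ndarray, nu_el: np.ndarray,
             thickness: float = 1.0,
             fixed: Optional[np.ndarray] = None,
             prescribed: Optional[np.ndarray] = None,
             nodal_forces: Optional[np.ndarray] = None,
             edge_tractions: Optional[Sequence[tuple]] = None,
             eigenstress: Optional[np.ndarray] = None) -> FEResult:
    """Solve quasi-static equilibrium on a quad mesh.

    fixed: (n_nodes, 2) boolean; prescribed: (n_nodes, 2) values where fixed.
    edge_tractions: iterable of (n1, n2, tx, ty) — constant traction
    (force / area) on the boundary segment n1-n2.
    eigenstress: (n_el, 3) initial stress sigma0 added to C:eps inside the
    element; its negative divergence is the applied load.
    """
    nodes = np.asarray(nodes, dtype=float)
    elems = np.asarray(elems, dtype=int)
    nn, ne = nodes.shape[0], elems.shape[0]
    D = plane_stress_D(E_el, nu_el)
    coords = nodes[elems]
    Kcc, Kca, Kaa, Bc_g, Ba_g, wdet = _element_matrices(coords, D, thickness)

    Kaa_inv = np.linalg.inv(Kaa)
    KcaKai = np.einsum("eij,ejk->eik", Kca, Kaa_inv)
    Kstar = Kcc - np.einsum("eij,ekj->eik", KcaKai, Kca)

    f = np.zeros((nn, 2))
    if nodal_forces is not None:
        f += nodal_forces
    if edge_tractions:
        for n1, n2, tx, ty in edge_tractions:
            L = np.linalg.norm(nodes[n2] - nodes[n1])
            for n in (n1, n2):
                f[n, 0] += 0.5 * tx * L * thickness
                f[n, 1] += 0.5 * ty * L * thickness

    fa = np.zeros((ne, 4))
    if eigenstress is not None:
        sig0 = np.asarray(eigenstress, dtype=float)
        fc_el = np.zeros((ne, 8))
        for g in range(4):
            w = wdet[g][:, None]
            fc_el -= w * np.einsum("eji,ej->ei", Bc_g[g], sig0)
            fa -= wdet[g][:, None] * np.einsum("eji,ej->ei", Ba_g[g], sig0)
        dof = np.empty((ne, 8), dtype=int)
        dof[:, 0::2] = 2 * elems
        dof[:, 1::2] = 2 * elems + 1
        np.add.at(f.ravel(), dof.ravel(), fc_el.ravel())
    # condense the internal-mode load into the element rhs
    if eigenstress is not None:
        fc_extra = -np.einsum("eij,ej->ei", KcaKai, fa)
        dof = np.empty((ne, 8), dtype=int)
        dof[:, 0::2] = 2 * elems
        dof[:, 1::2] = 2 * elems + 1
        np.add.at(f.ravel(), dof.ravel(), fc_extra.ravel())

    # assemble sparse K
    dof = np.empty((ne, 8), dtype=int)
    dof[:, 0::2] = 2 * elems
    dof[:, 1::2] = 2 * elems + 1
    rows = np.repeat(dof, 8, axis=1).ravel()
    cols = np.tile(dof, (1, 8)).ravel()
    K = sp.coo_matrix((Kstar.ravel(), (rows, cols)),
                      shape=(2 * nn, 2 * nn)).tocsr()

    fixed = np.zeros((nn, 2), dtype=bool) if fixed is None else fixed.astype(bool)
    u = np.zeros(2 * nn)
    if prescribed is not None:
        u[fixed.ravel()] = prescribed[fixed]
    free = ~fixed.ravel()
    rhs = f.ravel() - K @ u
    if free.any():
        Kff = K[free][:, free]
        u_free = spla.spsolve(Kff.tocsc(), rhs[free])
        u[free] = u_free
        res = float(np.linalg.norm(Kff @ u_free - rhs[free]) /
                    max(np.linalg.norm(rhs[free]), 1e-30))
    else:
        res = 0.0

    # recover internal modes and Gauss-point strain/stress
    ue = u.reshape(nn, 2)[elems].reshape(ne, 8)
    rhs_a = -fa - np.einsum("eji,ej->ei", Kca, ue)
    a = np.einsum("eij,ej->ei", Kaa_inv, rhs_a)
    strain = np.empty((ne, 4, 3))
    for g in range(4):
        strain[:, g] = (np.einsum("eij,ej->ei", Bc_g[g], ue)
                        + np.einsum("eij,ej->ei", Ba_g[g], a))
    stress = np.einsum("eij,egj->egi", D, strain)
    dens = 0.5 * np.einsum("egk,egk->eg", stress, strain)
    el_energy = np.einsum("eg,ge->e", dens, wdet)
    el_vol = wdet.sum(axis=0)
    V = float(el_vol.sum())
    return FEResult(u=u.reshape(nn, 2), strain=strain, stress=stress,
                    element_energy=el_energy, element_volume=el_vol,
                    U=float(el_energy.sum() / V), V=V, residual=res)


def rect_mesh(length: float, height: float, nx: int, ny: int,
              x0: float = 0.0, y0: float = 0.0):
    """Structured rectangle mesh; returns (nodes (N,2), elems (E,4) CCW)."""
    xs = np.linspace(x0, x0 + length, nx + 1)
    ys = np.linspace(y0, y0 + height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    elems = []
    for j in range(ny):
        for i in range(nx):
            n0 = j * (nx + 1) + i
            elems.append([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return nodes, np.array(elems, dtype=int)
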