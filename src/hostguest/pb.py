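"""Finite-difference linearized Poisson-Boltzmann polar solvation energy.

The model is the standard two-dielectric continuum: the solute interior
(the union of atom spheres at their PB radii) has dielectric constant
``eps_solute`` and the exterior ``eps_solvent``; atomic point charges are
spread onto a regular grid by trilinear interpolation, and the linearized
PB equation

    ∇·(ε ∇φ) − ε_out κ² φ = −4π ρ        (κ² > 0 only in the solvent)

is discretised with the symmetric 7-point stencil (face-centred dielectric
sampling) and solved by preconditioned conjugate gradients. Dirichlet
boundary values come from the Debye-Hückel monopole sum over all charges.

The polar solvation (reaction-field) energy is

    ΔG_pol = ½ Σ_i q_i φ_i [solvated] − ½ Σ_i q_i φ_i [uniform ε_in]

evaluated on the identical grid, so the divergent grid self-energy of the
point charges cancels between the two solves.

Internal unit system: length Å, charge e, potential e/Å; energies are
converted to kcal/mol with the electrostatic constant
k_e = 332.0637 kcal·Å/(mol·e²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .chem_io import ForceFieldParameters, MolecularSystem

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)
_KT_298 = 0.593  # kcal/mol at 298.15 K, used only for the Debye kappa


class PBConvergenceError(RuntimeError):
    """PB solver failed to reach the requested residual."""


@dataclass(frozen=True)
class PBGridSpec:
    """Grid and physics parameters for the finite-difference PB solve.

    spacing : grid spacing h, Å (default 0.5)
    padding : minimum distance from any atom to the box face, Å (default 8)
    eps_solute / eps_solvent : interior / exterior dielectric constants
    ionic_strength : monovalent salt concentration, mol/L (default 0)
    tolerance : relative residual for the CG solve (default 1e-6)
    max_iter : iteration cap before PBConvergenceError
    """

    spacing: float = 0.5
    padding: float = 8.0
    eps_solute: float = 1.0
    eps_solvent: float = 80.0
    ionic_strength: float = 0.0
    tolerance: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if not (self.eps_solvent >= self.eps_solute >= 1.0):
            raise ValueError("require eps_solvent >= eps_solute >= 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")


def debye_kappa(ionic_strength: float, eps_solvent: float) -> float:
    """Inverse Debye length κ (Å⁻¹) for a 1:1 salt at ~298 K."""
    if ionic_strength == 0:
        return 0.0
    # κ² = 8π k_e N_A c I / (ε kT), with number density per mol/L in Å⁻³
    density = 6.02214076e-4  # particles/Å³ per mol/L
    kappa2 = 8.0 * np.pi * COULOMB_CONSTANT * density * ionic_strength / (
        eps_solvent * _KT_298)
    return float(np.sqrt(kappa2))


def _build_grid(coords: np.ndarray, grid: PBGridSpec):
    h = grid.spacing
    lo = coords.min(axis=0) - grid.padding
    hi = coords.max(axis=0) + grid.padding
    n = np.ceil((hi - lo) / h).astype(int) + 1
    axes = [lo[k] + h * np.arange(n[k]) for k in range(3)]
    return axes, n


def _spread_charges(coords: np.ndarray, charges: np.ndarray, axes, n, h: float) -> np.ndarray:
    """Trilinear spreading of point charges onto grid nodes (units: e)."""
    q_grid = np.zeros(tuple(n))
    lo = np.array([a[0] for a in axes])
    frac = (coords - lo) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for a, (i, j, k), (tx, ty, tz) in zip(charges, base, t):
        for di, wi in ((0, 1 - tx), (1, tx)):
            for dj, wj in ((0, 1 - ty), (1, ty)):
                for dk, wk in ((0, 1 - tz), (1, tz)):
                    q_grid[i + di, j + dj, k + dk] += a * wi * wj * wk
    return q_grid


def _node_sdf(coords: np.ndarray, radii: np.ndarray, axes) -> np.ndarray:
    """Signed distance from each grid node to the union-of-spheres solute
    surface (< 0 inside)."""
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sdf = np.full(gx.shape, np.inf)
    for c, r in zip(coords, radii):
        d = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) - r
        np.minimum(sdf, d, out=sdf)
    return sdf


def _face_eps(coords: np.ndarray, radii: np.ndarray, axes, n, h: float,
              eps_in: float, eps_out: float):
    """Dielectric constant on the three families of cell faces.

    eps_x[i,j,k] sits on the edge between nodes (i,j,k) and (i+1,j,k), etc.
    The dielectric map itself is sharp and two-valued (solute = union of
    atom spheres at their PB radii); an edge that crosses the interface is
    assigned the harmonic mean of the two dielectrics weighted by the
    fraction of the edge inside the solute, the standard flux-continuous
    treatment for a coefficient jump.
    """
    if eps_in == eps_out:
        return [np.full((n[0] - 1, n[1], n[2]), eps_out),
                np.full((n[0], n[1] - 1, n[2]), eps_out),
                np.full((n[0], n[1], n[2] - 1), eps_out)]

    sdf = _node_sdf(coords, radii, axes)
    out = []
    for axis in range(3):
        d0 = sdf[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))]
        d1 = sdf[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))]
        both_in = (d0 <= 0) & (d1 <= 0)
        both_out = (d0 >= 0) & (d1 >= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                both_in, 1.0,
                np.where(both_out, 0.0,
                         -np.minimum(d0, d1) / np.abs(d1 - d0)))
        frac = np.clip(frac, 0.0, 1.0)
        out.append(1.0 / (frac / eps_in + (1.0 - frac) / eps_out))
    return out


def _boundary_potential(coords, charges, axes, n, eps_ref: float, kappa: float):
    """Dirichlet boundary: screened-Coulomb monopole sum at boundary nodes."""
    phi = np.zeros(tuple(n))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    border = np.zeros(tuple(n), dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    pts = np.stack([gx[border], gy[border], gz[border]], axis=1)
    vals = np.zeros(len(pts))
    for q, c in zip(charges, coords):
        if q == 0.0:
            continue
        r = np.linalg.norm(pts - c, axis=1)
        r = np.maximum(r, 1e-6)
        vals += q * np.exp(-kappa * r) / (eps_ref * r)
    phi[border] = vals
    return phi, border


def _solve_fd(q_grid, eps_faces, phi_bc, border, n, h, kappa2_eps, tol, max_iter):
    """Solve the 7-point FD system for interior nodes (Dirichlet boundary)."""
    ex, ey, ez = eps_faces
    interior = ~border
    n_int = int(interior.sum())
    index = -np.ones(tuple(n), dtype=np.int64)
    index[interior] = np.arange(n_int)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_int)
    ii, jj, kk = np.nonzero(interior)
    my_idx = index[ii, jj, kk]
    diag = np.zeros(n_int)

    # rhs source: sum_f eps_f (phi_nb - phi_i) - kappa_bar^2 h^2 phi_i = -4 pi q_i / h
    rhs += 4.0 * np.pi * q_grid[ii, jj, kk] / h

    neighbor_face = [
        ((-1, 0, 0), lambda i, j, k: ex[i - 1, j, k]),
        ((+1, 0, 0), lambda i, j, k: ex[i, j, k]),
        ((0, -1, 0), lambda i, j, k: ey[i, j - 1, k]),
        ((0, +1, 0), lambda i, j, k: ey[i, j, k]),
        ((0, 0, -1), lambda i, j, k: ez[i, j, k - 1]),
        ((0, 0, +1), lambda i, j, k: ez[i, j, k]),
    ]
    for (di, dj, dk), face in neighbor_face:
        ni, nj, nk = ii + di, jj + dj, kk + dk
        eps_f = face(ii, jj, kk)
        diag += eps_f
        nb_interior = interior[ni, nj, nk]
        m = nb_interior
        rows.append(my_idx[m])
        cols.append(index[ni[m], nj[m], nk[m]])
        vals.append(-eps_f[m])
        mb = ~nb_interior
        rhs[my_idx[mb]] += eps_f[mb] * phi_bc[ni[mb], nj[mb], nk[mb]]

    diag += kappa2_eps[ii, jj, kk] * h * h
    rows.append(my_idx)
    cols.append(my_idx)
    vals.append(diag)

    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int)).tocsr()
    d_inv = 1.0 / A.diagonal()
    M = LinearOperator((n_int, n_int), matvec=lambda x: d_inv * x)
    phi_int, info = cg(A, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ phi_int - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise PBConvergenceError(
            f"PB solve did not converge in {max_iter} iterations "
            f"(relative residual {res:.3e})")
    phi = phi_bc.copy()
    phi[interior] = phi_int
    return phi


def pb_solvation_energy(system: MolecularSystem | np.ndarray,
                        params: ForceFieldParameters,
                        grid: PBGridSpec = PBGridSpec()) -> float:
    """Polar solvation energy (kcal/mol) of a charge distribution.

    The reaction-field energy is the difference of ½Σqφ between the
    two-dielectric solve and a uniform-``eps_solute`` reference solve on
    the same grid, cancelling the grid self-energy.
    """
    coords = system.coords if isinstance(system, MolecularSystem) else np.asarray(system, float)
    charges = params.charge
    radii = params.pb_radius
    if len(charges) != len(coords):
        raise ValueError("parameter table does not match atom count")
    if np.all(charges == 0.0):
        return 0.0
    if grid.eps_solvent == grid.eps_solute:
        return 0.0

    axes, n = _build_grid(coords, grid)
    h = grid.spacing
    q_grid = _spread_charges(coords, charges, axes, n, h)
    kappa = debye_kappa(grid.ionic_strength, grid.eps_solvent)

    energies = []
    for solvated in (True, False):
        if solvated:
            eps_faces = _face_eps(coords, radii, axes, n, h,
                                  grid.eps_solute, grid.eps_solvent)
            eps_ref = grid.eps_solvent
            kap = kappa
        else:
            eps_faces = _face_eps(coords, radii, axes, n, h,
                                  grid.eps_solute, grid.eps_solute)
            eps_ref = grid.eps_solute
            kap = 0.0
        phi_bc, border = _boundary_potential(coords, charges, axes, n, eps_ref, kap)
        if kap > 0:
            # screening acts only in the solvent region (nodes outside every
            # atom sphere)
            from scipy.spatial import cKDTree

            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
            tree = cKDTree(coords)
            inside = np.zeros(len(nodes), dtype=bool)
            for m, js in enumerate(tree.query_ball_point(nodes, radii.max())):
                for j in js:
                    if np.linalg.norm(nodes[m] - coords[j]) < radii[j]:
                        inside[m] = True
                        break
            solvent_like = (~inside).astype(float).reshape(tuple(n))
            kappa2_eps = grid.eps_solvent * kap * kap * solvent_like
        else:
            kappa2_eps = np.zeros(tuple(n))
        phi = _solve_fd(q_grid, eps_faces, phi_bc, border, n, h, kappa2_eps,
                        grid.tolerance, grid.max_iter)
        energies.append(0.5 * float(np.sum(q_grid * phi)))
    reaction = energies[0] - energies[1]
    return COULOMB_CONSTANT * reaction


def born_energy(charge: float, radius: float, eps_out: float = 80.0,
                eps_in: float = 1.0) -> float:
    """Closed-form Born-ion solvation energy (kcal/mol): the analytic
    oracle −(k_e q²/2a)(1/ε_in − 1/ε_out)."""
    return -COULOMB_CONSTANT * charge * charge / (2.0 * radius) * (
        1.0 / eps_in - 1.0 / eps_out)
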