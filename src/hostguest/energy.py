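"""MM-PB/SA-style interaction-enthalpy decomposition.

The interaction enthalpy between a receptor (host) and ligand (guest) cut
from the same complex geometry (single-trajectory approximation) is

    ΔH = ΔE_Coulomb + ΔE_PB + ΔE_NP + ΔE_VDW (+ ΔE_Valence, zero here)

with pairwise inter-selection Coulomb and Lennard-Jones sums, a
finite-difference Poisson-Boltzmann polar solvation difference
PB(complex) − PB(receptor) − PB(ligand), and a linear surface-area
nonpolar term γ·ΔSASA + b.

No cutoffs are applied to the pairwise sums: systems at this scale are
finite and exactness is preferred over speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .chem_io import ForceFieldParameters, MolecularSystem, Trajectory
from .pb import COULOMB_CONSTANT, PBGridSpec, pb_solvation_energy
from .sasa import SasaSpec, sasa

DEFAULT_NONPOLAR_GAMMA = 0.0072  # kcal/(mol·Å²)


@dataclass
class EnergyDecomposition:
    """Component energies (kcal/mol) and their sum.

    total_enthalpy is always the exact sum of the five components.
    """

    e_coulomb: float
    e_pb: float
    e_np: float
    e_vdw: float
    e_valence: float = 0.0

    @property
    def total_enthalpy(self) -> float:
        return self.e_valence + self.e_coulomb + self.e_pb + self.e_np + self.e_vdw

    def as_series(self) -> pd.Series:
        return pd.Series({
            "E_Coulomb": self.e_coulomb, "E_PB": self.e_pb, "E_NP": self.e_np,
            "E_VDW": self.e_vdw, "E_Valence": self.e_valence,
            "H_MMPBSA": self.total_enthalpy,
        })


def coulomb_energy(coords_a: np.ndarray, charges_a: np.ndarray,
                   coords_b: np.ndarray, charges_b: np.ndarray) -> float:
    """Inter-set Coulomb energy, kcal/mol: k_e Σ q_i q_j / r_ij over all
    pairs between the two (disjoint) sets."""
    coords_a = np.atleast_2d(np.asarray(coords_a, float))
    coords_b = np.atleast_2d(np.asarray(coords_b, float))
    qa = np.atleast_1d(np.asarray(charges_a, float))
    qb = np.atleast_1d(np.asarray(charges_b, float))
    r = cdist(coords_a, coords_b)
    if np.any(r == 0.0):
        raise ValueError("zero interatomic distance in Coulomb sum")
    return float(COULOMB_CONSTANT * np.sum(np.outer(qa, qb) / r))


def lennard_jones_energy(coords_a: np.ndarray, params_a: ForceFieldParameters,
                         coords_b: np.ndarray, params_b: ForceFieldParameters) -> float:
    """Inter-set 12-6 Lennard-Jones energy, kcal/mol, with Lorentz-Berthelot
    combination: r_min = rmin_half_i + rmin_half_j, ε = sqrt(ε_i ε_j);
    E = Σ ε[(r_min/r)¹² − 2(r_min/r)⁶]."""
    coords_a = np.atleast_2d(np.asarray(coords_a, float))
    coords_b = np.atleast_2d(np.asarray(coords_b, float))
    r = cdist(coords_a, coords_b)
    if np.any(r == 0.0):
        raise ValueError("zero interatomic distance in Lennard-Jones sum")
    rmin = params_a.lj_rmin_half[:, None] + params_b.lj_rmin_half[None, :]
    eps = np.sqrt(np.outer(params_a.lj_epsilon, params_b.lj_epsilon))
    x6 = (rmin / r) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


def nonpolar_energy(delta_sasa: float, gamma: float = DEFAULT_NONPOLAR_GAMMA,
                    offset: float = 0.0) -> float:
    """Surface-area nonpolar solvation term: γ·ΔSASA + b, kcal/mol."""
    return gamma * delta_sasa + offset


def mmpbsa_decompose(complex_system: MolecularSystem,
                     receptor_selection: Sequence[int],
                     ligand_selection: Sequence[int],
                     params: ForceFieldParameters,
                     grid: PBGridSpec = PBGridSpec(),
                     sasa_spec: SasaSpec = SasaSpec(),
                     gamma: float = DEFAULT_NONPOLAR_GAMMA,
                     nonpolar_offset: float = 0.0) -> EnergyDecomposition:
    """Single-snapshot MM-PB/SA interaction-energy decomposition.

    Receptor and ligand are cut from the complex geometry without
    relaxation (single-trajectory approximation). The two selections must
    partition the complex.
    """
    rec = sorted(set(int(i) for i in receptor_selection))
    lig = sorted(set(int(i) for i in ligand_selection))
    if set(rec) & set(lig):
        raise ValueError("receptor and ligand selections overlap")
    if set(rec) | set(lig) != set(range(complex_system.n_atoms)):
        raise ValueError("selections must partition the complex")
    coords = complex_system.coords
    p_rec, p_lig = params.subset(rec), params.subset(lig)

    e_coul = coulomb_energy(coords[rec], p_rec.charge, coords[lig], p_lig.charge)
    e_vdw = lennard_jones_energy(coords[rec], p_rec, coords[lig], p_lig)

    e_pb = (pb_solvation_energy(coords, params, grid)
            - pb_solvation_energy(coords[rec], p_rec, grid)
            - pb_solvation_energy(coords[lig], p_lig, grid))

    sasa_cpx, _ = sasa(coords, params.pb_radius, sasa_spec)
    sasa_rec, _ = sasa(coords[rec], p_rec.pb_radius, sasa_spec)
    sasa_lig, _ = sasa(coords[lig], p_lig.pb_radius, sasa_spec)
    e_np = nonpolar_energy(sasa_cpx - sasa_rec - sasa_lig, gamma, nonpolar_offset)

    return EnergyDecomposition(e_coulomb=e_coul, e_pb=e_pb, e_np=e_np, e_vdw=e_vdw)


def mmpbsa_trajectory(traj: Trajectory,
                      receptor_selection: Sequence[int],
                      ligand_selection: Sequence[int],
                      params: ForceFieldParameters,
                      grid: PBGridSpec = PBGridSpec(),
                      sasa_spec: SasaSpec = SasaSpec(),
                      gamma: float = DEFAULT_NONPOLAR_GAMMA,
                      stride: int = 1) -> tuple[EnergyDecomposition, pd.DataFrame]:
    """Frame-averaged MM-PB/SA decomposition over a trajectory.

    Returns the mean decomposition and the per-frame component table.
    """
    rows = []
    for fr in traj.frames[::stride]:
        dec = mmpbsa_decompose(traj.topology.with_coords(fr), receptor_selection,
                               ligand_selection, params, grid, sasa_spec, gamma)
        rows.append(dec.as_series())
    df = pd.DataFrame(rows).reset_index(drop=True)
    mean = df.mean()
    avg = EnergyDecomposition(
        e_coulomb=float(mean["E_Coulomb"]), e_pb=float(mean["E_PB"]),
        e_np=float(mean["E_NP"]), e_vdw=float(mean["E_VDW"]),
        e_valence=float(mean["E_Valence"]))
    return avg, df
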