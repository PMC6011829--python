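"""Rigid-rotor / harmonic-oscillator statistical thermodynamics.

Given an optimized stationary point (electronic energy, geometry, masses,
harmonic frequencies), computes ideal-gas partition-function components and
the derived entropy, enthalpy and Gibbs free energy at a stated temperature
and pressure, following the standard RRHO conventions of quantum-chemistry
codes:

* translation — Sackur-Tetrode at the stated pressure (V = k_B T / P);
* rotation — classical rigid rotor with symmetry number, linear or
  nonlinear detected from the principal moments of inertia;
* vibration — product over real harmonic modes, bottom-of-well reference
  with the zero-point energy separated; the single imaginary mode of a
  transition state is excluded from all thermal functions;
* electronic — spin multiplicity only.

Units: energies kcal/mol, entropies cal/(mol·K), T in K, P in atm.

Activation decompositions ΔG‡ = ΔH‡ + (−TΔS‡) are formed as differences
between a transition state and a reactant reference, which may be a single
pre-reactive supermolecule complex or a sum of separated species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import constants as sc

from .chem_io import FrequencyDataset

R_CAL = sc.R / sc.calorie  # gas constant, cal/(mol·K)
R_KCAL = R_CAL / 1000.0  # kcal/(mol·K)
_AMU = sc.atomic_mass
_ANG = 1e-10


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature (K) and pressure (atm) of the thermodynamic state."""

    temperature: float = 298.15
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and self.pressure > 0):
            raise ValueError("temperature and pressure must be > 0")


@dataclass
class ThermoResult:
    """Partition-function components and derived state functions.

    s_* in cal/(mol·K); zpe, h_total, g_total in kcal/mol. h_total is
    E_elec + ZPE + thermal corrections + RT; g_total = h_total − T·S.
    """

    q_trans: float
    q_rot: float
    q_vib: float
    q_elec: float
    zpe: float
    s_trans: float
    s_rot: float
    s_vib: float
    s_elec: float
    h_total: float
    g_total: float
    temperature: float
    pressure: float
    linear: bool
    title: str = ""

    @property
    def s_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib + self.s_elec


def _principal_moments(masses: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Principal moments of inertia, amu·Å² (ascending)."""
    com = np.average(coords, axis=0, weights=masses)
    x = coords - com
    tensor = np.zeros((3, 3))
    for m, r in zip(masses, x):
        tensor += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    return np.sort(np.linalg.eigvalsh(tensor))


def _rotational_temperatures(moments_amu_A2: np.ndarray) -> np.ndarray:
    """Θ_rot = ħ²/(2 I k_B) for each nonzero principal moment, K."""
    I_si = moments_amu_A2 * _AMU * _ANG ** 2
    with np.errstate(divide="ignore"):
        return sc.hbar ** 2 / (2.0 * I_si * sc.k)


def vibrational_mode_entropy(wavenumber: float, temperature: float = 298.15) -> float:
    """Closed-form harmonic-oscillator entropy of one mode, cal/(mol·K):
    R[x/(eˣ−1) − ln(1−e⁻ˣ)] with x = hcν̃/k_BT."""
    x = sc.h * sc.c * 100.0 * wavenumber / (sc.k * temperature)
    return R_CAL * (x / np.expm1(x) - np.log1p(-np.exp(-x)))


def thermo_result(state: FrequencyDataset,
                  cond: ThermoConditions = ThermoConditions()) -> ThermoResult:
    """RRHO partition functions, S, H and G for one stationary point."""
    T, P = cond.temperature, cond.pressure
    n = state.n_atoms
    freqs = state.real_frequencies

    # translation (Sackur-Tetrode; V = kT/P)
    m_kg = state.masses.sum() * _AMU
    p_pa = P * sc.atm
    q_trans = (2.0 * np.pi * m_kg * sc.k * T / sc.h ** 2) ** 1.5 * sc.k * T / p_pa
    s_trans = R_CAL * (np.log(q_trans) + 2.5)
    e_trans = 1.5 * R_KCAL * T

    # rotation
    if n == 1:
        q_rot, s_rot, e_rot, linear = 1.0, 0.0, 0.0, False
        expected_modes = 0
    else:
        moments = _principal_moments(state.masses, state.coords)
        linear = moments[0] < 1e-8 * moments[2]
        theta = _rotational_temperatures(moments)
        sigma = state.symmetry_number
        if linear:
            q_rot = T / (sigma * theta[1:].mean())
            s_rot = R_CAL * (np.log(q_rot) + 1.0)
            e_rot = R_KCAL * T
            expected_modes = 3 * n - 5
        else:
            q_rot = np.sqrt(np.pi) / sigma * np.sqrt(T ** 3 / np.prod(theta))
            s_rot = R_CAL * (np.log(q_rot) + 1.5)
            e_rot = 1.5 * R_KCAL * T
            expected_modes = 3 * n - 6

    if not state.is_transition_state and len(freqs) < max(0, expected_modes):
        raise ValueError(
            f"minimum with {n} atoms should carry {expected_modes} real modes, "
            f"found {len(freqs)}")

    # vibration (bottom-of-well; ZPE separated)
    x = sc.h * sc.c * 100.0 * freqs / (sc.k * T) if len(freqs) else np.array([])
    q_vib = float(np.prod(1.0 / -np.expm1(-x))) if len(x) else 1.0
    s_vib = float(np.sum(R_CAL * (x / np.expm1(x) - np.log1p(-np.exp(-x))))) if len(x) else 0.0
    e_vib = float(np.sum(R_KCAL * T * x / np.expm1(x))) if len(x) else 0.0
    zpe = float(np.sum(0.5 * sc.h * sc.c * 100.0 * freqs * sc.Avogadro / sc.calorie / 1000.0)) \
        if len(freqs) else 0.0

    # electronic
    q_elec = float(state.multiplicity)
    s_elec = R_CAL * np.log(q_elec)

    s_total = s_trans + s_rot + s_vib + s_elec
    h_total = (state.electronic_energy + zpe + e_trans + e_rot + e_vib + R_KCAL * T)
    g_total = h_total - T * s_total / 1000.0

    return ThermoResult(
        q_trans=float(q_trans), q_rot=float(q_rot), q_vib=q_vib, q_elec=q_elec,
        zpe=zpe, s_trans=float(s_trans), s_rot=float(s_rot), s_vib=s_vib,
        s_elec=float(s_elec), h_total=float(h_total), g_total=float(g_total),
        temperature=T, pressure=P, linear=bool(linear) if n > 1 else False,
        title=state.title)


@dataclass
class ActivationDecomposition:
    """ΔG‡ = ΔH‡ + (−TΔS‡), kcal/mol, with the reactant reference mode
    recorded ('supermolecule' for one pre-reactive complex, 'separated'
    for a sum of species)."""

    delta_g: float
    delta_h: float
    minus_t_delta_s: float
    reference: str = "supermolecule"


def activation_decomposition(reactants: ThermoResult | Sequence[ThermoResult],
                             ts: ThermoResult) -> ActivationDecomposition:
    """Activation free energy and its enthalpy/entropy split.

    ΔG‡ = G(TS) − ΣG(reactants), likewise for H; −TΔS‡ = ΔG‡ − ΔH‡.
    A single reactant is the supermolecule reference; a sequence is the
    separated-species reference.
    """
    if isinstance(reactants, ThermoResult):
        parts: list[ThermoResult] = [reactants]
        reference = "supermolecule"
    else:
        parts = list(reactants)
        reference = "supermolecule" if len(parts) == 1 else "separated"
    if not parts:
        raise ValueError("no reactants given")
    for r in parts:
        if abs(r.temperature - ts.temperature) > 1e-9:
            raise ValueError(
                f"mismatched temperatures: reactant at {r.temperature} K, "
                f"TS at {ts.temperature} K")
    delta_g = ts.g_total - sum(r.g_total for r in parts)
    delta_h = ts.h_total - sum(r.h_total for r in parts)
    return ActivationDecomposition(
        delta_g=delta_g, delta_h=delta_h,
        minus_t_delta_s=delta_g - delta_h, reference=reference)


def check_free_energy_identity(table: pd.DataFrame,
                               dg: str = "dg", dh: str = "dh",
                               minus_tds: str = "minus_tds",
                               tolerance: float = 0.015) -> pd.DataFrame:
    """Per-row residual of ΔG − (ΔH + (−TΔS)) with a flag at ``tolerance``
    (default 0.015 kcal/mol, the allowance for values printed to 0.01)."""
    residual = table[dg] - (table[dh] + table[minus_tds])
    out = table.copy()
    out["residual"] = residual
    out["flagged"] = residual.abs() > tolerance
    return out
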