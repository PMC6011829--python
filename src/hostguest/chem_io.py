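"""Readers and writers for structures, trajectories, parameter tables and
frequency datasets.

All downstream analysis consumes only the container types defined here.
Units follow the conventions used throughout the package: lengths in Å,
energies in kcal/mol, entropies in cal/(mol·K), time in ps (trajectory
metadata) or ns (kinetics / dwell times), charges in elementary charge e,
masses in amu, frequencies in cm⁻¹.

Formats
-------
* **PDB** — read/written through MDAnalysis (``ATOM``/``HETATM`` records,
  multi-``MODEL`` files supported for trajectories).
* **multi-model XYZ** — the package's canonical trajectory interchange: a
  plain concatenation of XYZ blocks (atom count line, comment line, one
  ``element x y z`` line per atom), all blocks with identical atom counts.
* **parameter table** — CSV with header ``index,charge,epsilon,rmin_half,
  pb_radius`` (units e, kcal/mol, Å, Å; no conversion applied).
* **frequency dataset** — YAML with scalar keys ``electronic_energy``
  (kcal/mol), ``symmetry_number``, ``multiplicity``,
  ``is_transition_state`` and list keys ``masses`` (amu), ``coords``
  (N×3, Å), ``frequencies`` (cm⁻¹; a transition state carries exactly one
  negative entry encoding its imaginary mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# --------------------------------------------------------------------------
# container types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom: index, element symbol, short name, residue id, coordinates (Å)."""

    index: int
    element: str
    name: str
    residue_id: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.index}")
        if not self.element:
            raise ValueError(f"empty element symbol for atom {self.index}")
        if self.index < 0:
            raise ValueError("atom index must be >= 0")


class MolecularSystem:
    """An ordered collection of atoms with a title.

    Atom indices must be unique and consecutive from 0; this is what lets
    every selection in the package be a plain integer index set.
    """

    def __init__(self, atoms: Sequence[AtomRecord], title: str = "") -> None:
        atoms = list(atoms)
        indices = [a.index for a in atoms]
        if indices != list(range(len(atoms))):
            raise ValueError("atom indices must be unique and consecutive from 0")
        self.atoms = atoms
        self.title = title

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "MolecularSystem":
        """Copy of this system with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape {(self.n_atoms, 3)}, got {coords.shape}")
        atoms = [
            AtomRecord(a.index, a.element, a.name, a.residue_id, c)
            for a, c in zip(self.atoms, coords)
        ]
        return MolecularSystem(atoms, self.title if title is None else title)

    def subset(self, indices: Sequence[int], title: str = "") -> "MolecularSystem":
        """New system from a selection, reindexed from 0 (original order kept)."""
        idx = sorted(set(int(i) for i in indices))
        atoms = [
            AtomRecord(k, self.atoms[i].element, self.atoms[i].name,
                       self.atoms[i].residue_id, self.atoms[i].coords)
            for k, i in enumerate(idx)
        ]
        return MolecularSystem(atoms, title)

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return f"MolecularSystem({self.n_atoms} atoms, title={self.title!r})"


class Trajectory:
    """Ordered frames of coordinates over a fixed topology.

    Parameters
    ----------
    frames : array-like, shape (n_frames, n_atoms, 3), Å
    frame_interval : float
        Time between consecutive frames, ps. This is metadata supplied by
        the caller (trajectory files do not carry it); default 20 ps.
    topology : MolecularSystem
    """

    def __init__(self, frames: np.ndarray, frame_interval: float,
                 topology: MolecularSystem) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (n_frames, n_atoms, 3), got {frames.shape}")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frames have {frames.shape[1]} atoms but topology has {topology.n_atoms}")
        if not frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        self.frames = frames
        self.frame_interval = float(frame_interval)
        self.topology = topology

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def total_time_ns(self) -> float:
        return self.n_frames * self.frame_interval / 1000.0

    def __len__(self) -> int:
        return self.n_frames

    def __repr__(self) -> str:
        return (f"Trajectory({self.n_frames} frames x {self.n_atoms} atoms, "
                f"dt={self.frame_interval} ps)")


@dataclass
class ForceFieldParameters:
    """Per-atom non-bonded parameters: charge (e), LJ well depth ε (kcal/mol),
    LJ r_min/2 (Å), and PB cavity radius (Å)."""

    charge: np.ndarray
    lj_epsilon: np.ndarray
    lj_rmin_half: np.ndarray
    pb_radius: np.ndarray

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        self.pb_radius = np.asarray(self.pb_radius, dtype=float)
        n = len(self.charge)
        for arr, nm in ((self.lj_epsilon, "lj_epsilon"),
                        (self.lj_rmin_half, "lj_rmin_half"),
                        (self.pb_radius, "pb_radius")):
            if len(arr) != n:
                raise ValueError(f"{nm} has {len(arr)} entries, expected {n}")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be >= 0")
        if np.any(self.pb_radius <= 0):
            raise ValueError("pb_radius must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    def subset(self, indices: Sequence[int]) -> "ForceFieldParameters":
        idx = sorted(set(int(i) for i in indices))
        return ForceFieldParameters(
            self.charge[idx], self.lj_epsilon[idx],
            self.lj_rmin_half[idx], self.pb_radius[idx])


@dataclass
class FrequencyDataset:
    """Electronic energy, geometry, masses and harmonic frequencies of one
    optimized stationary point, as needed for RRHO thermochemistry.

    A transition state carries exactly one negative frequency entry (the
    imaginary mode, stored as -|ν̃|); a minimum carries none.
    """

    electronic_energy: float
    masses: np.ndarray
    coords: np.ndarray
    frequencies: np.ndarray
    symmetry_number: int = 1
    multiplicity: int = 1
    is_transition_state: bool = False
    title: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.coords.shape[0] != len(self.masses):
            raise ValueError("coords and masses disagree on atom count")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be > 0")
        if self.symmetry_number < 1 or self.multiplicity < 1:
            raise ValueError("symmetry_number and multiplicity must be >= 1")
        n_imag = int(np.sum(self.frequencies < 0))
        if self.is_transition_state and n_imag != 1:
            raise ValueError(
                f"transition state must have exactly one imaginary (negative) "
                f"frequency, found {n_imag}")
        if not self.is_transition_state and n_imag != 0:
            raise ValueError(
                f"minimum declared but {n_imag} negative frequencies present")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def real_frequencies(self) -> np.ndarray:
        """Real vibrational modes (imaginary TS mode excluded)."""
        return self.frequencies[self.frequencies > 0]


# --------------------------------------------------------------------------
# structure I/O
# --------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "X"
    # two-letter symbols only when the second char is lower-case in the file
    if len(stripped) >= 2 and stripped[1].islower():
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _mda_universe(path: Path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def _system_from_universe(u, title: str) -> MolecularSystem:
    n = len(u.atoms)
    try:
        names = [str(x) for x in u.atoms.names]
    except Exception:
        names = [f"A{i}" for i in range(n)]
    try:
        elements = [str(e) if str(e).strip() else _element_from_name(names[i])
                    for i, e in enumerate(u.atoms.elements)]
    except Exception:
        elements = [_element_from_name(nm) for nm in names]
    try:
        resids = [int(r) for r in u.atoms.resids]
    except Exception:
        resids = [1] * n
    coords = np.asarray(u.atoms.positions, dtype=float)
    atoms = [AtomRecord(i, elements[i], names[i], resids[i], coords[i]) for i in range(n)]
    return MolecularSystem(atoms, title=title)


def read_structure(path: str | Path, format: str | None = None) -> MolecularSystem:
    """Read a single-model structure from a PDB or XYZ file.

    ``format`` may be ``"pdb"`` or ``"xyz"``; when omitted it is inferred
    from the file suffix. PDB coordinates are read at the format's 0.001 Å
    precision. A multi-model file yields its first model (use
    :func:`read_trajectory` for all of them).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        frames, systems = _read_xyz_models(path)
        return systems
    if fmt == "pdb":
        try:
            u = _mda_universe(path)
        except Exception as exc:  # surface MDAnalysis failures as parse errors
            raise ParseError(f"{path}: failed to parse PDB: {exc}") from exc
        return _system_from_universe(u, title=path.stem)
    raise ValueError(f"unknown structure format {fmt!r}")


def write_structure(system: MolecularSystem, path: str | Path) -> None:
    """Write a system to PDB or XYZ (inferred from suffix)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        _write_xyz_frames(path, system, system.coords[None, :, :])
        return
    if fmt == "pdb":
        _write_pdb(path, system, system.coords[None, :, :])
        return
    raise ValueError(f"unknown structure format {fmt!r}")


def _write_pdb(path: Path, system: MolecularSystem, frames: np.ndarray) -> None:
    import MDAnalysis as mda

    n = system.n_atoms
    resids = [a.residue_id for a in system.atoms]
    uniq = sorted(set(resids))
    resmap = {r: k for k, r in enumerate(uniq)}
    u = mda.Universe.empty(n, n_residues=len(uniq),
                           atom_resindex=[resmap[r] for r in resids],
                           trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in system.atoms])
    u.add_TopologyAttr("elements", [a.element for a in system.atoms])
    u.add_TopologyAttr("resids", uniq)
    u.add_TopologyAttr("resnames", ["MOL"] * len(uniq))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=len(frames) > 1) as w:
            for fr in frames:
                u.atoms.positions = fr
                w.write(u.atoms)


# --------------------------------------------------------------------------
# multi-model XYZ
# --------------------------------------------------------------------------

def _read_xyz_models(path: Path):
    """Parse a (possibly multi-model) XYZ file.

    Returns (frames array (m, n, 3), MolecularSystem from model 1).
    """
    lines = path.read_text().splitlines()
    pos = 0
    frames: list[np.ndarray] = []
    first_atoms: list[AtomRecord] | None = None
    n_expected: int | None = None
    model = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        model += 1
        try:
            n = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}, line {pos + 1}: expected an atom count, got {lines[pos]!r}")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise ParseError(
                f"{path}: frame {model} declares {n} atoms, expected {n_expected}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n or any(len(ln.split()) < 4 for ln in body):
            raise ParseError(f"{path}: frame {model} is truncated ({len(body)} of {n} atoms)")
        coords = np.empty((n, 3))
        symbols: list[str] = []
        for i, ln in enumerate(body):
            parts = ln.split()
            try:
                coords[i] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}, line {pos + 3 + i}: malformed coordinate record {ln!r}")
            symbols.append(parts[0])
        if first_atoms is None:
            first_atoms = [AtomRecord(i, s, s, 1, coords[i]) for i, s in enumerate(symbols)]
            title = comment.strip()
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ParseError(f"{path}: empty file")
    return np.array(frames), MolecularSystem(first_atoms, title=title)


def _write_xyz_frames(path: Path, system: MolecularSystem, frames: np.ndarray) -> None:
    elements = system.elements
    with open(path, "w") as fh:
        for k, fr in enumerate(frames):
            fh.write(f"{system.n_atoms}\n")
            fh.write(f"{system.title or 'frame'} {k}\n")
            for el, (x, y, z) in zip(elements, fr):
                fh.write(f"{el:<3s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def read_trajectory(path: str | Path, frame_interval: float = 20.0) -> Trajectory:
    """Read a multi-model XYZ (or multi-MODEL PDB) trajectory.

    ``frame_interval`` (ps) is caller-supplied metadata; neither format
    carries it. Every model must have the same atom count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        frames, system = _read_xyz_models(path)
        return Trajectory(frames, frame_interval, system)
    if fmt == "pdb":
        try:
            u = _mda_universe(path)
            system = _system_from_universe(u, title=path.stem)
            frames = np.array([np.asarray(ts.positions, dtype=float) for ts in u.trajectory])
        except Exception as exc:
            raise ParseError(f"{path}: failed to parse PDB trajectory: {exc}") from exc
        return Trajectory(frames, frame_interval, system)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model XYZ (or multi-MODEL PDB)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        _write_xyz_frames(path, traj.topology, traj.frames)
    elif fmt == "pdb":
        _write_pdb(path, traj.topology, traj.frames)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


# --------------------------------------------------------------------------
# parameter table
# --------------------------------------------------------------------------

_PARAM_COLUMNS = ["index", "charge", "epsilon", "rmin_half", "pb_radius"]


def read_parameter_table(path: str | Path, n_atoms: int | None = None) -> ForceFieldParameters:
    """Read per-atom parameters from CSV (columns
    ``index,charge,epsilon,rmin_half,pb_radius``; unit passthrough).

    When ``n_atoms`` is given, the table must cover exactly the indices
    0..n_atoms-1; missing indices are reported.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    idx = df["index"].to_numpy(dtype=int)
    dupes = sorted({int(i) for i in idx[pd.Series(idx).duplicated().to_numpy()]})
    if dupes:
        raise ParseError(f"{path}: duplicated atom indices {dupes}")
    n = n_atoms if n_atoms is not None else (idx.max() + 1 if len(idx) else 0)
    missing = sorted(set(range(n)) - set(idx.tolist()))
    if missing:
        raise ParseError(f"{path}: missing atom indices {missing}")
    order = np.argsort(idx)
    return ForceFieldParameters(
        charge=df["charge"].to_numpy(float)[order],
        lj_epsilon=df["epsilon"].to_numpy(float)[order],
        lj_rmin_half=df["rmin_half"].to_numpy(float)[order],
        pb_radius=df["pb_radius"].to_numpy(float)[order],
    )


def write_parameter_table(params: ForceFieldParameters, path: str | Path) -> None:
    pd.DataFrame({
        "index": np.arange(params.n_atoms),
        "charge": params.charge,
        "epsilon": params.lj_epsilon,
        "rmin_half": params.lj_rmin_half,
        "pb_radius": params.pb_radius,
    }).to_csv(path, index=False)


# --------------------------------------------------------------------------
# frequency dataset
# --------------------------------------------------------------------------

def read_frequency_dataset(path: str | Path) -> FrequencyDataset:
    """Read a frequency dataset from the package's YAML dialect."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a key-value document")
    required = {"electronic_energy", "masses", "coords", "frequencies"}
    missing = sorted(required - set(data))
    if missing:
        raise ParseError(f"{path}: missing keys {missing}")
    try:
        return FrequencyDataset(
            electronic_energy=float(data["electronic_energy"]),
            masses=np.asarray(data["masses"], dtype=float),
            coords=np.asarray(data["coords"], dtype=float),
            frequencies=np.asarray(data["frequencies"], dtype=float),
            symmetry_number=int(data.get("symmetry_number", 1)),
            multiplicity=int(data.get("multiplicity", 1)),
            is_transition_state=bool(data.get("is_transition_state", False)),
            title=str(data.get("title", path.stem)),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_frequency_dataset(ds: FrequencyDataset, path: str | Path) -> None:
    doc = {
        "title": ds.title,
        "electronic_energy": float(ds.electronic_energy),
        "symmetry_number": int(ds.symmetry_number),
        "multiplicity": int(ds.multiplicity),
        "is_transition_state": bool(ds.is_transition_state),
        "masses": [float(m) for m in ds.masses],
        "coords": [[float(x) for x in row] for row in ds.coords],
        "frequencies": [float(f) for f in ds.frequencies],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
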