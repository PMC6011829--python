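"""Synthetic host-guest fixtures with known ground truth.

The generator builds a toy truncated-cone host (two stacked rings of
pseudo-atoms with hydroxyl-like donor sites on the wide rim) plus two small
guests, and samples trajectories whose statistical structure matches what
the trajectory-analysis stage measures:

* guest A ("maleimide-like": two rigid moieties, one carrying an H-bond
  acceptor) sits in the cavity at a depth drawn per frame from
  Normal(depth_mean, depth_sd) along the host axis; with probability
  ``p_hbond`` its acceptor is placed in H-bonding geometry against a wide-rim
  donor (1.9 Å, 10° off linear), otherwise well outside the criterion;
* guest B ("diene-like") hops between a bound pose in the cavity and an
  unbound pose ≥ 10 Å away following a two-state Markov chain with rates
  k_on/k_off (per-frame transition probabilities 1 − exp(−k·Δt));
* all atoms get Gaussian coordinate jitter of ``noise_sd``.

Every random draw comes from one seeded generator, so identical parameters
and seed give bit-identical trajectories and ground truth.

Defaults model the dimethylated host system: 3000 frames spanning 300 ns,
H-bond probability 0.0067, stationary residence occupancy
k_on/(k_on+k_off) ≈ 0.349 with a 10-ns mean dwell, and a binding depth of
2.05 ± 0.73 Å toward the wide rim.

Thermochemistry and Born-ion fixtures with closed-form answers are provided
for the thermodynamics and PB stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc

from .chem_io import (AtomRecord, ForceFieldParameters, FrequencyDataset,
                      MolecularSystem, Trajectory)
from .pb import born_energy
from .thermo import R_CAL, R_KCAL, ThermoConditions, thermo_result, vibrational_mode_entropy

__all__ = [
    "SyntheticTrajectoryParams", "GroundTruth", "ToyHost", "build_toy_host",
    "simulate_binding_trajectory", "make_thermo_fixture", "make_born_fixture",
]


@dataclass(frozen=True)
class SyntheticTrajectoryParams:
    """Knobs of the synthetic binding trajectory (defaults = study-like
    conditions; see module docstring)."""

    n_frames: int = 3000
    frame_interval: float = 100.0  # ps; 3000 frames -> 300 ns
    p_hbond: float = 0.0067
    depth_mean: float = 2.05  # Å, toward the wide rim
    depth_sd: float = 0.73
    k_on: float = 0.0536  # ns⁻¹
    k_off: float = 0.1  # ns⁻¹; stationary occupancy k_on/(k_on+k_off) ≈ 0.349
    noise_sd: float = 0.1  # Å
    seed: int = 0
    start_bound: bool | None = None  # None -> drawn from the stationary law

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hbond <= 1.0):
            raise ValueError("p_hbond must be in [0, 1]")
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def stationary_occupancy(self) -> float:
        """Long-run bound fraction of the two-state chain."""
        if self.k_on + self.k_off == 0:
            return 1.0 if (self.start_bound is None or self.start_bound) else 0.0
        return self.k_on / (self.k_on + self.k_off)


@dataclass
class GroundTruth:
    """Imposed per-frame truth: H-bond flags, bound flags, depth (Å)."""

    hbond_flags: np.ndarray
    bound_flags: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.hbond_flags)
        if not (len(self.bound_flags) == len(self.depth) == n):
            raise ValueError("ground-truth series must have equal lengths")


@dataclass
class ToyHost:
    """Toy host bundle: structure plus the selections every analysis needs.

    ``host`` is the ring-atom selection used for the cavity geometric
    center (the donor hydroxyls sit above the wide rim and are excluded so
    the center of the default host is exactly the origin)."""

    system: MolecularSystem
    host: list[int]
    narrow_rim: list[int]
    wide_rim: list[int]
    donors: list[tuple[int, int]]  # (O, H) pairs on the wide rim


def build_toy_host(n_units: int = 7, narrow_radius: float = 3.0,
                   wide_radius: float = 4.5, height: float = 4.0) -> ToyHost:
    """Deterministic truncated-cone host.

    Two rings of ``n_units`` carbon pseudo-atoms (narrow rim at z = −h/2,
    wide rim at +h/2) and one O-H donor site above each wide-rim atom,
    mimicking the secondary-hydroxyl face of a cyclodextrin. The host
    frame of the result is centered at the origin with axis (0, 0, 1).
    """
    if n_units < 3:
        raise ValueError("n_units must be >= 3")
    if narrow_radius <= 0 or wide_radius <= 0:
        raise ValueError("rim radii must be > 0")
    angles = 2.0 * np.pi * np.arange(n_units) / n_units
    atoms: list[AtomRecord] = []
    narrow, wide, donors = [], [], []
    for k, a in enumerate(angles):
        atoms.append(AtomRecord(len(atoms), "C", f"CN{k}", 1,
                                [narrow_radius * np.cos(a), narrow_radius * np.sin(a),
                                 -height / 2.0]))
        narrow.append(atoms[-1].index)
    for k, a in enumerate(angles):
        atoms.append(AtomRecord(len(atoms), "C", f"CW{k}", 1,
                                [wide_radius * np.cos(a), wide_radius * np.sin(a),
                                 height / 2.0]))
        wide.append(atoms[-1].index)
    for k, a in enumerate(angles):
        base = np.array([wide_radius * np.cos(a), wide_radius * np.sin(a), height / 2.0])
        o_pos = base + np.array([0.0, 0.0, 0.6])
        h_pos = o_pos + 0.96 * np.array([-np.cos(a) * 0.5, -np.sin(a) * 0.5, 0.5]) / np.linalg.norm([0.5 * np.cos(a), 0.5 * np.sin(a), 0.5])
        atoms.append(AtomRecord(len(atoms), "O", f"OW{k}", 1, o_pos))
        o_idx = atoms[-1].index
        atoms.append(AtomRecord(len(atoms), "H", f"HW{k}", 1, h_pos))
        donors.append((o_idx, atoms[-1].index))
    system = MolecularSystem(atoms, title=f"toy truncated-cone host ({n_units} units)")
    return ToyHost(system=system, host=narrow + wide, narrow_rim=narrow,
                   wide_rim=wide, donors=donors)


# guest templates: rigid point clusters, coordinates relative to their centroid
def _guest_a_template() -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Two-moiety guest: a 'cyclohexyl' blob 1 Å below the centroid and an
    'imide' blob 1 Å above it whose first atom is the H-bond acceptor."""
    coords = np.array([
        # cyclohexyl-like moiety, centroid at (0, 0, -1)
        [0.6, 0.0, -1.0], [-0.3, 0.5, -1.0], [-0.3, -0.5, -1.0],
        # imide-like moiety, centroid at (0, 0, +1); atom 3 is the carbonyl O
        [0.0, 0.0, 1.6], [0.5, 0.0, 0.7], [-0.5, 0.0, 0.7],
    ])
    elements = ["C", "C", "C", "O", "C", "N"]
    groups = {"cyclohexyl": [0, 1, 2], "imide": [3, 4, 5], "acceptor": [3]}
    return coords, elements, groups


def _guest_b_template() -> tuple[np.ndarray, list[str]]:
    """Small rigid 'diene-like' guest."""
    coords = np.array([
        [0.7, 0.0, 0.0], [-0.7, 0.0, 0.0], [0.0, 0.7, 0.0], [0.0, -0.7, 0.0],
    ])
    return coords, ["C", "C", "C", "C"]


@dataclass
class SyntheticBundle:
    """Trajectory plus ground truth plus the selections for analysis.

    ``reference`` is the noise-free bound-state conformation (guest B in
    its cavity pose), the natural reference for RMSD-based bound-state
    classification."""

    trajectory: Trajectory
    ground_truth: GroundTruth
    host: ToyHost
    selections: dict
    reference: np.ndarray


def simulate_binding_trajectory(host: ToyHost | None = None,
                                params: SyntheticTrajectoryParams = SyntheticTrajectoryParams(),
                                ) -> SyntheticBundle:
    """Sample a synthetic binding trajectory with known ground truth.

    See the module docstring for the generative model. The returned
    selections dictionary carries every index set the analysis stages
    need (host/rims/donors, guest moieties, acceptor, second guest).
    """
    if host is None:
        host = build_toy_host()
    rng = np.random.default_rng(params.seed)
    host_xyz = host.system.coords
    nh = host.system.n_atoms

    ga_xyz, ga_el, ga_groups = _guest_a_template()
    gb_xyz, gb_el = _guest_b_template()
    na, nb = len(ga_xyz), len(gb_xyz)

    # assemble topology from frame-0 layout (placed below)
    sel = {
        "host": host.host,
        "narrow_rim": host.narrow_rim,
        "wide_rim": host.wide_rim,
        "donors": [(x, h) for x, h in host.donors],
        "guest_a": [nh + i for i in range(na)],
        "guest_a_cyclohexyl": [nh + i for i in ga_groups["cyclohexyl"]],
        "guest_a_imide": [nh + i for i in ga_groups["imide"]],
        "acceptors": [nh + ga_groups["acceptor"][0]],
        "guest_b": [nh + na + i for i in range(nb)],
    }
    acceptor_local = ga_groups["acceptor"][0]

    dt_ns = params.frame_interval / 1000.0
    p_on = 1.0 - np.exp(-params.k_on * dt_ns)
    p_off = 1.0 - np.exp(-params.k_off * dt_ns)

    if params.start_bound is None:
        bound = bool(rng.random() < params.stationary_occupancy)
    else:
        bound = bool(params.start_bound)

    bound_pose = np.array([0.3, 0.2, 0.8])  # fixed pose inside the cavity
    n_don = len(host.donors)

    frames = np.empty((params.n_frames, nh + na + nb, 3))
    hb_flags = np.empty(params.n_frames, dtype=bool)
    bd_flags = np.empty(params.n_frames, dtype=bool)
    depths = np.empty(params.n_frames)

    for t in range(params.n_frames):
        fr = np.empty((nh + na + nb, 3))
        fr[:nh] = host_xyz

        depth = rng.normal(params.depth_mean, params.depth_sd)
        depths[t] = depth
        # the guest body (acceptor included) never reaches the donor sites on
        # its own: its closest approach to any wide-rim O-H exceeds 4 Å, so
        # only the explicit placement below can create an H-bond
        fr[nh:nh + na] = ga_xyz + np.array([0.0, 0.0, depth])
        hb = bool(rng.random() < params.p_hbond)
        hb_flags[t] = hb
        don_idx = int(rng.integers(n_don))

        if t > 0:
            if bound and rng.random() < p_off:
                bound = False
            elif not bound and rng.random() < p_on:
                bound = True
        bd_flags[t] = bound
        if bound:
            gb = gb_xyz + bound_pose
        else:
            az = rng.uniform(0.0, 2.0 * np.pi)
            gb = gb_xyz + np.array([14.0 * np.cos(az), 14.0 * np.sin(az), 6.0])
        fr[nh + na:] = gb

        fr += rng.normal(0.0, params.noise_sd, size=fr.shape)

        if hb:
            # exact criterion-satisfying geometry in the final (jittered)
            # frame: acceptor 1.9 Å from the donor H, 10° off linearity
            don_o, don_h = host.donors[don_idx]
            o_pos, h_pos = fr[don_o], fr[don_h]
            xh = h_pos - o_pos
            xh /= np.linalg.norm(xh)
            perp = np.cross(xh, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(xh, [1.0, 0.0, 0.0])
            perp /= np.linalg.norm(perp)
            off_linear = (np.cos(np.radians(10.0)) * xh
                          + np.sin(np.radians(10.0)) * perp)
            fr[nh + acceptor_local] = h_pos + 1.9 * off_linear
        frames[t] = fr

    atoms = list(host.system.atoms)
    for i, el in enumerate(ga_el):
        atoms.append(AtomRecord(nh + i, el, f"GA{i}", 2, frames[0, nh + i]))
    for i, el in enumerate(gb_el):
        atoms.append(AtomRecord(nh + na + i, el, f"GB{i}", 3, frames[0, nh + na + i]))
    topology = MolecularSystem(atoms, title="synthetic host-guest complex")

    reference = np.empty((nh + na + nb, 3))
    reference[:nh] = host_xyz
    reference[nh:nh + na] = ga_xyz + np.array([0.0, 0.0, params.depth_mean])
    reference[nh + na:] = gb_xyz + bound_pose

    traj = Trajectory(frames, params.frame_interval, topology)
    return SyntheticBundle(
        trajectory=traj,
        ground_truth=GroundTruth(hb_flags, bd_flags, depths),
        host=host,
        selections=sel,
        reference=reference,
    )


def default_force_field(system: MolecularSystem, seed: int = 0) -> ForceFieldParameters:
    """Plausible per-atom parameters for toy systems (element-typed charges
    and Amber-like LJ/PB radii; net charge not constrained)."""
    table = {
        "C": (0.05, 0.1094, 1.9080, 1.7),
        "O": (-0.50, 0.2100, 1.6612, 1.5),
        "N": (-0.40, 0.1700, 1.8240, 1.55),
        "H": (0.30, 0.0157, 0.6000, 1.0),
    }
    rows = [table.get(a.element, (0.0, 0.1, 1.8, 1.6)) for a in system.atoms]
    arr = np.array(rows)
    return ForceFieldParameters(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


# --------------------------------------------------------------------------
# closed-form thermochemistry fixtures
# --------------------------------------------------------------------------

def _sackur_tetrode(mass_amu: float, T: float, P_atm: float) -> float:
    """Closed-form monatomic translational entropy, cal/(mol·K)."""
    m = mass_amu * sc.atomic_mass
    q = (2.0 * np.pi * m * sc.k * T / sc.h ** 2) ** 1.5 * sc.k * T / (P_atm * sc.atm)
    return R_CAL * (np.log(q) + 2.5)


def make_thermo_fixture(kind: str, cond: ThermoConditions = ThermoConditions(), **kw):
    """Frequency datasets with analytically known thermodynamics.

    kind='monatomic' (kw: mass) -> (dataset, {'s_total': Sackur-Tetrode})
    kind='diatomic' (kw: masses, bond_length, frequency, symmetry_number)
        -> (dataset, {'s_trans', 's_vib'}) with closed forms
    kind='ts_pair' (kw: barrier, dropped_mode) -> ((reactant, ts),
        {'delta_h', 'minus_t_delta_s', 'delta_g'}): the TS equals the
        reactant geometry with one low-frequency mode removed (replaced by
        the imaginary mode) and the electronic energy raised by ``barrier``,
        so the activation entropy is exactly that mode's closed-form
        harmonic entropy.
    """
    T = cond.temperature
    if kind == "monatomic":
        mass = kw.get("mass", 39.948)
        ds = FrequencyDataset(0.0, [mass], [[0.0, 0.0, 0.0]], [], title="monatomic")
        return ds, {"s_total": _sackur_tetrode(mass, T, cond.pressure)}
    if kind == "diatomic":
        masses = kw.get("masses", (14.003074, 14.003074))
        bond = kw.get("bond_length", 1.0977)
        freq = kw.get("frequency", 2358.6)
        sigma = kw.get("symmetry_number", 2)
        ds = FrequencyDataset(0.0, list(masses),
                              [[0.0, 0.0, 0.0], [0.0, 0.0, bond]], [freq],
                              symmetry_number=sigma, title="diatomic")
        return ds, {
            "s_trans": _sackur_tetrode(sum(masses), T, cond.pressure),
            "s_vib": vibrational_mode_entropy(freq, T),
        }
    if kind == "ts_pair":
        barrier = kw.get("barrier", 15.0)
        dropped = kw.get("dropped_mode", 50.0)
        masses = [12.011, 12.011, 15.999, 1.008]
        coords = [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.2, 1.1, 0.0], [-0.9, 0.7, 0.3]]
        base_modes = [3000.0, 1500.0, 1200.0, 800.0, 400.0]
        reactant = FrequencyDataset(0.0, masses, coords, base_modes + [dropped],
                                    title="reactant")
        ts = FrequencyDataset(barrier, masses, coords, base_modes + [-500.0],
                              is_transition_state=True, title="ts")
        # same geometry/masses: trans+rot+elec cancel exactly; only the
        # dropped mode's vibrational functions survive in the difference
        x = sc.h * sc.c * 100.0 * dropped / (sc.k * T)
        e_mode = R_KCAL * T * x / np.expm1(x)
        zpe_mode = 0.5 * sc.h * sc.c * 100.0 * dropped * sc.Avogadro / sc.calorie / 1000.0
        s_mode = vibrational_mode_entropy(dropped, T)
        delta_h = barrier - zpe_mode - e_mode
        minus_t_delta_s = T * s_mode / 1000.0
        return (reactant, ts), {
            "delta_h": delta_h,
            "minus_t_delta_s": minus_t_delta_s,
            "delta_g": delta_h + minus_t_delta_s,
        }
    raise ValueError(f"unknown thermo fixture kind {kind!r}")


def make_born_fixture(charge: float = 1.0, radius: float = 2.0,
                      eps_out: float = 80.0):
    """One-ion PB fixture with its analytic Born solvation energy."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    system = MolecularSystem(
        [AtomRecord(0, "Na", "ION", 1, [0.0, 0.0, 0.0])], title="Born ion")
    params = ForceFieldParameters([charge], [0.1], [1.5], [radius])
    return system, params, born_energy(charge, radius, eps_out)
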