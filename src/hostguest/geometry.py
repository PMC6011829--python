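"""Trajectory statistics for host-guest complexes.

Implements the quantities used to characterise guest binding in a
truncated-cone host (a cyclodextrin-like macrocycle):

* hydrogen-bond detection under a distance + linearity criterion, and the
  per-trajectory occurrence percentage;
* a host-fixed reference frame (cavity center and narrow-rim → wide-rim
  axis) and signed binding-depth metrics d1/d2/d3 for a guest and its
  moieties;
* guest RMSD after least-squares superposition on the host, a bound-state
  classification by RMSD threshold, and residence (occupancy / dwell-time)
  summaries for a ternary complex.

Sign convention for depths: positive values point toward the wide rim,
so a small or negative value means the guest sits deep in the cavity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .chem_io import MolecularSystem, Trajectory

__all__ = [
    "HbondCriterion", "HostFrameAxes", "DepthMetrics", "ResidenceSeries",
    "ResidenceSummary", "HbondOccupancy", "host_frame", "detect_hbonds",
    "hbond_occupancy", "depth_metrics", "depth_metrics_trajectory",
    "guest_rmsd", "classify_bound", "residence_summary",
]


@dataclass(frozen=True)
class HbondCriterion:
    """Geometric H-bond rule for X-H···Y: H···Y distance strictly below
    ``max_h_acceptor_distance`` (Å) and deviation from linearity,
    180° − angle(X-H···Y), strictly below ``max_linearity_deviation``
    (degrees)."""

    max_h_acceptor_distance: float = 2.2
    max_linearity_deviation: float = 90.0

    def __post_init__(self) -> None:
        if not (self.max_h_acceptor_distance > 0 and self.max_linearity_deviation > 0):
            raise ValueError("criterion thresholds must be strictly positive")


@dataclass(frozen=True)
class HostFrameAxes:
    """Host reference frame: cavity geometric center and unit axis oriented
    narrow rim → wide rim."""

    center: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"axis must be a unit vector (|axis| = {norm})")
        object.__setattr__(self, "axis", axis)


@dataclass(frozen=True)
class DepthMetrics:
    """Signed distances (Å) along the host axis: whole guest (d1),
    first moiety (d2), second moiety (d3)."""

    d1: float
    d2: float
    d3: float


@dataclass
class ResidenceSeries:
    """Per-frame bound/unbound flags with the trajectory frame interval (ps)."""

    bound_flags: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.bound_flags = np.asarray(self.bound_flags, dtype=bool)
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")


@dataclass
class ResidenceSummary:
    """Occupancy percentage and dwell-time statistics (ns)."""

    occupancy_percent: float
    dwell_times: np.ndarray  # ns, one entry per maximal contiguous bound run
    max_dwell: float  # ns
    n_frames: int
    n_bound: int


@dataclass
class HbondOccupancy:
    """Frame-level occurrence percentage plus per-donor-acceptor breakdown."""

    percent: float
    per_pair: pd.Series  # index (X, H, Y) -> percentage
    frame_flags: np.ndarray  # per-frame: any H-bond present
    n_frames: int


# --------------------------------------------------------------------------
# host frame and depths
# --------------------------------------------------------------------------

def _heavy_indices(system: MolecularSystem, selection: Iterable[int]) -> list[int]:
    return [i for i in selection if system.atoms[i].element.upper() != "H"]


def host_frame(system: MolecularSystem | np.ndarray,
               host_selection: Sequence[int],
               rim_narrow: Sequence[int],
               rim_wide: Sequence[int],
               coords: np.ndarray | None = None) -> HostFrameAxes:
    """Host center (mean of host heavy-atom coordinates) and unit axis from
    the narrow-rim centroid to the wide-rim centroid.

    ``system`` supplies elements for the heavy-atom filter; per-frame
    coordinates may be passed via ``coords`` (defaults to the system's own).
    """
    host_selection = list(host_selection)
    rim_narrow, rim_wide = list(rim_narrow), list(rim_wide)
    if not host_selection or not rim_narrow or not rim_wide:
        raise ValueError("host and rim selections must be non-empty")
    if set(rim_narrow) & set(rim_wide):
        raise ValueError("rim selections must be disjoint")
    if isinstance(system, MolecularSystem):
        xyz = system.coords if coords is None else np.asarray(coords, dtype=float)
        heavy = _heavy_indices(system, host_selection)
    else:  # bare coordinate array: every atom counts as heavy
        xyz = np.asarray(system, dtype=float)
        heavy = host_selection
    if not heavy:
        raise ValueError("host selection contains no heavy atoms")
    center = xyz[heavy].mean(axis=0)
    vec = xyz[rim_wide].mean(axis=0) - xyz[rim_narrow].mean(axis=0)
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("rim centroids coincide; axis undefined")
    return HostFrameAxes(center=center, axis=vec / norm)


def depth_metrics(frame: np.ndarray, axes: HostFrameAxes,
                  selections: Sequence[Sequence[int]]) -> DepthMetrics:
    """Signed projection of each selection centroid onto the host axis,
    measured from the host center (positive toward the wide rim)."""
    if len(selections) != 3:
        raise ValueError("expected three selections (whole guest, moiety 1, moiety 2)")
    frame = np.asarray(frame, dtype=float)
    vals = []
    for sel in selections:
        sel = list(sel)
        if not sel:
            raise ValueError("empty selection in depth_metrics")
        centroid = frame[sel].mean(axis=0)
        vals.append(float(np.dot(centroid - axes.center, axes.axis)))
    return DepthMetrics(*vals)


def depth_metrics_trajectory(traj: Trajectory,
                             host_selection: Sequence[int],
                             rim_narrow: Sequence[int],
                             rim_wide: Sequence[int],
                             selections: Sequence[Sequence[int]]) -> pd.DataFrame:
    """Per-frame d1/d2/d3 with the host frame recomputed every frame.

    Returns a DataFrame with columns d1, d2, d3 (Å); summarise with
    ``df.mean()`` / ``df.std()`` for the mean ± sd table layout.
    """
    rows = np.empty((traj.n_frames, 3))
    for k, fr in enumerate(traj.frames):
        axes = host_frame(traj.topology, host_selection, rim_narrow, rim_wide, coords=fr)
        dm = depth_metrics(fr, axes, selections)
        rows[k] = (dm.d1, dm.d2, dm.d3)
    return pd.DataFrame(rows, columns=["d1", "d2", "d3"])


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

def detect_hbonds(frame: np.ndarray,
                  donors: Sequence[tuple[int, int]],
                  acceptors: Sequence[int],
                  criterion: HbondCriterion = HbondCriterion()) -> set[tuple[int, int, int]]:
    """H-bonds present in one frame.

    ``donors`` are (X, H) index pairs with H covalently bound to X;
    ``acceptors`` are Y indices. A triple (X, H, Y) is formed iff
    dist(H, Y) < d_max and 180° − angle(X-H···Y) < dev_max, both strict.
    """
    frame = np.asarray(frame, dtype=float)
    found: set[tuple[int, int, int]] = set()
    for x_idx, h_idx in donors:
        xh = frame[x_idx] - frame[h_idx]
        nxh = np.linalg.norm(xh)
        if nxh == 0:
            raise ValueError(f"donor ({x_idx}, {h_idx}) has coincident X and H; "
                             "angle undefined")
        for y_idx in acceptors:
            if y_idx in (x_idx, h_idx):
                continue
            hy = frame[y_idx] - frame[h_idx]
            d = np.linalg.norm(hy)
            if not d < criterion.max_h_acceptor_distance:
                continue
            if d == 0:
                continue
            cosang = np.clip(np.dot(xh, hy) / (nxh * d), -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))  # angle X-H···Y at H
            if (180.0 - angle) < criterion.max_linearity_deviation:
                found.add((x_idx, h_idx, y_idx))
    return found


def hbond_occupancy(traj: Trajectory,
                    donors: Sequence[tuple[int, int]],
                    acceptors: Sequence[int],
                    criterion: HbondCriterion = HbondCriterion()) -> HbondOccupancy:
    """Occurrence percentage of H-bonding over a trajectory.

    The frame-level percentage counts frames containing at least one
    H-bond (multiple simultaneous H-bonds count once); the per-pair
    breakdown reports each (X, H, Y) triple separately.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    frame_flags = np.zeros(traj.n_frames, dtype=bool)
    pair_counts: dict[tuple[int, int, int], int] = {}
    for k, fr in enumerate(traj.frames):
        triples = detect_hbonds(fr, donors, acceptors, criterion)
        frame_flags[k] = bool(triples)
        for t in triples:
            pair_counts[t] = pair_counts.get(t, 0) + 1
    n = traj.n_frames
    per_pair = pd.Series(
        {t: 100.0 * c / n for t, c in sorted(pair_counts.items())}, dtype=float)
    per_pair.index.name = "(X, H, Y)"
    return HbondOccupancy(
        percent=100.0 * frame_flags.sum() / n,
        per_pair=per_pair,
        frame_flags=frame_flags,
        n_frames=n,
    )


# --------------------------------------------------------------------------
# RMSD, bound-state classification, residence
# --------------------------------------------------------------------------

def guest_rmsd(traj: Trajectory,
               reference: np.ndarray,
               align_selection: Sequence[int],
               rmsd_selection: Sequence[int]) -> np.ndarray:
    """Per-frame guest RMSD (Å) after Kabsch superposition of the host.

    Each frame is least-squares superposed onto ``reference`` using
    ``align_selection`` (uniform weights, proper rotations only), then the
    RMSD is evaluated over ``rmsd_selection``.
    """
    align = list(align_selection)
    target = list(rmsd_selection)
    if len(align) < 3:
        raise ValueError("need at least 3 alignment atoms (rotation underdetermined)")
    if not target:
        raise ValueError("empty rmsd selection")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError(f"reference must have shape {(traj.n_atoms, 3)}")
    ref_align = reference[align]
    ref_cen = ref_align.mean(axis=0)
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        mob_cen = fr[align].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_align - ref_cen, fr[align] - mob_cen)
        moved = rot.apply(fr[target] - mob_cen) + ref_cen
        diff = moved - reference[target]
        out[k] = np.sqrt((diff ** 2).sum(axis=1).mean())
    return out


def classify_bound(rmsd_series: np.ndarray, threshold: float = 5.0,
                   frame_interval: float = 20.0) -> ResidenceSeries:
    """Bound iff RMSD < threshold (strict), per frame."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    rmsd_series = np.asarray(rmsd_series, dtype=float)
    return ResidenceSeries(bound_flags=rmsd_series < threshold,
                           frame_interval=frame_interval)


def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """Lengths of maximal contiguous runs of True."""
    if flags.size == 0:
        return np.array([], dtype=int)
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return edges[1::2] - edges[0::2]


def residence_summary(series: ResidenceSeries) -> ResidenceSummary:
    """Occupancy percentage and dwell times of the bound state.

    Dwell times are the lengths of maximal contiguous bound runs times the
    frame interval, reported in ns.
    """
    flags = series.bound_flags
    if flags.size == 0:
        raise ValueError("empty residence series")
    runs = _run_lengths(flags)
    dwell_ns = runs * series.frame_interval / 1000.0
    return ResidenceSummary(
        occupancy_percent=100.0 * flags.mean(),
        dwell_times=dwell_ns,
        max_dwell=float(dwell_ns.max()) if dwell_ns.size else 0.0,
        n_frames=int(flags.size),
        n_bound=int(flags.sum()),
    )
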