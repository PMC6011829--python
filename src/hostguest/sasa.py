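"""Solvent-accessible surface area by the Shrake-Rupley rolling-probe
algorithm with a deterministic Fibonacci-spiral point set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SasaSpec:
    """SASA parameters: probe radius (Å, default 1.4, water) and number of
    test points per atomic sphere (default 960)."""

    probe_radius: float = 1.4
    points_per_atom: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.points_per_atom < 12:
            raise ValueError("points_per_atom must be >= 12")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic golden-spiral set)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def sasa(coords: np.ndarray, radii: np.ndarray,
         spec: SasaSpec = SasaSpec()) -> tuple[float, np.ndarray]:
    """Total and per-atom solvent-accessible surface area (Å²).

    Each atom's sphere of radius r_i + probe is sampled with the
    deterministic point set; a point is exposed if it lies outside every
    other atom's inflated sphere. Per-atom area = exposed fraction ×
    4π(r_i + probe)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be > 0")
    n = len(coords)
    inflated = radii + spec.probe_radius
    unit = fibonacci_sphere(spec.points_per_atom)
    tree = cKDTree(coords)
    rmax = inflated.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        # candidate occluders: any atom whose inflated sphere can reach this one
        nbrs = [j for j in tree.query_ball_point(coords[i], inflated[i] + rmax)
                if j != i]
        if nbrs:
            nbrs_arr = np.asarray(nbrs)
            d = np.linalg.norm(pts[:, None, :] - coords[nbrs_arr][None, :, :], axis=2)
            rn = inflated[nbrs_arr][None, :]
            tol = 1e-9 * rn
            # strictly inside a neighbour sphere buries a point; a point exactly
            # on a neighbour's surface (degenerate overlap) is assigned to the
            # lower-indexed atom so a union of coincident spheres keeps the
            # area of one sphere
            buried = (d < rn - tol) | ((d <= rn + tol) & (nbrs_arr[None, :] < i))
            exposed = ~np.any(buried, axis=1)
        else:
            exposed = np.ones(spec.points_per_atom, dtype=bool)
        areas[i] = exposed.mean() * 4.0 * np.pi * inflated[i] ** 2
    return float(areas.sum()), areas
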