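"""Pore-point path, radial distance profiles, and scale grids.

Every quantity downstream is evaluated on nested open balls B(p, l) centered
on a pore point p.  A pore path is a straight z-grid of points whose in-plane
position tracks the local geometric center of the atom cloud; the radial
profile of a pore point is the sorted list of atom distances, from which the
nearest-neighbor distance R̄, the outer radius L (smallest all-enclosing
ball) and the radial size s = L − R̄ follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import MolecularStructure

__all__ = ["PorePath", "RadialProfile", "ScaleGrid", "build_pore_path",
           "radial_profile", "cumulative_count", "build_scale_grid"]

log = logging.getLogger(__name__)


@dataclass
class PorePath:
    """Ordered pore points on the z-grid, spaced by ``spacing`` Å."""
    points: np.ndarray          # (m, 3)
    spacing: float
    z_range: tuple

    def __len__(self):
        return len(self.points)


@dataclass
class RadialProfile:
    """Sorted atom distances r_a = ‖p − a‖ around one pore point."""
    pore_point: np.ndarray
    radii: np.ndarray           # sorted, one per atom
    r_bar: float                # R̄: nearest-neighbor distance
    outer_radius: float         # L: radius of the smallest all-enclosing ball
    radial_size: float          # s = L − R̄
    n_at_outer: int             # count at L (= n_total)


@dataclass
class ScaleGrid:
    """Uniform scale discretization l_α = R̄ + (α/N_α)·s, α = 1..N_α."""
    alphas: np.ndarray
    l_values: np.ndarray
    n_alpha: int

    @property
    def delta_l(self) -> float:
        return float(self.l_values[1] - self.l_values[0])


def build_pore_path(structure: MolecularStructure, z_min: float,
                    z_max: float, spacing: float = 0.1,
                    slab_half: float = 5.0) -> PorePath:
    """Approximate the pore axis by slab-wise in-plane geometric centers.

    Pore points sit at ((x̄, ȳ), z) for z on the spacing grid, where (x̄, ȳ)
    is the in-plane center of atoms in the slab |z_a − z| ≤ slab_half.  An
    empty slab falls back to the whole-molecule center (logged).
    """
    if not z_min < z_max:
        raise ValueError("empty z-range: z_min must be < z_max")
    n_pts = int(round((z_max - z_min) / spacing)) + 1
    z_grid = z_min + spacing * np.arange(n_pts)
    coords = structure.coords
    global_xy = coords[:, :2].mean(axis=0)
    points = np.empty((n_pts, 3))
    n_fallback = 0
    for k, z in enumerate(z_grid):
        mask = np.abs(coords[:, 2] - z) <= slab_half
        if mask.any():
            points[k, :2] = coords[mask, :2].mean(axis=0)
        else:
            points[k, :2] = global_xy
            n_fallback += 1
        points[k, 2] = z
    if n_fallback:
        log.info("pore path: %d/%d slabs empty, whole-molecule center used",
                 n_fallback, n_pts)
    return PorePath(points=points, spacing=float(spacing),
                    z_range=(float(z_min), float(z_max)))


def radial_profile(structure: MolecularStructure,
                   p: np.ndarray) -> RadialProfile:
    """Sorted distances of all atoms from the pore point p."""
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError("pore point must be a finite 3-vector")
    radii = np.sort(np.linalg.norm(structure.coords - p, axis=1))
    if radii[0] <= 0.0:
        raise ValueError("atom coincident with the pore point: the ball "
                         "B at l = R̄ must be devoid of atoms")
    r_bar = float(radii[0])
    outer = float(radii[-1])
    return RadialProfile(pore_point=p, radii=radii, r_bar=r_bar,
                         outer_radius=outer, radial_size=outer - r_bar,
                         n_at_outer=len(radii))


def cumulative_count(profile: RadialProfile, l) -> np.ndarray | int:
    """Empirical cumulative atom number N(l): atoms with r_a < l (open ball)."""
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("probe radius must be non-negative")
    counts = np.searchsorted(profile.radii, l, side="left")
    return int(counts) if counts.ndim == 0 else counts


def build_scale_grid(profile: RadialProfile, n_alpha: int = 800) -> ScaleGrid:
    """Uniform grid spanning (R̄, L] in N_α steps."""
    alphas = np.arange(1, n_alpha + 1)
    l_values = profile.r_bar + alphas / n_alpha * profile.radial_size
    return ScaleGrid(alphas=alphas, l_values=l_values, n_alpha=n_alpha)
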