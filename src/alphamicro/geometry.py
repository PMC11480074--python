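"""Cell, tissue-lattice and emission geometry.

The target is always a spherical cell nucleus of radius ``r_n`` centred at
the origin, concentric with a spherical cell of radius ``r_c``.  Eight
source regions are supported: four for a single cell in suspension
(nucleus, cell surface, cytoplasm, outside the cell) and four for a
tissue-like simple-cubic lattice of identical cells (uniform everywhere,
everywhere except the nuclei, a perinuclear shell between 1.25*r_n and the
cell membrane, and the cytoplasm of every cell).

Emission directions that can deposit energy in the nucleus lie inside the
cone of half-angle ``theta_max = arcsin(r_n / d_t)`` subtended by the
nucleus at the emission point (``pi`` for points inside the nucleus).
Isotropic emission conditioned on geometric intersection is uniform over
that cone's solid angle, which is what :func:`sample_direction_in_cone`
draws; the per-point hit probability ``(1 - cos theta_max)/2`` is the
associated solid-angle weight.

Two point samplers are provided:

* :func:`sample_source_point` draws points uniformly over a region's
  support (the physical activity distribution).
* :func:`sample_hit_conditioned_points` draws points from the conditional
  distribution of emission sites *given a geometric hit*, i.e. with radial
  density proportional to ``d^2 * (1 - cos theta_max(d))/2`` over the
  support.  Pairing it with cone directions yields equal-weight hit events,
  so single-event spectra need no per-event weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "SourceRegion",
    "CellModel",
    "TissueLattice",
    "PERINUCLEAR_INNER_FACTOR",
    "theta_max",
    "hit_probability",
    "sample_direction_in_cone",
    "chord_intersection",
    "build_tissue_lattice",
    "sample_source_point",
    "sample_hit_conditioned_points",
    "region_membership",
]

PERINUCLEAR_INNER_FACTOR = 1.25


class SourceRegion(IntEnum):
    """Source-activity distributions; codes double as the network input."""

    NUCLEUS = 1
    CELL_SURFACE = 2
    CYTOPLASM = 3
    EXTRACELLULAR = 4
    TISSUE_UNIFORM = 5
    TISSUE_EXCEPT_NUCLEI = 6
    TISSUE_PERINUCLEAR = 7
    TISSUE_CYTOPLASM = 8

    @property
    def is_tissue(self) -> bool:
        return self >= SourceRegion.TISSUE_UNIFORM


@dataclass(frozen=True)
class CellModel:
    """Concentric spherical nucleus (radius ``r_n``) and cell (``r_c``), um."""

    r_n: float
    r_c: float

    def __post_init__(self) -> None:
        if not (0 < self.r_n <= self.r_c):
            raise ValueError(f"need 0 < r_n <= r_c, got {self.r_n}, {self.r_c}")


def theta_max(d_t, r_n):
    """Half-angle of the cone subtended by the nucleus at distance ``d_t``.

    ``pi`` for emission points inside the nucleus (every direction can
    deposit energy).
    """
    d = np.asarray(d_t, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(d <= r_n, np.pi, np.arcsin(np.minimum(r_n / np.maximum(d, r_n), 1.0)))
    return float(out) if np.isscalar(d_t) else out


def hit_probability(d_t, r_n):
    """Solid-angle fraction (1 - cos theta_max)/2 of hitting the nucleus."""
    return (1.0 - np.cos(theta_max(d_t, r_n))) / 2.0


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to each row of ``axis`` (n, 3)."""
    a = axis
    # Pick the helper axis least aligned with `a` to avoid degeneracy.
    helper = np.zeros_like(a)
    idx = np.argmin(np.abs(a), axis=1)
    helper[np.arange(a.shape[0]), idx] = 1.0
    u = np.cross(a, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(a, u)
    return u, v


def sample_direction_in_cone(axis, theta_max_rad, rng: np.random.Generator):
    """Directions uniform over the solid angle of a cone about ``axis``.

    cos(angle to axis) is uniform on [cos theta_max, 1] and the azimuth is
    uniform on [0, 2 pi).  ``axis`` may be a single vector or an (n, 3)
    batch; ``theta_max_rad`` broadcasts against the batch.
    """
    a = np.atleast_2d(np.asarray(axis, dtype=float))
    n = a.shape[0]
    tm = np.broadcast_to(np.asarray(theta_max_rad, dtype=float), (n,))
    cos_tm = np.cos(tm)
    mu = cos_tm + (1.0 - cos_tm) * rng.random(n)
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(np.maximum(1.0 - mu**2, 0.0))
    u, v = _orthonormal_frame(a)
    d = (
        mu[:, None] * a
        + (sin_t * np.cos(phi))[:, None] * u
        + (sin_t * np.sin(phi))[:, None] * v
    )
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d[0] if np.asarray(axis).ndim == 1 else d


def chord_intersection(point, direction, r_n):
    """Entry/exit path lengths of a ray through the origin-centred nucleus.

    Solves ``|p + s u|^2 = r_n^2`` for ``s >= 0``.  Returns ``(s_entry,
    s_exit)`` arrays with NaN where the ray misses.  For points inside the
    nucleus ``s_entry`` is 0.
    """
    p = np.atleast_2d(np.asarray(point, dtype=float))
    u = np.atleast_2d(np.asarray(direction, dtype=float))
    b = np.einsum("ij,ij->i", p, u)
    c = np.einsum("ij,ij->i", p, p) - r_n**2
    disc = b * b - c
    inside = c <= 0.0
    sq = np.sqrt(np.maximum(disc, 0.0))
    s_exit = -b + sq
    s_entry = np.where(inside, 0.0, -b - sq)
    miss = (~inside) & ((disc < 0.0) | (s_entry < 0.0))
    s_entry = np.where(miss, np.nan, s_entry)
    s_exit = np.where(miss, np.nan, s_exit)
    if np.asarray(point).ndim == 1:
        return float(s_entry[0]), float(s_exit[0])
    return s_entry, s_exit


@dataclass(frozen=True)
class TissueLattice:
    """Simple-cubic lattice of identical cells with spacing ``2 r_c``.

    The lattice holds every cell whose centre lies within ``d_max`` of the
    central target nucleus at the origin; the central cell is always
    present.  Cells are non-overlapping by construction.
    """

    cell: CellModel
    d_max: float

    @property
    def spacing(self) -> float:
        return 2.0 * self.cell.r_c

    def sites(self) -> np.ndarray:
        """All lattice-site centres (n, 3), by exhaustive enumeration."""
        k = int(np.floor(self.d_max / self.spacing))
        axis = np.arange(-k, k + 1)
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1)
        centres = grid.reshape(-1, 3) * self.spacing
        keep = np.linalg.norm(centres, axis=1) <= self.d_max
        return centres[keep]

    def n_cells(self) -> int:
        return int(self.sites().shape[0])

    def nearest_site(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest lattice site per point and whether it is in the lattice."""
        p = np.atleast_2d(points)
        site = np.rint(p / self.spacing) * self.spacing
        in_lattice = np.linalg.norm(site, axis=1) <= self.d_max
        return site, in_lattice


def build_tissue_lattice(cell: CellModel, e0_mev: float, model) -> TissueLattice:
    """Lattice extending to ``range(E0) + 2 r_c`` from the target nucleus."""
    d_max = model.range_from_energy(e0_mev) + 2.0 * cell.r_c
    return TissueLattice(cell=cell, d_max=d_max)


# ---------------------------------------------------------------------------
# Region support
# ---------------------------------------------------------------------------

def _radial_support(region: SourceRegion, cell: CellModel, r0: float,
                    d_max: float) -> tuple[float, float]:
    """Radial bounds [d_lo, d_hi] of a region's support around the target."""
    r_n, r_c = cell.r_n, cell.r_c
    if region == SourceRegion.NUCLEUS:
        return 0.0, r_n
    if region == SourceRegion.CELL_SURFACE:
        return r_c, r_c
    if region == SourceRegion.CYTOPLASM:
        return r_n, r_c
    if region == SourceRegion.EXTRACELLULAR:
        return r_c, r_c + r0
    # Tissue regions: bounded by the lattice extent.
    lo = {
        SourceRegion.TISSUE_UNIFORM: 0.0,
        SourceRegion.TISSUE_EXCEPT_NUCLEI: r_n,
        SourceRegion.TISSUE_PERINUCLEAR: PERINUCLEAR_INNER_FACTOR * r_n,
        SourceRegion.TISSUE_CYTOPLASM: r_n,
    }[region]
    return lo, d_max


def region_membership(region: SourceRegion, cell: CellModel,
                      lattice: TissueLattice | None, points: np.ndarray) -> np.ndarray:
    """Boolean mask: does each point lie in the region's support?

    For tissue regions membership is resolved against the nearest lattice
    cell (cells are disjoint, so only the nearest site's cell can contain a
    point); points in packing gaps belong to no cell.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(p, axis=1)
    r_n, r_c = cell.r_n, cell.r_c
    if region == SourceRegion.NUCLEUS:
        return d <= r_n
    if region == SourceRegion.CELL_SURFACE:
        return np.abs(d - r_c) <= 1e-9 * max(r_c, 1.0)
    if region == SourceRegion.CYTOPLASM:
        return (d > r_n) & (d <= r_c)
    if region == SourceRegion.EXTRACELLULAR:
        return d > r_c
    if lattice is None:
        raise ValueError("tissue regions require a lattice")
    site, in_lat = lattice.nearest_site(p)
    rho = np.linalg.norm(p - site, axis=1)
    in_cell = in_lat & (rho <= r_c)
    in_extent = d <= lattice.d_max
    if region == SourceRegion.TISSUE_UNIFORM:
        return in_extent
    if region == SourceRegion.TISSUE_EXCEPT_NUCLEI:
        return in_extent & ~(in_cell & (rho < r_n))
    if region == SourceRegion.TISSUE_PERINUCLEAR:
        return in_extent & in_cell & (rho > PERINUCLEAR_INNER_FACTOR * r_n)
    if region == SourceRegion.TISSUE_CYTOPLASM:
        return in_extent & in_cell & (rho > r_n)
    raise ValueError(f"unknown region {region!r}")


def _uniform_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_source_point(region: SourceRegion, cell: CellModel, e0_mev: float,
                        rng: np.random.Generator, model, n: int = 1,
                        max_attempts: int = 10_000) -> np.ndarray:
    """``n`` points uniform over the region's support (n, 3) in um.

    Suspension regions are sampled exactly (inverse-CDF shells); tissue
    regions by rejection from the bounding ball of radius ``d_max``.
    Raises if the tissue rejection acceptance rate falls below 1e-4.
    """
    r0 = model.range_from_energy(e0_mev)
    if not region.is_tissue:
        lo, hi = _radial_support(region, cell, r0, 0.0)
        if region == SourceRegion.CELL_SURFACE:
            d = np.full(n, cell.r_c)
        else:
            u = rng.random(n)
            d = (lo**3 + u * (hi**3 - lo**3)) ** (1.0 / 3.0)
        return d[:, None] * _uniform_unit_vectors(n, rng)

    lattice = build_tissue_lattice(cell, e0_mev, model)
    out = np.empty((0, 3))
    attempts = 0
    drawn = 0
    while out.shape[0] < n:
        m = max(4 * (n - out.shape[0]), 1024)
        u = rng.random(m)
        d = (u * lattice.d_max**3) ** (1.0 / 3.0)
        p = d[:, None] * _uniform_unit_vectors(m, rng)
        keep = region_membership(region, cell, lattice, p)
        out = np.vstack([out, p[keep]])
        drawn += m
        attempts += 1
        if drawn >= 1e5 and out.shape[0] < 1e-4 * drawn:
            raise RuntimeError(
                f"rejection acceptance below 1e-4 for {region.name} "
                f"(cell {cell}); degenerate support?"
            )
        if attempts > max_attempts:  # pragma: no cover - safety valve
            raise RuntimeError("sampling did not converge")
    return out[:n]


def _radial_hit_cdf(region: SourceRegion, cell: CellModel, r0: float,
                    d_max: float, n_grid: int = 2048
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated inverse-CDF nodes for the hit-weighted radial density.

    Density over the radial support: g(d) proportional to
    ``d^2 * (1 - cos theta_max(d))/2``, truncated at the maximum reachable
    distance ``r0 + r_n`` (beyond it no emission can deposit energy).
    """
    lo, hi = _radial_support(region, cell, r0, d_max)
    hi = min(hi, r0 + cell.r_n)
    if hi <= lo:
        raise ValueError(
            f"empty radial support for {region.name}: [{lo:.3g}, {hi:.3g}] um"
        )
    d = np.linspace(lo, hi, n_grid)
    g = d**2 * hit_probability(d, cell.r_n)
    cdf = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(d))])
    if cdf[-1] <= 0:
        raise ValueError(f"degenerate hit-weighted density for {region.name}")
    return cdf / cdf[-1], d


def sample_hit_conditioned_points(region: SourceRegion, cell: CellModel,
                                  e0_mev: float, rng: np.random.Generator,
                                  model, n: int,
                                  lattice: TissueLattice | None = None,
                                  _cdf_cache: tuple | None = None
                                  ) -> np.ndarray:
    """``n`` emission points distributed as uniform-support points
    *conditioned on a geometric hit* of the target nucleus.

    The radial coordinate is importance-sampled with density proportional
    to ``d^2 * (1 - cos theta_max)/2``; for tissue regions, support
    membership is then enforced by rejection (valid for non-spherically
    symmetric supports because the proposal density depends only on ``d``).
    """
    r0 = model.range_from_energy(e0_mev)
    if region == SourceRegion.CELL_SURFACE:
        return cell.r_c * _uniform_unit_vectors(n, rng)
    if _cdf_cache is not None:
        cdf, dgrid = _cdf_cache
    else:
        d_max = lattice.d_max if lattice is not None else 0.0
        cdf, dgrid = _radial_hit_cdf(region, cell, r0, d_max)
    if not region.is_tissue:
        d = np.interp(rng.random(n), cdf, dgrid)
        return d[:, None] * _uniform_unit_vectors(n, rng)

    if lattice is None:
        lattice = build_tissue_lattice(cell, e0_mev, model)
    out = np.empty((0, 3))
    drawn = 0
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 2048)
        d = np.interp(rng.random(m), cdf, dgrid)
        p = d[:, None] * _uniform_unit_vectors(m, rng)
        keep = region_membership(region, cell, lattice, p)
        out = np.vstack([out, p[keep]])
        drawn += m
        if drawn >= 1e5 and out.shape[0] < 1e-4 * drawn:
            raise RuntimeError(
                f"hit-conditioned acceptance below 1e-4 for {region.name}"
            )
    return out[:n]
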