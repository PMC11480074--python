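"""Single-event specific-energy spectra, microdosimetric moments and the
cell-survival model.

A *hit* is an emission whose track deposits nonzero energy in the target
nucleus; the single-event spectrum ``f1(z1)`` is the probability density of
the specific energy deposited by exactly one hit.  It is represented here
by its maximum ``z_max`` and 20 equal-width density bins over
``(0, z_max]`` normalised to unit area, the k-th bin sitting at
``z = k * z_max / 20``.

Survival after an average dose giving ``<n>`` hits follows the
single-event Laplace-transform model ``S = exp(-<n> (1 - T1(z_o)))`` where
``T1(z_o) = E[exp(-z1/z_o)]`` and ``z_o`` is the specific energy reducing
survival to 1/e.  ``t1_approx`` is the second-order cumulant approximation
``exp(-<z1>/z_o + var(z1)/(2 z_o^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from alphamicro import geometry as geo
from alphamicro import physics

if TYPE_CHECKING:  # pragma: no cover
    from alphamicro.dataset import DesignPoint

__all__ = [
    "N_BINS",
    "SingleEventSpectrum",
    "MicrodoseMoments",
    "score_events",
    "simulate_design",
    "build_spectrum",
    "moments_from_samples",
    "moments_from_spectrum",
    "moments",
    "t1_exact",
    "t1_approx",
    "survival",
    "survival_from_dose",
]

N_BINS = 20


@dataclass(frozen=True)
class SingleEventSpectrum:
    """z_max (Gy) plus 20 unit-area density bins (per Gy) over (0, z_max]."""

    z_max: float
    f: np.ndarray
    n_events: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if self.z_max <= 0:
            raise ValueError("z_max must be positive")
        if f.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} density bins, got {f.shape}")
        if np.any(f < 0):
            raise ValueError("densities must be non-negative")

    @property
    def bin_width(self) -> float:
        return self.z_max / N_BINS

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.z_max, N_BINS + 1)

    @property
    def bin_upper(self) -> np.ndarray:
        """The axis rule: the k-th value sits at z = k * z_max / 20."""
        return np.arange(1, N_BINS + 1) * self.bin_width

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (np.arange(N_BINS) + 0.5) * self.bin_width

    @property
    def area(self) -> float:
        return float(np.sum(self.f) * self.bin_width)


@dataclass(frozen=True)
class MicrodoseMoments:
    """First and second moments of f1; z_F = <z1>, z_D = <z1^2>/<z1>."""

    z1_mean: float
    z1_sq: float

    @property
    def z_f(self) -> float:
        return self.z1_mean

    @property
    def z_d(self) -> float:
        return self.z1_sq / self.z1_mean

    @property
    def variance(self) -> float:
        return self.z1_sq - self.z1_mean**2


# ---------------------------------------------------------------------------
# Monte Carlo scoring
# ---------------------------------------------------------------------------

def score_events(design: "DesignPoint", n_score: int,
                 rng: np.random.Generator,
                 model: physics.RangeEnergyModel | None = None,
                 ) -> np.ndarray:
    """Score ``n_score`` single-hit specific energies (Gy) for a design.

    Emission points are drawn from the hit-conditioned distribution
    (solid-angle weighting folded into the radial sampler, see
    :mod:`alphamicro.geometry`) and directions uniformly over the subtended
    cone, so every returned sample is an equal-weight draw from f1.
    Tracks that exhaust their range before entering the nucleus are misses
    and are discarded.  Deterministic given ``rng``'s state.
    """
    z, _ = simulate_design(design, n_score, rng, model=model)
    return z


def simulate_design(design: "DesignPoint", n_score: int,
                    rng: np.random.Generator,
                    model: physics.RangeEnergyModel | None = None,
                    estimate_hit_probability: bool = False,
                    ) -> tuple[np.ndarray, dict]:
    """Run the single-design MC; return (z samples, metadata dict)."""
    if n_score < 1:
        raise ValueError("n_score must be positive")
    if model is None:
        model = _default_model()
    region = geo.SourceRegion(design.region)
    cell = geo.CellModel(design.r_n, design.r_c)
    e0 = design.e0
    r0 = model.range_from_energy(e0)
    mass = physics.nucleus_mass_kg(cell.r_n)
    to_gray = physics.MEV_TO_JOULE / mass

    lattice = geo.build_tissue_lattice(cell, e0, model) if region.is_tissue else None
    if region == geo.SourceRegion.CELL_SURFACE:
        cdf_cache = None
    else:
        d_max = lattice.d_max if lattice is not None else 0.0
        cdf_cache = geo._radial_hit_cdf(region, cell, r0, d_max)

    samples: list[np.ndarray] = []
    n_have = 0
    n_candidates = 0
    eff = 0.7  # running hit-efficiency estimate
    while n_have < n_score:
        m = int(min(max((n_score - n_have) / max(eff, 0.05) * 1.2, 2048), 400_000))
        p = geo.sample_hit_conditioned_points(
            region, cell, e0, rng, model, m, lattice=lattice, _cdf_cache=cdf_cache
        )
        d = np.linalg.norm(p, axis=1)
        tm = geo.theta_max(d, cell.r_n)
        axis = -p / d[:, None]
        u = geo.sample_direction_in_cone(axis, tm, rng)
        s_entry, s_exit = geo.chord_intersection(p, u, cell.r_n)
        ok = np.isfinite(s_entry)
        eps = np.zeros(m)
        eps[ok] = physics.deposited_energy(
            model, e0, s_entry[ok], s_exit[ok] - s_entry[ok]
        )
        z = eps * to_gray
        hit = z > 0.0
        samples.append(z[hit])
        n_have += int(hit.sum())
        n_candidates += m
        if n_candidates >= 1e6 and n_have < 1e-5 * n_candidates:
            raise RuntimeError(
                f"hit efficiency below 1e-5 for design {design!r}: "
                f"{n_have}/{n_candidates} candidates scored"
            )
        eff = max(n_have / n_candidates, 1e-3)

    z = np.concatenate(samples)[:n_score]
    meta = {
        "n_candidates": n_candidates,
        "hit_efficiency": n_have / n_candidates,
        "range_um": r0,
        "n_cells": lattice.n_cells() if lattice is not None else 1,
    }
    if estimate_hit_probability:
        # Region-average geometric hit probability (solid-angle weight) over
        # the *uniform* source distribution, for absolute-frequency
        # reconstruction; estimated on a side batch of uniform points.
        pts = geo.sample_source_point(region, cell, e0, rng, model, n=20_000)
        w = geo.hit_probability(np.linalg.norm(pts, axis=1), cell.r_n)
        meta["mean_hit_probability"] = float(np.mean(w))
    return z, meta


_MODEL_SINGLETON: physics.RangeEnergyModel | None = None


def _default_model() -> physics.RangeEnergyModel:
    global _MODEL_SINGLETON
    if _MODEL_SINGLETON is None:
        _MODEL_SINGLETON = physics.RangeEnergyModel()
    return _MODEL_SINGLETON


# ---------------------------------------------------------------------------
# Spectrum construction and moments
# ---------------------------------------------------------------------------

def build_spectrum(z_samples) -> SingleEventSpectrum:
    """20-bin unit-area density histogram with z_max = max(samples)."""
    z = np.asarray(z_samples, dtype=float)
    if z.size == 0:
        raise ValueError("cannot build a spectrum from zero samples")
    if np.any(z <= 0):
        raise ValueError("all specific-energy samples must be positive")
    z_max = float(np.max(z))
    width = z_max / N_BINS
    # Right-closed bins over (0, z_max]; the maximum lands in the last bin.
    idx = np.minimum(np.ceil(z / width).astype(int) - 1, N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS).astype(float)
    f = counts / (z.size * width)
    return SingleEventSpectrum(z_max=z_max, f=f, n_events=int(z.size))


def moments_from_samples(z_samples) -> MicrodoseMoments:
    z = np.asarray(z_samples, dtype=float)
    return MicrodoseMoments(z1_mean=float(np.mean(z)), z1_sq=float(np.mean(z**2)))


def moments_from_spectrum(spectrum: SingleEventSpectrum) -> MicrodoseMoments:
    """Midpoint-rule moments of the binned density."""
    zk = spectrum.bin_midpoints
    w = spectrum.f * spectrum.bin_width
    return MicrodoseMoments(
        z1_mean=float(np.sum(zk * w)), z1_sq=float(np.sum(zk**2 * w))
    )


def moments(obj) -> MicrodoseMoments:
    """Moments from either a spectrum (midpoint rule) or raw samples."""
    if isinstance(obj, SingleEventSpectrum):
        return moments_from_spectrum(obj)
    return moments_from_samples(obj)


def t1_exact(z_samples, z_o: float) -> float:
    """Laplace transform of f1 at 1/z_o: mean of exp(-z/z_o) over samples."""
    if z_o <= 0:
        raise ValueError("z_o must be positive")
    z = np.asarray(z_samples, dtype=float)
    return float(np.mean(np.exp(-z / z_o)))


def t1_approx(m: MicrodoseMoments, z_o: float) -> float:
    """Second-order cumulant approximation of T1, clipped to (0, 1]."""
    if z_o <= 0:
        raise ValueError("z_o must be positive")
    val = np.exp(-m.z1_mean / z_o + m.variance / (2.0 * z_o**2))
    return float(np.minimum(val, 1.0))


def survival(n_mean: float, t1: float) -> float:
    """Surviving fraction S = exp(-<n> (1 - T1))."""
    if n_mean < 0:
        raise ValueError("mean hit number must be non-negative")
    if not (0.0 < t1 <= 1.0):
        raise ValueError("T1 must lie in (0, 1]")
    return float(np.exp(-n_mean * (1.0 - t1)))


def survival_from_dose(dose_gy: float, m: MicrodoseMoments, z_samples,
                       z_o: float) -> float:
    """Survival after average absorbed dose D, with <n> = D / <z1>."""
    n_mean = dose_gy / m.z1_mean
    return survival(n_mean, t1_exact(z_samples, z_o))
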