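"""Alpha-particle range-energy physics in unit-density liquid water.

The transport model is the continuous-slowing-down approximation (CSDA)
along straight tracks: an alpha particle of initial kinetic energy ``E0``
has residual range ``R(E0)``, and after travelling a path length ``s``
its residual energy is ``E(R(E0) - s)``.  Energy deposited over a chord is
the difference of residual energies at chord entry and exit.  No straggling,
no delta-ray escape, and no density heterogeneity are modelled: the medium
is water at 1 g/cm^3 everywhere, including the gaps between cells in
tissue geometries.

The range-energy relationship is a monotone piecewise-cubic (PCHIP) fit in
log-log space to an embedded CSDA reference table (see
``data/alpha_water_csda_range.tsv``).  The fit is sampled onto a dense
log-log grid so that the forward and inverse maps are exact mutual
inverses (piecewise-linear in log-log, with shared nodes) and evaluate
fast on large arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "MEV_TO_JOULE",
    "WATER_DENSITY_KG_M3",
    "RangeEnergyModel",
    "load_reference_table",
    "nucleus_mass_kg",
    "specific_energy",
    "deposited_energy",
]

MEV_TO_JOULE = 1.602176634e-13
WATER_DENSITY_KG_M3 = 1000.0

_TABLE_RESOURCE = "alpha_water_csda_range.tsv"


def load_reference_table() -> tuple[np.ndarray, np.ndarray]:
    """Return the embedded (energy MeV, CSDA range um) reference table."""
    text = (
        resources.files("alphamicro.data").joinpath(_TABLE_RESOURCE).read_text()
    )
    rows = [
        line.split()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


@dataclass
class RangeEnergyModel:
    """Monotone range <-> energy map for alpha particles in water.

    Parameters
    ----------
    energies, ranges:
        Reference table (MeV, um).  Defaults to the embedded table.
    grid_size:
        Number of nodes of the dense evaluation grid.

    The fit domain is ``(0, e_max]`` MeV; below the lowest table energy the
    log-log curve is extended linearly (a power law) so that R -> 0 as
    E -> 0.
    """

    energies: np.ndarray | None = None
    ranges: np.ndarray | None = None
    grid_size: int = 6144

    e_min_fit: float = field(init=False)
    e_max: float = field(init=False)

    def __post_init__(self) -> None:
        if self.energies is None or self.ranges is None:
            self.energies, self.ranges = load_reference_table()
        e = np.asarray(self.energies, dtype=float)
        r = np.asarray(self.ranges, dtype=float)
        if e.ndim != 1 or e.shape != r.shape or e.size < 4:
            raise ValueError("reference table must be two equal 1-D columns")
        if np.any(np.diff(e) <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("reference table must be strictly increasing")
        self.e_min_fit = float(e[0])
        self.e_max = float(e[-1])

        log_e, log_r = np.log(e), np.log(r)
        pchip = PchipInterpolator(log_e, log_r)
        slope0 = float(pchip.derivative()(log_e[0]))
        if slope0 <= 0:  # pragma: no cover - monotone table guarantees > 0
            raise ValueError("non-monotone fit at the low-energy end")

        # Dense shared-node grid: piecewise-linear log-log forward and
        # inverse maps through the same nodes are exact mutual inverses.
        grid_log_e = np.linspace(np.log(1e-8), log_e[-1], self.grid_size)
        grid_log_r = np.where(
            grid_log_e >= log_e[0],
            pchip(np.minimum(grid_log_e, log_e[-1])),
            log_r[0] + slope0 * (grid_log_e - log_e[0]),
        )
        self._pchip = pchip
        self._log_e_grid = grid_log_e
        self._log_r_grid = grid_log_r
        self._r_max = float(np.exp(grid_log_r[-1]))

    # -- forward ---------------------------------------------------------
    def range_from_energy(self, energy_mev):
        """CSDA range (um) for kinetic energy in ``(0, e_max]`` MeV."""
        e = np.asarray(energy_mev, dtype=float)
        if np.any(~np.isfinite(e)) or np.any(e <= 0.0) or np.any(e > self.e_max):
            raise ValueError(
                f"energy must lie in (0, {self.e_max}] MeV, got {energy_mev!r}"
            )
        out = np.exp(np.interp(np.log(e), self._log_e_grid, self._log_r_grid))
        return float(out) if np.isscalar(energy_mev) else out

    # -- inverse ---------------------------------------------------------
    def energy_from_range(self, range_um):
        """Kinetic energy (MeV) of an alpha with residual range ``range_um``."""
        r = np.asarray(range_um, dtype=float)
        if np.any(~np.isfinite(r)) or np.any(r < 0.0) or np.any(r > self._r_max * (1 + 1e-9)):
            raise ValueError(
                f"range must lie in [0, {self._r_max:.4g}] um, got {range_um!r}"
            )
        out = self._energy_from_range_unchecked(r)
        return float(out) if np.isscalar(range_um) else out

    def _energy_from_range_unchecked(self, r: np.ndarray) -> np.ndarray:
        """Inverse map with clipping instead of validation (hot path).

        Residual ranges below the grid floor carry < 1e-8 MeV and map to 0.
        """
        r = np.asarray(r, dtype=float)
        tiny = np.exp(self._log_r_grid[0])
        safe = np.maximum(r, tiny)
        e = np.exp(np.interp(np.log(safe), self._log_r_grid, self._log_e_grid))
        # guard against float round-up past the fit ceiling at r = r_max
        e = np.minimum(e, self.e_max)
        return np.where(r < tiny, 0.0, e)

    @property
    def max_range_um(self) -> float:
        return self._r_max

    def stopping_power(self, energy_mev):
        """dE/dx (MeV/um) from the derivative of the fitted R(E)."""
        e = np.asarray(energy_mev, dtype=float)
        log_e = np.log(np.clip(e, self.e_min_fit, self.e_max))
        # dR/dE = R/E * dlogR/dlogE
        dlog = self._pchip.derivative()(log_e)
        drde = self.range_from_energy(e) / e * dlog
        out = 1.0 / drde
        return float(out) if np.isscalar(energy_mev) else out

    def fit_r_squared(self) -> float:
        """Coefficient of determination of the fit against the table."""
        pred = self.range_from_energy(self.energies)
        resid = pred - self.ranges
        ss_tot = float(np.sum((self.ranges - np.mean(self.ranges)) ** 2))
        return 1.0 - float(np.sum(resid**2)) / ss_tot


def nucleus_mass_kg(r_n_um: float) -> float:
    """Mass (kg) of a unit-density spherical nucleus of radius ``r_n_um`` um."""
    if r_n_um <= 0:
        raise ValueError("nucleus radius must be positive")
    return 4.0 / 3.0 * np.pi * (r_n_um * 1e-6) ** 3 * WATER_DENSITY_KG_M3


def specific_energy(epsilon_mev, r_n_um: float):
    """Specific energy z (Gy) from deposited energy epsilon (MeV).

    z = epsilon / m: the stochastic analog of absorbed dose for a single
    energy-deposition event in a spherical nucleus of radius ``r_n_um``.
    """
    eps = np.asarray(epsilon_mev, dtype=float)
    if np.any(eps < 0):
        raise ValueError("deposited energy must be non-negative")
    z = eps * MEV_TO_JOULE / nucleus_mass_kg(r_n_um)
    return float(z) if np.isscalar(epsilon_mev) else z


def deposited_energy(model: RangeEnergyModel, e0_mev, s_entry_um, chord_um):
    """Energy (MeV) deposited inside a chord of the target nucleus.

    The alpha starts with energy ``e0_mev``, travels ``s_entry_um`` of water
    before entering the target, then crosses a chord of length ``chord_um``.
    Under the CSDA, epsilon = E(R0 - s_entry) - E(max(R0 - s_entry - chord, 0)).
    Zero is returned when the particle stops before entry.
    """
    e0 = np.asarray(e0_mev, dtype=float)
    s_in = np.asarray(s_entry_um, dtype=float)
    chord = np.asarray(chord_um, dtype=float)
    if np.any(s_in < 0) or np.any(chord < 0):
        raise ValueError("path lengths must be non-negative")
    r0 = model.range_from_energy(e0)
    r_at_entry = np.maximum(r0 - s_in, 0.0)
    r_at_exit = np.maximum(r_at_entry - chord, 0.0)
    eps = model._energy_from_range_unchecked(
        r_at_entry
    ) - model._energy_from_range_unchecked(r_at_exit)
    eps = np.maximum(eps, 0.0)
    scalar = all(np.isscalar(x) for x in (e0_mev, s_entry_um, chord_um))
    return float(eps) if scalar else eps
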