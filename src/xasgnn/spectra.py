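"""Energy grids, Gaussian broadening, relative spectral error and peak windows.

Carbon K-edge absorption spectra arrive from excited-state calculations as
*stick spectra*: discrete transitions (energy in eV, oscillator strength).
For machine learning they are broadened with Gaussians and discretized onto a
fixed energy grid, so every molecule's target is a vector of the same length.
This module owns that grid convention, the broadening, the relative spectral
error (RSE) used to score predictions, and the peak/FWHM bookkeeping used to
pool attribution scores per spectral peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import peak_widths as _scipy_peak_widths

#: Conversion between a Gaussian's full width at half maximum and its sigma,
#: 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Defaults of the carbon K-edge window: 100 grid points between 270 and
# 300 eV, Gaussian broadening of 0.8 eV FWHM.
DEFAULT_E_MIN = 270.0
DEFAULT_E_MAX = 300.0
DEFAULT_N_GRID = 100
DEFAULT_WIDTH = 0.8


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy grid of ``n_grid`` bin centers between e_min and e_max.

    ``delta_e = (e_max - e_min) / n_grid`` and energies sit at bin centers
    ``e_min + (i + 0.5) * delta_e``, so the grid spacing matches the
    discretization step used in the RSE definition exactly.
    """

    e_min: float
    e_max: float
    n_grid: int

    def __post_init__(self) -> None:
        if self.e_max <= self.e_min:
            raise ValueError(f"e_max ({self.e_max}) must exceed e_min ({self.e_min})")
        if self.n_grid < 2:
            raise ValueError(f"n_grid must be >= 2, got {self.n_grid}")

    @property
    def delta_e(self) -> float:
        return (self.e_max - self.e_min) / self.n_grid

    @property
    def energies(self) -> np.ndarray:
        return self.e_min + (np.arange(self.n_grid) + 0.5) * self.delta_e

    def index_of(self, energy: float) -> int:
        """Grid index of the bin whose center is nearest to ``energy``."""
        return int(np.argmin(np.abs(self.energies - energy)))

    def to_dict(self) -> dict:
        return {"e_min": self.e_min, "e_max": self.e_max, "n_grid": self.n_grid}

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyGrid":
        return cls(float(d["e_min"]), float(d["e_max"]), int(d["n_grid"]))


def make_grid(e_min: float = DEFAULT_E_MIN, e_max: float = DEFAULT_E_MAX,
              n_grid: int = DEFAULT_N_GRID) -> EnergyGrid:
    """Build the uniform bin-center energy grid."""
    return EnergyGrid(float(e_min), float(e_max), int(n_grid))


@dataclass
class StickSpectrum:
    """Discrete transitions of one molecule: (energy eV, oscillator strength)."""

    molecule_id: str
    sticks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e, f in self.sticks:
            if not np.isfinite(e):
                raise ValueError(f"non-finite stick energy {e} in {self.molecule_id}")
            if f < 0:
                raise ValueError(
                    f"negative oscillator strength {f} in {self.molecule_id}")

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.sticks], dtype=float)

    @property
    def strengths(self) -> np.ndarray:
        return np.array([f for _, f in self.sticks], dtype=float)

    def __len__(self) -> int:
        return len(self.sticks)


@dataclass
class GridSpectrum:
    """Intensities on an :class:`EnergyGrid` (arbitrary absorption units)."""

    grid: EnergyGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_grid,):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"grid length {self.grid.n_grid}")


@dataclass
class PeakRegion:
    """One spectral peak with its FWHM window on the grid.

    ``window`` is a half-open grid-index range ``[start, stop)`` covering the
    energies within +-fwhm/2 of the peak center; sticks are assigned to the
    peak by the matching half-open energy window.
    """

    center_energy: float
    center_index: int
    fwhm: float
    window: tuple[int, int]
    member_stick_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if hi <= lo:
            raise ValueError(f"empty peak window {self.window}")
        if not (lo <= self.center_index < hi):
            raise ValueError(
                f"center index {self.center_index} outside window {self.window}")
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")

    @property
    def energy_window(self) -> tuple[float, float]:
        """Half-open energy interval [center - fwhm/2, center + fwhm/2)."""
        return (self.center_energy - self.fwhm / 2.0,
                self.center_energy + self.fwhm / 2.0)


def broaden(sticks: StickSpectrum, grid: EnergyGrid,
            width: float = DEFAULT_WIDTH) -> GridSpectrum:
    """Broaden a stick spectrum with Gaussians of FWHM ``width`` onto ``grid``.

    Each stick contributes ``f_s * exp(-(E - E_s)^2 / (2 sigma^2))`` with
    ``sigma = width / (2 sqrt(2 ln 2))``; amplitudes are peak-height
    normalized (a stick of strength f reaches f at its center), which is all
    that matters for the scale-free RSE and rank-based attribution scores.
    """
    if width <= 0:
        raise ValueError(f"broadening width must be positive, got {width}")
    sigma = width / FWHM_TO_SIGMA
    intensities = np.zeros(grid.n_grid)
    if len(sticks) > 0:
        e = grid.energies[:, None]          # (n_grid, 1)
        es = sticks.energies[None, :]       # (1, n_sticks)
        fs = sticks.strengths[None, :]
        intensities = (fs * np.exp(-((e - es) ** 2) / (2.0 * sigma ** 2))).sum(axis=1)
    return GridSpectrum(grid, intensities)


def rse(target: GridSpectrum, predicted: GridSpectrum) -> float:
    """Relative spectral error between a target and a predicted spectrum.

    RMSE over the grid points divided by the target's total spectral energy
    ``sum_i y_i^tar * delta_E``; dimensionless and invariant under joint
    rescaling of both spectra.
    """
    if target.grid != predicted.grid:
        raise ValueError("target and predicted spectra are on different grids")
    total = float(np.sum(target.intensities) * target.grid.delta_e)
    if total == 0.0:
        raise ZeroDivisionError("all-zero target spectrum: RSE undefined")
    rmse = float(np.sqrt(np.mean((target.intensities - predicted.intensities) ** 2)))
    return rmse / total


def constant_mean_baseline(spectra: Sequence[GridSpectrum]) -> GridSpectrum:
    """Pointwise mean spectrum of a collection — the trivial predictor that
    ignores the molecule. Used as the floor any trained model must beat."""
    if not spectra:
        raise ValueError("empty spectrum collection")
    grid = spectra[0].grid
    stack = np.stack([s.intensities for s in spectra])
    return GridSpectrum(grid, stack.mean(axis=0))


def find_peaks(spec: GridSpectrum, prominence_fraction: float = 0.05) -> list[PeakRegion]:
    """Locate peaks and their FWHM windows on a grid spectrum.

    Local maxima with prominence >= ``prominence_fraction`` of the global
    maximum are kept; the FWHM comes from linear interpolation of the
    half-height crossings, and the window collects the grid indices whose
    energies fall in [center - fwhm/2, center + fwhm/2].
    """
    if not (0.0 < prominence_fraction < 1.0):
        raise ValueError(
            f"prominence_fraction must be in (0, 1), got {prominence_fraction}")
    y = spec.intensities
    top = float(y.max(initial=0.0))
    if top <= 0.0:
        return []
    idx, _ = _scipy_find_peaks(y, prominence=prominence_fraction * top)
    if idx.size == 0:
        return []
    widths, _, _, _ = _scipy_peak_widths(y, idx, rel_height=0.5)
    grid = spec.grid
    regions: list[PeakRegion] = []
    for i, w in zip(idx, widths):
        fwhm = float(w) * grid.delta_e
        center = float(grid.energies[i])
        lo_e, hi_e = center - fwhm / 2.0, center + fwhm / 2.0
        inside = np.where((grid.energies >= lo_e) & (grid.energies <= hi_e))[0]
        if inside.size == 0:
            inside = np.array([i])
        regions.append(PeakRegion(
            center_energy=center,
            center_index=int(i),
            fwhm=fwhm,
            window=(int(inside[0]), int(inside[-1]) + 1),
        ))
    return regions


def assign_sticks_to_peak(sticks: StickSpectrum, peak: PeakRegion) -> list[int]:
    """Indices of sticks whose energy falls in the peak's half-open FWHM
    energy window [center - fwhm/2, center + fwhm/2)."""
    lo, hi = peak.energy_window
    return [i for i, (e, _) in enumerate(sticks.sticks) if lo <= e < hi]
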