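"""ESI spectra: adduct m/z arithmetic, charge deconvolution, stoichiometry.

Intact-protein electrospray spectra of calcium-incubated samples show, for
each charge state z (protonated, positive mode), an envelope of species
M + n * (m_Ca - 2 m_H+): each bound Ca2+ displaces two protons, so the net
per-calcium mass shift is 38.063 Da (average masses; the intact-protein
regime is not isotope-resolved). Deconvolution scans a zero-charge mass
grid, sums spectral intensity found near each candidate's theoretical m/z
over all charge states, and keeps local maxima supported by several charge
states; counting then assigns each species to the nearest calcium-ladder
rung.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from synucalc.errors import InputError

#: Average mass of calcium (Da).
M_CA = 40.078
#: Proton mass (Da).
M_PROTON = 1.00728
#: Net mass shift per bound Ca2+ (displaces two protons).
CA_MASS_SHIFT = M_CA - 2.0 * M_PROTON


@dataclass
class Spectrum:
    """m/z (Th, ascending) and nonnegative intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise InputError("mz and intensity must align")
        if len(self.mz) and np.any(np.diff(self.mz) < 0):
            raise InputError("mz must be ascending")
        if np.any(self.intensity < 0):
            raise InputError("intensities must be nonnegative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class DeconvolvedSpecies:
    mass: float
    abundance: float
    n_charges_supporting: int


def theoretical_mz(protein_mass: float, n_ca: int, z: int) -> float:
    """m/z of [M + n_ca Ca - 2 n_ca H + z H]^(z+) with average masses."""
    if z < 1:
        raise InputError("charge must be at least 1")
    if n_ca < 0:
        raise InputError("n_ca must be nonnegative")
    if protein_mass <= 0:
        raise InputError("protein_mass must be positive")
    return (protein_mass + n_ca * M_CA - 2 * n_ca * M_PROTON + z * M_PROTON) / z


def charge_deconvolve(
    spec: Spectrum,
    z_range=range(9, 20),
    grid_step: float = 0.2,
    tolerance: float = 0.05,
    mass_range: tuple[float, float] | None = None,
    noise_floor: float | None = None,
    rel_floor: float = 0.01,
    min_charge_support: int = 3,
    min_peak_separation: float = 10.0,
) -> list[DeconvolvedSpecies]:
    """Zero-charge mass inference from a multi-charge-state ion envelope.

    For every candidate mass M on a grid, the intensities within
    ``tolerance`` Th of its protonated m/z are summed at every charge in
    ``z_range``; local maxima of this score that clear the noise floor and
    are supported by at least ``min_charge_support`` charge states become
    species. Deterministic. The floor is
    ``max(noise_floor, rel_floor * max score)``, with ``noise_floor``
    defaulting to 3x the median score over the grid.
    """
    zs = list(z_range)
    if not zs:
        raise InputError("z_range is empty")
    if len(spec) == 0:
        return []
    if mass_range is None:
        zmin, zmax = min(zs), max(zs)
        mass_range = (
            zmin * (spec.mz[0] - M_PROTON),
            zmax * (spec.mz[-1] - M_PROTON),
        )
    grid = np.arange(mass_range[0], mass_range[1] + grid_step, grid_step)
    if len(grid) < 3:
        raise InputError("mass grid is too small")
    csum = np.concatenate([[0.0], np.cumsum(spec.intensity)])
    score = np.zeros(len(grid))
    support = np.zeros(len(grid), dtype=int)
    for z in zs:
        mz_grid = (grid + z * M_PROTON) / z
        lo = np.searchsorted(spec.mz, mz_grid - tolerance, side="left")
        hi = np.searchsorted(spec.mz, mz_grid + tolerance, side="right")
        s = csum[hi] - csum[lo]
        score += s
        support += s > 0
    if noise_floor is None:
        noise_floor = 3.0 * float(np.median(score))
    height = max(noise_floor, rel_floor * float(score.max()))
    distance = max(int(round(min_peak_separation / grid_step)), 1)
    peaks, props = find_peaks(score, height=height, distance=distance)
    species = [
        DeconvolvedSpecies(
            mass=float(grid[i]),
            abundance=float(score[i]),
            n_charges_supporting=int(support[i]),
        )
        for i in peaks
        if support[i] >= min_charge_support
    ]
    species.sort(key=lambda s: s.mass)
    return species


def count_stoichiometry(
    species: list[DeconvolvedSpecies],
    protein_mass: float,
    tolerance: float = 5.0,
) -> int:
    """Maximum calcium count on the adduct ladder M + n * 38.063 Da.

    Each species is assigned to the nearest nonnegative integer rung;
    assignments whose residual mass error exceeds ``tolerance`` (Da) are
    rejected. Returns 0 when only the apo species (or nothing) is accepted.
    """
    if protein_mass <= 0:
        raise InputError("protein_mass must be positive")
    best = 0
    for sp in species:
        n = int(round((sp.mass - protein_mass) / CA_MASS_SHIFT))
        if n < 0:
            continue
        resid = abs(sp.mass - (protein_mass + n * CA_MASS_SHIFT))
        if resid <= tolerance:
            best = max(best, n)
    return best
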