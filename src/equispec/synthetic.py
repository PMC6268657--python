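"""Synthetic spectral titrations and pH-potentiometric titrations.

Every generator is a pure function of its parameters and a seed, so the
analysis modules can be exercised and validated without instrument data.
Spectra follow Beer-Lambert bilinearity (1 cm path): each responding
species contributes its molar response times its concentration, plus
optional homoscedastic Gaussian noise.  Titrations are forward-simulated
with the equilibrium solver, plus optional Gaussian pH noise.

Default band parameters mimic the qualitative spectroscopy of the
Al(III)/ciprofloxacin/NADP system: a strong CIP band at 272 nm (shifting
to 275 nm on complexation, with weak bands near 323/335 nm), the NADP
adenine band at 261 nm (intensity increase on complexation), and a CIP
emission maximum at 426 nm shifting to 433 nm with a 2.5-fold gain.
They control presentation realism only; the statistical structure the
analyses rely on is the bilinearity and the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import EquilibriumModel, solve_speciation
from .rafa import SpectraMatrix, bound_fraction_1to1
from .potentiometry import TitrationDataset, simulate_titration

__all__ = [
    "BandSpec",
    "NoiseSpec",
    "gen_species_spectrum",
    "gen_uvvis_titration",
    "gen_ternary_titration",
    "gen_potentiometric_titration",
    "default_wavelength_grid",
    "CIP_BANDS",
    "AL_CIP_COMPLEX_BANDS",
    "NADP_BANDS",
    "AL_NADP_COMPLEX_BANDS",
    "CIP_EMISSION_BANDS",
    "AL_CIP_EMISSION_BANDS",
]


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian band: center and width in nm, amplitude in molar
    response units (AU/M or counts/M at unit path length)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise levels and the seed that makes them reproducible."""

    sigma_intensity: float = 0.0
    sigma_ph: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_intensity < 0 or self.sigma_ph < 0:
            raise ValueError("noise sigmas must be nonnegative")


# molar absorptivities around 2e4-4e4 AU/M, typical of the aromatic
# chromophores involved; the complex bands are red-shifted (CIP) or
# intensified and slightly broadened (NADP) relative to the free ligand
CIP_BANDS = (
    BandSpec(272.0, 9.0, 4.0e4),
    BandSpec(323.0, 7.0, 5.5e3),
    BandSpec(335.0, 7.0, 5.0e3),
)
AL_CIP_COMPLEX_BANDS = (
    BandSpec(275.0, 9.0, 4.4e4),
    BandSpec(323.0, 7.0, 5.0e3),
    BandSpec(335.0, 7.0, 4.5e3),
)
NADP_BANDS = (BandSpec(261.0, 9.0, 1.8e4),)
AL_NADP_COMPLEX_BANDS = (BandSpec(261.0, 10.5, 2.3e4),)

# fluorescence channel (counts/M): emission max 426 -> 433 nm, 2.5x gain
CIP_EMISSION_BANDS = (BandSpec(426.0, 22.0, 2.0e7),)
AL_CIP_EMISSION_BANDS = (BandSpec(433.0, 22.0, 5.0e7),)


def default_wavelength_grid(channel: str = "absorbance") -> np.ndarray:
    """240-360 nm step 0.5 nm (absorbance) or 380-520 nm step 1 nm
    (emission)."""
    if channel == "absorbance":
        return 240.0 + 0.5 * np.arange(241)
    if channel == "emission":
        return 380.0 + 1.0 * np.arange(141)
    raise ValueError(f"unknown channel {channel!r}")


def gen_species_spectrum(
    bands: tuple[BandSpec, ...] | list[BandSpec], wavelength_grid: np.ndarray
) -> np.ndarray:
    """Sum of Gaussian bands evaluated on the grid (molar response)."""
    grid = np.asarray(wavelength_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if not bands:
        raise ValueError("at least one band is required")
    out = np.zeros_like(grid)
    for b in bands:
        if not grid[0] <= b.center <= grid[-1]:
            raise ValueError(
                f"band center {b.center} nm outside grid span "
                f"[{grid[0]}, {grid[-1]}] nm"
            )
        out += b.amplitude * np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
    return out


def _totals_frame(metal_totals, ligand_totals: dict[str, float], metal: str) -> pd.DataFrame:
    df = pd.DataFrame({metal: np.asarray(metal_totals, dtype=float)})
    for lig, tot in ligand_totals.items():
        df[lig] = tot
    return df


def gen_uvvis_titration(
    ligand_spectrum: np.ndarray,
    complex_spectrum: np.ndarray,
    ligand_total: float,
    metal_totals: np.ndarray,
    logk_cond: float,
    noise: NoiseSpec = NoiseSpec(),
    wavelengths: np.ndarray | None = None,
    ligand: str = "CIP",
    metal: str = "Al",
    channel: str = "absorbance",
) -> SpectraMatrix:
    """Bilinear 1:1 binding titration matrix (plus Gaussian noise).

    ``intensity = ligand_spectrum x [L]_free + complex_spectrum x [ML]``
    column by column, with concentrations from the binding quadratic at
    ``logk_cond``.  ``metal_totals`` must include a metal-free sample so
    the analysis can calibrate the ligand response.
    """
    ligand_spectrum = np.asarray(ligand_spectrum, dtype=float)
    complex_spectrum = np.asarray(complex_spectrum, dtype=float)
    if ligand_spectrum.shape != complex_spectrum.shape:
        raise ValueError("ligand and complex spectra must share the grid")
    if wavelengths is None:
        wavelengths = default_wavelength_grid(channel)
    if np.asarray(wavelengths).shape != ligand_spectrum.shape:
        raise ValueError("spectra do not match the wavelength grid")
    metal_totals = np.asarray(metal_totals, dtype=float)
    if not np.any(metal_totals == 0.0):
        raise ValueError("metal_totals must include a metal-free sample")
    ml, free_l = bound_fraction_1to1(metal_totals, ligand_total, logk_cond)
    intensity = np.outer(ligand_spectrum, free_l) + np.outer(complex_spectrum, ml)
    if noise.sigma_intensity > 0:
        rng = np.random.default_rng(noise.seed)
        intensity = intensity + rng.normal(0.0, noise.sigma_intensity, intensity.shape)
    return SpectraMatrix(
        wavelengths,
        intensity,
        _totals_frame(metal_totals, {ligand: ligand_total}, metal),
        channel=channel,
        metadata={"logk_cond": logk_cond, "seed": noise.seed},
    )


def gen_ternary_titration(
    ligand_spectra: dict[str, np.ndarray],
    complex_spectra: dict[str, np.ndarray],
    ligand_totals: dict[str, float],
    metal_totals: np.ndarray,
    conditional_constants: dict[str, float],
    interaction_band: BandSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
    wavelengths: np.ndarray | None = None,
    metal: str = "Al",
    channel: str = "absorbance",
) -> SpectraMatrix:
    """Two ligands competing for the metal, four responding species.

    Speciation is solved with the two 1:1 complexes at their conditional
    constants (no ternary species, no ligand-ligand interaction).  An
    optional ``interaction_band`` adds a fixed spectral term to every
    column -- scaled by the smaller ligand total so its amplitude stays
    in molar-response units -- emulating a constant ligand-ligand
    interaction signature the two-binary model cannot explain.
    """
    from .rafa import _two_complex_model

    ligands = sorted(ligand_totals)
    if len(ligands) != 2:
        raise ValueError("exactly two ligands are required")
    if wavelengths is None:
        wavelengths = default_wavelength_grid(channel)
    wavelengths = np.asarray(wavelengths, dtype=float)
    for name in ligands:
        for spec in (ligand_spectra[name], complex_spectra[name]):
            if np.asarray(spec).shape != wavelengths.shape:
                raise ValueError(f"spectrum for {name!r} does not match the grid")
    metal_totals = np.asarray(metal_totals, dtype=float)
    model = _two_complex_model(metal, ligands[0], ligands[1], conditional_constants)
    intensity = np.zeros((len(wavelengths), len(metal_totals)))
    for j, m in enumerate(metal_totals):
        totals = {**{l: ligand_totals[l] for l in ligands}, metal: float(m)}
        sol = solve_speciation(model, totals, fixed_ph=7.0)
        col = np.zeros(len(wavelengths))
        for lig in ligands:
            col += np.asarray(ligand_spectra[lig]) * sol.free[lig]
            col += np.asarray(complex_spectra[lig]) * sol.species_conc[f"{metal}({lig})"]
        intensity[:, j] = col
    if interaction_band is not None:
        scale = min(ligand_totals.values())
        intensity += gen_species_spectrum([interaction_band], wavelengths)[:, None] * scale
    if noise.sigma_intensity > 0:
        rng = np.random.default_rng(noise.seed)
        intensity = intensity + rng.normal(0.0, noise.sigma_intensity, intensity.shape)
    return SpectraMatrix(
        wavelengths,
        intensity,
        _totals_frame(metal_totals, ligand_totals, metal),
        channel=channel,
        metadata={"conditional_constants": dict(conditional_constants), "seed": noise.seed},
    )


def gen_potentiometric_titration(
    model: EquilibriumModel,
    design: TitrationDataset,
    noise: NoiseSpec = NoiseSpec(),
) -> TitrationDataset:
    """Forward-simulated titration with Gaussian pH noise added.

    ``design`` carries the initial composition, titrant and volume grid
    (its pH values, if any, are ignored).  Identical inputs and seed give
    bit-identical output.
    """
    clean = simulate_titration(model, design)
    if noise.sigma_ph > 0:
        rng = np.random.default_rng(noise.seed)
        ph = clean.ph + rng.normal(0.0, noise.sigma_ph, len(clean.ph))
        return clean.with_ph(ph)
    return clean
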