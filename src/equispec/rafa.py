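"""Rank annihilation factor analysis (RAFA) of spectral titration matrices.

A spectral titration at fixed ligand total and increasing metal total is,
under Beer-Lambert bilinearity, a low-rank matrix: one rank per
responding species.  For a 1:1 binding equilibrium with conditional
constant K the data are rank 2 (free ligand + complex).  RAFA subtracts
the known ligand contribution -- its molar response calibrated from the
metal-free sample, scaled by the free-ligand concentration profile that a
trial K implies -- and asks how close the residual matrix is to rank 1.
The trial constant minimizing an eigenvalue-based relative standard
deviation (RSD) is the estimate of log K.

The estimator :class:`RankAnnihilationScan` wraps the grid scan in a
scikit-learn style ``fit`` interface; the module-level functions do the
individual steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .equilibria import EquilibriumModel, solve_speciation

__all__ = [
    "SpectraMatrix",
    "RafaScan",
    "bound_fraction_1to1",
    "rsd_statistic",
    "annihilate",
    "scan_logk",
    "estimate_rank",
    "residual_spectra",
    "RankAnnihilationScan",
]

logger = logging.getLogger(__name__)


@dataclass
class SpectraMatrix:
    """Wavelength x sample intensity matrix with per-sample totals.

    ``sample_totals`` is a DataFrame with one row per sample and one
    column per analytical total (mol/L), e.g. ``Al``, ``CIP``, ``NADP``.
    ``channel`` is ``"absorbance"`` or ``"emission"``.
    """

    wavelengths: np.ndarray
    intensity: np.ndarray
    sample_totals: pd.DataFrame
    channel: str = "absorbance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be 1-D")
        if np.any(self.wavelengths <= 0) or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be positive and strictly increasing")
        if self.intensity.shape != (len(self.wavelengths), len(self.sample_totals)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{len(self.wavelengths)} wavelengths x {len(self.sample_totals)} samples"
            )
        if self.channel not in ("absorbance", "emission"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    def metal_totals(self, metal: str = "Al") -> np.ndarray:
        return self.sample_totals[metal].to_numpy(dtype=float)

    def ligand_total(self, ligand: str) -> float:
        vals = self.sample_totals[ligand].to_numpy(dtype=float)
        if not np.allclose(vals, vals[0], rtol=1e-12, atol=0):
            raise ValueError(f"ligand total for {ligand!r} varies across samples")
        return float(vals[0])

    def metal_free_column(self, metal: str = "Al") -> np.ndarray:
        m = self.metal_totals(metal)
        idx = np.flatnonzero(m == 0.0)
        if len(idx) == 0:
            raise ValueError("no metal-free sample in the matrix")
        return self.intensity[:, idx[0]]


@dataclass
class RafaScan:
    """Result of a log K grid scan: RSD per grid value and the argmin."""

    logk_grid: np.ndarray
    rsd: np.ndarray
    best_logk: float
    n_principal: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"logK": self.logk_grid, "RSD": self.rsd})


def bound_fraction_1to1(
    metal_total: float | np.ndarray,
    ligand_total: float,
    logk_cond: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex and free-ligand concentrations of a 1:1 equilibrium.

    Solves ``K = [ML] / ([M][L])`` with mass balance exactly (positive
    root of the binding quadratic, written in the numerically stable
    form).  Returns ``(complex, free_ligand)``; scalars in give scalars
    out.
    """
    m = np.asarray(metal_total, dtype=float)
    scalar = m.ndim == 0
    m = np.atleast_1d(m)
    if np.any(m < 0) or ligand_total < 0:
        raise ValueError("totals must be nonnegative")
    if not np.isfinite(logk_cond):
        raise ValueError("logk_cond must be finite")
    k = 10.0 ** logk_cond
    l = ligand_total
    # K c^2 - (K(m+l)+1) c + K m l = 0 ;  stable root via q-formula
    b = k * (m + l) + 1.0
    disc = b * b - 4.0 * k * k * m * l
    disc = np.maximum(disc, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 2.0 * k * m * l / (b + np.sqrt(disc))
    c = np.where(k * m * l == 0.0, 0.0, c)
    c = np.minimum(c, np.minimum(m, l))
    free_l = l - c
    if scalar:
        return float(c[0]), float(free_l[0])
    return c, free_l


def _eigenvalues(matrix: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the (uncentered) sample covariance
    square matrix ``M.T @ M``."""
    m = np.asarray(matrix, dtype=float)
    ev = np.linalg.eigvalsh(m.T @ m)[::-1]
    return np.maximum(ev, 0.0)


def rsd_statistic(
    matrix: np.ndarray, n_principal: int, normalize: bool = False
) -> float:
    """PCA relative standard deviation of a data matrix.

    ``RSD(n) = sqrt( sum_{j>n} lambda_j / (r (s-n)) )`` from the
    eigenvalues ``lambda_j`` of the covariance square matrix of the
    (wavelength x sample) data, with r wavelengths and s samples.  With
    ``normalize=True`` the trailing eigenvalue sum is divided by the
    total variance ``sum_j lambda_j``, making the statistic scale-free.
    Either variant is zero iff the matrix has rank <= n.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("matrix must be 2-D with at least 2 rows")
    r, s = m.shape
    if not 0 < n_principal < s:
        raise ValueError("n_principal must be in [1, n_samples)")
    ev = _eigenvalues(m)
    tail = float(np.sum(ev[n_principal:]))
    denom = r * (s - n_principal)
    if normalize:
        total = float(np.sum(ev))
        if total == 0.0:
            return 0.0
        return float(np.sqrt(tail / (denom * total)))
    return float(np.sqrt(tail / denom))


def annihilate(
    matrix: SpectraMatrix,
    ligand_spectrum: np.ndarray | None,
    trial_logk: float,
    metal: str = "Al",
    ligand: str | None = None,
) -> np.ndarray:
    """Subtract the ligand's bilinear contribution at a trial log K.

    The free-ligand concentration in each sample comes from the 1:1
    binding quadratic at ``trial_logk``; the ligand molar response is
    either supplied per wavelength or calibrated from the metal-free
    sample divided by the ligand total.  Returns the signed residual
    intensity matrix.
    """
    if ligand is None:
        ligand = _infer_ligand(matrix, metal)
    l_tot = matrix.ligand_total(ligand)
    if ligand_spectrum is None:
        ligand_spectrum = matrix.metal_free_column(metal) / l_tot
    else:
        ligand_spectrum = np.asarray(ligand_spectrum, dtype=float)
        if ligand_spectrum.shape != matrix.wavelengths.shape:
            raise ValueError("ligand_spectrum does not match the wavelength grid")
    _, free_l = bound_fraction_1to1(matrix.metal_totals(metal), l_tot, trial_logk)
    return matrix.intensity - np.outer(ligand_spectrum, free_l)


def _infer_ligand(matrix: SpectraMatrix, metal: str) -> str:
    cand = [c for c in matrix.sample_totals.columns if c != metal]
    if len(cand) != 1:
        raise ValueError(
            f"cannot infer the ligand from totals columns {list(matrix.sample_totals.columns)}; "
            "pass ligand= explicitly"
        )
    return cand[0]


def scan_logk(
    matrix: SpectraMatrix,
    ligand_spectrum: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    n_principal: int = 1,
    normalize: bool = False,
    metal: str = "Al",
    ligand: str | None = None,
) -> RafaScan:
    """RSD versus trial log K over a grid; the argmin estimates log K.

    The default grid is 6.0 to 14.0 in steps of 0.05.  Exact RSD ties are
    broken toward the smallest log K with a logged warning.
    """
    if grid is None:
        grid = default_logk_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("grid must be a nonempty 1-D array")
    if len(grid) > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    rsd = np.array(
        [
            rsd_statistic(
                annihilate(matrix, ligand_spectrum, lk, metal=metal, ligand=ligand),
                n_principal,
                normalize=normalize,
            )
            for lk in grid
        ]
    )
    i_min = int(np.argmin(rsd))  # argmin returns the first (smallest logK) tie
    if np.sum(rsd == rsd[i_min]) > 1:
        logger.warning(
            "flat RSD valley: %d grid points tie at the minimum; "
            "reporting the smallest logK",
            int(np.sum(rsd == rsd[i_min])),
        )
    return RafaScan(grid, rsd, float(grid[i_min]), n_principal)


def default_logk_grid(start: float = 6.0, stop: float = 14.0, step: float = 0.05) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def estimate_rank(
    matrix: SpectraMatrix | np.ndarray,
    rsd_threshold: float,
    normalize: bool = False,
) -> int:
    """Number of principal (responding) species in a titration matrix.

    The smallest n with ``rsd_statistic(matrix, n) < threshold``; if no
    n below the sample count qualifies, the sample count is returned.
    """
    if rsd_threshold <= 0:
        raise ValueError("rsd_threshold must be positive")
    m = matrix.intensity if isinstance(matrix, SpectraMatrix) else np.asarray(matrix)
    s = m.shape[1]
    for n in range(1, s):
        if rsd_statistic(m, n, normalize=normalize) < rsd_threshold:
            return n
    return s


def residual_spectra(
    ternary_matrix: SpectraMatrix,
    ligand_spectra: dict[str, np.ndarray],
    binary_complex_spectra: dict[str, np.ndarray],
    conditional_constants: dict[str, float],
    metal: str = "Al",
) -> np.ndarray:
    """Observed minus synthetic spectra under the two-binary-complex model.

    The synthetic spectra assume (1) no ligand-ligand interaction and
    (2) no mixed ternary complex: speciation at each metal total is
    solved with only the two 1:1 complexes at their conditional
    constants, and the bilinear Beer-Lambert mixture of the two free
    ligands and two complexes is subtracted from the observed matrix.
    A structured residual (e.g. a consistent band) flags chemistry the
    two-binary model does not capture.

    ``ligand_spectra`` maps ligand name -> molar response;
    ``binary_complex_spectra`` and ``conditional_constants`` map ligand
    name -> complex molar response / conditional log K.
    """
    ligands = sorted(ligand_spectra)
    if sorted(conditional_constants) != ligands or sorted(binary_complex_spectra) != ligands:
        raise ValueError("ligand_spectra, complex spectra and constants must share keys")
    grid = ternary_matrix.wavelengths
    for name, spec in list(ligand_spectra.items()) + list(binary_complex_spectra.items()):
        if np.asarray(spec).shape != grid.shape:
            raise ValueError(f"spectrum for {name!r} does not match the wavelength grid")

    lig_a, lig_b = ligands
    model = _two_complex_model(metal, lig_a, lig_b, conditional_constants)
    synth = np.zeros_like(ternary_matrix.intensity)
    totals_df = ternary_matrix.sample_totals
    for j in range(ternary_matrix.n_samples):
        totals = {
            lig_a: float(totals_df[lig_a].iloc[j]),
            lig_b: float(totals_df[lig_b].iloc[j]),
            metal: float(totals_df[metal].iloc[j]),
        }
        sol = solve_speciation(model, totals, fixed_ph=7.0)
        col = np.zeros(len(grid))
        for lig in ligands:
            col += np.asarray(ligand_spectra[lig]) * sol.free[lig]
            col += (
                np.asarray(binary_complex_spectra[lig])
                * sol.species_conc[f"{metal}({lig})"]
            )
        synth[:, j] = col
    return ternary_matrix.intensity - synth


def _two_complex_model(metal, lig_a, lig_b, constants) -> EquilibriumModel:
    from .equilibria import Component, Species

    return EquilibriumModel(
        [
            Component(metal, 3, "metal"),
            Component(lig_a, -1, "ligand"),
            Component(lig_b, -1, "ligand"),
            Component("H", 1, "proton"),
        ],
        [
            Species(f"{metal}({lig_a})", {metal: 1, lig_a: 1}, constants[lig_a]),
            Species(f"{metal}({lig_b})", {metal: 1, lig_b: 1}, constants[lig_b]),
        ],
    )


class RankAnnihilationScan(BaseEstimator):
    """Estimate a 1:1 conditional stability constant by RAFA.

    Scikit-learn style estimator: ``fit`` takes a :class:`SpectraMatrix`
    and scans trial log K values, annihilating the ligand contribution
    and scoring the residual matrix with the PCA RSD statistic.

    Parameters
    ----------
    logk_min, logk_max, logk_step : float
        Trial grid (default 6.0 to 14.0, step 0.05).
    n_principal : int
        Principal components retained by the RSD statistic (1 for a
        single remaining complex).
    normalize : bool
        Divide the trailing eigenvalue sum by the total variance.
    metal, ligand : str or None
        Totals columns naming the metal and the ligand; the ligand is
        inferred when the matrix has exactly one non-metal column.

    Attributes
    ----------
    best_logk_ : float
        Argmin-RSD estimate of the conditional log K.
    scan_ : RafaScan
        Full RSD-versus-logK curve.
    ligand_spectrum_ : ndarray
        Molar response used for annihilation (calibrated from the
        metal-free sample unless supplied to ``fit``).
    """

    def __init__(
        self,
        logk_min: float = 6.0,
        logk_max: float = 14.0,
        logk_step: float = 0.05,
        n_principal: int = 1,
        normalize: bool = False,
        metal: str = "Al",
        ligand: str | None = None,
    ):
        self.logk_min = logk_min
        self.logk_max = logk_max
        self.logk_step = logk_step
        self.n_principal = n_principal
        self.normalize = normalize
        self.metal = metal
        self.ligand = ligand

    def fit(self, X: SpectraMatrix, y=None, ligand_spectrum: np.ndarray | None = None):
        if not isinstance(X, SpectraMatrix):
            raise TypeError("X must be a SpectraMatrix")
        ligand = self.ligand or _infer_ligand(X, self.metal)
        if ligand_spectrum is None:
            ligand_spectrum = X.metal_free_column(self.metal) / X.ligand_total(ligand)
        grid = default_logk_grid(self.logk_min, self.logk_max, self.logk_step)
        self.scan_ = scan_logk(
            X,
            ligand_spectrum,
            grid,
            n_principal=self.n_principal,
            normalize=self.normalize,
            metal=self.metal,
            ligand=ligand,
        )
        self.best_logk_ = self.scan_.best_logk
        self.ligand_spectrum_ = np.asarray(ligand_spectrum, dtype=float)
        self.ligand_ = ligand
        return self

    def score(self, X: SpectraMatrix | None = None, y=None) -> float:
        """Negative RSD at the fitted optimum (higher is better)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scan_")
        return -float(np.min(self.scan_.rsd))
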