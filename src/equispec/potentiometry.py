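"""pH-potentiometric titration simulation and formation-constant refinement.

A titration adds strong base (KOH) to an acidified metal/ligand solution
and records pH versus added volume.  The forward model dilutes every
analytical total by ``V0/(V0+v)``, subtracts the added base from the
signed proton total, and solves the equilibrium speciation for the free
proton concentration; pH is taken as ``-log10 [H]`` (concentration
scale, electrode calibrated for hydrogen-ion concentration).

Formation constants are refined by damped Gauss-Newton least squares on
the pH residuals with respect to the adjustable cumulative log betas --
the same shape of computation as the classical BEST refinement.  The
model-acceptance statistic is ``sigma_fit``, the root-mean-square pH
residual; a stepwise builder adds candidate species one at a time until
sigma_fit falls below threshold (default 0.01) or no candidate helps.

Titration points where the speciation solver fails to converge are
excluded from the fit and reported, mirroring the practice of dropping
points that do not equilibrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .equilibria import (
    ConvergenceError,
    EquilibriumModel,
    Species,
    solve_speciation,
)

__all__ = [
    "TitrationDataset",
    "FitResult",
    "standard_design",
    "simulate_titration",
    "sigma_fit",
    "refine_constants",
    "stepwise_model_build",
    "FormationConstantRefiner",
    "RefinementError",
]


class RefinementError(RuntimeError):
    pass


@dataclass
class TitrationDataset:
    """A pH-potentiometric titration: design plus (optionally) readings.

    ``totals`` is the analytical composition of the initial solution in
    mol/L, with a signed proton total (strong-acid excess positive).
    ``volumes`` are added titrant volumes in L, strictly increasing;
    ``ph`` may be None for a bare design.  ``excluded`` lists
    ``(index, reason)`` pairs of points left out of any fit.
    """

    initial_volume: float
    totals: dict[str, float]
    titrant_conc: float
    volumes: np.ndarray
    ph: np.ndarray | None = None
    medium: str = "0.2 M KCl, 25 C"
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 1 or len(self.volumes) == 0:
            raise ValueError("volumes must be a nonempty 1-D array")
        if np.any(np.diff(self.volumes) <= 0):
            raise ValueError("added volumes must be strictly increasing")
        if self.titrant_conc <= 0:
            raise ValueError("titrant concentration must be positive")
        if self.initial_volume <= 0:
            raise ValueError("initial volume must be positive")
        if self.ph is not None:
            self.ph = np.asarray(self.ph, dtype=float)
            if self.ph.shape != self.volumes.shape:
                raise ValueError("ph and volumes must have the same length")

    def totals_at(self, v: float, proton: str = "H") -> dict[str, float]:
        """Diluted analytical totals after adding ``v`` L of titrant."""
        d = self.initial_volume / (self.initial_volume + v)
        out = {c: t * d for c, t in self.totals.items()}
        out[proton] = (
            self.totals.get(proton, 0.0) * self.initial_volume
            - self.titrant_conc * v
        ) / (self.initial_volume + v)
        return out

    def with_ph(self, ph: np.ndarray) -> "TitrationDataset":
        return replace(self, ph=np.asarray(ph, dtype=float))

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of points not excluded and with finite pH."""
        mask = np.ones(len(self.volumes), dtype=bool)
        for i, _ in self.excluded:
            mask[i] = False
        if self.ph is not None:
            mask &= np.isfinite(self.ph)
        return mask


@dataclass
class FitResult:
    """Refined log betas with approximate standard deviations."""

    refined: dict[str, tuple[float, float]]
    sigma_fit: float
    n_points_used: int
    excluded_points: list[tuple[int, int, str]]
    n_iter: int = 0
    converged: bool = True

    def log_beta(self, label: str) -> float:
        return self.refined[label][0]


def standard_design(
    ligand_totals: Mapping[str, float],
    metal_total: float = 0.0,
    metal: str = "Al",
    n_points: int = 60,
    initial_volume: float = 0.050,
    titrant_conc: float = 0.1026,
    acid_excess: float = 0.010,
    n_protons: Mapping[str, int] | None = None,
    v_max: float | None = None,
) -> TitrationDataset:
    """Titration design: 50 mL sample, KOH 0.1026 M, acidified to pH 2.

    The signed proton total counts the strong-acid excess plus the
    dissociable protons the fully protonated ligands carry (CIP 2,
    NADP 3 by default).  The volume span covers neutralizing the acid,
    the ligand protons and up to four hydroxides per metal, ending in
    mild base excess (final pH around 11).
    """
    if n_protons is None:
        from .models import _N_PROT

        n_protons = _N_PROT
    h_total = acid_excess + sum(
        n_protons.get(lig, 0) * tot for lig, tot in ligand_totals.items()
    )
    totals = {**{k: float(v) for k, v in ligand_totals.items()}, "H": h_total}
    if metal_total > 0:
        totals[metal] = float(metal_total)
    if v_max is None:
        v_max = (h_total + 4.0 * metal_total + 2e-3) * initial_volume / titrant_conc
    volumes = np.linspace(0.0, v_max, n_points)
    return TitrationDataset(initial_volume, totals, titrant_conc, volumes)


def simulate_titration(
    model: EquilibriumModel,
    design: TitrationDataset,
    tol: float = 1e-10,
) -> TitrationDataset:
    """Compute the pH at every titration point of a design.

    Points where the speciation solver does not converge are flagged in
    ``excluded`` and carry NaN pH.
    """
    proton = model.proton
    if proton is None:
        raise ValueError("model has no proton component")
    ph = np.full(len(design.volumes), np.nan)
    excluded: list[tuple[int, str]] = []
    warm = None
    for i, v in enumerate(design.volumes):
        totals = design.totals_at(float(v), proton)
        try:
            sol = solve_speciation(model, totals, tol=tol, x0=warm)
        except ConvergenceError:
            # a warm start from across a steep equivalence jump can
            # strand the Newton iteration; retry from scratch
            try:
                sol = solve_speciation(model, totals, tol=tol, x0=None)
            except ConvergenceError as exc:
                excluded.append((i, f"no convergence: {exc}"))
                warm = None
                continue
        warm = sol.free
        ph[i] = -np.log10(sol.free[proton])
    return replace(design, ph=ph, excluded=list(design.excluded) + excluded)


def _ph_residuals(
    model: EquilibriumModel, dataset: TitrationDataset, tol: float
) -> np.ndarray:
    """Observed minus calculated pH; NaN where either is unavailable."""
    calc = simulate_titration(model, dataset, tol=tol)
    return dataset.ph - calc.ph


def sigma_fit(
    model: EquilibriumModel, dataset: TitrationDataset, tol: float = 1e-10
) -> float:
    """Root-mean-square pH residual of a model against one dataset."""
    if dataset.ph is None:
        raise ValueError("dataset carries no pH readings")
    res = _ph_residuals(model, dataset, tol)
    res = res[dataset.usable & np.isfinite(res)]
    if len(res) == 0:
        raise ValueError("all titration points are excluded")
    return float(np.sqrt(np.mean(res**2)))


def refine_constants(
    model: EquilibriumModel,
    datasets: Sequence[TitrationDataset] | TitrationDataset,
    adjustable: Sequence[str],
    max_iter: int = 50,
    xtol: float = 1e-5,
    jac_step: float = 1e-4,
    max_step: float = 1.0,
    speciation_tol: float = 1e-10,
) -> tuple[EquilibriumModel, FitResult]:
    """Least-squares refinement of cumulative log betas against pH data.

    Gauss-Newton iteration with Levenberg damping on the sum of squared
    pH residuals over all datasets; the Jacobian is forward-difference
    in log beta (step ``jac_step``).  Converged when every parameter
    update is below ``xtol``.  Standard deviations come from the
    Jacobian at the optimum.  Raises :class:`RefinementError`, naming
    the species, when a parameter has no influence on any retained
    point (singular normal equations).
    """
    if isinstance(datasets, TitrationDataset):
        datasets = [datasets]
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    adjustable = list(adjustable)
    if not adjustable:
        raise ValueError("no adjustable species given")
    for label in adjustable:
        model.get_species(label)  # raises KeyError if absent
    for ds in datasets:
        if ds.ph is None:
            raise ValueError("datasets must carry pH readings")

    theta = np.array([model.get_species(l).log_beta for l in adjustable])
    current = model

    def residual_vector(m: EquilibriumModel) -> np.ndarray:
        parts = []
        for ds in datasets:
            r = _ph_residuals(m, ds, speciation_tol)
            r[~ds.usable] = np.nan
            parts.append(r)
        return np.concatenate(parts)

    r0 = residual_vector(current)
    lam = 1e-3
    n_iter = 0
    converged = False
    jac = None
    mask = np.isfinite(r0)
    for n_iter in range(1, max_iter + 1):
        # forward-difference Jacobian of pH_calc w.r.t. log beta
        jac = np.empty((len(r0), len(theta)))
        for k, label in enumerate(adjustable):
            pert = current.with_log_betas({label: theta[k] + jac_step})
            rp = residual_vector(pert)
            jac[:, k] = (r0 - rp) / jac_step  # d pH_calc / d log beta
        mask = np.isfinite(r0) & np.all(np.isfinite(jac), axis=1)
        if not np.any(mask):
            raise RefinementError("all titration points excluded during refinement")
        jm, rm = jac[mask], r0[mask]
        col_norm = np.linalg.norm(jm, axis=0)
        # a parameter with strictly zero influence (species absent from
        # the chemistry) is unidentifiable; merely ill-determined ones
        # are left to the Levenberg damping
        dead = [adjustable[k] for k in range(len(theta)) if col_norm[k] == 0.0]
        if dead:
            raise RefinementError(
                f"species {dead} have no influence on the data "
                "(singular normal equations); remove them or change the design"
            )
        jtj = jm.T @ jm
        jtr = jm.T @ rm
        sse0 = float(rm @ rm)
        # Levenberg loop: accept the first damped step that lowers the SSE
        step = None
        for _ in range(30):
            try:
                delta = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj)), jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            # per-component trust region on log beta: a runaway
            # ill-determined parameter must not crush the step of the
            # well-determined ones
            delta = np.clip(delta, -max_step, max_step)
            trial_theta = theta + delta
            trial = current.with_log_betas(dict(zip(adjustable, trial_theta)))
            r_trial = residual_vector(trial)
            m_t = np.isfinite(r_trial) & mask
            if np.sum(m_t) < np.sum(mask):
                # the trial parameters break speciation convergence at
                # points the current model handles: reject the step
                lam *= 10.0
                continue
            sse_t = float(r_trial[m_t] @ r_trial[m_t])
            if sse_t <= sse0 or np.max(np.abs(delta)) < xtol * 1e-3:
                step = delta
                theta, current, r0 = trial_theta, trial, r_trial
                lam = max(lam * 0.3, 1e-12)
                break
            lam *= 10.0
        if step is None:
            break
        if np.max(np.abs(step)) < xtol:
            converged = True
            break

    mask = np.isfinite(r0)
    rm = r0[mask]
    n_used = int(np.sum(mask))
    sigma = float(np.sqrt(np.mean(rm**2)))
    # approximate standard deviations from the final Jacobian
    dof = max(n_used - len(theta), 1)
    s2 = float(rm @ rm) / dof
    jm = jac[mask]
    try:
        cov = s2 * np.linalg.inv(jm.T @ jm)
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sds = np.full(len(theta), np.nan)

    excluded: list[tuple[int, int, str]] = []
    for di, ds in enumerate(datasets):
        for i, reason in ds.excluded:
            excluded.append((di, i, reason))
    offset = 0
    for di, ds in enumerate(datasets):
        n = len(ds.volumes)
        bad = np.flatnonzero(~np.isfinite(r0[offset : offset + n]) & ds.usable)
        for i in bad:
            excluded.append((di, int(i), "no convergence at refined parameters"))
        offset += n

    refined = {
        label: (float(t), float(sd)) for label, t, sd in zip(adjustable, theta, sds)
    }
    result = FitResult(refined, sigma, n_used, excluded, n_iter, converged)
    return current, result


def stepwise_model_build(
    base_model: EquilibriumModel,
    candidate_species: Sequence[Species],
    datasets: Sequence[TitrationDataset] | TitrationDataset,
    sigma_threshold: float = 0.01,
    min_improvement: float = 0.05,
    **refine_kw,
) -> tuple[EquilibriumModel, list[tuple[str, FitResult]]]:
    """Greedy stepwise model building on sigma_fit.

    Candidates are tried one at a time; the one whose inclusion (with
    refinement of every candidate added so far) lowers sigma_fit most is
    kept.  The loop stops when sigma_fit drops below
    ``sigma_threshold``, when no candidate improves it by at least
    ``min_improvement`` (relative), or when candidates run out.
    Returns the final model and the ``(label, FitResult)`` trail.
    """
    if isinstance(datasets, TitrationDataset):
        datasets = [datasets]
    base_labels = set(base_model.species_labels)
    for c in candidate_species:
        if c.label in base_labels:
            raise ValueError(f"candidate {c.label!r} already in the base model")
    remaining = list(candidate_species)
    current = base_model
    accepted: list[str] = []
    trail: list[tuple[str, FitResult]] = []
    sigma_now = float(np.sqrt(np.mean([sigma_fit(current, ds) ** 2 for ds in datasets])))
    while remaining and sigma_now >= sigma_threshold:
        best = None
        for cand in remaining:
            try:
                trial_model, fit = refine_constants(
                    current.with_species([cand]),
                    datasets,
                    accepted + [cand.label],
                    **refine_kw,
                )
            except RefinementError:
                continue
            if best is None or fit.sigma_fit < best[2].sigma_fit:
                best = (cand, trial_model, fit)
        if best is None:
            break
        cand, trial_model, fit = best
        if fit.sigma_fit > sigma_now * (1.0 - min_improvement):
            break
        current = trial_model
        accepted.append(cand.label)
        remaining = [c for c in remaining if c.label != cand.label]
        trail.append((cand.label, fit))
        sigma_now = fit.sigma_fit
    return current, trail


class FormationConstantRefiner(BaseEstimator):
    """Scikit-learn style wrapper around :func:`refine_constants`.

    Parameters
    ----------
    model : EquilibriumModel
        Starting model; the log betas of ``adjustable`` species are the
        starting values of the refinement.
    adjustable : sequence of str or None
        Species labels to refine; defaults to the species flagged
        ``adjustable`` in the model.
    max_iter, xtol, jac_step : see :func:`refine_constants`.

    Attributes
    ----------
    log_betas_ : dict of label -> refined log beta
    std_devs_ : dict of label -> approximate standard deviation
    sigma_fit_ : float, rms pH residual at the optimum
    model_ : EquilibriumModel with refined constants
    result_ : FitResult
    """

    def __init__(
        self,
        model: EquilibriumModel,
        adjustable: Sequence[str] | None = None,
        max_iter: int = 50,
        xtol: float = 1e-5,
        jac_step: float = 1e-4,
    ):
        self.model = model
        self.adjustable = adjustable
        self.max_iter = max_iter
        self.xtol = xtol
        self.jac_step = jac_step

    def fit(self, X: Sequence[TitrationDataset] | TitrationDataset, y=None):
        adjustable = self.adjustable
        if adjustable is None:
            adjustable = [s.label for s in self.model.species if s.adjustable]
        self.model_, self.result_ = refine_constants(
            self.model,
            X,
            adjustable,
            max_iter=self.max_iter,
            xtol=self.xtol,
            jac_step=self.jac_step,
        )
        self.log_betas_ = {l: v[0] for l, v in self.result_.refined.items()}
        self.std_devs_ = {l: v[1] for l, v in self.result_.refined.items()}
        self.sigma_fit_ = self.result_.sigma_fit
        return self

    def score(self, X=None, y=None) -> float:
        """Negative sigma_fit (higher is better)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        return -self.sigma_fit_
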