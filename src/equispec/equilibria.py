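"""Multicomponent chemical equilibrium speciation.

Solves the coupled mass-balance equations of a metal/ligand/proton system
described by cumulative formation constants (log beta).  Every dissolved
species is expressed as assembled directly from the free components,

    M_p L_q H_r :   beta = [MpLqHr] / ([M]^p [L]^q [H]^r)

with hydroxide and hydrolysis species carrying negative proton
coefficients (one -1 per OH).  The solver works on the natural logarithm
of the free concentrations, which keeps every concentration strictly
positive, and damps Newton steps by halving until the residual norm
decreases.

The module also provides side-reaction coefficients, conditional
stability constants at a fixed pH, species distribution tables versus pH
or versus total metal, and the Gibbs free energy associated with a
formation constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Component",
    "Species",
    "EquilibriumModel",
    "SpeciationResult",
    "ConvergenceError",
    "build_model",
    "solve_speciation",
    "distribution_vs_ph",
    "distribution_vs_metal",
    "side_reaction_coefficient",
    "conditional_constant",
    "gibbs_from_logk",
    "LN10",
    "R_KCAL",
]

LN10 = float(np.log(10.0))
#: gas constant in kcal/(mol K)
R_KCAL = 1.987204e-3


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails to reach tolerance.

    Carries the last scaled mass-balance residuals in ``residuals``.
    """

    def __init__(self, message: str, residuals: Mapping[str, float] | None = None):
        super().__init__(message)
        self.residuals = dict(residuals or {})


@dataclass(frozen=True)
class Component:
    """A free component of the equilibrium model (metal, ligand or proton)."""

    name: str
    charge: int = 0
    role: str = "ligand"  # metal | ligand | proton

    def __post_init__(self):
        if self.role not in ("metal", "ligand", "proton"):
            raise ValueError(f"unknown component role {self.role!r}")


@dataclass(frozen=True)
class Species:
    """A complex species formed from the components.

    ``stoichiometry`` maps component names to signed integer coefficients;
    ``log_beta`` is the cumulative formation constant in common logarithm.
    A bare component is representable with a single coefficient 1 and
    log_beta 0.
    """

    label: str
    stoichiometry: Mapping[str, int]
    log_beta: float
    adjustable: bool = False

    def __post_init__(self):
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if not any(v != 0 for v in self.stoichiometry.values()):
            raise ValueError(f"species {self.label!r} has no nonzero coefficient")
        if not np.isfinite(self.log_beta):
            raise ValueError(f"species {self.label!r} has non-finite log_beta")


@dataclass
class EquilibriumModel:
    """Components plus species with cumulative formation constants."""

    components: list[Component]
    species: list[Species]
    temperature: float = 298.15

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")
        protons = [c for c in self.components if c.role == "proton"]
        if len(protons) > 1:
            raise ValueError("more than one proton component")
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate species labels")
        for s in self.species:
            for cname in s.stoichiometry:
                if cname not in names:
                    raise ValueError(
                        f"species {s.label!r} references unknown component {cname!r}"
                    )

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def proton(self) -> str | None:
        for c in self.components:
            if c.role == "proton":
                return c.name
        return None

    @property
    def species_labels(self) -> list[str]:
        return [s.label for s in self.species]

    def get_species(self, label: str) -> Species:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_species, n_components) signed coefficient matrix."""
        names = self.component_names
        a = np.zeros((len(self.species), len(names)))
        for i, s in enumerate(self.species):
            for cname, coeff in s.stoichiometry.items():
                a[i, names.index(cname)] = coeff
        return a

    def log_betas(self) -> np.ndarray:
        return np.array([s.log_beta for s in self.species], dtype=float)

    def with_log_betas(self, updates: Mapping[str, float]) -> "EquilibriumModel":
        """Return a copy with the log_beta of the named species replaced."""
        unknown = set(updates) - set(self.species_labels)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        new_species = [
            Species(s.label, s.stoichiometry, updates.get(s.label, s.log_beta), s.adjustable)
            for s in self.species
        ]
        return EquilibriumModel(list(self.components), new_species, self.temperature)

    def with_species(self, extra: Iterable[Species]) -> "EquilibriumModel":
        return EquilibriumModel(
            list(self.components), list(self.species) + list(extra), self.temperature
        )


@dataclass
class SpeciationResult:
    """Free and complexed concentrations solving all mass balances."""

    free: dict[str, float]
    species_conc: dict[str, float]
    residuals: dict[str, float]
    n_iter: int = 0

    def total(self, component: str, model: EquilibriumModel) -> float:
        """Recompute the analytical total of ``component`` from the solution."""
        tot = self.free.get(component, 0.0)
        for s in model.species:
            tot += s.stoichiometry.get(component, 0) * self.species_conc[s.label]
        return tot


def build_model(
    components: Sequence[Component | tuple | str],
    species_defs: Sequence[Species | Mapping],
    temperature: float = 298.15,
) -> EquilibriumModel:
    """Assemble and validate an :class:`EquilibriumModel`.

    Components may be given as :class:`Component`, ``(name, charge, role)``
    tuples or bare names (role defaults to ligand).  Species may be given
    as :class:`Species` or mappings with keys ``label``, ``stoichiometry``,
    ``log_beta`` and optionally ``adjustable``.
    """
    comps: list[Component] = []
    for c in components:
        if isinstance(c, Component):
            comps.append(c)
        elif isinstance(c, str):
            comps.append(Component(c))
        else:
            comps.append(Component(*c))
    specs: list[Species] = []
    for s in species_defs:
        if isinstance(s, Species):
            specs.append(s)
        else:
            specs.append(
                Species(
                    s["label"],
                    s["stoichiometry"],
                    float(s["log_beta"]),
                    bool(s.get("adjustable", False)),
                )
            )
    return EquilibriumModel(comps, specs, temperature)


def _scaled_residuals(totals, free, conc, a_abs, a, t):
    calc = free + a.T @ conc
    gross = free + a_abs.T @ conc
    denom = np.maximum(np.abs(t), gross)
    denom = np.maximum(denom, 1e-300)
    return (calc - t) / denom


def solve_speciation(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    fixed_ph: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    x0: Mapping[str, float] | None = None,
) -> SpeciationResult:
    """Solve the mass-balance system for the free concentrations.

    Parameters
    ----------
    model
        The equilibrium model.
    totals
        Analytical (total) molar concentration per component.  The proton
        total is signed: strong acid counts positive, strong base negative.
        Totals must be supplied for every non-proton component.
    fixed_ph
        If given, the free proton concentration is clamped to ``10**-pH``
        and the proton mass balance is dropped.
    tol
        Maximum scaled mass-balance residual at convergence.
    max_iter
        Newton iteration limit.
    x0
        Optional warm-start free concentrations per component.

    Notes
    -----
    Newton iteration on the natural log of the free concentrations with
    step halving; initial guess equals the totals (1e-10 M floor).
    Components with an exactly zero total (other than the proton) are
    eliminated: their free concentration and every species containing
    them are zero.
    """
    names = model.component_names
    proton = model.proton
    for n in names:
        if n == proton:
            continue
        if n not in totals:
            raise ValueError(f"missing total for component {n!r}")
        if totals[n] < 0:
            raise ValueError(f"negative total for component {n!r}")
    if proton is not None and fixed_ph is None and proton not in totals:
        raise ValueError(f"missing total for proton component {proton!r}")

    # eliminate zero-total non-proton components
    zero = {n for n in names if n != proton and totals.get(n, 0.0) == 0.0}
    live_species = [
        s for s in model.species if not any(s.stoichiometry.get(z, 0) != 0 for z in zero)
    ]
    active = [n for n in names if n not in zero]
    if fixed_ph is not None and proton is not None:
        clamped = proton
        free_h = 10.0 ** (-fixed_ph)
    else:
        clamped = None
        free_h = None
    unknowns = [n for n in active if n != clamped]

    a_full = np.zeros((len(live_species), len(active)))
    for i, s in enumerate(live_species):
        for cname, coeff in s.stoichiometry.items():
            if cname in active:
                a_full[i, active.index(cname)] = coeff
    lnbeta = np.array([s.log_beta for s in live_species]) * LN10

    idx_u = [active.index(n) for n in unknowns]
    a_u = a_full[:, idx_u] if live_species else np.zeros((0, len(unknowns)))
    a_u_abs = np.abs(a_u)
    t_u = np.array([totals.get(n, 0.0) for n in unknowns])

    ln_fixed = 0.0
    if clamped is not None and live_species:
        j = active.index(clamped)
        ln_fixed = a_full[:, j] * np.log(free_h)

    # initial guess
    x = np.empty(len(unknowns))
    for k, n in enumerate(unknowns):
        guess = totals.get(n, 0.0)
        if n == proton:
            guess = max(guess, 1e-7)
        guess = max(guess, 1e-10)
        if x0 is not None and n in x0 and x0[n] > 0:
            guess = x0[n]
        x[k] = np.log(guess)

    def species_conc(xv):
        if not live_species:
            return np.zeros(0)
        ln_c = lnbeta + ln_fixed + a_u @ xv
        return np.exp(np.minimum(ln_c, 700.0))

    # fixed weights for the line-search merit: the adaptive scaled
    # residual saturates near 1 when the calculated totals are orders of
    # magnitude too large, which would blind the step-halving search
    w = np.maximum(np.abs(t_u), 1e-14)

    n_iter = 0
    if len(unknowns) == 0:
        conc = species_conc(x)
        res = np.zeros(0)
    else:
        conc = species_conc(x)
        free = np.exp(x)
        res = _scaled_residuals(totals, free, conc, a_u_abs, a_u, t_u)
        for n_iter in range(1, max_iter + 1):
            if np.max(np.abs(res)) < tol:
                break
            # Newton step on ln free
            jac = np.diag(free) + a_u.T @ (conc[:, None] * a_u)
            raw = free + a_u.T @ conc - t_u
            try:
                dx = np.linalg.solve(jac, -raw)
            except np.linalg.LinAlgError:
                dx = np.linalg.lstsq(jac, -raw, rcond=None)[0]
            dx = np.clip(dx, -20.0, 20.0)
            merit0 = np.linalg.norm(raw / w)
            step = 1.0
            for _ in range(60):
                x_new = x + step * dx
                conc_new = species_conc(x_new)
                free_new = np.exp(x_new)
                raw_new = free_new + a_u.T @ conc_new - t_u
                if np.linalg.norm(raw_new / w) < merit0 or step < 1e-12:
                    break
                step *= 0.5
            x, conc, free = x_new, conc_new, free_new
            res = _scaled_residuals(totals, free, conc, a_u_abs, a_u, t_u)
        else:
            resid = {n: float(r) for n, r in zip(unknowns, res)}
            raise ConvergenceError(
                f"speciation did not converge in {max_iter} iterations "
                f"(max residual {np.max(np.abs(res)):.3e})",
                resid,
            )

    free_out = {n: 0.0 for n in names}
    for k, n in enumerate(unknowns):
        free_out[n] = float(np.exp(x[k]))
    if clamped is not None:
        free_out[clamped] = float(free_h)
    conc_out = {s.label: 0.0 for s in model.species}
    for s, c in zip(live_species, conc):
        conc_out[s.label] = float(c)
    res_out = {n: float(r) for n, r in zip(unknowns, res)}
    return SpeciationResult(free_out, conc_out, res_out, n_iter)


def distribution_vs_ph(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    ph_grid: Sequence[float],
    reference: str,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Species fractions of ``reference``'s total over a pH grid.

    Returns a DataFrame indexed by pH whose columns are the free
    component plus every species containing the reference component;
    each row sums to 1.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    if ph_grid.ndim != 1 or len(ph_grid) == 0 or np.any(np.diff(ph_grid) <= 0):
        raise ValueError("ph_grid must be nonempty and strictly increasing")
    if reference not in model.component_names:
        raise ValueError(f"unknown reference component {reference!r}")
    t_ref = totals.get(reference, 0.0)
    if t_ref <= 0:
        raise ValueError("reference component must have a positive total")
    carriers = [
        s for s in model.species if s.stoichiometry.get(reference, 0) != 0
    ]
    cols = [f"{reference}(free)"] + [s.label for s in carriers]
    rows = []
    warm: Mapping[str, float] | None = None
    for ph in ph_grid:
        sol = solve_speciation(model, totals, fixed_ph=float(ph), tol=tol, x0=warm)
        warm = sol.free
        row = [sol.free[reference] / t_ref]
        for s in carriers:
            row.append(s.stoichiometry[reference] * sol.species_conc[s.label] / t_ref)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(ph_grid, name="pH"), columns=cols)


def distribution_vs_metal(
    model: EquilibriumModel,
    ligand_totals: Mapping[str, float],
    metal_grid: Sequence[float],
    fixed_ph: float,
    metal: str = "Al",
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Free-ligand and complex fractions versus total metal at fixed pH.

    For every ligand with a positive total the table carries the fraction
    left free and the fraction bound in each species containing it; the
    two groups sum to 1 per ligand.
    """
    metal_grid = np.asarray(metal_grid, dtype=float)
    if np.any(metal_grid < 0):
        raise ValueError("metal totals must be nonnegative")
    ligands = [
        c.name
        for c in model.components
        if c.role == "ligand" and ligand_totals.get(c.name, 0.0) > 0
    ]
    cols: list[str] = []
    for lig in ligands:
        cols.append(f"{lig}(free)")
        for s in model.species:
            if s.stoichiometry.get(lig, 0) != 0:
                cols.append(f"{lig}:{s.label}")
    rows = []
    warm = None
    for m in metal_grid:
        totals = dict(ligand_totals)
        totals[metal] = float(m)
        sol = solve_speciation(model, totals, fixed_ph=fixed_ph, tol=tol, x0=warm)
        if m > 0:
            warm = sol.free
        row = []
        for lig in ligands:
            t_l = ligand_totals[lig]
            row.append(sol.free[lig] / t_l)
            for s in model.species:
                q = s.stoichiometry.get(lig, 0)
                if q != 0:
                    row.append(q * sol.species_conc[s.label] / t_l)
        rows.append(row)
    return pd.DataFrame(
        rows, index=pd.Index(metal_grid, name=f"{metal}_total"), columns=cols
    )


def side_reaction_coefficient(
    hydrolysis_log_betas: Mapping[int, float] | EquilibriumModel,
    ph: float,
    metal: str = "Al",
) -> float:
    """log10 of the side-reaction coefficient alpha_M at a given pH.

    ``alpha_M = 1 + sum_q 10**(log beta_q) [H]**(-q)`` over the hydroxo
    species M(OH)_q.  Accepts either ``{q: log beta_q}`` or an
    :class:`EquilibriumModel`, from which every species built from the
    metal and a negative proton count alone is taken.
    """
    if isinstance(hydrolysis_log_betas, EquilibriumModel):
        model = hydrolysis_log_betas
        proton = model.proton
        terms = {}
        for s in model.species:
            st = dict(s.stoichiometry)
            if st.get(metal, 0) == 1 and st.get(proton, 0) < 0:
                extra = {k: v for k, v in st.items() if k not in (metal, proton) and v}
                if not extra:
                    terms[-st[proton]] = s.log_beta
    else:
        terms = dict(hydrolysis_log_betas)
    log_terms = np.array([lb + q * ph for q, lb in terms.items()])
    alpha = 1.0 + np.sum(10.0 ** log_terms)
    return float(np.log10(alpha))


def conditional_constant(
    log_beta_abs: float,
    side_reactions: Mapping[int, float] | EquilibriumModel,
    ph: float,
    metal: str = "Al",
) -> float:
    """Conditional (effective) log stability constant at a fixed pH.

    Subtracts the metal side-reaction coefficient:
    ``logK' = log beta - log alpha_M(pH)``.
    """
    return log_beta_abs - side_reaction_coefficient(side_reactions, ph, metal)


def gibbs_from_logk(logk: float, temperature: float = 298.15) -> float:
    """Gibbs free energy (kcal/mol) of dissociation of a complex with
    formation constant ``logk``: ``ln(10) R T logK``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return LN10 * R_KCAL * temperature * logk
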