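# Methods

## Equilibrium model and solver

A model is a set of components (metal, ligands, proton) and species
defined by signed stoichiometric coefficients and cumulative formation
constants log β (common logarithm, species assembled from free
components). Hydroxide is the species `OH = −H` with log β = −pK_w;
Al hydrolysis species Al(OH)_q carry proton coefficients −q. The proton
analytical total is signed: strong acid counts positive, strong base
negative, and a fully protonated ligand contributes its dissociable
protons to the total. This is the standard bookkeeping of BEST/HySS-type
programs.

Constants shipped in `equispec.models` (25 °C): CIP protonation
8.60/14.76; NADP protonation 9.93/16.09/19.90; Al–CIP binaries
9.36/15.85/21.38; Al–NADP binaries 10.71/16.01/19.16/37.84/29.82/57.53;
mixed 1:1:1 complexes 26.56 (Al(CIP)(HNADP)) and 32.49
(Al(HCIP)(HNADP)); Al(OH)_q −5.5/−11.1/−16.6/−23.2; pK_w 13.78. All are
used as printed, mixing the ionic strengths at which they were
determined (hydrolysis at I = 0.16, the rest at 0.2 M KCl); no
Davies/Debye–Hückel correction is applied, and temperature is fixed at
298.15 K. The NADP H₄L constant reported only from earlier literature
is excluded from the default model. All printed constants are treated
as cumulative β values from free components (the output convention of
BEST); if any were stepwise constants only the model table would
change, not the code.

The solver does damped Newton iteration on the natural log of the free
concentrations (positivity for free), with the analytical Jacobian
`J = diag(f) + Aᵀ diag(c) A`. Two numerical details matter:

- Convergence is declared when every scaled mass-balance residual
  `|calc − T| / max(|T|, gross)` falls below 1e-10 (`gross` is the sum
  of absolute contributions, which keeps the criterion meaningful for a
  zero or negative proton total). Default iteration cap 200; failure
  raises an error carrying the last residuals.
- The line search cannot use that scaled residual: far from the
  solution it saturates at 1 and gives no descent signal. Step halving
  therefore monitors raw residuals weighted by `max(|T|, 1e-14)`.

The initial guess equals the totals (floored at 1e-10 M, proton at
1e-7 M); a warm start from a neighbouring condition can be supplied and
is used along titrations and distribution grids. With `fixed_ph` the
free proton is clamped to 10^(−pH) and the proton balance dropped.
Components with an exactly zero total are eliminated together with
their species. Fractions in distribution tables are relative to a
reference component's total and sum to 1 to 1e-8 by construction
(mass balance).

Side-reaction coefficient: `log α_M(pH) = log10(1 + Σ_q β_q [H]^{−q})`
over the hydroxo ladder; conditional constants are
`log K′ = log β − log α_M`. Dissociation free energy:
`ΔG = ln(10)·R·T·log K` with R = 1.987204e-3 kcal/(mol·K).

## RAFA

The scan subtracts the ligand's bilinear contribution
`e_L ⊗ [L]free(K′)` from the titration matrix, with the free-ligand
profile from the exact 1:1 binding quadratic (numerically stable root)
and the molar response e_L calibrated from the metal-free sample
divided by the ligand total (a separately measured spectrum can be
supplied instead). The residual matrix is scored by

    RSD(n) = sqrt( Σ_{j>n} λ_j / (r (s − n)) )

with λ_j the descending eigenvalues of the uncentered covariance square
matrix `MᵀM`, r the wavelength count and s the sample count
(Malinowski's real-error form). `normalize=True` divides the trailing
sum by the total variance Σλ; either variant is zero iff rank ≤ n, and
both are exposed because the literature does not fix one formula. The
unnormalized form is the default: on noisy data the normalized variant
biases the argmin upward, because its denominator also grows with the
trial constant. Only the argmin is treated as meaningful; absolute RSD
values depend on the formula choice. Exact ties are broken toward the
smallest log K with a logged warning. Default grid 6.0–14.0, step 0.05.
No hydrolysis correction is applied inside the scan: the fitted
constant is conditional at the buffer pH, and
`conditional_constant`/`side_reaction_coefficient` convert to the
absolute scale.

Residual spectra for the two-ligand system are observed minus synthetic
matrices, the synthetic built from speciation with only the two 1:1
complexes at their conditional constants (no mixed species, no
ligand–ligand interaction). A consistent structured residual — e.g. the
band near 290 nm the generator can inject — flags chemistry outside
that model. Negative residual intensities are allowed (residuals are
signed).

### Identifiability limit at saturated binding

At 20 µM ligand and conditional K = 10^10.2–10^10.7 the 1:1 binding is
stoichiometric: ~99.8 % of the limiting species is bound at the 1:1
point, and the only K-sensitive observable is the residual free ligand
at equivalence, √(L/K) ≈ 36 nM, worth ~1.4 mAU against realistic molar
absorptivities (≤ ~5e4 M⁻¹cm⁻¹). With 2 mAU per-point noise the
coherent signal separating the true constant from K → ∞ across the full
241-channel grid is only a few noise standard deviations, so the argmin
scatters over several log units. Monte-Carlo runs with the default
generator confirm this; with the same design and noise but a generating
constant in the sub-saturated regime (log K ≈ 5–6.5, K·c ~ 1–100) the
scan recovers the constant to about ±0.1. Noise-free, the argmin is
exact at any generating value on the grid. Passing tests therefore
demonstrate correctness of the machinery and accurate recovery in the
informative regime — not that a 10^10 constant is measurable from a
20 µM titration, which no estimator can do at this noise level.

## Potentiometric simulation and refinement

A titration point at added volume v has totals diluted by V₀/(V₀+v)
and proton total `(T_H V₀ − C_KOH v)/(V₀+v)`; pH is −log10 of the free
proton concentration (electrode calibrated on the concentration scale;
no activity correction, no junction-potential or carbonate model). The
standard design is 50 mL, 0.001 M ligand, 0.1026 M KOH, 0.010 M strong
acid excess (start pH 2.0), 60 evenly spaced volumes ending in mild
base excess (pH ≈ 11), matching the 0:1 / 1:1 / 1:2 / 1:5 / 1:1:1
ratio designs. Points where the speciation solver fails are excluded
and reported — the computational analogue of dropping points that do
not equilibrate kinetically, which an equilibrium code cannot model; a
warm start failing across a steep equivalence jump is retried cold
before exclusion.

Refinement minimises the unweighted sum of squared pH residuals over
all datasets with respect to the adjustable log β values: Gauss–Newton
with Levenberg (Marquardt-scaled) damping, forward-difference Jacobian
(step 1e-4 in log β), per-component step clip of 1 log unit, and
convergence when every update is below 1e-5. Trial steps that break
speciation convergence at points the current model handles are
rejected. A parameter whose Jacobian column is identically zero
(species absent from the chemistry) raises a singularity error naming
the species; merely ill-determined parameters — e.g. the 1:3 Al–NADP
complex in a 1:1 dataset — are left to the damping and the per-component
clip, which the six-parameter Al–NADP refinement requires. Standard
deviations come from `s²(JᵀJ)⁻¹` at the optimum; σ_fit is the rms pH
residual over the points used. The stepwise builder adds the candidate
species giving the largest σ_fit reduction, refining all accepted
candidates jointly, and stops below σ_fit = 0.01 or when no candidate
improves σ_fit by 5 % relative.

## Synthetic data

Generators are pure functions of parameters and seed. Spectra are sums
of Gaussian bands on a 240–360 nm grid (step 0.5 nm; emission 380–520
nm, step 1 nm), combined bilinearly at unit path length with
concentrations from the binding quadratic (binary) or the speciation
solver (two-ligand), plus homoscedastic Gaussian intensity noise.
Default bands encode the system's qualitative spectroscopy — CIP 272 nm
(ε ≈ 4e4) shifting to 275 nm on complexation with weak 323/335 nm
bands, NADP 261 nm (ε ≈ 1.8e4) gaining intensity with a slight
broadening on complexation, CIP emission 426 → 433 nm with ~2.5× gain —
and are presentation realism only; the analyses rely on the
bilinearity, the noise level and the concentration designs (20 µM
ligand, Al 0–25 µM; σ = 0.002 AU where noise is used). A shot-noise
mode is deliberately absent: no noise model is reported for the source
data, and homoscedastic noise is the assumption under which the RSD
statistic is natural. Titration curves are the forward simulation plus
Gaussian pH noise (σ_pH = 0.005 in the noisy recovery studies).

What the generator does **not** emulate: baseline drift and stray
light, wavelength calibration error, heteroscedastic detector noise,
ligand–ligand adducts (except the optional fixed interaction band),
slow Al ligand-exchange kinetics, carbonate contamination and electrode
drift. Recovery results on synthetic data are therefore best-case for
real instruments.

## Problem sizes

The acceptance script uses the study's own scales throughout: 5–6
sample spectral matrices on 241 wavelengths, 20 noise seeds for the
RAFA Monte Carlo, and 60-point titrations for the refinements; it
completes in a few seconds on one CPU, as does the test suite.
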