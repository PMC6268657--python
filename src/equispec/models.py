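"""Ready-made equilibrium models for the Al(III)/ciprofloxacin/NADP system.

Cumulative formation constants (log beta, 25 C) for the proton, binary
and ternary complexes of ciprofloxacin (CIP) and beta-nicotinamide
adenine dinucleotide phosphate (NADP) with Al(III) in 0.2 M KCl, the
cumulative Al(III) hydrolysis constants, and the ionic product of water
in the same medium.  All species are expressed from the free components
Al, CIP (fully deprotonated, 2 protonation sites), NADP (fully
deprotonated, 3 protonation sites) and H; hydroxide enters with a proton
coefficient of -1.
"""

from __future__ import annotations

from .equilibria import Component, EquilibriumModel, Species

__all__ = [
    "PKW",
    "AL_HYDROLYSIS_LOG_BETAS",
    "CIP_PROTONATION",
    "NADP_PROTONATION",
    "AL_CIP_BINARY",
    "AL_NADP_BINARY",
    "TERNARY",
    "CONDITIONAL_LOGK_AL_CIP",
    "CONDITIONAL_LOGK_AL_NADP",
    "water_model",
    "al_hydrolysis_model",
    "ligand_model",
    "binary_model",
    "ternary_model",
    "conditional_binding_model",
]

#: -log10 ionic product of water, 25 C, 0.2 M KCl
PKW = 13.78

#: cumulative Al(III) hydrolysis constants log beta_q for Al(OH)_q, q = 1..4
AL_HYDROLYSIS_LOG_BETAS = {1: -5.5, 2: -11.1, 3: -16.6, 4: -23.2}

#: ligand protonation log betas (HL, H2L, ...)
CIP_PROTONATION = {"H(CIP)": 8.60, "H2(CIP)": 14.76}
NADP_PROTONATION = {"H(NADP)": 9.93, "H2(NADP)": 16.09, "H3(NADP)": 19.90}

#: binary Al(III) complexes, log beta from free components
AL_CIP_BINARY = {
    "Al(CIP)": 9.36,
    "Al(HCIP)": 15.85,
    "Al(CIP)(HCIP)": 21.38,
}
AL_NADP_BINARY = {
    "Al(NADP)": 10.71,
    "Al(HNADP)": 16.01,
    "Al(H2NADP)": 19.16,
    "Al(H2NADP)2": 37.84,
    "Al(NADP)2(HNADP)": 29.82,
    "Al(H2NADP)3": 57.53,
}

#: mixed-ligand 1:1:1 complexes
TERNARY = {
    "Al(CIP)(HNADP)": 26.56,
    "Al(HCIP)(HNADP)": 32.49,
}

#: conditional 1:1 stability constants at pH 7.0, micromolar regime
CONDITIONAL_LOGK_AL_CIP = 10.2
CONDITIONAL_LOGK_AL_NADP = 10.7

_AL = Component("Al", 3, "metal")
_H = Component("H", 1, "proton")
_CIP = Component("CIP", -1, "ligand")
_NADP = Component("NADP", -3, "ligand")

# proton counts of the ligand protonation ladders
_N_PROT = {"CIP": 2, "NADP": 3}


def _oh_species() -> list[Species]:
    return [Species("OH", {"H": -1}, -PKW)]


def _hydrolysis_species() -> list[Species]:
    return [
        Species(f"Al(OH){q if q > 1 else ''}", {"Al": 1, "H": -q}, lb)
        for q, lb in AL_HYDROLYSIS_LOG_BETAS.items()
    ]


def _protonation_species(ligand: str) -> list[Species]:
    table = CIP_PROTONATION if ligand == "CIP" else NADP_PROTONATION
    out = []
    for label, lb in table.items():
        n = int(label[1]) if label[1].isdigit() else 1
        out.append(Species(label, {ligand: 1, "H": n}, lb))
    return out


def _binary_species(ligand: str) -> list[Species]:
    if ligand == "CIP":
        return [
            Species("Al(CIP)", {"Al": 1, "CIP": 1}, AL_CIP_BINARY["Al(CIP)"]),
            Species("Al(HCIP)", {"Al": 1, "CIP": 1, "H": 1}, AL_CIP_BINARY["Al(HCIP)"]),
            Species(
                "Al(CIP)(HCIP)",
                {"Al": 1, "CIP": 2, "H": 1},
                AL_CIP_BINARY["Al(CIP)(HCIP)"],
            ),
        ]
    return [
        Species("Al(NADP)", {"Al": 1, "NADP": 1}, AL_NADP_BINARY["Al(NADP)"]),
        Species("Al(HNADP)", {"Al": 1, "NADP": 1, "H": 1}, AL_NADP_BINARY["Al(HNADP)"]),
        Species(
            "Al(H2NADP)", {"Al": 1, "NADP": 1, "H": 2}, AL_NADP_BINARY["Al(H2NADP)"]
        ),
        Species(
            "Al(H2NADP)2", {"Al": 1, "NADP": 2, "H": 4}, AL_NADP_BINARY["Al(H2NADP)2"]
        ),
        Species(
            "Al(NADP)2(HNADP)",
            {"Al": 1, "NADP": 3, "H": 1},
            AL_NADP_BINARY["Al(NADP)2(HNADP)"],
        ),
        Species(
            "Al(H2NADP)3", {"Al": 1, "NADP": 3, "H": 6}, AL_NADP_BINARY["Al(H2NADP)3"]
        ),
    ]


def _ternary_species() -> list[Species]:
    return [
        Species(
            "Al(CIP)(HNADP)",
            {"Al": 1, "CIP": 1, "NADP": 1, "H": 1},
            TERNARY["Al(CIP)(HNADP)"],
        ),
        Species(
            "Al(HCIP)(HNADP)",
            {"Al": 1, "CIP": 1, "NADP": 1, "H": 2},
            TERNARY["Al(HCIP)(HNADP)"],
        ),
    ]


def water_model() -> EquilibriumModel:
    """Proton and hydroxide only."""
    return EquilibriumModel([_H], _oh_species())


def al_hydrolysis_model() -> EquilibriumModel:
    """Al(III) with its four hydroxo species and water."""
    return EquilibriumModel([_AL, _H], _oh_species() + _hydrolysis_species())


def ligand_model(ligand: str = "CIP") -> EquilibriumModel:
    """A single ligand with its protonation ladder and water."""
    comp = _CIP if ligand == "CIP" else _NADP
    return EquilibriumModel([comp, _H], _oh_species() + _protonation_species(ligand))


def binary_model(ligand: str = "CIP", hydrolysis: bool = True) -> EquilibriumModel:
    """Al(III) plus one ligand: protonation, binary complexes, hydrolysis."""
    comp = _CIP if ligand == "CIP" else _NADP
    species = _oh_species() + _protonation_species(ligand) + _binary_species(ligand)
    if hydrolysis:
        species += _hydrolysis_species()
    return EquilibriumModel([_AL, comp, _H], species)


def ternary_model(hydrolysis: bool = True, include_ternary: bool = True) -> EquilibriumModel:
    """The full Al(III)-CIP-NADP model with all tabulated constants."""
    species = (
        _oh_species()
        + _protonation_species("CIP")
        + _protonation_species("NADP")
        + _binary_species("CIP")
        + _binary_species("NADP")
    )
    if hydrolysis:
        species += _hydrolysis_species()
    if include_ternary:
        species += _ternary_species()
    return EquilibriumModel([_AL, _CIP, _NADP, _H], species)


def conditional_binding_model(
    logk_cip: float = CONDITIONAL_LOGK_AL_CIP,
    logk_nadp: float = CONDITIONAL_LOGK_AL_NADP,
) -> EquilibriumModel:
    """Effective 1:1 binding model at fixed pH with conditional constants.

    Protonation and hydrolysis are absorbed into the conditional
    constants, so the species carry no proton coefficients; solve with
    ``fixed_ph`` set (the proton balance is then inert).
    """
    species = [
        Species("Al(CIP)", {"Al": 1, "CIP": 1}, logk_cip),
        Species("Al(NADP)", {"Al": 1, "NADP": 1}, logk_nadp),
    ]
    return EquilibriumModel([_AL, _CIP, _NADP, _H], species)
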