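import numpy as np
import pytest

from equispec import models, standard_design, simulate_titration
from equispec import synthetic as syn


@pytest.fixture(scope="session")
def uv_grid():
    return syn.default_wavelength_grid()


@pytest.fixture(scope="session")
def cip_spectra(uv_grid):
    """(ligand, complex) molar responses for the CIP absorbance channel."""
    return (
        syn.gen_species_spectrum(syn.CIP_BANDS, uv_grid),
        syn.gen_species_spectrum(syn.AL_CIP_COMPLEX_BANDS, uv_grid),
    )


@pytest.fixture(scope="session")
def nadp_spectra(uv_grid):
    return (
        syn.gen_species_spectrum(syn.NADP_BANDS, uv_grid),
        syn.gen_species_spectrum(syn.AL_NADP_COMPLEX_BANDS, uv_grid),
    )


@pytest.fixture(scope="session")
def fig3_metal_totals():
    """Metal totals of the 5-sample absorbance design (mol/L)."""
    return np.array([0.0, 5e-6, 10e-6, 15e-6, 20e-6])


@pytest.fixture(scope="session")
def cip_titration():
    """Noise-free ligand-only CIP titration at the standard design."""
    model = models.ligand_model("CIP")
    return model, simulate_titration(model, standard_design({"CIP": 1e-3}))


@pytest.fixture(scope="session")
def ternary_titration():
    """Noise-free 1:1:1 Al/CIP/NADP titration with the full model."""
    model = models.ternary_model()
    design = standard_design({"CIP": 1e-3, "NADP": 1e-3}, metal_total=1e-3)
    return model, simulate_titration(model, design)
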