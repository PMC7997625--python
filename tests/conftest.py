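import numpy as np
import pytest

import spequil as sq
from spequil.core import Component, EquilibriumModel, SpeciesLine


@pytest.fixture(scope="session")
def dmsa():
    """Packaged H+-DMSA protonation model (four temperatures)."""
    return sq.load_packaged_model("dmsa-protonation")


@pytest.fixture(scope="session")
def asdmsa():
    """Packaged As(III)-DMSA model: protonation ladder plus MLH/MLH2/MLH3."""
    return sq.load_packaged_model("as3-dmsa")


@pytest.fixture(scope="session")
def water():
    return sq.water_model({298.15: 13.75})


def make_model(species, components=("M", "L", "H"), pKw=13.75, T=298.15):
    """Small helper: build a model from {stoich: log_beta} at one temperature."""
    roles = {"M": "metal", "L": "ligand", "H": "proton"}
    comps = [Component(n, roles[n]) for n in components]
    lines = [SpeciesLine(st, {T: lb}) for st, lb in species.items()]
    return EquilibriumModel(comps, lines, {T: pKw})


@pytest.fixture(scope="session")
def asdmsa_titration(asdmsa):
    """Equimolar As(III):DMSA titration protocol used for refinement studies."""
    comp = sq.SolutionComposition(C_M=0.001, C_L=0.001, C_HCl=0.008)
    return sq.TitrationProtocol(
        initial=comp, titrant_concentration=0.1,
        volumes=np.linspace(0.0, 4.0, 51), T=298.15,
    )


@pytest.fixture(scope="session")
def uv_bands():
    """Gaussian-band molar absorptivity profiles for all DMSA species, 200-350 nm."""
    lam = np.arange(200.0, 351.0, 5.0)
    eps = {
        "L":    sq.gaussian_bands(lam, [(236, 18, 9000)]),
        "HL":   sq.gaussian_bands(lam, [(232, 17, 8200)]),
        "H2L":  sq.gaussian_bands(lam, [(226, 16, 7000)]),
        "H3L":  sq.gaussian_bands(lam, [(220, 15, 5600)]),
        "H4L":  sq.gaussian_bands(lam, [(214, 14, 4500)]),
        "MLH":  sq.gaussian_bands(lam, [(260, 20, 11000)]),
        "MLH2": sq.gaussian_bands(lam, [(252, 19, 9500)]),
        "MLH3": sq.gaussian_bands(lam, [(246, 18, 8000)]),
    }
    return lam, eps
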