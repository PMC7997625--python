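"""Synthetic potentiometric and spectrophotometric titrations.

Emulates the experimental workflow behind the packaged constants: 25 mL of
ligand (+ metal) fully protonated with HCl in 0.15 mol/L NaCl, titrated with
standard NaOH across 2 <= pH <= 10.5.  The glass electrode follows the
Nernst relation with optional junction terms,

    E = E0 + s log10[H+] + ja [H+] + jb [OH-],   s = RT ln(10)/F,

and instrument noise defaults to the stated reading precisions
(+/-0.15 mV on emf, +/-0.003 mL on delivered volume).  Spectra obey
Beer-Lambert additivity over a configurable wavelength window.  A single
integer seed expands into independent streams for emf, volume and
absorbance noise; without a seed the simulation is noiseless and bit-stable.

Each dataset retains a truth block (generating constants, electrode
parameters, seed) so that refinement tests can score parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CompiledSystem,
    ConvergenceError,
    EquilibriumModel,
    ModelError,
    SolutionComposition,
)

R_GAS = 8.314
FARADAY = 96485.33212
LN10 = math.log(10.0)


def nernst_slope(T: float) -> float:
    """Theoretical electrode slope RT ln(10)/F in mV per decade (59.16 at 298.15 K)."""
    return R_GAS * T * LN10 / FARADAY * 1000.0


@dataclass
class ElectrodeParams:
    """Glass-electrode calibration: formal potential, slope, junction terms, noise."""

    E0: float = 400.0               # mV
    slope: float | None = None      # mV/decade; None = theoretical at the run T
    ja: float = 0.0                 # acid junction, mV L/mol
    jb: float = 0.0                 # alkaline junction, mV L/mol
    sigma_E: float = 0.15           # mV
    sigma_v: float = 0.003          # mL

    def __post_init__(self):
        if self.slope is not None and self.slope <= 0:
            raise ModelError("electrode slope must be positive")
        if self.sigma_E < 0 or self.sigma_v < 0:
            raise ModelError("noise sigmas must be >= 0")

    def slope_at(self, T: float) -> float:
        return self.slope if self.slope is not None else nernst_slope(T)

    def emf(self, h: float, oh: float, T: float) -> float:
        return self.E0 + self.slope_at(T) * math.log10(h) + self.ja * h + self.jb * oh


@dataclass
class TitrationProtocol:
    """Initial solution, titrant and volume schedule of one titration."""

    initial: SolutionComposition
    titrant_concentration: float    # mol/L NaOH
    volumes: np.ndarray             # mL of titrant added, strictly increasing
    T: float = 298.15
    v0: float = 25.0                # initial volume, mL

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.titrant_concentration <= 0:
            raise ModelError("titrant concentration must be positive")
        if self.volumes.ndim != 1 or self.volumes.size == 0:
            raise ModelError("volume schedule must be a non-empty 1-D sequence")
        if self.volumes.size > 1 and not np.all(np.diff(self.volumes) > 0):
            raise ModelError("volumes must be strictly increasing")
        if self.v0 <= 0:
            raise ModelError("initial volume must be positive")

    def totals_at(self, model: EquilibriumModel, v: float,
                  composition: SolutionComposition | None = None) -> dict[str, float]:
        """Analytical totals after adding v mL of titrant (dilution included)."""
        comp = composition if composition is not None else self.initial
        dil = self.v0 / (self.v0 + v)
        out: dict[str, float] = {}
        for c in model.components:
            if c.role == "metal":
                out[c.name] = comp.C_M * dil
            elif c.role == "ligand":
                out[c.name] = comp.C_L * dil
            else:
                moles_h = comp.proton_total(model) * self.v0 - v * self.titrant_concentration
                out[c.name] = moles_h / (self.v0 + v)
        return out


@dataclass
class SpectralModel:
    """Molar absorption profiles per species over a wavelength grid (1 cm path)."""

    wavelengths: np.ndarray                  # nm
    epsilon: dict[str, np.ndarray]           # species label -> L mol-1 cm-1 per lambda
    path: float = 1.0                        # cm
    sigma_A: float = 0.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.size == 0:
            raise ModelError("wavelength grid must be non-empty")
        self.epsilon = {k: np.asarray(v, dtype=float) for k, v in self.epsilon.items()}
        for lab, eps in self.epsilon.items():
            if eps.shape != self.wavelengths.shape:
                raise ModelError(f"epsilon for {lab} does not match the wavelength grid")
            if np.any(eps < 0):
                raise ModelError(f"epsilon for {lab} must be >= 0")
        if self.sigma_A < 0:
            raise ModelError("sigma_A must be >= 0")


def gaussian_bands(wavelengths: Sequence[float],
                   bands: Sequence[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian absorption bands: (center nm, sigma nm, peak height)."""
    lam = np.asarray(wavelengths, dtype=float)
    eps = np.zeros_like(lam)
    for center, width, height in bands:
        eps += height * np.exp(-0.5 * ((lam - center) / width) ** 2)
    return eps


@dataclass
class TitrationDataset:
    """Simulated (or loaded) titration: volumes plus emf and/or absorbance."""

    protocol: TitrationProtocol
    volumes: np.ndarray                       # nominal mL added, as recorded
    emf: np.ndarray | None = None             # mV per point
    absorbance: pd.DataFrame | None = None    # rows: points, columns: wavelengths
    electrode: ElectrodeParams | None = None
    spectral: SpectralModel | None = None
    truth: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if self.emf is not None:
            return pd.DataFrame({"v_mL": self.volumes, "emf_mV": self.emf})
        return self.to_long_frame()

    def to_long_frame(self) -> pd.DataFrame:
        if self.absorbance is None:
            raise ModelError("dataset has no absorbance block")
        long = self.absorbance.copy()
        long.index = pd.Index(self.volumes, name="v_mL")
        long = long.reset_index().melt("v_mL", var_name="lambda_nm", value_name="A")
        long["lambda_nm"] = long["lambda_nm"].astype(float)
        return long.sort_values(["v_mL", "lambda_nm"], ignore_index=True)


def _noise_streams(seed: int | None):
    if seed is None:
        return None, None, None
    ss = np.random.SeedSequence(int(seed))
    return tuple(np.random.default_rng(child) for child in ss.spawn(3))


def _solve_titration(model: EquilibriumModel, protocol: TitrationProtocol,
                     actual_volumes: np.ndarray):
    system = CompiledSystem(model, protocol.T)
    states = []
    prev = None
    for v in actual_volumes:
        totals = protocol.totals_at(model, float(v))
        state = system.solve(totals, x0=prev)
        prev = state.free
        states.append(state)
    return states


def simulate_potentiometric(
    model: EquilibriumModel,
    protocol: TitrationProtocol,
    electrode: ElectrodeParams,
    seed: int | None = None,
) -> TitrationDataset:
    """Simulate an emf-vs-volume titration.

    The volume error perturbs the delivered volume before speciation while
    the nominal schedule is what gets recorded, mirroring a buret whose
    reading is trusted but whose delivery is imperfect.
    """
    rng_e, rng_v, _ = _noise_streams(seed)
    v_nom = protocol.volumes
    v_act = v_nom.copy()
    if rng_v is not None and electrode.sigma_v > 0:
        v_act = v_nom + rng_v.normal(0.0, electrode.sigma_v, size=v_nom.shape)
        v_act = np.maximum(v_act, 0.0)
    states = _solve_titration(model, protocol, v_act)
    kw = 10.0 ** (-model.pKw(protocol.T))
    proton = model.proton.name
    emf = np.array([
        electrode.emf(s.free[proton], kw / s.free[proton], protocol.T) for s in states
    ])
    if rng_e is not None and electrode.sigma_E > 0:
        emf = emf + rng_e.normal(0.0, electrode.sigma_E, size=emf.shape)
    truth = {
        "log_beta": {sp.label: sp.log_beta(protocol.T) for sp in model.species},
        "pKw": model.pKw(protocol.T),
        "electrode": asdict(electrode),
        "seed": seed,
        "pH": [s.pH for s in states],
    }
    return TitrationDataset(protocol=protocol, volumes=v_nom.copy(), emf=emf,
                            electrode=electrode, truth=truth)


def simulate_calibration(
    protocol: TitrationProtocol,
    electrode: ElectrodeParams,
    model: EquilibriumModel,
    seed: int | None = None,
) -> TitrationDataset:
    """Electrode calibration: strong acid vs strong base on a species-free model."""
    if model.species:
        raise ModelError("calibration expects a species-free (water-only) model")
    return simulate_potentiometric(model, protocol, electrode, seed=seed)


def simulate_spectrophotometric(
    model: EquilibriumModel,
    protocol: TitrationProtocol,
    spectral: SpectralModel,
    seed: int | None = None,
) -> TitrationDataset:
    """Simulate absorbance matrices A(point, lambda) = path * sum eps * conc."""
    for lab in spectral.epsilon:
        if lab not in {sp.label for sp in model.species} | {c.name for c in model.components}:
            raise ModelError(f"epsilon given for unknown species {lab!r}")
    _, _, rng_a = _noise_streams(seed)
    states = _solve_titration(model, protocol, protocol.volumes)
    labels = list(spectral.epsilon)
    C = np.array([[s.species_conc[lab] for lab in labels] for s in states])
    E = np.array([spectral.epsilon[lab] for lab in labels])
    A = spectral.path * (C @ E)
    if rng_a is not None and spectral.sigma_A > 0:
        A = A + rng_a.normal(0.0, spectral.sigma_A, size=A.shape)
    truth = {
        "log_beta": {sp.label: sp.log_beta(protocol.T) for sp in model.species},
        "pKw": model.pKw(protocol.T),
        "seed": seed,
        "pH": [s.pH for s in states],
    }
    frame = pd.DataFrame(A, columns=spectral.wavelengths)
    return TitrationDataset(protocol=protocol, volumes=protocol.volumes.copy(),
                            absorbance=frame, spectral=spectral, truth=truth)
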