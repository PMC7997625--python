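"""Thermodynamic formation parameters from multi-temperature constants.

Free energies follow directly from the overall constants,
dG = -RT ln(10) log beta.  Formation enthalpies come from the integrated
van't Hoff relation ln beta = -dH/(R T) + dS/R, fitted as an unweighted
ordinary least-squares line of ln beta against 1/T (dCp assumed 0 over the
narrow 288-318 K window); the entropic term is the identity TdS = dH - dG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EquilibriumModel, ModelError

R_GAS = 8.314  # J mol-1 K-1
LN10 = math.log(10.0)


def delta_g(log_beta: float, T: float) -> float:
    """Standard free energy dG = -RT ln(10) log beta, in kJ/mol."""
    if T <= 0:
        raise ModelError("temperature must be positive")
    return -R_GAS * T * LN10 * log_beta / 1000.0


def vant_hoff(log_beta_by_T: dict) -> tuple[float, float]:
    """Formation enthalpy and its standard error from a van't Hoff line.

    Fits ln(10)*log beta against 1/T by unweighted OLS; dH = -R * slope.
    Returns (dH, sd) in kJ/mol.  Requires constants at >= 2 temperatures.
    """
    items = sorted((float(t), float(lb)) for t, lb in log_beta_by_T.items())
    if len(items) < 2:
        raise ModelError("van't Hoff regression needs constants at >= 2 temperatures")
    x = np.array([1.0 / t for t, _ in items])
    y = np.array([LN10 * lb for _, lb in items])
    if len(items) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return -R_GAS * slope / 1000.0, 0.0
    fit = stats.linregress(x, y)
    dH = -R_GAS * fit.slope / 1000.0
    sd = R_GAS * fit.stderr / 1000.0
    return dH, sd


def entropy_term(deltaG: float, deltaH: float) -> float:
    """TdS = dH - dG (kJ/mol), both inputs at the same temperature."""
    return deltaH - deltaG


@dataclass
class ThermoRecord:
    """dG, dH and TdS for one formation reaction at a stated temperature."""

    reaction: str
    T: float
    deltaG: float
    deltaH: float
    TdeltaS: float
    deltaH_sd: float
    deltaG_sd: float = 0.0


def _reaction_label(model: EquilibriumModel, stoich) -> str:
    parts = []
    for comp, n in zip(model.components, stoich):
        if n == 0:
            continue
        parts.append(comp.name if n == 1 else f"{n}{comp.name}")
    sp = model.species_by_stoich(stoich)
    return " + ".join(parts) + " = " + sp.label


def thermo_table(model: EquilibriumModel, T: float = 298.15) -> list[ThermoRecord]:
    """One ThermoRecord per species, dH from the species' full T series.

    Every species needs constants at >= 2 temperatures and a constant at T.
    """
    records = []
    for sp in model.species:
        dH, dH_sd = vant_hoff(sp.log_beta_by_T)
        dG = delta_g(sp.log_beta(T), T)
        dG_sd = abs(delta_g(sp.sd_by_T.get(float(T), 0.0), T))
        records.append(ThermoRecord(
            reaction=_reaction_label(model, sp.stoich), T=float(T),
            deltaG=dG, deltaH=dH, TdeltaS=entropy_term(dG, dH),
            deltaH_sd=dH_sd, deltaG_sd=dG_sd,
        ))
    return records


def thermo_frame(records: list[ThermoRecord]) -> pd.DataFrame:
    """Tabular (CSV-ready) view: reaction, -dG, dH, TdS and sd columns."""
    return pd.DataFrame({
        "reaction": [r.reaction for r in records],
        "T_K": [r.T for r in records],
        "minus_deltaG_kJ_mol": [-r.deltaG for r in records],
        "deltaG_sd_kJ_mol": [r.deltaG_sd for r in records],
        "deltaH_kJ_mol": [r.deltaH for r in records],
        "deltaH_sd_kJ_mol": [r.deltaH_sd for r in records],
        "TdeltaS_kJ_mol": [r.TdeltaS for r in records],
    })
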