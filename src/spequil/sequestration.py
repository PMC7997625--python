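"""Sequestering ability of a ligand toward a trace metal: chi vs pL and pL0.5.

pL0.5 is the -log10 of the total ligand concentration at which half of a
trace metal is bound at fixed pH, temperature and ionic medium.  In the
trace limit the bound fraction is independent of the metal concentration:

    chi = S / (1 + S_side + S),   S = sum_i beta_11i [L] [H]^i

with [L] the free (fully deprotonated) ligand concentration obtained from
the ligand-only speciation at the stated pH, and S_side the analogous sum
over metal side-reaction species (hydrolysis, medium interaction), supplied
as extra species lines because they come from independent determinations.

chi(pL) is a decreasing sigmoid with asymptotes 1 (pL -> -inf) and
0 (pL -> +inf); pL0.5 is located by bisection and, as a cross-check, by a
least-squares fit of the base-10 Boltzmann form chi = 1/(1 + 10^(pL - pL0.5)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .core import (
    CompiledSystem,
    EquilibriumModel,
    ModelError,
    SolutionComposition,
    SpeciesLine,
)


def _complex_terms(model: EquilibriumModel, T: float):
    """(stoich in L, stoich in H, log beta) for every metal complex; all must
    be mononuclear in the metal for the trace limit to apply."""
    imetal = [i for i, c in enumerate(model.components) if c.role == "metal"]
    il = [i for i, c in enumerate(model.components) if c.role == "ligand"]
    ip = model.proton_index
    if not imetal:
        raise ModelError("model has no metal component")
    terms = []
    for sp in model.species:
        m = sum(sp.stoich[i] for i in imetal)
        if m == 0:
            continue
        if m > 1:
            raise ModelError(
                f"species {sp.label} is polynuclear in the metal; trace limit invalid"
            )
        l = sum(sp.stoich[i] for i in il)
        terms.append((l, sp.stoich[ip], sp.log_beta(T)))
    return terms


def _side_sum(side_reactions: Iterable[SpeciesLine] | None, pH: float, T: float) -> float:
    """Sum of beta_10h [H]^h over metal side-reaction species (m=1, l=0)."""
    total = 0.0
    for sp in side_reactions or []:
        h = sp.stoich[-1]  # side-reaction lines use [m, l, h] convention
        if sp.stoich[0] != 1 or sp.stoich[1] != 0:
            raise ModelError(
                f"side reaction {sp.stoich} must be mononuclear in M with no ligand"
            )
        total += 10.0 ** (sp.log_beta(T) + h * (-pH))
    return total


def chi_trace(
    model: EquilibriumModel,
    side_reactions: Iterable[SpeciesLine] | None,
    pH: float,
    T: float,
    C_L_total: float,
) -> float:
    """Mole fraction of a trace metal complexed by the ligand.

    Analytic trace limit: independent of C_M.  The free ligand concentration
    comes from the ligand-only speciation (C_M = 0) at the fixed pH.
    """
    terms = _complex_terms(model, T)
    ligand = model.component("ligand")
    if ligand is None:
        raise ModelError("model has no ligand component")
    if C_L_total <= 0:
        return 0.0
    state = CompiledSystem(model, T).solve(
        SolutionComposition(C_M=0.0, C_L=C_L_total), fixed_pH=pH
    )
    free_L = state.free[ligand.name]
    S = sum(10.0 ** (lb + l * math.log10(free_L) + h * (-pH)) for l, h, lb in terms)
    return S / (1.0 + _side_sum(side_reactions, pH, T) + S)


@dataclass
class SequestrationResult:
    """chi-vs-pL curve with the bisected and sigmoid-fitted pL0.5."""

    pH: float
    T: float
    pL_grid: np.ndarray
    chi: np.ndarray
    pL05: float
    sigmoid_pL05: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pL": self.pL_grid, "chi": self.chi})


def sequestration_curve(
    model: EquilibriumModel,
    side_reactions: Iterable[SpeciesLine] | None,
    pH: float,
    T: float,
    pL_grid: Sequence[float],
    fit: bool = True,
) -> SequestrationResult:
    """Evaluate chi over a pL grid and solve chi(pL0.5) = 0.5 by bisection.

    The bisection bracket starts from the grid and is extended by up to 10
    log units on either side; failure to bracket 0.5 is an error.
    """
    pL = np.asarray(pL_grid, dtype=float)
    if pL.ndim != 1 or pL.size == 0 or (pL.size > 1 and not np.all(np.diff(pL) > 0)):
        raise ModelError("pL grid must be non-empty and strictly increasing")

    def chi_of(pl: float) -> float:
        return chi_trace(model, side_reactions, pH, T, 10.0 ** (-pl))

    chi = np.array([chi_of(p) for p in pL])
    lo, hi = float(pL[0]), float(pL[-1])
    f_lo, f_hi = chi_of(lo) - 0.5, chi_of(hi) - 0.5
    steps = 0
    while f_lo < 0 and steps < 10:
        lo -= 1.0
        f_lo = chi_of(lo) - 0.5
        steps += 1
    steps = 0
    while f_hi > 0 and steps < 10:
        hi += 1.0
        f_hi = chi_of(hi) - 0.5
        steps += 1
    if f_lo < 0 or f_hi > 0:
        raise ModelError("chi never crosses 0.5 within the extended search bracket")
    pl05 = brentq(lambda p: chi_of(p) - 0.5, lo, hi, xtol=1e-10)

    result = SequestrationResult(pH=float(pH), T=float(T), pL_grid=pL, chi=chi,
                                 pL05=float(pl05))
    if fit:
        try:
            result.sigmoid_pL05 = fit_sigmoid(result)
        except ModelError:
            result.sigmoid_pL05 = None
    return result


def fit_sigmoid(curve: SequestrationResult | tuple) -> float:
    """pL0.5 from a least-squares fit of chi = 1/(1 + 10^(pL - pL0.5)).

    Needs >= 5 points with chi spanning below 0.1 and above 0.9.
    """
    if isinstance(curve, SequestrationResult):
        pL, chi = curve.pL_grid, curve.chi
    else:
        pL, chi = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if pL.size < 5 or chi.min() >= 0.1 or chi.max() <= 0.9:
        raise ModelError(
            "insufficient dynamic range: need >= 5 points with chi spanning <0.1 to >0.9"
        )

    def boltzmann(pl, pl05):
        return 1.0 / (1.0 + 10.0 ** (pl - pl05))

    p0 = float(pL[np.argmin(np.abs(chi - 0.5))])
    popt, _ = curve_fit(boltzmann, pL, chi, p0=[p0])
    return float(popt[0])
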