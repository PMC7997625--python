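"""Multicomponent chemical-equilibrium models and mass-balance speciation.

A model is a set of components (metal M, ligand L, proton H) plus species
defined by signed stoichiometric coefficients and overall formation constants

    m M + l L + h H  =  M_m L_l H_h,      beta = [M_m L_l H_h] / ([M]^m [L]^l [H]^h)

written from the fully deprotonated ligand and the free metal ion.  Negative
proton coefficients denote hydroxo/deprotonated species; the hydroxide ion
(0, 0, -1) with log beta = -pKw is always implied and must not be declared.
All constants are conditional on the stated ionic medium (activity ==
concentration convention, pH = -log10[H+]).

The solver performs damped Newton-Raphson iteration on the natural logarithms
of the free component concentrations, which guarantees positivity and copes
with the very large overall constants (log beta up to ~30) typical of
polyprotic thiol ligands and their As(III) complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LN10 = math.log(10.0)

ROLES = ("metal", "ligand", "proton")


class ModelError(ValueError):
    """Invalid model definition or invalid input to an equilibrium query."""


class ConvergenceError(RuntimeError):
    """Mass-balance iteration failed; carries the final relative residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Component:
    """A chemical component (building block of all species)."""

    name: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ModelError(f"component role must be one of {ROLES}, got {self.role!r}")
        if not self.name:
            raise ModelError("component name must be non-empty")


def _float_keyed(d: Mapping) -> dict[float, float]:
    return {float(k): float(v) for k, v in d.items()}


@dataclass
class SpeciesLine:
    """One species: stoichiometry plus log10 overall constants per temperature."""

    stoich: tuple[int, ...]
    log_beta_by_T: dict[float, float]
    sd_by_T: dict[float, float] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self):
        self.stoich = tuple(int(v) for v in self.stoich)
        self.log_beta_by_T = _float_keyed(self.log_beta_by_T)
        self.sd_by_T = _float_keyed(self.sd_by_T)
        if not self.log_beta_by_T:
            raise ModelError(f"species {self.stoich} needs at least one temperature entry")
        if any(sd < 0 for sd in self.sd_by_T.values()):
            raise ModelError(f"species {self.stoich}: standard deviations must be >= 0")

    def log_beta(self, T: float) -> float:
        try:
            return self.log_beta_by_T[float(T)]
        except KeyError:
            raise ModelError(
                f"species {self.label or self.stoich} has no log beta at T = {T} K"
            ) from None

    def temperatures(self) -> set[float]:
        return set(self.log_beta_by_T)


def default_label(stoich: Sequence[int], components: Sequence[Component]) -> str:
    """Conventional species label: MLH2, H3L, OH, ML(OH) ..."""
    ip = next(i for i, c in enumerate(components) if c.role == "proton")
    h = stoich[ip]
    others = [
        (components[i], n)
        for i, n in enumerate(stoich)
        if i != ip and n != 0
    ]
    if any(n < 0 for _, n in others):
        raise ModelError("negative coefficients are only allowed on the proton component")

    def _hpart(n: int) -> str:
        if n == 0:
            return ""
        if n > 0:
            return "H" + (str(n) if n > 1 else "")
        return "(OH)" + (str(-n) if -n > 1 else "")

    if not others:
        if h == 1:
            return "H"
        if h == -1:
            return "OH"
        if h == 0:
            raise ModelError("species with all-zero stoichiometry is not allowed")
        return _hpart(h)

    body = "".join(c.name + (str(n) if n > 1 else "") for c, n in others)
    has_metal = any(c.role == "metal" for c, _ in others)
    if has_metal or h <= 0:
        return body + _hpart(h)
    # ligand-only protonated species read H-first: H3L
    return _hpart(h) + body


@dataclass
class Medium:
    ionic_strength: float = 0.15
    electrolyte: str = "NaCl"


@dataclass
class EquilibriumModel:
    """Components, species and conditional constants of one chemical system."""

    components: list[Component]
    species: list[SpeciesLine]
    pKw_by_T: dict[float, float]
    medium: Medium = field(default_factory=Medium)
    name: str = ""
    provenance: str = ""

    def __post_init__(self):
        self.pKw_by_T = _float_keyed(self.pKw_by_T)
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ModelError("component names must be unique")
        protons = [c for c in self.components if c.role == "proton"]
        if len(protons) != 1:
            raise ModelError("exactly one proton component is required")
        nc = len(self.components)
        seen: set[tuple[int, ...]] = set()
        ip = self.proton_index
        for sp in self.species:
            if len(sp.stoich) != nc:
                raise ModelError(
                    f"species stoichiometry {sp.stoich} does not match the "
                    f"{nc} declared components"
                )
            if sp.stoich in seen:
                raise ModelError(f"duplicate species stoichiometry {sp.stoich}")
            seen.add(sp.stoich)
            if all(n == 0 for i, n in enumerate(sp.stoich) if i != ip) and sp.stoich[ip] == -1:
                raise ModelError("the hydroxide species (0,0,-1) is implied; do not declare it")
            if all(n == 0 for n in sp.stoich):
                raise ModelError("species with all-zero stoichiometry is not allowed")
            for i, n in enumerate(sp.stoich):
                if n < 0 and i != ip:
                    raise ModelError("only the proton coefficient may be negative")
            if sp.label is None:
                sp.label = default_label(sp.stoich, self.components)
        labels = [sp.label for sp in self.species]
        if len(set(labels)) != len(labels):
            raise ModelError("species labels must be unique")
        needed = set().union(*(sp.temperatures() for sp in self.species)) if self.species else set()
        missing = needed - set(self.pKw_by_T)
        if missing:
            raise ModelError(f"pKw is not defined at temperature(s) {sorted(missing)}")
        if not self.pKw_by_T:
            raise ModelError("pKw must be given for at least one temperature")

    # -- lookups ----------------------------------------------------------

    @property
    def proton_index(self) -> int:
        return next(i for i, c in enumerate(self.components) if c.role == "proton")

    @property
    def proton(self) -> Component:
        return self.components[self.proton_index]

    def component(self, role: str) -> Component | None:
        return next((c for c in self.components if c.role == role), None)

    def component_index(self, name: str) -> int:
        for i, c in enumerate(self.components):
            if c.name == name:
                return i
        raise ModelError(f"unknown component {name!r}")

    def pKw(self, T: float) -> float:
        try:
            return self.pKw_by_T[float(T)]
        except KeyError:
            raise ModelError(f"pKw not defined at T = {T} K") from None

    def temperatures(self) -> list[float]:
        """Temperatures at which every declared species has a constant."""
        if not self.species:
            return sorted(self.pKw_by_T)
        common = set.intersection(*(sp.temperatures() for sp in self.species))
        return sorted(common)

    def species_by_label(self, label: str) -> SpeciesLine:
        for sp in self.species:
            if sp.label == label:
                return sp
        raise ModelError(f"unknown species {label!r}")

    def species_by_stoich(self, stoich: Sequence[int]) -> SpeciesLine:
        key = tuple(int(v) for v in stoich)
        for sp in self.species:
            if sp.stoich == key:
                return sp
        raise ModelError(f"no species with stoichiometry {key}")

    def log_beta(self, key, T: float) -> float:
        sp = self.species_by_label(key) if isinstance(key, str) else self.species_by_stoich(key)
        return sp.log_beta(T)

    def ligand_protonation_level(self) -> int:
        """Maximum proton count on a pure-ligand species (4 for DMSA)."""
        ip = self.proton_index
        il = [i for i, c in enumerate(self.components) if c.role == "ligand"]
        level = 0
        for sp in self.species:
            if any(sp.stoich[i] != 0 for i in il) and all(
                sp.stoich[i] == 0 for i, c in enumerate(self.components) if c.role == "metal"
            ):
                level = max(level, sp.stoich[ip])
        return level

    def with_log_beta(self, updates: Mapping[str, float], T: float) -> "EquilibriumModel":
        """Copy of the model with selected log beta values replaced at one T."""
        new_species = []
        for sp in self.species:
            lb = dict(sp.log_beta_by_T)
            if sp.label in updates:
                lb[float(T)] = float(updates[sp.label])
            new_species.append(SpeciesLine(sp.stoich, lb, dict(sp.sd_by_T), sp.label))
        return EquilibriumModel(
            list(self.components), new_species, dict(self.pKw_by_T),
            Medium(self.medium.ionic_strength, self.medium.electrolyte),
            self.name, self.provenance,
        )


def water_model(pKw_by_T: Mapping, medium: Medium | None = None) -> EquilibriumModel:
    """Strong acid/base only system: a single proton component plus implied OH-."""
    return EquilibriumModel(
        [Component("H", "proton")], [], _float_keyed(pKw_by_T),
        medium or Medium(), name="water",
        provenance="strong acid/base blank",
    )


def build_model(config: Mapping) -> EquilibriumModel:
    """Build a validated model from a structured (TOML-shaped) description.

    ``config`` declares ``[components]`` (roles -> names; proton mandatory),
    ``[[species]]`` tables with ``stoich = [m, l, h]`` (slots for metal,
    ligand, proton; omit-role slots must be zero), ``logbeta`` / optional
    ``sd`` maps keyed by temperature, ``[pKw]`` and optional ``[medium]``.
    """
    comp_cfg = config.get("components")
    if not comp_cfg or "proton" not in comp_cfg:
        raise ModelError("config must declare [components] with at least a proton")
    slot_roles = ("metal", "ligand", "proton")
    components = [Component(comp_cfg[r], r) for r in slot_roles if r in comp_cfg]
    present = [r for r in slot_roles if r in comp_cfg]

    species = []
    for entry in config.get("species", []):
        stoich3 = list(entry["stoich"])
        if len(stoich3) != 3:
            raise ModelError(f"species stoich must be [m, l, h], got {stoich3}")
        for r, v in zip(slot_roles, stoich3):
            if r not in present and v != 0:
                raise ModelError(
                    f"species {stoich3} uses the {r} slot but no {r} component is declared"
                )
        stoich = tuple(stoich3[slot_roles.index(r)] for r in present)
        species.append(
            SpeciesLine(stoich, entry["logbeta"], entry.get("sd", {}), entry.get("label"))
        )

    med_cfg = config.get("medium", {})
    medium = Medium(
        float(med_cfg.get("ionic_strength", 0.15)), str(med_cfg.get("electrolyte", "NaCl"))
    )
    pkw = config.get("pKw") or config.get("pkw")
    if not pkw:
        raise ModelError("config must declare [pKw] (temperature -> -log10 Kw)")
    return EquilibriumModel(
        components, species, pkw, medium,
        name=str(config.get("name", "")), provenance=str(config.get("provenance", "")),
    )


# ---------------------------------------------------------------------------
# Solution composition and the speciation solver
# ---------------------------------------------------------------------------


@dataclass
class SolutionComposition:
    """Analytical (total) concentrations of one solution, mol/L.

    The total proton concentration is computed relative to the fully
    deprotonated ligand and the free metal ion as reference forms:
    C_H = n_H * C_L + C_HCl - C_NaOH, with n_H the full-protonation level
    of the ligand (4 for DMSA).  C_H may be negative (excess base).
    """

    C_M: float = 0.0
    C_L: float = 0.0
    C_HCl: float = 0.0
    C_NaOH_added: float = 0.0
    C_NaCl: float = 0.15
    full_protonation: int | None = None

    def __post_init__(self):
        for name in ("C_M", "C_L", "C_HCl", "C_NaOH_added", "C_NaCl"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")

    def proton_total(self, model: EquilibriumModel) -> float:
        n = self.full_protonation
        if n is None:
            n = model.ligand_protonation_level()
        return n * self.C_L + self.C_HCl - self.C_NaOH_added

    def totals(self, model: EquilibriumModel) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in model.components:
            if c.role == "metal":
                out[c.name] = self.C_M
            elif c.role == "ligand":
                out[c.name] = self.C_L
            else:
                out[c.name] = self.proton_total(model)
        return out


@dataclass
class SpeciationState:
    """Converged free and species concentrations for one solution point."""

    model: EquilibriumModel
    T: float
    fixed_pH: float | None
    free: dict[str, float]
    species_conc: dict[str, float]
    stoich: dict[str, tuple[int, ...]]
    totals: dict[str, float]
    residual: float
    iterations: int

    @property
    def pH(self) -> float:
        return -math.log10(self.free[self.model.proton.name])


class CompiledSystem:
    """Model frozen at one temperature into solver-ready arrays.

    Reuse one instance across many solves (titration loops, refinement inner
    loops): building the arrays once and warm-starting from the previous
    point's free concentrations dominates the per-point cost.
    """

    def __init__(self, model: EquilibriumModel, T: float):
        self.model = model
        self.T = float(T)
        comps = model.components
        nc = len(comps)
        ip = model.proton_index
        rows: list[tuple[tuple[int, ...], float, str]] = []
        for i, c in enumerate(comps):
            st = tuple(1 if j == i else 0 for j in range(nc))
            rows.append((st, 0.0, c.name))
        for sp in model.species:
            rows.append((sp.stoich, LN10 * sp.log_beta(T), sp.label))
        oh = tuple(-1 if j == ip else 0 for j in range(nc))
        rows.append((oh, -LN10 * model.pKw(T), "OH"))

        self.labels = [r[2] for r in rows]
        self.N = np.array([r[0] for r in rows], dtype=float)
        self.lnK = np.array([r[1] for r in rows], dtype=float)
        self.stoich = {r[2]: r[0] for r in rows}
        self.comp_names = [c.name for c in comps]
        self.ip = ip
        self.pKw = model.pKw(T)

    def solve(
        self,
        totals: SolutionComposition | Mapping[str, float],
        fixed_pH: float | None = None,
        x0: Mapping[str, float] | None = None,
        tol: float = 1e-10,
        max_iter: int = 200,
    ) -> SpeciationState:
        model = self.model
        if isinstance(totals, SolutionComposition):
            tot_map = totals.totals(model)
        else:
            tot_map = dict(totals)
        tot = np.array([float(tot_map.get(n, 0.0)) for n in self.comp_names])
        if not np.all(np.isfinite(tot)):
            raise ModelError("totals must be finite")
        nc = len(self.comp_names)
        ip = self.ip
        for i in range(nc):
            if i != ip and tot[i] < 0:
                raise ModelError(f"negative total for component {self.comp_names[i]}")

        active = np.ones(nc, dtype=bool)
        for i in range(nc):
            if i != ip and tot[i] <= 0.0:
                active[i] = False
        live = ~np.any((self.N != 0) & ~active[None, :], axis=1)
        N = self.N[live]
        lnK = self.lnK[live].copy()
        live_labels = [lab for lab, keep in zip(self.labels, live) if keep]

        unknown = [i for i in range(nc) if active[i] and not (fixed_pH is not None and i == ip)]
        if fixed_pH is not None:
            lnK = lnK + N[:, ip] * (-LN10 * fixed_pH)
        Nu = N[:, unknown]
        NuT = Nu.T
        absNuT = np.abs(NuT)
        tu = tot[unknown]

        def concentrations(xu: np.ndarray) -> np.ndarray:
            return np.exp(np.minimum(lnK + Nu @ xu, 700.0))

        def residual_scale(c: np.ndarray):
            r = NuT @ c - tu
            scale = np.maximum(np.maximum(np.abs(tu), absNuT @ c), 1e-15)
            return r, scale

        if not unknown:
            c = concentrations(np.zeros(0))
            return self._state(fixed_pH, c, live_labels, tot_map, 0.0, 0, unknown, np.zeros(0))

        starts = []
        if x0 is not None:
            starts.append(np.array([
                math.log(max(float(x0[self.comp_names[i]]), 1e-300)) for i in unknown
            ]))
        g = np.empty(len(unknown))
        for k, i in enumerate(unknown):
            if i == ip:
                g[k] = math.log(tot[i]) if tot[i] > 0 else -0.5 * LN10 * self.pKw
            else:
                g[k] = math.log(tot[i])
        starts.append(g)
        if ip in unknown:
            k = unknown.index(ip)
            for h_guess in (1e-2, 1e-5, 1e-9, 1e-11):
                alt = g.copy()
                alt[k] = math.log(h_guess)
                starts.append(alt)

        best_rel = math.inf
        best: tuple | None = None
        for xu0 in starts:
            xu = xu0.copy()
            n_it = 0
            for n_it in range(1, max_iter + 1):
                c = concentrations(xu)
                r, scale = residual_scale(c)
                rel = float(np.max(np.abs(r) / scale))
                if rel <= 1e-13:
                    break
                J = NuT @ (c[:, None] * Nu)
                try:
                    d = np.linalg.solve(J, -r)
                except np.linalg.LinAlgError:
                    d = np.linalg.solve(J + 1e-12 * np.trace(J) * np.eye(len(unknown)), -r)
                np.clip(d, -4.6, 4.6, out=d)
                f0 = float(np.sum((r / scale) ** 2))
                t = 1.0
                accepted = False
                for _ in range(50):
                    ct = concentrations(xu + t * d)
                    rt = NuT @ ct - tu
                    if float(np.sum((rt / scale) ** 2)) < f0:
                        accepted = True
                        break
                    t *= 0.5
                if not accepted:
                    break
                xu = xu + t * d
                if float(np.max(np.abs(t * d))) < 1e-12:
                    c = concentrations(xu)
                    r, scale = residual_scale(c)
                    rel = float(np.max(np.abs(r) / scale))
                    break
            c = concentrations(xu)
            r, scale = residual_scale(c)
            rel = float(np.max(np.abs(r) / scale))
            if rel < best_rel:
                best_rel = rel
                best = (c, n_it, xu)
            if rel <= tol:
                break

        assert best is not None
        c, n_it, xu = best
        if best_rel > tol:
            raise ConvergenceError(
                f"speciation did not converge (relative residual {best_rel:.3e})",
                residual=best_rel,
            )
        return self._state(fixed_pH, c, live_labels, tot_map, best_rel, n_it, unknown, xu)

    def _state(self, fixed_pH, c, live_labels, tot_map, rel, n_it, unknown, xu):
        conc = {lab: 0.0 for lab in self.labels}
        for lab, v in zip(live_labels, c):
            conc[lab] = float(v)
        free = {}
        for i, name in enumerate(self.comp_names):
            if fixed_pH is not None and i == self.ip:
                free[name] = 10.0 ** (-fixed_pH)
            else:
                free[name] = conc.get(name, 0.0)
        return SpeciationState(
            model=self.model, T=self.T, fixed_pH=fixed_pH, free=free,
            species_conc=conc, stoich=dict(self.stoich),
            totals={n: float(tot_map.get(n, 0.0)) for n in self.comp_names},
            residual=rel, iterations=n_it,
        )


def solve_free_concentrations(
    model: EquilibriumModel,
    totals: SolutionComposition | Mapping[str, float],
    T: float,
    fixed_pH: float | None = None,
    x0: Mapping[str, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> SpeciationState:
    """Solve the mass-balance system at fixed totals (or fixed pH).

    With ``fixed_pH`` the proton activity is clamped to 10**-pH and the
    proton total is ignored; all other components keep their mass balances.
    """
    return CompiledSystem(model, T).solve(totals, fixed_pH=fixed_pH, x0=x0,
                                          tol=tol, max_iter=max_iter)


def species_fractions(state: SpeciationState, component: str) -> dict[str, float]:
    """Mole fractions of one component over all species that contain it.

    The free reference form counts as a species; fractions sum to 1.
    """
    if component not in state.free:
        raise ModelError(f"unknown component {component!r}")
    entries = [
        (lab, state.stoich[lab][state.model.component_index(component)], conc)
        for lab, conc in state.species_conc.items()
    ]
    entries = [(lab, nu, conc) for lab, nu, conc in entries if nu > 0]
    den = sum(nu * conc for _, nu, conc in entries)
    if not entries or den <= 0.0:
        raise ModelError(f"component {component!r} occurs in no species at this point")
    return {lab: nu * conc / den for lab, nu, conc in entries}


def distribution_diagram(
    model: EquilibriumModel,
    base_composition: SolutionComposition,
    pH_grid: Sequence[float],
    T: float,
    component: str | None = None,
) -> pd.DataFrame:
    """Species mole fractions of one component over a pH grid.

    Returns a DataFrame indexed by pH with one column per species of the
    chosen component (default: metal if present in solution, else ligand,
    else proton).  Writable directly as CSV.
    """
    pH = np.asarray(pH_grid, dtype=float)
    if pH.ndim != 1 or pH.size == 0 or (pH.size > 1 and not np.all(np.diff(pH) > 0)):
        raise ModelError("pH grid must be non-empty and strictly increasing")
    if component is None:
        metal = model.component("metal")
        ligand = model.component("ligand")
        if metal is not None and base_composition.C_M > 0:
            component = metal.name
        elif ligand is not None and base_composition.C_L > 0:
            component = ligand.name
        else:
            component = model.proton.name

    system = CompiledSystem(model, T)
    rows = []
    prev_free: dict[str, float] | None = None
    for ph in pH:
        try:
            state = system.solve(base_composition, fixed_pH=float(ph), x0=prev_free)
        except ConvergenceError as err:
            raise ConvergenceError(f"speciation failed at pH {ph:.3f}: {err}",
                                   residual=err.residual) from err
        prev_free = state.free
        rows.append(species_fractions(state, component))
    df = pd.DataFrame(rows, index=pd.Index(pH, name="pH")).fillna(0.0)
    return df


def stepwise_constants(model: EquilibriumModel, T: float) -> list[float]:
    """Stepwise protonation constants log K_i for H + H_(i-1)L = H_iL.

    log K_i is the difference of consecutive overall constants; the full
    ladder H_1L .. H_nL must be present at T (a gap is an error).
    """
    ligand = model.component("ligand")
    if ligand is None:
        raise ModelError("model has no ligand component")
    il = model.component_index(ligand.name)
    ip = model.proton_index
    ladder: dict[int, float] = {}
    for sp in model.species:
        if sp.stoich[il] == 1 and sp.stoich[ip] > 0 and all(
            sp.stoich[j] == 0 for j in range(len(sp.stoich)) if j not in (il, ip)
        ):
            ladder[sp.stoich[ip]] = sp.log_beta(T)
    if not ladder:
        raise ModelError("no ligand protonation species in the model")
    n = max(ladder)
    missing = [i for i in range(1, n + 1) if i not in ladder]
    if missing:
        raise ModelError(f"protonation ladder has gaps at i = {missing}")
    out = []
    prev = 0.0
    for i in range(1, n + 1):
        out.append(ladder[i] - prev)
        prev = ladder[i]
    return out


def partial_constant(model: EquilibriumModel, complex_stoich: Sequence[int], T: float) -> float:
    """log K for M + LH_i = MLH_i: the metal-binding step isolated from
    ligand protonation, log K_11i = log beta_11i - log beta_01i."""
    sp = model.species_by_stoich(complex_stoich)
    ip = model.proton_index
    base = list(sp.stoich)
    for i, c in enumerate(model.components):
        if c.role == "metal":
            base[i] = 0
    if base[ip] == 0:
        # counterpart is the fully deprotonated free ligand, log beta = 0
        return sp.log_beta(T)
    try:
        counterpart = model.species_by_stoich(tuple(base))
    except ModelError:
        raise ModelError(
            f"missing ligand counterpart {tuple(base)} for complex {sp.label}"
        ) from None
    return sp.log_beta(T) - counterpart.log_beta(T)
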