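"""Stability-constant refinement from titration data.

Estimates overall formation constants — and, optionally, nuisance parameters
(formal electrode potential E0, pKw, analytical concentrations, junction
coefficients) — by weighted nonlinear least squares on emf curves, and
stability constants plus molar absorbances from multiwavelength spectra by
variable projection.  The optimizer is Gauss-Newton with Levenberg damping
and central-difference Jacobians; accepted steps never increase the
objective.  Standard deviations come from the inverse normal matrix scaled
by the weighted RMS residual.

Potentiometric weights propagate the instrument precisions,
w_i = 1 / (sigma_E^2 + (dE/dv)_i^2 sigma_v^2), so points on the steep
equivalence region (where a volume error moves the emf a lot) count less.

Model selection ranks candidate speciation models by the weighted fit
standard deviation, flags species whose maximum formation percentage is
negligible, and breaks near-ties in favour of the simpler model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CompiledSystem,
    ConvergenceError,
    EquilibriumModel,
    ModelError,
    SolutionComposition,
)
from .synthetic import ElectrodeParams, TitrationDataset

LN10 = math.log(10.0)

_SHARED = ("pKw", "ja", "jb")
_PER_DATASET = ("E0", "C_L", "C_HCl", "C_M")


class IdentifiabilityError(RuntimeError):
    """A parameter cannot be determined from the data (singular normal matrix)."""

    def __init__(self, parameter: str, message: str | None = None):
        super().__init__(message or f"parameter {parameter!r} is not identifiable from the data")
        self.parameter = parameter


@dataclass
class RefinementSpec:
    """What to refine: a model holding initial guesses plus free-parameter names.

    Free-parameter grammar: ``logB:<species label>`` for a formation
    constant; ``pKw``, ``ja``, ``jb`` (shared across datasets); ``E0``,
    ``C_L``, ``C_HCl``, ``C_M`` (one parameter per dataset).  Everything not
    listed stays frozen at its input value.
    """

    model: EquilibriumModel
    free: list[str]
    weighting: str = "propagated"   # or "unit"
    name: str = ""
    absorbing: list[str] | None = None
    max_iter: int = 100

    def __post_init__(self):
        if not self.free:
            raise ModelError("at least one free parameter is required")
        labels = {sp.label for sp in self.model.species}
        for p in self.free:
            if p.startswith("logB:"):
                if p[5:] not in labels:
                    raise ModelError(f"free parameter {p!r} names an unknown species")
            elif p not in _SHARED + _PER_DATASET:
                raise ModelError(f"unknown free parameter {p!r}")
        if self.weighting not in ("propagated", "unit"):
            raise ModelError("weighting must be 'propagated' or 'unit'")


@dataclass
class RefinementResult:
    estimates: dict[str, float]
    sd: dict[str, float]
    sigma_fit: float
    iterations: int
    converged: bool
    residuals: np.ndarray
    message: str = ""
    negligible: list[str] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Core damped Gauss-Newton engine
# ---------------------------------------------------------------------------


def _covariance(A: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Inverse of the (symmetric) normal matrix via eigendecomposition;
    a numerically singular direction names the offending parameter."""
    evals, evecs = np.linalg.eigh(A)
    if evals[-1] <= 0.0 or evals[0] <= evals[-1] * 1e-14:
        bad = names[int(np.argmax(np.abs(evecs[:, 0])))]
        raise IdentifiabilityError(bad)
    return (evecs / evals) @ evecs.T


def _gauss_newton(
    fun: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    weights: np.ndarray,
    steps: np.ndarray,
    names: Sequence[str],
    max_iter: int = 100,
):
    theta = theta0.astype(float).copy()
    w = weights
    r = fun(theta)
    obj = float(np.sum(w * r * r))
    trace = [obj]
    lam = 1e-3
    converged = False
    message = ""
    n_iter = 0
    J = None

    for n_iter in range(1, max_iter + 1):
        J = np.empty((r.size, theta.size))
        for k in range(theta.size):
            tp = theta.copy(); tp[k] += steps[k]
            tm = theta.copy(); tm[k] -= steps[k]
            J[:, k] = (fun(tp) - fun(tm)) / (2.0 * steps[k])
        col = np.sqrt(np.sum(w[:, None] * J * J, axis=0)) * steps
        if np.any(col == 0.0):
            bad = names[int(np.argmin(col))]
            raise IdentifiabilityError(bad, f"normal matrix singular: {bad!r} has no "
                                            "effect on the calculated data")
        A = J.T @ (w[:, None] * J)
        g = J.T @ (w * r)
        accepted = False
        for _ in range(40):
            damp = lam * np.diag(np.maximum(np.diag(A), 1e-30))
            try:
                d = np.linalg.solve(A + damp, -g)
            except np.linalg.LinAlgError:
                lam *= 8.0
                continue
            rt = fun(theta + d)
            objt = float(np.sum(w * rt * rt))
            if objt <= obj * (1.0 + 1e-14):
                accepted = True
                break
            lam *= 8.0
        if not accepted:
            # at numerically-exact fits no step can improve the objective
            if math.sqrt(obj / max(r.size - theta.size, 1)) < 1e-5:
                converged = True
            else:
                message = "no admissible damped step found"
            break
        rel_drop = (obj - objt) / max(obj, 1e-300)
        theta = theta + d
        r = rt
        obj = objt
        trace.append(obj)
        lam = max(lam / 8.0, 1e-12)
        step_norm = float(np.max(np.abs(d)))
        if step_norm < 1e-8 or (rel_drop < 1e-10 and step_norm < 1e-6) \
                or (math.sqrt(obj / max(r.size - theta.size, 1)) < 1e-5 and step_norm < 1e-6):
            converged = True
            break
    else:
        message = "maximum iterations reached"

    if not converged and not message:
        message = "stalled before meeting the convergence criteria"

    n, p = r.size, theta.size
    dof = max(n - p, 1)
    sigma_fit = math.sqrt(obj / dof)
    # recompute the Jacobian at the accepted optimum for honest uncertainties
    J = np.empty((r.size, theta.size))
    for k in range(theta.size):
        tp = theta.copy(); tp[k] += steps[k]
        tm = theta.copy(); tm[k] -= steps[k]
        J[:, k] = (fun(tp) - fun(tm)) / (2.0 * steps[k])
    A = J.T @ (weights[:, None] * J)
    cov = _covariance(A, names)
    sd = sigma_fit * np.sqrt(np.maximum(np.diag(cov), 0.0))
    return theta, sd, sigma_fit, n_iter, converged, r, trace, message


# ---------------------------------------------------------------------------
# Potentiometric refinement
# ---------------------------------------------------------------------------


def _expand_parameters(spec: RefinementSpec, datasets: list[TitrationDataset], T: float):
    """Flatten the free-parameter grammar into named scalars with initial
    values and finite-difference steps."""
    names: list[str] = []
    init: list[float] = []
    steps: list[float] = []
    single = len(datasets) == 1

    def add(name, value, step):
        names.append(name); init.append(value); steps.append(step)

    for p in spec.free:
        if p.startswith("logB:"):
            add(p, spec.model.log_beta(p[5:], T), 1e-4)
        elif p == "pKw":
            add(p, spec.model.pKw(T), 1e-4)
        elif p in ("ja", "jb"):
            el = datasets[0].electrode or ElectrodeParams()
            add(p, getattr(el, p), 1e-3)
        else:
            for i, ds in enumerate(datasets):
                label = p if single else f"{p}[{i}]"
                if p == "E0":
                    el = ds.electrode or ElectrodeParams()
                    add(label, el.E0, 1e-3)
                else:
                    attr = {"C_L": "C_L", "C_HCl": "C_HCl", "C_M": "C_M"}[p]
                    value = getattr(ds.protocol.initial, attr)
                    add(label, value, max(1e-4 * abs(value), 1e-9))
    return names, np.array(init), np.array(steps)


def _weights_for(ds: TitrationDataset, scheme: str) -> np.ndarray:
    if scheme == "unit" or ds.electrode is None:
        return np.ones_like(ds.emf)
    el = ds.electrode
    order = np.argsort(ds.volumes)
    dEdv = np.empty_like(ds.emf)
    if ds.volumes.size > 1:
        dEdv[order] = np.gradient(ds.emf[order], ds.volumes[order])
    else:
        dEdv[:] = 0.0
    var = el.sigma_E ** 2 + (dEdv ** 2) * el.sigma_v ** 2
    return 1.0 / np.maximum(var, 1e-12)


def _with_pkw(model: EquilibriumModel, T: float, pkw: float) -> EquilibriumModel:
    new = model.with_log_beta({}, T)
    new.pKw_by_T[float(T)] = float(pkw)
    return new


def refine_potentiometric(
    datasets: TitrationDataset | list[TitrationDataset],
    spec: RefinementSpec,
) -> RefinementResult:
    """Refine constants (and nuisance parameters) from emf titration curves.

    Supports joint refinement over several titrations at one temperature:
    thermodynamic parameters are shared, E0 and analytical concentrations
    are per dataset.
    """
    if isinstance(datasets, TitrationDataset):
        datasets = [datasets]
    if not datasets:
        raise ModelError("at least one dataset is required")
    for ds in datasets:
        if ds.emf is None:
            raise ModelError("potentiometric refinement needs emf data")
    T = datasets[0].protocol.T
    if any(ds.protocol.T != T for ds in datasets):
        raise ModelError("joint refinement requires a single temperature")

    names, theta0, steps = _expand_parameters(spec, datasets, T)
    single = len(datasets) == 1
    w = np.concatenate([_weights_for(ds, spec.weighting) for ds in datasets])
    e_obs = np.concatenate([ds.emf for ds in datasets])

    def lookup(theta, base, i):
        label = base if single else f"{base}[{i}]"
        if label in names:
            return theta[names.index(label)]
        return None

    # warm-start cache: free concentrations per point from the previous
    # residual evaluation (theta moves little between evaluations)
    cache: list[list[dict | None]] = [[None] * ds.volumes.size for ds in datasets]

    def residual(theta: np.ndarray) -> np.ndarray:
        beta_updates = {names[k][5:]: theta[k] for k in range(len(names))
                        if names[k].startswith("logB:")}
        model = spec.model.with_log_beta(beta_updates, T)
        if "pKw" in names:
            model = _with_pkw(model, T, theta[names.index("pKw")])
        kw = 10.0 ** (-model.pKw(T))
        out = []
        for i, ds in enumerate(datasets):
            el = ds.electrode or ElectrodeParams()
            e0 = lookup(theta, "E0", i)
            el_eff = replace(el,
                             E0=float(e0) if e0 is not None else el.E0,
                             ja=float(theta[names.index("ja")]) if "ja" in names else el.ja,
                             jb=float(theta[names.index("jb")]) if "jb" in names else el.jb)
            comp = ds.protocol.initial
            for base, attr in (("C_L", "C_L"), ("C_HCl", "C_HCl"), ("C_M", "C_M")):
                v = lookup(theta, base, i)
                if v is not None:
                    comp = replace(comp, **{attr: float(max(v, 0.0))})
            system = CompiledSystem(model, T)
            prev = None
            proton = model.proton.name
            e_calc = np.empty_like(ds.emf)
            try:
                for j, v_add in enumerate(ds.volumes):
                    totals = ds.protocol.totals_at(model, float(v_add), composition=comp)
                    state = system.solve(totals, x0=cache[i][j] or prev)
                    prev = cache[i][j] = state.free
                    h = state.free[proton]
                    e_calc[j] = el_eff.emf(h, kw / h, T)
            except (ConvergenceError, ModelError):
                return np.full(e_obs.shape, 1e6)
            out.append(ds.emf - e_calc)
        return np.concatenate(out)

    theta, sd, sigma_fit, n_iter, conv, r, trace, msg = _gauss_newton(
        residual, theta0, w, steps, names, max_iter=spec.max_iter)
    return RefinementResult(
        estimates=dict(zip(names, theta.tolist())),
        sd=dict(zip(names, sd.tolist())),
        sigma_fit=sigma_fit, iterations=n_iter, converged=conv,
        residuals=r, message=msg, objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Spectrophotometric refinement (variable projection)
# ---------------------------------------------------------------------------


def refine_spectrophotometric(
    dataset: TitrationDataset,
    spec: RefinementSpec,
    known_epsilon: dict | None = None,
    negligible_threshold: float = 0.01,
) -> tuple[RefinementResult, pd.DataFrame]:
    """Refine formation constants from an absorbance matrix.

    For each trial set of constants the species concentrations follow from
    mass balance and the molar absorbances from a linear least-squares solve
    per wavelength (variable projection); the nonlinear search runs over the
    constants only.  Ligand protonation constants stay fixed unless listed
    free.  ``known_epsilon`` supplies molar-absorptivity profiles established
    independently (typically the ligand species from a ligand-only
    titration); their contribution is subtracted and only the remaining
    species' absorbances are estimated, which conditions the fit the same
    way the two-stage experimental workflow does.  Returns the result plus
    the fitted epsilon matrix (species x wavelength).  Species whose maximum
    formation fraction stays below ``negligible_threshold`` are flagged in
    ``result.negligible``.
    """
    if dataset.absorbance is None:
        raise ModelError("spectrophotometric refinement needs an absorbance matrix")
    for p in spec.free:
        if not p.startswith("logB:"):
            raise ModelError("spectral refinement refines formation constants only")
    T = dataset.protocol.T
    model0 = spec.model
    ligand = model0.component("ligand")
    if spec.absorbing is not None:
        absorbing = list(spec.absorbing)
    else:
        il = model0.component_index(ligand.name) if ligand else None
        absorbing = ([ligand.name] if ligand else []) + [
            sp.label for sp in model0.species if il is not None and sp.stoich[il] > 0
        ]
    known_epsilon = dict(known_epsilon or {})
    for lab in known_epsilon:
        if lab not in absorbing:
            raise ModelError(f"known epsilon given for non-absorbing species {lab!r}")
    fitted_abs = [lab for lab in absorbing if lab not in known_epsilon]
    A_obs = dataset.absorbance.to_numpy(dtype=float)
    n_pts, n_lam = A_obs.shape
    if n_pts < len(fitted_abs) or n_lam < len(fitted_abs):
        raise ModelError(
            f"{len(fitted_abs)} absorbing species cannot be resolved from "
            f"{n_pts} points x {n_lam} wavelengths"
        )
    names = list(spec.free)
    theta0 = np.array([model0.log_beta(p[5:], T) for p in names])
    steps = np.full(theta0.shape, 1e-4)
    sigma_A = dataset.spectral.sigma_A if dataset.spectral else 0.0
    w_scalar = 1.0 / max(sigma_A, 1e-3) ** 2
    w = np.full(A_obs.size, w_scalar)

    cache: list[dict | None] = [None] * n_pts

    def conc_matrix(theta: np.ndarray) -> np.ndarray:
        model = model0.with_log_beta({n[5:]: t for n, t in zip(names, theta)}, T)
        system = CompiledSystem(model, T)
        prev = None
        C = np.empty((n_pts, len(absorbing)))
        for j, v_add in enumerate(dataset.volumes):
            totals = dataset.protocol.totals_at(model, float(v_add))
            state = system.solve(totals, x0=cache[j] or prev)
            prev = cache[j] = state.free
            C[j] = [state.species_conc[lab] for lab in absorbing]
        return C

    path = dataset.spectral.path if dataset.spectral else 1.0
    i_known = [absorbing.index(lab) for lab in known_epsilon]
    i_fit = [absorbing.index(lab) for lab in fitted_abs]
    E_known = (np.array([np.asarray(known_epsilon[lab], float) for lab in known_epsilon])
               if known_epsilon else np.zeros((0, n_lam)))

    def project(C):
        """Fitted-species epsilon by linear least squares, given concentrations."""
        A_red = A_obs - path * C[:, i_known] @ E_known
        if i_fit:
            eps_fit, *_ = np.linalg.lstsq(path * C[:, i_fit], A_red, rcond=None)
        else:
            eps_fit = np.zeros((0, n_lam))
        resid = A_red - path * C[:, i_fit] @ eps_fit
        return eps_fit, resid

    def residual(theta: np.ndarray) -> np.ndarray:
        try:
            C = conc_matrix(theta)
        except (ConvergenceError, ModelError):
            return np.full(A_obs.size, 1e6)
        return project(C)[1].ravel()

    theta, sd, sigma_fit, n_iter, conv, r, trace, msg = _gauss_newton(
        residual, theta0, w, steps, names, max_iter=spec.max_iter)

    C = conc_matrix(theta)
    eps_fit, _ = project(C)
    if np.any(eps_fit < -1e-6):
        warnings.warn("fitted molar absorbances contain negative values", stacklevel=2)
    lam = (dataset.spectral.wavelengths if dataset.spectral
           else dataset.absorbance.columns.to_numpy(float))
    eps = np.empty((len(absorbing), n_lam))
    for row, lab in enumerate(known_epsilon):
        eps[absorbing.index(lab)] = E_known[row]
    for row, j in enumerate(i_fit):
        eps[j] = eps_fit[row]
    eps_frame = pd.DataFrame(eps, index=absorbing, columns=lam)

    # flag species that never form appreciably (over-parameterized models)
    model = model0.with_log_beta({n[5:]: t for n, t in zip(names, theta)}, T)
    negligible = _negligible_species(model, [dataset], T, negligible_threshold)
    result = RefinementResult(
        estimates=dict(zip(names, theta.tolist())),
        sd=dict(zip(names, sd.tolist())),
        sigma_fit=sigma_fit, iterations=n_iter, converged=conv,
        residuals=r, message=msg, negligible=negligible, objective_trace=trace,
    )
    return result, eps_frame


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def _negligible_species(model: EquilibriumModel, datasets: list[TitrationDataset],
                        T: float, threshold: float) -> list[str]:
    """Species whose maximum formation never exceeds ``threshold`` of the
    reference component total (metal if present, else ligand)."""
    metal = model.component("metal")
    ref = metal or model.component("ligand")
    if ref is None:
        return []
    iref = model.component_index(ref.name)
    peak = {sp.label: 0.0 for sp in model.species if sp.stoich[iref] > 0}
    if not peak:
        return []
    for ds in datasets:
        system = CompiledSystem(model, T)
        prev = None
        for v_add in ds.volumes:
            totals = ds.protocol.totals_at(model, float(v_add))
            total_ref = totals.get(ref.name, 0.0)
            if total_ref <= 0:
                continue
            try:
                state = system.solve(totals, x0=prev)
            except ConvergenceError:
                continue
            prev = state.free
            for lab in peak:
                nu = state.stoich[lab][iref]
                peak[lab] = max(peak[lab], nu * state.species_conc[lab] / total_ref)
    return [lab for lab, frac in peak.items() if frac < threshold]


def select_model(
    candidates: list[RefinementSpec],
    datasets: TitrationDataset | list[TitrationDataset],
    negligible_threshold: float = 0.01,
    tie_tol: float = 0.01,
) -> pd.DataFrame:
    """Rank candidate speciation models against shared titration data.

    Converged candidates are ordered by sigma_fit; candidates whose fit
    standard deviations agree within ``tie_tol`` (relative) are treated as
    ties and ordered by species count ("simplicity").  Candidates that fail
    to converge are excluded with the reason recorded.
    """
    if isinstance(datasets, TitrationDataset):
        datasets = [datasets]
    if len(candidates) < 2:
        raise ModelError("model selection needs >= 2 candidate specifications")
    rows = []
    for idx, spec in enumerate(candidates):
        name = spec.name or f"candidate-{idx}"
        try:
            res = refine_potentiometric(datasets, spec)
        except (IdentifiabilityError, ConvergenceError, ModelError) as err:
            rows.append({"name": name, "sigma_fit": np.nan,
                         "n_species": len(spec.model.species), "converged": False,
                         "negligible": "", "reason": str(err)})
            continue
        T = datasets[0].protocol.T
        beta_updates = {k[5:]: v for k, v in res.estimates.items() if k.startswith("logB:")}
        fitted = spec.model.with_log_beta(beta_updates, T)
        negligible = _negligible_species(fitted, datasets, T, negligible_threshold)
        rows.append({"name": name, "sigma_fit": res.sigma_fit,
                     "n_species": len(spec.model.species), "converged": res.converged,
                     "negligible": ",".join(negligible),
                     "reason": "" if res.converged else res.message})
    report = pd.DataFrame(rows)

    ok = report[report["converged"]].sort_values("sigma_fit").copy()
    ranked_order: list[int] = []
    remaining = list(ok.index)
    while remaining:
        group_min = ok.loc[remaining[0], "sigma_fit"]
        group = [i for i in remaining if ok.loc[i, "sigma_fit"] <= group_min * (1 + tie_tol)]
        group.sort(key=lambda i: (ok.loc[i, "n_species"], ok.loc[i, "sigma_fit"]))
        ranked_order.extend(group)
        remaining = [i for i in remaining if i not in group]
    report["rank"] = np.nan
    for pos, i in enumerate(ranked_order, start=1):
        report.loc[i, "rank"] = pos
    return report.sort_values(["rank"], na_position="last").reset_index(drop=True)[
        ["rank", "name", "sigma_fit", "n_species", "negligible", "converged", "reason"]
    ]
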