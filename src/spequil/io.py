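"""Configuration loading, packaged constant sets, readers/writers, pipeline.

Models and results travel as TOML (human-diffable, language-neutral), tabular
data as CSV.  The packaged database ships the H+-DMSA protonation constants
and the As(III)-DMSA formation constants (0.15 mol/L NaCl, four
temperatures) ready to load by name.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from . import core, refine, sequestration, synthetic, thermo
from .core import EquilibriumModel, ModelError, SolutionComposition

log = logging.getLogger("spequil")

_PACKAGED = {
    "dmsa-protonation": "dmsa_protonation.toml",
    "as3-dmsa": "as3_dmsa.toml",
}


def available_models() -> list[str]:
    """Names of the packaged constant sets."""
    return sorted(_PACKAGED)


def load_packaged_model(name: str) -> EquilibriumModel:
    try:
        fname = _PACKAGED[name]
    except KeyError:
        raise ModelError(f"no packaged constants entry {name!r}; "
                         f"available: {available_models()}") from None
    text = resources.files("spequil.data").joinpath(fname).read_text()
    model = core.build_model(tomllib.loads(text))
    if not model.provenance:
        raise ModelError(f"packaged entry {name!r} lacks provenance")
    return model


def load_model(path: str | Path) -> EquilibriumModel:
    """Read a model config from a TOML file (or a packaged name)."""
    p = Path(path)
    if not p.exists() and str(path) in _PACKAGED:
        return load_packaged_model(str(path))
    with open(p, "rb") as fh:
        cfg = tomllib.load(fh)
    units = str(cfg.get("units", "mol/L"))
    if units not in ("mol/L", "mmol/L"):
        raise ModelError("units must be 'mol/L' or 'mmol/L'")
    return core.build_model(cfg)


# ---------------------------------------------------------------------------
# Minimal TOML writer (stdlib has a reader only)
# ---------------------------------------------------------------------------


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    if isinstance(v, Mapping):
        return "{ " + ", ".join(f"{json.dumps(str(k))} = {_toml_scalar(x)}"
                                for k, x in v.items() if x is not None) + " }"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _toml_table(d: Mapping, lines: list[str]):
    for k, v in d.items():
        if v is None:
            continue  # TOML has no null; omit the key
        key = k if k.replace("_", "").replace("-", "").isalnum() and not k[0].isdigit() \
            else json.dumps(str(k))
        lines.append(f"{key} = {_toml_scalar(v)}")


def dumps_toml(doc: Mapping) -> str:
    """Serialize a restricted document: scalars, inline maps/lists, one level
    of sub-tables, and lists of tables."""
    lines: list[str] = []
    scalars = {k: v for k, v in doc.items()
               if not isinstance(v, Mapping) and not
               (isinstance(v, list) and v and isinstance(v[0], Mapping))}
    _toml_table(scalars, lines)
    for k, v in doc.items():
        if isinstance(v, Mapping):
            lines.append(f"\n[{k}]")
            _toml_table(v, lines)
        elif isinstance(v, list) and v and isinstance(v[0], Mapping):
            for entry in v:
                lines.append(f"\n[[{k}]]")
                _toml_table(entry, lines)
    return "\n".join(lines) + "\n"


def _tkey(t: float) -> str:
    return f"{t:g}"


def dumps_model(model: EquilibriumModel) -> str:
    """Serialize a model to TOML; round-trips through ``load_model`` exactly."""
    comps = {c.role: c.name for c in model.components}
    doc = {
        "name": model.name,
        "provenance": model.provenance,
        "components": comps,
        "medium": {"ionic_strength": model.medium.ionic_strength,
                   "electrolyte": model.medium.electrolyte},
        "pKw": {_tkey(t): v for t, v in sorted(model.pKw_by_T.items())},
        "species": [],
    }
    slot_roles = ("metal", "ligand", "proton")
    present = [r for r in slot_roles if r in comps]
    for sp in model.species:
        by_name = dict(zip([comps[r] for r in present], sp.stoich))
        stoich3 = [by_name.get(comps.get(r, ""), 0) for r in slot_roles]
        entry = {
            "label": sp.label,
            "stoich": stoich3,
            "logbeta": {_tkey(t): v for t, v in sorted(sp.log_beta_by_T.items())},
        }
        if sp.sd_by_T:
            entry["sd"] = {_tkey(t): v for t, v in sorted(sp.sd_by_T.items())}
        doc["species"].append(entry)
    return dumps_toml(doc)


def save_model(model: EquilibriumModel, path: str | Path):
    Path(path).write_text(dumps_model(model))


def write_titration_csv(dataset: synthetic.TitrationDataset, path: str | Path,
                        truth_path: str | Path | None = None):
    """Dataset as CSV (potentiometric: v_mL, emf_mV; spectral: long format)
    with an optional TOML truth sidecar for tests."""
    dataset.to_frame().to_csv(path, index=False)
    if truth_path is not None:
        truth = dict(dataset.truth)
        truth.pop("pH", None)
        Path(truth_path).write_text(dumps_toml(truth))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _composition_from(cfg: Mapping) -> SolutionComposition:
    scale = 1e-3 if str(cfg.get("units", "mol/L")) == "mmol/L" else 1.0
    return SolutionComposition(
        C_M=scale * float(cfg.get("C_M", 0.0)),
        C_L=scale * float(cfg.get("C_L", 0.0)),
        C_HCl=scale * float(cfg.get("C_HCl", 0.0)),
        C_NaOH_added=scale * float(cfg.get("C_NaOH_added", 0.0)),
        C_NaCl=float(cfg.get("C_NaCl", 0.15)),
    )


_STAGES = ("speciate", "diagram", "thermo", "pl05", "simulate", "refine")


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages in order, writing CSV/TOML outputs and a log.

    The config declares ``[pipeline]`` (constants entry or model path, stage
    list, seed, out_dir) plus one optional table per stage.  Returns a report
    dict with per-stage summaries; deterministic given config + seed.
    """
    if not isinstance(config, Mapping):
        with open(config, "rb") as fh:
            config = tomllib.load(fh)
    pcfg = config.get("pipeline", {})
    stages = list(pcfg.get("stages", []))
    for st in stages:
        if st not in _STAGES:
            raise ModelError(f"unknown stage {st!r}; known stages: {_STAGES}")
    model_ref = pcfg.get("constants")
    if model_ref is None:
        raise ModelError("pipeline config must name a constants entry or model file")
    model = load_model(model_ref)
    seed = int(pcfg.get("seed", 0))
    out = Path(out_dir or pcfg.get("out_dir", "."))
    report: dict = {"stages": {}, "seed": seed, "model": model.name}
    if not stages:
        return report
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"spequil pipeline | model={model.name} seed={seed}"]

    refine_input = None
    for stage in stages:
        t0 = time.perf_counter()
        cfg = config.get(stage, {})
        T = float(cfg.get("temp", 298.15))
        if stage == "speciate":
            comp = _composition_from(cfg)
            ph = cfg.get("ph")
            state = core.solve_free_concentrations(
                model, comp, T, fixed_pH=float(ph) if ph is not None else None)
            comp_name = cfg.get("component") or (
                model.component("metal").name if model.component("metal") and comp.C_M > 0
                else model.component("ligand").name if model.component("ligand") else
                model.proton.name)
            fr = core.species_fractions(state, comp_name)
            Path(out / "speciation.json").write_text(json.dumps(
                {"pH": state.pH, "T": T, "fractions": fr, "residual": state.residual},
                indent=2))
            summary = {"pH": state.pH, "n_species": len(fr)}
        elif stage == "diagram":
            comp = _composition_from(cfg)
            grid = np.arange(float(cfg.get("ph_min", 2.0)),
                             float(cfg.get("ph_max", 10.5)) + 1e-9,
                             float(cfg.get("ph_step", 0.1)))
            df = core.distribution_diagram(model, comp, grid, T,
                                           component=cfg.get("component"))
            df.to_csv(out / "distribution.csv")
            summary = {"rows": len(df)}
        elif stage == "thermo":
            records = thermo.thermo_table(model, T)
            thermo.thermo_frame(records).to_csv(out / "thermo.csv", index=False)
            summary = {"n_reactions": len(records)}
        elif stage == "pl05":
            grid = np.arange(float(cfg.get("pl_min", 1.0)),
                             float(cfg.get("pl_max", 12.0)) + 1e-9,
                             float(cfg.get("pl_step", 0.25)))
            res = sequestration.sequestration_curve(
                model, None, float(cfg.get("ph", 7.4)), float(cfg.get("temp", 310.15)), grid)
            res.to_frame().to_csv(out / "sequestration.csv", index=False)
            summary = {"pL05": round(res.pL05, 2)}
        elif stage == "simulate":
            comp = _composition_from(cfg if cfg else
                                     {"C_L": 2, "C_HCl": 8, "C_M": 1, "units": "mmol/L"})
            volumes = np.arange(0.0, float(cfg.get("v_max", 5.0)) + 1e-9,
                                float(cfg.get("v_step", 0.1)))
            protocol = synthetic.TitrationProtocol(
                initial=comp, titrant_concentration=float(cfg.get("titrant", 0.1)),
                volumes=volumes, T=T)
            electrode = synthetic.ElectrodeParams(E0=float(cfg.get("E0", 400.0)))
            ds = synthetic.simulate_potentiometric(model, protocol, electrode, seed=seed)
            write_titration_csv(ds, out / "titration.csv", out / "titration_truth.toml")
            refine_input = ds
            summary = {"points": len(ds.volumes)}
        elif stage == "refine":
            if refine_input is None:
                raise ModelError("refine stage requires a preceding simulate stage")
            free = list(cfg.get("free", [])) or [
                f"logB:{sp.label}" for sp in model.species
                if any(sp.stoich[i] > 0 for i, c in enumerate(model.components)
                       if c.role == "metal")
            ] or [f"logB:{sp.label}" for sp in model.species]
            spec = refine.RefinementSpec(model=model, free=free)
            res = refine.refine_potentiometric(refine_input, spec)
            doc = {"converged": res.converged, "sigma_fit": res.sigma_fit,
                   "iterations": res.iterations,
                   "estimates": res.estimates,
                   "sd": res.sd,
                   "truth": refine_input.truth["log_beta"]}
            (out / "refinement.toml").write_text(dumps_toml(doc))
            summary = {"converged": res.converged, "sigma_fit": res.sigma_fit}
        dt = time.perf_counter() - t0
        report["stages"][stage] = summary
        line = f"stage={stage} runtime={dt:.2f}s {summary}"
        log.info(line)
        log_lines.append(line)

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report
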