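"""Orchestration: simulate/load → features → gate → report, as one run.

A run is described by a :class:`RunConfig` (YAML-serializable): exactly one
input source (a manifest of real images or a simulation config), feature
parameters, an ordered gate list, the control sample ids used to resolve
marker thresholds, an output directory and a seed.  Outputs are
``features.csv``, ``report.csv``, ``run.log`` and ``resolved_config.yaml``;
replaying the resolved config reproduces the report exactly.

Named recipes package the standard senescence analyses (single-marker
SA-β-gal percentages, SA⁺∧HMGB1⁻ overlap, cell-type-resolved tissue
scenarios, aging size shift) as preset simulation + gate configs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import gating
from .gating import Gate, GatingError, GatingResult
from .imgio import read_dataset, write_feature_table
from .synthcells import SynthConfig, generate_cells

__all__ = ["RunConfig", "RunResult", "run", "recipe", "list_recipes", "build_gates"]

log = logging.getLogger("senescan")

#: packaged scenario presets: name -> (simulation yaml, gates yaml)
_RECIPES = {
    "bj_dis": "Etoposide-senescent vs growing human fibroblasts: % SA-β-gal+, "
    "% γH2AX focus+, cell areas",
    "hmgb1_overlap": "Two-marker senescence call: SA-β-gal+ AND nuclear HMGB1-",
    "tumor_p53": "Dissociated tumors (p53 restoration): viability gate, GFP+ tumor "
    "vs CD45+ immune cells, % SA-β-gal+ per type",
    "bleomycin_lung": "Dissociated fibrotic lung: pCK+ epithelial vs CD45+ immune "
    "cells, % SA-β-gal+ per type",
    "lung_proliferation": "Proliferation-marker overlap in lung: Ki67-/BrdU- within "
    "SA-β-gal+ and SA-β-gal- cells",
    "aged_adipose": "Adipose stromal cells from young vs old mice: % SA-β-gal+ and "
    "size of SA+ vs SA- cells",
}


class RunError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Fully describes one reproducible run (exactly one input source)."""

    simulation: str | Mapping | None = None  # SynthConfig yaml path or dict
    manifest: str | None = None              # dataset manifest path
    gates: str | Sequence[Mapping] | None = None  # gates yaml path or spec list
    control_samples: list[str] = field(default_factory=list)
    features: Mapping = field(default_factory=dict)  # FeatureParams overrides
    out_dir: str = "senescan_out"
    seed: int = 0
    log_level: str = "INFO"
    max_error_fraction: float = 0.05  # tolerated fraction of failed cells

    def validate(self) -> None:
        if (self.simulation is None) == (self.manifest is None):
            raise RunError(
                "config: exactly one of 'simulation' or 'manifest' is required"
            )
        if self.gates is None:
            raise RunError("config: 'gates' is required")
        if not 0 <= self.max_error_fraction <= 1:
            raise RunError("config: max_error_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            return cls(**d)
        except TypeError as err:
            raise RunError(f"config schema error: {err}") from err


@dataclass
class RunResult:
    table: pd.DataFrame
    gating: GatingResult
    report: pd.DataFrame
    out_dir: Path
    failures: list


def _feature_params(overrides: Mapping) -> feat.FeatureParams:
    d = dict(overrides or {})
    spot = feat.SpotParams(**d.pop("spot", {}))
    try:
        return feat.FeatureParams(spot=spot, **d)
    except TypeError as err:
        raise RunError(f"config features: {err}") from err


# ---------------------------------------------------------------------------
# gate building from declarative specs


def _spec_err(i: int, spec: Mapping, msg: str) -> RunError:
    return RunError(f"gates[{i}] ({spec.get('name', '?')}): {msg}")


def build_gates(
    table: pd.DataFrame,
    specs: Sequence[Mapping],
    control_samples: Sequence[str] = (),
) -> list[Gate]:
    """Materialize declarative gate specs into concrete gates.

    ``control_threshold`` gates get their cutoff from the named control
    samples' cells that pass the gate's parent — the unstained-reference
    convention.  Gates are resolved in order, so parents/boolean references
    must appear first.
    """
    gates: list[Gate] = []

    def membership_of(name: str | None) -> pd.Series:
        if name is None:
            return pd.Series(True, index=table.index)
        res = gating.apply_gates(table, gates)
        if name not in res.membership.columns:
            raise GatingError(f"parent gate {name!r} not defined yet")
        return res.membership[name]

    for i, spec in enumerate(specs):
        spec = dict(spec)
        kind = spec.pop("type", None)
        name = spec.get("name")
        if not name:
            raise _spec_err(i, spec, "missing 'name'")
        parent = spec.get("parent")
        try:
            if kind == "singlet_bf":
                area = spec.get("area", [50.0, 5000.0])
                gates.append(
                    gating.singlet_gate_bf(
                        name, parent, spec.get("min_ar", 0.6), area[0], area[1]
                    )
                )
            elif kind == "singlet_dapi":
                gates.append(
                    gating.singlet_gate_dapi(
                        table,
                        name,
                        parent,
                        tuple(spec.get("area_band", (0.3, 3.0))),
                        tuple(spec.get("intensity_band", (0.45, 1.6))),
                    )
                )
            elif kind == "focus":
                gates.extend(
                    gating.make_focus_gates(
                        name,
                        parent,
                        spec.get("min_grms", 3.5),
                        spec.get("min_contrast", 0.005),
                    )
                )
            elif kind == "control_threshold":
                feature = spec["feature"]
                if feature not in table.columns:
                    raise _spec_err(i, spec, f"unknown feature {feature!r}")
                if not control_samples:
                    raise _spec_err(i, spec, "no control_samples configured")
                sel = (
                    table["sample_id"].isin(control_samples)
                    & membership_of(parent)
                    & table[feature].notna()
                )
                g = gating.threshold_from_control(
                    table.loc[sel, feature].to_numpy(),
                    direction=spec["direction"],
                    quantile=spec.get("quantile"),
                    feature=feature,
                    name=name,
                    parent=parent,
                )
                gates.append(g)
            elif kind == "threshold":
                gates.append(
                    Gate(
                        name=name,
                        kind="threshold",
                        parent=parent,
                        feature=spec["feature"],
                        direction=spec["direction"],
                        cutoff=float(spec["cutoff"]),
                    )
                )
            elif kind == "interval":
                gates.append(
                    Gate(
                        name=name,
                        kind="interval",
                        parent=parent,
                        feature=spec["feature"],
                        lo=float(spec["lo"]),
                        hi=float(spec["hi"]),
                    )
                )
            elif kind == "rect2d":
                gates.append(
                    Gate(
                        name=name,
                        kind="rect2d",
                        parent=parent,
                        feature_x=spec["feature_x"],
                        feature_y=spec["feature_y"],
                        box=tuple(spec["box"]),
                    )
                )
            elif kind == "boolean":
                gates.append(
                    Gate(
                        name=name,
                        kind="boolean",
                        parent=parent,
                        op=spec["op"],
                        gates=tuple(spec["gates"]),
                    )
                )
            else:
                raise _spec_err(i, spec, f"unknown gate type {kind!r}")
        except KeyError as err:
            raise _spec_err(i, spec, f"missing key {err}") from err
    gating.apply_gates(table.iloc[:0], gates)  # validate the complete tree
    return gates


def _load_gate_specs(gates: str | Sequence[Mapping]) -> list[dict]:
    if isinstance(gates, (str, Path)):
        with open(gates) as fh:
            d = yaml.safe_load(fh)
    else:
        d = gates
    if isinstance(d, Mapping):
        d = d.get("gates", d)
    if not isinstance(d, (list, tuple)) or not d:
        raise RunError("gates config must be a non-empty list of gate specs")
    return [dict(s) for s in d]


# ---------------------------------------------------------------------------
# the run


def run(config: RunConfig) -> RunResult:
    """Execute a full run and write its outputs.

    Per-cell mask failures are logged and the cells excluded; the run fails
    if more than ``max_error_fraction`` of cells error out.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, str(config.log_level).upper(), logging.INFO))
    try:
        gate_specs = _load_gate_specs(config.gates)
        params = _feature_params(config.features)
        resolved: dict = {
            "seed": config.seed,
            "control_samples": list(config.control_samples),
            "gates": gate_specs,
            "features": config.features or {},
            "max_error_fraction": config.max_error_fraction,
        }
        if config.simulation is not None:
            synth = (
                SynthConfig.from_yaml(config.simulation)
                if isinstance(config.simulation, (str, Path))
                else SynthConfig.from_dict(config.simulation)
            )
            resolved["simulation"] = synth.to_dict()
            n_total = sum(p.n_cells for p in synth.populations)
            log.info("simulating %d cells (seed %d)", n_total, config.seed)
            render_failures: list = []
            cells = generate_cells(synth, config.seed, failures=render_failures)
        else:
            resolved["manifest"] = str(config.manifest)
            render_failures = []
            cells = read_dataset(config.manifest)
            n_total = len(cells)
            log.info("loaded %d cells from %s", n_total, config.manifest)
        if n_total == 0:
            raise RunError("empty dataset: no cells to analyze")

        table, failures = feat.extract_feature_table(cells, params)
        failures = render_failures + failures
        for cid, msg in failures:
            log.warning("cell %s excluded: %s", cid, msg)
        if len(table) == 0:
            raise RunError("no cell produced features")
        frac_failed = len(failures) / (len(table) + len(failures))
        if frac_failed > config.max_error_fraction:
            raise RunError(
                f"{frac_failed:.1%} of cells failed feature extraction "
                f"(tolerance {config.max_error_fraction:.0%})"
            )
        log.info("features: %d cells ok, %d failed", len(table), len(failures))

        gates = build_gates(table, gate_specs, config.control_samples)
        result = gating.apply_gates(table, gates)
        report = _make_report(table, result)
        for g in [g for g in gates if not g.name.startswith("__")]:
            n = int(result.membership[g.name].sum())
            log.info(
                "gate %-20s %6d cells (%d ungated)", g.name, n, result.ungated[g.name]
            )
        resolved["resolved_gates"] = [_gate_dict(g) for g in gates]

        write_feature_table(table, out_dir / "features.csv")
        report.to_csv(out_dir / "report.csv", index=False, float_format="%.6g")
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)
        log.info("wrote outputs to %s", out_dir)
        return RunResult(
            table=table, gating=result, report=report, out_dir=out_dir,
            failures=failures,
        )
    finally:
        log.removeHandler(handler)
        handler.close()


def _gate_dict(g: Gate) -> dict:
    d = {"name": g.name, "kind": g.kind, "parent": g.parent}
    if g.kind == "threshold":
        d.update(feature=g.feature, direction=g.direction, cutoff=g.cutoff)
    elif g.kind == "interval":
        d.update(feature=g.feature, lo=g.lo, hi=g.hi)
    elif g.kind == "rect2d":
        d.update(feature_x=g.feature_x, feature_y=g.feature_y, box=list(g.box))
    elif g.kind == "boolean":
        d.update(op=g.op, gates=list(g.gates))
    return d


def _make_report(table: pd.DataFrame, result: GatingResult) -> pd.DataFrame:
    """Per-(sample, gate) counts plus mean area ± SEM of in-gate cells."""
    rep = result.counts()
    rep = rep[~rep["gate"].str.startswith("__")].reset_index(drop=True)
    means, sems = [], []
    for row in rep.itertuples(index=False):
        sel = (result.sample_id == row.sample_id) & result.membership[row.gate]
        areas = table.loc[sel.to_numpy(), "area_um2"].dropna().to_numpy()
        if areas.size:
            means.append(float(np.mean(areas)))
            sems.append(
                float(np.std(areas, ddof=1) / np.sqrt(areas.size))
                if areas.size > 1
                else np.nan
            )
        else:
            means.append(np.nan)
            sems.append(np.nan)
    rep["mean_area_um2"] = means
    rep["sem_area_um2"] = sems
    return rep


# ---------------------------------------------------------------------------
# recipes


def list_recipes() -> dict[str, str]:
    return dict(_RECIPES)


def _config_path(fname: str) -> Path:
    return Path(resources.files("senescan") / "configs" / fname)


def recipe(
    name: str, out_dir: str = "senescan_out", seed: int = 0, n_scale: float = 1.0
) -> RunConfig:
    """A packaged scenario as a ready-to-run config.

    ``n_scale`` multiplies every population size (for quick smoke runs or
    larger Monte-Carlo runs).
    """
    if name not in _RECIPES:
        raise RunError(
            f"unknown recipe {name!r}; available: {', '.join(sorted(_RECIPES))}"
        )
    sim_path = _config_path(f"{name}.yaml")
    with open(sim_path) as fh:
        sim = yaml.safe_load(fh)
    if n_scale != 1.0:
        for pop in sim["populations"]:
            pop["n_cells"] = max(1, int(round(pop["n_cells"] * n_scale)))
    controls = [p["name"] for p in sim["populations"] if p.get("unstained")]
    return RunConfig(
        simulation=sim,
        gates=str(_config_path(f"{name}_gates.yaml")),
        control_samples=controls,
        out_dir=out_dir,
        seed=seed,
    )
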