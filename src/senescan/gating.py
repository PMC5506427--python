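"""Hierarchical, control-referenced gating and population statistics.

Gates are named predicates over feature-table columns, arranged in a tree:
singlets → focused → (viable) → cell type → marker-positive.  Marker
thresholds are set from an unstained control sample (quantile of the control
distribution), mirroring cytometry practice where positivity is defined
against an unstained reference rather than an absolute intensity.  Boolean
gates combine earlier gates (e.g. SA-β-gal⁺ AND HMGB1⁻ for a
two-marker senescence call).

Cells missing a feature required by a gate fall out of that gate (and are
tallied as "ungated") instead of failing the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Gate",
    "GatingResult",
    "PopulationStats",
    "GatingError",
    "threshold_from_control",
    "singlet_gate_bf",
    "singlet_gate_dapi",
    "focus_gate",
    "apply_gates",
    "percent_positive",
    "summarize_percent",
    "area_by_gate",
    "two_sample_test",
]


class GatingError(ValueError):
    pass


@dataclass
class Gate:
    """One named gate.

    predicate kinds:
      threshold — feature, direction ("above"/"below"), cutoff (strict)
      interval  — feature, lo ≤ value ≤ hi
      rect2d    — feature_x in [x_lo, x_hi] and feature_y in [y_lo, y_hi]
      boolean   — op in {AND, OR, NOT} over previously defined gate names
    """

    name: str
    kind: str
    parent: str | None = None
    feature: str | None = None
    direction: str | None = None
    cutoff: float | None = None
    lo: float | None = None
    hi: float | None = None
    feature_x: str | None = None
    feature_y: str | None = None
    box: tuple[float, float, float, float] | None = None  # x_lo, x_hi, y_lo, y_hi
    op: str | None = None
    gates: tuple[str, ...] = ()

    def required_features(self) -> list[str]:
        if self.kind in ("threshold", "interval"):
            return [self.feature]
        if self.kind == "rect2d":
            return [self.feature_x, self.feature_y]
        return []


@dataclass
class GatingResult:
    """Per-cell boolean membership for every gate, plus ungated tallies.

    membership: DataFrame indexed like the feature table, one bool column per
    gate.  ungated[gate] counts cells excluded from that gate because a
    required feature was missing (while the parent admitted them).
    """

    membership: pd.DataFrame
    ungated: dict[str, int]
    sample_id: pd.Series
    gates: dict[str, Gate]

    def counts(self) -> pd.DataFrame:
        """Per-(sample, gate) counts: n_parent, n_gate, percent."""
        rows = []
        for name, gate in self.gates.items():
            parent = (
                self.membership[gate.parent]
                if gate.parent
                else pd.Series(True, index=self.membership.index)
            )
            member = self.membership[name]
            for sid, idx in self.sample_id.groupby(self.sample_id).groups.items():
                n_parent = int(parent.loc[idx].sum())
                n_gate = int(member.loc[idx].sum())
                rows.append(
                    {
                        "sample_id": sid,
                        "gate": name,
                        "n_parent": n_parent,
                        "n_gate": n_gate,
                        "percent": 100.0 * n_gate / n_parent if n_parent else np.nan,
                        "ungated": self.ungated.get(name, 0),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PopulationStats:
    sample_id: str
    gate: str
    n_parent: int
    n_in_gate: int
    percent: float
    mean_area_um2: float | None = None
    sem: float | None = None


def threshold_from_control(
    control_values: Sequence[float],
    direction: str,
    quantile: float | None = None,
    feature: str = "value",
    name: str = "positive",
    parent: str | None = None,
) -> Gate:
    """Threshold gate whose cutoff is a quantile of an unstained control.

    direction "above" (fluorescence positivity) defaults to the 0.99 control
    quantile; "below" (bright-field darkness, i.e. SA-β-gal positivity)
    defaults to 0.01.  Quantiles use linear interpolation between order
    statistics so cutoffs are bit-reproducible.
    """
    vals = np.asarray(control_values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise GatingError("control values must be finite")
    if vals.size < 50:
        raise GatingError(f"need >= 50 control values, got {vals.size}")
    if direction not in ("above", "below"):
        raise GatingError(f"direction must be 'above' or 'below', got {direction!r}")
    if quantile is None:
        quantile = 0.99 if direction == "above" else 0.01
    if not 0 < quantile < 1:
        raise GatingError("quantile must be in (0, 1)")
    cutoff = float(np.quantile(vals, quantile))
    return Gate(
        name=name,
        kind="threshold",
        parent=parent,
        feature=feature,
        direction=direction,
        cutoff=cutoff,
    )


def singlet_gate_bf(
    name: str = "singlets",
    parent: str | None = None,
    min_ar: float = 0.6,
    area_lo: float = 50.0,
    area_hi: float = 5000.0,
) -> Gate:
    """Single-cell gate on bright-field area and aspect ratio.

    Doublets and aggregates are elongated (low aspect ratio); debris and
    clumps fall outside the plausible cell-area window.
    """
    return Gate(
        name=name,
        kind="rect2d",
        parent=parent,
        feature_x="area_um2",
        feature_y="aspect_ratio",
        box=(area_lo, area_hi, min_ar, 1.0 + 1e-9),
    )


def singlet_gate_dapi(
    table: pd.DataFrame,
    name: str = "singlets",
    parent: str | None = None,
    area_band: tuple[float, float] = (0.3, 3.0),
    intensity_band: tuple[float, float] = (0.45, 1.6),
) -> Gate:
    """Single-cell gate on DAPI area and total intensity (dissociated tissue).

    Total DAPI intensity tracks DNA content, so doublets (two nuclei, ≈2×
    intensity) fall outside a band around the sample median while nuclei of
    any size pass; the wide area band only removes debris and clumps.
    Bounds are multiples of the sample medians; the resolved absolute box is
    stored on the returned gate.
    """
    for col in ("dapi_area_um2", "dapi_intensity"):
        if col not in table.columns:
            raise GatingError(f"feature {col!r} not in table")
    med_a = float(np.nanmedian(table["dapi_area_um2"]))
    med_i = float(np.nanmedian(table["dapi_intensity"]))
    if not (np.isfinite(med_a) and np.isfinite(med_i)):
        raise GatingError("cannot calibrate DAPI singlet gate: no DAPI features")
    return Gate(
        name=name,
        kind="rect2d",
        parent=parent,
        feature_x="dapi_area_um2",
        feature_y="dapi_intensity",
        box=(
            area_band[0] * med_a,
            area_band[1] * med_a,
            intensity_band[0] * med_i,
            intensity_band[1] * med_i,
        ),
    )


def focus_gate(
    name: str = "focused",
    parent: str | None = None,
    min_grms: float = 3.5,
    min_contrast: float = 0.005,
) -> Gate:
    """Focused-cell gate: gradient RMS and contrast above floor values.

    Defaults were frozen from synthetic calibration renders at default noise
    (between the defocused and in-focus gradient-RMS distributions of
    tissue-scale cells); large weak-edged cells need a lower floor, and real
    data will need retuning.
    """
    return Gate(
        name=name,
        kind="boolean",
        parent=parent,
        op="AND",
        gates=(f"__{name}_grms", f"__{name}_contrast"),
    )


def _focus_subgates(gate: Gate, min_grms: float, min_contrast: float) -> list[Gate]:
    return [
        Gate(name=gate.gates[0], kind="threshold", feature="gradient_rms",
             direction="above", cutoff=min_grms),
        Gate(name=gate.gates[1], kind="threshold", feature="contrast",
             direction="above", cutoff=min_contrast),
    ]


def make_focus_gates(
    name: str = "focused",
    parent: str | None = None,
    min_grms: float = 3.5,
    min_contrast: float = 0.005,
) -> list[Gate]:
    """Focus gate plus its two hidden threshold sub-gates, ready for
    :func:`apply_gates`."""
    g = focus_gate(name, parent, min_grms, min_contrast)
    return _focus_subgates(g, min_grms, min_contrast) + [g]


# ---------------------------------------------------------------------------
# evaluation


def _validate_tree(gates: Sequence[Gate], columns: Sequence[str]) -> None:
    names: set[str] = set()
    for g in gates:
        if g.name in names:
            raise GatingError(f"duplicate gate name {g.name!r}")
        if g.parent is not None and g.parent not in names:
            raise GatingError(
                f"gate {g.name!r}: parent {g.parent!r} not defined earlier "
                "(tree must be ordered, no cycles)"
            )
        if g.kind == "boolean":
            if g.op not in ("AND", "OR", "NOT"):
                raise GatingError(f"gate {g.name!r}: unknown op {g.op!r}")
            if g.op == "NOT" and len(g.gates) != 1:
                raise GatingError(f"gate {g.name!r}: NOT takes exactly one gate")
            for ref in g.gates:
                if ref not in names:
                    raise GatingError(
                        f"gate {g.name!r} references undefined gate {ref!r}"
                    )
        elif g.kind in ("threshold", "interval", "rect2d"):
            for feat in g.required_features():
                if feat is None or feat not in columns:
                    raise GatingError(f"gate {g.name!r}: unknown feature {feat!r}")
        else:
            raise GatingError(f"gate {g.name!r}: unknown kind {g.kind!r}")
        names.add(g.name)


def _base_membership(gate: Gate, table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(member, defined) — defined marks rows whose required features are
    all present."""
    if gate.kind == "threshold":
        v = table[gate.feature]
        defined = v.notna()
        member = v > gate.cutoff if gate.direction == "above" else v < gate.cutoff
    elif gate.kind == "interval":
        v = table[gate.feature]
        defined = v.notna()
        member = (v >= gate.lo) & (v <= gate.hi)
    elif gate.kind == "rect2d":
        x, y = table[gate.feature_x], table[gate.feature_y]
        defined = x.notna() & y.notna()
        x_lo, x_hi, y_lo, y_hi = gate.box
        member = (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi)
    else:
        raise GatingError(f"gate {gate.name!r}: not a predicate gate")
    return member.fillna(False) & defined, defined


def apply_gates(table: pd.DataFrame, gates: Sequence[Gate]) -> GatingResult:
    """Evaluate a gate tree over a feature table.

    Gates are evaluated in the given (topological) order; membership in a
    child is always intersected with its parent, so hierarchy containment
    holds by construction.  Validation errors are raised before any
    evaluation.
    """
    gates = list(gates)
    _validate_tree(gates, table.columns)
    membership = pd.DataFrame(index=table.index)
    ungated: dict[str, int] = {}
    for g in gates:
        parent = (
            membership[g.parent]
            if g.parent
            else pd.Series(True, index=table.index)
        )
        if g.kind == "boolean":
            refs = [membership[r] for r in g.gates]
            if g.op == "AND":
                base = np.logical_and.reduce(refs)
            elif g.op == "OR":
                base = np.logical_or.reduce(refs)
            else:
                base = ~refs[0]
            base = pd.Series(base, index=table.index)
            defined = pd.Series(True, index=table.index)
        else:
            base, defined = _base_membership(g, table)
        membership[g.name] = base & parent
        ungated[g.name] = int((parent & ~defined).sum())
    sample = (
        table["sample_id"]
        if "sample_id" in table.columns
        else pd.Series("all", index=table.index)
    )
    return GatingResult(
        membership=membership,
        ungated=ungated,
        sample_id=sample,
        gates={g.name: g for g in gates},
    )


# ---------------------------------------------------------------------------
# population statistics


def percent_positive(
    result: GatingResult, gate: str, parent: str | None = None
) -> pd.DataFrame:
    """Percent of parent-gated cells inside ``gate``, per sample."""
    if gate not in result.membership.columns:
        raise GatingError(f"unknown gate {gate!r}")
    if parent is None:
        parent = result.gates[gate].parent
    pmask = (
        result.membership[parent]
        if parent
        else pd.Series(True, index=result.membership.index)
    )
    rows = []
    for sid, idx in result.sample_id.groupby(result.sample_id).groups.items():
        n_parent = int(pmask.loc[idx].sum())
        n_gate = int((result.membership[gate].loc[idx] & pmask.loc[idx]).sum())
        rows.append(
            {
                "sample_id": sid,
                "gate": gate,
                "n_parent": n_parent,
                "n_gate": n_gate,
                "percent": 100.0 * n_gate / n_parent if n_parent else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_percent(per_sample: pd.DataFrame) -> tuple[float, float]:
    """Across-sample mean ± SEM of percent positive (SEM = sd/√n, ddof=1)."""
    vals = np.asarray(per_sample["percent"], dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise GatingError("no samples with a defined percentage")
    sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
    return float(np.mean(vals)), sem


def area_by_gate(
    table: pd.DataFrame,
    result: GatingResult,
    gate: str,
    parent: str | None = None,
    area_column: str = "area_um2",
) -> tuple[PopulationStats, PopulationStats]:
    """Mean area ± SEM of cells inside vs outside ``gate`` (within the parent).

    The in/out split within one parent is how cell size is compared between
    SA-β-gal-positive and -negative populations.
    """
    if parent is None:
        parent = result.gates[gate].parent
    pmask = (
        result.membership[parent]
        if parent
        else pd.Series(True, index=table.index)
    )
    inside = result.membership[gate] & pmask
    outside = ~result.membership[gate] & pmask
    out = []
    for label, mask in (("in", inside), ("out", outside)):
        areas = table.loc[mask, area_column].dropna().to_numpy()
        if areas.size == 0:
            raise GatingError(f"no cells {label}side gate {gate!r}")
        sem = float(np.std(areas, ddof=1) / np.sqrt(areas.size)) if areas.size > 1 else np.nan
        out.append(
            PopulationStats(
                sample_id="all",
                gate=f"{gate}[{label}]",
                n_parent=int(pmask.sum()),
                n_in_gate=int(mask.sum()),
                percent=100.0 * mask.sum() / pmask.sum() if pmask.sum() else np.nan,
                mean_area_um2=float(np.mean(areas)),
                sem=sem,
            )
        )
    return out[0], out[1]


def two_sample_test(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t-test (equal variances): (t, p)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise GatingError("two_sample_test needs n >= 2 in each group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
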