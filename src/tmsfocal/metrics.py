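"""Focality and somatotopy metrics.

AAD (average absolute deviation): mean distance from the target of all
observation nodes whose field magnitude is at or above a threshold
fraction of the field's own current maximum -- an effective radius of the
suprathreshold "hot spot" and the cost function of the inverse search.

ARD (average relative differentiation): one minus the mean ratio of the
neighbour-target to selected-target field magnitudes, each magnitude
being an average over the few observation nodes nearest the point; 0 when
neighbours see the same field, 1 when they see none.

Field loss: percent decrease of the target field after optimization
relative to the sulcus-aligned start (negative = gain). Peak deviation:
distance from target to the centroid of the top-percentile nodes.
Focality improvement: 1 - (DF_final * AAD_final) / (DF_initial *
AAD_initial), the AAD reduction corrected by the coil-placement
defocalization factors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .coilkit import CoilPose
from .forward import FieldMap

__all__ = [
    "MetricConfig",
    "IPReport",
    "aad",
    "ard",
    "field_loss",
    "peak_deviation",
    "focality_improvement",
    "summarize_batch",
    "DEFAULT_DF_COND",
]

#: fixed conductivity-uncertainty defocalization factor used in map values
DEFAULT_DF_COND = 1.05


@dataclass
class MetricConfig:
    field_threshold: float = 0.80    # fraction of the current field maximum
    n_avg_nodes: int = 4             # nodes averaged per target field value
    peak_percentile: float = 0.99
    df_cond: float = DEFAULT_DF_COND

    def __post_init__(self):
        if not 0.0 < self.field_threshold < 1.0:
            raise ValueError("field_threshold must be in (0, 1)")
        if self.n_avg_nodes < 1:
            raise ValueError("n_avg_nodes must be >= 1")


@dataclass
class IPReport:
    """Final per-target metrics of one inverse-problem run."""

    target: tuple
    aad_initial: float
    aad_final: float
    df_initial: float
    df_final: float
    ard_initial: float | None
    ard_final: float | None
    field_loss: float | None
    peak_dev_initial: float
    peak_dev_final: float
    improvement: float
    pose_initial: CoilPose
    pose_final: CoilPose
    n_passes: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        d = asdict(self)
        for key in ("pose_initial", "pose_final"):
            p = d[key]
            d[key] = {"center": list(p["center"]), "pitch": p["pitch"],
                      "roll": p["roll"], "yaw": p["yaw"],
                      "convention": "R = R_y(roll) R_x(pitch) R_z(yaw)"}
        return json.dumps(d, indent=2, sort_keys=True, **kw)


def suprathreshold_nodes(field: FieldMap, threshold: float) -> np.ndarray:
    """Indices of nodes at/above ``threshold`` x the field's own maximum."""
    mag = field.magnitude
    peak = mag.max()
    if peak <= 0:
        raise ValueError("all-zero field: the threshold is undefined")
    return np.flatnonzero(mag >= threshold * peak)


def aad(field: FieldMap, target, threshold: float = 0.80) -> float:
    """Average absolute deviation (mm) of the suprathreshold nodes from target."""
    if len(field) == 0:
        raise ValueError("empty field map")
    idx = suprathreshold_nodes(field, threshold)
    d = np.linalg.norm(field.points[idx] - np.asarray(target, float), axis=1)
    return float(d.mean())


def _node_average(field: FieldMap, point, n_avg_nodes: int,
                  tree: cKDTree | None = None) -> float:
    tree = tree or cKDTree(field.points)
    _, idx = tree.query(np.asarray(point, float), k=min(n_avg_nodes, len(field)))
    return float(field.magnitude[np.atleast_1d(idx)].mean())


def target_field_value(field: FieldMap, point, n_avg_nodes: int = 4) -> float:
    """Field magnitude at a target = mean over its nearest observation nodes."""
    return _node_average(field, point, n_avg_nodes)


def ard(field: FieldMap, targets, n_avg_nodes: int = 4,
        target_index: int | None = None) -> float:
    """Average relative differentiation at one target of a TargetSet.

    ``targets`` is a ``TargetSet``; ``target_index`` selects the target
    (default: the middle one). Edge targets are averaged over the
    neighbours that exist.
    """
    idx = len(targets) // 2 if target_index is None else target_index
    nbrs = targets.neighbors[idx]
    if not nbrs:
        raise ValueError("ARD undefined: the target has no neighbours")
    tree = cKDTree(field.points)
    e_t = _node_average(field, targets.targets[idx], n_avg_nodes, tree)
    if e_t <= 0:
        raise ValueError("zero field at the target: ARD undefined")
    ratios = [
        _node_average(field, targets.targets[j], n_avg_nodes, tree) / e_t
        for j in nbrs
    ]
    return float(1.0 - np.mean(ratios))


def field_loss(field_before: FieldMap, field_after: FieldMap, target,
               n_avg_nodes: int = 4) -> float:
    """Percent field decrease at target after optimization (negative = gain)."""
    e_before = target_field_value(field_before, target, n_avg_nodes)
    e_after = target_field_value(field_after, target, n_avg_nodes)
    if e_after <= 0:
        raise ValueError("zero field after optimization: field loss undefined")
    return float(100.0 * (e_before / e_after - 1.0))


def peak_deviation(field: FieldMap, target, percentile: float = 0.99) -> float:
    """Distance (mm) from target to the centroid of the top-percentile nodes."""
    mag = field.magnitude
    cut = np.quantile(mag, percentile)
    sel = mag >= cut
    centroid = field.points[sel].mean(axis=0)
    return float(np.linalg.norm(centroid - np.asarray(target, float)))


def focality_improvement(report: IPReport) -> float:
    """1 - (DF_final AAD_final) / (DF_initial AAD_initial), as a fraction."""
    denom = report.df_initial * report.aad_initial
    if denom == 0:
        raise ValueError("zero initial defocalization-weighted AAD")
    return float(1.0 - report.df_final * report.aad_final / denom)


def summarize_batch(reports: list[IPReport], df_cond: float = DEFAULT_DF_COND
                    ) -> pd.DataFrame:
    """Mean/STD summary over a batch of runs plus the paired ARD t-test.

    Columns mirror the per-run metrics; the map value is the
    conductivity- and coil-defocalization-weighted AAD,
    DF_cond x DF_coil x AAD. Sample (n-1) standard deviations. The
    paired-sample two-sided t-test compares ARD after vs before; with
    fewer than two runs the p-value column is omitted.
    """
    rows = []
    for r in reports:
        rows.append({
            "aad_initial": r.aad_initial,
            "aad_final": r.aad_final,
            "df_initial": r.df_initial,
            "df_final": r.df_final,
            "ard_initial": r.ard_initial,
            "ard_final": r.ard_final,
            "field_loss": r.field_loss,
            "peak_dev_initial": r.peak_dev_initial,
            "peak_dev_final": r.peak_dev_final,
            "improvement": r.improvement,
            "map_value_initial": df_cond * r.df_initial * r.aad_initial,
            "map_value_final": df_cond * r.df_final * r.aad_final,
        })
    df = pd.DataFrame(rows)
    summary = df.agg(["mean", "std"]).T
    if len(reports) >= 2:
        before = df["ard_initial"].to_numpy(float)
        after = df["ard_final"].to_numpy(float)
        if np.allclose(after - before, 0.0):
            p = 1.0
        else:
            p = float(stats.ttest_rel(after, before).pvalue)
        summary.loc["ard_paired_ttest_p"] = [p, np.nan]
    return summary
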