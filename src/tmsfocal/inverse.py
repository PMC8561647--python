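"""Coordinate-descent inverse engine with stability correction.

The search minimizes the AAD focality cost over the 6 coil degrees of
freedom (yaw, pitch, roll, then x, y, z, updated sequentially with fixed
steps), subject to the hard 10 mm coil-scalp clearance constraint;
infeasible poses carry a +inf cost sentinel and are never adopted. A
perturbation-based defocalization factor DF (mean AAD ratio over +-1.5 mm
/ +-0.1 rad pose perturbations, the accuracy envelope of a robotized coil
holder) classifies solutions with DF >= 1.25 as geometrically unstable;
such solutions are reverted, accepted update by accepted update, until
the bound is met. An exhaustive grid search over the same pose grid
serves as the validation oracle for the descent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .coilkit import Coil, CoilPose, coil_scalp_clearance, transform_coil
from .forward import BemSystem, FieldMap, assemble_system, field_evaluator, solve_charges
from .meshkit import HeadModel, ObservationSurface
from .metrics import (
    IPReport,
    MetricConfig,
    aad,
    ard,
    field_loss,
    focality_improvement,
    peak_deviation,
)
from .placement import sulcus_aligned_pose

log = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "IPTrace",
    "EvaluationContext",
    "evaluate_pose",
    "descend",
    "defocalization",
    "stability_correct",
    "exhaustive_search",
    "run_ip",
]

INFEASIBLE = float("inf")
_FULL6D_ORDER = ("yaw", "pitch", "roll", "x", "y", "z")


@dataclass
class SearchConfig:
    step_linear: float = 2.0        # mm
    step_angular: float = 0.1       # rad
    df_step_linear: float = 1.5     # mm
    df_step_angular: float = 0.1    # rad
    df_limit: float = 1.25
    max_passes: int = 20
    saturation_tol: float = 0.05    # mm
    min_clearance: float = 10.0     # mm
    mode: str = "full6d"            # "full6d" | "tangential3"
    df_include_unperturbed: bool = True
    revert_granularity: str = "update"  # "update" | "pass"

    def __post_init__(self):
        if min(self.step_linear, self.step_angular,
               self.df_step_linear, self.df_step_angular) <= 0:
            raise ValueError("all steps must be > 0")
        if self.df_limit <= 1:
            raise ValueError("df_limit must exceed 1")
        if self.mode not in ("full6d", "tangential3"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class IPTrace:
    """Accepted-update history of one descent (pose + AAD per update)."""

    iterations: list = field(default_factory=list)  # (pass, variable, CoilPose, aad)
    accepted_index: int = -1
    df_history: list = field(default_factory=list)  # (iteration index, DF)
    n_passes: int = 0
    saturated: bool = False

    @property
    def final(self):
        return self.iterations[self.accepted_index]

    @property
    def aads(self) -> np.ndarray:
        return np.array([a for _, _, _, a in self.iterations])


class EvaluationContext:
    """Factorized forward operator + observation-surface evaluator + cache.

    Bundles everything a pose evaluation needs so that one head
    discretization is factorized once and reused across the entire
    search (and across searches on the same head). Evaluations are
    memoized on the rounded pose vector, which also makes repeat
    evaluations bit-reproducible.
    """

    def __init__(self, head: HeadModel, coil: Coil, obs: ObservationSurface,
                 mcfg: MetricConfig | None = None,
                 scfg: SearchConfig | None = None,
                 dIdt: float = 9.4e7,
                 system: BemSystem | None = None):
        self.head = head
        self.coil = coil
        self.obs = obs
        self.mcfg = mcfg or MetricConfig()
        self.scfg = scfg or SearchConfig()
        self.dIdt = dIdt
        self.system = system if system is not None else assemble_system(head)
        self.skin = head.shell("skin")
        self._evaluate_obs = field_evaluator(self.system, obs.points)
        self._cache: dict = {}

    def _key(self, pose: CoilPose, target, enforce: bool) -> tuple:
        return (tuple(np.round(pose.as_array(), 9)),
                tuple(np.round(np.asarray(target, float), 9)), enforce)

    def evaluate(self, pose: CoilPose, target,
                 enforce_clearance: bool = True) -> tuple[FieldMap | None, float]:
        """Field map and AAD for one pose; (None, inf) when infeasible.

        With ``enforce_clearance`` (the search path) the constraint is
        checked first and no forward solve is spent on a pose closer
        than ``min_clearance`` to the scalp. The defocalization analysis
        passes ``enforce_clearance=False``: pose *perturbations* model
        involuntary placement error, whose field exists regardless of
        the search-space constraint.
        """
        key = self._key(pose, target, enforce_clearance)
        if key in self._cache:
            return self._cache[key]
        placed = transform_coil(self.coil, pose)
        if enforce_clearance and \
                coil_scalp_clearance(placed, self.skin) < self.scfg.min_clearance - 1e-6:
            result = (None, INFEASIBLE)
        else:
            charges = solve_charges(self.system, placed, pose=None, dIdt=self.dIdt)
            fmap = self._evaluate_obs(charges, placed, self.dIdt, pose_ref=pose)
            result = (fmap, aad(fmap, target, self.mcfg.field_threshold))
        self._cache[key] = result
        return result


def evaluate_pose(ctx: EvaluationContext, pose: CoilPose, target):
    """Functional wrapper over :meth:`EvaluationContext.evaluate`."""
    return ctx.evaluate(pose, target)


# ---------------------------------------------------------------------------
# Pose arithmetic
# ---------------------------------------------------------------------------

_VAR_INDEX = {"x": 0, "y": 1, "z": 2, "pitch": 3, "roll": 4, "yaw": 5}


def _step_of(var: str, cfg: SearchConfig) -> float:
    return cfg.step_linear if var in ("x", "y", "z") else cfg.step_angular


def _shift(pose: CoilPose, var: str, delta: float) -> CoilPose:
    a = pose.as_array()
    a[_VAR_INDEX[var]] += delta
    return CoilPose.from_array(a)


def _tangent_axes(pose: CoilPose, coil: Coil):
    """Scalp-tangential translation axes: the coil-plane handle and its
    in-plane perpendicular at the current pose."""
    R = pose.rotation()
    return R @ coil.handle_axis, np.cross(R @ coil.normal_axis, R @ coil.handle_axis)


def _translate(pose: CoilPose, axis: np.ndarray, delta: float) -> CoilPose:
    c = np.asarray(pose.center) + delta * axis
    return replace(pose, center=tuple(c))


def _retangentialize(ctx: EvaluationContext, pose: CoilPose) -> CoilPose:
    """Re-normalize the centerline to the skin after a tangential move.

    The coil is re-seated so its normal matches the skin normal under the
    new center and the original skin standoff is restored; the handle is
    carried over by projection (restricted 3-parameter search mode).
    """
    from .placement import _ray_mesh_intersection  # shared ray helper

    R = pose.rotation()
    normal = R @ ctx.coil.normal_axis
    handle = R @ ctx.coil.handle_axis
    center = np.asarray(pose.center)
    hit = _ray_mesh_intersection(center, -normal, ctx.skin)
    if hit is None:
        return pose
    skin_point, face = hit
    standoff = float(np.linalg.norm(center - skin_point))
    new_normal = ctx.skin.normals[face]
    if new_normal @ normal < 0:
        new_normal = -new_normal
    from .coilkit import pose_from_frame

    new_center = skin_point + standoff * new_normal
    return pose_from_frame(new_center, new_normal, handle)


# ---------------------------------------------------------------------------
# Descent, defocalization, stability, exhaustive oracle
# ---------------------------------------------------------------------------

def descend(ctx: EvaluationContext, pose0: CoilPose, target,
            cfg: SearchConfig | None = None) -> IPTrace:
    """Sequential coordinate descent from ``pose0``.

    Per pass the variables are updated in the order yaw, pitch, roll, x,
    y, z (tangential mode: yaw plus the two scalp-tangential
    translations); each variable is probed at {v - step, v, v + step} and
    the minimizer adopted immediately, current value kept on ties. Passes
    repeat until the per-pass AAD decrease falls below the saturation
    tolerance or ``max_passes`` is reached. The accepted-update AAD
    sequence is non-increasing by construction.
    """
    cfg = cfg or ctx.scfg
    _, aad0 = ctx.evaluate(pose0, target)
    if not np.isfinite(aad0):
        raise ValueError("initial pose violates the coil-scalp clearance constraint")
    trace = IPTrace()
    trace.iterations.append((0, "init", pose0, aad0))
    pose, cur = pose0, aad0

    for p in range(1, cfg.max_passes + 1):
        start = cur
        if cfg.mode == "full6d":
            moves = [(var, lambda q, d, v=var: _shift(q, v, d), _step_of(var, cfg))
                     for var in _FULL6D_ORDER]
        else:
            t1, t2 = _tangent_axes(pose, ctx.coil)
            moves = [
                ("yaw", lambda q, d: _shift(q, "yaw", d), cfg.step_angular),
                ("t1", lambda q, d, ax=t1: _retangentialize(ctx, _translate(q, ax, d)),
                 cfg.step_linear),
                ("t2", lambda q, d, ax=t2: _retangentialize(ctx, _translate(q, ax, d)),
                 cfg.step_linear),
            ]
        for var, move, step in moves:
            best_pose, best = pose, cur
            for d in (-step, +step):
                cand = move(pose, d)
                _, val = ctx.evaluate(cand, target)
                if val < best:           # strict: keep current value on ties
                    best_pose, best = cand, val
            if best < cur:
                pose, cur = best_pose, best
                trace.iterations.append((p, var, pose, cur))
        trace.n_passes = p
        if start - cur < cfg.saturation_tol:
            trace.saturated = True
            break
    trace.accepted_index = len(trace.iterations) - 1
    return trace


def defocalization(ctx: EvaluationContext, pose: CoilPose, target,
                   cfg: SearchConfig | None = None,
                   aad_at_pose: float | None = None) -> float:
    """Relative average defocalization DF at ``pose``.

    Mean of the AAD ratios over the unperturbed pose (ratio exactly 1)
    and the 12 single-variable perturbations +-df_step_linear /
    +-df_step_angular. Perturbations model involuntary placement error,
    so they are evaluated without the search-space clearance gate; a
    perturbation that still cannot be evaluated is skipped with a log
    line. Ratios are not clamped at 1, so a raw mean slightly below 1
    is reported as-is.
    """
    cfg = cfg or ctx.scfg
    if aad_at_pose is None:
        _, aad_at_pose = ctx.evaluate(pose, target)
    if not np.isfinite(aad_at_pose) or aad_at_pose <= 0:
        raise ValueError("DF requires a feasible pose with AAD > 0")
    ratios = [1.0] if cfg.df_include_unperturbed else []
    n_skipped = 0
    for var in _FULL6D_ORDER:
        step = cfg.df_step_linear if var in ("x", "y", "z") else cfg.df_step_angular
        for d in (-step, +step):
            try:
                _, val = ctx.evaluate(_shift(pose, var, d), target,
                                      enforce_clearance=False)
            except TypeError:  # minimal evaluator without the flag
                _, val = ctx.evaluate(_shift(pose, var, d), target)
            if not np.isfinite(val):
                n_skipped += 1
                log.info("DF perturbation %s%+g not evaluable; skipped", var, d)
                continue
            ratios.append(val / aad_at_pose)
    if n_skipped == 12:
        raise RuntimeError("all DF perturbations infeasible")
    return float(np.mean(ratios))


def stability_correct(trace: IPTrace, ctx: EvaluationContext, target,
                      cfg: SearchConfig | None = None) -> IPTrace:
    """Revert unstable solutions until DF < df_limit.

    Walks back through the accepted updates (or whole passes, per
    ``revert_granularity``) re-checking DF at each; raises if no
    iteration satisfies the bound.
    """
    cfg = cfg or ctx.scfg
    if not trace.iterations:
        raise ValueError("empty trace")
    idx = trace.accepted_index if trace.accepted_index >= 0 else len(trace.iterations) - 1
    while True:
        _, _, pose, aad_val = trace.iterations[idx]
        df = defocalization(ctx, pose, target, cfg, aad_at_pose=aad_val)
        trace.df_history.append((idx, df))
        if df < cfg.df_limit:
            trace.accepted_index = idx
            return trace
        if idx == 0:
            raise RuntimeError(
                f"no iteration satisfies DF < {cfg.df_limit}; last DF = {df:.3f}"
            )
        if cfg.revert_granularity == "pass":
            this_pass = trace.iterations[idx][0]
            while idx > 0 and trace.iterations[idx][0] == this_pass:
                idx -= 1
        else:
            idx -= 1
        log.info("solution unstable (DF=%.3f >= %.2f); reverting to iteration %d",
                 df, cfg.df_limit, idx)


def exhaustive_search(ctx: EvaluationContext, pose0: CoilPose, target,
                      grid: dict, max_poses: int = 5000):
    """Global minimum of the AAD cost over a pose grid (validation oracle).

    ``grid`` maps variable names to arrays of absolute offsets applied to
    ``pose0``. The full cartesian product is evaluated (bounded by
    ``max_poses``); infeasible poses are excluded.
    """
    names = list(grid)
    axes = [np.asarray(grid[v], float) for v in names]
    n_total = int(np.prod([len(a) for a in axes]))
    if n_total > max_poses:
        raise ValueError(f"grid of {n_total} poses exceeds the cap of {max_poses}")
    best_pose, best = None, INFEASIBLE
    for combo in itertools.product(*axes):
        pose = pose0
        for var, off in zip(names, combo):
            pose = _shift(pose, var, float(off))
        _, val = ctx.evaluate(pose, target)
        if val < best:
            best_pose, best = pose, val
    if best_pose is None:
        raise RuntimeError("all grid poses violate the clearance constraint")
    return best_pose, best


# ---------------------------------------------------------------------------
# Full pipeline for one target
# ---------------------------------------------------------------------------

def run_ip(ctx: EvaluationContext, target_set, target_index: int,
           wall_normal="auto", standoff: float = 10.0) -> IPReport:
    """Full inverse-problem pipeline for one target of a TargetSet.

    sulcus-aligned pose -> initial metrics -> coordinate descent ->
    stability correction -> defocalization at both poses -> report with
    the corrected focality improvement and the target field loss.
    """
    cfg, mcfg = ctx.scfg, ctx.mcfg
    target = target_set.targets[target_index]
    pose0 = sulcus_aligned_pose(ctx.head, target, ctx.coil,
                                wall_normal=wall_normal, standoff=standoff)
    pose0 = _nudge_feasible(ctx, pose0)

    field0, aad0 = ctx.evaluate(pose0, target)
    peak0 = peak_deviation(field0, target, mcfg.peak_percentile)
    try:
        ard0 = ard(field0, target_set, mcfg.n_avg_nodes, target_index)
    except ValueError:
        ard0 = None

    trace = descend(ctx, pose0, target, cfg)
    trace = stability_correct(trace, ctx, target, cfg)
    _, _, pose_f, aad_f = trace.iterations[trace.accepted_index]
    field_f, _ = ctx.evaluate(pose_f, target)

    df_init = defocalization(ctx, pose0, target, cfg, aad_at_pose=aad0)
    df_fin = trace.df_history[-1][1]
    peak_f = peak_deviation(field_f, target, mcfg.peak_percentile)
    try:
        ard_f = ard(field_f, target_set, mcfg.n_avg_nodes, target_index)
    except ValueError:
        ard_f = None
    loss = field_loss(field0, field_f, target, mcfg.n_avg_nodes)

    report = IPReport(
        target=tuple(np.asarray(target, float)),
        aad_initial=aad0,
        aad_final=aad_f,
        df_initial=df_init,
        df_final=df_fin,
        ard_initial=ard0,
        ard_final=ard_f,
        field_loss=loss,
        peak_dev_initial=peak0,
        peak_dev_final=peak_f,
        improvement=0.0,
        pose_initial=pose0,
        pose_final=pose_f,
        n_passes=trace.n_passes,
        config={
            "field_threshold": mcfg.field_threshold,
            "n_avg_nodes": mcfg.n_avg_nodes,
            "mode": cfg.mode,
            "step_linear": cfg.step_linear,
            "step_angular": cfg.step_angular,
            "df_limit": cfg.df_limit,
            "max_passes": cfg.max_passes,
            "dIdt": ctx.dIdt,
        },
    )
    report.improvement = focality_improvement(report)
    return report


def _nudge_feasible(ctx: EvaluationContext, pose: CoilPose,
                    max_nudge: float = 2.0) -> CoilPose:
    """Lift the coil minimally along its centerline if the faceted-skin
    clearance lands marginally below the hard constraint."""
    placed = transform_coil(ctx.coil, pose)
    clearance = coil_scalp_clearance(placed, ctx.skin)
    deficit = ctx.scfg.min_clearance - clearance
    if deficit <= 0:
        return pose
    if deficit > max_nudge:
        raise ValueError(
            f"initial pose clearance {clearance:.2f} mm is far below the "
            f"{ctx.scfg.min_clearance:.0f} mm constraint"
        )
    normal = pose.rotation() @ ctx.coil.normal_axis
    log.info("initial pose lifted %.2f mm to honour the clearance constraint",
             deficit + 0.05)
    return _translate(pose, normal, deficit + 0.05)
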