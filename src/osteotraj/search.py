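"""Iterative posture search: propose, evaluate, rank, terminate.

Automates the posture-refinement protocol as a deterministic
coordinate descent over the joint hierarchy (hip extension first, then
knee, then the hip coronal-plane angles), with steps shrinking from 10
to 2.5 degrees.  Every candidate posture is repaired to admissibility
before evaluation: the metatarsophalangeal angle is reset so the pes
lies flat on the ground, the ankle is adjusted so the pes centroid
(COP) sits under the whole-body COM, and hip abduction is reduced if
the step width exceeds 15% of hip height.  A candidate is accepted
only if it strictly improves the weighted alignment score; the search
terminates when a full sweep at the minimum step brings no improvement
beyond the similarity threshold (0.5 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import fem, statics, trajectories
from .kinematics import (
    POSTURE_RANGES,
    ConstraintReport,
    Posture,
    PostureRangeError,
    START_POSTURE,
    check_posture_constraints,
    flat_foot_mtp,
    pose_limb,
)


class SearchStallError(RuntimeError):
    pass


@dataclass
class SearchConfig:
    start: Posture = START_POSTURE
    steps: tuple = (10.0, 5.0, 2.5)
    min_improvement: float = 0.5  # degrees; smaller changes count as "similar"
    max_evaluations: int = 200
    cop_tol: float = 1e-3
    step_width_limit: float = 0.15
    region_weights: dict | None = None
    seed: int = 0


# hierarchical priorities: hip extension > knee > (hip coronal angles);
# the ankle and MTP are slaved to the admissibility repair
SEARCH_JOINTS = ("hip_extension", "knee_flexion", "hip_abduction", "hip_lar")


def repair_posture(model, posture: Posture, config: SearchConfig | None = None) -> Posture:
    """Make a posture admissible: pes flat, COP under COM, step width ok.

    The MTP angle is always reset to place the pes flat on the ground;
    the ankle absorbs the COP-under-COM constraint (root find on the
    anteroposterior offset); hip abduction is reduced toward the
    midline if the step width exceeds the limit.
    """
    cfg = config or SearchConfig()
    lo, hi = POSTURE_RANGES["ankle_flexion"]

    def with_flat_foot(p: Posture) -> Posture:
        return p.replace(mtp_angle=flat_foot_mtp(model, p))

    def cop_dx(ankle: float, p: Posture) -> float:
        q = with_flat_foot(p.replace(ankle_flexion=ankle))
        posed = pose_limb(model, q, validate=False)
        return float(posed.cop[0] - posed.com[0])

    def step_ratio(p: Posture) -> float:
        ps = pose_limb(model, with_flat_foot(p), validate=False)
        return 2.0 * abs(float(ps.cop[1])) / ps.hip_height

    def fix_width(p: Posture, joint: str) -> Posture | None:
        """Root-find one coronal hip angle so the pes lands slightly
        lateral of the midline at 80% of the step-width limit."""
        j_lo, j_hi = POSTURE_RANGES[joint]

        def cop_y_excess(v):
            q = with_flat_foot(p.replace(**{joint: v}))
            ps = pose_limb(model, q, validate=False)
            # target: foot lateral (cop_y < 0 for the right limb)
            return float(ps.cop[1]) + 0.4 * cfg.step_width_limit * ps.hip_height

        try:
            v = brentq(cop_y_excess, j_lo + 1.0, j_hi - 1.0, xtol=1e-4)
        except ValueError:
            return None
        return with_flat_foot(p.replace(**{joint: float(v)}))

    p = posture
    for _ in range(2):  # COM moves slightly with the ankle; iterate twice
        f_lo, f_hi = cop_dx(lo + 1.0, p), cop_dx(hi - 1.0, p)
        if f_lo * f_hi <= 0:
            ankle = brentq(cop_dx, lo + 1.0, hi - 1.0, args=(p,), xtol=1e-6)
        else:
            res = minimize_scalar(
                lambda a: abs(cop_dx(a, p)), bounds=(lo + 1.0, hi - 1.0), method="bounded"
            )
            ankle = float(res.x)
        p = with_flat_foot(p.replace(ankle_flexion=float(ankle)))

        if step_ratio(p) >= cfg.step_width_limit:
            # long-axis rotation first (it steers the folded distal limb
            # most directly), abduction as the fallback
            fixed = fix_width(p, "hip_lar") or fix_width(p, "hip_abduction")
            if fixed is not None:
                p = fixed
    try:
        p.validate()
    except PostureRangeError as exc:
        raise SearchStallError(f"repair left posture out of range: {exc}") from exc
    return p


def compute_principal_fields(model, posture: Posture, apply_ankle_moment: bool = False):
    """Forward pipeline at one posture: statics, the two FE solves, and
    principal-stress fields in each focal bone's *local* frame (fabric
    is a bone property, so comparisons happen in bone coordinates)."""
    posed = pose_limb(model, posture, validate=False)
    loads = statics.build_external_loads(posed, model)
    sol = statics.solve_static_optimization(model, posed, loads)
    jr = statics.joint_reactions(model, posed, sol, loads)
    out = {}
    for bone, seg in (("femur", "thigh"), ("tibiotarsus_fibula", "shank")):
        case = fem.build_bone_case(
            model, posed, sol, jr, loads, which=bone, apply_ankle_moment=apply_ankle_moment
        )
        sf = fem.solve_bone_case(case)
        R, t = posed.rotations[seg], posed.translations[seg]
        pts_local = (sf.points - t) @ R
        tens_local = np.einsum("ji,njk,kl->nil", R, sf.tensors, R)
        out[bone] = trajectories.principal_field(pts_local, tens_local)
    out["_solution"] = sol
    out["_joint_loads"] = jr
    out["_loads"] = loads
    out["_posed"] = posed
    return out


def scored_regions(model) -> list[tuple[str, trajectories.RegionSpec]]:
    """Default quantified comparison regions: the two femoral regions
    plus a proximal-tibiotarsus region under the articular surface.

    The femoral head and medial condyle carry the quantitative
    priority; the proximal tibiotarsus formalizes the whole-limb
    correspondence that otherwise guides the search only qualitatively
    (and is what makes the knee angle identifiable)."""
    p = model.params
    d = p.head_offset
    out = [("femur", r) for r in trajectories.femoral_regions(model)]
    out.append(
        ("femur", trajectories.RegionSpec("trochanteric", (0.0, -d, -0.014), 0.005))
    )
    out.append(
        (
            "tibiotarsus_fibula",
            trajectories.RegionSpec("proximal_tibiotarsus", (0.0, 0.0, -0.014), 0.005),
        )
    )
    out.append(
        (
            "tibiotarsus_fibula",
            trajectories.RegionSpec(
                "distal_tibiotarsus", (0.0, 0.0, -(p.tibiotarsus_length - 0.010)), 0.005
            ),
        )
    )
    return out


DEFAULT_SCORE_WEIGHTS = {
    "femoral_head": 2.0,
    "medial_condyle": 1.0,
    "trochanteric": 1.0,
    "proximal_tibiotarsus": 1.0,
    "distal_tibiotarsus": 1.0,
}


@dataclass
class EvalResult:
    posture: Posture
    score: trajectories.ScoreReport
    constraints: ConstraintReport
    solution: statics.ActivationSolution = None
    fields: dict = None


def _fabric_map(fabric) -> dict:
    if isinstance(fabric, dict):
        return fabric
    return {"femur": fabric}


def evaluate_posture(
    model,
    posture: Posture,
    fabric,
    regions: list | None = None,
    weights: dict | None = None,
) -> EvalResult:
    """Full evaluation of one admissible posture: statics -> two FE
    solves -> eigenanalysis -> regional sigma3-vs-u1 deviations and the
    weighted scalar score.

    ``fabric`` is a FabricField (femur) or a dict bone -> FabricField;
    regions whose bone has no fabric are reported as errors and omitted
    from the scalar."""
    posed = pose_limb(model, posture, validate=False)
    constraints = check_posture_constraints(posed, model)
    fields = compute_principal_fields(model, posture)
    fmap = _fabric_map(fabric)
    region_list = regions if regions is not None else scored_regions(model)
    weights = dict(weights or DEFAULT_SCORE_WEIGHTS)
    devs, errs = {}, {}
    for bone, region in region_list:
        if bone not in fmap:
            errs[region.name] = f"no fabric for bone {bone}"
            continue
        pf, fab = fields[bone], fmap[bone]
        try:
            s_dir = trajectories.regional_axis(
                pf.points, pf.axis("sigma3"), region, exclude=pf.degenerate
            )
            u_dir = trajectories.regional_axis(fab.points, fab.u1, region)
            devs[region.name] = trajectories.angular_deviation(s_dir, u_dir)
        except trajectories.EmptyRegionError as exc:
            errs[region.name] = str(exc)
    if devs:
        wsum = sum(weights.get(k, 1.0) for k in devs)
        scalar = sum(weights.get(k, 1.0) * v for k, v in devs.items()) / wsum
    else:
        scalar = float("nan")
    score = trajectories.ScoreReport(
        region_deviation=devs, weighted_score=float(scalar), weights=weights, region_errors=errs
    )
    return EvalResult(posture=posture, score=score, constraints=constraints,
                      solution=fields["_solution"], fields=fields)


@dataclass
class SearchState:
    history: list = field(default_factory=list)  # (posture, score report, constraints)
    best: EvalResult = None
    evaluations: int = 0
    step: float = 0.0
    seed: int = 0
    stopped_reason: str = ""

    def accepted_scores(self):
        out = []
        cur = np.inf
        for _, rep, _ in self.history:
            if rep.weighted_score < cur:
                cur = rep.weighted_score
            out.append(cur)
        return out


def propose_posture(model, state: SearchState, config: SearchConfig, joint: str, sign: float) -> Posture:
    """One hierarchical proposal: perturb a joint from the current best
    by the current step, then repair admissibility (flat pes, COP under
    COM, step width)."""
    base = state.best.posture
    value = getattr(base, joint) + sign * state.step
    lo, hi = POSTURE_RANGES[joint]
    if not (lo <= value <= hi):
        raise SearchStallError(f"{joint} step leaves declared range")
    return repair_posture(model, base.replace(**{joint: value}), config)


def run_search(model, fabric, config: SearchConfig | None = None):
    """Coordinate descent over the joint hierarchy with shrinking steps.

    Returns (solution posture, SearchState with the audit trail).
    Accepted-score sequence is non-increasing; every evaluated posture
    satisfied the admissibility constraints.
    """
    cfg = config or SearchConfig()
    regions = scored_regions(model)
    state = SearchState(seed=cfg.seed)

    def evaluate(p: Posture) -> EvalResult:
        res = evaluate_posture(model, p, fabric, regions=regions, weights=cfg.region_weights)
        state.history.append((p, res.score, res.constraints))
        state.evaluations += 1
        return res

    start = repair_posture(model, cfg.start, cfg)
    state.best = evaluate(start)

    for step in cfg.steps:
        state.step = step
        improved = True
        while improved and state.evaluations < cfg.max_evaluations:
            improved = False
            for joint in SEARCH_JOINTS:
                for sign in (+1.0, -1.0):
                    if state.evaluations >= cfg.max_evaluations:
                        break
                    try:
                        cand = propose_posture(model, state, cfg, joint, sign)
                    except SearchStallError:
                        continue
                    if _same_posture(cand, state.best.posture):
                        continue
                    # cheap admissibility gate before the expensive solves
                    pre = check_posture_constraints(pose_limb(model, cand, validate=False), model)
                    if not pre.all_ok:
                        continue
                    try:
                        res = evaluate(cand)
                    except statics.InfeasibleError:
                        continue
                    if not res.constraints.all_ok:
                        continue
                    gain = state.best.score.weighted_score - res.score.weighted_score
                    # 1e-6 deg floor: improvements at rounding-noise scale
                    # are not improvements
                    if gain > 1e-6 and (step > cfg.steps[-1] or gain >= cfg.min_improvement):
                        state.best = res
                        improved = True
                        break  # restart from the highest-priority joint
                if improved:
                    break
        if state.evaluations >= cfg.max_evaluations:
            state.stopped_reason = "evaluation cap reached"
            break
    if not state.stopped_reason:
        state.stopped_reason = "no improvement at minimum step"
    return state.best.posture, state


def _same_posture(a: Posture, b: Posture, tol: float = 1e-9) -> bool:
    return all(abs(getattr(a, k) - getattr(b, k)) < tol for k in a.as_dict())
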