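"""Musculoskeletal statics: external loads, moment arms, static optimization.

A test posture is analysed as a quasi-static system.  The only
acceleration is gravity; the applied ground reaction force (GRF) is
vertical and of magnitude 1 BW at the pes centroid (the COP), with a
mediolateral moment M_x = BW * (COP_y - COM_y) balancing the step-width
offset and a small M_y cancelling any residual anteroposterior offset,
so the whole model is in exact static equilibrium without pelvis
residual actuators.

Muscle redundancy is resolved by minimizing the sum of squared
activations subject to moment balance at the six free degrees of
freedom (hip x3, knee, ankle, MTP), with 0 <= a <= 1, a
metatarsophalangeal reserve actuator bounded at 1000 Nm, and ligaments
included as linear reserve actuators (no slack length or elasticity).
Each actuator contributes M_i = a * F_max * r_i per DOF, with the
moment arm r_i = -dL/dtheta_i obtained by tendon excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import PosedLimb, Posture, pose_limb

DOFS = (
    "hip_extension",
    "hip_abduction",
    "hip_lar",
    "knee_flexion",
    "ankle_flexion",
    "mtp_angle",
)

#: flip factors mapping coordinate-sense moment arms to the reporting
#: convention "extension positive" (flexion coordinates are flipped)
EXTENSION_SIGN = {
    "hip_extension": 1.0,
    "hip_abduction": 1.0,
    "hip_lar": 1.0,
    "knee_flexion": -1.0,
    "ankle_flexion": -1.0,
    "mtp_angle": 1.0,
}

MTP_RESERVE_CAPACITY = 1000.0  # Nm


class InfeasibleError(RuntimeError):
    def __init__(self, dofs, residuals):
        self.dofs = list(dofs)
        self.residuals = residuals
        super().__init__(
            "static optimization infeasible; unbalanced DOFs: "
            + ", ".join(f"{d} ({r:+.3g} Nm)" for d, r in zip(dofs, residuals))
        )


@dataclass
class Actuator:
    """A via-point musculotendon (or ligament) actuator.

    ``path`` is an ordered list of (segment, point) pairs from origin to
    insertion, points in segment-local coordinates.  Inactive actuators
    exert zero force.  Ligaments are plain linear reserve actuators.
    """

    name: str
    kind: str  # 'muscle' | 'ligament'
    path: list[tuple[str, np.ndarray]]
    active: bool = True
    f_max: float = 1.0

    def __post_init__(self):
        if len(self.path) < 2:
            raise ValueError(f"{self.name}: actuator path needs >= 2 points")
        if self.f_max <= 0:
            raise ValueError(f"{self.name}: f_max must be positive")
        self.path = [(seg, np.asarray(p, float)) for seg, p in self.path]

    def posed_points(self, posed: PosedLimb) -> np.ndarray:
        return np.array([posed.to_global(seg, p) for seg, p in self.path])

    def length(self, posed: PosedLimb) -> float:
        pts = self.posed_points(posed)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def segments_crossed(self) -> set[str]:
        return {seg for seg, _ in self.path}


@dataclass
class ExternalLoads:
    """GRF + balancing moments + segment weights for one posture.

    ``m_x`` follows the ground-reaction sense BW*(COP_y - COM_y);
    ``m_y`` = BW*(COM_x - COP_x).  The moment vector actually applied
    to the pes for global equilibrium is ``applied_moment`` = -(m_x,
    m_y, 0).
    """

    grf: np.ndarray  # N, at cop
    cop: np.ndarray  # global, m
    cop_local: np.ndarray  # pes-frame material point of the COP
    m_x: float  # Nm
    m_y: float  # Nm
    applied_moment: np.ndarray  # Nm vector on the pes
    segment_weights: dict[str, float]  # name -> N (downward)


def build_external_loads(posed: PosedLimb, model) -> ExternalLoads:
    if posed.com is None or posed.cop is None:
        raise ValueError("posed limb lacks COM/COP")
    bw = model.body_weight
    com, cop = posed.com, posed.cop
    m_x = bw * (cop[1] - com[1])
    m_y = bw * (com[0] - cop[0])
    Rp, tp = posed.rotations["pes"], posed.translations["pes"]
    cop_local = Rp.T @ (cop - tp)
    return ExternalLoads(
        grf=np.array([0.0, 0.0, bw]),
        cop=cop.copy(),
        cop_local=cop_local,
        m_x=float(m_x),
        m_y=float(m_y),
        applied_moment=np.array([-m_x, -m_y, 0.0]),
        segment_weights={s.name: s.mass * model.gravity for s in model.segments.values()},
    )


# ---------------------------------------------------------------------------
# moment arms and generalized external moments (virtual work)
# ---------------------------------------------------------------------------

_FD_STEP_DEG = 0.05


def _perturbed(posture: Posture, dof: str, delta_deg: float) -> Posture:
    return posture.replace(**{dof: getattr(posture, dof) + delta_deg})


def moment_arm(
    actuator: Actuator,
    model,
    posture: Posture,
    dof: str,
    sign_convention: str = "coordinate",
) -> float:
    """Tendon-excursion moment arm r = -dL/dtheta (central difference).

    ``coordinate`` sign convention is conjugate to the posture
    coordinate (used by the solver); ``extension_positive`` flips
    flexion coordinates for Fig.-style reporting.
    """
    h = _FD_STEP_DEG
    lp = actuator.length(pose_limb(model, _perturbed(posture, dof, +h), validate=False))
    lm = actuator.length(pose_limb(model, _perturbed(posture, dof, -h), validate=False))
    r = -(lp - lm) / (2.0 * np.radians(h))
    if abs(r) < 1e-12:
        r = 0.0
    if sign_convention == "extension_positive":
        r *= EXTENSION_SIGN[dof]
    return float(r)


def moment_arm_matrix(model, posture: Posture, actuators: list[Actuator]) -> np.ndarray:
    """r[i, j]: DOF i x actuator j, coordinate sign convention."""
    h = _FD_STEP_DEG
    R = np.zeros((len(DOFS), len(actuators)))
    for i, dof in enumerate(DOFS):
        pp = pose_limb(model, _perturbed(posture, dof, +h), validate=False)
        pm = pose_limb(model, _perturbed(posture, dof, -h), validate=False)
        for j, act in enumerate(actuators):
            R[i, j] = -(act.length(pp) - act.length(pm)) / (2.0 * np.radians(h))
    R[np.abs(R) < 1e-12] = 0.0
    return R


def _external_wrench_points(model, loads: ExternalLoads):
    """(segment, local point, force) plus (segment, moment) of external loads."""
    forces = [("pes", loads.cop_local, loads.grf)]
    for seg in model.segments.values():
        forces.append(
            (seg.name, seg.com_local, np.array([0.0, 0.0, -loads.segment_weights[seg.name]]))
        )
    moments = [("pes", loads.applied_moment)]
    return forces, moments


def generalized_external_moments(model, posture: Posture, loads: ExternalLoads) -> np.ndarray:
    """Virtual-work projection of external loads onto the free DOFs.

    M_ext[i] = sum F . dp/dq_i + sum M . domega/dq_i, by central finite
    difference of the forward kinematics (load vectors held fixed,
    attached to their material points).
    """
    h = _FD_STEP_DEG
    forces, moments = _external_wrench_points(model, loads)
    out = np.zeros(len(DOFS))
    for i, dof in enumerate(DOFS):
        pp = pose_limb(model, _perturbed(posture, dof, +h), validate=False)
        pm = pose_limb(model, _perturbed(posture, dof, -h), validate=False)
        dq = 2.0 * np.radians(h)
        m = 0.0
        for seg, pt, f in forces:
            dp = (pp.to_global(seg, pt) - pm.to_global(seg, pt)) / dq
            m += f @ dp
        for seg, mv in moments:
            dR = (pp.rotations[seg] - pm.rotations[seg]) / dq
            W = dR @ pm.rotations[seg].T  # ~ skew(domega/dq)
            domega = np.array([W[2, 1], W[0, 2], W[1, 0]])
            m += mv @ domega
        out[i] = m
    return out


# ---------------------------------------------------------------------------
# static optimization (box-constrained minimum-norm QP)
# ---------------------------------------------------------------------------


def _box_least_norm(A, b, lb, ub, tol=1e-10, max_iter=200):
    """min 1/2|x|^2 s.t. Ax=b, lb<=x<=ub, by semismooth Newton on the dual.

    KKT: x = clip(A^T lam, lb, ub); solve g(lam) = A x(lam) - b = 0.
    """
    m = A.shape[0]
    lam = np.zeros(m)
    scale = max(1.0, np.abs(b).max())

    def x_of(l):
        return np.clip(A.T @ l, lb, ub)

    g = A @ x_of(lam) - b
    for _ in range(max_iter):
        if np.abs(g).max() < tol * scale:
            break
        y = A.T @ lam
        # inclusive at the kink (generalized derivative), else the
        # iteration stalls when variables sit exactly on a bound
        free = (y >= lb - 1e-14) & (y <= ub + 1e-14)
        J = (A[:, free] @ A[:, free].T) + 1e-12 * np.eye(m)
        step = np.linalg.solve(J, -g)
        # damped line search on |g|
        t = 1.0
        g0 = np.linalg.norm(g)
        for _ in range(40):
            cand = lam + t * step
            gc = A @ x_of(cand) - b
            if np.linalg.norm(gc) < (1.0 - 1e-4 * t) * g0:
                lam, g = cand, gc
                break
            t *= 0.5
        else:  # stalled
            break
    return x_of(lam), g


@dataclass
class ActivationSolution:
    activations: dict[str, float]
    forces: dict[str, float]  # a * f_max, N
    mtp_reserve_moment: float  # Nm
    objective: float  # sum a^2 (muscles+ligaments) + weighted reserve term
    residuals: np.ndarray  # per-DOF moment balance residual, Nm
    dofs: tuple[str, ...] = DOFS
    moment_arms: np.ndarray | None = None
    external_moments: np.ndarray | None = None
    actuator_names: list[str] = field(default_factory=list)


def solve_static_optimization(
    model,
    posed: PosedLimb,
    loads: ExternalLoads,
    actuators: list[Actuator] | None = None,
    reserve_weight: float = 1.0,
    reserve_capacity: float = MTP_RESERVE_CAPACITY,
    tol: float = 1e-8,
) -> ActivationSolution:
    """Minimize sum of squared activations subject to moment balance.

    Inactive actuators are excluded (zero force).  The MTP reserve
    enters only the MTP balance row, with activation M/1000 Nm and a
    quadratic objective weight ``reserve_weight``.
    """
    posture = posed.posture
    all_acts = actuators if actuators is not None else model.actuators
    acts = [a for a in all_acts if a.active]
    R = moment_arm_matrix(model, posture, acts)
    m_ext = generalized_external_moments(model, posture, loads)

    n = len(acts)
    gains = np.array([a.f_max for a in acts])
    # equality rows: sum_j a_j Fmax_j r_ij + G*s (MTP row) = -M_ext_i
    A = np.zeros((len(DOFS), n + 1))
    A[:, :n] = R * gains
    A[DOFS.index("mtp_angle"), n] = reserve_capacity
    b = -m_ext

    # scale variables so the objective is 1/2|y|^2: y_j = sqrt(w_j) a_j
    w = np.concatenate([np.ones(n), [reserve_weight]])
    sw = np.sqrt(w)
    At = A / sw
    lb = np.concatenate([np.zeros(n), [-np.sqrt(reserve_weight)]])
    ub = np.concatenate([np.ones(n), [np.sqrt(reserve_weight)]])

    y, g = _box_least_norm(At, b, lb, ub, tol=tol * 0.01)
    x = y / sw
    residual = A @ x - b
    mag = max(1.0, np.abs(b).max())
    if np.abs(residual).max() > max(tol * mag, 1e-6):
        bad = [(DOFS[i], residual[i]) for i in np.where(np.abs(residual) > tol * mag)[0]]
        raise InfeasibleError([d for d, _ in bad], [r for _, r in bad])

    a = x[:n]
    s = x[n]
    names = [ac.name for ac in acts]
    activations = {ac.name: 0.0 for ac in all_acts}
    activations.update({nm: float(ai) for nm, ai in zip(names, a)})
    forces = {ac.name: float(activations[ac.name] * ac.f_max) for ac in all_acts}
    return ActivationSolution(
        activations=activations,
        forces=forces,
        mtp_reserve_moment=float(s * reserve_capacity),
        objective=float((a**2).sum() + reserve_weight * s**2),
        residuals=A @ x + m_ext,
        moment_arms=R,
        external_moments=m_ext,
        actuator_names=names,
    )


# ---------------------------------------------------------------------------
# actuator line of action and joint reactions
# ---------------------------------------------------------------------------


def actuator_force_directions(actuator: Actuator, posed: PosedLimb) -> tuple[np.ndarray, np.ndarray]:
    """Unit path tangents at origin and insertion, pointing away from
    the attachment (the direction the attachment is pulled)."""
    pts = actuator.posed_points(posed)
    segs = np.diff(pts, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    if (lens < 1e-12).any():
        raise ValueError(f"{actuator.name}: degenerate (zero-length) path segment")
    return segs[0] / lens[0], -segs[-1] / lens[-1]


def actuator_point_forces(actuator: Actuator, tension: float, posed: PosedLimb):
    """Force exerted by the actuator at each path point on its host segment.

    The polyline under tension T pulls each attachment/via point along
    the local tangents; the forces sum to zero over the whole path.
    Returns a list of (segment, global point, force vector).
    """
    pts = actuator.posed_points(posed)
    segs = np.diff(pts, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    if (lens < 1e-12).any():
        raise ValueError(f"{actuator.name}: degenerate (zero-length) path segment")
    t = segs / lens[:, None]
    out = []
    for k, (seg_name, _) in enumerate(actuator.path):
        f = np.zeros(3)
        if k < len(t):
            f += tension * t[k]
        if k > 0:
            f -= tension * t[k - 1]
        out.append((seg_name, pts[k], f))
    return out


@dataclass
class JointLoads:
    """Reaction force/moment exerted on the distal segment by the
    proximal segment at each joint, in the global frame."""

    forces: dict[str, np.ndarray]
    moments: dict[str, np.ndarray]
    segment_residuals: dict[str, float] = field(default_factory=dict)


_CHAIN = ("pes", "tarsometatarsus", "shank", "thigh")  # distal -> proximal
_JOINT_OF_SEGMENT = {"pes": "mtp", "tarsometatarsus": "ankle", "shank": "knee", "thigh": "hip"}


def joint_reactions(
    model, posed: PosedLimb, solution: ActivationSolution, loads: ExternalLoads
) -> JointLoads:
    """Newton-Euler balance, distal to proximal, under gravity, actuator
    point forces, the MTP reserve moment and the external loads.

    Quasi-static (zero accelerations): the reaction at a joint equals
    minus the resultant of everything applied to the distal subtree.
    """
    # collect applied forces/moments per segment
    seg_forces = {s: [] for s in model.segments}  # (point, force)
    seg_moments = {s: [] for s in model.segments}
    g = model.gravity
    for seg in model.segments.values():
        p = posed.to_global(seg.name, seg.com_local)
        seg_forces[seg.name].append((p, np.array([0.0, 0.0, -seg.mass * g])))
    seg_forces["pes"].append((loads.cop, loads.grf))
    seg_moments["pes"].append(loads.applied_moment)
    act_lookup = {a.name: a for a in model.actuators}
    for name, tension in solution.forces.items():
        if tension == 0.0:
            continue
        for seg_name, pt, f in actuator_point_forces(act_lookup[name], tension, posed):
            seg_forces[seg_name].append((pt, f))
    # MTP reserve: internal moment pair between tarsometatarsus and pes
    mtp_axis = posed.direction_to_global("tarsometatarsus", model.joints["mtp"].axis)
    reserve_vec = solution.mtp_reserve_moment * mtp_axis
    seg_moments["pes"].append(reserve_vec)
    seg_moments["tarsometatarsus"].append(-reserve_vec)

    forces, moments = {}, {}
    acc_f = np.zeros(3)
    acc_m = np.zeros(3)  # about origin
    for seg in _CHAIN:
        for p, f in seg_forces[seg]:
            acc_f += f
            acc_m += np.cross(p, f)
        for mv in seg_moments[seg]:
            acc_m += mv
        joint = _JOINT_OF_SEGMENT[seg]
        jdef = model.joints[joint]
        centre = posed.to_global(jdef.parent, jdef.centre)
        forces[joint] = -acc_f
        moments[joint] = -(acc_m - np.cross(centre, acc_f))
        # the reaction closes the subtree balance; continue accumulating
    jl = JointLoads(forces=forces, moments=moments)
    # per-segment equilibrium residuals (audit): applied + joint reactions
    child_joint = {"tarsometatarsus": "mtp", "shank": "ankle", "thigh": "knee", "pelvis": "hip"}
    for seg in _CHAIN:
        f_net = np.zeros(3)
        m_net = np.zeros(3)
        jprox = _JOINT_OF_SEGMENT[seg]
        centre = posed.to_global(model.joints[jprox].parent, model.joints[jprox].centre)
        f_net += forces[jprox]
        m_net += moments[jprox]
        for p, f in seg_forces[seg]:
            f_net += f
            m_net += np.cross(p - centre, f)
        for mv in seg_moments[seg]:
            m_net += mv
        if seg in child_joint:
            jd = model.joints[child_joint[seg]]
            c2 = posed.to_global(jd.parent, jd.centre)
            f_net -= forces[child_joint[seg]]
            m_net -= moments[child_joint[seg]] + np.cross(c2 - centre, forces[child_joint[seg]])
        jl.segment_residuals[seg] = float(max(np.abs(f_net).max(), np.abs(m_net).max()))
    return jl
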