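"""Joint definitions, posture parameterization and forward posing.

Global frame: +x anterior, +y medial, +z dorsal (right limb); the
pelvis is fixed at the identity.  In the neutral posture (all joint
angles zero) every bone's anatomical axes are parallel to the global
axes with +z proximal, i.e. the limb hangs as a straight vertical
column under the hip.

Posture angles (degrees):

* ``hip_extension`` — femur long axis relative to the *horizontal*;
  negative values point the femur anteroventrally (the avian mid-stance
  convention: -30 means 30 degrees below horizontal).
* ``hip_abduction`` — positive abducts (knee moves laterally).
* ``hip_lar`` — long-axis rotation, positive = external rotation.
* ``knee_flexion``, ``ankle_flexion`` — relative to the proximal
  segment, positive = flexed.
* ``mtp_angle`` — metatarsophalangeal angle from neutral, positive =
  extension; normally set so the pes lies flat on the ground.

The hip rotation is composed flexion-extension, then adduction-
abduction, then long-axis rotation (intrinsic order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

#: articulating bone pairs whose (soft-tissue bridged) proximity is intended
ARTICULATING_PAIRS = {
    frozenset(("pelvis", "femur")),
    frozenset(("femur", "tibiotarsus_fibula")),
    frozenset(("tibiotarsus_fibula", "tarsometatarsus")),
    frozenset(("tarsometatarsus", "pes")),
}

POSTURE_RANGES = {
    "hip_extension": (-85.0, 25.0),
    "hip_abduction": (-25.0, 40.0),
    "hip_lar": (-25.0, 55.0),
    "knee_flexion": (10.0, 145.0),
    "ankle_flexion": (0.0, 125.0),
    "mtp_angle": (-60.0, 85.0),
}


class PostureRangeError(ValueError):
    pass


@dataclass(frozen=True)
class JointDefinition:
    name: str
    type: str  # 'ball_and_socket' | 'hinge'
    parent: str
    child: str
    centre: np.ndarray  # parent-segment frame
    axis: np.ndarray | None = None  # hinge axis, parent-segment frame

    def __post_init__(self):
        object.__setattr__(self, "centre", np.asarray(self.centre, float))
        if self.type == "hinge":
            a = np.asarray(self.axis, float)
            n = np.linalg.norm(a)
            if abs(n - 1.0) > 1e-9:
                a = a / n
            object.__setattr__(self, "axis", a)


@dataclass(frozen=True)
class Posture:
    hip_extension: float = -30.0
    hip_abduction: float = 5.0
    hip_lar: float = 20.0
    knee_flexion: float = 93.0
    ankle_flexion: float = 46.0
    mtp_angle: float = 16.0

    def as_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "Posture":
        d = self.as_dict()
        d.update(kw)
        return Posture(**d)

    def validate(self) -> None:
        for k, (lo, hi) in POSTURE_RANGES.items():
            v = getattr(self, k)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise PostureRangeError(f"{k}={v} outside declared range [{lo}, {hi}]")


#: the general avian mid-stance starting posture
START_POSTURE = Posture(-30.0, 5.0, 20.0, 93.0, 46.0, 16.0)


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def hip_rotation(posture: Posture) -> np.ndarray:
    """FE -> AB/AD -> LAR, intrinsic.

    FE is a rotation about the mediolateral (y) axis taking the neutral
    (vertical, -z distal) femur to ``hip_extension`` degrees from the
    horizontal; abduction is about the anterior (x) axis (positive
    lateral for the right limb, i.e. toward -y); LAR is about the femur
    long axis (positive external).
    """
    fe = rot_y(-(90.0 + posture.hip_extension))
    ab = rot_x(-posture.hip_abduction)
    lar = rot_z(-posture.hip_lar)
    return fe @ ab @ lar


@dataclass
class PosedLimb:
    """Per-segment rigid transforms and derived posture geometry."""

    rotations: dict[str, np.ndarray]
    translations: dict[str, np.ndarray]
    posture: Posture
    com: np.ndarray | None = None  # whole-body COM, global
    cop: np.ndarray | None = None  # pes centroid, global
    hip_centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ground_z: float = 0.0

    def to_global(self, segment: str, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.rotations[segment].T + self.translations[segment]

    def direction_to_global(self, segment: str, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, float) @ self.rotations[segment].T

    @property
    def hip_height(self) -> float:
        return float(self.hip_centre[2] - self.ground_z)

    def posed_block(self, model, bone: str):
        seg = model.segment_of_bone(bone)
        return model.blocks[bone].transformed(self.rotations[seg], self.translations[seg])


_SEGMENT_JOINTS = [("thigh", "hip"), ("shank", "knee"), ("tarsometatarsus", "ankle"), ("pes", "mtp")]


def pose_limb(model, posture: Posture, validate: bool = True) -> PosedLimb:
    """Compose segment transforms down the chain hip -> knee -> ankle -> MTP."""
    if validate:
        posture.validate()
    rotations = {"pelvis": np.eye(3)}
    translations = {"pelvis": np.zeros(3)}
    local_rot = {
        "thigh": hip_rotation(posture),
        "shank": rot_y(posture.knee_flexion),
        "tarsometatarsus": rot_y(-posture.ankle_flexion),
        "pes": rot_y(posture.mtp_angle),
    }
    for seg, joint in _SEGMENT_JOINTS:
        j = model.joints[joint]
        Rp, tp = rotations[j.parent], translations[j.parent]
        rotations[seg] = Rp @ local_rot[seg]
        translations[seg] = Rp @ j.centre + tp

    posed = PosedLimb(rotations, translations, posture)
    posed.hip_centre = translations["thigh"].copy()
    pes_block = posed.posed_block(model, "pes")
    pes_nodes = pes_block.node_array()
    posed.ground_z = float(pes_nodes[:, 2].min())
    posed.cop = pes_nodes.mean(axis=0)
    posed.com = whole_body_com(posed, model)
    return posed


def flat_foot_mtp(model, posture: Posture) -> float:
    """MTP angle positioning the pes flat on the ground (sole horizontal).

    Maximizes the vertical component of the pes dorsal axis over the
    single MTP degree of freedom; with zero hip abduction/rotation this
    makes the pes exactly parallel to the x-y plane.
    """
    probe = pose_limb(model, posture.replace(mtp_angle=0.0), validate=False)
    R = probe.rotations["tarsometatarsus"]
    return float(np.degrees(np.arctan2(R[2, 0], R[2, 2])))


def whole_body_com(posed: PosedLimb, model) -> np.ndarray:
    """Mass-weighted mean of segment COMs in the global frame."""
    total = model.body_mass
    if total <= 0:
        raise ValueError("zero total mass")
    acc = np.zeros(3)
    for seg in model.segments.values():
        acc += seg.mass * posed.to_global(seg.name, seg.com_local)
    return acc / total


@dataclass
class ConstraintReport:
    no_interpenetration: bool
    min_bone_clearance: float  # m, over checked (non-articulating) pairs
    cop_under_com: bool
    cop_com_dx: float  # m, anteroposterior COP-COM offset
    step_width_ok: bool
    step_width_ratio: float  # (2 |COP_y|) / hip height
    details: dict = field(default_factory=dict)

    @property
    def all_ok(self) -> bool:
        return self.no_interpenetration and self.cop_under_com and self.step_width_ok


def _hull_contains(hull_points: np.ndarray, query: np.ndarray) -> int:
    tri = Delaunay(hull_points[ConvexHull(hull_points).vertices])
    return int((tri.find_simplex(query) >= 0).sum())


def check_posture_constraints(
    posed: PosedLimb,
    model,
    cop_tol: float = 1e-3,
    step_width_limit: float = 0.15,
) -> ConstraintReport:
    """Evaluate the three admissibility criteria for a posed limb.

    1. no bone-bone interpenetration between non-articulating bones
       (articulating pairs are bridged by soft tissue and whitelisted);
    2. pes centroid (COP) under the whole-body COM in x, within
       ``cop_tol`` (the mediolateral offset is absorbed by the Mx
       correction, and a residual x offset by My);
    3. step width (twice |COP_y|) below ``step_width_limit`` of hip height.
    """
    bones = ["pelvis", "femur", "tibiotarsus_fibula", "tarsometatarsus", "pes"]
    surfs = {}
    for b in bones:
        seg = model.segment_of_bone(b)
        surf = model.bone_surface(b)
        surfs[b] = posed.to_global(seg, surf.vertices[np.unique(surf.triangles)])

    n_inside = 0
    clearance = np.inf
    pair_details = {}
    for i, a in enumerate(bones):
        for b in bones[i + 1 :]:
            if frozenset((a, b)) in ARTICULATING_PAIRS:
                continue
            inside = _hull_contains(surfs[b], surfs[a]) + _hull_contains(surfs[a], surfs[b])
            d = float(cKDTree(surfs[a]).query(surfs[b])[0].min())
            n_inside += inside
            clearance = min(clearance, d)
            pair_details[f"{a}|{b}"] = dict(points_inside=inside, min_distance=d)

    dx = float(posed.cop[0] - posed.com[0])
    ratio = 2.0 * abs(float(posed.cop[1])) / posed.hip_height
    return ConstraintReport(
        no_interpenetration=(n_inside == 0),
        min_bone_clearance=float(clearance),
        cop_under_com=abs(dx) <= cop_tol,
        cop_com_dx=dx,
        step_width_ok=ratio < step_width_limit,
        step_width_ratio=ratio,
        details=pair_details,
    )


@dataclass
class CrouchResult:
    value: float
    metric: str

    def __float__(self) -> float:
        return self.value


def _crouch_hip_height_ratio(posed: PosedLimb, model) -> float:
    p = model.params
    limb_length = (
        p.femur_length + p.tibiotarsus_length + p.tarsometatarsus_length + p.pes_height
    )
    if limb_length <= 0:
        raise ValueError("zero limb length")
    return 1.0 - posed.hip_height / limb_length


CROUCH_METRICS = {"one_minus_hip_height_ratio": _crouch_hip_height_ratio}


def degree_of_crouch(
    posed: PosedLimb, model, metric: str = "one_minus_hip_height_ratio"
) -> CrouchResult:
    """Scalar limb-flexion summary; 0 for a fully extended vertical limb.

    The metric is pluggable (``CROUCH_METRICS`` registry) because the
    literature definition this emulates is not uniquely fixed; the
    default is 1 - hip height / total functional limb length.
    """
    return CrouchResult(value=float(CROUCH_METRICS[metric](posed, model)), metric=metric)
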