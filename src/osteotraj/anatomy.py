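"""Idealized bipedal hindlimb anatomy: meshes, materials, synthetic geometry.

The synthetic generator produces a bird-like right hindlimb — femur
(shaft + medially offset spherical head + flared condylar end),
tibiotarsus with anterior cnemial-crest flare and a lateral fibular
lobe that merges distally, tarsometatarsus, a rectangular-prism pes and
a pelvis (acetabular) stub — together with the soft-tissue volumes that
bridge each articulation.  All volumes are conformal structured tet
meshes (see :mod:`osteotraj.meshing`), so bonded interfaces share nodes
exactly.

Units are SI throughout (m, kg, N, Pa); material tables quoted in MPa
are converted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import meshing
from .meshing import StructuredBlock

GRAVITY = 9.81

#: isotropic linear-elastic materials (MPa values converted to Pa)
DEFAULT_MATERIALS = {
    "bone": dict(density=2060.0, youngs_modulus=17_000e6, poissons_ratio=0.3),
    "cartilage": dict(density=1100.0, youngs_modulus=50e6, poissons_ratio=0.45),
    "knee_soft_tissue": dict(density=1100.0, youngs_modulus=100e6, poissons_ratio=0.3),
}


class GenerationError(RuntimeError):
    """Raised when synthetic meshing produces an invalid mesh."""


@dataclass(frozen=True)
class Material:
    density: float  # kg/m^3
    youngs_modulus: float  # Pa
    poissons_ratio: float

    def __post_init__(self):
        if self.youngs_modulus <= 0 or self.density <= 0:
            raise ValueError("E and density must be positive")
        if not (0.0 <= self.poissons_ratio < 0.5):
            raise ValueError("Poisson's ratio must be in [0, 0.5)")


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (n, 3) m
    triangles: np.ndarray  # (m, 3) int
    name: str = ""

    @property
    def area(self) -> float:
        a = self.vertices[self.triangles[:, 1]] - self.vertices[self.triangles[:, 0]]
        b = self.vertices[self.triangles[:, 2]] - self.vertices[self.triangles[:, 0]]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())

    def edge_counts(self) -> np.ndarray:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        return counts

    def is_watertight(self) -> bool:
        return bool((self.edge_counts() == 2).all())

    def mean_edge_length(self) -> float:
        return mean_edge_length(self.area, len(self.triangles))


@dataclass
class VolumeMesh:
    nodes: np.ndarray  # (n, 3) m
    tets: np.ndarray  # (m, 4) int
    entity_ids: np.ndarray  # (m,) int, index into entity_names
    entity_names: list[str]

    def tet_volumes(self) -> np.ndarray:
        return meshing.tet_volumes(self.nodes, self.tets)

    def entity_tets(self, name: str) -> np.ndarray:
        return self.tets[self.entity_ids == self.entity_names.index(name)]

    def entity_nodes(self, name: str) -> np.ndarray:
        """Indices of nodes referenced by an entity's tets."""
        return np.unique(self.entity_tets(name))

    def surface_of(self, name: str) -> SurfaceMesh:
        tri = meshing.boundary_triangles(self.nodes, self.entity_tets(name))
        return SurfaceMesh(self.nodes, tri, name=name)

    def surface_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.surface_of(name).triangles)


@dataclass
class Segment:
    name: str
    mass: float  # kg
    com_local: np.ndarray  # segment frame, m
    bones: tuple[str, ...] = ()  # attached bone mesh names

    def __post_init__(self):
        if self.mass < 0:
            raise ValueError("segment mass must be >= 0")
        self.com_local = np.asarray(self.com_local, float)


@dataclass(frozen=True)
class LimbParams:
    """Shape, mass and resolution parameters of the synthetic limb.

    Defaults emulate a 1.56 kg adult chicken: right-hindlimb mass
    0.159 kg (so the pelvis segment — body minus the modelled limb —
    is 1.401 kg), femur ~75 mm, and bone proportions of a mid-sized
    ground bird.  The pelvis-segment COM sits 0.068 m anterior to the
    hip, level with it.
    """

    body_mass: float = 1.56
    thigh_mass: float = 0.100
    shank_mass: float = 0.045
    tarsometatarsus_mass: float = 0.010
    pes_mass: float = 0.004
    pelvis_com_anterior: float = 0.068

    femur_length: float = 0.075
    tibiotarsus_length: float = 0.110
    tarsometatarsus_length: float = 0.072
    pes_length: float = 0.055
    pes_width: float = 0.014
    pes_height: float = 0.008

    head_radius: float = 0.0045
    head_offset: float = 0.0045  # medial offset of head centre from shaft axis
    shaft_radius: float = 0.0042
    condyle_halfwidth: float = 0.006  # femur distal mediolateral semi-axis
    cnemial_crest: float = 0.0045  # anterior flare of the proximal tibiotarsus
    fibular_lobe: float = 0.0030  # lateral flare representing the fused fibula
    joint_gap: float = 0.004  # bone end face to joint centre, per side

    # cross-section grid is n x n cells; axial station spacing ~ this
    section_cells: int = 4
    axial_spacing: float = 0.0034

    @property
    def limb_mass(self) -> float:
        return self.thigh_mass + self.shank_mass + self.tarsometatarsus_mass + self.pes_mass

    @property
    def pelvis_mass(self) -> float:
        return self.body_mass - self.limb_mass


@dataclass
class LimbModel:
    """Full musculoskeletal description of the idealized hindlimb."""

    params: LimbParams
    segments: dict[str, Segment]
    joints: dict  # name -> kinematics.JointDefinition
    actuators: list  # statics.Actuator
    blocks: dict[str, StructuredBlock]  # bone volumes, segment-local frames
    materials: dict[str, Material]
    entity_materials: dict[str, str]  # entity name -> material name
    metadata: dict = field(default_factory=dict)
    gravity: float = GRAVITY

    @property
    def body_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    @property
    def body_weight(self) -> float:
        return self.body_mass * self.gravity

    def bone_volume_mesh(self, name: str) -> VolumeMesh:
        nodes, tets = self.blocks[name].volume()
        return VolumeMesh(nodes, tets, np.zeros(len(tets), dtype=np.int64), [name])

    def bone_surface(self, name: str) -> SurfaceMesh:
        return self.bone_volume_mesh(name).surface_of(name)

    def segment_of_bone(self, bone: str) -> str:
        for seg in self.segments.values():
            if bone in seg.bones:
                return seg.name
        raise KeyError(bone)


def mean_edge_length(area: float, n_triangles: int) -> float:
    """Mean triangle edge length of an isoparametric surface mesh.

    Assumes the average triangle is equilateral: L = sqrt(4 A / (sqrt(3) n)).
    The volume-mesh edge cap is twice this value.
    """
    if area <= 0 or n_triangles < 1:
        raise ValueError("area must be > 0 and n_triangles >= 1")
    return float(np.sqrt(4.0 * area / (np.sqrt(3.0) * n_triangles)))


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit; exact for noiseless data.

    Solves |p|^2 = 2 c.p + (r^2 - |c|^2) as a linear system.
    """
    p = np.asarray(points, float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise ValueError("need >= 4 three-dimensional points")
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = (p**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar/collinear) points: sphere fit failed")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise ValueError("sphere fit failed (non-positive radius)")
    return centre, float(np.sqrt(r2))


# ---------------------------------------------------------------------------
# synthetic limb generation
# ---------------------------------------------------------------------------


def _femur_stations(p: LimbParams) -> list[dict]:
    """Femur profile, distal (condyles) to proximal (spherical head).

    The head band sections are circles lying exactly on a sphere of
    radius ``head_radius`` centred at the local origin (the hip joint
    centre); the flat proximal cap truncates the sphere at 0.6 r.  The
    section centre blends medially from the shaft axis (y = -offset)
    onto the head axis over closely spaced neck stations.
    """
    g, L = p.joint_gap, p.femur_length
    rh, d, rs = p.head_radius, p.head_offset, p.shaft_radius
    cw, ca = p.condyle_halfwidth, 0.005
    st = []

    def add(z, a, b, cy):
        st.append(dict(z=z, a_ant=a, a_post=a, b_med=b, b_lat=b, cy=cy))

    zd = -(L - g)
    add(zd, ca, cw, -d)
    add(zd + 0.0028, ca, cw, -d)
    add(zd + 0.0056, 0.92 * ca, 0.88 * cw, -d)
    add(zd + 0.0084, 1.05 * rs, 0.70 * cw, -d)
    z = zd + 0.0084 + p.axial_spacing
    while z < -0.0125 - 1e-9:
        add(z, rs, rs, -d)
        z += p.axial_spacing
    zs = np.array([-0.0125, -0.0105, -0.0085, -0.0065, -0.005])
    t = (zs - zs[0]) / (zs[-1] - zs[0])
    s = t * t * (3 - 2 * t)
    for zi, si in zip(zs, s):
        r = rs * (1 - 0.12 * si)
        add(zi, r, r, -d * (1 - si))
    for f in (-0.6, -0.15, 0.25, 0.6):
        rho = np.sqrt(1.0 - f * f) * rh
        add(f * rh, rho, rho, 0.0)
    return st


def _tibfib_stations(p: LimbParams) -> list[dict]:
    """Tibiotarsus+fibula profile, distal to proximal: anterior cnemial
    crest and lateral fibular lobe proximally (the lobe merges distally,
    i.e. the fibula is fused), mild condylar widening distally."""
    g, L = p.joint_gap, p.tibiotarsus_length
    rs = 0.0045
    st = []
    z = -g
    while True:
        depth = (-z - g) / (L - 2 * g)  # 0 proximal .. 1 distal
        crest = max(0.0, 1.0 - depth / 0.28)
        fib = max(0.0, 1.0 - depth / 0.60)
        condyle = max(0.0, (depth - 0.88) / 0.12)
        st.append(
            dict(
                z=float(z),
                a_ant=rs + p.cnemial_crest * crest + 0.0008 * condyle,
                a_post=rs + 0.0012 * crest,
                b_med=rs + 0.0018 * crest + 0.0015 * condyle,
                b_lat=rs + p.fibular_lobe * fib + 0.0015 * condyle,
                cy=0.0,
            )
        )
        if z <= -(L - g) + 1e-9:
            break
        dz = 0.0026 if depth < 0.3 else p.axial_spacing
        z = max(z - dz, -(L - g))
    return list(reversed(st))


def _tmt_stations(p: LimbParams) -> list[dict]:
    g, L = p.joint_gap, p.tarsometatarsus_length
    rs = 0.0035
    st = []
    z = -g
    while True:
        depth = (-z - g) / (L - 2 * g)
        prox = max(0.0, 1.0 - depth / 0.25)
        condyle = max(0.0, (depth - 0.85) / 0.15)
        b = rs + 0.4 * (p.pes_width / 2 - rs) * condyle + 0.0010 * prox
        st.append(
            dict(z=float(z), a_ant=rs + 0.0008 * prox, a_post=rs + 0.0013 * prox,
                 b_med=b, b_lat=b, cy=0.0)
        )
        if z <= -(L - g) + 1e-9:
            break
        z = max(z - 0.0030, -(L - g))
    return list(reversed(st))


def build_bone_blocks(p: LimbParams) -> dict[str, StructuredBlock]:
    n = p.section_cells
    blocks = {
        # stations are listed distal -> proximal (ascending local z)
        "femur": meshing.sweep_block(_femur_stations(p), ni=n, nj=n),
        "tibiotarsus_fibula": meshing.sweep_block(_tibfib_stations(p), ni=n, nj=n),
        "tarsometatarsus": meshing.sweep_block(_tmt_stations(p), ni=n, nj=n),
    }
    # pes: rectangular prism, long axis anterior, base at z = -pes_height
    blocks["pes"] = meshing.box_block(
        (-0.2 * p.pes_length, 0.8 * p.pes_length),
        (-p.pes_width / 2, p.pes_width / 2),
        (-p.pes_height, 0.0),
        ni=10,
        nj=3,
        nk=2,
    )
    # pelvis (acetabular) stub: box above the femoral head; its lower face
    # is the acetabular surface bridged to the head cap by hip soft tissue
    cap_z = 0.6 * p.head_radius
    blocks["pelvis"] = meshing.box_block(
        (-0.010, 0.010),
        (-0.010, 0.010),
        (cap_z + 0.0045, cap_z + 0.0245),
        ni=n,
        nj=n,
        nk=4,
    )
    return blocks


def _segments(p: LimbParams) -> dict[str, Segment]:
    d = p.head_offset
    segs = {
        "pelvis": Segment("pelvis", p.pelvis_mass, (p.pelvis_com_anterior, 0.0, 0.0), ("pelvis",)),
        "thigh": Segment("thigh", p.thigh_mass, (0.0, -d, -p.femur_length / 2), ("femur",)),
        "shank": Segment(
            "shank", p.shank_mass, (0.0, 0.0, -p.tibiotarsus_length * 0.45), ("tibiotarsus_fibula",)
        ),
        "tarsometatarsus": Segment(
            "tarsometatarsus",
            p.tarsometatarsus_mass,
            (0.0, 0.0, -p.tarsometatarsus_length / 2),
            ("tarsometatarsus",),
        ),
        "pes": Segment("pes", p.pes_mass, (0.3 * p.pes_length, 0.0, -p.pes_height / 2), ("pes",)),
    }
    total = sum(s.mass for s in segs.values())
    if abs(total - p.body_mass) > 1e-12:
        raise GenerationError(f"segment masses sum to {total}, not body mass {p.body_mass}")
    return segs


def generate_synthetic_limb(params: LimbParams | None = None, seed: int = 0) -> LimbModel:
    """Generate the idealized hindlimb model.

    Deterministic for a given (params, seed); the seed is recorded for
    provenance and for downstream modules that fan randomness out from
    the model.
    """
    from . import kinematics
    from ._actuators import build_actuators

    p = params or LimbParams()
    for name in ("femur_length", "tibiotarsus_length", "tarsometatarsus_length", "pes_length"):
        if getattr(p, name) <= 0:
            raise GenerationError(f"{name} must be positive")

    blocks = build_bone_blocks(p)
    for name, blk in blocks.items():
        audit = meshing.mesh_audit(*blk.volume())
        if audit["min_volume"] <= 0:
            raise GenerationError(f"degenerate tets in generated {name} mesh")

    joints = {
        "hip": kinematics.JointDefinition(
            name="hip",
            type="ball_and_socket",
            parent="pelvis",
            child="thigh",
            centre=np.zeros(3),
        ),
        "knee": kinematics.JointDefinition(
            name="knee",
            type="hinge",
            parent="thigh",
            child="shank",
            centre=np.array([0.0, -p.head_offset, -p.femur_length]),
            axis=np.array([0.0, 1.0, 0.0]),
        ),
        "ankle": kinematics.JointDefinition(
            name="ankle",
            type="hinge",
            parent="shank",
            child="tarsometatarsus",
            centre=np.array([0.0, 0.0, -p.tibiotarsus_length]),
            axis=np.array([0.0, 1.0, 0.0]),
        ),
        "mtp": kinematics.JointDefinition(
            name="mtp",
            type="hinge",
            parent="tarsometatarsus",
            child="pes",
            centre=np.array([0.0, 0.0, -p.tarsometatarsus_length]),
            axis=np.array([0.0, 1.0, 0.0]),
        ),
    }

    materials = {k: Material(**v) for k, v in DEFAULT_MATERIALS.items()}
    entity_materials = {
        "femur": "bone",
        "tibiotarsus_fibula": "bone",
        "tarsometatarsus": "bone",
        "pes": "bone",
        "pelvis": "bone",
        "hip_soft": "cartilage",
        "ankle_soft": "cartilage",
        "mtp_soft": "cartilage",
        "knee_soft": "knee_soft_tissue",
    }

    model = LimbModel(
        params=p,
        segments=_segments(p),
        joints=joints,
        actuators=[],
        blocks=blocks,
        materials=materials,
        entity_materials=entity_materials,
        metadata=dict(
            seed=int(seed),
            head_centre=np.zeros(3),  # femur local frame
            head_radius=p.head_radius,
            medial_condyle_centre=np.array(
                [0.0, -p.head_offset + 0.6 * p.condyle_halfwidth,
                 -(p.femur_length - p.joint_gap - 0.003)]
            ),
            frame="+x anterior, +y medial, +z dorsal (right limb)",
        ),
    )
    # "fitted" condyle sphere: algebraic sphere through the medial half of
    # the distal articular surface (the anatomical condyle centre is kept)
    surf = model.bone_surface("femur")
    v = surf.vertices[np.unique(surf.triangles)]
    zd = -(p.femur_length - p.joint_gap)
    sel = (v[:, 2] < zd + 0.0065) & (v[:, 1] > -p.head_offset)
    try:
        _, cr = fit_sphere(v[sel])
    except ValueError:
        cr = p.condyle_halfwidth
    model.metadata["medial_condyle_radius"] = float(min(cr, 2.0 * p.condyle_halfwidth))
    model.actuators = build_actuators(model)
    return model


def femoral_head_points(model: LimbModel) -> np.ndarray:
    """Femur surface nodes lying on the spherical head band (local frame)."""
    surf = model.bone_surface("femur")
    v = surf.vertices[np.unique(surf.triangles)]
    rh = model.metadata["head_radius"]
    r = np.linalg.norm(v - model.metadata["head_centre"], axis=1)
    # lateral surface of the head band only (the flat end cap is off-sphere)
    on_band = (np.abs(r - rh) < 0.03 * rh) & (v[:, 2] < 0.6 * rh - 1e-9)
    return v[on_band]
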