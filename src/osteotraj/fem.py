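"""Linear-elastic 4-node tetrahedral finite elements.

Implements the bone-loading simulations: constant-strain tets, bonded
(node-shared) interfaces, muscle forces spread over ~20 surface nodes,
joint forces introduced through neighbouring-bone "bookend" structures
via statically equivalent remote-point distributions, joint moments as
equivalent nodal couples, segment weight via a remote point at the
segment COM, restraints on bookend outer faces, and inertia relief for
unrestrained load sets.

Per posture two simulations are assembled from the same joint loads:
the femur (restrained at the acetabular bookend, knee force applied via
the proximal-crus bookend) and the tibiotarsus+fibula (restrained at
the proximal-tarsometatarsus bookend, knee force via the distal-femur
bookend).  The ankle joint moment is deliberately not applied in the
tibiotarsus simulation (the restraint sits too close to transmit it
meaningfully); a flag can enable it for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import meshing
from .anatomy import Material, VolumeMesh
from .statics import actuator_point_forces


class AssemblyError(RuntimeError):
    pass


class RankDeficiencyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# core element machinery
# ---------------------------------------------------------------------------


def elasticity_matrix(material: Material) -> np.ndarray:
    """Isotropic D (6x6), Voigt order (xx, yy, zz, xy, yz, zx), engineering shear."""
    E, nu = material.youngs_modulus, material.poissons_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


def _element_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Shape-function gradients (ntet, 4, 3) and volumes (ntet,)."""
    X = nodes[tets]  # (m, 4, 3)
    M = X[:, 1:] - X[:, :1]  # (m, 3, 3)
    detM = np.linalg.det(M)
    vols = detM / 6.0
    if np.any(vols <= 0):
        bad = int(np.argmax(vols <= 0))
        raise AssemblyError(f"inverted tetrahedron at element {bad}")
    invM = np.linalg.inv(M)
    g123 = np.transpose(invM, (0, 2, 1))  # rows: grad of barycentric 1..3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vols


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement B (ntet, 6, 12) in Voigt engineering order."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def assemble_stiffness(mesh: VolumeMesh, materials: dict[str, Material]) -> sp.csr_matrix:
    """Global stiffness; SPD up to exactly 6 rigid-body modes before restraints."""
    grads, vols = _element_gradients(mesh.nodes, mesh.tets)
    B = _b_matrices(grads)
    D = np.zeros((len(mesh.tets), 6, 6))
    for i, name in enumerate(mesh.entity_names):
        D[mesh.entity_ids == i] = elasticity_matrix(materials[name])
    Ke = np.einsum("eji,ejk,ekl,e->eil", B, D, B, vols)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * len(mesh.nodes)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def element_stresses(mesh: VolumeMesh, materials: dict[str, Material], u: np.ndarray):
    grads, vols = _element_gradients(mesh.nodes, mesh.tets)
    B = _b_matrices(grads)
    D = np.zeros((len(mesh.tets), 6, 6))
    for i, name in enumerate(mesh.entity_names):
        D[mesh.entity_ids == i] = elasticity_matrix(materials[name])
    ue = u.reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    sig = np.einsum("eij,ejk,ek->ei", D, B, ue)  # Voigt per element
    return sig, vols


def _voigt_to_tensor(sig: np.ndarray) -> np.ndarray:
    t = np.zeros(sig.shape[:-1] + (3, 3))
    t[..., 0, 0] = sig[..., 0]
    t[..., 1, 1] = sig[..., 1]
    t[..., 2, 2] = sig[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = sig[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = sig[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = sig[..., 5]
    return t


@dataclass
class StressField:
    """Per-node symmetric stress tensors over one entity of a mesh."""

    node_ids: np.ndarray  # indices into the model mesh nodes
    points: np.ndarray  # (n, 3) global coordinates
    tensors: np.ndarray  # (n, 3, 3) Pa
    entity: str = ""


def nodal_stress(
    mesh: VolumeMesh, materials: dict[str, Material], u: np.ndarray, entity: str
) -> StressField:
    """Volume-weighted average of adjacent-element stresses, restricted
    to the tets of one entity (stress is discontinuous across material
    interfaces, so averaging never mixes entities)."""
    sig, vols = element_stresses(mesh, materials, u)
    eid = mesh.entity_names.index(entity)
    mask = mesh.entity_ids == eid
    sig, vols, tets = sig[mask], vols[mask], mesh.tets[mask]
    n = len(mesh.nodes)
    acc = np.zeros((n, 6))
    wacc = np.zeros(n)
    for a in range(4):
        np.add.at(acc, tets[:, a], sig * vols[:, None])
        np.add.at(wacc, tets[:, a], vols)
    ids = np.unique(tets)
    avg = acc[ids] / wacc[ids, None]
    return StressField(
        node_ids=ids, points=mesh.nodes[ids], tensors=_voigt_to_tensor(avg), entity=entity
    )


# ---------------------------------------------------------------------------
# loads
# ---------------------------------------------------------------------------


@dataclass
class FEModel:
    mesh: VolumeMesh
    materials: dict[str, Material]
    loads: np.ndarray = None  # (n, 3) nodal forces
    restrained: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    use_inertia_relief: bool = False
    log: list = field(default_factory=list)

    def __post_init__(self):
        if self.loads is None:
            self.loads = np.zeros_like(self.mesh.nodes)


def distribute_point_force(
    model: FEModel, force: np.ndarray, focal_node: int, spread_count: int = 20
) -> np.ndarray:
    """Spread a point force evenly over ~``spread_count`` surface nodes
    of the focal node's entity, centred about the focal node."""
    eid = None
    for i, name in enumerate(model.mesh.entity_names):
        if focal_node in model.mesh.entity_nodes(name):
            eid = name
            break
    surf = model.mesh.surface_nodes(eid)
    if len(surf) < spread_count:
        spread_count = len(surf)
    tree = cKDTree(model.mesh.nodes[surf])
    _, idx = tree.query(model.mesh.nodes[focal_node], k=spread_count)
    chosen = surf[np.atleast_1d(idx)]
    per = np.asarray(force, float) / len(chosen)
    model.loads[chosen] += per
    return chosen


def apply_remote_force(
    model: FEModel,
    remote_point: np.ndarray,
    force: np.ndarray,
    scoped_nodes: np.ndarray,
) -> np.ndarray:
    """Statically equivalent minimum-norm nodal load set on the scoped
    nodes: resultant equals ``force`` and resultant moment about the
    remote point is zero (the net force line of action passes through
    the remote point)."""
    nodes = np.asarray(scoped_nodes)
    if len(nodes) == 0:
        raise ValueError("empty remote-force scope")
    f = _equivalent_load(model.mesh.nodes[nodes], remote_point, np.asarray(force, float), np.zeros(3))
    model.loads[nodes] += f
    return f


def apply_surface_moment(model: FEModel, node_set: np.ndarray, moment: np.ndarray) -> np.ndarray:
    """Pure couple applied as a minimum-norm nodal force distribution
    (zero resultant force, prescribed resultant moment about the node
    set centroid)."""
    nodes = np.asarray(node_set)
    pts = model.mesh.nodes[nodes]
    f = _equivalent_load(pts, pts.mean(axis=0), np.zeros(3), np.asarray(moment, float))
    model.loads[nodes] += f
    return f


def _equivalent_load(points: np.ndarray, about: np.ndarray, force, moment) -> np.ndarray:
    """min sum|f_i|^2 s.t. sum f_i = force, sum (r_i - about) x f_i = moment."""
    n = len(points)
    r = points - about
    G = np.zeros((6, 3 * n))
    G[:3] = np.tile(np.eye(3), n)
    # cross-product rows
    G[3, 1::3] = -r[:, 2]
    G[3, 2::3] = r[:, 1]
    G[4, 0::3] = r[:, 2]
    G[4, 2::3] = -r[:, 0]
    G[5, 0::3] = -r[:, 1]
    G[5, 1::3] = r[:, 0]
    rhs = np.concatenate([force, moment])
    lam = np.linalg.solve(G @ G.T + 1e-30 * np.eye(6), rhs)
    return (G.T @ lam).reshape(n, 3)


def nodal_masses(mesh: VolumeMesh, materials: dict[str, Material]) -> np.ndarray:
    vols = mesh.tet_volumes()
    dens = np.array([materials[n].density for n in mesh.entity_names])[mesh.entity_ids]
    m = np.zeros(len(mesh.nodes))
    for a in range(4):
        np.add.at(m, mesh.tets[:, a], 0.25 * dens * vols)
    return m


def inertia_relief(model: FEModel) -> np.ndarray:
    """Mass-proportional balancing loads cancelling the net force and
    moment of the applied load set (d'Alembert rigid-body inertia)."""
    masses = nodal_masses(model.mesh, model.materials)
    M = masses.sum()
    if M <= 0:
        raise ValueError("zero total mass")
    x = model.mesh.nodes
    c = (masses[:, None] * x).sum(axis=0) / M
    rho = x - c
    F_net = model.loads.sum(axis=0)
    M_net = np.cross(x, model.loads).sum(axis=0) - np.cross(c, F_net)
    # translational part
    corr = -(masses / M)[:, None] * F_net
    # rotational part: alpha from the rigid inertia tensor about c
    I = np.einsum("i,ij->j", masses, rho**2).sum() * np.eye(3) - np.einsum(
        "i,ij,ik->jk", masses, rho, rho
    )
    alpha = np.linalg.solve(I, M_net)
    corr -= masses[:, None] * np.cross(alpha, rho)
    model.loads += corr
    return corr


# ---------------------------------------------------------------------------
# solution
# ---------------------------------------------------------------------------


def rigid_body_modes(nodes: np.ndarray) -> np.ndarray:
    """Six rigid-body displacement modes (3n x 6)."""
    n = len(nodes)
    R = np.zeros((3 * n, 6))
    R[0::3, 0] = R[1::3, 1] = R[2::3, 2] = 1.0
    c = nodes.mean(axis=0)
    r = nodes - c
    R[1::3, 3] = -r[:, 2]
    R[2::3, 3] = r[:, 1]
    R[0::3, 4] = r[:, 2]
    R[2::3, 4] = -r[:, 0]
    R[0::3, 5] = -r[:, 1]
    R[1::3, 5] = r[:, 0]
    return R


def solve_linear_static(model: FEModel) -> tuple[np.ndarray, dict[str, StressField]]:
    """Displacement solve + per-entity nodal stress recovery.

    Restrained nodes are fixed in all translations.  Without restraints
    the model must be load-balanced (inertia relief); rigid-body modes
    are then removed by a Lagrange orthogonality constraint.
    """
    K = assemble_stiffness(model.mesh, model.materials)
    f = model.loads.ravel().copy()
    n = K.shape[0]
    u = np.zeros(n)
    if len(model.restrained):
        if model.use_inertia_relief:
            inertia_relief(model)
            f = model.loads.ravel().copy()
        fixed = np.zeros(n, dtype=bool)
        for i in np.asarray(model.restrained):
            fixed[3 * i : 3 * i + 3] = True
        free = ~fixed
        Kff = K[free][:, free].tocsc()
        try:
            u[free] = spla.spsolve(Kff, f[free])
        except Exception as exc:  # pragma: no cover
            raise RankDeficiencyError(str(exc)) from exc
    else:
        inertia_relief(model)
        f = model.loads.ravel()
        R = rigid_body_modes(model.mesh.nodes)
        A = sp.bmat([[K, sp.csr_matrix(R)], [sp.csr_matrix(R.T), None]]).tocsc()
        sol = spla.spsolve(A, np.concatenate([f, np.zeros(6)]))
        u = sol[:n]
    fields = {
        name: nodal_stress(model.mesh, model.materials, u, name)
        for name in model.mesh.entity_names
    }
    return u.reshape(-1, 3), fields


def reaction_forces(model: FEModel, u: np.ndarray) -> np.ndarray:
    K = assemble_stiffness(model.mesh, model.materials)
    r = (K @ u.ravel()).reshape(-1, 3) - model.loads
    return r


# ---------------------------------------------------------------------------
# the two bone-loading cases
# ---------------------------------------------------------------------------


def _lookup(nodes: np.ndarray):
    """Bitwise coordinate -> merged node index map."""
    key = {}
    for i, row in enumerate(np.ascontiguousarray(nodes)):
        key[row.tobytes()] = i
    def find(points):
        pts = np.ascontiguousarray(np.atleast_2d(points))
        return np.array([key[row.tobytes()] for row in pts], dtype=np.int64)
    return find


def _soft_loft(posed, model, parent_seg, child_seg, face_a, face_b, centre):
    q = posed.rotations[child_seg] @ posed.rotations[parent_seg].T
    return meshing.loft_block(face_a, face_b, centre, q)


@dataclass
class BoneCase:
    """An assembled FE case for one focal bone plus its audit trail."""

    model: FEModel
    focal: str
    focal_nodes_lookup: object = None


def build_bone_case(
    limb,
    posed,
    solution,
    joint_loads,
    loads,
    which: str = "femur",
    spread_count: int = 20,
    apply_ankle_moment: bool = False,
) -> BoneCase:
    """Assemble the femur or tibiotarsus+fibula simulation.

    Muscle/ligament forces attach to the same points used by the
    musculoskeletal statics; joint force enters via the neighbouring
    bookend as a remote force through the knee centre; the knee moment
    is applied directly to the focal bone's contact surface; segment
    weight acts via a remote point at the segment COM; the outer face
    of the far bookend is restrained in all translations.
    """
    p = limb.params
    femur = posed.posed_block(limb, "femur")
    tib = posed.posed_block(limb, "tibiotarsus_fibula")
    knee_centre = posed.to_global("thigh", limb.joints["knee"].centre)

    if which == "femur":
        pelvis = posed.posed_block(limb, "pelvis")
        nk_t = tib.shape[0]
        crus = tib.sub(nk_t - 2, nk_t)
        hip_soft = _soft_loft(
            posed, limb, "pelvis", "thigh", pelvis.face("first"), femur.face("last"),
            posed.to_global("pelvis", limb.joints["hip"].centre),
        )
        knee_soft = _soft_loft(
            posed, limb, "thigh", "shank", femur.face("first"), crus.face("last"), knee_centre
        )
        parts = [
            ("femur", femur),
            ("pelvis", pelvis),
            ("crus_bookend", crus),
            ("hip_soft", hip_soft),
            ("knee_soft", knee_soft),
        ]
        entity_mats = {
            "femur": "bone",
            "pelvis": "bone",
            "crus_bookend": "bone",
            "hip_soft": "cartilage",
            "knee_soft": "knee_soft_tissue",
        }
        focal, focal_seg = "femur", "thigh"
        restrain_face = pelvis.face("last")  # acetabulum bookend outer face
        joint_force_scope = "crus_bookend"
        joint_force = -joint_loads.forces["knee"]  # on femur, from shank
        joint_moment = -joint_loads.moments["knee"]
        moment_face = femur.face("first")  # distal femur, knee contact
        weight = loads.segment_weights["thigh"]
        com = posed.to_global("thigh", limb.segments["thigh"].com_local)
    elif which == "tibiotarsus_fibula":
        tmt = posed.posed_block(limb, "tarsometatarsus")
        nk_m = tmt.shape[0]
        femur_bk = femur.sub(0, 2)
        tmt_bk = tmt.sub(nk_m - 2, nk_m)
        knee_soft = _soft_loft(
            posed, limb, "thigh", "shank", femur_bk.face("first"), tib.face("last"), knee_centre
        )
        ankle_soft = _soft_loft(
            posed, limb, "shank", "tarsometatarsus", tib.face("first"), tmt_bk.face("last"),
            posed.to_global("shank", limb.joints["ankle"].centre),
        )
        parts = [
            ("tibiotarsus_fibula", tib),
            ("femur_bookend", femur_bk),
            ("tmt_bookend", tmt_bk),
            ("knee_soft", knee_soft),
            ("ankle_soft", ankle_soft),
        ]
        entity_mats = {
            "tibiotarsus_fibula": "bone",
            "femur_bookend": "bone",
            "tmt_bookend": "bone",
            "knee_soft": "knee_soft_tissue",
            "ankle_soft": "cartilage",
        }
        focal, focal_seg = "tibiotarsus_fibula", "shank"
        restrain_face = tmt_bk.face("first")  # proximal-tmt bookend outer face
        joint_force_scope = "femur_bookend"
        joint_force = joint_loads.forces["knee"]  # on shank, from thigh
        joint_moment = joint_loads.moments["knee"]
        moment_face = tib.face("last")  # proximal tibiotarsus, knee contact
        weight = loads.segment_weights["shank"]
        com = posed.to_global("shank", limb.segments["shank"].com_local)
    else:
        raise ValueError(which)

    nodes, tets, ent, names = meshing.merge_blocks(parts)
    mesh = VolumeMesh(nodes, tets, ent, names)
    materials = {n: limb.materials[entity_mats[n]] for n in names}
    fem = FEModel(mesh=mesh, materials=materials)
    find = _lookup(nodes)

    # muscle and ligament forces, same attachment points as the statics
    focal_surf = mesh.surface_nodes(focal)
    tree = cKDTree(nodes[focal_surf])
    act_by_name = {a.name: a for a in limb.actuators}
    for name, tension in solution.forces.items():
        if tension == 0.0:
            continue
        for seg_name, pt, fvec in actuator_point_forces(act_by_name[name], tension, posed):
            if seg_name != focal_seg:
                continue
            _, i = tree.query(pt)
            focal_node = focal_surf[int(i)]
            k = min(spread_count, len(focal_surf))
            _, idx = tree.query(nodes[focal_node], k=k)
            fem.loads[focal_surf[np.atleast_1d(idx)]] += fvec / k
            fem.log.append(("muscle", name, seg_name, tension))

    # segment weight via remote point at the segment COM, scoped to the bone
    focal_ids = mesh.entity_nodes(focal)
    apply_remote_force(fem, com, np.array([0.0, 0.0, -weight]), focal_ids)

    # knee joint force via the neighbouring bookend, through the knee centre
    scope = mesh.entity_nodes(joint_force_scope)
    apply_remote_force(fem, knee_centre, joint_force, scope)

    # knee joint moment directly on the focal bone's contact surface
    moment_nodes = find(moment_face.reshape(-1, 3))
    apply_surface_moment(fem, moment_nodes, joint_moment)

    if which == "tibiotarsus_fibula" and apply_ankle_moment:
        ankle_nodes = find(tib.face("first").reshape(-1, 3))
        apply_surface_moment(fem, ankle_nodes, joint_loads.moments["ankle"])

    fem.restrained = find(restrain_face.reshape(-1, 3))
    return BoneCase(model=fem, focal=focal)


def solve_bone_case(case: BoneCase) -> StressField:
    _, fields = solve_linear_static(case.model)
    return fields[case.focal]
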