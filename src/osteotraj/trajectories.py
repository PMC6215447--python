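"""Principal stress trajectories and fabric alignment.

Eigenanalysis of nodal stress tensors gives the principal stresses
sigma1 >= sigma2 >= sigma3 and their (axial, sign-free) directions.
The minimum principal stress sigma3 (compression) is compared with the
primary cancellous-bone fabric direction u1 in spherical scoring
regions — by default the femoral head (sphere of half the fitted head
radius, just under the loaded surface) and the medial femoral condyle
(one third of the fitted condyle radius at the condyle centre) — with
higher weight on the femoral head.  All directional statistics are
axial: means use the dominant eigenvector of the orientation tensor
(1/N) sum v v^T, and angles are arccos|a.b| in [0, 90] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEGENERACY_RTOL = 1e-6


class EmptyRegionError(ValueError):
    pass


@dataclass
class PrincipalField:
    points: np.ndarray  # (n, 3)
    values: np.ndarray  # (n, 3) eigenvalues, descending (s1 >= s2 >= s3)
    directions: np.ndarray  # (n, 3, 3); directions[:, i] is the sigma_{i+1} axis
    degenerate: np.ndarray = None  # (n,) bool: repeated-eigenvalue nodes

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.points), dtype=bool)

    def axis(self, which: str) -> np.ndarray:
        i = {"sigma1": 0, "sigma2": 1, "sigma3": 2}[which]
        return self.directions[:, i]


@dataclass
class FabricField:
    points: np.ndarray  # (n, 3)
    u1: np.ndarray  # (n, 3) unit axial vectors
    provenance: str = "imported"  # synthetic-forward | archetype | imported

    def __post_init__(self):
        self.u1 = _normalized(self.u1)


@dataclass
class RegionSpec:
    name: str
    centre: np.ndarray
    radius: float

    def __post_init__(self):
        self.centre = np.asarray(self.centre, float)
        if self.radius <= 0:
            raise ValueError("region radius must be positive")

    def mask(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - self.centre, axis=1) <= self.radius


def _normalized(v: np.ndarray, warn: bool = False) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n == 0, 1.0, n)


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic representative of an axial vector: the first
    component of magnitude > 1e-12 is made positive."""
    v = np.atleast_2d(v).copy()
    lead = np.argmax(np.abs(v) > 1e-12, axis=1)
    sign = np.sign(v[np.arange(len(v)), lead])
    sign[sign == 0] = 1.0
    return v * sign[:, None]


def principal_stresses(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and axial unit eigenvectors of one
    symmetric stress tensor."""
    t = np.asarray(tensor, float)
    if np.abs(t - t.T).max() > 1e-6 * max(1.0, np.abs(t).max()):
        raise ValueError("stress tensor not symmetric")
    w, v = np.linalg.eigh(0.5 * (t + t.T))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    return w, _canonical_sign(v.T)


def principal_field(points: np.ndarray, tensors: np.ndarray) -> PrincipalField:
    """Vectorized eigenanalysis of a nodal stress-tensor field."""
    t = 0.5 * (tensors + np.transpose(tensors, (0, 2, 1)))
    w, v = np.linalg.eigh(t)
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    dirs = np.transpose(v, (0, 2, 1))  # (n, 3 eigen, 3 comp)
    for i in range(3):
        dirs[:, i] = _canonical_sign(dirs[:, i])
    scale = np.maximum(np.abs(w).max(axis=1), 1e-300)
    degen = (np.abs(np.diff(w, axis=1)) < DEGENERACY_RTOL * scale[:, None]).any(axis=1)
    return PrincipalField(points=np.asarray(points, float), values=w, directions=dirs,
                          degenerate=degen)


def orientation_tensor(axes: np.ndarray) -> np.ndarray:
    a = _normalized(axes)
    return np.einsum("ni,nj->ij", a, a) / len(a)


def mean_axial_direction(axes: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the orientation tensor (sign-free mean)."""
    w, v = np.linalg.eigh(orientation_tensor(axes))
    return _canonical_sign(v[:, -1])[0]


def regional_mean_direction(
    points: np.ndarray,
    axes: np.ndarray,
    region: RegionSpec,
    exclude: np.ndarray | None = None,
    min_samples: int = 5,
) -> np.ndarray:
    """Axial mean direction over samples inside a spherical region.

    ``exclude`` can mask out degenerate-eigenvalue nodes whose
    directions are meaningless.
    """
    sel = region.mask(points)
    if exclude is not None:
        sel &= ~exclude
    if sel.sum() < min_samples:
        raise EmptyRegionError(
            f"region {region.name}: {int(sel.sum())} samples inside (need {min_samples})"
        )
    return mean_axial_direction(axes[sel])


def angular_deviation(a: np.ndarray, b: np.ndarray) -> float:
    """Axial angle between two directions, degrees in [0, 90]."""
    a = _normalized(np.asarray(a, float))
    b = _normalized(np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.abs(a @ b), 0.0, 1.0))))


def regional_axis(
    points: np.ndarray,
    axes: np.ndarray,
    region: RegionSpec,
    exclude: np.ndarray | None = None,
    min_samples: int = 5,
) -> np.ndarray:
    """Regional axial mean, resampling when the region is small
    relative to the field's sampling density.

    Falls back to a deterministic sub-grid of the sphere with
    nearest-sample interpolation, so region radii prescribed in
    physical units remain usable on coarse meshes.
    """
    try:
        return regional_mean_direction(points, axes, region, exclude, min_samples)
    except EmptyRegionError:
        g = region.radius / 2.5
        lin = np.arange(-region.radius, region.radius + 0.5 * g, g)
        X, Y, Z = np.meshgrid(lin, lin, lin, indexing="ij")
        q = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        q = q[np.linalg.norm(q, axis=1) <= region.radius] + region.centre
        ok = np.ones(len(points), dtype=bool) if exclude is None else ~exclude
        tree = cKDTree(points[ok])
        d, idx = tree.query(q)
        # only keep grid samples supported by the field
        support = float(np.median(tree.query(points[ok], k=2)[0][:, 1]))
        keep = d <= max(2.0 * support, region.radius)
        if keep.sum() < min_samples:
            raise
        return mean_axial_direction(axes[ok][idx[keep]])


DEFAULT_REGION_WEIGHTS = {"femoral_head": 2.0, "medial_condyle": 1.0}


@dataclass
class ScoreReport:
    region_deviation: dict[str, float]  # degrees
    weighted_score: float  # degrees (weighted mean deviation)
    weights: dict[str, float]
    region_errors: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def alignment_score(
    principal: PrincipalField,
    fabric: FabricField,
    regions: list[RegionSpec],
    weights: dict[str, float] | None = None,
    which: str = "sigma3",
) -> ScoreReport:
    """Regional angular deviation between sigma3 and u1, plus the
    weighted scalar used to rank postures (femoral head weighted above
    the medial condyle by default)."""
    weights = dict(weights or DEFAULT_REGION_WEIGHTS)
    devs, errs = {}, {}
    for region in regions:
        try:
            s_dir = regional_axis(
                principal.points, principal.axis(which), region, exclude=principal.degenerate
            )
            u_dir = regional_axis(fabric.points, fabric.u1, region)
            devs[region.name] = angular_deviation(s_dir, u_dir)
        except EmptyRegionError as exc:
            errs[region.name] = str(exc)
    if devs:
        wsum = sum(weights.get(k, 1.0) for k in devs)
        score = sum(weights.get(k, 1.0) * v for k, v in devs.items()) / wsum
    else:
        score = float("nan")
    return ScoreReport(region_deviation=devs, weighted_score=float(score),
                       weights=weights, region_errors=errs)


def percent_reduction(worst: float, best: float) -> float:
    """Percent improvement of an angular deviation from worst to best."""
    return 100.0 * (worst - best) / worst


def femoral_regions(model, sub_surface_offset: float | None = None) -> list[RegionSpec]:
    """The two scored femur regions, in the femur-local frame.

    Femoral head: sphere of half the fitted head radius, centred one
    half-radius below the loaded (proximal) surface of the head.
    Medial condyle: sphere of one third the condyle radius at the
    anatomical condyle centre.
    """
    c = np.asarray(model.metadata["head_centre"], float)
    r = float(model.metadata["head_radius"])  # fitted head sphere radius
    r_head = 0.5 * r
    if sub_surface_offset is None:
        sub_surface_offset = r_head
    head_centre = c + np.array([0.0, 0.0, r - sub_surface_offset])
    cc = np.asarray(model.metadata["medial_condyle_centre"], float)
    cr = float(model.metadata["medial_condyle_radius"])  # fitted condyle sphere radius
    return [
        RegionSpec("femoral_head", head_centre, r_head),
        RegionSpec("medial_condyle", cc, cr / 3.0),
    ]


def downsample_field(
    points: np.ndarray, axes: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation-tensor-averaged axial vectors on a regular grid.

    Grid cells that contain no samples are omitted (points outside the
    bone produce no output).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = np.asarray(points, float)
    idx = np.floor(pts / spacing).astype(np.int64)
    out_p, out_v = [], []
    _, inverse = np.unique(idx, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        sel = inverse == g
        out_p.append(pts[sel].mean(axis=0))
        out_v.append(mean_axial_direction(axes[sel]))
    if not out_p:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return np.array(out_p), np.array(out_v)


@dataclass
class MidshaftSummary:
    obliquity_deg: float  # most axis-parallel principal direction vs long axis
    torsion_sense: int  # +1 / -1 / 0
    neutral_surface_angle_deg: float  # from the mediolateral axis
    n_nodes: int


def midshaft_loading_summary(
    field: PrincipalField,
    bone_axis: np.ndarray,
    section_centre: np.ndarray,
    half_thickness: float = 0.004,
    mediolateral_axis: np.ndarray = (0.0, 1.0, 0.0),
) -> MidshaftSummary:
    """Torsion obliquity/sense and bending neutral-surface angle at a
    mid-shaft section.

    Obliquity: angle between the long axis and whichever of the sigma1
    / sigma3 mean directions is most axis-parallel (45 degrees for pure
    torsion, 0 for pure axial load).  Sense: sign of the circumferential
    drift of that direction (positive = proximal end rotated
    counterclockwise seen from proximal, for +z long axis).  Neutral
    surface: the zero line of axial stress across the section, measured
    from the mediolateral axis.
    """
    axis = _normalized(np.asarray(bone_axis, float))
    d = (field.points - section_centre) @ axis
    sel = np.abs(d) <= half_thickness
    if sel.sum() < 5:
        raise EmptyRegionError("mid-shaft slab contains too few nodes")
    pts = field.points[sel]
    # per-node angles to the long axis (a mean *direction* would cancel
    # the circumferential components of a helical field around the
    # shaft); the most axis-parallel principal family sets the obliquity
    obliq = []
    for which in ("sigma1", "sigma3"):
        v = field.axis(which)[sel]
        ang = np.degrees(np.arccos(np.clip(np.abs(v @ axis), 0.0, 1.0)))
        obliq.append(float(ang.mean()))
    obliquity = float(min(obliq))
    # torsion sense from the circumferential drift of the tension
    # (sigma1) helix: positive twist (proximal end counterclockwise,
    # viewed from proximal, +z long axis) drives sigma1 to positive
    # circulation
    vv = field.axis("sigma1")[sel]
    r = pts - section_centre
    r_perp = r - np.outer(r @ axis, axis)
    tang = np.cross(axis, r_perp)
    tn = np.linalg.norm(tang, axis=1)
    ok = tn > 1e-12
    # orient each axial vector to have positive axial component
    sgn = np.sign(vv @ axis)
    sgn[sgn == 0] = 1.0
    vv = vv * sgn[:, None]
    circ = np.einsum("ij,ij->i", vv[ok], tang[ok] / tn[ok, None])
    mean_circ = float(circ.mean()) if ok.any() else 0.0
    sense = int(np.sign(mean_circ)) if abs(mean_circ) > 1e-6 else 0
    return MidshaftSummary(
        obliquity_deg=obliquity,
        torsion_sense=sense,
        neutral_surface_angle_deg=_neutral_angle(field, sel, axis, section_centre,
                                                 np.asarray(mediolateral_axis, float)),
        n_nodes=int(sel.sum()),
    )


def _neutral_angle(field, sel, axis, centre, ml_axis):
    # axial normal stress from the principal decomposition
    lam = field.values[sel]
    dirs = field.directions[sel]
    comp = np.einsum("nki,i->nk", dirs, axis)
    s_axial = np.einsum("nk,nk->n", lam, comp**2)
    r = field.points[sel] - centre
    e1 = _normalized(ml_axis - (ml_axis @ axis) * axis)
    e2 = np.cross(axis, e1)
    X = np.column_stack([np.ones(sel.sum()), r @ e1, r @ e2])
    coef, *_ = np.linalg.lstsq(X, s_axial, rcond=None)
    _, b1, b2 = coef
    if abs(b1) < 1e-12 and abs(b2) < 1e-12:
        return 0.0
    # neutral line direction is perpendicular to the stress gradient
    ang = np.degrees(np.arctan2(-b1, b2))  # angle of the zero line from e1
    ang = ((ang + 90.0) % 180.0) - 90.0
    return float(abs(ang))
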