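"""Synthetic cancellous-bone fabric fields.

Real fabric (the primary direction u1 of trabecular alignment) is a
bone-frame property measured from imaging.  This module supplies two
stand-ins so the comparison and search layers are testable without
image data:

* ``fabric_from_posture`` — forward-generates fabric from the pipeline
  itself: run the musculoskeletal + FE chain at a known posture and
  take the minimum-principal-stress (sigma3) axial directions at the
  bone nodes as u1, optionally perturbed by seeded angular noise.
  Under the trajectorial hypothesis this is exactly the fabric a bone
  habitually loaded in that posture would build, so scoring the same
  posture with zero noise returns 0 degrees in every region (the
  pipeline's fixed point).
* ``archetype_fabric`` — analytic per-region axial fields (e.g. a
  proximomedially inclined femoral-head axis), smoothly blended.

Noise model: each axis is rotated about a uniformly random
perpendicular axis by a folded-normal angle of the requested standard
deviation (axial data semantics; the sign of u1 is meaningless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectories import FabricField, RegionSpec, _normalized


@dataclass
class FabricGenSpec:
    mode: str = "forward_from_posture"  # or 'archetype'
    noise_sd_deg: float = 0.0
    seed: int = 0
    bone: str = "femur"
    use_sigma1_regions: list = field(default_factory=list)  # RegionSpec list (tension-dominated)

    def __post_init__(self):
        if self.noise_sd_deg < 0:
            raise ValueError("noise sd must be >= 0")


def perturb_axes(axes: np.ndarray, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate each axis about a random perpendicular by |N(0, sd)|."""
    if sd_deg == 0.0:
        return axes.copy()
    v = _normalized(axes)
    n = len(v)
    # random unit vectors, projected perpendicular to each axis
    raw = rng.standard_normal((n, 3))
    perp = raw - np.einsum("ni,ni->n", raw, v)[:, None] * v
    perp = _normalized(perp)
    ang = np.abs(rng.standard_normal(n)) * np.radians(sd_deg)
    c, s = np.cos(ang)[:, None], np.sin(ang)[:, None]
    # rotate v about perp by ang (Rodrigues; v is perpendicular to perp)
    k = perp
    out = v * c + np.cross(k, v) * s
    return _normalized(out)


def fabric_from_posture(model, posture, spec: FabricGenSpec | None = None) -> FabricField:
    """Forward-generate fabric for ``spec.bone`` at a given posture.

    Samples the sigma3 axial directions of the forward pipeline at the
    bone's FE nodes, expressed in the bone-local frame; sigma1 is used
    instead inside any tension-dominated regions supplied in the spec
    (e.g. an anterior cnemial-crest region of the tibiotarsus).
    """
    from .search import compute_principal_fields

    spec = spec or FabricGenSpec()
    fields = compute_principal_fields(model, posture)
    pf = fields[spec.bone]
    u1 = pf.axis("sigma3").copy()
    for region in spec.use_sigma1_regions:
        sel = region.mask(pf.points)
        u1[sel] = pf.axis("sigma1")[sel]
    rng = np.random.default_rng(spec.seed)
    u1 = perturb_axes(u1, spec.noise_sd_deg, rng)
    return FabricField(points=pf.points.copy(), u1=u1, provenance="synthetic-forward")


def fabric_suite_from_posture(model, posture, spec: FabricGenSpec | None = None) -> dict:
    """Forward-generate fabric for both focal bones from one pipeline
    run (femur and tibiotarsus+fibula), with independent noise streams
    derived from the spec seed."""
    from .search import compute_principal_fields

    spec = spec or FabricGenSpec()
    fields = compute_principal_fields(model, posture)
    out = {}
    for i, bone in enumerate(("femur", "tibiotarsus_fibula")):
        pf = fields[bone]
        u1 = pf.axis("sigma3").copy()
        if spec.bone == bone:
            for region in spec.use_sigma1_regions:
                sel = region.mask(pf.points)
                u1[sel] = pf.axis("sigma1")[sel]
        rng = np.random.default_rng((int(spec.seed) * 7919 + i) % (2**31))
        u1 = perturb_axes(u1, spec.noise_sd_deg, rng)
        out[bone] = FabricField(points=pf.points.copy(), u1=u1, provenance="synthetic-forward")
    return out


def archetype_fabric(
    model,
    region_axes: dict[str, tuple[RegionSpec, np.ndarray]] | None = None,
    bone: str = "femur",
    fallback_axis=(0.0, 0.0, 1.0),
) -> FabricField:
    """Analytic per-region axial field, smoothly blended between regions.

    ``region_axes`` maps a name to (RegionSpec, axis).  Between regions
    the axes are blended with inverse-distance weights on orientation
    tensors, which interpolates monotonically in angle along a path
    from one region to another.  Missing regions fall back to the bone
    long axis with a warning entry in the provenance.
    """
    from .trajectories import mean_axial_direction

    surfless = model.bone_volume_mesh(bone)
    points = surfless.nodes
    if not region_axes:
        region_axes = {}
    axes_list = [(r, _normalized(np.asarray(a, float))) for r, a in region_axes.values()]
    u1 = np.zeros_like(points)
    fb = _normalized(np.asarray(fallback_axis, float))
    for i, p in enumerate(points):
        wsum = 0.0
        T = np.zeros((3, 3))
        for region, axis in axes_list:
            d = np.linalg.norm(p - region.centre)
            w = 1.0 if d <= region.radius else (region.radius / d) ** 3
            T += w * np.outer(axis, axis)
            wsum += w
        # weak pull toward the fallback long axis far from all regions
        w0 = max(1e-6, 1.0 - min(1.0, wsum))
        T += w0 * np.outer(fb, fb)
        w, v = np.linalg.eigh(T)
        u1[i] = v[:, -1]
    prov = "archetype" if region_axes else "archetype (defaults)"
    return FabricField(points=points.copy(), u1=_normalized(u1), provenance=prov)
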