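"""File formats: VTK output, STL/PLY meshes, CSV tables, YAML configs.

Every writer stamps the global coordinate convention (+x anterior,
+y medial, +z dorsal; right limb) into its header or metadata so frame
mismatches fail loudly rather than silently.  Volume meshes and
attached fields go out as legacy-ASCII VTK unstructured grids (a
deliberately simple, text-only format); surface meshes round-trip
through trimesh as STL or PLY; postures, configs and score reports as
YAML; fabric fields and activation tables as CSV.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .anatomy import SurfaceMesh, VolumeMesh
from .kinematics import Posture
from .trajectories import FabricField

FRAME_NOTE = "+x anterior, +y medial, +z dorsal (right limb); SI units (m, kg, N, Pa)"


# ---------------------------------------------------------------------------
# VTK (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------


def write_vtk(
    path: str | Path,
    mesh: VolumeMesh,
    point_tensors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    point_vectors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> Path:
    """Write a tet mesh (+ optional nodal tensor/vector fields) as a
    legacy-ASCII VTK unstructured grid.

    Field values are given as (node_ids, values); nodes without data
    get zeros.  Cell data carries the entity id of every tet.
    """
    path = Path(path)
    n, m = len(mesh.nodes), len(mesh.tets)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"osteotraj output; frame: {FRAME_NOTE}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {m} {5 * m}\n")
        np.savetxt(f, np.column_stack([np.full(m, 4), mesh.tets]), fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 10), fmt="%d")  # VTK_TETRA
        f.write(f"CELL_DATA {m}\nSCALARS entity_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.entity_ids, fmt="%d")
        wrote_pd = False
        for name, (ids, tensors) in (point_tensors or {}).items():
            if not wrote_pd:
                f.write(f"POINT_DATA {n}\n")
                wrote_pd = True
            full = np.zeros((n, 3, 3))
            full[ids] = tensors
            f.write(f"TENSORS {name} double\n")
            np.savetxt(f, full.reshape(-1, 3), fmt="%.9g")
        for name, (ids, vecs) in (point_vectors or {}).items():
            if not wrote_pd:
                f.write(f"POINT_DATA {n}\n")
                wrote_pd = True
            full = np.zeros((n, 3))
            full[ids] = vecs
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, full, fmt="%.9g")
    return path


# ---------------------------------------------------------------------------
# surface meshes (STL / PLY via trimesh)
# ---------------------------------------------------------------------------


def write_surface(path: str | Path, surf: SurfaceMesh) -> Path:
    path = Path(path)
    tm = trimesh.Trimesh(vertices=surf.vertices, faces=surf.triangles, process=False)
    tm.export(path)
    return path


def read_surface(path: str | Path, name: str = "") -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    tm.merge_vertices()  # STL stores one vertex copy per facet
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, float),
        triangles=np.asarray(tm.faces, np.int64),
        name=name or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# postures, configs, reports (YAML)
# ---------------------------------------------------------------------------


def write_posture(path: str | Path, posture: Posture) -> Path:
    path = Path(path)
    doc = {
        "frame": FRAME_NOTE,
        "units": "degrees",
        "sign_conventions": {
            "hip_extension": "from horizontal; negative = anteroventral",
            "hip_abduction": "positive = abduction",
            "hip_lar": "positive = external rotation",
            "knee_flexion": "positive = flexed, relative to femur",
            "ankle_flexion": "positive = flexed (dorsiflexed), relative to tibiotarsus",
            "mtp_angle": "positive = extension, from neutral",
        },
        "posture": posture.as_dict(),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_posture(path: str | Path) -> Posture:
    doc = yaml.safe_load(Path(path).read_text())
    return Posture(**doc["posture"])


def write_yaml(path: str | Path, doc: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({"frame": FRAME_NOTE, **doc}, sort_keys=False))
    return path


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# fabric fields (CSV: x,y,z,u1x,u1y,u1z)
# ---------------------------------------------------------------------------


def write_fabric(path: str | Path, fabric: FabricField) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow([f"# frame: {FRAME_NOTE}; provenance: {fabric.provenance}"])
        w.writerow(["x", "y", "z", "u1x", "u1y", "u1z"])
        for p, u in zip(fabric.points, fabric.u1):
            w.writerow([f"{v:.9g}" for v in (*p, *u)])
    return path


def read_fabric(path: str | Path) -> FabricField:
    rows = []
    provenance = "imported"
    with open(path, newline="") as f:
        for row in csv.reader(f):
            if not row:
                continue
            if row[0].startswith("#"):
                if "provenance:" in row[0]:
                    provenance = row[0].split("provenance:")[1].strip()
                continue
            if row[0] == "x":
                continue
            rows.append([float(v) for v in row])
    arr = np.array(rows)
    return FabricField(points=arr[:, :3], u1=arr[:, 3:6], provenance=provenance)


# ---------------------------------------------------------------------------
# actuator tables (structured text: name, kind, active, f_max, path)
# ---------------------------------------------------------------------------


def write_actuator_table(path: str | Path, actuators) -> Path:
    """One row per actuator; the path column is
    ``segment:x:y:z; segment:x:y:z; ...`` from origin to insertion."""
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow([f"# frame: {FRAME_NOTE}"])
        w.writerow(["name", "kind", "active", "f_max_N", "path"])
        for a in actuators:
            spec = "; ".join(
                f"{seg}:{p[0]:.9g}:{p[1]:.9g}:{p[2]:.9g}" for seg, p in a.path
            )
            w.writerow([a.name, a.kind, int(a.active), f"{a.f_max:.9g}", spec])
    return path


def read_actuator_table(path: str | Path):
    from .statics import Actuator

    out = []
    with open(path, newline="") as f:
        for row in csv.reader(f):
            if not row or row[0].startswith("#") or row[0] == "name":
                continue
            name, kind, active, fmax, spec = row
            pts = []
            for item in spec.split(";"):
                seg, x, y, z = item.strip().split(":")
                pts.append((seg, np.array([float(x), float(y), float(z)])))
            out.append(
                Actuator(name=name, kind=kind, path=pts, active=bool(int(active)),
                         f_max=float(fmax))
            )
    return out


# ---------------------------------------------------------------------------
# stereoplot export (azimuth/inclination of axial vectors)
# ---------------------------------------------------------------------------


def write_stereoplot_csv(path: str | Path, axes: np.ndarray) -> Path:
    """Axial vectors as (azimuth, inclination) degree pairs.

    Azimuth is measured from +x (anterior) toward +y (medial);
    inclination is the angle below the horizontal plane.  Vectors are
    first oriented into the lower hemisphere (axial data).
    """
    v = np.atleast_2d(np.asarray(axes, float))
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    v = v * np.where(v[:, 2] > 0, -1.0, 1.0)[:, None]  # lower hemisphere
    azim = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360.0
    incl = np.degrees(np.arcsin(-v[:, 2]))
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow([f"# frame: {FRAME_NOTE}"])
        w.writerow(["azimuth_deg", "inclination_deg"])
        for a, i in zip(azim, incl):
            w.writerow([f"{a:.6g}", f"{i:.6g}"])
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Whole-pipeline configuration, YAML round-trippable.

    Defaults reproduce the standard study conditions: uniform 2 BW
    actuator forces, the default materials, the mid-stance start
    posture and the shrinking-step search.
    """

    model_params: dict = field(default_factory=dict)
    model_seed: int = 0
    material_overrides: dict = field(default_factory=dict)  # name -> property dict
    actuator_table: str | None = None  # optional path; None = built-in topology
    f_max_mode: str = "uniform"  # 'uniform' | 'per_muscle'
    search: dict = field(default_factory=dict)  # SearchConfig overrides
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.f_max_mode not in ("uniform", "per_muscle"):
            raise ValueError(f"unknown f_max_mode {self.f_max_mode!r}")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")


def write_run_config(path: str | Path, cfg: RunConfig) -> Path:
    cfg.validate()
    return write_yaml(Path(path), {"run_config": dataclasses.asdict(cfg)})


def read_run_config(path: str | Path) -> RunConfig:
    doc = read_yaml(path)
    cfg = RunConfig(**doc["run_config"])
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# activation solutions and joint loads
# ---------------------------------------------------------------------------


def write_solution(csv_path: str | Path, json_path: str | Path, solution, joint_loads) -> None:
    with open(csv_path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["actuator", "activation", "force_N"])
        for name, a in solution.activations.items():
            w.writerow([name, f"{a:.9g}", f"{solution.forces[name]:.9g}"])
    doc = {
        "frame": FRAME_NOTE,
        "mtp_reserve_moment_Nm": solution.mtp_reserve_moment,
        "objective_sum_sq_activation": solution.objective,
        "joints": {
            j: {
                "force_N": [float(v) for v in joint_loads.forces[j]],
                "moment_Nm": [float(v) for v in joint_loads.moments[j]],
            }
            for j in joint_loads.forces
        },
    }
    Path(json_path).write_text(json.dumps(doc, indent=1))


def write_audit_csv(path: str | Path, state) -> Path:
    """Search audit trail: one row per evaluated posture."""
    path = Path(path)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        header = [
            "iteration",
            *Posture().as_dict().keys(),
            "weighted_score_deg",
            "admissible",
        ]
        region_names = sorted(
            {k for _, rep, _ in state.history for k in rep.region_deviation}
        )
        w.writerow(header + [f"dev_{r}_deg" for r in region_names])
        for i, (p, rep, cons) in enumerate(state.history):
            row = [i, *[f"{v:.6g}" for v in p.as_dict().values()],
                   f"{rep.weighted_score:.6g}", int(cons.all_ok)]
            row += [f"{rep.region_deviation.get(r, float('nan')):.6g}" for r in region_names]
            w.writerow(row)
    return path


def read_audit_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as f:
        return list(csv.DictReader(f))
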