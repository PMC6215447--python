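"""Structured tetrahedral meshing primitives.

Every volume mesh in the package is built from a mapped structured
hexahedral grid whose cells are split into six tetrahedra along a
consistent main diagonal.  Splitting every hex the same way makes the
face diagonals of neighbouring cells agree, so separately generated
blocks that share a face grid (bone end face -> joint soft-tissue
volume, bone slab -> bookend) are conformal: bonded interfaces share
nodes *exactly*, which is how bonded contact is realised throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

# Faces of the hex in cyclic corner order.
# Local corner order: v0=(0,0,0) v1=(1,0,0) v2=(1,1,0) v3=(0,1,0)
#                     v4=(0,0,1) v5=(1,0,1) v6=(1,1,1) v7=(0,1,1)
_HEX_FACES = np.array(
    [
        (0, 1, 2, 3),  # z = 0
        (4, 5, 6, 7),  # z = 1
        (0, 1, 5, 4),  # y = 0
        (3, 2, 6, 7),  # y = 1
        (0, 3, 7, 4),  # x = 0
        (1, 2, 6, 5),  # x = 1
    ],
    dtype=np.int64,
)


@dataclass
class StructuredBlock:
    """A (nk+1, nj+1, ni+1) grid of nodes defining nk*nj*ni hex cells.

    Axis k is the sweep (axial) direction; j and i span the cross
    section.  ``nodes`` has shape (nk+1, nj+1, ni+1, 3).
    """

    nodes: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        nk, nj, ni = self.nodes.shape[:3]
        return nk - 1, nj - 1, ni - 1

    def node_array(self) -> np.ndarray:
        return self.nodes.reshape(-1, 3)

    def hexes(self) -> np.ndarray:
        """Hex cells as (ncell, 8) corner indices into ``node_array()``."""
        nk, nj, ni = self.shape
        npj, npi = nj + 1, ni + 1

        def nid(k, j, i):
            return (k * npj + j) * npi + i

        kk, jj, ii = np.meshgrid(
            np.arange(nk), np.arange(nj), np.arange(ni), indexing="ij"
        )
        kk, jj, ii = kk.ravel(), jj.ravel(), ii.ravel()
        return np.stack(
            [
                nid(kk, jj, ii),
                nid(kk, jj, ii + 1),
                nid(kk, jj + 1, ii + 1),
                nid(kk, jj + 1, ii),
                nid(kk + 1, jj, ii),
                nid(kk + 1, jj, ii + 1),
                nid(kk + 1, jj + 1, ii + 1),
                nid(kk + 1, jj + 1, ii),
            ],
            axis=1,
        )

    def volume(self) -> tuple[np.ndarray, np.ndarray]:
        """Tetrahedralize: grid nodes + one centre node per hex.

        Each hex face is split along its *shortest* diagonal (ties
        broken by a coordinate-lexicographic rule), and each face
        triangle is joined to the hex centre: 12 tets per hex.  The
        shortest-diagonal rule is purely geometric, so two blocks that
        share a face grid bitwise produce identical interface
        triangulations — conformality is preserved across separately
        generated, bonded blocks.
        """
        grid = self.node_array()
        hx = self.hexes()
        centres = grid[hx].mean(axis=1)
        nodes = np.vstack([grid, centres])
        centre_ids = np.arange(len(grid), len(grid) + len(hx))

        quads = hx[:, _HEX_FACES].reshape(-1, 4)  # (ncell*6, 4)
        tris = _split_quads(nodes, quads)  # (ncell*6*2, 3)
        c = np.repeat(centre_ids, 12)
        tets = np.column_stack([tris, c])
        # orient positively
        vols = tet_volumes(nodes, tets)
        neg = vols < 0
        tets[neg] = tets[neg][:, [1, 0, 2, 3]]
        return nodes, tets

    def face(self, end: str) -> np.ndarray:
        """End-face node grid, shape (nj+1, ni+1, 3). end in {'first','last'}."""
        return self.nodes[0].copy() if end == "first" else self.nodes[-1].copy()

    def sub(self, k0: int, k1: int) -> "StructuredBlock":
        """Axial slab covering stations k0..k1 inclusive."""
        return StructuredBlock(self.nodes[k0 : k1 + 1].copy())

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "StructuredBlock":
        return StructuredBlock(self.nodes @ rot.T + trans)


def _split_quads(nodes: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Split cyclic quads into triangle pairs along the shortest diagonal.

    The choice is geometric (coordinates, not indices): identical quads
    seen from two different blocks split identically.
    """
    p = nodes[quads]
    d1 = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    d2 = np.linalg.norm(p[:, 1] - p[:, 3], axis=1)
    use1 = d1 < d2 - 1e-12
    tie = ~use1 & ~(d2 < d1 - 1e-12)
    if tie.any():
        for idx in np.where(tie)[0]:
            k1 = sorted((tuple(p[idx, 0]), tuple(p[idx, 2])))
            k2 = sorted((tuple(p[idx, 1]), tuple(p[idx, 3])))
            if k1 <= k2:
                use1[idx] = True
    tris = np.empty((len(quads), 2, 3), dtype=np.int64)
    q1, q2 = quads[use1], quads[~use1]
    tris[use1] = np.stack([q1[:, [0, 1, 2]], q1[:, [0, 2, 3]]], axis=1)
    tris[~use1] = np.stack([q2[:, [1, 2, 3]], q2[:, [1, 3, 0]]], axis=1)
    return tris.reshape(-1, 3)


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def boundary_triangles(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a tet mesh."""
    # face (a,b,c) opposite d, oriented so the normal points away from d
    faces = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    tri = faces[counts[inv] == 1]
    # fix orientation: normal must point away from the opposite vertex
    opp = np.concatenate([tets[:, 0], tets[:, 1], tets[:, 2], tets[:, 3]])
    opp = opp[counts[inv] == 1]
    n = np.cross(nodes[tri[:, 1]] - nodes[tri[:, 0]], nodes[tri[:, 2]] - nodes[tri[:, 0]])
    inward = np.einsum("ij,ij->i", n, nodes[opp] - nodes[tri[:, 0]]) > 0
    tri[inward] = tri[inward][:, ::-1]
    return tri


def _disc_section(xi, eta, a_ant, a_post, b_med, b_lat):
    """Rounded cross-section grid with arc-length-uniform boundary nodes.

    The outline is a four-lobed oval with per-quadrant semi-axes; grid
    boundary nodes are spread uniformly by arc length along it (so
    elongated lobes such as a cnemial crest do not produce long
    boundary chords), and interior nodes follow radially (the outline
    is star shaped about the centre).
    """
    phi = np.linspace(-np.pi, np.pi, 721)
    ax = np.where(np.cos(phi) >= 0, a_ant, a_post)
    by = np.where(np.sin(phi) >= 0, b_med, b_lat)
    ox, oy = np.cos(phi) * ax, np.sin(phi) * by
    ds = np.hypot(np.diff(ox), np.diff(oy))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    s /= s[-1]

    rho = np.maximum(np.abs(xi), np.abs(eta))
    psi = np.arctan2(eta, xi)
    frac = (psi + np.pi) / (2.0 * np.pi)
    phi_n = np.interp(frac, s, phi)
    ax_n = np.where(np.cos(phi_n) >= 0, a_ant, a_post)
    by_n = np.where(np.sin(phi_n) >= 0, b_med, b_lat)
    x_arc = rho * np.cos(phi_n) * ax_n
    y_arc = rho * np.sin(phi_n) * by_n
    # smooth elliptical map in the interior (avoids slanted radial edges),
    # fading into the arc-uniform boundary
    u = xi * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * eta**2))
    v = eta * np.sqrt(np.maximum(0.0, 1.0 - 0.5 * xi**2))
    x_ell = u * np.where(u >= 0, a_ant, a_post)
    y_ell = v * np.where(v >= 0, b_med, b_lat)
    w = rho**2
    return (1 - w) * x_ell + w * x_arc, (1 - w) * y_ell + w * y_arc


def sweep_block(stations: list[dict], ni: int = 4, nj: int = 4) -> StructuredBlock:
    """Sweep a varying cross section along local +z.

    Each station dict: z, a_ant, a_post (semi-axes toward +x / -x),
    b_med, b_lat (toward +y / -y), cx, cy (section centre), and
    shape ('disc' | 'box').  Stations are ordered by increasing z.
    """
    xi1 = np.linspace(-1.0, 1.0, ni + 1)
    eta1 = np.linspace(-1.0, 1.0, nj + 1)
    eta, xi = np.meshgrid(eta1, xi1, indexing="ij")  # (nj+1, ni+1)
    layers = []
    for st in stations:
        if st.get("shape", "disc") == "disc":
            x, y = _disc_section(xi, eta, st["a_ant"], st["a_post"], st["b_med"], st["b_lat"])
        else:
            x = xi * np.where(xi >= 0.0, st["a_ant"], st["a_post"])
            y = eta * np.where(eta >= 0.0, st["b_med"], st["b_lat"])
        x = x + st.get("cx", 0.0)
        y = y + st.get("cy", 0.0)
        z = np.full_like(x, st["z"])
        layers.append(np.stack([x, y, z], axis=-1))
    return StructuredBlock(np.array(layers))


def box_block(
    xlim: tuple[float, float],
    ylim: tuple[float, float],
    zlim: tuple[float, float],
    ni: int = 4,
    nj: int = 4,
    nk: int = 3,
) -> StructuredBlock:
    xs = np.linspace(*xlim, ni + 1)
    ys = np.linspace(*ylim, nj + 1)
    zs = np.linspace(*zlim, nk + 1)
    z, y, x = np.meshgrid(zs, ys, xs, indexing="ij")
    return StructuredBlock(np.stack([x, y, z], axis=-1))


def loft_block(
    face_a: np.ndarray,
    face_b: np.ndarray,
    centre: np.ndarray,
    rel_rotation: np.ndarray | None = None,
    n_layers: int | None = None,
) -> StructuredBlock:
    """Loft a soft-tissue wedge between two conformal face grids.

    ``face_a`` and ``face_b`` are (nj+1, ni+1, 3) grids (the end face of
    the parent bone and the start face of the child bone, posed in the
    global frame).  When the child is rotated relative to the parent
    (``rel_rotation``, a 3x3 matrix), intermediate layers are generated
    by rotating about the joint ``centre`` while blending the two face
    shapes, so the wedge follows the articulation instead of cutting
    across it (which would invert cells at large joint angles).

    Layers 0 and -1 are *bitwise copies* of face_a / face_b, so merging
    with the adjacent bone meshes shares interface nodes exactly.
    """
    q = np.eye(3) if rel_rotation is None else np.asarray(rel_rotation, float)
    rot = Rotation.from_matrix(np.stack([np.eye(3), q]))
    angle = Rotation.from_matrix(q).magnitude()
    if n_layers is None:
        n_layers = max(2, int(np.ceil(np.degrees(angle) / 25.0)) + 1)
    slerp = Slerp([0.0, 1.0], rot)
    c = np.asarray(centre, float)
    b_back = (face_b - c) @ q + c  # q^{-1} applied to row vectors
    layers = [face_a.copy()]
    for t in np.linspace(0.0, 1.0, n_layers + 1)[1:-1]:
        mid = (1.0 - t) * face_a + t * b_back
        rt = slerp(t).as_matrix()
        layers.append((mid - c) @ rt.T + c)
    layers.append(face_b.copy())
    return StructuredBlock(np.array(layers))


def merge_blocks(named_blocks: list[tuple[str, StructuredBlock]]):
    """Merge blocks into one node/tet set, deduplicating identical nodes.

    Returns (nodes, tets, entity_ids, entity_names).  Nodes are matched
    bitwise, which is sufficient because conformal interfaces are built
    by copying coordinate arrays.
    """
    all_nodes = []
    all_tets = []
    ent_ids = []
    names = []
    offset = 0
    for name, blk in named_blocks:
        nd, tt = blk.volume()
        tt = tt + offset
        all_nodes.append(nd)
        all_tets.append(tt)
        ent_ids.append(np.full(len(tt), len(names), dtype=np.int64))
        names.append(name)
        offset += len(nd)
    nodes = np.concatenate(all_nodes)
    tets = np.concatenate(all_tets)
    ent = np.concatenate(ent_ids)
    view = np.ascontiguousarray(nodes).view([("x", float), ("y", float), ("z", float)])
    _, first, inv = np.unique(view, return_index=True, return_inverse=True)
    # keep stable node ordering (first occurrence)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_nodes = nodes[first[order]]
    tets = rank[inv.ravel()][tets]
    return new_nodes, tets, ent, names


def mesh_audit(nodes: np.ndarray, tets: np.ndarray) -> dict:
    """Quality/validity report used by the generation invariant tests."""
    vols = tet_volumes(nodes, tets)
    edges = tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
    elen = np.linalg.norm(nodes[edges[..., 1]] - nodes[edges[..., 0]], axis=-1)
    used = np.zeros(len(nodes), dtype=bool)
    used[tets.ravel()] = True
    return {
        "min_volume": float(vols.min()) if len(vols) else 0.0,
        "max_edge": float(elen.max()) if len(tets) else 0.0,
        "all_nodes_referenced": bool(used.all()),
        "n_tets": int(len(tets)),
        "n_nodes": int(len(nodes)),
    }
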