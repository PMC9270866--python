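"""Triangulated free-wall strain mesh and modified Loop subdivision.

The sparse 20-crystal array is triangulated deterministically: consecutive
rows (annulus -> basal -> mid -> lower) are stitched by greedy quad-splitting
(shorter-diagonal rule, index-order tie-break) and an apex fan closes the
bottom.  Vertex order equals layout order, so meshes built for Baseline and
TRA from the same layout always share connectivity.

Refinement uses the Loop subdivision scheme with the standard boundary
modification: interior even vertices use the valence-dependent beta mask
``beta = (1/n) * (5/8 - (3/8 + cos(2*pi/n)/4)^2)``, boundary even vertices the
cubic-spline mask (1/8, 3/4, 1/8), interior edge midpoints the (3/8, 3/8,
1/8, 1/8) mask, and boundary edge midpoints the plain average of the edge
endpoints.  The operator is linear in vertex positions and its connectivity
depends only on the input connectivity, so the same operator matrix can be
applied to reference and deformed vertex sets in strain computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import ParameterError, SchemaError, TopologyError
from .recording import CrystalLayout

__all__ = [
    "SurfaceMesh",
    "build_base_mesh",
    "subdivision_operator",
    "loop_subdivide",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """Oriented manifold-with-boundary triangle mesh at one time point.

    ``face_region`` assigns each face to a wall region (basal/mid/lower);
    ``vertex_labels`` keeps provenance (crystal labels at level 0, inherited
    labels after subdivision).
    """

    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int
    face_region: tuple[str, ...]
    vertex_labels: tuple[str, ...]
    subdivision_level: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ParameterError("vertices must be (V, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ParameterError("faces must be (F, 3)")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            raise TopologyError("face indices out of range")
        if len(self.face_region) != len(f):
            raise ParameterError("face_region length must match faces")
        if len(self.vertex_labels) != len(v):
            raise ParameterError("vertex_labels length must match vertices")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        _edge_tables(f)  # raises TopologyError on non-manifold/inconsistent input

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        return _edge_tables(self.faces)[0]

    @property
    def boundary_vertex_flags(self) -> np.ndarray:
        edges, counts, _ = _edge_tables(self.faces)
        flags = np.zeros(self.n_vertices, dtype=bool)
        flags[np.unique(edges[counts == 1])] = True
        return flags

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_faces

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same connectivity with replaced vertex positions."""
        return SurfaceMesh(
            vertices=np.asarray(vertices, dtype=float),
            faces=self.faces,
            face_region=self.face_region,
            vertex_labels=self.vertex_labels,
            subdivision_level=self.subdivision_level,
        )

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        nrm = np.linalg.norm(cr, axis=1, keepdims=True)
        if np.any(nrm == 0):
            raise TopologyError("mesh contains a zero-area face")
        return cr / nrm


def _edge_tables(faces: np.ndarray):
    """Undirected edge list, per-edge face counts, and edge id lookup.

    Raises :class:`TopologyError` if any edge belongs to more than two faces
    or if two faces traverse a shared edge in the same direction (inconsistent
    orientation).
    """
    faces = np.asarray(faces, dtype=int)
    directed: dict[tuple[int, int], int] = {}
    undirected: dict[tuple[int, int], int] = {}
    counts: list[int] = []
    edges: list[tuple[int, int]] = []
    for face in faces:
        for a, b in ((face[0], face[1]), (face[1], face[2]), (face[2], face[0])):
            a, b = int(a), int(b)
            if a == b:
                raise TopologyError("degenerate face with repeated vertex")
            if (a, b) in directed:
                raise TopologyError(
                    f"directed edge ({a}, {b}) appears twice: inconsistent orientation"
                )
            directed[(a, b)] = 1
            key = (a, b) if a < b else (b, a)
            if key in undirected:
                counts[undirected[key]] += 1
                if counts[undirected[key]] > 2:
                    raise TopologyError(f"edge {key} shared by > 2 faces")
            else:
                undirected[key] = len(edges)
                edges.append(key)
                counts.append(1)
    return np.array(edges, dtype=int), np.array(counts, dtype=int), undirected


def _stitch_rows(
    upper: Sequence[int], lower: Sequence[int], pts: np.ndarray
) -> list[tuple[int, int, int]]:
    """Greedy strip triangulation between two ordered open chains.

    At each step the chain advance producing the shorter new diagonal is
    taken; exact ties advance the upper chain (index order).
    """
    faces: list[tuple[int, int, int]] = []
    i, j = 0, 0
    while i < len(upper) - 1 or j < len(lower) - 1:
        if j == len(lower) - 1:
            advance_upper = True
        elif i == len(upper) - 1:
            advance_upper = False
        else:
            d_upper = np.linalg.norm(pts[upper[i + 1]] - pts[lower[j]])
            d_lower = np.linalg.norm(pts[upper[i]] - pts[lower[j + 1]])
            # near-ties (within rounding of a rigid motion) count as ties so
            # connectivity is invariant under rotation/translation
            tol = 1e-9 * max(d_upper, d_lower)
            advance_upper = d_upper <= d_lower + tol
        if advance_upper:
            faces.append((upper[i], upper[i + 1], lower[j]))
            i += 1
        else:
            faces.append((upper[i], lower[j + 1], lower[j]))
            j += 1
    return faces


def build_base_mesh(
    layout: CrystalLayout, frame: Mapping[str, np.ndarray]
) -> SurfaceMesh:
    """Deterministic level-0 mesh over annulus, free-wall rows, and apex.

    Vertex order is the layout order (annular, basal, mid, lower, apex), so
    connectivity is shared between any two frames of the same layout.  Band
    regions: annulus-to-basal faces are 'basal', basal-to-mid 'mid', and both
    mid-to-lower and the apex fan 'lower'.
    """
    layout.validate()
    labels = layout.all_labels
    missing = [lab for lab in labels if lab not in frame]
    if missing:
        raise SchemaError(f"frame missing crystal(s) {missing}")
    pts = np.array([frame[lab] for lab in labels], dtype=float)
    index = {lab: i for i, lab in enumerate(labels)}

    chains = [[index[lab] for lab in layout.annular]]
    for row in layout.rows:
        chains.append([index[lab] for lab in layout.parallels[row]])
    apex = index[layout.apex]

    band_regions = [layout.region_of_row.get(r, r) for r in layout.rows]
    faces: list[tuple[int, int, int]] = []
    regions: list[str] = []
    for band, (upper, lower) in enumerate(zip(chains[:-1], chains[1:])):
        band_faces = _stitch_rows(upper, lower, pts)
        faces.extend(band_faces)
        regions.extend([band_regions[band]] * len(band_faces))
    last = chains[-1]
    for a, b in zip(last[:-1], last[1:]):
        faces.append((a, b, apex))
        regions.append(band_regions[-1])

    return SurfaceMesh(
        vertices=pts,
        faces=np.array(faces, dtype=int),
        face_region=tuple(regions),
        vertex_labels=tuple(labels),
        subdivision_level=0,
    )


def _loop_beta(n: int) -> float:
    # Loop's valence-dependent weight for interior even vertices
    c = 3.0 / 8.0 + 0.25 * np.cos(2.0 * np.pi / n)
    return (5.0 / 8.0 - c * c) / n


def _one_level(
    faces: np.ndarray, n_vertices: int
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """One Loop subdivision level: (operator S, child faces).

    ``S`` is ((V + E) x V); child vertex ``V + e`` is the odd vertex of edge e.
    """
    edges, counts, edge_id = _edge_tables(faces)
    n_edges = len(edges)
    boundary_edge = counts == 1
    boundary_vertex = np.zeros(n_vertices, dtype=bool)
    boundary_vertex[np.unique(edges[boundary_edge])] = True

    neighbors: list[set[int]] = [set() for _ in range(n_vertices)]
    boundary_neighbors: list[set[int]] = [set() for _ in range(n_vertices)]
    for (a, b), on_boundary in zip(edges, boundary_edge):
        neighbors[a].add(int(b))
        neighbors[b].add(int(a))
        if on_boundary:
            boundary_neighbors[a].add(int(b))
            boundary_neighbors[b].add(int(a))

    # opposite vertices of interior edges (the two 1/8 weights)
    opposite: dict[int, list[int]] = {e: [] for e in range(n_edges)}
    for face in faces:
        for a, b, c in (
            (face[0], face[1], face[2]),
            (face[1], face[2], face[0]),
            (face[2], face[0], face[1]),
        ):
            key = (int(a), int(b)) if a < b else (int(b), int(a))
            opposite[edge_id[key]].append(int(c))

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def put(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for v in range(n_vertices):
        if boundary_vertex[v]:
            bn = sorted(boundary_neighbors[v])
            if len(bn) != 2:
                raise TopologyError(
                    f"boundary vertex {v} has {len(bn)} boundary neighbors"
                )
            put(v, v, 0.75)
            put(v, bn[0], 0.125)
            put(v, bn[1], 0.125)
        else:
            nb = sorted(neighbors[v])
            n = len(nb)
            if n < 3:
                raise TopologyError(f"interior vertex {v} has valence {n}")
            beta = _loop_beta(n)
            put(v, v, 1.0 - n * beta)
            for u in nb:
                put(v, u, beta)

    for e, ((a, b), on_boundary) in enumerate(zip(edges, boundary_edge)):
        r = n_vertices + e
        if on_boundary:
            put(r, int(a), 0.5)
            put(r, int(b), 0.5)
        else:
            put(r, int(a), 0.375)
            put(r, int(b), 0.375)
            for c in opposite[e]:
                put(r, c, 0.125)

    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_vertices + n_edges, n_vertices)
    )

    child_faces = []
    for face in faces:
        v0, v1, v2 = (int(x) for x in face)
        e01 = n_vertices + edge_id[(min(v0, v1), max(v0, v1))]
        e12 = n_vertices + edge_id[(min(v1, v2), max(v1, v2))]
        e20 = n_vertices + edge_id[(min(v2, v0), max(v2, v0))]
        child_faces.extend(
            [(v0, e01, e20), (v1, e12, e01), (v2, e20, e12), (e01, e12, e20)]
        )
    return S, np.array(child_faces, dtype=int)


def subdivision_operator(
    mesh: SurfaceMesh, levels: int
) -> tuple[sparse.csr_matrix, "SurfaceMesh"]:
    """Composite subdivision operator and the refined template mesh.

    Returns ``(S, refined)`` with ``refined.vertices == S @ mesh.vertices``.
    ``S`` depends only on ``mesh``'s connectivity, so it can be applied to any
    vertex set sharing that connectivity (Baseline and TRA frames, every
    normalized-cycle frame): subdivided meshes then share connectivity too.
    """
    if levels < 0:
        raise ParameterError("levels must be >= 0")
    faces = mesh.faces
    regions = list(mesh.face_region)
    labels = list(mesh.vertex_labels)
    n_v = mesh.n_vertices
    S: sparse.csr_matrix = sparse.identity(n_v, format="csr")
    for _ in range(levels):
        edges, _, _ = _edge_tables(faces)
        S_level, faces = _one_level(faces, n_v)
        # children inherit: edge vertex takes the label of its lower-index endpoint
        labels = labels + [labels[a] for a, _ in edges]
        regions = [r for r in regions for _ in range(4)]
        S = S_level @ S
        n_v = S.shape[0]
    refined = SurfaceMesh(
        vertices=S @ mesh.vertices,
        faces=faces,
        face_region=tuple(regions),
        vertex_labels=tuple(labels),
        subdivision_level=mesh.subdivision_level + levels,
    )
    return S, refined


def loop_subdivide(mesh: SurfaceMesh, levels: int = 1) -> SurfaceMesh:
    """Refine ``mesh`` by ``levels`` rounds of modified Loop subdivision."""
    _, refined = subdivision_operator(mesh, levels)
    return refined
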