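"""Regional epicardial Green-Lagrange strains on the subdivided crystal mesh.

Per-face membrane kinematics: an orthonormal tangent frame is built on each
triangle (first axis along the first edge, second the in-plane perpendicular);
the 2x2 deformation gradient F maps reference-frame edge coordinates to
deformed-frame edge coordinates exactly, and E = (F^T F - I)/2 is the
Green-Lagrange tensor.  Directional strains are d^T E d for unit in-plane
directions; areal strain is det F - 1 = dA/dA0 - 1.

Two reference conventions are provided:

* *cardiac strain* - each state referenced to its own end-diastolic frame,
  evaluated over the whole normalized cycle;
* *interventional strain* - the TRA state referenced to Baseline at the same
  cycle time point (ED or ES).

Circumferential/longitudinal directions derive from the ventricular long axis
(annular-crystal centroid to apex): per face, longitudinal is the in-plane
projection of the long axis and circumferential its in-plane perpendicular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cycles import AveragedBeat
from .errors import CorrespondenceError, DegeneracyError, ParameterError
from .mesh import SurfaceMesh, build_base_mesh, subdivision_operator
from .recording import CrystalLayout

__all__ = [
    "StrainField",
    "face_deformation_gradient",
    "green_lagrange",
    "directional_strain",
    "areal_strain",
    "material_directions",
    "cardiac_strain_timecourse",
    "interventional_strain",
    "regional_aggregate",
    "CardiacStrainResult",
]

_COMPONENTS = ("e_cc", "e_ll", "areal")


def _frames(vertices: np.ndarray, faces: np.ndarray):
    """Orthonormal tangent frames per face: (e1, e2, n), each (F, 3)."""
    p0 = vertices[faces[:, 0]]
    u = vertices[faces[:, 1]] - p0
    w = vertices[faces[:, 2]] - p0
    nrm_u = np.linalg.norm(u, axis=1, keepdims=True)
    cr = np.cross(u, w)
    nrm_c = np.linalg.norm(cr, axis=1, keepdims=True)
    if np.any(nrm_u == 0) or np.any(nrm_c == 0):
        raise DegeneracyError("zero-area triangle in mesh")
    e1 = u / nrm_u
    n = cr / nrm_c
    e2 = np.cross(n, e1)
    return e1, e2, n


def _edge_matrix(vertices: np.ndarray, faces: np.ndarray, e1, e2) -> np.ndarray:
    """In-frame 2x2 edge matrices D with columns = the two edge vectors."""
    p0 = vertices[faces[:, 0]]
    u = vertices[faces[:, 1]] - p0
    w = vertices[faces[:, 2]] - p0
    D = np.empty((len(faces), 2, 2))
    D[:, 0, 0] = np.einsum("ij,ij->i", e1, u)
    D[:, 0, 1] = np.einsum("ij,ij->i", e1, w)
    D[:, 1, 0] = np.einsum("ij,ij->i", e2, u)
    D[:, 1, 1] = np.einsum("ij,ij->i", e2, w)
    return D


def _inv2(M: np.ndarray) -> np.ndarray:
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    if np.any(np.abs(det) < 1e-300):
        raise DegeneracyError("singular edge matrix (degenerate triangle)")
    inv = np.empty_like(M)
    inv[..., 0, 0] = M[..., 1, 1]
    inv[..., 1, 1] = M[..., 0, 0]
    inv[..., 0, 1] = -M[..., 0, 1]
    inv[..., 1, 0] = -M[..., 1, 0]
    return inv / det[..., None, None]


def deformation_gradients(
    ref_vertices: np.ndarray, def_vertices: np.ndarray, faces: np.ndarray
) -> np.ndarray:
    """Per-face 2x2 deformation gradients between two vertex sets, (F, 2, 2)."""
    e1r, e2r, _ = _frames(ref_vertices, faces)
    e1d, e2d, _ = _frames(def_vertices, faces)
    Dref = _edge_matrix(ref_vertices, faces, e1r, e2r)
    Ddef = _edge_matrix(def_vertices, faces, e1d, e2d)
    return Ddef @ _inv2(Dref)


def face_deformation_gradient(ref_face: np.ndarray, def_face: np.ndarray) -> np.ndarray:
    """2x2 deformation gradient of a single triangle (rows of 3 points)."""
    ref = np.asarray(ref_face, dtype=float).reshape(1, 3, 3)
    dfm = np.asarray(def_face, dtype=float).reshape(1, 3, 3)
    faces = np.array([[0, 1, 2]])
    return deformation_gradients(ref[0], dfm[0], faces)[0]


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange tensor E = (F^T F - I)/2 (single 2x2 or batched)."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ParameterError("F must be finite")
    Ft = np.swapaxes(F, -1, -2)
    return 0.5 * (Ft @ F - np.eye(2))


def directional_strain(E: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Normal strain d^T E d for a unit direction in the reference frame."""
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d, axis=-1)
    if np.any(nrm < 1e-12):
        raise ParameterError("direction must be non-zero")
    if not np.allclose(nrm, 1.0, atol=1e-8):
        d = d / nrm[..., None]
    return np.einsum("...i,...ij,...j->...", d, E, d)


def areal_strain(F: np.ndarray) -> np.ndarray:
    """Areal strain det F - 1 = dA/dA0 - 1; inverted elements are an error."""
    F = np.asarray(F, dtype=float)
    det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(det <= 0):
        raise DegeneracyError("inverted element: det F <= 0")
    return det - 1.0


def long_axis_from_frame(frame: Mapping[str, np.ndarray], layout: CrystalLayout) -> np.ndarray:
    """Unit long axis from the annular-crystal centroid to the apex crystal."""
    centroid = np.mean([frame[lab] for lab in layout.annular], axis=0)
    axis = np.asarray(frame[layout.apex], dtype=float) - centroid
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise DegeneracyError("apex coincides with annular centroid")
    return axis / nrm


def material_directions(
    mesh: SurfaceMesh, long_axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-face circumferential/longitudinal unit directions on the reference.

    Returns ``(c2, l2, c3, l3)``: 2-vectors in each face's tangent frame and
    the corresponding 3-vectors.  Faces whose normal is (near) parallel to the
    long axis fall back to the mean longitudinal direction of their neighbors.
    """
    L = np.asarray(long_axis, dtype=float)
    L = L / np.linalg.norm(L)
    e1, e2, n = _frames(mesh.vertices, mesh.faces)
    l3 = L[None, :] - (n @ L)[:, None] * n
    nrm = np.linalg.norm(l3, axis=1)
    degenerate = nrm < 1e-8
    if degenerate.any():
        # neighbor fallback: faces sharing a vertex with the degenerate face
        ok = ~degenerate
        mean_l = l3[ok].mean(axis=0)
        for i in np.nonzero(degenerate)[0]:
            shared = np.isin(mesh.faces, mesh.faces[i]).any(axis=1) & ok
            cand = l3[shared].mean(axis=0) if shared.any() else mean_l
            cand = cand - (cand @ n[i]) * n[i]
            if np.linalg.norm(cand) < 1e-12:
                raise DegeneracyError(f"no longitudinal direction for face {i}")
            l3[i] = cand
        nrm = np.linalg.norm(l3, axis=1)
    l3 = l3 / nrm[:, None]
    c3 = np.cross(n, l3)
    c2 = np.stack([np.einsum("ij,ij->i", c3, e1), np.einsum("ij,ij->i", c3, e2)], axis=1)
    l2 = np.stack([np.einsum("ij,ij->i", l3, e1), np.einsum("ij,ij->i", l3, e2)], axis=1)
    return c2, l2, c3, l3


@dataclass(frozen=True)
class StrainField:
    """Per-face strain state relative to a stated reference configuration."""

    F: np.ndarray  # (F, 2, 2)
    E: np.ndarray  # (F, 2, 2)
    e_cc: np.ndarray
    e_ll: np.ndarray
    areal: np.ndarray
    face_region: tuple[str, ...]
    ref_face_area: np.ndarray  # mm^2, reference configuration
    timepoint: str
    reference: str

    @property
    def n_faces(self) -> int:
        return len(self.e_cc)


def compute_strain_field(
    ref_mesh: SurfaceMesh,
    def_vertices: np.ndarray,
    directions: tuple[np.ndarray, np.ndarray] | None = None,
    *,
    long_axis: np.ndarray | None = None,
    timepoint: str = "",
    reference: str = "",
) -> StrainField:
    """Strain of ``def_vertices`` against ``ref_mesh`` (shared connectivity)."""
    if np.shape(def_vertices) != ref_mesh.vertices.shape:
        raise CorrespondenceError(
            f"deformed vertex set {np.shape(def_vertices)} does not match "
            f"reference {ref_mesh.vertices.shape}"
        )
    if directions is None:
        if long_axis is None:
            raise ParameterError("need directions or long_axis")
        c2, l2, _, _ = material_directions(ref_mesh, long_axis)
    else:
        c2, l2 = directions
    F = deformation_gradients(ref_mesh.vertices, np.asarray(def_vertices, float),
                              ref_mesh.faces)
    E = green_lagrange(F)
    return StrainField(
        F=F,
        E=E,
        e_cc=directional_strain(E, c2),
        e_ll=directional_strain(E, l2),
        areal=areal_strain(F),
        face_region=ref_mesh.face_region,
        ref_face_area=ref_mesh.face_areas(),
        timepoint=timepoint,
        reference=reference,
    )


@dataclass(frozen=True)
class CardiacStrainResult:
    """Strain fields over the normalized cycle, referenced to the state's ED."""

    grid: np.ndarray  # percent of cycle
    fields: tuple[StrainField, ...]
    ref_mesh: SurfaceMesh
    state_tag: str

    def regional_timecourse(self, weighted: bool = True) -> pd.DataFrame:
        """Tidy table of regional mean strain per grid time and component."""
        rows = []
        for pct, field in zip(self.grid, self.fields):
            agg = regional_aggregate(field, weighted=weighted)
            for _, r in agg.iterrows():
                rows.append(
                    {
                        "time_pct": pct,
                        "region": r["region"],
                        "component": r["component"],
                        "mean": r["mean"],
                        "sd": r["sd"],
                    }
                )
        return pd.DataFrame(rows)

    def field_at(self, timepoint_pct: float) -> StrainField:
        return self.fields[int(np.argmin(np.abs(self.grid - timepoint_pct)))]


def _base_vertices(beat: AveragedBeat, layout: CrystalLayout, index: int) -> np.ndarray:
    return np.array([beat.crystals[lab][index] for lab in layout.all_labels])


def cardiac_strain_timecourse(
    beat: AveragedBeat, layout: CrystalLayout, levels: int = 2
) -> CardiacStrainResult:
    """Cardiac strain of one state over its cycle, referenced to its own ED.

    The base crystal mesh is built at the ED frame, refined by ``levels`` of
    Loop subdivision; the identical (linear) operator maps every frame's base
    crystal positions to deformed fine vertices, so reference and deformed
    meshes share connectivity exactly.
    """
    base = build_base_mesh(layout, beat.frame("ED"))
    S, ref_mesh = subdivision_operator(base, levels)
    axis = long_axis_from_frame(beat.frame("ED"), layout)
    c2, l2, _, _ = material_directions(ref_mesh, axis)
    fields = []
    for i, pct in enumerate(beat.grid):
        def_fine = S @ _base_vertices(beat, layout, i)
        fields.append(
            compute_strain_field(
                ref_mesh,
                def_fine,
                (c2, l2),
                timepoint=f"{pct:g}%",
                reference="same-state ED",
            )
        )
    return CardiacStrainResult(
        grid=beat.grid, fields=tuple(fields), ref_mesh=ref_mesh,
        state_tag=beat.state_tag,
    )


def interventional_strain(
    baseline_beat: AveragedBeat,
    tra_beat: AveragedBeat,
    layout: CrystalLayout,
    timepoint: str = "ED",
    levels: int = 2,
) -> StrainField:
    """Strain of the TRA state referenced to Baseline at the same time point.

    Connectivity is built once from the Baseline frame and reused for the TRA
    vertex set, guaranteeing face-by-face correspondence.
    """
    for lab in layout.all_labels:
        if lab not in tra_beat.crystals:
            raise CorrespondenceError(f"TRA beat missing crystal {lab!r}")
        if lab not in baseline_beat.crystals:
            raise CorrespondenceError(f"Baseline beat missing crystal {lab!r}")
    base = build_base_mesh(layout, baseline_beat.frame(timepoint))
    S, ref_mesh = subdivision_operator(base, levels)
    axis = long_axis_from_frame(baseline_beat.frame(timepoint), layout)
    i_tra = tra_beat.grid_index(timepoint)
    def_fine = S @ _base_vertices(tra_beat, layout, i_tra)
    return compute_strain_field(
        ref_mesh,
        def_fine,
        long_axis=axis,
        timepoint=str(timepoint),
        reference="Baseline, matched time point",
    )


def regional_aggregate(field: StrainField, weighted: bool = True) -> pd.DataFrame:
    """Per-region mean and SD of each strain component.

    ``weighted=True`` (default) weights faces by reference area; the SD is the
    weighted population SD.  Regions with no faces are reported absent (NaN).
    """
    regions = sorted(set(field.face_region))
    reg = np.asarray(field.face_region)
    rows = []
    for region in regions:
        sel = reg == region
        w = field.ref_face_area[sel] if weighted else np.ones(sel.sum())
        wsum = w.sum()
        for comp in _COMPONENTS:
            x = getattr(field, comp)[sel]
            if wsum == 0 or len(x) == 0:
                mean, sd = float("nan"), float("nan")
            else:
                mean = float(np.sum(w * x) / wsum)
                sd = float(np.sqrt(np.sum(w * (x - mean) ** 2) / wsum))
            rows.append(
                {
                    "region": region,
                    "component": comp,
                    "mean": mean,
                    "sd": sd,
                    "n_faces": int(sel.sum()),
                    "weighting": "area" if weighted else "uniform",
                }
            )
    return pd.DataFrame(rows)


def strain_map_figure(field: StrainField, mesh: SurfaceMesh, component: str = "areal",
                      path=None):
    """Colour map of a per-face strain component (red = compression,
    blue = stretch), projected along the viewing x-axis.  Returns the figure;
    saves to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    if component not in _COMPONENTS:
        raise ParameterError(f"unknown component {component!r}")
    values = getattr(field, component)
    verts2d = mesh.vertices[:, [1, 2]]
    polys = [verts2d[f] for f in mesh.faces]
    vmax = max(np.max(np.abs(values)), 1e-6)
    fig, ax = plt.subplots(figsize=(5, 5))
    coll = PolyCollection(polys, array=values, cmap="RdBu", edgecolor="k",
                          linewidth=0.2)
    coll.set_clim(-vmax, vmax)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_title(f"{component} ({field.reference})")
    fig.colorbar(coll, ax=ax, label=component)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
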