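"""Shared triangulation of corresponded marker points.

Markers are triangulated once, on the turgid (imaged) configuration, and
the connectivity is transferred to the unturgid markers through the
point correspondence.  A direct 3D Delaunay of surface markers yields
poor triangle quality, so the markers are first flattened by a
stereographic-like projection: tip-region markers are projected from a
single center (the center of the tip sphere), pipe-region markers are
unrolled about the axis, and the two regions meet continuously.  In the
plane, the point set gets a standard 2D Delaunay triangulation whose
connectivity is then applied to both 3D marker sets.

Each face stores the basis matrices A (unturgid) and B (turgid) built
from two side vectors and the outward unit normal; the deformation
gradient of the face is the solution of F A = B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .axis_reduction import AxisFrame, optimize_long_axis, outward_reference
from .baseline_spherefit import fit_sphere

__all__ = [
    "SurfaceMesh",
    "estimate_tip_radius",
    "project_markers",
    "delaunay_connectivity",
    "build_mesh",
    "compactness",
    "mean_triangle_area",
]

#: Faces below this compactness are dropped as projection-seam slivers.
MIN_COMPACTNESS = 0.2


def estimate_tip_radius(points: np.ndarray, frame: AxisFrame) -> float:
    """Radius of a sphere fitted to the apex-most cap of a cloud."""
    points = np.asarray(points, dtype=float)
    t = frame.axial(points)
    r_est = float(np.percentile(frame.radial_distance(points), 90))
    cap = points[t >= t.max() - 0.6 * r_est]
    if len(cap) < 4:
        return r_est
    fit = fit_sphere(cap)
    return float(np.clip(fit.radius, 0.2 * r_est, 3.0 * r_est))


def project_markers(
    markers: np.ndarray,
    frame: AxisFrame,
    tip_radius: Optional[float] = None,
    alpha_cut_deg: float = 80.0,
) -> np.ndarray:
    """Flatten markers to a plane above the cell tip.

    Uses polar coordinates ``(R_p, theta)``: ``theta`` is the azimuth
    about the long axis, and ``R_p`` grows monotonically with the
    meridian position.  Within the tip cap (polar angle ``gamma`` about
    the tip-sphere center below ``alpha_cut_deg``) the radius is the
    stereographic ``2 R tan(gamma/2)``; beyond the cut it continues with
    the matched slope as a linear function of the axial drop, so the map
    is continuous, slope-continuous at the seam, and injective for any
    tube-like cell.  Azimuthal and meridional orderings are preserved.
    """
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    R = estimate_tip_radius(markers, frame) if tip_radius is None else float(tip_radius)
    gcut = np.radians(alpha_cut_deg)
    center = frame.tip - R * frame.axis
    u = markers - center
    un = np.linalg.norm(u, axis=1)
    if np.any(un < 1e-12):
        raise ValueError("marker coincides with the projection center")
    gamma = np.arccos(np.clip((u @ frame.axis) / un, -1.0, 1.0))
    t_back = (frame.tip - markers) @ frame.axis          # axial drop behind the tip
    t_cut = R * (1.0 - np.cos(gcut))
    slope = 1.0 / np.cos(gcut / 2.0) ** 2
    r_tip = 2.0 * R * np.tan(np.minimum(gamma, gcut) / 2.0)
    r_pipe = np.maximum(t_back - t_cut, 0.0) * slope
    rp = np.where(gamma < gcut, r_tip, 2.0 * R * np.tan(gcut / 2.0) + r_pipe)
    theta = np.arctan2(markers @ frame.e2 - center @ frame.e2,
                       markers @ frame.e1 - center @ frame.e1)
    return np.column_stack([rp * np.cos(theta), rp * np.sin(theta)])


def delaunay_connectivity(points2d: np.ndarray) -> np.ndarray:
    """Planar Delaunay faces (empty-circumcircle triangulation)."""
    pts = np.asarray(points2d, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    rounded = np.round(pts, 12)
    if len(np.unique(rounded, axis=0)) < len(pts):
        raise ValueError("duplicate projected points")
    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise ValueError(f"degenerate point set: {err}") from None
    if tri.simplices.size == 0:
        raise ValueError("collinear points admit no triangulation")
    return np.sort(tri.simplices, axis=1)


def _face_geometry(pts: np.ndarray, faces: np.ndarray, out_ref: np.ndarray):
    """Side vectors, outward normals, areas, compactness for one config."""
    p0, p1, p2 = (pts[faces[:, k]] for k in range(3))
    v1, v2 = p1 - p0, p2 - p0
    cross = np.cross(v1, v2)
    twice_area = np.linalg.norm(cross, axis=1)
    area = 0.5 * twice_area
    safe = np.where(twice_area > 0, twice_area, 1.0)
    n = cross / safe[:, None]
    flip = np.einsum("ij,ij->i", n, out_ref) < 0
    n[flip] *= -1.0
    e = np.stack([np.linalg.norm(v1, axis=1), np.linalg.norm(v2, axis=1),
                  np.linalg.norm(p2 - p1, axis=1)])
    perim = e.sum(axis=0)
    comp = np.where(perim > 0, 4.0 * np.pi * area / perim**2, 0.0)
    return v1, v2, n, area, comp, e.mean(axis=0)


@dataclass
class SurfaceMesh:
    """Shared triangulation with per-face bases for both configurations.

    ``usable`` marks faces that survive the degeneracy and compactness
    screens; downstream stages add their own masks (sensitivity bound,
    non-physical filter) on top.
    """

    ids: np.ndarray
    pts_unturgid: np.ndarray
    pts_turgid: np.ndarray
    faces: np.ndarray
    A: np.ndarray
    B: np.ndarray
    area_unturgid: np.ndarray
    area_turgid: np.ndarray
    normals_unturgid: np.ndarray
    normals_turgid: np.ndarray
    compactness: np.ndarray
    mean_edge: np.ndarray
    usable: np.ndarray

    @property
    def centroids_turgid(self) -> np.ndarray:
        return self.pts_turgid[self.faces].mean(axis=1)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def build_mesh(
    markers_unturgid: np.ndarray,
    markers_turgid: np.ndarray,
    faces: np.ndarray,
    ids: Optional[np.ndarray] = None,
    frame_turgid: Optional[AxisFrame] = None,
    min_compactness: float = MIN_COMPACTNESS,
    min_area: float = 1e-12,
) -> SurfaceMesh:
    """Assemble per-face bases A and B on the shared connectivity.

    Vertex order is identical in both configurations (the correspondence
    is material), while each configuration's normal is oriented outward
    independently, so ``F = B A^-1`` carries outward normal to outward
    normal.
    """
    mu = np.asarray(markers_unturgid, dtype=float)
    mt = np.asarray(markers_turgid, dtype=float)
    if mu.shape != mt.shape:
        raise ValueError("marker sets must correspond one-to-one")
    faces = np.asarray(faces, dtype=int)
    ids = np.arange(len(mu)) if ids is None else np.asarray(ids)

    ft = optimize_long_axis(mt) if frame_turgid is None else frame_turgid
    try:
        fu = optimize_long_axis(mu)
    except ValueError:
        # marker set too small/ambiguous on its own; the two
        # configurations are nearly aligned, so reuse the turgid frame
        fu = ft
    rt = estimate_tip_radius(mt, ft)
    ru = estimate_tip_radius(mu, fu)
    cen_t = mt[faces].mean(axis=1)
    cen_u = mu[faces].mean(axis=1)
    ref_t = outward_reference(cen_t, ft, rt)
    ref_u = outward_reference(cen_u, fu, ru)

    v1u, v2u, nu_, area_u, _, _ = _face_geometry(mu, faces, ref_u)
    v1t, v2t, nt_, area_t, comp_t, medge = _face_geometry(mt, faces, ref_t)

    A = np.stack([v1u, v2u, nu_], axis=2)
    B = np.stack([v1t, v2t, nt_], axis=2)
    usable = (area_u > min_area) & (area_t > min_area) & (comp_t >= min_compactness)
    return SurfaceMesh(
        ids=ids, pts_unturgid=mu, pts_turgid=mt, faces=faces, A=A, B=B,
        area_unturgid=area_u, area_turgid=area_t,
        normals_unturgid=nu_, normals_turgid=nt_,
        compactness=comp_t, mean_edge=medge, usable=usable,
    )


def write_off(path, points: np.ndarray, faces: np.ndarray) -> None:
    """Write a triangulation as an OFF file for external inspection."""
    points = np.asarray(points, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(points)} {len(faces)} 0\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def compactness(vertices: np.ndarray) -> float:
    """Compactness score 4 pi A / P^2 of one triangle (1 for equilateral-like
    disks is unattainable; equilateral triangles score ~0.605)."""
    v = np.asarray(vertices, dtype=float)
    a = 0.5 * np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0]))
    p = (np.linalg.norm(v[1] - v[0]) + np.linalg.norm(v[2] - v[1])
         + np.linalg.norm(v[0] - v[2]))
    if p == 0:
        raise ValueError("degenerate triangle has no perimeter")
    return float(4.0 * np.pi * a / p**2)


def mean_triangle_area(mesh: SurfaceMesh, L_ref: float) -> Tuple[float, np.ndarray]:
    """Nondimensional mean triangle area and the per-face values.

    The mean of the turgid-face areas over ``L_ref^2`` is the
    triangulation-resolution parameter; the per-face values feed
    histograms.
    """
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    per_face = mesh.area_turgid[mesh.usable] / L_ref**2
    return float(per_face.mean()), per_face
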