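"""Principal curvatures of the wall surface from outline point clouds.

The wall outline extracted from image stacks is an unstructured 3D point
cloud.  To estimate curvature the cloud is split into overlapping charts
by surface orientation -- one cap chart facing the tip and four side
charts around the axis -- and each chart is resampled as a height field
``w(u, v)`` on a regular grid (the "pixel" grid).  First and second
fundamental forms come from centered finite differences with a stride of
``fd_spacing`` grid units, evaluated at every 1-unit shift of the grid;
the Weingarten map ``W = I^-1 II`` (sign fixed so a sphere with outward
normals has positive curvature) yields the principal curvatures and
directions.

Per-point curvatures are rotated into meridional and circumferential
components with Euler's relation

    kappa_s = kappa_1 cos^2 psi + kappa_2 sin^2 psi
    kappa_theta = kappa_2 cos^2 psi + kappa_1 sin^2 psi

where ``psi`` is the angle between the first principal direction and the
local meridional direction, and finally averaged over the wall points
covered by each triangle of the marker mesh.

An analytic surface-of-revolution oracle (exact curvatures of a profile
curve revolved about the axis) backs the discrete pipeline in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, CubicSpline
from scipy.spatial import cKDTree

from .axis_reduction import AxisFrame, local_angle, outward_reference
from .shell_model import CurvaturePair

__all__ = [
    "GridPatch",
    "CurvatureField",
    "parameterize_regions",
    "weingarten_curvatures",
    "analytic_revolution_curvatures",
    "rotate_to_meridional",
    "curvature_field",
    "assign_points_to_faces",
    "average_onto_triangles",
]

#: Grid pitch for synthetic clouds, as a fraction of the cell radius
#: (the "pixel" size; the finite-difference stride is in these units).
DEFAULT_PITCH_FRACTION = 1.0 / 50.0
#: Minimum alignment between a point's outward direction and a chart
#: direction for the point to enter the chart (cos 60 deg).
CHART_ALIGNMENT = 0.5


@dataclass
class GridPatch:
    """One height-field chart: ``X(u,v) = u*e_u + v*e_v + w(u,v)*d``."""

    direction: np.ndarray
    e_u: np.ndarray
    e_v: np.ndarray
    pitch: float
    u0: float
    v0: float
    W: np.ndarray  # (nu, nv) heights, NaN where invalid

    def grid_points(self) -> Tuple[np.ndarray, np.ndarray]:
        nu, nv = self.W.shape
        u = self.u0 + self.pitch * np.arange(nu)
        v = self.v0 + self.pitch * np.arange(nv)
        return u, v

    def embed(self, iu: np.ndarray, iv: np.ndarray) -> np.ndarray:
        """3D position of grid node (iu, iv)."""
        u = self.u0 + self.pitch * np.asarray(iu)
        v = self.v0 + self.pitch * np.asarray(iv)
        w = self.W[iu, iv]
        return (np.multiply.outer(u, self.e_u) + np.multiply.outer(v, self.e_v)
                + np.multiply.outer(w, self.direction))


def _chart_directions(frame: AxisFrame) -> List[np.ndarray]:
    return [frame.axis, frame.e1, -frame.e1, frame.e2, -frame.e2]


def parameterize_regions(
    cloud: np.ndarray,
    frame: AxisFrame,
    tip_radius: float,
    pitch: float,
    alignment: float = CHART_ALIGNMENT,
) -> List[GridPatch]:
    """Split a cloud into orientation charts and resample each on a grid.

    A point joins every chart whose direction is within 60 degrees of its
    approximate outward direction, so neighbouring charts overlap and
    their union covers a tube-like cloud.  Heights are interpolated onto
    the grid with a C1 cubic (Clough-Tocher) scheme; grid nodes farther
    than 2.5 pitches from any data point are invalidated.
    """
    cloud = np.asarray(cloud, dtype=float)
    out = outward_reference(cloud, frame, tip_radius)
    patches: List[GridPatch] = []
    for d in _chart_directions(frame):
        sel = out @ d >= alignment
        if sel.sum() < 16:
            continue
        pts = cloud[sel]
        # orthonormal in-plane axes for this chart
        ref = frame.axis if abs(d @ frame.axis) < 0.9 else frame.e1
        e_u = np.cross(d, ref)
        e_u /= np.linalg.norm(e_u)
        e_v = np.cross(d, e_u)
        u, v, w = pts @ e_u, pts @ e_v, pts @ d
        u0 = u.min()
        v0 = v.min()
        nu = int(np.floor((u.max() - u0) / pitch)) + 1
        nv = int(np.floor((v.max() - v0) / pitch)) + 1
        if nu < 4 or nv < 4:
            continue
        gu = u0 + pitch * np.arange(nu)
        gv = v0 + pitch * np.arange(nv)
        GU, GV = np.meshgrid(gu, gv, indexing="ij")
        interp = CloughTocher2DInterpolator(np.column_stack([u, v]), w)
        W = interp(GU, GV)
        # drop nodes with no nearby data (extrapolation across holes)
        tree = cKDTree(np.column_stack([u, v]))
        dist, _ = tree.query(np.column_stack([GU.ravel(), GV.ravel()]), k=1)
        W.ravel()[dist > 2.5 * pitch] = np.nan
        patches.append(GridPatch(direction=d, e_u=e_u, e_v=e_v, pitch=pitch,
                                 u0=u0, v0=v0, W=W))
    if not patches:
        raise ValueError("cloud too sparse to parameterize")
    return patches


def weingarten_curvatures(patch: GridPatch, fd_spacing: int = 3):
    """Principal curvatures at every grid node with a full stencil.

    Centered differences at stride ``fd_spacing`` are applied at every
    1-unit shift, so all interior nodes receive values.  Returns a dict of
    (nu, nv[, 3]) arrays: ``kappa1 >= kappa2``, 3D principal directions,
    unit outward normals; NaN/invalid where the stencil is incomplete or
    the first fundamental form is ill-conditioned.
    """
    if fd_spacing < 1:
        raise ValueError("fd_spacing must be >= 1 grid unit")
    W = patch.W
    h = patch.pitch * fd_spacing
    k = fd_spacing
    nu, nv = W.shape
    shape = (nu, nv)
    wu = np.full(shape, np.nan)
    wv = np.full(shape, np.nan)
    wuu = np.full(shape, np.nan)
    wvv = np.full(shape, np.nan)
    wuv = np.full(shape, np.nan)
    c = slice(k, -k)
    wu[c, :] = (W[2 * k:, :] - W[:-2 * k, :]) / (2 * h)
    wv[:, c] = (W[:, 2 * k:] - W[:, :-2 * k]) / (2 * h)
    wuu[c, :] = (W[2 * k:, :] - 2 * W[k:-k, :] + W[:-2 * k, :]) / h**2
    wvv[:, c] = (W[:, 2 * k:] - 2 * W[:, k:-k] + W[:, :-2 * k]) / h**2
    wuv[c, c] = (W[2 * k:, 2 * k:] - W[2 * k:, :-2 * k]
                 - W[:-2 * k, 2 * k:] + W[:-2 * k, :-2 * k]) / (4 * h**2)

    E = 1.0 + wu**2
    Ff = wu * wv
    G = 1.0 + wv**2
    denom = np.sqrt(1.0 + wu**2 + wv**2)
    # sign: outward normal has a +d component; a convex cell then gets
    # positive curvatures
    L = -wuu / denom
    M = -wuv / denom
    N = -wvv / denom
    detI = E * G - Ff**2
    with np.errstate(invalid="ignore", divide="ignore"):
        # shape operator S = I^-1 II (2x2), closed form
        s11 = (G * L - Ff * M) / detI
        s12 = (G * M - Ff * N) / detI
        s21 = (E * M - Ff * L) / detI
        s22 = (E * N - Ff * M) / detI
        H = 0.5 * (s11 + s22)
        Kg = s11 * s22 - s12 * s21
        disc = np.sqrt(np.maximum(H**2 - Kg, 0.0))
    k1 = H + disc
    k2 = H - disc
    # eigenvector of S for k1 in (u, v) parameter coordinates
    a1 = np.where(np.abs(s12) + np.abs(k1 - s11) > np.abs(k1 - s22) + np.abs(s21),
                  s12, k1 - s22)
    b1 = np.where(np.abs(s12) + np.abs(k1 - s11) > np.abs(k1 - s22) + np.abs(s21),
                  k1 - s11, s21)
    near_umb = np.abs(a1) + np.abs(b1) < 1e-12
    a1 = np.where(near_umb, 1.0, a1)
    b1 = np.where(near_umb, 0.0, b1)
    # 3D tangent vectors X_u, X_v
    Xu = (patch.e_u[None, None, :] + wu[..., None] * patch.direction[None, None, :])
    Xv = (patch.e_v[None, None, :] + wv[..., None] * patch.direction[None, None, :])
    dir1 = a1[..., None] * Xu + b1[..., None] * Xv
    nrm = np.linalg.norm(dir1, axis=-1, keepdims=True)
    dir1 = dir1 / np.where(nrm > 0, nrm, 1.0)
    normal = (-wu[..., None] * patch.e_u[None, None, :]
              - wv[..., None] * patch.e_v[None, None, :]
              + patch.direction[None, None, :]) / denom[..., None]
    valid = np.isfinite(k1) & np.isfinite(k2) & (detI > 1e-6)
    return {"kappa1": k1, "kappa2": k2, "dir1": dir1, "normal": normal, "valid": valid}


def analytic_revolution_curvatures(meridian: np.ndarray) -> CurvaturePair:
    """Exact curvatures of a revolved meridian (test oracle).

    The meridian is an ``(n, 2)`` array of ``(x, r)`` with the apex on the
    axis.  ``kappa_s`` is the profile-curve curvature, ``kappa_theta =
    sin(phi)/r`` with ``phi`` the tangent angle; at the apex both limits
    agree.
    """
    m = np.asarray(meridian, dtype=float)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(m[:, 0]), np.diff(m[:, 1])))])
    x = CubicSpline(s, m[:, 0])
    r = CubicSpline(s, m[:, 1])
    phi = np.unwrap(np.arctan2(-x(s, 1), r(s, 1)))
    kappa_s = CubicSpline(s, phi)(s, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_t = np.sin(phi) / m[:, 1]
    on_axis = m[:, 1] <= 1e-9
    if np.any(on_axis[1:-1] | on_axis[-1:]):
        raise ValueError("radius vanishes away from the apex")
    kappa_t[on_axis] = kappa_s[on_axis]
    return CurvaturePair(kappa_s=kappa_s, kappa_theta=kappa_t)


def rotate_to_meridional(kappa1, kappa2, psi) -> CurvaturePair:
    """Euler's relation: principal -> meridional/circumferential curvatures."""
    c2 = np.cos(psi) ** 2
    s2 = np.sin(psi) ** 2
    return CurvaturePair(kappa_s=np.asarray(kappa1) * c2 + np.asarray(kappa2) * s2,
                         kappa_theta=np.asarray(kappa2) * c2 + np.asarray(kappa1) * s2)


@dataclass
class CurvatureField:
    """Per-wall-point curvature data."""

    points: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray
    kappa_s: np.ndarray
    kappa_theta: np.ndarray
    normal: np.ndarray
    alpha_deg: np.ndarray
    psi: np.ndarray
    valid: np.ndarray


def _bilinear(patch_vals: np.ndarray, fi: np.ndarray, fj: np.ndarray, valid: np.ndarray):
    """Bilinear interpolation of node values with validity fallback."""
    nu, nv = valid.shape
    i0 = np.clip(np.floor(fi).astype(int), 0, nu - 2)
    j0 = np.clip(np.floor(fj).astype(int), 0, nv - 2)
    ti = fi - i0
    tj = fj - j0
    corners = [(i0, j0, (1 - ti) * (1 - tj)), (i0 + 1, j0, ti * (1 - tj)),
               (i0, j0 + 1, (1 - ti) * tj), (i0 + 1, j0 + 1, ti * tj)]
    wsum = np.zeros(len(fi))
    if patch_vals.ndim == 3:
        acc = np.zeros((len(fi), patch_vals.shape[-1]))
    else:
        acc = np.zeros(len(fi))
    for ii, jj, wgt in corners:
        ok = valid[ii, jj]
        wgt = np.where(ok, wgt, 0.0)
        wsum += wgt
        if patch_vals.ndim == 3:
            acc += np.where(ok[:, None], patch_vals[ii, jj], 0.0) * wgt[:, None]
        else:
            acc += np.where(ok, patch_vals[ii, jj], 0.0) * wgt
    good = wsum > 1e-12
    if patch_vals.ndim == 3:
        acc[good] /= wsum[good, None]
    else:
        acc[good] /= wsum[good]
    return acc, good


def curvature_field(
    cloud: np.ndarray,
    frame: AxisFrame,
    tip_radius: float,
    pitch: Optional[float] = None,
    fd_spacing: int = 3,
    L_ref: float = 1.0,
) -> CurvatureField:
    """Full per-point curvature estimation for a wall-outline cloud.

    Each point is evaluated on the chart best aligned with its outward
    direction (falling back to the next best where the stencil is
    incomplete).  ``pitch`` defaults to ``L_ref/50``.  Curvatures are
    returned in cloud length units; multiply by ``L_ref`` for the
    nondimensional values.
    """
    cloud = np.asarray(cloud, dtype=float)
    pitch = DEFAULT_PITCH_FRACTION * L_ref if pitch is None else pitch
    patches = parameterize_regions(cloud, frame, tip_radius, pitch)
    results = [weingarten_curvatures(p, fd_spacing) for p in patches]
    out = outward_reference(cloud, frame, tip_radius)

    n = len(cloud)
    kap1 = np.full(n, np.nan)
    kap2 = np.full(n, np.nan)
    nrm = np.full((n, 3), np.nan)
    dir1 = np.full((n, 3), np.nan)
    done = np.zeros(n, dtype=bool)

    align = np.stack([out @ p.direction for p in patches], axis=1)
    order = np.argsort(-align, axis=1)
    for rank in range(len(patches)):
        todo = ~done
        if not np.any(todo):
            break
        for pi in range(len(patches)):
            sel = todo & (order[:, rank] == pi) & (align[:, pi] >= CHART_ALIGNMENT)
            if not np.any(sel):
                continue
            p, res = patches[pi], results[pi]
            pts = cloud[sel]
            fi = (pts @ p.e_u - p.u0) / p.pitch
            fj = (pts @ p.e_v - p.v0) / p.pitch
            k1v, ok1 = _bilinear(res["kappa1"], fi, fj, res["valid"])
            k2v, _ = _bilinear(res["kappa2"], fi, fj, res["valid"])
            nv_, _ = _bilinear(res["normal"], fi, fj, res["valid"])
            d1v, _ = _bilinear(res["dir1"], fi, fj, res["valid"])
            idx = np.where(sel)[0][ok1]
            kap1[idx] = k1v[ok1]
            kap2[idx] = k2v[ok1]
            nrm[idx] = nv_[ok1]
            dir1[idx] = d1v[ok1]
            done[idx] = True

    valid = done & np.isfinite(kap1)
    # re-normalize interpolated vectors
    ln = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm = nrm / np.where(ln > 0, ln, 1.0)
    ld = np.linalg.norm(dir1, axis=1, keepdims=True)
    dir1 = dir1 / np.where(ld > 0, ld, 1.0)

    # meridional direction at each point: tangent-plane projection of the
    # tip direction; psi is its angle to the first principal direction
    tau = frame.tip - cloud
    tau_t = tau - np.einsum("ij,ij->i", tau, nrm)[:, None] * nrm
    lt = np.linalg.norm(tau_t, axis=1, keepdims=True)
    apexish = lt[:, 0] < 1e-9
    tau_t = np.where(apexish[:, None], dir1, tau_t / np.where(lt > 0, lt, 1.0))
    cospsi = np.clip(np.abs(np.einsum("ij,ij->i", dir1, tau_t)), 0.0, 1.0)
    psi = np.arccos(cospsi)
    rot = rotate_to_meridional(kap1, kap2, psi)
    alpha = local_angle(nrm, frame.axis)
    if valid.mean() < 0.95:
        warnings.warn(f"curvature estimated on only {valid.mean():.0%} of wall points")
    return CurvatureField(points=cloud, kappa1=kap1, kappa2=kap2,
                          kappa_s=rot.kappa_s, kappa_theta=rot.kappa_theta,
                          normal=nrm, alpha_deg=alpha, psi=psi, valid=valid)


def assign_points_to_faces(
    points: np.ndarray,
    mesh_points: np.ndarray,
    faces: np.ndarray,
    mean_edge: np.ndarray,
    n_candidates: int = 6,
    plane_tol_fraction: float = 0.25,
) -> np.ndarray:
    """Map each wall point to at most one mesh face.

    A point belongs to the first of its nearest candidate faces that
    contains its projection (barycentric test on the face plane) *and*
    lies close to that plane -- within ``plane_tol_fraction`` of the face
    mean edge, which admits the sag of a curved wall over its chordal
    triangle but rejects e.g. apex-crown points hovering far above
    surrounding faces, whose material region does not cover them.  If no
    candidate contains the point, it falls back to the nearest face
    centroid within one mean edge length (same plane criterion).
    Returns the face index per point, -1 if unassigned.
    """
    points = np.asarray(points, dtype=float)
    centroids = mesh_points[faces].mean(axis=1)
    tree = cKDTree(centroids)
    kq = min(n_candidates, len(faces))
    dist, cand = tree.query(points, k=kq)
    if kq == 1:
        dist, cand = dist[:, None], cand[:, None]
    assigned = np.full(len(points), -1, dtype=int)
    p0 = mesh_points[faces[:, 0]]
    v1 = mesh_points[faces[:, 1]] - p0
    v2 = mesh_points[faces[:, 2]] - p0
    nrm = np.cross(v1, v2)
    nlen = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm = nrm / np.where(nlen > 0, nlen, 1.0)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d12 = np.einsum("ij,ij->i", v1, v2)
    d22 = np.einsum("ij,ij->i", v2, v2)
    inv_det = 1.0 / np.maximum(d11 * d22 - d12**2, 1e-300)
    for r in range(kq):
        todo = assigned < 0
        if not np.any(todo):
            break
        f = cand[todo, r]
        w = points[todo] - p0[f]
        dw1 = np.einsum("ij,ij->i", w, v1[f])
        dw2 = np.einsum("ij,ij->i", w, v2[f])
        b1 = (d22[f] * dw1 - d12[f] * dw2) * inv_det[f]
        b2 = (d11[f] * dw2 - d12[f] * dw1) * inv_det[f]
        h = np.abs(np.einsum("ij,ij->i", w, nrm[f]))
        inside = ((b1 >= -1e-9) & (b2 >= -1e-9) & (b1 + b2 <= 1 + 1e-9)
                  & (h <= plane_tol_fraction * mean_edge[f]))
        idx = np.where(todo)[0][inside]
        assigned[idx] = f[inside]
    # fallback: nearest centroid within one mean edge length
    todo = assigned < 0
    f0 = cand[todo, 0]
    w = points[todo] - p0[f0]
    h = np.abs(np.einsum("ij,ij->i", w, nrm[f0]))
    close = (dist[todo, 0] <= mean_edge[f0]) & (h <= plane_tol_fraction * mean_edge[f0])
    idx = np.where(todo)[0][close]
    assigned[idx] = f0[close]
    return assigned


def average_onto_triangles(
    per_point: Dict[str, np.ndarray],
    assigned: np.ndarray,
    n_faces: int,
    point_valid: Optional[np.ndarray] = None,
    alpha_deg: Optional[np.ndarray] = None,
):
    """Arithmetic per-face means of point-wise fields, plus alpha ranges.

    Returns ``(means, alpha_ranges, counts)``: ``means`` maps each field
    name to an (n_faces,) array (NaN where a face has no points);
    ``alpha_ranges`` is (n_faces, 2).
    """
    ok = assigned >= 0
    if point_valid is not None:
        ok &= point_valid
    counts = np.bincount(assigned[ok], minlength=n_faces)
    means = {}
    for name, vals in per_point.items():
        s = np.bincount(assigned[ok], weights=np.asarray(vals)[ok], minlength=n_faces)
        means[name] = np.where(counts > 0, s / np.maximum(counts, 1), np.nan)
    alpha_ranges = np.full((n_faces, 2), np.nan)
    if alpha_deg is not None:
        a = np.asarray(alpha_deg)
        amin = np.full(n_faces, np.inf)
        amax = np.full(n_faces, -np.inf)
        np.minimum.at(amin, assigned[ok], a[ok])
        np.maximum.at(amax, assigned[ok], a[ok])
        alpha_ranges[:, 0] = np.where(np.isfinite(amin), amin, np.nan)
        alpha_ranges[:, 1] = np.where(np.isfinite(amax), amax, np.nan)
    return means, alpha_ranges, counts
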