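"""Reduction of surface quantities to the axisymmetric outline model.

A tip-growing cell is approximately a surface of revolution; the
pipeline therefore reduces per-triangle and per-point surface fields to
one-dimensional profiles.  The coordinate is the local angle

    alpha = arccos(n . z)    (0 deg at the apex, 90 deg on the shank)

between the outward surface normal ``n`` and an optimized long axis
``z``.  Because each triangle spans a range of wall points, it carries a
range of alpha values; binned profiles spread every triangle over the
bins its range overlaps, which is also what smooths the meridional
curvature in the last (side) bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .shell_model import StretchPair

__all__ = [
    "AxisFrame",
    "BinnedProfile",
    "optimize_long_axis",
    "local_angle",
    "outward_reference",
    "triangle_frames",
    "directional_stretches",
    "bin_by_alpha",
    "bin_points_by_alpha",
    "default_bin_edges",
    "profile_endpoint_values",
]

#: Side region demarcation: alpha in [80 deg, 90 deg] is "cell side".
SIDE_ALPHA_DEG = 80.0


def default_bin_edges(n_bins: int = 9) -> np.ndarray:
    """Equal-width alpha bins partitioning [0 deg, 90 deg]."""
    return np.linspace(0.0, 90.0, n_bins + 1)


@dataclass(frozen=True)
class AxisFrame:
    """Optimized long axis, tip point and a transverse orthonormal basis."""

    axis: np.ndarray
    tip: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    @classmethod
    def from_axis_tip(cls, axis, tip) -> "AxisFrame":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        return cls(axis=axis, tip=np.asarray(tip, dtype=float), e1=e1, e2=e2)

    def axial(self, points: np.ndarray) -> np.ndarray:
        """Axial coordinate (projection on the axis), tip at the maximum."""
        return np.asarray(points) @ self.axis

    def radial_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points) - self.tip
        t = p @ self.axis
        return np.linalg.norm(p - np.outer(t, self.axis), axis=-1)


def optimize_long_axis(cloud: np.ndarray) -> AxisFrame:
    """Long axis as the principal second-moment direction of the cloud.

    The sign is chosen so the axis points toward the cell tip: of the two
    extreme points along the candidate axis, the apex lies on the axis
    while the cut shank end is a full ring, so the orientation whose
    extreme point sits closest to the axis line wins.  The tip is the
    point of maximal axial projection (rotation-invariant, unlike a raw
    max of one lab coordinate).
    """
    cloud = np.asarray(cloud, dtype=float)
    center = cloud.mean(axis=0)
    dev = cloud - center
    cov = dev.T @ dev / len(cloud)
    w, v = np.linalg.eigh(cov)
    # the transverse second moments of an axisymmetric tube form a
    # degenerate pair; the axis is the remaining eigenvector (largest
    # moment for a long cell, but the smallest for a strongly inflated
    # short cell).  The pair must be much tighter than its separation
    # from the isolated eigenvalue, otherwise no axis is defined.
    g01, g12 = w[1] - w[0], w[2] - w[1]
    pair_gap, isolated_gap = min(g01, g12), max(g01, g12)
    if isolated_gap < 4.0 * max(pair_gap, 1e-12 * w[2]) or isolated_gap < 1e-6 * w[2]:
        raise ValueError("cloud is too isotropic to define a long axis")
    axis = v[:, 0] if g01 > g12 else v[:, 2]
    best = None
    for sign in (1.0, -1.0):
        cand = sign * axis
        t = dev @ cand
        i_ext = int(np.argmax(t))
        radial = np.linalg.norm(dev[i_ext] - t[i_ext] * cand)
        if best is None or radial < best[0]:
            best = (radial, cand, cloud[i_ext])
    _, axis, tip = best
    return AxisFrame.from_axis_tip(axis, tip)


def local_angle(normals: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Local angle alpha in degrees, clipped to [0, 90]."""
    n = np.atleast_2d(np.asarray(normals, dtype=float))
    c = np.clip(n @ np.asarray(axis, dtype=float), -1.0, 1.0)
    alpha = np.degrees(np.arccos(c))
    return np.clip(alpha, 0.0, 90.0)


def outward_reference(points: np.ndarray, frame: AxisFrame, tip_radius: float) -> np.ndarray:
    """Approximate outward directions for orientation decisions.

    On the pipe the outward direction is radial from the axis; near the
    apex it is the direction from the center of the tip sphere.  Realized
    by clamping the axis foot point to at least ``tip_radius`` behind the
    tip, which blends the two continuously.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    t = (points - frame.tip) @ frame.axis  # <= 0 going back from the tip
    t_clamped = np.minimum(t, -tip_radius)
    feet = frame.tip + np.outer(t_clamped, frame.axis)
    out = points - feet
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return out / norms


def triangle_frames(
    dir1_t: np.ndarray,
    dir2_t: np.ndarray,
    normals_t: np.ndarray,
    centroids_t: np.ndarray,
    tip: np.ndarray,
    degenerate_cos: float = 0.995,
):
    """Meridional/circumferential unit directions on each turgid face.

    With the principal stretch directions ``{x1b, x2b}`` as the tangent
    basis, the circumferential direction is the in-plane vector
    ``v(phi*) = cos(phi*) x1b + sin(phi*) x2b`` exactly perpendicular to
    the tip direction ``tau``; the meridional direction is its in-plane
    orthogonal complement oriented toward the tip.  Faces whose tangent
    plane is nearly perpendicular to ``tau`` (apex-covering faces) are
    flagged and fall back to the principal directions.

    Returns ``(v_s, v_theta, degenerate_mask)``.
    """
    x1 = np.atleast_2d(dir1_t)
    x2 = np.atleast_2d(dir2_t)
    n = np.atleast_2d(normals_t)
    tau = np.asarray(tip, dtype=float) - np.atleast_2d(centroids_t)
    tau /= np.linalg.norm(tau, axis=1, keepdims=True)

    a = np.einsum("ij,ij->i", x1, tau)
    b = np.einsum("ij,ij->i", x2, tau)
    degenerate = np.hypot(a, b) < np.sqrt(1.0 - degenerate_cos**2)
    phi = np.arctan2(-a, b)  # v(phi).tau = a cos(phi) + b sin(phi) = 0
    v_theta = np.cos(phi)[:, None] * x1 + np.sin(phi)[:, None] * x2
    v_s = -np.sin(phi)[:, None] * x1 + np.cos(phi)[:, None] * x2
    flip = np.einsum("ij,ij->i", v_s, tau) < 0
    v_s[flip] *= -1.0
    if np.any(degenerate):
        v_s[degenerate] = x1[degenerate]
        v_theta[degenerate] = x2[degenerate]
        warnings.warn(f"{int(degenerate.sum())} apex-degenerate triangle frame(s); "
                      "falling back to principal directions")
    return v_s, v_theta, degenerate


def directional_stretches(F_inv: np.ndarray, v_s: np.ndarray, v_theta: np.ndarray) -> StretchPair:
    """Stretch ratios along the meridional/circumferential directions.

    The optimized directions live on the turgid tangent plane, so the
    inverse map carries them back: ``lambda = 1 / |F^-1 v|``.
    """
    ls = 1.0 / np.linalg.norm(np.einsum("fij,fj->fi", F_inv, v_s), axis=1)
    lt = 1.0 / np.linalg.norm(np.einsum("fij,fj->fi", F_inv, v_theta), axis=1)
    return StretchPair(lambda_s=ls, lambda_theta=lt)


@dataclass
class BinnedProfile:
    """An alpha-binned scalar profile: per-bin mean, SD, count, weight."""

    edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray
    weight: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.count > 0

    def side_bins(self, side_min: float = SIDE_ALPHA_DEG) -> np.ndarray:
        return (self.centers >= side_min) & self.nonempty


def bin_by_alpha(
    values: np.ndarray,
    alpha_ranges: np.ndarray,
    edges: Optional[np.ndarray] = None,
) -> BinnedProfile:
    """Bin per-face values whose faces span alpha ranges.

    Each face contributes to every bin its ``[alpha_min, alpha_max]``
    range overlaps, weighted by the fractional overlap, so a face is
    never double counted and sharp bin boundaries are smoothed at the
    triangle scale.
    """
    edges = default_bin_edges() if edges is None else np.asarray(edges, dtype=float)
    values = np.asarray(values, dtype=float)
    rng = np.atleast_2d(np.asarray(alpha_ranges, dtype=float))
    lo, hi = rng[:, 0], rng[:, 1]
    width = np.maximum(hi - lo, 0.0)
    nb = len(edges) - 1
    w = np.zeros((len(values), nb))
    for j in range(nb):
        overlap = np.minimum(hi, edges[j + 1]) - np.maximum(lo, edges[j])
        frac = np.where(width > 0, np.clip(overlap, 0.0, None) / np.where(width > 0, width, 1.0), 0.0)
        # zero-width ranges: point mass in the containing bin
        inside = (width == 0) & (lo >= edges[j]) & ((lo < edges[j + 1]) | (j == nb - 1) & (lo <= edges[j + 1]))
        w[:, j] = np.where(inside, 1.0, frac)
    ok = np.isfinite(values)
    w[~ok] = 0.0
    wsum = w.sum(axis=0)
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    nonzero = wsum > 0
    vals = np.where(ok, values, 0.0)
    mean[nonzero] = (w[:, nonzero] * vals[:, None]).sum(axis=0) / wsum[nonzero]
    var = np.zeros(nb)
    var[nonzero] = (w[:, nonzero] * (vals[:, None] - mean[None, :])[:, nonzero] ** 2).sum(axis=0) / wsum[nonzero]
    sd[nonzero] = np.sqrt(var[nonzero])
    count = (w > 0).sum(axis=0)
    return BinnedProfile(edges=edges, mean=mean, sd=sd, count=count, weight=wsum)


def bin_points_by_alpha(
    alpha: np.ndarray,
    values: np.ndarray,
    edges: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> BinnedProfile:
    """Bin point-wise values by their alpha (used for ground-truth profiles)."""
    edges = default_bin_edges() if edges is None else np.asarray(edges, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    values = np.asarray(values, dtype=float)
    weights = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    idx = np.clip(np.digitize(alpha, edges) - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    wsum = np.zeros(nb)
    for j in range(nb):
        m = idx == j
        count[j] = int(m.sum())
        if count[j]:
            wj = weights[m]
            wsum[j] = wj.sum()
            mean[j] = np.average(values[m], weights=wj)
            sd[j] = np.sqrt(np.average((values[m] - mean[j]) ** 2, weights=wj))
    return BinnedProfile(edges=edges, mean=mean, sd=sd, count=count, weight=wsum)


def profile_endpoint_values(profile: BinnedProfile, side_min: float = SIDE_ALPHA_DEG) -> Tuple[float, float]:
    """Side and tip endpoint values of a binned profile.

    The side endpoint averages the side-region bins (centers at or above
    ``side_min``, weight-averaged); the tip endpoint is the apex-most
    nonempty bin.  Their ratio ``K_side/K_tip`` is the pipeline's summary
    of a spatial modulus gradient.
    """
    side = profile.side_bins(side_min)
    nonempty = profile.nonempty
    if not np.any(side) or not np.any(nonempty):
        raise ValueError("endpoint bins are empty")
    k_side = float(np.average(profile.mean[side], weights=profile.weight[side]))
    k_tip = float(profile.mean[np.argmax(nonempty)])
    return k_side, k_tip
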