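"""Radius-change baseline for wall surface modulus estimation.

The comparison method from the filamentous-fungi literature infers the
wall surface modulus ``Y`` from how much the cell radius relaxes on
plasmolysis, with no marker tracking.  With pressure and wall thickness
scaled out (lengths in units of the unturgid side radius, ``Y`` in units
of ``P*L``):

    side (cylinder):  Y_side = R_A * R_B / (R_B - R_A)
    tip  (sphere):    Y_tip  = R_A * R_B / (2 * (R_B - R_A))

where ``R_A`` and ``R_B`` are the unturgid and turgid radii.  These are
the linear-elastic relations ``Y = sigma_theta / epsilon_theta`` for a
pressurized cylinder (hoop tension ``P R_B``) and sphere (tension
``P R_B / 2``) at Poisson ratio zero, where ``Y = Eh = 2 K_h``.  Because
the tip of a real cell is not a sphere, the fitted tip radius depends on
how much of the wall outline is used; the method is therefore evaluated
over a sweep of coverages rather than at a single number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .axis_reduction import AxisFrame

__all__ = [
    "SphereFitResult",
    "fit_sphere",
    "side_radius",
    "surface_modulus_side",
    "surface_modulus_tip",
    "coverage_sweep",
]


@dataclass(frozen=True)
class SphereFitResult:
    center: np.ndarray
    radius: float
    rms_residual: float
    coverage_deg: Optional[float] = None


def fit_sphere(points: np.ndarray, refine: int = 1) -> SphereFitResult:
    """Least-squares sphere through a point cloud.

    Algebraic (linear) least squares on ``|p|^2 = 2 c.p + (R^2 - |c|^2)``
    followed by ``refine`` Gauss-Newton steps on the geometric residual
    ``|p - c| - R``.  Exact for points sampled on a sphere, even partial
    caps.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[0] < 4:
        raise ValueError("need at least 4 points")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar or collinear) point set")
    c = sol[:3]
    R = float(np.sqrt(sol[3] + c @ c))
    for _ in range(refine):
        d = p - c
        r = np.linalg.norm(d, axis=1)
        J = np.column_stack([-d / r[:, None], -np.ones(len(p))])
        res = r - R
        try:
            step = np.linalg.lstsq(J, res, rcond=None)[0]
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        c = c - step[:3]
        R = R - float(step[3])
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - c, axis=1) - R) ** 2)))
    return SphereFitResult(center=c, radius=float(R), rms_residual=rms)


def side_radius(cloud: np.ndarray, frame: AxisFrame, tail_fraction: float = 0.3) -> float:
    """Cell-side radius: mean distance to the axis over the far shank.

    Uses the rearmost ``tail_fraction`` of the cell's axial extent, where
    the meridian is closest to its cylindrical asymptote.
    """
    cloud = np.asarray(cloud, dtype=float)
    t = frame.axial(cloud)
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("degenerate cloud")
    m = t <= t.min() + tail_fraction * span
    if m.sum() < 10:
        raise ValueError("no identifiable shank region")
    return float(np.mean(frame.radial_distance(cloud[m])))


def surface_modulus_side(R_A: float, R_B: float) -> float:
    """Side surface modulus from the radius change; units of ``P * R_A``."""
    if R_A <= 0:
        raise ValueError("R_A must be positive")
    return R_A * R_B / (R_B - R_A)


def surface_modulus_tip(R_A: float, R_B: float) -> float:
    """Tip surface modulus from the fitted tip radii; units of ``P * R_A``.

    ``R_B < R_A`` yields a negative, non-physical value -- returned as is,
    since that failure mode (rounder cells at partial coverage) is part of
    what the coverage sweep reports.
    """
    return R_A * R_B / (2.0 * (R_B - R_A))


def _tip_cap(cloud: np.ndarray, frame: AxisFrame, coverage_deg: float) -> np.ndarray:
    """Points of the tip cap up to a polar-angle coverage.

    The polar angle is measured about the center of a sphere pre-fitted
    to the apex-most cap, so coverages are comparable between turgid and
    unturgid configurations.
    """
    cloud = np.asarray(cloud, dtype=float)
    t = frame.axial(cloud)
    t_tip = t.max()
    r_est = np.percentile(frame.radial_distance(cloud), 90)
    seed = cloud[t >= t_tip - 0.5 * r_est]
    pre = fit_sphere(seed)
    u = cloud - pre.center
    polar = np.degrees(np.arccos(np.clip((u @ frame.axis) / np.linalg.norm(u, axis=1), -1, 1)))
    return cloud[polar <= coverage_deg]


def coverage_sweep(
    cloud_unturgid: np.ndarray,
    cloud_turgid: np.ndarray,
    frame_unturgid: Optional[AxisFrame] = None,
    frame_turgid: Optional[AxisFrame] = None,
    coverages_deg: Sequence[float] = tuple(range(20, 100, 10)),
):
    """Sphere-fit both tip caps at matched coverages and evaluate Y_tip.

    Returns a list of records ``(coverage, R_A, R_B, Y_tip)``; ``Y_tip``
    is normalized by the unturgid side radius so it is comparable with
    ``2 K_h``.
    """
    from .axis_reduction import optimize_long_axis

    fu = optimize_long_axis(cloud_unturgid) if frame_unturgid is None else frame_unturgid
    ft = optimize_long_axis(cloud_turgid) if frame_turgid is None else frame_turgid
    L = side_radius(cloud_unturgid, fu)
    rows = []
    for cov in coverages_deg:
        fit_a = fit_sphere(_tip_cap(cloud_unturgid, fu, cov))
        fit_b = fit_sphere(_tip_cap(cloud_turgid, ft, cov))
        R_A, R_B = fit_a.radius / L, fit_b.radius / L
        rows.append({
            "coverage_deg": float(cov), "R_A": R_A, "R_B": R_B,
            "Y_tip": surface_modulus_tip(R_A, R_B),
        })
    return rows
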