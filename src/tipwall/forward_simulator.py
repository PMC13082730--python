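"""Synthetic tip-growing cells with known ground-truth wall elasticity.

The unturgid (plasmolyzed) meridian is a hyphoid curve

    x(y) = (pi * y * cot(pi * y) - 1) / a

whose single parameter ``a`` controls the taper: ``a = 4.1`` matches the
more tapered caulonema cells of *Physcomitrium patens*, ``a = 5.7`` the
rounder chloronema cells.  A spatial profile of surface bulk modulus
``K_h`` (constant, linear, or sigmoidal in the axial coordinate) is
prescribed on this unloaded outline, the shear modulus following from a
constant Poisson ratio.  The turgid configuration is then solved as an
axisymmetric membrane equilibrium: at every material station the tensions
from the constitutive law (with ``lambda_theta = r_t/r_u`` and
``lambda_s = ds_t/ds_u``) equal the Young-Laplace tensions of the turgid
geometry.

The equilibrium is a two-point boundary-value problem in the unturgid
arclength ``S`` with state ``(r, phi)`` (turgid radius and tangent
angle), the meridional stretch eliminated pointwise from the axial force
balance, the apex stretch as an unknown parameter fixed by apex
regularity, and a cylindrical far field ``phi = pi/2`` imposed on a
padded shank so the boundary condition cannot pollute the reported cell.

From the solved meridian the module builds the observable data an
experiment would provide: revolved 3D wall-outline clouds, ring-structured
corresponded marker sets, Gaussian marker noise (z variance above the
x-y variance, as measured for the imaging setup), a normal-direction
outline bias, and cohorts of cells with size variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_bvp
from scipy.interpolate import CubicSpline

from .shell_model import ModuliPair, NondimScheme, StretchPair, TensionPair

__all__ = [
    "HyphoidSpec",
    "ModulusProfile",
    "NoiseSpec",
    "ForwardSolution",
    "CellConfigurationPair",
    "CAULONEMA_A",
    "CHLORONEMA_A",
    "hyphoid_outline",
    "hyphoid_apex_curvature",
    "solve_turgid_outline",
    "revolve_surface",
    "generate_marker_sets",
    "apply_marker_noise",
    "apply_outline_noise",
    "generate_cell",
    "generate_cohort",
]

CAULONEMA_A = 4.1
CHLORONEMA_A = 5.7


@dataclass(frozen=True)
class HyphoidSpec:
    """Geometry and sampling of a synthetic hyphoid cell.

    ``radius`` is the asymptotic shank radius (the length scale L of the
    nondimensionalization).  The meridian is truncated where the radius
    reaches ``shank_fraction`` of the asymptote; the equilibrium solver
    internally pads the shank by ``pad_length`` radii.
    """

    a: float = CAULONEMA_A
    radius: float = 1.0
    n_outline: int = 129
    n_marker_stations: int = 17
    n_revolve: int = 256
    n_revolve_markers: int = 16
    outline_upsample: int = 2  # outline-cloud stations = upsample*(n_outline-1)+1
    shank_fraction: float = 0.93
    pad_length: float = 4.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("taper parameter a must be positive")
        if not (self.n_outline >= self.n_marker_stations >= 5):
            raise ValueError("need n_outline >= n_marker_stations >= 5")

    @property
    def length(self) -> float:
        """Axial length of the reported (truncated) cell, in radii."""
        return float(-_hyphoid_x(self.shank_fraction, self.a))


def caulonema(**kw) -> HyphoidSpec:
    return HyphoidSpec(a=CAULONEMA_A, **kw)


def chloronema(**kw) -> HyphoidSpec:
    return HyphoidSpec(a=CHLORONEMA_A, **kw)


def _hyphoid_x(y, a):
    """Hyphoid meridian, apex at the origin, axis along x (cell at x<0)."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = np.abs(y) < 1e-8
    # pi*y*cot(pi*y) -> 1 - (pi*y)^2/3 as y -> 0
    out[small] = -(np.pi * y[small]) ** 2 / (3.0 * a)
    ys = y[~small]
    out[~small] = (np.pi * ys / np.tan(np.pi * ys) - 1.0) / a
    return out if out.ndim else float(out)


def hyphoid_apex_curvature(a: float) -> float:
    """Meridian curvature at the hyphoid apex (nondimensional, radius 1)."""
    return 2.0 * np.pi**2 / (3.0 * a)


def hyphoid_outline(spec: HyphoidSpec, n: Optional[int] = None) -> np.ndarray:
    """Unturgid meridian sampled uniformly in arclength.

    Returns an ``(n, 2)`` array of ``(x, r)`` with the apex at the origin,
    scaled by ``spec.radius``.
    """
    n = spec.n_outline if n is None else n
    x, r, S = _dense_meridian(spec.a, spec.shank_fraction)
    s_out = np.linspace(0.0, S[-1], n)
    return np.column_stack([np.interp(s_out, S, x), np.interp(s_out, S, r)]) * spec.radius


def _dense_meridian(a: float, y_max: float, n: int = 20001):
    y = np.linspace(1e-7, y_max, n)
    x = _hyphoid_x(y, a)
    S = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    return x, y, S


@dataclass(frozen=True)
class ModulusProfile:
    """Spatial profile of the surface bulk modulus along the unturgid cell.

    ``kind`` is one of ``constant``, ``linear``, ``nonlinear``.  The
    profile is a function of the axial distance ``z`` from the apex (in
    radii): linear profiles interpolate from ``K_tip`` at the apex to
    ``K_side`` at the end of the cell; nonlinear profiles are a logistic
    transition of midpoint ``transition_mid`` and width ``transition_width``
    so that side and tip plateaus each occupy most of the cell.  The shear
    modulus follows from a constant Poisson ratio ``nu``
    (``mu_h = K_h (1 - nu)/(1 + nu)``).
    """

    kind: str = "constant"
    K_side: float = 5.0
    K_tip: float = 5.0
    nu: float = 0.5
    transition_mid: float = 0.8
    transition_width: float = 0.15
    ramp_length: Optional[float] = None  # linear kind: axial span of the ramp

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "nonlinear"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "constant" and self.K_side != self.K_tip:
            raise ValueError("constant profile requires K_side == K_tip")
        if not (self.K_side >= self.K_tip > 0):
            raise ValueError("need K_side >= K_tip > 0")

    @classmethod
    def constant(cls, K: float, nu: float = 0.5) -> "ModulusProfile":
        return cls(kind="constant", K_side=K, K_tip=K, nu=nu)

    def bulk_at(self, z, length: float):
        """``K_h`` at axial distance ``z`` (radii) from the apex."""
        z = np.asarray(z, dtype=float)
        if self.kind == "constant":
            return np.full_like(z, self.K_side)
        if self.kind == "linear":
            # linear ramp K_tip -> K_side over ramp_length (the cell
            # length by default), saturating at K_side beyond; the ramp
            # end is softened over transition_width because a derivative
            # kink stalls the collocation solver
            zr = length if self.ramp_length is None else self.ramp_length
            w = self.transition_width
            sp = np.logaddexp(0.0, (zr - np.maximum(z, 0.0)) / w)  # softplus
            return self.K_side - (self.K_side - self.K_tip) * (w / zr) * sp
        arg = np.clip((z - self.transition_mid) / self.transition_width, -60, 60)
        return self.K_tip + (self.K_side - self.K_tip) / (1.0 + np.exp(-arg))

    def moduli_at(self, z, length: float) -> ModuliPair:
        return ModuliPair.from_bulk(self.bulk_at(z, length), nu=self.nu)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian marker noise and outline bias, in units of the cell radius.

    The turgid configuration carries only localization-software noise; the
    unturgid configuration carries the (larger) experimental-setup noise of
    the chosen level.  z SDs exceed the x-y SDs, reflecting the poorer
    axial resolution of the imaging.  ``outline_shift`` is the amplitude of
    the inward/outward normal-direction bias of the wall-outline detection.
    """

    sd_xy_unturgid: float = 0.0
    sd_z_unturgid: float = 0.0
    sd_xy_turgid: float = 0.0
    sd_z_turgid: float = 0.0
    outline_shift: float = 0.0
    seed: Optional[int] = None

    @classmethod
    def preset(cls, level: str) -> "NoiseSpec":
        """Named levels: ``none``, ``low`` (software only, the printed
        0.002/0.005 pair on both configurations), ``medium`` and ``high``
        (experimental-setup noise on the unturgid markers at 2.5x and 5x
        the software x-y SD, with z twice x-y)."""
        table = {
            "none": (0.0, 0.0, 0.0, 0.0),
            "low": (0.002, 0.005, 0.002, 0.005),
            "medium": (0.005, 0.010, 0.002, 0.005),
            "high": (0.010, 0.020, 0.002, 0.005),
        }
        if level not in table:
            raise ValueError(f"unknown noise level {level!r}")
        u_xy, u_z, t_xy, t_z = table[level]
        return cls(u_xy, u_z, t_xy, t_z, outline_shift=u_xy)

    @property
    def delta_rms(self) -> float:
        """RMS 3D marker displacement of the noisier (unturgid) level."""
        return float(np.sqrt(2 * self.sd_xy_unturgid**2 + self.sd_z_unturgid**2))

    @property
    def delta_upper(self) -> float:
        """Upper-limit displacement scale |delta| used in the sensitivity bound."""
        return 3.0 * self.delta_rms


class ForwardSolution:
    """Solved turgid equilibrium of a hyphoid cell (nondimensional).

    Exposes the ground-truth fields (stretches, curvatures, tensions,
    moduli) as functions of the unturgid arclength over the reported
    region.  All lengths are in units of the shank radius; multiply by
    ``spec.radius`` for dimensional coordinates.
    """

    def __init__(self, spec, profile, scheme, S_rep, rho_u, x_u, bvp_sol, lam0, S_min=1e-4):
        self.spec = spec
        self.profile = profile
        self.scheme = scheme
        self.S_rep = float(S_rep)
        self._rho_u = rho_u          # unturgid radius spline rho(S)
        self._x_u = x_u              # unturgid axial spline x(S)
        self._sol = bvp_sol          # (r, phi)(S) on the padded domain
        self._S_min = float(S_min)   # collocation domain start (apex series below)
        self.apex_stretch = float(lam0)
        # turgid axial coordinate by quadrature of lambda_s * sin(phi)
        Sd = np.linspace(1e-6, self.S_rep, 4097)
        f = self.fields(Sd)
        z_t = cumulative_trapezoid(f["lambda_s"] * np.sin(f["phi"]), Sd, initial=0.0)
        self._z_t = CubicSpline(Sd, z_t)

    @property
    def apex_area_stretch(self) -> float:
        """Ground-truth area elastic stretch lambda_s*lambda_theta at the apex."""
        return self.apex_stretch**2

    def fields(self, S) -> Dict[str, np.ndarray]:
        S = np.atleast_1d(np.asarray(S, dtype=float))
        r, phi = self._sol(S)
        dr, dphi = self._sol(S, 1)
        rho = self._rho_u(S)
        lam_t = np.where(S > 1e-9, r / np.where(rho > 0, rho, 1.0), np.nan)
        length = self.spec.length
        z_u = -self._x_u(S)
        mod = self.profile.moduli_at(z_u, length)
        K, mu = np.asarray(mod.K_h), np.asarray(mod.mu_h)
        # lambda_s from the axial force balance sigma_s = P r / (2 sin phi)
        sphi = np.sin(phi)
        target = self.scheme.P * r / (2.0 * sphi)
        lam_s = _solve_lambda_s(lam_t, target, K, mu)
        # apex limit: isotropy
        apex = S <= 1e-9
        lam_t[apex] = self.apex_stretch
        lam_s[apex] = self.apex_stretch
        sig_s = 0.5 * mu * (1 / lam_t**2 - 1 / lam_s**2) + K * (lam_s * lam_t - 1)
        sig_t = 0.5 * mu * (1 / lam_s**2 - 1 / lam_t**2) + K * (lam_s * lam_t - 1)
        kap_t = np.where(apex, np.nan, sphi / np.where(r > 0, r, 1.0))
        kap_s = dphi / lam_s
        if self.apex_stretch > 1:
            K0_apex = float(self.profile.bulk_at(0.0, length))
            k0 = self.scheme.P / (2 * K0_apex * (self.apex_stretch**2 - 1))
        else:
            k0 = np.nan
        kap_t[apex] = k0
        kap_s[apex] = k0
        return {
            "S": S, "r_u": np.where(apex, 0.0, rho), "x_u": self._x_u(S),
            "r_t": np.where(apex, 0.0, r), "phi": phi,
            "lambda_s": lam_s, "lambda_theta": lam_t,
            "kappa_s": kap_s, "kappa_theta": kap_t,
            "sigma_s": sig_s, "sigma_theta": sig_t,
            "K_h": K, "mu_h": mu,
            "alpha_deg": np.degrees(phi),
            "alpha_u_deg": np.degrees(np.arctan2(-self._x_u(S, 1), self._rho_u(S, 1))),
        }

    def stations(self, n: int) -> Dict[str, np.ndarray]:
        """Ground-truth table at ``n`` stations uniform in unturgid arclength."""
        S = np.linspace(0.0, self.S_rep, n)
        f = self.fields(S)
        f["x_t"] = -self._z_t(np.clip(S, 1e-6, None))
        f["x_t"][S <= 1e-9] = 0.0
        return f

    def stations_y(self, n: int) -> Dict[str, np.ndarray]:
        """Ground truth at ``n`` stations uniform in the unturgid radius y.

        This is the natural discretization of the hyphoid outline (the
        meridian is given as x(y)): stations crowd toward the apex, where
        the geometry varies fastest, and spread out along the nearly
        cylindrical shank.
        """
        y = np.linspace(0.0, self._rho_u(self.S_rep), n)
        Sd = np.linspace(0.0, self.S_rep, 4097)
        S = np.interp(y, self._rho_u(Sd), Sd)
        f = self.fields(S)
        f["x_t"] = -self._z_t(np.clip(S, 1e-6, None))
        f["x_t"][S <= 1e-9] = 0.0
        return f

    def meridians(self, n: int, spacing: str = "radius") -> Tuple[np.ndarray, np.ndarray]:
        """Corresponded unturgid and turgid (x, r) meridians, radius units.

        ``spacing`` is ``"radius"`` (uniform in unturgid radius, the
        outline discretization) or ``"arclength"``.
        """
        f = self.stations_y(n) if spacing == "radius" else self.stations(n)
        un = np.column_stack([f["x_u"], f["r_u"]])
        tu = np.column_stack([f["x_t"], f["r_t"]])
        return un, tu

    def max_equilibrium_residual(self, n: int = 1001) -> float:
        """Max |constitutive - Young-Laplace| tension mismatch over stations."""
        f = self.fields(np.linspace(self._S_min, self.S_rep, n))
        sig_s_yl = self.scheme.P / (2 * f["kappa_theta"])
        sig_t_yl = sig_s_yl * (2 - f["kappa_s"] / f["kappa_theta"])
        return float(max(np.max(np.abs(f["sigma_s"] - sig_s_yl)),
                         np.max(np.abs(f["sigma_theta"] - sig_t_yl))))


def _solve_lambda_s(lam_t, target, K, mu, n_iter: int = 80):
    """Invert sigma_s(lambda_s; lambda_theta) = target (monotone in lambda_s)."""
    lam_t = np.asarray(lam_t, dtype=float)
    ls = np.clip(np.where(np.isfinite(lam_t), lam_t, 1.0), 0.5, 3.0).copy()
    for _ in range(n_iter):
        f = 0.5 * mu * (1 / lam_t**2 - 1 / ls**2) + K * (ls * lam_t - 1) - target
        df = mu / ls**3 + K * lam_t
        step = f / df
        ls = np.clip(ls - step, 0.2, 5.0)
        if np.nanmax(np.abs(step)) < 1e-14:
            break
    return ls


class ForwardSolverError(RuntimeError):
    pass


def solve_turgid_outline(
    spec: HyphoidSpec,
    profile: ModulusProfile,
    scheme: NondimScheme = NondimScheme(),
    *,
    tol: float = 1e-9,
) -> ForwardSolution:
    """Solve the turgid membrane equilibrium for a hyphoid cell.

    Uses collocation with continuation in pressure if the direct solve
    fails.  Raises :class:`ForwardSolverError` on non-convergence.
    """
    a = spec.a
    y_rep = spec.shank_fraction
    L_pad = spec.length + spec.pad_length
    y_pad = 1.0 - 1.0 / (a * L_pad)
    x, y, S = _dense_meridian(a, y_pad, n=40001)
    rho_u = CubicSpline(S, y)
    x_u = CubicSpline(S, x)
    S_rep = float(np.interp(y_rep, y, S))
    S_max = S[-1]
    length = spec.length
    kap_u0 = hyphoid_apex_curvature(a)

    if scheme.P == 0:
        return _identity_solution(spec, profile, scheme, S_rep, rho_u, x_u)

    def make_rhs(P):
        def rhs(Sv, u, p):
            r, phi = u
            rho = rho_u(Sv)
            lam_t = r / rho
            mod = profile.moduli_at(-x_u(Sv), length)
            K, mu = np.asarray(mod.K_h), np.asarray(mod.mu_h)
            sphi = np.sin(phi)
            target = P * r / (2.0 * sphi)
            ls = _solve_lambda_s(lam_t, target, K, mu)
            sig_t = 0.5 * mu * (1 / ls**2 - 1 / lam_t**2) + K * (ls * lam_t - 1)
            kap_t = sphi / r
            kap_s = (P - kap_t * sig_t) / target
            return np.vstack([ls * np.cos(phi), ls * kap_s])
        return rhs

    eps = 1e-3 * S_max / 6.0
    K0 = float(profile.bulk_at(0.0, length))

    def make_bc(P):
        def bc(u0, u1, p):
            lam0 = p[0]
            k0 = P / (2.0 * K0 * (lam0**2 - 1.0))
            return np.array([
                u0[0] - lam0 * rho_u(eps),
                u0[1] - k0 * lam0 * eps,
                u1[1] - np.pi / 2.0,
            ])
        return bc

    Sm = np.linspace(eps, S_max, 600)
    phi_guess = np.arctan2(-x_u(Sm, 1), rho_u(Sm, 1))
    c = scheme.P / (2.0 * kap_u0)
    lam0_guess = (c + np.sqrt(c * c + 4.0 * K0 * K0)) / (2.0 * K0)
    guess = np.vstack([lam0_guess * rho_u(Sm), phi_guess])

    last_err = None
    for pressures in ([scheme.P], np.linspace(scheme.P / 4, scheme.P, 4)):
        mesh, ystart, p0 = Sm, guess, [lam0_guess]
        sol = None
        try:
            for P in pressures:
                sol = solve_bvp(make_rhs(P), make_bc(P), mesh, ystart, p=p0,
                                tol=tol, max_nodes=100000)
                if sol.status != 0:
                    raise ForwardSolverError(sol.message)
                mesh, ystart, p0 = sol.x, sol.y, sol.p
        except (ForwardSolverError, FloatingPointError) as err:
            last_err = err
            continue
        if np.any(sol.y[0] <= 0):
            raise ForwardSolverError("non-physical geometry: negative turgid radius")
        out = ForwardSolution(spec, profile, scheme, S_rep, rho_u, x_u, sol.sol,
                              sol.p[0], S_min=eps)
        res = out.max_equilibrium_residual()
        if res > 1e-6:
            raise ForwardSolverError(f"equilibrium residual {res:.2e} exceeds 1e-6")
        return out
    raise ForwardSolverError(f"forward solve failed to converge: {last_err}")


def _identity_solution(spec, profile, scheme, S_rep, rho_u, x_u):
    """Zero-pressure limit: the turgid configuration equals the unturgid."""
    sol = ForwardSolution.__new__(ForwardSolution)
    sol.spec, sol.profile, sol.scheme = spec, profile, scheme
    sol.S_rep = S_rep
    sol._rho_u, sol._x_u = rho_u, x_u
    sol.apex_stretch = 1.0

    def ident(S, der=0):
        S = np.atleast_1d(S)
        if der == 0:
            phi = np.arctan2(-x_u(S, 1), rho_u(S, 1))
            return np.vstack([rho_u(S), phi])
        dphi = np.gradient(np.arctan2(-x_u(S, 1), rho_u(S, 1)), S) if len(S) > 1 else np.zeros((1,))
        return np.vstack([rho_u(S, 1), dphi])

    sol._sol = ident
    sol._S_min = 1e-4
    Sd = np.linspace(1e-6, S_rep, 2049)
    sol._z_t = CubicSpline(Sd, -x_u(Sd))
    return sol


def revolve_surface(meridian: np.ndarray, n_revolve: int, phase: float = 0.0,
                    axis_eps: float = 1e-9):
    """Revolve an ``(x, r)`` meridian about the x axis.

    Returns ``(points, station)``: each station with ``r > axis_eps``
    becomes a ring of ``n_revolve`` points uniformly spaced in azimuth;
    on-axis stations become single points.  Every revolved point sits at
    exactly its station's distance from the axis.
    """
    meridian = np.asarray(meridian, dtype=float)
    theta = phase + 2.0 * np.pi * np.arange(n_revolve) / n_revolve
    pts, sid = [], []
    for i, (x, r) in enumerate(meridian):
        if r <= axis_eps:
            pts.append(np.array([[x, 0.0, 0.0]]))
            sid.append(np.array([i]))
        else:
            ring = np.column_stack([np.full(n_revolve, x), r * np.cos(theta), r * np.sin(theta)])
            pts.append(ring)
            sid.append(np.full(n_revolve, i))
    return np.concatenate(pts), np.concatenate(sid)


def generate_marker_sets(
    meridian_u: np.ndarray,
    meridian_t: np.ndarray,
    n_subset: int,
    min_dist: float,
    rng: np.random.Generator,
    n_revolve: int = 16,
):
    """Random corresponded marker subsets on the two configurations.

    The candidate grid revolves the marker-station meridians (same
    stations, same azimuths in both configurations, one random phase per
    ring so repeated triangulations of one cell differ).  A random subset
    of ``n_subset`` candidates is drawn subject to a pairwise 3D distance
    of at least ``min_dist`` in the turgid configuration; the identical
    id selection is applied to both configurations, so the material
    correspondence is a bijection by construction.
    """
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(meridian_u))
    pts_u, pts_t, ids = [], [], []
    theta0 = 2.0 * np.pi * np.arange(n_revolve) / n_revolve
    next_id = 0
    for i in range(len(meridian_u)):
        xu, ru = meridian_u[i]
        xt, rt = meridian_t[i]
        if min(ru, rt) <= 1e-9:
            pts_u.append([[xu, 0.0, 0.0]])
            pts_t.append([[xt, 0.0, 0.0]])
            ids.append([next_id]); next_id += 1
        else:
            th = theta0 + phases[i]
            pts_u.append(np.column_stack([np.full(n_revolve, xu), ru * np.cos(th), ru * np.sin(th)]))
            pts_t.append(np.column_stack([np.full(n_revolve, xt), rt * np.cos(th), rt * np.sin(th)]))
            ids.append(next_id + np.arange(n_revolve)); next_id += n_revolve
    pts_u = np.concatenate(pts_u); pts_t = np.concatenate(pts_t)
    ids = np.concatenate(ids)
    if n_subset > len(ids):
        raise ValueError("requested more markers than candidates")

    order = rng.permutation(len(ids))
    chosen: List[int] = []
    for j in order:
        p = pts_t[j]
        if all(np.linalg.norm(p - pts_t[k]) >= min_dist for k in chosen):
            chosen.append(j)
            if len(chosen) == n_subset:
                break
    if len(chosen) < n_subset:
        warnings.warn(
            f"min_dist={min_dist} admits only {len(chosen)} of {n_subset} markers")
    idx = np.sort(np.array(chosen))
    return pts_u[idx], pts_t[idx], ids[idx]


def apply_marker_noise(points: np.ndarray, sd_xy: float, sd_z: float,
                       rng: np.random.Generator, radius: float = 1.0) -> np.ndarray:
    """Independent Gaussian displacement per axis; SDs in radius units.

    Axes follow the imaging convention: x and y span the focal plane
    (``sd_xy``), z is the optical axis (``sd_z``).
    """
    sds = np.array([sd_xy, sd_xy, sd_z]) * radius
    return points + rng.normal(0.0, 1.0, size=points.shape) * sds


def apply_outline_noise(points: np.ndarray, normals: np.ndarray, amplitude: float,
                        rng: np.random.Generator, radius: float = 1.0) -> np.ndarray:
    """Shift a wall-outline cloud along its outward normals.

    Emulates the outline-detection bias: the whole detected wall sits
    inward or outward of the true mid-surface; the sign is drawn once per
    cloud.
    """
    if amplitude == 0.0:
        return points.copy()
    sign = rng.choice([-1.0, 1.0])
    return points + sign * amplitude * radius * normals


@dataclass
class CellConfigurationPair:
    """One synthetic cell: corresponded marker sets, outline clouds, truth.

    Coordinates are dimensional (radius-scaled); ``radius`` is the length
    used to nondimensionalize downstream.  ``truth`` retains the full
    forward solution (radius-1 units).
    """

    radius: float
    markers_unturgid: np.ndarray
    markers_turgid: np.ndarray
    marker_ids: np.ndarray
    outline_unturgid: np.ndarray
    outline_turgid: np.ndarray
    outline_station: Optional[np.ndarray]
    truth: Optional[ForwardSolution]
    noise: NoiseSpec
    seed: Optional[int] = None

    def truth_stations(self, n: int = 513) -> Dict[str, np.ndarray]:
        return self.truth.stations(n)


def _outline_normals(solution: ForwardSolution, S, theta):
    """Outward normals of the turgid/unturgid revolved surface at stations."""
    f = solution.fields(np.atleast_1d(S))
    phi = f["phi"]
    return np.column_stack([np.cos(phi), np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta)])


def generate_cell(
    spec: HyphoidSpec,
    profile: ModulusProfile,
    noise: NoiseSpec,
    n_subset: int = 155,
    min_dist: float = 0.12,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    solution: Optional[ForwardSolution] = None,
) -> CellConfigurationPair:
    """Generate one synthetic cell pair (markers + outlines + ground truth).

    ``min_dist`` is in radius units.  A precomputed ``solution`` may be
    passed (the nondimensional equilibrium is radius-independent, so one
    solve serves a whole cohort).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if solution is None:
        solution = solve_turgid_outline(spec, profile)
    R = spec.radius

    n_cloud = spec.outline_upsample * (spec.n_outline - 1) + 1
    f = solution.stations_y(n_cloud)
    mer_u = np.column_stack([f["x_u"], f["r_u"]])
    mer_t = np.column_stack([f["x_t"], f["r_t"]])
    cloud_u, sid = revolve_surface(mer_u, spec.n_revolve)
    cloud_t, _ = revolve_surface(mer_t, spec.n_revolve)
    theta = np.arctan2(cloud_u[:, 2], cloud_u[:, 1])
    phi_u = np.radians(f["alpha_u_deg"])[sid]
    n_u = np.column_stack([np.cos(phi_u), np.sin(phi_u) * np.cos(theta), np.sin(phi_u) * np.sin(theta)])
    phi_t = f["phi"][sid]
    theta_t = np.arctan2(cloud_t[:, 2], cloud_t[:, 1])
    n_t = np.column_stack([np.cos(phi_t), np.sin(phi_t) * np.cos(theta_t), np.sin(phi_t) * np.sin(theta_t)])

    mu_, mt_ = solution.meridians(spec.n_marker_stations)
    mk_u, mk_t, ids = generate_marker_sets(mu_, mt_, n_subset, min_dist, rng,
                                           n_revolve=spec.n_revolve_markers)

    # scale to dimensional coordinates, then perturb
    mk_u, mk_t = mk_u * R, mk_t * R
    cloud_u, cloud_t = cloud_u * R, cloud_t * R
    mk_u = apply_marker_noise(mk_u, noise.sd_xy_unturgid, noise.sd_z_unturgid, rng, R)
    mk_t = apply_marker_noise(mk_t, noise.sd_xy_turgid, noise.sd_z_turgid, rng, R)
    cloud_u = apply_outline_noise(cloud_u, n_u, noise.outline_shift, rng, R)
    cloud_t = apply_outline_noise(cloud_t, n_t, noise.outline_shift, rng, R)

    return CellConfigurationPair(
        radius=R, markers_unturgid=mk_u, markers_turgid=mk_t, marker_ids=ids,
        outline_unturgid=cloud_u, outline_turgid=cloud_t, outline_station=sid,
        truth=solution, noise=noise, seed=seed,
    )


def resample_markers(pair: CellConfigurationPair, rng: np.random.Generator,
                     n_subset: int = 155, min_dist: float = 0.12) -> CellConfigurationPair:
    """A fresh marker subset (and fresh marker noise) on the same cell.

    Outline clouds, ground truth and cell size are shared; only the marker
    triangulation data changes.  This is the two-triangulation trick:
    more deformation samples without more cells.
    """
    spec = pair.truth.spec
    R = pair.radius
    mu_, mt_ = pair.truth.meridians(spec.n_marker_stations)
    mk_u, mk_t, ids = generate_marker_sets(mu_, mt_, n_subset, min_dist, rng,
                                           n_revolve=spec.n_revolve_markers)
    mk_u, mk_t = mk_u * R, mk_t * R
    noise = pair.noise
    mk_u = apply_marker_noise(mk_u, noise.sd_xy_unturgid, noise.sd_z_unturgid, rng, R)
    mk_t = apply_marker_noise(mk_t, noise.sd_xy_turgid, noise.sd_z_turgid, rng, R)
    return replace(pair, markers_unturgid=mk_u, markers_turgid=mk_t, marker_ids=ids)


def generate_cohort(
    n_cells: int,
    spec: HyphoidSpec,
    profile: ModulusProfile,
    noise: NoiseSpec,
    size_range: Tuple[float, float] = (0.8, 1.2),
    seed: Optional[int] = None,
    n_subset: int = 155,
    min_dist: float = 0.12,
) -> List[CellConfigurationPair]:
    """Cohort of cells sharing a ground truth, with size variation.

    Radii are drawn uniformly from ``size_range`` times the spec radius;
    per-cell RNG streams derive from the master seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ss = np.random.SeedSequence(seed)
    solution = solve_turgid_outline(spec, profile)
    cells = []
    for i, child in enumerate(ss.spawn(n_cells)):
        rng = np.random.default_rng(child)
        R = spec.radius * rng.uniform(*size_range)
        cell_spec = replace(spec, radius=R)
        cells.append(generate_cell(cell_spec, profile, noise, n_subset=n_subset,
                                   min_dist=min_dist, rng=rng, solution=solution))
    return cells
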