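"""Axisymmetric thin-shell wall mechanics.

The cell wall is treated as a pressurized, 2D-isotropic elastic membrane.
Force balance on the shell gives the Young-Laplace relations between the
turgor pressure ``P``, the principal curvatures ``(kappa_s, kappa_theta)``
and the wall tensions ``(sigma_s, sigma_theta)``; the constitutive law
relates the tensions to the elastic stretch ratios ``(lambda_s,
lambda_theta)`` through the surface bulk modulus ``K_h`` (resisting area
change) and the surface shear modulus ``mu_h`` (resisting in-plane shape
change).  All quantities are nondimensional: lengths by the cell radius
``L``, tensions by ``P*L``, moduli by ``P*L``.

Inverting the constitutive law yields the two inference formulas used by
the pipeline,

    K_h  = (sigma_s + sigma_theta) / (2 (lambda_s lambda_theta - 1))
    mu_h = (sigma_s - sigma_theta) / (1/lambda_theta^2 - 1/lambda_s^2)

both of which are singular where their denominator vanishes: the bulk
modulus when the area stretch is 1 (no area strain), the shear modulus
wherever the deformation is isotropic -- which is always the case at the
apex of an axisymmetric cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "NondimScheme",
    "CurvaturePair",
    "TensionPair",
    "StretchPair",
    "ModuliPair",
    "SingularGeometryError",
    "InferenceInstabilityError",
    "young_laplace_tensions",
    "constitutive_tensions",
    "infer_bulk_modulus",
    "infer_shear_modulus",
    "bulk_modulus_area_method",
    "bulk_sensitivity",
    "filter_nonphysical",
]

#: |lambda_s*lambda_theta - 1| below this is treated as a singular area stretch.
AREA_STRETCH_TOL = 1e-6
#: |1/lambda_theta^2 - 1/lambda_s^2| below this is treated as isotropic.
ANISOTROPY_TOL = 1e-8


class SingularGeometryError(ValueError):
    """Raised when curvatures make the tension recovery singular."""


class InferenceInstabilityError(ValueError):
    """Raised when a modulus inference sits on its singular manifold."""


@dataclass(frozen=True)
class NondimScheme:
    """Nondimensionalization of the shell problem.

    ``P`` is the nondimensional turgor pressure (1 by convention) and
    ``L_ref`` the cell-radius length scale.  ``P_dim`` (MPa) and ``h_dim``
    (um) enable conversion of surface moduli to 3D moduli in MPa via
    ``K = P_dim * L_ref / h_dim * K_h``; the core pipeline never stores
    dimensional moduli.
    """

    P: float = 1.0
    L_ref: float = 1.0
    P_dim: Optional[float] = None
    h_dim: Optional[float] = None

    def __post_init__(self) -> None:
        # P = 0 is admitted as the unloaded (plasmolyzed) limit
        if self.P < 0 or self.L_ref <= 0:
            raise ValueError("P must be non-negative and L_ref positive")

    @property
    def has_dimensions(self) -> bool:
        return self.P_dim is not None and self.h_dim is not None

    def modulus_to_mpa(self, k_h):
        """Convert a nondimensional surface modulus to a 3D modulus in MPa."""
        if not self.has_dimensions:
            raise ValueError("set P_dim and h_dim to obtain dimensional moduli")
        return np.asarray(k_h) * self.P_dim * self.L_ref / self.h_dim


@dataclass(frozen=True)
class CurvaturePair:
    kappa_s: np.ndarray
    kappa_theta: np.ndarray


@dataclass(frozen=True)
class TensionPair:
    sigma_s: np.ndarray
    sigma_theta: np.ndarray


@dataclass(frozen=True)
class StretchPair:
    lambda_s: np.ndarray
    lambda_theta: np.ndarray

    @property
    def area_stretch(self) -> np.ndarray:
        return np.asarray(self.lambda_s) * np.asarray(self.lambda_theta)


@dataclass(frozen=True)
class ModuliPair:
    """Surface bulk and shear moduli, optionally tied by a Poisson ratio.

    With a constant Poisson ratio ``nu`` the pair derives from a single
    surface Young modulus ``Eh``:  ``mu_h = Eh/(2(1+nu))`` and
    ``K_h = Eh/(2(1-nu))``.
    """

    K_h: np.ndarray
    mu_h: np.ndarray
    nu: Optional[float] = None

    @classmethod
    def from_young(cls, Eh, nu: float) -> "ModuliPair":
        Eh = np.asarray(Eh, dtype=float)
        return cls(K_h=Eh / (2.0 * (1.0 - nu)), mu_h=Eh / (2.0 * (1.0 + nu)), nu=nu)

    @classmethod
    def from_bulk(cls, K_h, nu: float) -> "ModuliPair":
        """Shear modulus implied by ``K_h`` at constant Poisson ratio."""
        K_h = np.asarray(K_h, dtype=float)
        return cls(K_h=K_h, mu_h=K_h * (1.0 - nu) / (1.0 + nu), nu=nu)

    @property
    def young(self) -> np.ndarray:
        if self.nu is None:
            raise ValueError("Poisson ratio not set")
        return 2.0 * (1.0 - self.nu) * np.asarray(self.K_h)


def young_laplace_tensions(curv: CurvaturePair, scheme: NondimScheme = NondimScheme()) -> TensionPair:
    """Recover wall tensions from curvatures by force balance.

    ``sigma_s = P/(2 kappa_theta)`` expresses the axial force balance of a
    closed cap; combining it with the normal balance
    ``kappa_s sigma_s + kappa_theta sigma_theta = P`` gives
    ``sigma_theta = P/(2 kappa_theta) (2 - kappa_s/kappa_theta)``.
    """
    ks = np.asarray(curv.kappa_s, dtype=float)
    kt = np.asarray(curv.kappa_theta, dtype=float)
    if np.any(np.abs(kt) < 1e-12):
        raise SingularGeometryError("circumferential curvature vanishes; tensions undefined")
    s_s = scheme.P / (2.0 * kt)
    s_t = s_s * (2.0 - ks / kt)
    return TensionPair(sigma_s=s_s, sigma_theta=s_t)


def constitutive_tensions(stretch: StretchPair, moduli: ModuliPair) -> TensionPair:
    """Tensions of the 2D-isotropic membrane law at finite stretch."""
    ls = np.asarray(stretch.lambda_s, dtype=float)
    lt = np.asarray(stretch.lambda_theta, dtype=float)
    if np.any(ls <= 0) or np.any(lt <= 0):
        raise ValueError("stretch ratios must be positive")
    K = np.asarray(moduli.K_h, dtype=float)
    mu = np.asarray(moduli.mu_h, dtype=float)
    areal = K * (ls * lt - 1.0)
    dev = 0.5 * mu * (1.0 / lt**2 - 1.0 / ls**2)
    return TensionPair(sigma_s=dev + areal, sigma_theta=-dev + areal)


def infer_bulk_modulus(tension: TensionPair, stretch: StretchPair, *, strict: bool = True):
    """Surface bulk modulus from tensions and stretches.

    The deviatoric parts cancel in ``sigma_s + sigma_theta``, so the
    round trip with :func:`constitutive_tensions` is an algebraic
    identity.  A negative result (area stretch < 1 with positive
    tensions) is non-physical; with ``strict=False`` it is returned for
    the caller to filter (see :func:`filter_nonphysical`).
    """
    js = np.asarray(stretch.lambda_s) * np.asarray(stretch.lambda_theta) - 1.0
    if strict and np.any(np.abs(js) < AREA_STRETCH_TOL):
        raise InferenceInstabilityError("area stretch ~ 1: bulk-modulus inference singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.asarray(tension.sigma_s) + np.asarray(tension.sigma_theta)) / (2.0 * js)


def infer_shear_modulus(tension: TensionPair, stretch: StretchPair, *, tol: float = ANISOTROPY_TOL):
    """Surface shear modulus; singular wherever the stretch is isotropic.

    At the apex of a tip-growing cell the deformation is isotropic by
    symmetry, so this inference is suppressed there (the instability is
    intrinsic, not numerical).
    """
    ls = np.asarray(stretch.lambda_s, dtype=float)
    lt = np.asarray(stretch.lambda_theta, dtype=float)
    denom = 1.0 / lt**2 - 1.0 / ls**2
    if np.any(np.abs(denom) < tol):
        raise InferenceInstabilityError("isotropic stretch: shear-modulus inference singular")
    return (np.asarray(tension.sigma_s) - np.asarray(tension.sigma_theta)) / denom


def bulk_modulus_area_method(area_turgid, area_unturgid, tension: TensionPair, *, strict: bool = True):
    """Bulk modulus with the area stretch replaced by the triangle area ratio.

    For an affine in-plane map the turgid/unturgid area ratio equals
    ``lambda_1 lambda_2`` exactly, so this variant needs no deformation
    gradient.
    """
    sb = np.asarray(area_turgid, dtype=float)
    sa = np.asarray(area_unturgid, dtype=float)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("triangle areas must be positive")
    js = sb / sa - 1.0
    if strict and np.any(np.abs(js) < AREA_STRETCH_TOL):
        raise InferenceInstabilityError("area ratio ~ 1: bulk-modulus inference singular")
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.asarray(tension.sigma_s) + np.asarray(tension.sigma_theta)) / (2.0 * js)


def bulk_sensitivity(stretch: StretchPair, delta_area_stretch):
    """First-order relative perturbation of ``K_h`` from an area-stretch error.

    ``dK/K ~ -d(lambda_s lambda_theta) / (2 (lambda_s lambda_theta - 1))``;
    the tension-perturbation term is dropped because in practice it is
    dominated by the stretch error.  Diverges as the area stretch
    approaches 1 -- which is exactly the diagnostic value of the formula.
    """
    js = np.asarray(stretch.lambda_s) * np.asarray(stretch.lambda_theta) - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.asarray(delta_area_stretch, dtype=float) / (2.0 * js)


def filter_nonphysical(k_h, area_stretch=None):
    """Remove non-physical bulk-modulus samples.

    Retains entries with ``K_h > 0`` and, when the area stretch is given,
    ``lambda_s lambda_theta > 1``.  Returns ``(kept_values, keep_mask)``;
    the mask is the pipeline's error-accounting record.  Near a small true
    area strain, noise pushes samples below 1 and the filter keeps only
    upward fluctuations, biasing retained tip values low -- the mechanism
    behind false side-to-tip gradients.
    """
    k_h = np.asarray(k_h, dtype=float)
    keep = np.isfinite(k_h) & (k_h > 0)
    if area_stretch is not None:
        keep &= np.asarray(area_stretch) > 1.0
    if not np.any(keep):
        import warnings

        warnings.warn("all bulk-modulus samples removed by the non-physical filter")
    return k_h[keep], keep
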