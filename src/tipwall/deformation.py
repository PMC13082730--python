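"""Per-triangle deformation gradients and their noise sensitivity.

For each face the linear map ``F = B A^-1`` carries the unturgid triangle
basis onto the turgid one.  Its polar decomposition

    F = lambda_1 x1b (x) x1a + lambda_2 x2b (x) x2a + nb (x) na

separates the two in-plane principal stretches from the rotation of the
tangent plane; the third singular pair is the normal-to-normal map with
unit stretch.  The principal stretches are the square roots of the
non-unity eigenvalues of the Cauchy-Green tensors F^T F (unturgid
directions) and F F^T (turgid directions).

Because A and B are built from measured vertex positions, vertex noise of
scale ``|delta|`` propagates into F.  First-order perturbation of
``F = B A^-1`` gives ``dF = dB A^-1 - F dA A^-1``, and bounding the
column-wise perturbations of each basis matrix by triangle geometry
yields a per-face amplification factor ``Gamma`` with

    |dF| / |F|  <=  Gamma |delta|,

hence a guaranteed bound ``2 Gamma |delta|`` on the relative error of the
area stretch ``lambda_1 lambda_2``.  Small or sliver-shaped triangles have
large ``Gamma``; filtering on the per-cell ``Gamma`` distribution
preferentially retains compact triangles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .surface_mesh import SurfaceMesh

__all__ = [
    "DeformationPatches",
    "deformation_gradient",
    "principal_stretches",
    "inverse_map",
    "gamma_bound",
    "filter_by_gamma",
    "compute_patches",
]


def deformation_gradient(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``F A = B`` per face (batched); raises on singular A."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    det = np.linalg.det(A)
    if np.any(np.abs(det) < 1e-300):
        raise np.linalg.LinAlgError("degenerate triangle: singular basis matrix")
    # F = B A^-1  <=>  A^T F^T = B^T
    return np.linalg.solve(np.swapaxes(A, -1, -2), np.swapaxes(B, -1, -2)).swapaxes(-1, -2)


def principal_stretches(F: np.ndarray, normals_unturgid: np.ndarray):
    """In-plane principal stretches and directions from the Cauchy-Green tensors.

    Of the three eigenpairs of ``F^T F``, the one whose eigenvector is
    closest to the unturgid normal is the (unit-stretch) normal map; the
    other two give ``lambda_1 >= lambda_2`` and the unturgid principal
    directions.  The turgid directions follow by pushing forward,
    ``x_ib = F x_ia / lambda_i``.

    Returns ``(lam1, lam2, dir1_u, dir2_u, dir1_t, dir2_t)``.
    """
    F = np.asarray(F, dtype=float)
    n_a = np.asarray(normals_unturgid, dtype=float)
    C = np.swapaxes(F, -1, -2) @ F
    w, v = np.linalg.eigh(C)  # ascending eigenvalues, orthonormal columns
    # pick the eigenvector most aligned with the unturgid normal
    align = np.abs(np.einsum("fi,fik->fk", n_a, v))
    k_norm = np.argmax(align, axis=1)
    f_idx = np.arange(len(F))
    order = np.argsort(w, axis=1)[:, ::-1]  # descending
    # remove the normal eigenpair from the descending order
    keep = order != k_norm[:, None]
    order_t = order[keep].reshape(len(F), 2)
    lam1 = np.sqrt(w[f_idx, order_t[:, 0]])
    lam2 = np.sqrt(w[f_idx, order_t[:, 1]])
    d1u = v[f_idx, :, order_t[:, 0]]
    d2u = v[f_idx, :, order_t[:, 1]]
    d1t = np.einsum("fij,fj->fi", F, d1u) / lam1[:, None]
    d2t = np.einsum("fij,fj->fi", F, d2u) / lam2[:, None]
    return lam1, lam2, d1u, d2u, d1t, d2t


def inverse_map(F: np.ndarray) -> np.ndarray:
    """Inverse deformation gradient (turgid -> unturgid tangent map)."""
    return np.linalg.inv(np.asarray(F, dtype=float))


def _column_amplification(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Frobenius bound on the basis-matrix perturbation per unit |delta|.

    Each side vector is the difference of two vertices (perturbation up to
    ``2 |delta|``); the unit normal, as the normalized cross product,
    moves by at most ``(|v1| + |v2|) / S |delta|`` with ``S`` the triangle
    area.
    """
    l1 = np.linalg.norm(v1, axis=-1)
    l2 = np.linalg.norm(v2, axis=-1)
    area = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=-1)
    area = np.where(area > 0, area, np.inf)
    return np.sqrt(8.0 + ((l1 + l2) / area) ** 2)


def gamma_bound(A: np.ndarray, B: np.ndarray, F: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-face sensitivity bound Gamma with ``|dF|/|F| <= Gamma |delta|``.

    ``|delta|`` is the vertex displacement scale (same length units as the
    coordinates).  Degenerate faces return ``inf``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if F is None:
        F = deformation_gradient(A, B)
    cA = _column_amplification(A[:, :, 0], A[:, :, 1])
    cB = _column_amplification(B[:, :, 0], B[:, :, 1])
    normF = np.linalg.norm(F, ord=2, axis=(-2, -1))
    # spectral norm of A^-1 is the reciprocal smallest singular value of A
    smin = np.linalg.svd(A, compute_uv=False)[..., -1]
    normAinv = np.where(smin > 0, 1.0 / smin, np.inf)
    return normAinv * (cB + normF * cA) / normF


def filter_by_gamma(gamma: np.ndarray, percentile: float = 90.0,
                    absolute: Optional[float] = None) -> np.ndarray:
    """Keep-mask removing the most noise-sensitive faces.

    Default rule: drop faces above the given percentile of the per-cell
    Gamma distribution (a distribution-based threshold); an ``absolute``
    cutoff can replace it.  Under a uniform Gamma the percentile rule
    removes nothing.
    """
    gamma = np.asarray(gamma, dtype=float)
    finite = np.isfinite(gamma)
    if absolute is not None:
        return finite & (gamma <= absolute)
    if not np.any(finite):
        return finite
    cut = np.percentile(gamma[finite], percentile)
    return finite & (gamma <= cut * (1 + 1e-12))


@dataclass
class DeformationPatches:
    """Batched per-face deformation data for one mesh."""

    F: np.ndarray
    F_inv: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    dir1_unturgid: np.ndarray
    dir2_unturgid: np.ndarray
    dir1_turgid: np.ndarray
    dir2_turgid: np.ndarray
    gamma: np.ndarray

    @property
    def area_stretch(self) -> np.ndarray:
        return self.lambda1 * self.lambda2


def compute_patches(mesh: SurfaceMesh) -> DeformationPatches:
    """Deformation gradients, stretches and Gamma for every mesh face."""
    F = deformation_gradient(mesh.A, mesh.B)
    lam1, lam2, d1u, d2u, d1t, d2t = principal_stretches(F, mesh.normals_unturgid)
    return DeformationPatches(
        F=F, F_inv=inverse_map(F), lambda1=lam1, lambda2=lam2,
        dir1_unturgid=d1u, dir2_unturgid=d2u, dir1_turgid=d1t, dir2_turgid=d2t,
        gamma=gamma_bound(mesh.A, mesh.B, F),
    )
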