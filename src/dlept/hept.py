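"""Helmholtz-based MR-EPT reconstruction (the analytic baseline).

Assuming a locally homogeneous medium, the transmit field obeys the
homogeneous Helmholtz equation, and the electrical properties follow
per voxel from the Laplacian-to-field ratio:

    epsr(r)  = -1/(mu0 eps0 omega^2) * Re( lap(B1+) / B1+ )
    sigma(r) =  1/(mu0 omega)        * Im( lap(B1+) / B1+ )

with the e^{+i omega t} convention.  The complex field is formed from
the measured magnitude and the transceive phase assumption,
B = |B1+| exp(i phi±/2).  The Laplacian is estimated with a noise-robust
kernel: a least-squares second-order polynomial fit (Savitzky–Golay
type) over a 7x7 support by default.  Voxels whose kernel footprint
crosses the object boundary are excluded from the valid mask — boundary
regions cannot be reconstructed accurately with this method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.signal import fftconvolve

from .em_forward import MU0, EPS0, OMEGA_3T, Acquisition

__all__ = ["DerivativeKernel", "EpsMaps", "build_noise_robust_kernel",
           "hept_reconstruct", "erode_rois"]


@dataclass
class DerivativeKernel:
    """2D Laplacian estimator; weights carry the 1/m^2 spacing scaling."""

    weights: np.ndarray
    support: tuple
    spacing: float

    @property
    def half_width(self):
        return (self.support[0] // 2, self.support[1] // 2)

    @property
    def noise_amplification(self) -> float:
        """Sum of squared weights: noise variance gain of the estimator."""
        return float(np.sum(self.weights ** 2))


@dataclass
class EpsMaps:
    """Reconstructed conductivity / permittivity maps with provenance."""

    sigma_map: np.ndarray    # S/m
    epsr_map: np.ndarray     # dimensionless
    method: str              # {"H-EPT", "cGAN_mask", "cGAN_tissue", ...}
    valid_mask: np.ndarray


def build_noise_robust_kernel(support=(7, 7), spacing: float = 0.002
                              ) -> DerivativeKernel:
    """Savitzky–Golay-type Laplacian kernel over an odd rectangular support.

    The kernel weights are the Laplacian of the least-squares fit of a
    full second-order polynomial (1, x, y, x^2, y^2, xy) over the
    support, so it annihilates constants and linear fields exactly and
    returns exactly 2/spacing^2 on x^2 or y^2.  Larger supports trade
    resolution for a smaller noise amplification factor.
    """
    sy, sx = support if np.iterable(support) else (support, support)
    if sy % 2 == 0 or sx % 2 == 0 or sy < 3 or sx < 3:
        raise ValueError("support sizes must be odd and >= 3")
    hy, hx = sy // 2, sx // 2
    ys, xs = np.mgrid[-hy:hy + 1, -hx:hx + 1]
    ys, xs = ys.ravel().astype(float), xs.ravel().astype(float)
    design = np.stack([np.ones_like(xs), xs, ys, xs**2, ys**2, xs * ys], axis=1)
    pinv = np.linalg.pinv(design)            # (6, sy*sx)
    lap = (2.0 * (pinv[3] + pinv[4])).reshape(sy, sx) / spacing**2
    return DerivativeKernel(weights=lap, support=(sy, sx), spacing=spacing)


def _apply_kernel(field: np.ndarray, kernel: DerivativeKernel) -> np.ndarray:
    # correlation; the kernel is symmetric so convolution is identical
    return fftconvolve(field, kernel.weights[::-1, ::-1], mode="same")


def hept_reconstruct(acq: Acquisition, kernel: DerivativeKernel | None = None,
                     omega: float = OMEGA_3T) -> EpsMaps:
    """Helmholtz reconstruction from |B1+| and the transmit phase.

    The valid mask excludes voxels whose kernel footprint crosses the
    object boundary and voxels with vanishing field magnitude.
    """
    if kernel is None:
        kernel = build_noise_robust_kernel(spacing=acq.spacing)
    if abs(kernel.spacing - acq.spacing) > 1e-12:
        kernel = build_noise_robust_kernel(kernel.support, acq.spacing)
    B = acq.magnitude * np.exp(1j * acq.phase)
    hy, hx = kernel.half_width
    valid = binary_erosion(acq.mask, structure=np.ones((2 * hy + 1, 2 * hx + 1)))
    nz = np.abs(B) > 0
    valid &= nz
    lap = _apply_kernel(B, kernel)
    ratio = np.zeros_like(B)
    np.divide(lap, B, out=ratio, where=nz)
    epsr = -ratio.real / (MU0 * EPS0 * omega**2)
    sigma = ratio.imag / (MU0 * omega)
    epsr[~valid] = 0.0
    sigma[~valid] = 0.0
    return EpsMaps(sigma_map=sigma, epsr_map=epsr, method="H-EPT",
                   valid_mask=valid)


def erode_rois(labels: np.ndarray, n: int = 3) -> np.ndarray:
    """Erode every nonzero label region by ``n`` voxels.

    Regions that vanish under erosion are dropped with a warning; used to
    exclude boundary voxels before computing per-tissue statistics.  The
    structuring element is the 3x3 square, so an n-voxel erosion keeps
    exactly the voxels whose (2n+1)-square neighborhood lies inside the
    region — matched to the square support of the derivative kernel.
    """
    if n < 0:
        raise ValueError("erosion must be >= 0")
    out = np.zeros_like(labels)
    square = np.ones((3, 3), dtype=bool)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        reg = labels == lab
        er = binary_erosion(reg, structure=square, iterations=n) if n > 0 else reg
        if not er.any():
            warnings.warn(f"label {lab} vanished under {n}-voxel erosion")
            continue
        out[er] = lab
    return out
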