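"""Transmit/receive field simulation at 128 MHz.

A 2D TM-polarized (Ez-only) frequency-domain finite-difference solver
computes the complex longitudinal electric field of a tissue model driven
by a quadrature ring of line sources mimicking the dominant birdcage
mode.  The transverse magnetic field follows from the discrete curl, and
from it the circularly polarized transmit component

    B1+ = (Bx + iBy) / 2 .

The receive sensitivity B1- is obtained from a second solve with the
reversed quadrature polarity (the drive a transceive quadrature setup
uses in reception); in a left-right symmetric object its phase matches
the transmit phase, which is exactly the transceive phase assumption
exploited at 3 T: phi_transmit ~ (arg B1+ + arg B1-) / 2.

Time convention: e^{+i omega t}, complex permittivity
eps_tilde = eps0*epsr - i*sigma/omega, so a lossy medium delays and damps
the field and the Helmholtz reconstruction recovers +sigma.

An analytic homogeneous-cylinder solution (interior Bessel mode,
B1+ ∝ J0(k rho)) serves as an independent oracle for solver checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import jv

from .models import TissueModel

__all__ = [
    "MU0", "EPS0", "OMEGA_3T",
    "CoilConfig", "FieldSolution", "Acquisition",
    "solve_fields", "analytic_cylinder_field", "transceive_phase",
    "make_acquisition",
]

MU0 = 4e-7 * np.pi          # vacuum permeability, H/m
EPS0 = 8.8541878128e-12     # vacuum permittivity, F/m
OMEGA_3T = 2 * np.pi * 128e6  # Larmor angular frequency at 3 T, rad/s


@dataclass(frozen=True)
class CoilConfig:
    """Quadrature ring of line sources standing in for a birdcage coil."""

    n_sources: int = 16
    source_radius: float = 0.35   # m
    phase_scheme: int = +1        # +1 transmit polarity, -1 reversed
    amplitude: complex = 1.0      # A

    def __post_init__(self):
        if self.n_sources < 8:
            raise ValueError("need at least 8 sources for a clean mode")
        if self.phase_scheme not in (+1, -1):
            raise ValueError("phase_scheme must be +1 or -1")


@dataclass
class FieldSolution:
    """Complex fields on the model grid."""

    Ez: np.ndarray    # longitudinal electric field, V/m (transmit drive)
    B1p: np.ndarray   # transmit field B1+, T
    B1m: np.ndarray   # receive sensitivity B1-, T (reversed-polarity drive)
    omega: float      # rad/s
    spacing: float    # m

    def scaled(self, c: complex) -> "FieldSolution":
        return FieldSolution(self.Ez * c, self.B1p * c, self.B1m * c,
                             self.omega, self.spacing)


@dataclass
class Acquisition:
    """What an MR scan yields for one slice.

    Channels: transmit magnitude |B1+| (normalized so its in-mask mean is
    1), transmit phase phi+ (= half the transceive phase, rad), and one
    auxiliary channel (binary object mask or pseudo-SE tissue contrast).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    aux: np.ndarray
    mask: np.ndarray
    spacing: float
    aux_kind: str = "mask"
    snr: float = np.inf        # magnitude SNR actually applied
    phase_sd: float = 0.0      # phase noise SD actually applied, rad
    clean_magnitude: np.ndarray | None = None
    clean_phase: np.ndarray | None = None

    def channels(self) -> np.ndarray:
        return np.stack([self.magnitude, self.phase, self.aux])


# ----------------------------------------------------------------------
# FDFD Helmholtz solve
# ----------------------------------------------------------------------

_DAMP_VOXELS = 6       # conductive damping annulus at the domain edge
_DAMP_SIGMA = 2.0      # S/m, peak damping conductivity
_EDGE_MARGIN = 0.06    # m of vacuum beyond the source ring


def _padded_medium(model: TissueModel, coil: CoilConfig):
    """Embed the model grid in a domain large enough to hold the coil."""
    h = model.spacing
    ny, nx = model.shape
    half_needed = coil.source_radius + _EDGE_MARGIN
    pad_y = max(0, int(np.ceil(half_needed / h - ny / 2)))
    pad_x = max(0, int(np.ceil(half_needed / h - nx / 2)))
    eps = np.pad(model.epsr_map, ((pad_y, pad_y), (pad_x, pad_x)),
                 constant_values=1.0)
    sig = np.pad(model.sigma_map, ((pad_y, pad_y), (pad_x, pad_x)),
                 constant_values=0.0)
    # damping annulus: quadratic conductivity ramp over the outer voxels
    Ny, Nx = eps.shape
    iy = np.arange(Ny)[:, None]
    ix = np.arange(Nx)[None, :]
    d = np.minimum(np.minimum(iy, Ny - 1 - iy),
                   np.minimum(ix, Nx - 1 - ix)).astype(float)
    ramp = np.clip((_DAMP_VOXELS - d) / _DAMP_VOXELS, 0, 1) ** 2
    sig = sig + _DAMP_SIGMA * ramp
    return eps, sig, (pad_y, pad_x)


def _source_vector(shape, spacing, coil: CoilConfig, polarity: int):
    """Current density RHS for the quadrature ring of line sources."""
    Ny, Nx = shape
    cy, cx = (Ny - 1) / 2.0, (Nx - 1) / 2.0
    J = np.zeros(shape, dtype=complex)
    angles = 2 * np.pi * np.arange(coil.n_sources) / coil.n_sources
    for ang in angles:
        iy = int(round(cy + coil.source_radius * np.sin(ang) / spacing))
        ix = int(round(cx + coil.source_radius * np.cos(ang) / spacing))
        if not (0 <= iy < Ny and 0 <= ix < Nx):
            raise ValueError("coil sources fall outside the padded domain")
        # co-rotating (polarity +1) phases launch the m=+1 mode whose
        # interior B1+ is uniform in vacuum
        J[iy, ix] += coil.amplitude * np.exp(-1j * polarity * ang) / spacing**2
    return J.ravel()


def _helmholtz_matrix(eps, sig, spacing, omega):
    Ny, Nx = eps.shape
    eps_c = EPS0 * eps - 1j * sig / omega
    k2 = omega**2 * MU0 * eps_c
    inv_h2 = 1.0 / spacing**2
    main = (-4.0 * inv_h2 + k2).ravel()
    A = sp.diags(main, 0, shape=(Ny * Nx, Ny * Nx), format="lil", dtype=complex)
    A = A.tocsr()
    # neighbor couplings with Dirichlet edges (field forced to 0 outside,
    # reflections absorbed by the damping annulus)
    offs = []
    ones = np.full(Ny * Nx, inv_h2, dtype=complex)
    ex = ones.copy()
    ex[np.arange(Nx - 1, Ny * Nx, Nx)] = 0.0   # no wrap across rows
    offs.append(sp.diags(ex[:-1], 1, shape=(Ny * Nx, Ny * Nx)))
    wx = ones.copy()
    wx[np.arange(0, Ny * Nx, Nx)] = 0.0
    offs.append(sp.diags(wx[1:], -1, shape=(Ny * Nx, Ny * Nx)))
    offs.append(sp.diags(ones[:-Nx], Nx, shape=(Ny * Nx, Ny * Nx)))
    offs.append(sp.diags(ones[:-Nx], -Nx, shape=(Ny * Nx, Ny * Nx)))
    for o in offs:
        A = A + o.astype(complex)
    return A.tocsc()


def _b_fields(Ez: np.ndarray, spacing: float, omega: float):
    """B = (i/omega) curl E for E = Ez z-hat, by central differences."""
    dy, dx = np.gradient(Ez, spacing)
    Bx = (1j / omega) * dy
    By = -(1j / omega) * dx
    return Bx, By


def solve_fields(model: TissueModel, coil: CoilConfig | None = None,
                 normalize: bool = True) -> FieldSolution:
    """Solve the 2D Helmholtz problem and form B1+ / B1- maps.

    One sparse factorization serves two right-hand sides: the transmit
    drive (co-rotating quadrature phases) and the reversed drive whose
    field gives the receive sensitivity.  If ``normalize``, fields are
    scaled so that mean |B1+| over the tissue mask is 1 (the Helmholtz
    reconstruction is invariant to this gauge and networks expect
    normalized inputs).
    """
    coil = coil or CoilConfig()
    omega = OMEGA_3T
    eps, sig, (pad_y, pad_x) = _padded_medium(model, coil)
    shape = eps.shape
    A = _helmholtz_matrix(eps, sig, model.spacing, omega)
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # pragma: no cover - singular system
        raise RuntimeError(f"singular Helmholtz system: {exc}") from exc

    sols = {}
    for pol in (+1, -1):
        rhs = -1j * omega * MU0 * _source_vector(shape, model.spacing, coil,
                                                 pol * coil.phase_scheme)
        Ez = lu.solve(rhs).reshape(shape)
        if not np.all(np.isfinite(Ez)):
            raise RuntimeError("solver produced non-finite field")
        sols[pol] = Ez

    ny, nx = model.shape
    crop = (slice(pad_y, pad_y + ny), slice(pad_x, pad_x + nx))
    Bx_t, By_t = _b_fields(sols[+1], model.spacing, omega)
    B1p = 0.5 * (Bx_t + 1j * By_t)[crop]
    Bx_r, By_r = _b_fields(sols[-1], model.spacing, omega)
    B1m = 0.5 * (Bx_r - 1j * By_r)[crop]
    Ez = sols[+1][crop]

    sol = FieldSolution(Ez, B1p, B1m, omega, model.spacing)
    if normalize:
        mask = model.mask
        ref = np.abs(B1p[mask]).mean() if mask.any() else np.abs(B1p).mean()
        sol = sol.scaled(1.0 / ref)
    return sol


# ----------------------------------------------------------------------
# Analytic oracle: homogeneous cylinder
# ----------------------------------------------------------------------

def analytic_cylinder_field(radius: float, sigma: float, epsr: float,
                            grid_shape=(128, 128), spacing: float = 0.002,
                            omega: float = OMEGA_3T) -> FieldSolution:
    """Interior Bessel-mode fields of a homogeneous cylinder.

    Under a circularly polarized excitation the interior transmit field is
    B1+(rho) = J0(k rho) / J0(k R) with k^2 = omega^2 mu0 (eps0 epsr -
    i sigma/omega) — unit field at the boundary.  The receive sensitivity
    of the reversed-quadrature drive has the same radial profile in a
    circularly symmetric object, so the transceive phase assumption is
    exact here.  Outside the cylinder the field is set to the boundary
    value (only the interior is used by reconstruction checks).
    """
    ny, nx = grid_shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    yy, xx = np.meshgrid(y, x, indexing="ij")
    rho = np.hypot(yy, xx)
    phi = np.arctan2(yy, xx)
    k = np.sqrt(omega**2 * MU0 * (EPS0 * epsr - 1j * sigma / omega))
    norm = jv(0, k * radius)
    B1p = np.where(rho <= radius, jv(0, k * rho) / norm, 1.0).astype(complex)
    B1m = B1p.copy()
    # longitudinal field of the co-rotating mode, Ez ∝ -J1(k rho) e^{-i phi}
    Ez = np.where(rho <= radius,
                  -2 * omega / k * jv(1, k * rho) * np.exp(-1j * phi) / norm,
                  0.0).astype(complex)
    return FieldSolution(Ez, B1p, B1m, omega, spacing)


# ----------------------------------------------------------------------
# Acquisition assembly
# ----------------------------------------------------------------------

def transceive_phase(sol: FieldSolution, mask: np.ndarray):
    """Transceive phase phi± = arg(B1+ B1-), unwrapped, and phi+ = phi±/2.

    The product phase is unwrapped in 2D (wrap-around jumps would
    otherwise explode under the Laplacian of the Helmholtz
    reconstruction); voxels where B1+ vanishes inside the mask raise.
    The unwrapped phase carries an arbitrary 2*pi*k offset — every
    consumer (Helmholtz ratio, network normalization) is invariant to it.
    """
    from skimage.restoration import unwrap_phase

    if mask.any() and np.any(np.abs(sol.B1p[mask]) == 0):
        raise ValueError("zero transmit field inside the mask")
    wrapped = np.angle(sol.B1p * sol.B1m)
    phi_pm = np.asarray(unwrap_phase(wrapped))
    return phi_pm, phi_pm / 2.0


def make_acquisition(sol: FieldSolution, model: TissueModel,
                     aux: str = "mask") -> Acquisition:
    """Bundle |B1+|, phi+ and an auxiliary channel into an acquisition.

    ``aux`` selects the third channel: a binary object mask
    (1: object, 0: air) or the pseudo spin-echo tissue contrast.
    """
    from .models import make_tissue_contrast

    if sol.B1p.shape != model.shape:
        raise ValueError("field and model grids differ")
    mask = model.mask
    mag = np.abs(sol.B1p)
    ref = mag[mask].mean() if mask.any() else mag.mean()
    mag = mag / ref
    _, phase = transceive_phase(sol, mask)
    if aux == "mask":
        aux_map = mask.astype(float)
    elif aux == "tissue_contrast":
        aux_map = make_tissue_contrast(model)
    else:
        raise ValueError("aux must be 'mask' or 'tissue_contrast'")
    return Acquisition(magnitude=mag, phase=phase, aux=aux_map, mask=mask,
                       spacing=sol.spacing, aux_kind=aux,
                       clean_magnitude=mag.copy(), clean_phase=phase.copy())
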