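"""Tissue models with known electrical properties.

Ground truth for both reconstruction routes is a 2D piecewise-constant
tissue model: an integer label map plus per-voxel conductivity (S/m) and
relative permittivity maps that are constant within each label region.
Three generators are provided:

* homogeneous cylindrical phantoms (circular cross-section),
* procedurally generated head-like models with nested, non-convex
  WM/GM/CSF shells,
* tumor inclusions inserted into an existing head model.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueProperties",
    "TissueModel",
    "LABELS",
    "lookup_tissue_properties",
    "build_phantom_model",
    "build_phantom_library",
    "build_head_model",
    "add_tumor",
    "make_tissue_contrast",
]

LARMOR_HZ_3T = 128e6

# Integer labels used throughout the package.
LABELS = {"air": 0, "WM": 1, "GM": 2, "CSF": 3, "phantom": 4, "tumor": 5}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# Literature dielectric values at 128 MHz (3 T Larmor frequency) used as
# ground truth for brain tissue, plus the agar phantom and the tumor
# analogue.  sigma in S/m, epsr dimensionless.
_TISSUE_TABLE_128MHZ = {
    "air": (0.0, 1.0),
    "WM": (0.34, 52.6),
    "GM": (0.59, 73.4),
    "CSF": (2.14, 84.0),
    "phantom": (0.88, 80.0),
    "tumor": (1.4, 73.0),
}

# Pseudo spin-echo intensities per tissue (arbitrary units before [0, 1]
# normalization).  Ordering follows a T2-weighted SE acquisition:
# CSF > GM > WM > air.
DEFAULT_SE_INTENSITY = {"air": 0.0, "WM": 0.45, "GM": 0.70, "CSF": 1.0,
                        "phantom": 0.80, "tumor": 0.85}


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue at a fixed frequency."""

    tissue_name: str
    sigma: float          # S/m
    epsr: float           # dimensionless
    frequency: float      # Hz

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("conductivity must be non-negative")
        if self.tissue_name == "air":
            if self.sigma != 0 or self.epsr != 1:
                raise ValueError("air must have sigma=0, epsr=1")
        elif self.epsr < 1:
            raise ValueError("relative permittivity must be >= 1 for tissue")


@dataclass
class TissueModel:
    """Labeled 2D grid with per-voxel electrical properties.

    ``label_grid`` holds an integer tissue label per voxel (0 = air);
    ``sigma_map``/``epsr_map`` are piecewise constant over the label
    regions; ``spacing`` is the isotropic voxel size in meters.
    """

    label_grid: np.ndarray
    sigma_map: np.ndarray
    epsr_map: np.ndarray
    spacing: float
    region_properties: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.label_grid != 0

    @property
    def shape(self):
        return self.label_grid.shape

    def validate(self) -> None:
        if self.label_grid.shape != self.sigma_map.shape != self.epsr_map.shape:
            raise ValueError("map shapes differ")
        if np.any(self.sigma_map < 0):
            raise ValueError("sigma_map must be non-negative")
        out = ~self.mask
        if not (np.all(self.sigma_map[out] == 0.0)
                and np.all(self.epsr_map[out] == 1.0)):
            raise ValueError("outside the mask sigma must be 0 and epsr 1")
        if np.any(self.epsr_map[self.mask] < 1.0):
            raise ValueError("epsr must be >= 1 inside the mask")
        for lab in np.unique(self.label_grid):
            reg = self.label_grid == lab
            if np.ptp(self.sigma_map[reg]) != 0 or np.ptp(self.epsr_map[reg]) != 0:
                raise ValueError(f"properties not constant within label {lab}")

    def copy(self) -> "TissueModel":
        return TissueModel(self.label_grid.copy(), self.sigma_map.copy(),
                           self.epsr_map.copy(), self.spacing,
                           dict(self.region_properties))


def lookup_tissue_properties(tissue: str, frequency: float = LARMOR_HZ_3T
                             ) -> TissueProperties:
    """Look up the literature (sigma, epsr) ground truth for a tissue.

    Only the 128 MHz (3 T) table is bundled.
    """
    if abs(frequency - LARMOR_HZ_3T) > 1e-6 * LARMOR_HZ_3T:
        raise ValueError(f"unsupported frequency {frequency:g} Hz; "
                         "only 128 MHz is tabulated")
    try:
        sigma, epsr = _TISSUE_TABLE_128MHZ[tissue]
    except KeyError:
        raise KeyError(f"unknown tissue {tissue!r}; known: "
                       f"{sorted(_TISSUE_TABLE_128MHZ)}") from None
    return TissueProperties(tissue, sigma, epsr, LARMOR_HZ_3T)


def _grid_coords(grid_shape, spacing):
    """Physical (y, x) coordinates of voxel centers, origin at grid center."""
    ny, nx = grid_shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    return np.meshgrid(y, x, indexing="ij")


def build_phantom_model(diameter: float, sigma: float, epsr: float,
                        grid_shape=(128, 128), spacing: float = 0.002
                        ) -> TissueModel:
    """Homogeneous cylindrical phantom (circular 2D cross-section).

    The default phantom diameter used by the simulated library is 12 cm.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if sigma < 0 or epsr < 1:
        raise ValueError("need sigma >= 0 and epsr >= 1")
    extent = min(grid_shape) * spacing
    if diameter >= extent:
        raise ValueError(f"diameter {diameter} m exceeds grid extent {extent} m")
    yy, xx = _grid_coords(grid_shape, spacing)
    disk = yy**2 + xx**2 <= (diameter / 2.0) ** 2
    labels = np.where(disk, LABELS["phantom"], 0).astype(np.int32)
    sig = np.where(disk, sigma, 0.0)
    eps = np.where(disk, epsr, 1.0)
    return TissueModel(labels, sig, eps, spacing,
                       {LABELS["phantom"]: (sigma, epsr)})


def build_phantom_library(n: int = 42,
                          sigma_range=(0.2, 2.2),
                          epsr_range=(40.0, 90.0),
                          seed: int = 0,
                          diameter: float = 0.12,
                          grid_shape=(128, 128),
                          spacing: float = 0.002):
    """Library of homogeneous phantoms with distinct (sigma, epsr) pairs.

    Property pairs are sampled uniformly (low-discrepancy stratified draw)
    from the configured ranges; the default ranges bracket the brain-tissue
    and agar-phantom values at 128 MHz.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if sigma_range[1] <= sigma_range[0] or epsr_range[1] <= epsr_range[0]:
        raise ValueError("degenerate sampling range")
    rng = np.random.default_rng(seed)
    # Stratified sampling keeps the library spread over the range so that
    # held-out phantoms are interpolations, not extrapolations.
    strata = (np.arange(n) + rng.uniform(0, 1, n)) / n
    sigmas = sigma_range[0] + rng.permutation(strata) * (sigma_range[1] - sigma_range[0])
    epsrs = epsr_range[0] + rng.permutation(strata) * (epsr_range[1] - epsr_range[0])
    return [build_phantom_model(diameter, float(s), float(e),
                                grid_shape=grid_shape, spacing=spacing)
            for s, e in zip(sigmas, epsrs)]


def _wobbly_radius(phi, base, rng, n_modes=3, rel_amp=0.07):
    """Radius of a perturbed circle: base * (1 + sum of low-order sinusoids)."""
    r = np.ones_like(phi)
    for m in range(2, 2 + n_modes):
        amp = rng.uniform(-rel_amp, rel_amp) / n_modes * 3.0
        ph = rng.uniform(0, 2 * np.pi)
        r = r + amp * np.cos(m * phi + ph)
    return base * r


def build_head_model(seed: int = 0, eps_variation: float = 0.1,
                     grid_shape=(128, 128), spacing: float = 0.002,
                     outer_radius: float = 0.088,
                     csf_thickness: float = 0.012,
                     gm_thickness: float = 0.026) -> TissueModel:
    """Procedural head-like model: nested non-convex WM/GM/CSF shells.

    Geometry is built from concentric perturbed-ellipse shells (outer CSF
    rim, GM ribbon, WM core) with sinusoidal boundary perturbations so the
    tissue interfaces are spatially convoluted.  Per-tissue electrical
    properties are the 128 MHz literature values perturbed by a uniform
    relative factor of at most ``eps_variation`` (0 gives the reference
    values exactly).  Everything is reproducible under ``seed``.
    """
    if eps_variation < 0:
        raise ValueError("eps_variation must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = _grid_coords(grid_shape, spacing)
    # mild anisotropy: heads are not circles
    elong = rng.uniform(1.05, 1.2)
    rr = np.hypot(yy * elong, xx)
    phi = np.arctan2(yy, xx)

    r_csf = _wobbly_radius(phi, outer_radius, rng, rel_amp=0.04)
    r_gm = _wobbly_radius(phi, outer_radius - csf_thickness, rng, rel_amp=0.05)
    r_wm = _wobbly_radius(phi, outer_radius - csf_thickness - gm_thickness,
                          rng, rel_amp=0.08)

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[rr <= r_csf] = LABELS["CSF"]
    labels[rr <= r_gm] = LABELS["GM"]
    labels[rr <= r_wm] = LABELS["WM"]

    sig = np.zeros(grid_shape)
    eps = np.ones(grid_shape)
    props = {}
    for tissue in ("WM", "GM", "CSF"):
        ref = lookup_tissue_properties(tissue)
        fs = 1.0 + rng.uniform(-eps_variation, eps_variation)
        fe = 1.0 + rng.uniform(-eps_variation, eps_variation)
        s, e = ref.sigma * fs, max(ref.epsr * fe, 1.0)
        reg = labels == LABELS[tissue]
        sig[reg], eps[reg] = s, e
        props[LABELS[tissue]] = (s, e)
    return TissueModel(labels, sig, eps, spacing, props)


def add_tumor(model: TissueModel, center=None, radius: float = 0.015,
              sigma: float = 1.4, epsr: float = 73.0) -> TissueModel:
    """Insert a disk-shaped tumor inclusion with the given properties.

    ``center`` is a (row, col) voxel coordinate; by default the inclusion
    is placed at the grid center (inside the WM core of the head models).
    The inclusion must lie fully inside tissue.
    """
    if radius == 0:
        return model.copy()
    if radius < 0:
        raise ValueError("radius must be >= 0")
    out = model.copy()
    ny, nx = model.shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    yy, xx = np.meshgrid(np.arange(ny, dtype=float),
                         np.arange(nx, dtype=float), indexing="ij")
    disk = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) \
        <= (radius / model.spacing) ** 2
    if not disk.any():
        return out
    if np.any(model.label_grid[disk] == 0):
        raise ValueError("tumor inclusion overlaps air; must lie inside tissue")
    out.label_grid[disk] = LABELS["tumor"]
    out.sigma_map[disk] = sigma
    out.epsr_map[disk] = epsr
    out.region_properties[LABELS["tumor"]] = (sigma, epsr)
    return out


def make_tissue_contrast(model: TissueModel, intensities=None) -> np.ndarray:
    """Pseudo spin-echo magnitude image: one intensity per tissue type.

    Each voxel gets the configured SE-like intensity of its tissue
    (defaults CSF > GM > WM > air = 0), normalized to [0, 1].
    """
    table = dict(DEFAULT_SE_INTENSITY)
    if intensities:
        table.update(intensities)
    img = np.zeros(model.shape)
    for lab in np.unique(model.label_grid):
        name = LABEL_NAMES.get(int(lab))
        if name is None or name not in table:
            raise KeyError(f"no spin-echo intensity configured for label {lab}")
        img[model.label_grid == lab] = table[name]
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img
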