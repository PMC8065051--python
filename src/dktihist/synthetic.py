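"""Synthetic inputs for both modalities.

Two generators make every pipeline stage testable without any acquisition:

* a multi-region DWI phantom whose per-region diffusion/kurtosis tensors are
  constructed to reproduce prescribed regional values (axially symmetric
  tensor pairs, optionally calibrated so the spherical-mean kurtosis hits a
  target), with optional Rician or Gaussian noise at a given SNR;
* dark-fiber-on-light-background texture images whose fiber orientations
  follow a von Mises distribution with controllable concentration kappa —
  the analogue of coherent white-matter bundles (high kappa) versus
  mixed-orientation subcortical tissue (low kappa).

All randomness flows through a single seeded generator recorded in the
returned metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon

from .dki import (
    DiffusionTensor,
    GradientScheme,
    KurtosisTensor,
    apparent_kurtosis,
    forward_signal,
    kurtosis_metrics,
)
from .hog import HistologyImage
from .quadrature import orthonormal_basis

__all__ = [
    "RegionSpec",
    "NoiseSpec",
    "FiberTextureSpec",
    "TensorConstructionError",
    "build_tensors",
    "simulate_dwi_phantom",
    "generate_fiber_texture",
    "sample_fiber_orientations",
    "reference_regions",
    "reference_phantom_layout",
]


class TensorConstructionError(ValueError):
    """No valid axially symmetric tensor pair reproduces the requested values."""


@dataclass(frozen=True)
class RegionSpec:
    """Ground truth for one phantom region.

    Diffusivities in mm^2/s.  Kurtosis may be given as the (axial, radial)
    pair, or as a spherical-mean target ``k_mean`` (the tensor is then
    scaled so the quadrature mean matches it exactly — K_app is linear in
    W).  ``box`` is ((x0, x1), (y0, y1), (z0, z1)) in voxel indices,
    half-open.
    """

    label: str
    tissue_class: str
    d_axial: float
    d_radial: float
    k_axial: float | None = None
    k_radial: float | None = None
    k_mean: float | None = None
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    box: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.d_axial <= 0 or self.d_radial <= 0:
            raise TensorConstructionError("diffusivities must be positive")
        if self.k_mean is None and (self.k_axial is None or self.k_radial is None):
            raise TensorConstructionError("specify k_mean or both k_axial and k_radial")
        for k in (self.k_axial, self.k_radial, self.k_mean):
            if k is not None and k < 0:
                raise TensorConstructionError("kurtosis values must be non-negative")
        if abs(np.linalg.norm(self.axis)) == 0:
            raise TensorConstructionError("axis must be a nonzero vector")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for the simulated magnitude signal.

    Rician: S' = sqrt((S + e1)^2 + e2^2), e ~ N(0, (s0/snr)^2) — the
    magnitude-MRI model.  Gaussian adds e1 only.
    """

    model: str = "rician"
    snr: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.model != "none" and self.snr <= 0:
            raise ValueError("SNR must be positive")


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is the (normalised) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    u, v = orthonormal_basis(axis)
    return np.column_stack([u, v, axis])


def build_tensors(
    spec: RegionSpec, sphere: np.ndarray | None = None
) -> tuple[DiffusionTensor, KurtosisTensor]:
    """Axially symmetric (D, W) pair reproducing the region's ground truth.

    In the frame with the symmetry axis along z: D = diag(d_radial,
    d_radial, d_axial); W has W3333 = K_par * d_axial^2 / MD^2 on the axis
    and a transversely isotropic in-plane part W1111 = W2222 = 3 W1122 =
    K_perp * d_radial^2 / MD^2, which makes K_app exactly K_par along the
    axis and K_perp in every perpendicular direction.  A closure check
    verifies both to 1e-9.
    """
    lam_par, lam_perp = spec.d_axial, spec.d_radial
    md = (lam_par + 2.0 * lam_perp) / 3.0
    if spec.k_mean is not None:
        k_par = k_perp = max(spec.k_mean, 1e-12)
    else:
        k_par, k_perp = spec.k_axial, spec.k_radial

    rot = _rotation_to(np.asarray(spec.axis, dtype=float))
    dt = DiffusionTensor(rot @ np.diag([lam_perp, lam_perp, lam_par]) @ rot.T)

    w_ax = k_par * lam_par**2 / md**2
    w_perp = k_perp * lam_perp**2 / md**2
    unique = np.zeros(15)
    unique[0] = unique[1] = w_perp                    # W1111, W2222
    unique[2] = w_ax                                  # W3333
    unique[9] = w_perp / 3.0                          # W1122
    # cross terms interpolate between the axial and in-plane levels; they
    # do not enter W_app on the axis or the equator, and for w_ax == w_perp
    # they complete w * I4 exactly (isotropic spec -> isotropic tensor)
    unique[10] = unique[11] = (w_ax + w_perp) / 6.0   # W1133, W2233
    kt = KurtosisTensor.from_unique(unique).rotated(rot)

    if spec.k_mean is not None:
        k_mean_now, _, _ = kurtosis_metrics(dt, kt, sphere=sphere)
        if k_mean_now <= 0:
            raise TensorConstructionError("cannot calibrate a zero spherical-mean kurtosis")
        kt = KurtosisTensor(kt.tensor * (spec.k_mean / k_mean_now))
    else:
        axis = np.asarray(spec.axis, dtype=float) / np.linalg.norm(spec.axis)
        perp = orthonormal_basis(axis)[0]
        if abs(apparent_kurtosis(dt, kt, axis) - k_par) > 1e-9 or (
            abs(apparent_kurtosis(dt, kt, perp) - k_perp) > 1e-9
        ):
            raise TensorConstructionError("axial/radial kurtosis closure check failed")
    return dt, kt


def reference_regions() -> list[RegionSpec]:
    """Four tissue classes at the regional values the analysis targets.

    d_mean / k_mean (x1e-3 mm^2/s, dimensionless): WM 0.60 / 1.17,
    GM 0.80 / 0.82, SCN 0.46 / 1.17, CSF 2.07 / 0.74; eigenvalue splits
    chosen so FA falls in the realistic per-class range (WM ~0.6, GM ~0.2,
    CSF ~0.05).
    """
    return [
        RegionSpec("wm", "WM", d_axial=1.10e-3, d_radial=0.35e-3, k_mean=1.17),
        RegionSpec("gm", "GM", d_axial=1.00e-3, d_radial=0.70e-3, k_mean=0.82),
        RegionSpec("scn", "SCN", d_axial=0.70e-3, d_radial=0.34e-3, k_mean=1.17,
                   axis=(1.0, 0.0, 0.0)),
        RegionSpec("csf", "CSF", d_axial=2.21e-3, d_radial=2.00e-3, k_mean=0.74),
    ]


def reference_phantom_layout(shape: tuple[int, int, int] = (40, 40, 16)) -> list[RegionSpec]:
    """The reference regions laid out as four quadrant boxes tiling the grid."""
    nx, ny, nz = shape
    hx, hy = nx // 2, ny // 2
    boxes = [
        ((0, hx), (0, hy), (0, nz)),
        ((hx, nx), (0, hy), (0, nz)),
        ((0, hx), (hy, ny), (0, nz)),
        ((hx, nx), (hy, ny), (0, nz)),
    ]
    from dataclasses import replace

    return [replace(r, box=b) for r, b in zip(reference_regions(), boxes)]


def simulate_dwi_phantom(
    regions: list[RegionSpec],
    scheme: GradientScheme,
    shape: tuple[int, int, int] = (40, 40, 16),
    noise: NoiseSpec | None = None,
    s0: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate a 4-D DWI grid from boxed regions.

    Returns ``(dwi, labels, info)``: dwi is (x, y, z, measurement), labels
    is int (-1 outside every region, else the region index), and info
    records tensors, seeds and per-region ground-truth metrics.  Noiseless
    voxels are exactly the forward model; overlapping boxes are an error.
    """
    noise = noise or NoiseSpec(model="none")
    labels = np.full(shape, -1, dtype=int)
    dwi = np.zeros(shape + (len(scheme),))
    info: dict = {"seed": noise.seed, "noise": noise.model, "snr": noise.snr,
                  "s0": s0, "regions": {}}
    for idx, spec in enumerate(regions):
        if spec.box is None:
            raise ValueError(f"region {spec.label!r} has no box")
        (x0, x1), (y0, y1), (z0, z1) = spec.box
        sl = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
        if np.any(labels[sl] >= 0):
            raise ValueError(f"region {spec.label!r} overlaps a previous region")
        labels[sl] = idx
        dt, kt = build_tensors(spec)
        dwi[sl] = forward_signal(s0, dt, kt, scheme)
        info["regions"][spec.label] = {
            "index": idx,
            "tissue_class": spec.tissue_class,
            "dt_unique": dt.unique.tolist(),
            "kt_unique": kt.unique.tolist(),
        }
    if noise.model != "none":
        rng = np.random.default_rng(noise.seed)
        sigma = s0 / noise.snr
        e1 = rng.normal(0.0, sigma, size=dwi.shape)
        if noise.model == "rician":
            e2 = rng.normal(0.0, sigma, size=dwi.shape)
            dwi = np.sqrt((dwi + e1) ** 2 + e2**2)
        else:
            dwi = dwi + e1
    return dwi, labels, info


@dataclass(frozen=True)
class FiberTextureSpec:
    """Parameters of a synthetic silver-stain-like fiber texture.

    Defaults emulate a 400x400 um field at 0.5 um/px densely permeated by
    faint, overlapping stained fibers (~1.5 um wide, ~75 um long) whose
    orientations follow vonMises(mean, kappa) on the half-circle (kappa = 0
    is uniform).  Each fiber darkens the light background additively by
    ``fiber_depth`` and the field is blurred by an optical-PSF-like
    Gaussian, so the texture is a dense smooth oriented field rather than a
    few isolated strokes — as in a real stained section, where thousands of
    axons overlap within any 100-um tile.  Additive Gaussian intensity
    noise is applied last; intensities are clipped to [0, 1].
    """

    size: tuple[int, int] = (800, 800)
    pixel_size_um: float = 0.5
    mean_orientation_deg: float = 100.0
    kappa: float = 8.0
    n_fibers: int = 3000
    fiber_length_um: float = 75.0
    fiber_length_sd_um: float = 15.0
    fiber_width_um: float = 1.5
    fiber_depth: float = 0.10
    depth_jitter: float = 0.30
    psf_sigma_um: float = 0.6
    background: float = 0.92
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


def sample_fiber_orientations(
    rng: np.random.Generator, mean_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Axial orientations (radians in [0, pi)) from a von Mises distribution.

    Sampled on the doubled-angle circle, the standard construction for
    axial data: theta = (vonMises(2*mean, kappa) / 2) mod pi.  kappa = 0
    yields the uniform distribution on [0, pi).
    """
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=n)
    return np.mod(doubled / 2.0, np.pi)


def generate_fiber_texture(spec: FiberTextureSpec) -> HistologyImage:
    """Render a fiber texture image; deterministic for a fixed seed.

    Fibers are rasterised as rectangles whose darkness accumulates
    additively where they overlap; the darkness field is then blurred and
    subtracted from the light background.
    """
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    darkness = np.zeros((h, w), dtype=float)
    if spec.n_fibers == 0:
        warnings.warn("zero fiber count: background-only image", stacklevel=2)
    angles = sample_fiber_orientations(
        rng, spec.mean_orientation_deg, spec.kappa, spec.n_fibers
    )
    lengths = np.clip(
        rng.normal(spec.fiber_length_um, spec.fiber_length_sd_um, spec.n_fibers), 2.0, None
    ) / spec.pixel_size_um
    width_px = max(spec.fiber_width_um / spec.pixel_size_um, 1.0)
    centers_r = rng.uniform(0, h, spec.n_fibers)
    centers_c = rng.uniform(0, w, spec.n_fibers)
    depths = spec.fiber_depth * (1.0 + spec.depth_jitter * rng.uniform(-1, 1, spec.n_fibers))
    for theta, length, cr, cc, depth in zip(angles, lengths, centers_r, centers_c, depths):
        # rectangle aligned with the fiber: orientation measured from the
        # image x (column) axis, rows increase downwards
        d = np.array([-np.sin(theta), np.cos(theta)])  # (row, col) unit direction
        p = np.array([np.cos(theta), np.sin(theta)])   # perpendicular
        half_l, half_w = length / 2.0, width_px / 2.0
        center = np.array([cr, cc])
        corners = np.array(
            [
                center + half_l * d + half_w * p,
                center + half_l * d - half_w * p,
                center - half_l * d - half_w * p,
                center - half_l * d + half_w * p,
            ]
        )
        rr, cc_idx = polygon(corners[:, 0], corners[:, 1], shape=darkness.shape)
        darkness[rr, cc_idx] += depth
    if spec.psf_sigma_um > 0:
        darkness = ndimage.gaussian_filter(darkness, spec.psf_sigma_um / spec.pixel_size_um)
    canvas = spec.background - darkness + rng.normal(0.0, spec.noise_sd, size=(h, w))
    canvas = np.clip(canvas, 0.0, 1.0)
    return HistologyImage(
        pixels=canvas,
        pixel_size_um=spec.pixel_size_um,
        roi_label=f"synthetic_kappa{spec.kappa:g}_seed{spec.seed}",
        tissue_class="WM" if spec.kappa >= 8 else "SCN",
    )
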