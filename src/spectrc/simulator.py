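"""Synthetic SPECT acquisition and OSEM reconstruction of the phantom.

This module is the synthetic-data generator: it rasterizes the analytic
phantom onto a voxel grid, forward-projects it with a parallel-beam
rotation projector (uniform attenuation, Gaussian collimator-detector
blur, Poisson counting noise) and reconstructs with a generic
ordered-subsets expectation-maximization (OSEM) algorithm.  Distinct
``SystemProfile`` presets — modelled on four clinical dual-head cameras —
differ in collimator resolution, reconstruction voxel size, iteration /
subset counts and post-filtering, which is what drives the inter-system
recovery-coefficient differences the analysis modules measure.

Deliberate physics simplifications: the point-spread function is a single
distance-independent Gaussian FWHM; attenuation is uniform water (ideal
CT-based correction, the same map in simulation and reconstruction);
scatter is not simulated and no energy-window scatter correction exists.
The projector works slice-by-slice transaxially, so a reconstruction of an
axial sub-slab of the phantom is exact, and the default acquisition covers
a 134.4 mm slab containing the sphere plane and the background VOI region.

Geometry conventions: image arrays are indexed ``[z, y, x]``; world
coordinates are mm with the cylinder axis at (x, y) = (0, 0) and the
sphere plane at z = 0.  Detector bins are shared by all systems (128
transaxial x 4.8 mm, 28 axial x 4.8 mm) so that the same raw sinogram can
be reconstructed both with a system's own settings ("vendor-specific")
and with one standardized setting ("vendor-neutral").
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import nibabel as nib
from scipy.ndimage import gaussian_filter

from .phantom import (
    ActivityFill,
    DecaySpec,
    LU177_HALF_LIFE_H,
    PhantomDefinition,
    decay_factor,
)

logger = logging.getLogger("spectrc")

#: Linear attenuation coefficient of water at 208 keV, 1/cm.
MU_WATER_208KEV = 0.137

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemProfile:
    """One simulated "scanner + reconstruction" configuration.

    ``sensitivity`` is the planar system sensitivity in cps/MBq that the
    calibration-factor chain should recover; ``psf_fwhm`` the collimator-
    detector blur at the phantom centre; the remaining fields are the
    reconstruction settings (iterations x subsets, Gaussian post-filter
    FWHM in mm, isotropic reconstruction voxel size in mm).
    """

    name: str
    voxel_size: float  # mm, isotropic
    psf_fwhm: float  # mm
    iterations: int
    subsets: int
    psf_modelling: bool = True
    post_filter_fwhm: float = 0.0  # mm, 0 = none
    sensitivity: float = 10.0  # cps/MBq
    attenuation_mu: float = MU_WATER_208KEV  # 1/cm, 0 = off
    hardware_group: str = ""
    #: Fraction of the true PSF FWHM the reconstruction models.  Clinical
    #: resolution recovery is incomplete (distance-dependent blur is
    #: approximated, scatter tails are unmodelled), so the default is < 1;
    #: set to 1.0 for a forward-model-matched reconstruction.
    model_psf_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.iterations * self.subsets < 1:
            raise ValueError("iterations * subsets must be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Harmonized acquisition protocol (dual-head treated as 128 angles)."""

    n_projections: int = 128
    reference_projection_time: float = 40.0  # s, before decay adjustment
    matrix: int = 128
    energy_window: str = "208 keV +/- 10%"
    orbit: str = "body contour"
    timestamp_h: float = 0.0  # time since experiment reference

    def __post_init__(self) -> None:
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")

    def projection_time(self, half_life_h: float = LU177_HALF_LIFE_H) -> float:
        """Decay-adjusted projection time, reference time / decay factor."""
        f = decay_factor(DecaySpec(half_life_h=half_life_h, elapsed_h=self.timestamp_h))
        return self.reference_projection_time / f


@dataclass(frozen=True)
class DetectorGeometry:
    """Shared detector sampling: transaxial bins, axial bins, slab centre."""

    n_bins: int = 128
    bin_mm: float = 4.8
    n_axial: int = 28
    axial_mm: float = 4.8
    slab_center_z: float = -24.0  # mm; slab covers sphere plane + bg VOI

    @property
    def axial_extent_mm(self) -> float:
        return self.n_axial * self.axial_mm


@dataclass(frozen=True)
class ImageGrid:
    """Isotropic-in-plane voxel grid, centred on the phantom axis."""

    n_xy: int
    n_z: int
    voxel_size: float  # mm, isotropic
    center_z: float = -24.0  # mm, world z of grid centre

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_z, self.n_xy, self.n_xy)

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def xy_coords(self) -> np.ndarray:
        return (np.arange(self.n_xy) - (self.n_xy - 1) / 2.0) * self.voxel_size

    def z_coords(self) -> np.ndarray:
        return self.center_z + (np.arange(self.n_z) - (self.n_z - 1) / 2.0) * self.voxel_size

    def world_to_index(self, point_mm) -> tuple[float, float, float]:
        """Fractional (z, y, x) index of a world-mm point."""
        x, y, z = point_mm
        iz = (z - self.center_z) / self.voxel_size + (self.n_z - 1) / 2.0
        iy = y / self.voxel_size + (self.n_xy - 1) / 2.0
        ix = x / self.voxel_size + (self.n_xy - 1) / 2.0
        return (iz, iy, ix)


def recon_grid_for(profile: SystemProfile, det: DetectorGeometry | None = None,
                   fov_xy_mm: float = 232.0) -> ImageGrid:
    """Reconstruction grid covering the phantom transaxially and the detector slab axially."""
    det = det or DetectorGeometry()
    n_xy = int(np.ceil(fov_xy_mm / profile.voxel_size))
    n_z = int(np.ceil(det.axial_extent_mm / profile.voxel_size))
    return ImageGrid(n_xy=n_xy, n_z=n_z, voxel_size=profile.voxel_size,
                     center_z=det.slab_center_z)


# ---------------------------------------------------------------------------
# System presets (four clinical cameras + the standardized reconstruction)
# ---------------------------------------------------------------------------

DISCOVERY_670: SystemProfile = SystemProfile(
    name="discovery_nm670_pro", voxel_size=2.0, psf_fwhm=12.3,
    iterations=9, subsets=10, post_filter_fwhm=0.0,
    sensitivity=6.2, hardware_group="ge",
)
INTEVO_BOLD: SystemProfile = SystemProfile(
    name="symbia_intevo_bold", voxel_size=4.9, psf_fwhm=11.6,
    iterations=6, subsets=8, post_filter_fwhm=5.0,
    sensitivity=10.2, hardware_group="siemens",
)
T16_SYSTEM1: SystemProfile = SystemProfile(
    name="symbia_t16_system1", voxel_size=4.8, psf_fwhm=11.9,
    iterations=4, subsets=8, post_filter_fwhm=4.0,
    sensitivity=10.3, hardware_group="siemens",
)
T16_SYSTEM2: SystemProfile = SystemProfile(
    name="symbia_t16_system2", voxel_size=4.8, psf_fwhm=12.1,
    iterations=5, subsets=16, post_filter_fwhm=5.0,
    sensitivity=10.1, hardware_group="siemens",
)

DEFAULT_PROFILES: tuple[SystemProfile, ...] = (
    DISCOVERY_670, INTEVO_BOLD, T16_SYSTEM1, T16_SYSTEM2,
)

#: Standardized ("vendor-neutral") reconstruction settings applied to every
#: system's raw data: 5 iterations x 16 subsets, 5 mm Gaussian, 4.8 mm voxels.
STANDARDIZED_SETTINGS = dict(iterations=5, subsets=16, post_filter_fwhm=5.0,
                             voxel_size=4.8)


def standardized(profile: SystemProfile) -> SystemProfile:
    """The vendor-neutral reconstruction of a system's raw data.

    Hardware properties (PSF, sensitivity) stay those of the acquiring
    system; reconstruction settings are replaced by the standardized ones.
    """
    return replace(profile, **STANDARDIZED_SETTINGS)


def get_profile(name: str) -> SystemProfile:
    for p in DEFAULT_PROFILES:
        if p.name == name:
            return p
    raise KeyError(f"unknown system profile {name!r}")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(phantom: PhantomDefinition, fill: ActivityFill, grid: ImageGrid,
              oversample: int = 2) -> np.ndarray:
    """Voxelize the phantom's activity distribution (kBq/ml per voxel).

    Each voxel value is the analytic concentration averaged over
    ``oversample^3`` subvoxel sample points, so boundary voxels take
    fractional (partial-volume) values.  The grid must cover the cylinder
    transaxially; axial sub-slabs are allowed (the projector treats
    transaxial slices independently).
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    if grid.n_xy * grid.voxel_size < phantom.cylinder_diameter:
        raise ValueError("voxel grid smaller than the phantom transaxially")
    xs = grid.xy_coords()
    zs = grid.z_coords()
    off = (np.arange(oversample) + 0.5) / oversample - 0.5
    img = np.zeros(grid.shape, dtype=np.float64)
    r_cyl = phantom.cylinder_diameter / 2.0
    h2 = phantom.cylinder_height / 2.0
    for oz in off:
        z = zs + oz * grid.voxel_size  # (nz,)
        for oy in off:
            y = xs + oy * grid.voxel_size  # (ny,)
            for ox in off:
                x = xs + ox * grid.voxel_size  # (nx,)
                r2 = y[:, None] ** 2 + x[None, :] ** 2  # (ny, nx)
                in_cyl = (r2 <= r_cyl**2)[None, :, :] & (np.abs(z) <= h2)[:, None, None]
                val = np.where(in_cyl, fill.background_concentration, 0.0)
                for s in phantom.spheres:
                    cx, cy, cz = s.center
                    d2 = ((x[None, None, :] - cx) ** 2
                          + (y[None, :, None] - cy) ** 2
                          + (z[:, None, None] - cz) ** 2)
                    val = np.where(d2 <= s.radius**2, fill.sphere_concentration, val)
                img += val
    img /= oversample**3
    return img


def rasterized_sphere_volume_ml(phantom: PhantomDefinition, label: str,
                                grid: ImageGrid, oversample: int = 3) -> float:
    """Numerical sphere volume from subvoxel occupancy (rasterizer cross-check)."""
    s = phantom.sphere(label)
    xs, zs = grid.xy_coords(), grid.z_coords()
    off = (np.arange(oversample) + 0.5) / oversample - 0.5
    frac = np.zeros(grid.shape)
    cx, cy, cz = s.center
    for oz in off:
        z = zs + oz * grid.voxel_size
        for oy in off:
            y = xs + oy * grid.voxel_size
            for ox in off:
                x = xs + ox * grid.voxel_size
                d2 = ((x[None, None, :] - cx) ** 2 + (y[None, :, None] - cy) ** 2
                      + (z[:, None, None] - cz) ** 2)
                frac += d2 <= s.radius**2
    frac /= oversample**3
    return float(frac.sum() * grid.voxel_volume_ml)


# ---------------------------------------------------------------------------
# Parallel-beam projector (rotation-based, matched forward/adjoint pair)
# ---------------------------------------------------------------------------

class _RotationCache:
    """Precomputed bilinear gather indices/weights for in-plane rotations."""

    _store: dict[tuple[int, float], tuple] = {}

    @classmethod
    def get(cls, n: int, angle_deg: float) -> tuple:
        key = (n, round(angle_deg % 360.0, 6))
        if key not in cls._store:
            cls._store[key] = cls._build(n, angle_deg)
        return cls._store[key]

    @staticmethod
    def _build(n: int, angle_deg: float) -> tuple:
        th = np.deg2rad(angle_deg)
        c = (n - 1) / 2.0
        grid = np.arange(n, dtype=np.float64) - c
        ys, xs = np.meshgrid(grid, grid, indexing="ij")
        ct, st = np.cos(th), np.sin(th)
        # pull interpolation: source = R(-theta) @ target
        sy = ct * ys - st * xs + c
        sx = st * ys + ct * xs + c
        y0 = np.floor(sy).astype(np.int64)
        x0 = np.floor(sx).astype(np.int64)
        fy = (sy - y0).astype(np.float32)
        fx = (sx - x0).astype(np.float32)
        idx, wts = [], []
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            for dx, wx in ((0, 1.0 - fx), (1, fx)):
                yy, xx = y0 + dy, x0 + dx
                ok = (yy >= 0) & (yy < n) & (xx >= 0) & (xx < n)
                w = np.where(ok, wy * wx, 0.0).astype(np.float32)
                flat = np.where(ok, yy * n + xx, 0).astype(np.int64).ravel()
                idx.append(flat)
                wts.append(w.ravel())
        return tuple(idx), tuple(wts)


def _rotate_stack(img: np.ndarray, n: int, angle_deg: float) -> np.ndarray:
    """Rotate every z-slice of ``img`` [z, y, x] by ``angle_deg`` about the grid centre."""
    idx, wts = _RotationCache.get(n, angle_deg)
    flat = img.reshape(img.shape[0], -1)
    out = flat[:, idx[0]] * wts[0]
    for i in range(1, 4):
        out += flat[:, idx[i]] * wts[i]
    return out.reshape(img.shape)


def _rebin_matrix(src_pos: np.ndarray, src_step: float,
                  dst_pos: np.ndarray, dst_step: float) -> np.ndarray:
    """Count-conserving interval-overlap matrix mapping source samples to bins.

    Each source sample represents an interval of width ``src_step``; its
    value is distributed over destination bins in proportion to the
    geometric overlap, which is exact for piecewise-constant profiles and
    free of the beat-frequency ripple a point-sample rebin produces when
    the two spacings are incommensurate.  Source intervals outside the
    destination span are dropped, never clamped, so simulation and
    reconstruction share the same field of view.
    """
    nd = len(dst_pos)
    m = np.zeros((nd, len(src_pos)))
    dst_lo = dst_pos - dst_step / 2.0
    dst_hi = dst_pos + dst_step / 2.0
    for i, x in enumerate(src_pos):
        a, b = x - src_step / 2.0, x + src_step / 2.0
        d_first = max(int(np.floor((a - dst_lo[0]) / dst_step)), 0)
        d_last = min(int(np.floor((b - dst_lo[0]) / dst_step)) + 1, nd - 1)
        for d in range(d_first, d_last + 1):
            overlap = min(b, dst_hi[d]) - max(a, dst_lo[d])
            if overlap > 0:
                m[d, i] += overlap / src_step
    return m


class ParallelProjector:
    """Attenuated parallel-beam projector between an image grid and the detector.

    Forward model per angle: rotate the emission volume so rays run along
    +y, apply the (rotation-invariant, cylinder-based) attenuation factor,
    sum along y, rebin transaxially and axially onto the detector grid,
    and blur with the Gaussian collimator-detector PSF.  The adjoint runs
    the transpose of the same chain with the inverse rotation.

    Output units: ``sum over ray of voxel values`` (dimensionless rebinning);
    physical scaling to expected counts is applied by the caller.
    """

    def __init__(self, grid: ImageGrid, det: DetectorGeometry, angles_deg: np.ndarray,
                 psf_fwhm: float = 0.0, attenuation_mu: float = 0.0,
                 cylinder_radius_mm: float = 108.0) -> None:
        self.grid = grid
        self.det = det
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.psf_fwhm = float(psf_fwhm)
        self.attenuation_mu = float(attenuation_mu)
        xy = grid.xy_coords()
        det_x = (np.arange(det.n_bins) - (det.n_bins - 1) / 2.0) * det.bin_mm
        self.T = _rebin_matrix(xy, grid.voxel_size, det_x, det.bin_mm)
        det_z = det.slab_center_z + (np.arange(det.n_axial) - (det.n_axial - 1) / 2.0) * det.axial_mm
        self.Z = _rebin_matrix(grid.z_coords(), grid.voxel_size, det_z, det.axial_mm)
        # attenuation in the rotated frame (rays along +y); the cylinder is
        # rotationally symmetric, so one 2-D map serves every angle
        if attenuation_mu > 0:
            mu_mm = attenuation_mu / 10.0
            y = xy[:, None]
            x = xy[None, :]
            inside = x**2 + y**2 <= cylinder_radius_mm**2
            y_exit = np.sqrt(np.maximum(cylinder_radius_mm**2 - x**2, 0.0))
            path = np.where(inside, y_exit - y, 0.0)
            self.att2d = np.exp(-mu_mm * np.maximum(path, 0.0))
        else:
            self.att2d = np.ones((grid.n_xy, grid.n_xy))
        if psf_fwhm > 0:
            self._sig_x = psf_fwhm * _FWHM_TO_SIGMA / det.bin_mm
            self._sig_z = psf_fwhm * _FWHM_TO_SIGMA / det.axial_mm
        else:
            self._sig_x = self._sig_z = 0.0

    @property
    def sino_shape(self) -> tuple[int, int, int]:
        return (len(self.angles_deg), self.det.n_axial, self.det.n_bins)

    def _blur(self, det2d: np.ndarray) -> np.ndarray:
        if self._sig_x == 0.0:
            return det2d
        return gaussian_filter(det2d, sigma=(self._sig_z, self._sig_x), mode="constant")

    def forward(self, img: np.ndarray, angle_indices=None) -> np.ndarray:
        """Project [z, y, x] image to sinogram [angle, det_z, det_x]."""
        idxs = list(range(len(self.angles_deg))) if angle_indices is None else list(angle_indices)
        out = np.empty((len(idxs), self.det.n_axial, self.det.n_bins))
        for k, a in enumerate(idxs):
            rot = _rotate_stack(img, self.grid.n_xy, self.angles_deg[a])
            prof = (rot * self.att2d[None, :, :]).sum(axis=1)  # [z, x]
            out[k] = self._blur(self.Z @ prof @ self.T.T)
        return out

    def adjoint(self, sino_part: np.ndarray, angle_indices=None) -> np.ndarray:
        """Backproject sinogram values [k, det_z, det_x] into image space."""
        idxs = list(range(len(self.angles_deg))) if angle_indices is None else list(angle_indices)
        img = np.zeros(self.grid.shape)
        for k, a in enumerate(idxs):
            prof = self.Z.T @ self._blur(sino_part[k]) @ self.T  # [z, x]
            vol = prof[:, None, :] * self.att2d[None, :, :]
            img += _rotate_stack(vol, self.grid.n_xy, -self.angles_deg[a])
        return img


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------

@dataclass
class Sinogram:
    """Projection data: [angle, axial bin, transaxial bin], counts or expected counts."""

    values: np.ndarray
    angles_deg: np.ndarray
    det: DetectorGeometry
    acquisition: AcquisitionSpec
    system: str = ""
    noisy: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("sinogram values must be finite and >= 0")


def _count_scale(profile: SystemProfile, grid: ImageGrid, projection_time_s: float) -> float:
    """Counts per (kBq/ml summed over a ray of source voxels).

    A voxel holds ``a * voxel_volume_ml`` kBq; the system records
    ``sensitivity/1000`` counts per second per kBq in each view.
    """
    return profile.sensitivity / 1000.0 * projection_time_s * grid.voxel_volume_ml


def forward_project(activity: np.ndarray, grid: ImageGrid, profile: SystemProfile,
                    acquisition: AcquisitionSpec, det: DetectorGeometry | None = None,
                    cylinder_radius_mm: float = 108.0,
                    half_life_h: float = LU177_HALF_LIFE_H,
                    apply_decay: bool = True) -> Sinogram:
    """Expected-count sinogram of a (reference-time) activity image.

    The activity is decayed to the acquisition timestamp and the projection
    time inflated by the reciprocal decay factor, which leaves expected
    counts independent of the timestamp — the study's decay-adjustment
    scheme.
    """
    det = det or DetectorGeometry()
    angles = np.arange(acquisition.n_projections) * (360.0 / acquisition.n_projections)
    proj = ParallelProjector(grid, det, angles, psf_fwhm=profile.psf_fwhm,
                             attenuation_mu=profile.attenuation_mu,
                             cylinder_radius_mm=cylinder_radius_mm)
    f = decay_factor(DecaySpec(half_life_h=half_life_h, elapsed_h=acquisition.timestamp_h)) \
        if apply_decay else 1.0
    t = acquisition.reference_projection_time / f if apply_decay \
        else acquisition.reference_projection_time
    expected = proj.forward(activity * f) * _count_scale(profile, grid, t)
    return Sinogram(values=expected, angles_deg=angles, det=det,
                    acquisition=replace(acquisition), system=profile.name, noisy=False)


def add_noise(sino: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw per bin, reproducible under a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noisy = rng.poisson(sino.values).astype(np.float64)
    return dataclasses.replace(sino, values=noisy, noisy=True)


def derive_seed(master_seed: int, name: str, repeat_index: int) -> int:
    """Stable per-(system, repeat) seed: crc32 mix of the master seed and labels."""
    tag = f"{master_seed}:{name}:{repeat_index}".encode()
    return zlib.crc32(tag) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# OSEM reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconImage:
    """Reconstructed volume in voxel units of counts, with acquisition metadata.

    ``voxels / (t * n * voxel_volume_ml * CF)`` with ``CF = sensitivity/1000``
    (cps/ml per kBq/ml) returns the activity-concentration image; that
    conversion lives in :mod:`spectrc.calibration`.
    """

    voxels: np.ndarray  # [z, y, x], counts
    grid: ImageGrid
    acquisition: AcquisitionSpec
    system: str
    repeat_index: int = 0
    mode: str = "vendor_specific"
    half_life_h: float = LU177_HALF_LIFE_H

    def __post_init__(self) -> None:
        if np.any(self.voxels < 0):
            raise ValueError("reconstructed voxels must be >= 0")

    @property
    def projection_time_s(self) -> float:
        return self.acquisition.projection_time(self.half_life_h)


def _subset_partition(n_projections: int, subsets: int) -> list[np.ndarray]:
    if subsets > n_projections:
        raise ValueError("more subsets than projections")
    if n_projections % subsets != 0:
        warnings.warn(
            f"{subsets} subsets do not divide {n_projections} projections; "
            "using a balanced round-robin partition", stacklevel=2)
    order = np.arange(n_projections)
    return [order[s::subsets] for s in range(subsets)]


def osem_reconstruct(sino: Sinogram, profile: SystemProfile,
                     grid: ImageGrid | None = None,
                     cylinder_radius_mm: float = 108.0,
                     half_life_h: float = LU177_HALF_LIFE_H) -> ReconImage:
    """Ordered-subsets EM reconstruction of a count sinogram.

    The reconstruction's forward model includes the same Gaussian PSF as
    the simulation when ``profile.psf_modelling`` is on (resolution
    recovery), and the same ideal uniform attenuation map.  The image is
    estimated in kBq/ml and returned in voxel counts so that the
    calibration chain (Eq.-1-style) applies downstream.
    """
    grid = grid or recon_grid_for(profile, sino.det)
    t = sino.acquisition.projection_time(half_life_h)
    scale = _count_scale(profile, grid, t)
    proj = ParallelProjector(
        grid, sino.det, sino.angles_deg,
        psf_fwhm=(profile.psf_fwhm * profile.model_psf_fraction
                  if profile.psf_modelling else 0.0),
        attenuation_mu=profile.attenuation_mu,
        cylinder_radius_mm=cylinder_radius_mm)
    parts = _subset_partition(len(sino.angles_deg), profile.subsets)
    sens = []
    for part in parts:
        ones = np.ones((len(part), sino.det.n_axial, sino.det.n_bins))
        s = proj.adjoint(ones, part)
        sens.append(s)
    x = np.ones(grid.shape)
    eps = 1e-12
    for _ in range(profile.iterations):
        for part, s in zip(parts, sens):
            fp = proj.forward(x, part) * scale
            meas = sino.values[part]
            ratio = np.divide(meas, fp, out=np.zeros_like(fp), where=fp > eps * max(fp.max(), 1.0))
            bp = proj.adjoint(ratio, part)
            upd = np.divide(bp, s, out=np.ones_like(bp), where=s > 1e-9 * s.max())
            x *= upd
    if profile.post_filter_fwhm > 0:
        sig = profile.post_filter_fwhm * _FWHM_TO_SIGMA / grid.voxel_size
        x = gaussian_filter(x, sigma=sig, mode="nearest")
    n = sino.acquisition.n_projections
    counts = x * (t * n * grid.voxel_volume_ml * profile.sensitivity / 1000.0)
    return ReconImage(voxels=counts, grid=grid, acquisition=sino.acquisition,
                      system=profile.name, half_life_h=half_life_h)


# ---------------------------------------------------------------------------
# Experiment-level simulation
# ---------------------------------------------------------------------------

def truth_grid(det: DetectorGeometry | None = None, voxel: float = 2.4,
               fov_xy_mm: float = 232.0) -> ImageGrid:
    """Fine grid for the ground-truth rasterization, spanning the detector slab.

    Activity outside the axial slab is invisible to the (idealized,
    slice-collimated) acquisition, so the truth grid matches the detector's
    axial span exactly; an over- or under-hanging grid would make the
    simulation and reconstruction forward models inconsistent.
    """
    det = det or DetectorGeometry()
    n_xy = int(np.ceil(fov_xy_mm / voxel))
    n_z = int(round(det.axial_extent_mm / voxel))
    return ImageGrid(n_xy=n_xy, n_z=n_z, voxel_size=voxel, center_z=det.slab_center_z)


def default_schedule(n_systems: int, n_repeats: int, span_h: float = 74.7) -> list[list[float]]:
    """Acquisition timestamps (hours): systems measured consecutively, the
    whole campaign spanning the study's 74.7 h first-to-last interval."""
    total = n_systems * n_repeats
    step = span_h / (total - 1) if total > 1 else 0.0
    return [[(k * n_repeats + r) * step for r in range(n_repeats)]
            for k in range(n_systems)]


def simulate_experiment(
    phantom: PhantomDefinition,
    fill: ActivityFill,
    profiles: tuple[SystemProfile, ...] = DEFAULT_PROFILES,
    n_repeats: int = 3,
    schedule: list[list[float]] | None = None,
    master_seed: int = 0,
    modes: tuple[str, ...] = ("vendor_specific", "vendor_neutral"),
    acquisition: AcquisitionSpec | None = None,
    det: DetectorGeometry | None = None,
    oversample: int = 2,
    truth_voxel: float = 2.4,
    noise: bool = True,
    half_life_h: float = LU177_HALF_LIFE_H,
) -> list[ReconImage]:
    """Simulate the full multi-system repeatability experiment.

    One noisy sinogram is generated per (system, repeat) — with a noise
    seed derived deterministically from the master seed — and every
    requested reconstruction mode reuses that same raw data, mirroring the
    study's vendor-specific vs vendor-neutral comparison.  Projection
    times are decay-adjusted per timestamp.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    det = det or DetectorGeometry()
    acquisition = acquisition or AcquisitionSpec()
    schedule = schedule or default_schedule(len(profiles), n_repeats)
    tgrid = truth_grid(det, voxel=truth_voxel)
    truth = rasterize(phantom, fill, tgrid, oversample=oversample)
    r_cyl = phantom.cylinder_diameter / 2.0
    images: list[ReconImage] = []
    for k, prof in enumerate(profiles):
        recon_profiles = {}
        for mode in modes:
            rp = prof if mode == "vendor_specific" else standardized(prof)
            recon_profiles[mode] = (rp, recon_grid_for(rp, det))
        for r in range(n_repeats):
            acq = replace(acquisition, timestamp_h=schedule[k][r])
            expected = forward_project(truth, tgrid, prof, acq, det,
                                       cylinder_radius_mm=r_cyl,
                                       half_life_h=half_life_h)
            sino = add_noise(expected, derive_seed(master_seed, prof.name, r)) \
                if noise else expected
            for mode, (rp, rgrid) in recon_profiles.items():
                img = osem_reconstruct(sino, rp, grid=rgrid,
                                       cylinder_radius_mm=r_cyl,
                                       half_life_h=half_life_h)
                img.repeat_index = r
                img.mode = mode
                img.system = prof.name
                images.append(img)
    return images


def simulate_calibration_phantom(
    volume_l: float = 6.8,
    activity_MBq: float = 500.0,
    profile: SystemProfile = T16_SYSTEM1,
    acquisition: AcquisitionSpec | None = None,
    det: DetectorGeometry | None = None,
    seed: int | None = None,
    cylinder_diameter: float = 216.0,
    oversample: int = 2,
    truth_voxel: float = 2.4,
) -> tuple[ReconImage, float]:
    """Uniform cylindrical calibration phantom; returns (image, true kBq/ml).

    Emulates the cross-calibration measurement: a homogeneous 6-7 l
    cylinder with ~500 MBq, acquired with the experiment protocol, from
    which the calibration factor is determined.  The returned true
    concentration is decayed to the acquisition timestamp — the activity
    the dose calibrator would report at scan time.
    """
    if activity_MBq <= 0:
        raise ValueError("activity must be > 0")
    det = det or DetectorGeometry()
    acquisition = acquisition or AcquisitionSpec()
    height = volume_l * 1e6 / (np.pi * (cylinder_diameter / 2.0) ** 2)
    conc = activity_MBq * 1000.0 / (volume_l * 1000.0)  # kBq/ml
    cal_phantom = PhantomDefinition(cylinder_diameter=cylinder_diameter,
                                    cylinder_height=height, spheres=())
    fill = ActivityFill(sphere_concentration=0.0, background_concentration=conc)
    tgrid = truth_grid(det, voxel=truth_voxel)
    truth = rasterize(cal_phantom, fill, tgrid, oversample=oversample)
    expected = forward_project(truth, tgrid, profile, acquisition, det,
                               cylinder_radius_mm=cylinder_diameter / 2.0)
    sino = add_noise(expected, seed) if seed is not None else expected
    img = osem_reconstruct(sino, profile, cylinder_radius_mm=cylinder_diameter / 2.0)
    conc_at_scan = conc * decay_factor(DecaySpec(elapsed_h=acquisition.timestamp_h))
    return img, conc_at_scan


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

def save_recon(image: ReconImage, path: str) -> None:
    """Write a ReconImage as NIfTI-1 (float64 voxel counts) + JSON sidecar."""
    g = image.grid
    affine = np.diag([g.voxel_size, g.voxel_size, g.voxel_size, 1.0])
    affine[0, 3] = -(g.n_xy - 1) / 2.0 * g.voxel_size
    affine[1, 3] = -(g.n_xy - 1) / 2.0 * g.voxel_size
    affine[2, 3] = g.center_z - (g.n_z - 1) / 2.0 * g.voxel_size
    data = np.ascontiguousarray(np.transpose(image.voxels, (2, 1, 0)))  # -> [x, y, z]
    nib.save(nib.Nifti1Image(data, affine), path)
    sidecar = {
        "projection_time_s": image.projection_time_s,
        "n_projections": image.acquisition.n_projections,
        "voxel_size_mm": g.voxel_size,
        "system": image.system,
        "repeat": image.repeat_index,
        "timestamp_h": image.acquisition.timestamp_h,
        "mode": image.mode,
        "reference_projection_time_s": image.acquisition.reference_projection_time,
        "half_life_h": image.half_life_h,
        "grid_center_z_mm": g.center_z,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def save_sinogram(sino: Sinogram, path: str) -> None:
    """Write a sinogram as a NIfTI stack [angle, axial, transaxial] + sidecar."""
    data = np.ascontiguousarray(np.transpose(sino.values, (2, 1, 0)))
    nib.save(nib.Nifti1Image(data, np.eye(4)), path)
    sidecar = {
        "angles_deg": [float(a) for a in sino.angles_deg],
        "n_projections": sino.acquisition.n_projections,
        "reference_projection_time_s": sino.acquisition.reference_projection_time,
        "timestamp_h": sino.acquisition.timestamp_h,
        "det": {"n_bins": sino.det.n_bins, "bin_mm": sino.det.bin_mm,
                "n_axial": sino.det.n_axial, "axial_mm": sino.det.axial_mm,
                "slab_center_z": sino.det.slab_center_z},
        "system": sino.system,
        "noisy": sino.noisy,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_sinogram(path: str) -> Sinogram:
    nii = nib.load(path)
    with open(_sidecar_path(path)) as fh:
        sc = json.load(fh)
    values = np.transpose(np.asarray(nii.dataobj, dtype=np.float64), (2, 1, 0))
    det = DetectorGeometry(**sc["det"])
    acq = AcquisitionSpec(n_projections=sc["n_projections"],
                          reference_projection_time=sc["reference_projection_time_s"],
                          timestamp_h=sc["timestamp_h"])
    return Sinogram(values=values, angles_deg=np.asarray(sc["angles_deg"]), det=det,
                    acquisition=acq, system=sc["system"], noisy=sc["noisy"])


def _sidecar_path(path: str) -> str:
    for suffix in (".nii.gz", ".nii"):
        if path.endswith(suffix):
            return path[: -len(suffix)] + ".json"
    return path + ".json"


def load_recon(path: str) -> ReconImage:
    """Read a NIfTI + sidecar pair back into a ReconImage (lossless)."""
    nii = nib.load(path)
    with open(_sidecar_path(path)) as fh:
        sc = json.load(fh)
    data = np.transpose(np.asarray(nii.dataobj, dtype=np.float64), (2, 1, 0))
    hdr_vox = float(nii.header.get_zooms()[0])
    if abs(hdr_vox - sc["voxel_size_mm"]) > 1e-6:
        raise ValueError(
            f"voxel size mismatch: header {hdr_vox} mm vs sidecar {sc['voxel_size_mm']} mm")
    grid = ImageGrid(n_xy=data.shape[2], n_z=data.shape[0],
                     voxel_size=sc["voxel_size_mm"], center_z=sc["grid_center_z_mm"])
    acq = AcquisitionSpec(
        n_projections=sc["n_projections"],
        reference_projection_time=sc.get("reference_projection_time_s", sc["projection_time_s"]),
        timestamp_h=sc["timestamp_h"])
    return ReconImage(voxels=data, grid=grid, acquisition=acq, system=sc["system"],
                      repeat_index=sc["repeat"], mode=sc.get("mode", "vendor_specific"),
                      half_life_h=sc.get("half_life_h", LU177_HALF_LIFE_H))
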