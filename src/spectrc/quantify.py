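"""Background statistics, isocontour sphere segmentation and recovery coefficients.

The segmentation follows the background-corrected 50% isocontour rule: for
sphere j the threshold is

    VOI_thresh,j = 0.5 * (VOI_max,j + VOI_mean,bg)

where VOI_max,j is the maximum voxel value in a bounded search region
around the sphere and VOI_mean,bg the mean of a cylindrical background VOI
(9 cm diameter, 5 cm height) placed in a uniform part of the phantom.  The
sphere VOI is the connected region above the threshold that contains the
seed voxel (region growing).  Recovery coefficients are

    RC_mean,j = A_i,j / A_a,j        RC_max,j = A_i,max,j / A_a,j

with A_i the imaged concentration averaged over the repeated measurements
and A_a the actual (decay-corrected) concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import PhantomDefinition
from .simulator import ImageGrid

logger = logging.getLogger("spectrc")


# ---------------------------------------------------------------------------
# Background VOI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundVOI:
    """Cylindrical background VOI and its first-order statistics."""

    center: tuple[float, float, float]  # mm, world
    diameter: float = 90.0  # mm
    height: float = 50.0  # mm
    mean_value: float = float("nan")
    sd: float = float("nan")
    n_voxels: int = 0


#: Default placement: on-axis, centred 57.5 mm below the sphere plane so the
#: VOI clears the bounding box of the largest (60 mm) sphere.
DEFAULT_BG_CENTER = (0.0, 0.0, -57.5)


def background_stats(conc_image: np.ndarray, grid: ImageGrid,
                     voi: BackgroundVOI | None = None,
                     phantom: PhantomDefinition | None = None) -> BackgroundVOI:
    """Mean/SD over voxels whose centres fall inside the background cylinder.

    When a phantom definition is supplied, the VOI is validated to lie
    inside the phantom and outside every sphere's bounding box.
    """
    voi = voi or BackgroundVOI(center=DEFAULT_BG_CENTER)
    cx, cy, cz = voi.center
    r = voi.diameter / 2.0
    if phantom is not None:
        if (np.hypot(cx, cy) + r > phantom.cylinder_diameter / 2.0
                or abs(cz) + voi.height / 2.0 > phantom.cylinder_height / 2.0):
            raise ValueError("background VOI extends outside the phantom")
        for s in phantom.spheres:
            sx, sy, sz = s.center
            # cylinder vs axis-aligned bounding-box overlap test
            dx = max(abs(cx - sx) - s.radius, 0.0)
            dy = max(abs(cy - sy) - s.radius, 0.0)
            overlap_xy = np.hypot(dx, dy) < r
            overlap_z = abs(cz - sz) < voi.height / 2.0 + s.radius
            if overlap_xy and overlap_z:
                raise ValueError(
                    f"background VOI intersects bounding box of sphere {s.label!r}")
    xy = grid.xy_coords()
    zs = grid.z_coords()
    in_plane = (xy[:, None] - cy) ** 2 + (xy[None, :] - cx) ** 2 <= r**2
    in_z = np.abs(zs - cz) <= voi.height / 2.0
    mask = in_z[:, None, None] & in_plane[None, :, :]
    if not mask.any():
        raise ValueError("background VOI contains no voxel centres")
    vals = conc_image[mask]
    return BackgroundVOI(center=voi.center, diameter=voi.diameter, height=voi.height,
                         mean_value=float(vals.mean()), sd=float(vals.std(ddof=1)) if
                         vals.size > 1 else 0.0, n_voxels=int(vals.size))


# ---------------------------------------------------------------------------
# Threshold and seed
# ---------------------------------------------------------------------------

def threshold_value(voi_max: float, bg_mean: float) -> float:
    """Background-corrected 50% isocontour level, 0.5 * (VOI_max + VOI_mean,bg)."""
    if voi_max < 0:
        raise ValueError("voi_max must be >= 0")
    return 0.5 * (voi_max + bg_mean)


def _ball_mask(grid: ImageGrid, center_mm, radius_mm: float) -> np.ndarray:
    cx, cy, cz = center_mm
    xy = grid.xy_coords()
    zs = grid.z_coords()
    d2 = ((xy[None, None, :] - cx) ** 2 + (xy[None, :, None] - cy) ** 2
          + (zs[:, None, None] - cz) ** 2)
    return d2 <= radius_mm**2


def find_seed(conc_image: np.ndarray, grid: ImageGrid,
              expected_center: tuple[float, float, float],
              search_radius: float) -> tuple[int, int, int]:
    """Voxel of maximum value within a search ball; lexicographic tie-break.

    The expected centre comes from the phantom definition (the physical
    study knew the sphere order from CT).  Ties resolve to the smallest
    (z, y, x) index, which is what C-order argmax returns.
    """
    ball = _ball_mask(grid, expected_center, search_radius)
    if not ball.any():
        raise ValueError("seed search ball contains no voxel centres")
    masked = np.where(ball, conc_image, -np.inf)
    flat = int(np.argmax(masked))
    return tuple(int(i) for i in np.unravel_index(flat, conc_image.shape))


# ---------------------------------------------------------------------------
# Region-growing segmentation
# ---------------------------------------------------------------------------

@dataclass
class SphereSegmentation:
    """Connected above-threshold region for one sphere, with its statistics."""

    label: str
    seed: tuple[int, int, int]
    threshold: float
    max_value: float
    mask: np.ndarray  # boolean, image shape
    segmented_volume_ml: float
    mean_value: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def segment_sphere(conc_image: np.ndarray, grid: ImageGrid,
                   seed: tuple[int, int, int], bg_mean: float,
                   label: str = "", max_search_radius_mm: float | None = None,
                   connectivity: int = 26) -> SphereSegmentation:
    """Two-pass background-corrected 50% isocontour region growing.

    Pass 1 finds VOI_max within a ball of ``max_search_radius_mm`` around
    the seed (bounded so a neighbouring sphere's maximum cannot leak in)
    and sets the threshold; pass 2 keeps the connected component at or
    above the threshold that contains the seed (26-connectivity by
    default, 6 available).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    seed = tuple(int(i) for i in seed)
    seed_value = float(conc_image[seed])
    if seed_value <= bg_mean:
        raise ValueError("seed voxel value must exceed the background mean")
    if max_search_radius_mm is not None:
        xy = grid.xy_coords()
        zs = grid.z_coords()
        center_mm = (xy[seed[2]], xy[seed[1]], zs[seed[0]])
        ball = _ball_mask(grid, center_mm, max_search_radius_mm)
        voi_max = float(conc_image[ball].max())
    else:
        voi_max = seed_value
    voi_max = max(voi_max, seed_value)
    thresh = threshold_value(voi_max, bg_mean)
    above = conc_image >= thresh
    labels, _ = ndimage.label(above, structure=_STRUCTURES[connectivity])
    region = labels == labels[seed]
    if labels[seed] == 0 or not region.any():
        raise ValueError(f"empty segmentation for sphere {label!r}")
    border = (region[0].any() or region[-1].any()
              or region[:, 0].any() or region[:, -1].any()
              or region[:, :, 0].any() or region[:, :, -1].any())
    if border:
        warnings.warn(f"segmentation of sphere {label!r} touches the image border",
                      stacklevel=2)
    vals = conc_image[region]
    return SphereSegmentation(
        label=label, seed=seed, threshold=float(thresh), max_value=float(vals.max()),
        mask=region, segmented_volume_ml=float(region.sum() * grid.voxel_volume_ml),
        mean_value=float(vals.mean()))


# ---------------------------------------------------------------------------
# Recovery coefficients
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Per-sphere recovery coefficients aggregated over repeated measurements."""

    label: str
    per_repeat_mean: list[float]  # mask mean concentration per repeat, kBq/ml
    per_repeat_max: list[float]
    per_repeat_rc_mean: list[float]
    per_repeat_rc_max: list[float]
    actual_concentration: float  # A_a at reference, kBq/ml
    rc_mean: float
    rc_max: float
    segmented_volumes_ml: list[float] = field(default_factory=list)

    @property
    def rc_median(self) -> float:
        return float(np.median(self.per_repeat_rc_mean))

    @property
    def rc_range(self) -> float:
        return float(np.max(self.per_repeat_rc_mean) - np.min(self.per_repeat_rc_mean))

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat_rc_mean)


def recovery_coefficients(repeats: list[SphereSegmentation],
                          actual_concentrations: float | list[float],
                          label: str | None = None,
                          max_aggregation: str = "mean") -> RecoveryResult:
    """RC_mean and RC_max over repeated measurements.

    ``actual_concentrations`` may be a scalar (constant A_a) or one value
    per repeat (A_a decay-corrected to each repeat's timestamp); each
    repeat's imaged concentration is referred to its own A_a.  A_i,max is
    by default the mean over repeats of the per-repeat maxima
    (``max_aggregation="mean"``); ``"max"`` uses the overall maximum.
    """
    if not repeats:
        raise ValueError("at least one repeat is required")
    if max_aggregation not in ("mean", "max"):
        raise ValueError("max_aggregation must be 'mean' or 'max'")
    n = len(repeats)
    a_a = actual_concentrations
    a_list = [float(a_a)] * n if np.isscalar(a_a) else [float(v) for v in a_a]
    if len(a_list) != n:
        raise ValueError("need one actual concentration per repeat (or a scalar)")
    if any(a <= 0 for a in a_list):
        raise ValueError("actual concentration must be > 0")
    means = [s.mean_value for s in repeats]
    maxes = [s.max_value for s in repeats]
    rc_mean_per = [m / a for m, a in zip(means, a_list)]
    rc_max_per = [m / a for m, a in zip(maxes, a_list)]
    rc_mean = float(np.mean(rc_mean_per))
    if max_aggregation == "mean":
        rc_max = float(np.mean(rc_max_per))
    else:
        rc_max = float(np.max(rc_max_per))
    return RecoveryResult(
        label=label if label is not None else repeats[0].label,
        per_repeat_mean=means, per_repeat_max=maxes,
        per_repeat_rc_mean=rc_mean_per, per_repeat_rc_max=rc_max_per,
        actual_concentration=a_list[0], rc_mean=rc_mean, rc_max=rc_max,
        segmented_volumes_ml=[s.segmented_volume_ml for s in repeats])
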