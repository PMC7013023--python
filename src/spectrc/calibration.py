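"""Camera cross-calibration and counts-to-concentration conversion.

The calibration factor (CF) converts reconstructed voxel count rate per ml
into activity concentration:

    CF [(cps/ml)/(kBq/ml)] = (mu / (t * n * nu)) / C

with mu the mean voxel value (counts) in a VOI of the uniform calibration
phantom, t the time per projection (s), n the number of projections, nu
the voxel volume (ml) and C the known activity concentration (kBq/ml).
Numerically CF in (cps/ml)/(kBq/ml) equals cps/kBq, i.e. 1000x the
customary cps/MBq figure; both unit views are exposed.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import ImageGrid, ReconImage

logger = logging.getLogger("spectrc")


@dataclass(frozen=True)
class CalibrationMeasurement:
    """Inputs of the CF formula; all strictly positive."""

    mean_voxel_counts: float  # mu
    projection_time_s: float  # t
    n_projections: int  # n
    voxel_volume_ml: float  # nu
    true_concentration: float  # C, kBq/ml

    def __post_init__(self) -> None:
        for name in ("mean_voxel_counts", "projection_time_s", "n_projections",
                     "voxel_volume_ml", "true_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CalibrationFactor:
    """System calibration factor with a relative uncertainty."""

    value: float  # (cps/ml)/(kBq/ml) == cps/kBq
    system: str = ""
    uncertainty: float = 0.05  # relative fraction
    method: str = "uniform-phantom"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("calibration factor must be > 0")
        if not 0 <= self.uncertainty < 1:
            raise ValueError("uncertainty must be in [0, 1)")

    @property
    def cps_per_MBq(self) -> float:
        """The same factor on the conventional cps/MBq scale."""
        return self.value * 1000.0


def compute_cf(m: CalibrationMeasurement, system: str = "",
               dose_calibrator_uncertainty: float = 0.05,
               repeat_means: list[float] | None = None,
               method: str = "uniform-phantom") -> CalibrationFactor:
    """Calibration factor from a uniform-phantom measurement.

    The uncertainty is the quadrature sum of the dose-calibrator activity
    uncertainty (default 5%) and, when repeated VOI means are supplied,
    their relative scatter.
    """
    value = m.mean_voxel_counts / (
        m.projection_time_s * m.n_projections * m.voxel_volume_ml) / m.true_concentration
    u = dose_calibrator_uncertainty
    if repeat_means and len(repeat_means) > 1:
        rel_sd = float(np.std(repeat_means, ddof=1) / np.mean(repeat_means))
        u = math.hypot(u, rel_sd)
    return CalibrationFactor(value=value, system=system, uncertainty=u, method=method)


def calibration_voi_mask(grid: ImageGrid, cylinder_diameter: float = 216.0,
                         cylinder_height: float = 186.0,
                         diameter_fraction: float = 0.6,
                         height_fraction: float = 0.5) -> np.ndarray:
    """Centred cylindrical VOI, 60% of the phantom diameter and 50% of its
    height by default — large enough to average out noise, far enough from
    the edges to avoid Gibbs/partial-volume contamination."""
    r_voi = cylinder_diameter * diameter_fraction / 2.0
    h_voi = cylinder_height * height_fraction
    xy = grid.xy_coords()
    zs = grid.z_coords()
    in_plane = xy[:, None] ** 2 + xy[None, :] ** 2 <= r_voi**2
    in_z = np.abs(zs) <= h_voi / 2.0
    mask = in_z[:, None, None] & in_plane[None, :, :]
    if not mask.any():
        # an axial sub-slab may not straddle z = 0; centre on the slab instead
        in_z = np.abs(zs - zs.mean()) <= h_voi / 2.0
        mask = in_z[:, None, None] & in_plane[None, :, :]
    return mask


def measure_cf(image: ReconImage, true_concentration: float,
               voi_mask: np.ndarray | None = None, **kwargs) -> CalibrationFactor:
    """Apply the CF formula to a reconstructed calibration-phantom image."""
    mask = voi_mask if voi_mask is not None else calibration_voi_mask(image.grid)
    mu = float(image.voxels[mask].mean())
    m = CalibrationMeasurement(
        mean_voxel_counts=mu,
        projection_time_s=image.projection_time_s,
        n_projections=image.acquisition.n_projections,
        voxel_volume_ml=image.grid.voxel_volume_ml,
        true_concentration=true_concentration,
    )
    return compute_cf(m, system=image.system, **kwargs)


def counts_to_concentration(image: ReconImage, cf: CalibrationFactor) -> np.ndarray:
    """Concentration image (kBq/ml): voxel counts / (t * n * nu * CF)."""
    missing = [name for name, val in (
        ("projection_time_s", image.projection_time_s),
        ("n_projections", image.acquisition.n_projections),
        ("voxel_size_mm", image.grid.voxel_size),
    ) if val is None or val <= 0]
    if missing:
        raise ValueError(f"missing or invalid acquisition metadata: {', '.join(missing)}")
    denom = (image.projection_time_s * image.acquisition.n_projections
             * image.grid.voxel_volume_ml * cf.value)
    return image.voxels / denom


@dataclass(frozen=True)
class DoseCalibratorCheck:
    """Syringe cross-check between a centre's dose calibrator and the reference."""

    measured_activity: float  # MBq
    reference_activity: float  # MBq

    @property
    def deviation(self) -> float:
        return self.measured_activity / self.reference_activity

    @property
    def flagged(self) -> bool:
        """True when the deviation exceeds the 5% tolerance."""
        return abs(self.deviation - 1.0) > 0.05


def dose_calibrator_deviation(measured: float, reference: float) -> DoseCalibratorCheck:
    if reference <= 0:
        raise ValueError("reference activity must be > 0")
    if measured <= 0:
        warnings.warn("measured activity is not positive; deviation degenerate",
                      stacklevel=2)
    return DoseCalibratorCheck(measured_activity=measured, reference_activity=reference)


# ---------------------------------------------------------------------------
# CF registry persistence
# ---------------------------------------------------------------------------

REGISTRY_COLUMNS = ["system", "cf_cps_per_MBq", "uncertainty", "method", "date"]


def registry_to_csv(factors: list[CalibrationFactor], path: str,
                    date: str = "") -> pd.DataFrame:
    df = pd.DataFrame(
        [{"system": f.system, "cf_cps_per_MBq": f.cps_per_MBq,
          "uncertainty": f.uncertainty, "method": f.method, "date": date}
         for f in factors], columns=REGISTRY_COLUMNS)
    df.to_csv(path, index=False)
    return df


def registry_from_csv(path: str) -> dict[str, CalibrationFactor]:
    df = pd.read_csv(path)
    return {
        row["system"]: CalibrationFactor(
            value=row["cf_cps_per_MBq"] / 1000.0, system=row["system"],
            uncertainty=row["uncertainty"], method=row["method"])
        for _, row in df.iterrows()
    }
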