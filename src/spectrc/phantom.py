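"""Analytic phantom geometry, activity fills and radioactive-decay bookkeeping.

The phantom emulated here is a modified cylindrical Jaszczak phantom: a
water-filled cylinder (background compartment, ~6.7 l) carrying six hollow
spherical inserts of 9.9-60.0 mm inner diameter that represent lesions of
increasing size.  Spheres and background are filled with a Lu-177 solution
at a nominal 10:1 concentration contrast (750 / 75 kBq/ml).

All lengths are millimetres, volumes in ml (spheres) or litres (compartments),
activity concentrations in kBq/ml and times in hours unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger("spectrc")

#: Physical half-life of Lu-177 in hours (6.647 days).
LU177_HALF_LIFE_H = 159.53

#: Inner diameters (mm) of the six default sphere inserts, smallest first.
DEFAULT_SPHERE_DIAMETERS_MM = (9.9, 15.4, 19.8, 24.8, 31.3, 60.0)


def sphere_volume(diameter_mm: float) -> float:
    """Volume in ml of a sphere with the given inner diameter in mm.

    Raises
    ------
    ValueError
        If the diameter is negative.
    """
    if diameter_mm < 0:
        raise ValueError(f"sphere diameter must be >= 0, got {diameter_mm}")
    return math.pi / 6.0 * diameter_mm**3 / 1000.0


@dataclass(frozen=True)
class SphereInsert:
    """One spherical insert: label, inner diameter and centre position.

    The centre is expressed in the phantom frame: origin on the cylinder
    axis at the sphere plane, z along the axis.
    """

    label: str
    inner_diameter: float  # mm
    center: tuple[float, float, float]  # mm (x, y, z)

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError(f"sphere {self.label!r}: diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def nominal_volume(self) -> float:
        """Analytic volume in ml, (pi/6) d^3."""
        return sphere_volume(self.inner_diameter)


@dataclass(frozen=True)
class PhantomDefinition:
    """Cylinder-plus-spheres phantom with analytic volume bookkeeping."""

    cylinder_diameter: float  # mm
    cylinder_height: float  # mm
    spheres: tuple[SphereInsert, ...]

    def __post_init__(self) -> None:
        r_cyl = self.cylinder_diameter / 2.0
        for s in self.spheres:
            x, y, z = s.center
            if math.hypot(x, y) + s.radius > r_cyl + 1e-9:
                raise ValueError(f"sphere {s.label!r} extends beyond cylinder wall")
            if abs(z) + s.radius > self.cylinder_height / 2.0 + 1e-9:
                raise ValueError(f"sphere {s.label!r} extends beyond cylinder ends")
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                d = math.dist(a.center, b.center)
                if d < a.radius + b.radius - 1e-9:
                    raise ValueError(f"spheres {a.label!r} and {b.label!r} overlap")

    @property
    def cylinder_volume_l(self) -> float:
        r = self.cylinder_diameter / 2.0
        return math.pi * r**2 * self.cylinder_height / 1e6

    @property
    def total_sphere_volume_ml(self) -> float:
        return sum(s.nominal_volume for s in self.spheres)

    @property
    def background_volume_l(self) -> float:
        """Cylinder volume minus the sphere volumes (exact bookkeeping)."""
        return self.cylinder_volume_l - self.total_sphere_volume_ml / 1000.0

    def sphere(self, label: str) -> SphereInsert:
        for s in self.spheres:
            if s.label == label:
                return s
        raise KeyError(f"no sphere labelled {label!r}")


def default_phantom(
    ring_radius: float = 65.0,
    cylinder_diameter: float = 216.0,
    cylinder_height: float = 186.0,
    start_angle_deg: float = 0.0,
) -> PhantomDefinition:
    """The default six-sphere phantom.

    Sphere centres lie on a ring at mid-height (sphere plane z = 0), 60
    degrees apart, ordered by increasing diameter.  The cylinder interior
    (216 mm diameter x 186 mm) gives ~6.82 l gross and ~6.67 l background
    after sphere subtraction.  The ring layout is configurable because only
    the ordering, not the exact placement, is fixed by the physical phantom.
    """
    spheres = []
    for k, d in enumerate(DEFAULT_SPHERE_DIAMETERS_MM):
        ang = math.radians(start_angle_deg + 60.0 * k)
        spheres.append(
            SphereInsert(
                label=f"d{d:g}",
                inner_diameter=d,
                center=(ring_radius * math.cos(ang), ring_radius * math.sin(ang), 0.0),
            )
        )
    return PhantomDefinition(
        cylinder_diameter=cylinder_diameter,
        cylinder_height=cylinder_height,
        spheres=tuple(spheres),
    )


@dataclass(frozen=True)
class ActivityFill:
    """Activity concentrations (kBq/ml) at a common reference time."""

    sphere_concentration: float
    background_concentration: float
    reference_time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.sphere_concentration < 0 or self.background_concentration < 0:
            raise ValueError("activity concentrations must be >= 0")

    @property
    def ratio(self) -> float:
        """Sphere-to-background concentration ratio."""
        if self.background_concentration <= 0:
            raise ZeroDivisionError("background concentration is zero; ratio undefined")
        return self.sphere_concentration / self.background_concentration


def nominal_fill() -> ActivityFill:
    """The nominal study fill: 750 kBq/ml spheres on 75 kBq/ml background (10:1)."""
    return ActivityFill(sphere_concentration=750.0, background_concentration=75.0)


@dataclass(frozen=True)
class DecaySpec:
    """Half-life and elapsed time, both in hours."""

    half_life_h: float = LU177_HALF_LIFE_H
    elapsed_h: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be > 0")


def decay_factor(spec: DecaySpec) -> float:
    """Fraction of activity remaining after the elapsed time, 2^(-t/T1/2).

    The same factor decays concentrations forward in time; its reciprocal
    inflates the per-projection acquisition time so that count statistics
    stay comparable across a multi-day measurement campaign.
    """
    return 2.0 ** (-spec.elapsed_h / spec.half_life_h)


# ---------------------------------------------------------------------------
# YAML serialization (canonical key order, round-trip stable)
# ---------------------------------------------------------------------------

def phantom_to_yaml(phantom: PhantomDefinition, fill: ActivityFill | None = None) -> str:
    doc: dict = {
        "cylinder_diameter_mm": phantom.cylinder_diameter,
        "cylinder_height_mm": phantom.cylinder_height,
        "spheres": [
            {
                "label": s.label,
                "inner_diameter_mm": s.inner_diameter,
                "center_mm": list(s.center),
            }
            for s in phantom.spheres
        ],
    }
    if fill is not None:
        doc["fill"] = {
            "sphere_kBq_per_ml": fill.sphere_concentration,
            "background_kBq_per_ml": fill.background_concentration,
            "reference_time_h": fill.reference_time_h,
        }
    return yaml.safe_dump(doc, sort_keys=False)


def phantom_from_yaml(text: str) -> tuple[PhantomDefinition, ActivityFill | None]:
    doc = yaml.safe_load(text)
    phantom = PhantomDefinition(
        cylinder_diameter=float(doc["cylinder_diameter_mm"]),
        cylinder_height=float(doc["cylinder_height_mm"]),
        spheres=tuple(
            SphereInsert(
                label=s["label"],
                inner_diameter=float(s["inner_diameter_mm"]),
                center=tuple(float(c) for c in s["center_mm"]),
            )
            for s in doc["spheres"]
        ),
    )
    fill = None
    if "fill" in doc:
        f = doc["fill"]
        fill = ActivityFill(
            sphere_concentration=float(f["sphere_kBq_per_ml"]),
            background_concentration=float(f["background_kBq_per_ml"]),
            reference_time_h=float(f.get("reference_time_h", 0.0)),
        )
    return phantom, fill
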