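"""Nominal geometry of the ACR CT accreditation phantom (model 464).

The phantom is a 20 cm diameter cylinder made of four 4 cm modules:

1. HU fidelity and slice width: five density plugs (air, polyethylene,
   water, acrylic, bone) plus two wire ramps for slice-width counting.
2. Low contrast: a 25 mm cylinder and rod groups (the four 6 mm rods are
   the ones scored) at ~0.6% contrast above the water-equivalent background.
3. Uniformity and in-plane distance: homogeneous material with two
   steel BBs embedded exactly 100.0 mm apart.
4. High contrast: bar patterns at discrete spatial frequencies (lp/cm).

Alignment BBs sit at the phantom surface on the module-1 and module-4
center planes and drive analysis-slice selection.

In-plane coordinates are mm relative to the phantom axis, x to the
right and y up in the axial image; angles are degrees counter-clockwise
from +x.  Exact in-plane plug/rod/BB placement is not standardized in
the analysis literature down to the millimetre, so it is configuration
with defaults that match the phantom layout qualitatively (four plugs at
the cardinal positions plus water near the center); renderer and
analyzer share this single description, which is what the metrics need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PlugSpec",
    "RampSpec",
    "LowContrastSpec",
    "BarPatternSpec",
    "PhantomGeometry",
    "CircularRoi",
    "RoiTemplate",
    "default_geometry",
    "roi_template",
    "rasterize_roi",
]

PLUG_NAMES = ("air", "polyethylene", "water", "acrylic", "bone")


@dataclass
class PlugSpec:
    """One density plug of module 1.

    ``accepted_range`` is the vendor-documentation HU acceptance window
    (per ACR CT Accreditation documentation; these windows are not part
    of the two-year QA dataset shipped with this package).
    """

    name: str
    center: tuple[float, float]  # mm from phantom axis
    diameter: float = 25.0  # mm
    nominal_hu: float = 0.0
    accepted_range: tuple[float, float] = (-7.0, 7.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("plug diameter must be positive")
        lo, hi = self.accepted_range
        if not (lo <= self.nominal_hu <= hi):
            raise ValueError(
                f"accepted HU range {self.accepted_range} for plug "
                f"{self.name!r} does not contain nominal {self.nominal_hu}"
            )


@dataclass
class RampSpec:
    """A wire ramp: wire k sits at in-plane (x_start + k*x_step, y) and at
    longitudinal offset (k + z_offset_frac) * pitch from the module plane.

    The quarter-pitch default offset keeps slab boundaries off the wire
    grid so the number of wires inside a slab of width T is exactly
    T / pitch for T a multiple of the pitch.
    """

    y: float
    x_start: float = -24.0
    x_step: float = 3.0
    n_wires: int = 17
    pitch: float = 0.5  # mm of z per wire
    z_offset_frac: float = 0.25

    def wire_positions(self) -> list[tuple[float, float, float]]:
        """(x, y, dz) per wire, dz relative to the module center plane."""
        k0 = (self.n_wires - 1) / 2.0
        out = []
        for k in range(self.n_wires):
            x = self.x_start + k * self.x_step
            dz = (k - k0 + self.z_offset_frac) * self.pitch
            out.append((x, self.y, dz))
        return out


@dataclass
class LowContrastSpec:
    """Module-2 layout: 25 mm cylinder plus four scored 6 mm rods."""

    cylinder_center: tuple[float, float] = (0.0, -50.0)
    cylinder_diameter: float = 25.0
    rod_diameter: float = 6.0
    rod_radius_mm: float = 50.0  # radial position of rod centers
    rod_angles_deg: tuple[float, ...] = (30.0, 70.0, 110.0, 150.0)
    background_angles_deg: tuple[float, ...] = (10.0, 50.0, 90.0, 130.0, 170.0)
    background_roi_center: tuple[float, float] = (0.0, -20.0)


@dataclass
class BarPatternSpec:
    """Module-4 bar patterns: squares of axial line pairs at fixed lp/cm."""

    frequencies_lp_cm: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 12.0)
    size_mm: float = 14.0
    radial_position_mm: float = 60.0
    start_angle_deg: float = 0.0

    def pattern_centers(self) -> list[tuple[float, float]]:
        n = len(self.frequencies_lp_cm)
        out = []
        for i in range(n):
            a = math.radians(self.start_angle_deg + 360.0 * i / n)
            out.append(
                (
                    self.radial_position_mm * math.cos(a),
                    self.radial_position_mm * math.sin(a),
                )
            )
        return out


def _default_plugs() -> list[PlugSpec]:
    # Accepted ranges per ACR CT Accreditation documentation (not from the
    # two-year QA dataset shipped with this package).
    return [
        PlugSpec("air", (0.0, 60.0), 25.0, -1000.0, (-1005.0, -970.0)),
        PlugSpec("bone", (60.0, 0.0), 25.0, 955.0, (850.0, 970.0)),
        PlugSpec("acrylic", (0.0, -60.0), 25.0, 120.0, (110.0, 135.0)),
        PlugSpec("polyethylene", (-60.0, 0.0), 25.0, -95.0, (-107.0, -84.0)),
        PlugSpec("water", (0.0, 0.0), 25.0, 0.0, (-7.0, 7.0)),
    ]


@dataclass
class PhantomGeometry:
    """Complete nominal description of the four-module phantom."""

    phantom_diameter: float = 200.0  # mm
    module_length: float = 40.0  # mm
    plugs: list[PlugSpec] = field(default_factory=_default_plugs)
    ramps: list[RampSpec] = field(
        default_factory=lambda: [RampSpec(y=40.0), RampSpec(y=-40.0)]
    )
    low_contrast: LowContrastSpec = field(default_factory=LowContrastSpec)
    bar_patterns: BarPatternSpec = field(default_factory=BarPatternSpec)
    # alignment BBs (slice selection) on module-1 and module-4 planes
    alignment_bb_radius_mm: float = 95.0
    alignment_bb_angles_deg: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    alignment_bb_modules: tuple[int, ...] = (1, 4)
    bb_diameter: float = 3.0
    # module-3 in-plane distance BBs
    distance_nominal: float = 100.0  # mm
    distance_bb_positions: tuple[tuple[float, float], ...] = ((-50.0, 0.0), (50.0, 0.0))
    # ROI areas per ACR guidance
    roi_area_hu_mm2: float = 200.0
    roi_area_low_contrast_mm2: float = 100.0
    roi_area_uniformity_mm2: float = 400.0
    # radial position of the four edge uniformity ROIs (12/3/6/9 o'clock)
    uniformity_edge_radius_mm: float = 80.0
    # absolute uniformity limits; both documented values are exposed
    uniformity_edge_limit_hu: float = 5.0
    uniformity_center_limit_hu: float = 7.0

    def __post_init__(self) -> None:
        if self.phantom_diameter <= 0 or self.module_length <= 0:
            raise ValueError("phantom dimensions must be positive")
        names = [p.name for p in self.plugs]
        if len(set(names)) != len(names):
            raise ValueError("plug names must be unique")
        for a in (
            self.roi_area_hu_mm2,
            self.roi_area_low_contrast_mm2,
            self.roi_area_uniformity_mm2,
        ):
            if a <= 0:
                raise ValueError("ROI areas must be positive")
        if self.distance_nominal != 100.0:
            # the phantom's BBs are machined 100.0 mm apart; allow override
            # but only deliberately via config, never silently
            pass

    # -- derived layout ----------------------------------------------------

    @property
    def radius(self) -> float:
        return self.phantom_diameter / 2.0

    @property
    def n_modules(self) -> int:
        return 4

    def module_z_centers(self) -> tuple[float, ...]:
        """z of each module center plane, relative to module 1 (mm)."""
        return tuple(i * self.module_length for i in range(self.n_modules))

    @property
    def length(self) -> float:
        return self.n_modules * self.module_length

    def plug(self, name: str) -> PlugSpec:
        for p in self.plugs:
            if p.name == name:
                return p
        raise KeyError(name)

    def uniformity_roi_centers(self) -> dict[str, tuple[float, float]]:
        r = self.uniformity_edge_radius_mm
        return {
            "center": (0.0, 0.0),
            "12": (0.0, r),
            "3": (r, 0.0),
            "6": (0.0, -r),
            "9": (-r, 0.0),
        }

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomGeometry":
        d = dict(d)
        d["plugs"] = [
            PlugSpec(
                name=p["name"],
                center=tuple(p["center"]),
                diameter=p["diameter"],
                nominal_hu=p["nominal_hu"],
                accepted_range=tuple(p["accepted_range"]),
            )
            for p in d.get("plugs", [])
        ] or _default_plugs()
        d["ramps"] = [RampSpec(**r) for r in d.get("ramps", [])] or [
            RampSpec(y=40.0),
            RampSpec(y=-40.0),
        ]
        if "low_contrast" in d:
            lc = dict(d["low_contrast"])
            for k in (
                "cylinder_center",
                "rod_angles_deg",
                "background_angles_deg",
                "background_roi_center",
            ):
                if k in lc:
                    lc[k] = tuple(lc[k])
            d["low_contrast"] = LowContrastSpec(**lc)
        if "bar_patterns" in d:
            bp = dict(d["bar_patterns"])
            if "frequencies_lp_cm" in bp:
                bp["frequencies_lp_cm"] = tuple(bp["frequencies_lp_cm"])
            d["bar_patterns"] = BarPatternSpec(**bp)
        for k in ("alignment_bb_angles_deg", "alignment_bb_modules"):
            if k in d:
                d[k] = tuple(d[k])
        if "distance_bb_positions" in d:
            d["distance_bb_positions"] = tuple(
                tuple(p) for p in d["distance_bb_positions"]
            )
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples/np scalars so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def default_geometry() -> PhantomGeometry:
    """The nominal ACR-464 description with every value overridable."""
    return PhantomGeometry()


# ---------------------------------------------------------------------------
# ROI templates
# ---------------------------------------------------------------------------


@dataclass
class CircularRoi:
    label: str
    center: tuple[float, float]  # mm relative to phantom axis
    radius: float  # mm


@dataclass
class RoiTemplate:
    module_id: int
    rois: list[CircularRoi]
    slice_rule: str  # identifier of the slice-selection rule

    def rotated(self, angle_deg: float) -> "RoiTemplate":
        """Template with every ROI center rotated about the phantom axis."""
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)
        rois = [
            CircularRoi(
                r.label,
                (c * r.center[0] - s * r.center[1], s * r.center[0] + c * r.center[1]),
                r.radius,
            )
            for r in self.rois
        ]
        return RoiTemplate(self.module_id, rois, self.slice_rule)


def _area_radius(area_mm2: float) -> float:
    return math.sqrt(area_mm2 / math.pi)


def roi_template(
    module_id: int,
    geometry: PhantomGeometry | None = None,
    pixel_spacing: float = 1.0,
) -> RoiTemplate:
    """ROI layout for one module, in mm relative to the phantom axis.

    ``pixel_spacing`` is accepted for validation of the rasterized area
    (the returned template itself is resolution independent).
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    g = geometry or default_geometry()
    if module_id == 1:
        r = _area_radius(g.roi_area_hu_mm2)
        rois = [CircularRoi(p.name, p.center, r) for p in g.plugs]
        rule = "alignment-bbs-visible"
    elif module_id == 2:
        r = _area_radius(g.roi_area_low_contrast_mm2)
        lc = g.low_contrast
        rois = [
            CircularRoi("cylinder", lc.cylinder_center, r),
            CircularRoi("background", lc.background_roi_center, r),
        ]
        rod_r = min(lc.rod_diameter / 2.0 - 1.0, 2.0)
        for a in lc.rod_angles_deg:
            ar = math.radians(a)
            rois.append(
                CircularRoi(
                    f"rod@{a:g}",
                    (lc.rod_radius_mm * math.cos(ar), lc.rod_radius_mm * math.sin(ar)),
                    max(rod_r, 1.0),
                )
            )
        for a in lc.background_angles_deg:
            ar = math.radians(a)
            rois.append(
                CircularRoi(
                    f"rodbg@{a:g}",
                    (lc.rod_radius_mm * math.cos(ar), lc.rod_radius_mm * math.sin(ar)),
                    max(rod_r, 1.0),
                )
            )
        rule = "module-midplane"
    elif module_id == 3:
        r = _area_radius(g.roi_area_uniformity_mm2)
        rois = [
            CircularRoi(label, c, r) for label, c in g.uniformity_roi_centers().items()
        ]
        rule = "distance-bbs-visible"
    elif module_id == 4:
        half = g.bar_patterns.size_mm / 2.0
        r = half * 0.7  # ROI inside the pattern square
        rois = [
            CircularRoi(f"{f:g}lp", c, r)
            for f, c in zip(g.bar_patterns.frequencies_lp_cm, g.bar_patterns.pattern_centers())
        ]
        rule = "alignment-bbs-visible"
    else:
        raise ValueError(f"unknown module_id {module_id!r}; expected 1-4")
    for roi in rois:
        d = math.hypot(*roi.center) + roi.radius
        if d > g.radius:
            raise ValueError(
                f"ROI {roi.label!r} extends outside the phantom cross-section"
            )
    return RoiTemplate(module_id, rois, rule)


def rasterize_roi(
    roi: CircularRoi,
    pixel_spacing: float | tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ROI circle.

    ``origin`` is the (x, y) mm position of pixel (row 0, col 0); if
    ``shape`` is None a minimal bounding grid around the ROI is used
    (useful for area-convergence checks).
    """
    if np.isscalar(pixel_spacing):
        sr = sc = float(pixel_spacing)
    else:
        sr, sc = map(float, pixel_spacing)
    cx, cy = roi.center
    if shape is None:
        n = int(math.ceil(2 * roi.radius / min(sr, sc))) + 4
        shape = (n, n)
        origin = (cx - (n - 1) / 2.0 * sc, cy - (n - 1) / 2.0 * sr)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    x = origin[0] + cols * sc
    y = origin[1] + rows * sr
    return (x - cx) ** 2 + (y - cy) ** 2 <= roi.radius**2
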