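"""The eight image-quality measurements of the phantom QA panel.

All measurements are ROI statistics on the analysis slice of the
relevant module, with the ACR ROI sizes (~200 mm^2 for HU plugs,
~100 mm^2 for low contrast, ~400 mm^2 for uniformity):

* HU accuracy: mean HU per density plug vs its accepted range.
* CNR (polyethylene and acrylic vs the water plug in the same slice):
  ``CNR = |ROI_mean - BG_mean| / BG_sd``.
* Noise per plug: ``100 * ROI_sd / (ROI_mean + 1000)`` — the +1000 HU
  rescale keeps the denominator away from zero for water-like plugs and
  deliberately makes the metric sensitive to HU calibration shifts.
* Uniformity: max over the four edge ROIs of |edge mean - center mean|,
  with the center mean separately checked against an absolute limit.
* In-plane distance: Euclidean distance between the two sub-pixel
  distance-BB centroids (nominal 100.0 mm).
* Slice thickness: wire-ramp count method — wires whose contrast
  exceeds half the maximum are "visible"; thickness = ramp z-pitch
  times the mean visible count over the two ramps.
* Low contrast: CNR of the 25 mm cylinder vs adjacent background, and
  visibility of the four 6 mm rods (contrast > k x background SD,
  default k = 1, mirroring the CNR >= 1 acceptance idea).  On
  CBCT-level noise a count of zero is a legitimate result.
* High contrast: a bar pattern resolves if its modulation statistic
  exceeds a fraction (default 0.4) of the coarsest pattern's; the scan
  runs coarse to fine and stops at the first failure, so the score is
  monotone by construction.

Visibility criteria that a human would judge by eye under suggested
window/levels are numeric surrogates here, with the constants exposed
in :class:`MetricSettings`.  ROIs that collide with a supplied artifact
mask (e.g. the CBCT crescent) are re-seated by searching angular
offsets about the phantom axis, automating artifact avoidance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .dicom_io import PhantomImageSeries
from .localization import LocalizationResult, LocalizationSettings, localize
from .phantom_model import (
    CircularRoi,
    PhantomGeometry,
    RoiTemplate,
    default_geometry,
    roi_template,
)

__all__ = [
    "MetricSettings",
    "RoiStats",
    "UniformityResult",
    "LowContrastResult",
    "HighContrastResult",
    "QASession",
    "extract_roi_stats",
    "measure_hu_accuracy",
    "compute_cnr",
    "compute_noise",
    "measure_uniformity",
    "measure_inplane_distance",
    "measure_slice_thickness",
    "score_low_contrast",
    "score_high_contrast",
    "run_session",
]


@dataclass
class MetricSettings:
    """Numeric surrogates for the visibility/acceptance judgements."""

    rod_visibility_k: float = 1.0  # rod contrast must exceed k x bg SD
    bar_resolvable_fraction: float = 0.4  # of the coarsest pattern's statistic
    bar_noise_correct: bool = True  # subtract the noise floor in quadrature
    bar_noise_floor_factor: float = 1.5  # coarsest must exceed this x bg SD
    wire_visible_fraction: float = 0.5  # of the max wire contrast
    wire_min_contrast_hu: float = 100.0
    reseat_max_masked_fraction: float = 0.3
    reseat_angles_deg: tuple[float, ...] = (0, 5, -5, 10, -10, 15, -15, 20, -20, 25, -25, 30, -30)


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------


@dataclass
class RoiStats:
    label: str
    mean: float
    sd: float
    n_pixels: int
    area_mm2: float
    center: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("ROI contains no pixels")


def _roi_mask(
    series: PhantomImageSeries, roi: CircularRoi
) -> np.ndarray:
    x, y = series.pixel_coords_mm()
    return (x - roi.center[0]) ** 2 + (y - roi.center[1]) ** 2 <= roi.radius**2


def extract_roi_stats(
    series: PhantomImageSeries,
    slice_index: int,
    roi: CircularRoi,
    artifact_mask: np.ndarray | None = None,
    reseat_about: tuple[float, float] | None = None,
    settings: MetricSettings | None = None,
) -> RoiStats:
    """Mean/SD over pixels whose centers fall inside the ROI circle.

    Pixels under ``artifact_mask`` (2D boolean, same in-plane shape) are
    excluded.  If more than ``reseat_max_masked_fraction`` of the ROI is
    masked the statistic is flagged and, when ``reseat_about`` (the
    phantom axis) is given, the ROI is re-seated at the angular offset
    about the axis that minimizes the masked fraction.
    """
    st = settings or MetricSettings()
    img = series.hu[slice_index]
    if artifact_mask is not None and artifact_mask.ndim == 3:
        artifact_mask = artifact_mask[slice_index]

    def stats_at(r: CircularRoi) -> tuple[np.ndarray, float]:
        mask = _roi_mask(series, r)
        if not mask.any():
            raise ValueError(f"ROI {r.label!r} lies fully outside the image")
        total = int(mask.sum())
        if artifact_mask is not None:
            mask = mask & ~artifact_mask
        frac = 1.0 - mask.sum() / total
        return mask, frac

    mask, masked_frac = stats_at(roi)
    flags: list[str] = []
    placed = roi
    if masked_frac > st.reseat_max_masked_fraction:
        flags.append("artifact_overlap")
        if reseat_about is not None:
            best = (masked_frac, roi, mask)
            rel = (roi.center[0] - reseat_about[0], roi.center[1] - reseat_about[1])
            for ang in st.reseat_angles_deg[1:]:
                a = math.radians(ang)
                c, s = math.cos(a), math.sin(a)
                cand = CircularRoi(
                    roi.label,
                    (
                        reseat_about[0] + c * rel[0] - s * rel[1],
                        reseat_about[1] + s * rel[0] + c * rel[1],
                    ),
                    roi.radius,
                )
                try:
                    m, f = stats_at(cand)
                except ValueError:
                    continue
                if f < best[0]:
                    best = (f, cand, m)
                if f == 0.0:
                    break
            masked_frac, placed, mask = best
            if placed is not roi:
                flags.append("reseated")
            if masked_frac > st.reseat_max_masked_fraction:
                flags.append("reseat_failed")
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} fully masked by artifacts")
    values = img[mask]
    n = int(mask.sum())
    return RoiStats(
        label=roi.label,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else 0.0,
        n_pixels=n,
        area_mm2=n * series.pixel_area_mm2(),
        center=placed.center,
        flags=flags,
    )


def _placed_template(
    template: RoiTemplate, center: tuple[float, float], roll_deg: float
) -> RoiTemplate:
    t = template.rotated(roll_deg)
    rois = [
        CircularRoi(r.label, (r.center[0] + center[0], r.center[1] + center[1]), r.radius)
        for r in t.rois
    ]
    return RoiTemplate(t.module_id, rois, t.slice_rule)


# ---------------------------------------------------------------------------
# the individual measurements
# ---------------------------------------------------------------------------


def measure_hu_accuracy(
    series: PhantomImageSeries,
    slice_index: int,
    template: RoiTemplate,
    geometry: PhantomGeometry,
    artifact_mask: np.ndarray | None = None,
    reseat_about: tuple[float, float] | None = None,
    settings: MetricSettings | None = None,
) -> dict[str, dict]:
    """Per-plug ROI stats plus the accepted-range check."""
    out = {}
    for roi in template.rois:
        plug = geometry.plug(roi.label)
        stats = extract_roi_stats(
            series, slice_index, roi, artifact_mask, reseat_about, settings
        )
        lo, hi = plug.accepted_range
        out[roi.label] = {
            "stats": stats,
            "accepted_range": (lo, hi),
            "in_range": bool(lo <= stats.mean <= hi),
        }
    return out


def compute_cnr(plug_stats: RoiStats, background_stats: RoiStats) -> float:
    """Contrast-to-noise ratio: |ROI mean - BG mean| / BG SD."""
    if background_stats.sd <= 0:
        raise ValueError(
            "CNR undefined: background SD is zero (noiseless input)"
        )
    return abs(plug_stats.mean - background_stats.mean) / background_stats.sd


def compute_noise(plug_stats: RoiStats) -> float:
    """Noise (%): 100 * SD / (mean + 1000 HU).

    The +1000 HU rescale maps the denominator onto an attenuation-like
    scale (water ~1000) so near-zero-HU plugs do not blow the ratio up.
    """
    denom = plug_stats.mean + 1000.0
    if denom <= 0:
        raise ValueError("noise undefined: ROI mean + 1000 HU is not positive")
    return 100.0 * plug_stats.sd / denom


@dataclass
class UniformityResult:
    center: RoiStats
    edges: dict[str, RoiStats]
    value: float  # max |edge mean - center mean|
    center_within_limit: bool
    edge_within_limit: bool
    flags: list[str] = field(default_factory=list)


def measure_uniformity(
    series: PhantomImageSeries,
    slice_index: int,
    template: RoiTemplate,
    geometry: PhantomGeometry,
    artifact_mask: np.ndarray | None = None,
    reseat_about: tuple[float, float] | None = None,
    settings: MetricSettings | None = None,
) -> UniformityResult:
    stats = {
        roi.label: extract_roi_stats(
            series, slice_index, roi, artifact_mask, reseat_about, settings
        )
        for roi in template.rois
    }
    center = stats.pop("center")
    diffs = {k: abs(s.mean - center.mean) for k, s in stats.items()}
    value = max(diffs.values())
    flags = [f for s in stats.values() for f in s.flags] + list(center.flags)
    return UniformityResult(
        center=center,
        edges=stats,
        value=value,
        center_within_limit=abs(center.mean) <= geometry.uniformity_center_limit_hu,
        edge_within_limit=value <= geometry.uniformity_edge_limit_hu,
        flags=flags,
    )


def measure_inplane_distance(localization: LocalizationResult) -> float:
    """Distance (mm) between the two in-plane distance-BB centroids."""
    matched = localization.matched
    bbs = [d for d in matched.values() if d.kind == "distance"]
    if len(bbs) != 2:
        raise ValueError(
            "in-plane distance not evaluable: "
            f"{len(bbs)} of 2 distance BBs detected"
        )
    (x1, y1, _), (x2, y2, _) = bbs[0].centroid, bbs[1].centroid
    return math.hypot(x2 - x1, y2 - y1)


def measure_slice_thickness(
    series: PhantomImageSeries,
    slice_index: int,
    geometry: PhantomGeometry,
    center: tuple[float, float],
    roll_deg: float = 0.0,
    settings: MetricSettings | None = None,
) -> tuple[float, list[int]]:
    """Wire-ramp count method; returns (thickness mm, counts per ramp).

    Samples the image at each candidate wire site of both ramps; sites
    whose contrast over the ramp-line background exceeds half of the
    maximum contrast count as visible wires.  Thickness is the ramp
    z-pitch times the mean visible count.
    """
    st = settings or MetricSettings()
    img = series.hu[slice_index]
    sp_r, sp_c = series.pixel_spacing
    a = math.radians(roll_deg)
    ca, sa = math.cos(a), math.sin(a)
    counts = []
    for ramp in geometry.ramps:
        samples = []
        for (x, y, _dz) in ramp.wire_positions():
            ax = center[0] + ca * x - sa * y
            ay = center[1] + sa * x + ca * y
            col = (ax - series.origin[0]) / sp_c
            row = (ay - series.origin[1]) / sp_r
            val = ndimage.map_coordinates(
                img, [[row], [col]], order=1, mode="nearest"
            )[0]
            samples.append(float(val))
        samples = np.array(samples)
        background = float(np.median(samples))
        contrast = samples - background
        max_c = float(contrast.max())
        if max_c < st.wire_min_contrast_hu:
            raise ValueError(
                "slice thickness not evaluable: no wires above background "
                f"(max contrast {max_c:.0f} HU)"
            )
        counts.append(int((contrast > st.wire_visible_fraction * max_c).sum()))
    pitch = geometry.ramps[0].pitch
    return pitch * float(np.mean(counts)), counts


@dataclass
class LowContrastResult:
    cnr: float | None
    rods_visible: int
    rod_contrasts: dict[str, float]
    background_sd: float
    flags: list[str] = field(default_factory=list)


def score_low_contrast(
    series: PhantomImageSeries,
    slice_index: int,
    template: RoiTemplate,
    settings: MetricSettings | None = None,
    artifact_mask: np.ndarray | None = None,
) -> LowContrastResult:
    st = settings or MetricSettings()
    by_label = {roi.label: roi for roi in template.rois}
    cyl = extract_roi_stats(series, slice_index, by_label["cylinder"], artifact_mask)
    bg = extract_roi_stats(series, slice_index, by_label["background"], artifact_mask)
    try:
        cnr = compute_cnr(cyl, bg)
    except ValueError:
        cnr = None
    # pooled local background for the rod test: all rodbg ROI pixels
    img = series.hu[slice_index]
    bg_pixels = []
    for label, roi in by_label.items():
        if label.startswith("rodbg@"):
            bg_pixels.append(img[_roi_mask(series, roi)])
    bg_pixels = np.concatenate(bg_pixels)
    bg_mean = float(bg_pixels.mean())
    bg_sd = float(bg_pixels.std(ddof=1))
    rod_contrasts = {}
    visible = 0
    for label, roi in by_label.items():
        if not label.startswith("rod@"):
            continue
        s = extract_roi_stats(series, slice_index, roi, artifact_mask)
        contrast = s.mean - bg_mean
        rod_contrasts[label] = contrast
        if bg_sd > 0 and contrast > st.rod_visibility_k * bg_sd:
            visible += 1
        elif bg_sd == 0 and contrast > 0:
            visible += 1
    flags = cyl.flags + bg.flags
    return LowContrastResult(
        cnr=cnr,
        rods_visible=visible,
        rod_contrasts=rod_contrasts,
        background_sd=bg_sd,
        flags=flags,
    )


@dataclass
class HighContrastResult:
    lp_cm: float | None  # best resolvable pattern; None if not evaluable
    statistics: dict[float, float]  # per-frequency modulation statistic
    noise_sd: float
    flags: list[str] = field(default_factory=list)


def score_high_contrast(
    series: PhantomImageSeries,
    slice_index: int,
    template: RoiTemplate,
    geometry: PhantomGeometry,
    center: tuple[float, float] | None = None,
    settings: MetricSettings | None = None,
) -> HighContrastResult:
    """Best resolvable bar pattern (lp/cm), scanned coarse to fine.

    The modulation statistic is the SD of HU inside the pattern ROI,
    by default corrected for the noise floor (SD of a same-size ROI at
    the uniform module center, subtracted in quadrature) so that under
    heavy noise an unresolved pattern does not ride the noise SD.
    """
    st = settings or MetricSettings()
    freqs = sorted(geometry.bar_patterns.frequencies_lp_cm)
    by_label = {roi.label: roi for roi in template.rois}
    radius = template.rois[0].radius
    noise_roi = CircularRoi("noise", center or (0.0, 0.0), radius)
    noise_sd = extract_roi_stats(series, slice_index, noise_roi).sd
    stats = {}
    for f in freqs:
        s = extract_roi_stats(series, slice_index, by_label[f"{f:g}lp"])
        sd = s.sd
        if st.bar_noise_correct:
            sd = math.sqrt(max(sd**2 - noise_sd**2, 0.0))
        stats[f] = sd
    coarsest = stats[freqs[0]]
    raw_coarsest = extract_roi_stats(series, slice_index, by_label[f"{freqs[0]:g}lp"]).sd
    if raw_coarsest < st.bar_noise_floor_factor * max(noise_sd, 1e-9) or coarsest <= 0:
        return HighContrastResult(
            lp_cm=None,
            statistics=stats,
            noise_sd=noise_sd,
            flags=["coarsest_pattern_below_noise_floor"],
        )
    best = None
    for f in freqs:
        if stats[f] > st.bar_resolvable_fraction * coarsest:
            best = f
        else:
            break
    return HighContrastResult(lp_cm=best, statistics=stats, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# the full session
# ---------------------------------------------------------------------------


@dataclass
class QASession:
    """All metric results for one series / protocol / machine."""

    machine: str
    modality: str
    protocol: str
    date: str
    results: dict[str, float] = field(default_factory=dict)
    not_evaluable: dict[str, str] = field(default_factory=dict)
    flags: dict[str, object] = field(default_factory=dict)
    hu_details: dict[str, dict] = field(default_factory=dict)
    uniformity: UniformityResult | None = None
    low_contrast: LowContrastResult | None = None
    high_contrast: HighContrastResult | None = None
    localization: LocalizationResult | None = None

    def metric_values(self) -> dict[str, float]:
        return dict(self.results)

    def to_json(self, path=None) -> str:
        payload = {
            "machine": self.machine,
            "modality": self.modality,
            "protocol": self.protocol,
            "date": self.date,
            "results": self.results,
            "not_evaluable": self.not_evaluable,
            "flags": {k: v for k, v in self.flags.items()},
        }
        if self.hu_details:
            payload["hu"] = {
                name: {
                    "mean": d["stats"].mean,
                    "sd": d["stats"].sd,
                    "accepted_range": list(d["accepted_range"]),
                    "in_range": d["in_range"],
                }
                for name, d in self.hu_details.items()
            }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def history_rows(self) -> list[dict]:
        """One row per metric for the longitudinal CSV log."""
        return [
            {
                "machine": self.machine,
                "modality": self.modality,
                "protocol": self.protocol,
                "date": self.date,
                "metric": metric,
                "value": value,
            }
            for metric, value in self.results.items()
        ]


_METRIC_GROUPS = (
    "hu",
    "uniformity",
    "cnr",
    "noise",
    "distance",
    "slice_thickness",
    "low_contrast",
    "high_contrast",
)


def run_session(
    series: PhantomImageSeries,
    geometry: PhantomGeometry | None = None,
    settings: MetricSettings | None = None,
    loc_settings: LocalizationSettings | None = None,
    artifact_mask: np.ndarray | None = None,
    nominal_slice_thickness: float | None = None,
) -> QASession:
    """Localize the phantom and compute the full measurement panel.

    A failing metric never aborts the session; it is recorded under
    ``not_evaluable`` with the reason.  A localization failure yields a
    session in which every metric is not evaluable.
    """
    g = geometry or default_geometry()
    st = settings or MetricSettings()
    session = QASession(
        machine=series.machine,
        modality=series.modality,
        protocol=series.protocol,
        date=series.acquisition_date,
    )
    try:
        loc = localize(series, g, loc_settings)
    except ValueError as exc:
        if "incomplete phantom coverage" in str(exc):
            loc = _partial_localize(series, g, loc_settings, session)
        else:
            for group in _METRIC_GROUPS:
                session.not_evaluable[group] = f"localization failed: {exc}"
            return session
    session.localization = loc
    session.flags.update(loc.flags)
    center = loc.center_mean
    roll = loc.roll_deg

    def template_for(module: int) -> RoiTemplate:
        return _placed_template(
            roi_template(module, g, series.pixel_spacing[0]), center, roll
        )

    # module 1: HU, CNR, noise, slice thickness ---------------------------
    if 1 in loc.module_slices:
        s1 = loc.module_slices[1]
        try:
            hu = measure_hu_accuracy(
                series, s1, template_for(1), g, artifact_mask, center, st
            )
            session.hu_details = hu
            for name, d in hu.items():
                session.results[f"hu_{name}"] = d["stats"].mean
            water = hu["water"]["stats"]
            for plug in ("polyethylene", "acrylic"):
                try:
                    session.results[f"cnr_{plug}"] = compute_cnr(
                        hu[plug]["stats"], water
                    )
                except ValueError as exc:
                    session.not_evaluable[f"cnr_{plug}"] = str(exc)
                try:
                    session.results[f"noise_{plug}"] = compute_noise(hu[plug]["stats"])
                except ValueError as exc:
                    session.not_evaluable[f"noise_{plug}"] = str(exc)
        except ValueError as exc:
            session.not_evaluable["hu"] = str(exc)
            session.not_evaluable["cnr"] = "HU ROIs not evaluable"
            session.not_evaluable["noise"] = "HU ROIs not evaluable"
        try:
            thickness, counts = measure_slice_thickness(series, s1, g, center, roll, st)
            session.results["slice_thickness_mm"] = thickness
            session.flags["wire_counts"] = counts
            if nominal_slice_thickness or series.slice_thickness:
                nominal = nominal_slice_thickness or series.slice_thickness
                session.flags["slice_thickness_within_0.5mm"] = (
                    abs(thickness - nominal) <= 0.5
                )
        except ValueError as exc:
            session.not_evaluable["slice_thickness"] = str(exc)
    else:
        session.not_evaluable["hu"] = "module 1 not covered"
        session.not_evaluable["slice_thickness"] = "module 1 not covered"

    # module 2: low contrast ----------------------------------------------
    if 2 in loc.module_slices:
        try:
            lc = score_low_contrast(
                series, loc.module_slices[2], template_for(2), st, artifact_mask
            )
            session.low_contrast = lc
            session.results["low_contrast_rods_visible"] = float(lc.rods_visible)
            if lc.cnr is not None:
                session.results["low_contrast_cnr"] = lc.cnr
            else:
                session.not_evaluable["low_contrast_cnr"] = "background SD is zero"
        except ValueError as exc:
            session.not_evaluable["low_contrast"] = str(exc)
    else:
        session.not_evaluable["low_contrast"] = "module 2 not covered"

    # module 3: uniformity + distance --------------------------------------
    if 3 in loc.module_slices:
        try:
            uni = measure_uniformity(
                series, loc.module_slices[3], template_for(3), g, artifact_mask,
                center, st,
            )
            session.uniformity = uni
            session.results["uniformity_hu"] = uni.value
            session.results["uniformity_center_hu"] = uni.center.mean
        except ValueError as exc:
            session.not_evaluable["uniformity"] = str(exc)
    else:
        session.not_evaluable["uniformity"] = "module 3 not covered"
    try:
        session.results["distance_mm"] = measure_inplane_distance(loc)
    except ValueError as exc:
        session.not_evaluable["distance"] = str(exc)

    # module 4: high contrast ----------------------------------------------
    if 4 in loc.module_slices:
        try:
            hc = score_high_contrast(
                series, loc.module_slices[4], template_for(4), g, center, st
            )
            session.high_contrast = hc
            if hc.lp_cm is not None:
                session.results["high_contrast_lp_cm"] = hc.lp_cm
            else:
                session.not_evaluable["high_contrast"] = (
                    "coarsest pattern below the noise floor"
                )
        except ValueError as exc:
            session.not_evaluable["high_contrast"] = str(exc)
    else:
        session.not_evaluable["high_contrast"] = "module 4 not covered"
    return session


def _partial_localize(
    series: PhantomImageSeries,
    g: PhantomGeometry,
    loc_settings: LocalizationSettings | None,
    session: QASession,
) -> LocalizationResult:
    """Best-effort localization of a truncated volume (coverage flagged).

    Module planes are taken at nominal offsets from the leading phantom
    face; modules whose plane is outside the imaged extent are dropped.
    """
    from .localization import detect_bbs, find_phantom_center

    st = loc_settings or LocalizationSettings()
    per_slice, center, z_extent = find_phantom_center(series, st)
    session.flags["incomplete_phantom_coverage"] = True
    detections = detect_bbs(series, st)
    module_slices = {}
    for m in range(1, g.n_modules + 1):
        plane = z_extent[0] + (m - 0.5) * g.module_length
        if plane <= z_extent[1] + series.slice_thickness / 2.0:
            module_slices[m] = series.slice_index_at(plane)
    return LocalizationResult(
        center_mean=center,
        per_slice_centers=per_slice,
        roll_deg=0.0,
        detections=detections,
        expected_bbs=[],
        module_slices=module_slices,
        z_extent=z_extent,
        flags={"incomplete_phantom_coverage": True},
    )
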