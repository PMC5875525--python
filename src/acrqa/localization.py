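"""Locate the phantom and its BBs; pick the analysis slice per module.

This automates the setup steps that commercial phantom-analysis
software is known to fail at on noisy CBCT data: the phantom body is
segmented at an absolute -300 HU threshold (safely between air at
~-1000 and any phantom material), BBs are connected components above
+800 HU with a small-object volume cap (which excludes the bone plug),
and the analysis slices are chosen from BB visibility with a fallback
to nominal 40 mm module offsets when BBs cannot be matched.  Roll is
estimated from the alignment BBs so ROI templates can be counter-
rotated instead of requiring a physical re-setup; rolls beyond a guard
angle are flagged as probable setup errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .dicom_io import PhantomImageSeries
from .phantom_model import PhantomGeometry, default_geometry

__all__ = [
    "LocalizationSettings",
    "BBDetection",
    "LocalizationResult",
    "find_phantom_center",
    "detect_bbs",
    "estimate_roll",
    "assign_module_slices",
    "localize",
]


@dataclass
class LocalizationSettings:
    """Thresholds for the automated setup steps (all HU-absolute)."""

    body_threshold_hu: float = -300.0
    bb_threshold_hu: float = 800.0
    bb_max_volume_mm3: float = 500.0
    bb_match_gate_mm: float = 5.0
    max_roll_deg: float = 5.0
    min_body_fraction: float = 0.05  # of the field of view


@dataclass
class BBDetection:
    centroid: tuple[float, float, float]  # mm
    volume_mm3: float
    matched_label: str | None = None
    kind: str | None = None  # alignment | distance once matched
    module: int | None = None


@dataclass
class LocalizationResult:
    center_mean: tuple[float, float]  # mm
    per_slice_centers: list[tuple[float, float] | None]
    roll_deg: float
    detections: list[BBDetection]
    expected_bbs: list[dict]  # label -> expected absolute position
    module_slices: dict[int, int]
    z_extent: tuple[float, float]
    flags: dict[str, bool | str] = field(default_factory=dict)

    @property
    def matched(self) -> dict[str, BBDetection]:
        return {d.matched_label: d for d in self.detections if d.matched_label}

    def unmatched_expected(self) -> list[str]:
        found = set(self.matched)
        return [bb["label"] for bb in self.expected_bbs if bb["label"] not in found]

    def to_json(self, path=None) -> str:
        payload = {
            "center_mean": list(self.center_mean),
            "roll_deg": self.roll_deg,
            "module_slices": {str(k): v for k, v in self.module_slices.items()},
            "z_extent": list(self.z_extent),
            "flags": dict(self.flags),
            "detections": [asdict(d) for d in self.detections],
            "unmatched_expected": self.unmatched_expected(),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------


def find_phantom_center(
    series: PhantomImageSeries, settings: LocalizationSettings | None = None
) -> tuple[list[tuple[float, float] | None], tuple[float, float], tuple[float, float]]:
    """Per-slice phantom centroid, mean center, and z extent.

    The centroid is taken over the hole-filled largest above-threshold
    connected region per slice (hole filling keeps the air plug from
    biasing the centroid).  Raises if no slice contains a region larger
    than ``min_body_fraction`` of the field of view.
    """
    st = settings or LocalizationSettings()
    x_mm, y_mm = series.pixel_coords_mm()
    n_px = series.hu.shape[1] * series.hu.shape[2]
    centers: list[tuple[float, float] | None] = []
    body_z = []
    for i in range(series.n_slices):
        mask = series.hu[i] > st.body_threshold_hu
        if not mask.any():
            centers.append(None)
            continue
        labels, n = ndimage.label(mask)
        if n == 0:
            centers.append(None)
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1
        if sizes[biggest - 1] < st.min_body_fraction * n_px:
            centers.append(None)
            continue
        region = ndimage.binary_fill_holes(labels == biggest)
        cx = float(x_mm[region].mean())
        cy = float(y_mm[region].mean())
        centers.append((cx, cy))
        body_z.append(series.z_positions[i])
    if not body_z:
        raise ValueError("phantom not found: no region above the body threshold")
    valid = np.array([c for c in centers if c is not None])
    mean_center = (float(valid[:, 0].mean()), float(valid[:, 1].mean()))
    z_extent = (float(min(body_z)), float(max(body_z)))
    return centers, mean_center, z_extent


def _expected_bbs(
    geometry: PhantomGeometry,
    center: tuple[float, float],
    z_extent: tuple[float, float],
    roll_deg: float = 0.0,
) -> list[dict]:
    """Expected absolute BB positions given the detected phantom pose.

    The longitudinal module planes are inferred from the phantom's z
    midpoint (module 1 sits half a module in from the leading face).
    """
    mid = 0.5 * (z_extent[0] + z_extent[1])
    ml = geometry.module_length
    plane = {m: mid + (m - 2.5) * ml for m in range(1, geometry.n_modules + 1)}
    a0 = math.radians(roll_deg)
    out = []
    for m in geometry.alignment_bb_modules:
        for a in geometry.alignment_bb_angles_deg:
            ar = math.radians(a) + a0
            out.append(
                {
                    "label": f"align_m{m}_{a:g}",
                    "kind": "alignment",
                    "module": m,
                    "xyz": (
                        center[0] + geometry.alignment_bb_radius_mm * math.cos(ar),
                        center[1] + geometry.alignment_bb_radius_mm * math.sin(ar),
                        plane[m],
                    ),
                    "nominal_angle_deg": a,
                }
            )
    for i, p in enumerate(geometry.distance_bb_positions):
        c, s = math.cos(a0), math.sin(a0)
        out.append(
            {
                "label": f"distance_{i}",
                "kind": "distance",
                "module": 3,
                "xyz": (
                    center[0] + c * p[0] - s * p[1],
                    center[1] + s * p[0] + c * p[1],
                    plane[3],
                ),
            }
        )
    return out


def detect_bbs(
    series: PhantomImageSeries, settings: LocalizationSettings | None = None
) -> list[BBDetection]:
    """Small bright connected components, as intensity-weighted centroids.

    Components above the BB threshold whose volume exceeds the
    small-object cap (e.g. the bone plug) are discarded.
    """
    st = settings or LocalizationSettings()
    mask = series.hu > st.bb_threshold_hu
    if not mask.any():
        return []
    voxel_mm3 = series.pixel_area_mm2() * series.slice_thickness
    labels, n = ndimage.label(mask)
    x_mm, y_mm = series.pixel_coords_mm()
    detections = []
    for idx in range(1, n + 1):
        region = labels == idx
        vol = float(region.sum()) * voxel_mm3
        if vol > st.bb_max_volume_mm3:
            continue
        w = series.hu[region] - st.bb_threshold_hu
        sl, rr, cc = np.nonzero(region)
        wsum = w.sum()
        cx = float((x_mm[rr, cc] * w).sum() / wsum)
        cy = float((y_mm[rr, cc] * w).sum() / wsum)
        cz = float((series.z_positions[sl] * w).sum() / wsum)
        detections.append(BBDetection(centroid=(cx, cy, cz), volume_mm3=vol))
    return detections


def estimate_roll(
    detections: list[BBDetection],
    geometry: PhantomGeometry,
    center: tuple[float, float],
    z_extent: tuple[float, float],
    slice_thickness: float,
    settings: LocalizationSettings | None = None,
) -> tuple[float, dict]:
    """In-plane roll from the alignment BBs (degrees, (-180, 180]).

    Detections at the alignment-BB radius near a module-1/4 plane are
    assigned to the nominal BB of closest polar angle; the roll is the
    mean wrapped angular deviation.  With fewer than two usable BBs the
    roll is reported as 0 and flagged.
    """
    st = settings or LocalizationSettings()
    flags: dict = {}
    mid = 0.5 * (z_extent[0] + z_extent[1])
    ml = geometry.module_length
    planes = [mid + (m - 2.5) * ml for m in geometry.alignment_bb_modules]
    deviations = []
    for det in detections:
        x, y, z = det.centroid
        if not any(abs(z - p) <= max(slice_thickness, ml / 4.0) for p in planes):
            continue
        r = math.hypot(x - center[0], y - center[1])
        if abs(r - geometry.alignment_bb_radius_mm) > st.bb_match_gate_mm:
            continue
        ang = math.degrees(math.atan2(y - center[1], x - center[0]))
        dev = [
            (ang - a + 180.0) % 360.0 - 180.0 for a in geometry.alignment_bb_angles_deg
        ]
        deviations.append(min(dev, key=abs))
    if len(deviations) < 2:
        flags["roll_assumed_zero"] = True
        return 0.0, flags
    roll = float(np.mean(deviations))
    roll = (roll + 180.0) % 360.0 - 180.0
    if abs(roll) > st.max_roll_deg:
        flags["roll_exceeds_guard"] = (
            f"estimated roll {roll:.1f} deg exceeds guard "
            f"{st.max_roll_deg:.1f} deg; check phantom setup"
        )
    return roll, flags


def _match(
    detections: list[BBDetection], expected: list[dict], gate_mm: float
) -> None:
    """Greedy nearest matching of detections to expected BBs (in place)."""
    taken = set()
    pairs = []
    for bb in expected:
        ex = np.array(bb["xyz"])
        for j, det in enumerate(detections):
            d = float(np.linalg.norm(ex - np.array(det.centroid)))
            if d <= gate_mm:
                pairs.append((d, bb, j))
    pairs.sort(key=lambda t: t[0])
    matched_labels = set()
    for d, bb, j in pairs:
        if j in taken or bb["label"] in matched_labels:
            continue
        taken.add(j)
        matched_labels.add(bb["label"])
        detections[j].matched_label = bb["label"]
        detections[j].kind = bb["kind"]
        detections[j].module = bb["module"]


def assign_module_slices(
    series: PhantomImageSeries,
    matched: dict[int, list[BBDetection]],
    z_extent: tuple[float, float],
    geometry: PhantomGeometry,
    flags: dict,
) -> dict[int, int]:
    """Analysis slice per module.

    Modules 1 and 4: the slice with the most visible alignment BBs;
    module 3: the slice holding both distance BBs; module 2: the slice
    nearest the module mid-plane.  When BBs are unmatched the slice at
    the nominal 40 mm offset from the phantom mid-plane is used and the
    fallback is flagged.
    """
    ml = geometry.module_length
    if z_extent[1] - z_extent[0] + series.slice_thickness < geometry.length - 2 * series.slice_thickness:
        raise ValueError(
            "incomplete phantom coverage: z extent "
            f"{z_extent[1] - z_extent[0]:.1f} mm is shorter than the "
            f"{geometry.length:.0f} mm four-module phantom"
        )
    mid = 0.5 * (z_extent[0] + z_extent[1])
    nominal = {m: mid + (m - 2.5) * ml for m in range(1, geometry.n_modules + 1)}
    slices: dict[int, int] = {}
    for m in (1, 4):
        dets = [d for d in matched.get(m, []) if d.kind == "alignment"]
        if dets:
            counts = np.zeros(series.n_slices, dtype=int)
            for d in dets:
                counts[series.slice_index_at(d.centroid[2])] += 1
            slices[m] = int(np.argmax(counts))
        else:
            slices[m] = series.slice_index_at(nominal[m])
            flags[f"module{m}_slice_fallback"] = True
    dist = [d for d in matched.get(3, []) if d.kind == "distance"]
    if len(dist) == 2:
        zs = [series.slice_index_at(d.centroid[2]) for d in dist]
        slices[3] = int(round(np.mean(zs)))
        if zs[0] != zs[1]:
            flags["distance_bbs_span_slices"] = True
    else:
        slices[3] = series.slice_index_at(nominal[3])
        flags["module3_slice_fallback"] = True
    slices[2] = series.slice_index_at(nominal[2])
    return slices


def localize(
    series: PhantomImageSeries,
    geometry: PhantomGeometry | None = None,
    settings: LocalizationSettings | None = None,
) -> LocalizationResult:
    """Full localization chain: center, BBs, roll, module slices."""
    g = geometry or default_geometry()
    st = settings or LocalizationSettings()
    per_slice, center, z_extent = find_phantom_center(series, st)
    detections = detect_bbs(series, st)
    roll, flags = estimate_roll(
        detections, g, center, z_extent, series.slice_thickness, st
    )
    expected = _expected_bbs(g, center, z_extent, roll)
    _match(detections, expected, st.bb_match_gate_mm)
    unmatched = [
        bb["label"] for bb in expected if bb["label"] not in {
            d.matched_label for d in detections if d.matched_label
        }
    ]
    if unmatched:
        flags["unmatched_bbs"] = ",".join(unmatched)
    by_module: dict[int, list[BBDetection]] = {}
    for d in detections:
        if d.module is not None:
            by_module.setdefault(d.module, []).append(d)
    module_slices = assign_module_slices(series, by_module, z_extent, g, flags)
    return LocalizationResult(
        center_mean=center,
        per_slice_centers=per_slice,
        roll_deg=roll,
        detections=detections,
        expected_bbs=expected,
        module_slices=module_slices,
        z_extent=z_extent,
        flags=flags,
    )
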