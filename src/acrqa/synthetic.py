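"""Synthetic DICOM-ready renderings of the ACR-464 phantom.

The renderer draws an ideal HU map of the four modules (plugs, wire
ramps, low-contrast rods, uniform section with distance BBs, bar
patterns, alignment BBs), blurs it with a Gaussian in-plane PSF, adds
artifact fields (parabolic cupping, optional crescent arc) and i.i.d.
Gaussian noise, and rounds to integral HU.  The pipeline order is
ideal -> PSF -> artifacts -> noise.  Everything is controlled by
:class:`SimulationConfig`; a fixed seed reproduces the volume
bit-exactly.

It emulates the image *features* the analysis must handle — HU levels,
quantum-noise magnitude, resolution loss, cupping/crescent
nonuniformity, session-to-session drift — not the acquisition physics:
noise is uncorrelated (no streaks), cupping is a radial parabola and
there is no beam hardening, scatter or projection-domain modeling.

The cupping amplitude is parameterized so that it equals the analytic
center-vs-edge-ROI uniformity difference: the depression field is
``-A * (1 - (r/r_ref)**2)`` with ``r_ref`` the radial position of the
edge uniformity ROIs, hence ~A between the center ROI and the edge
ROIs.  The per-render ground-truth log records artifact-adjusted
expected ROI means so recovery can be scored even with artifacts on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage

from .dicom_io import PhantomImageSeries
from .phantom_model import PhantomGeometry, default_geometry

__all__ = [
    "CrescentSpec",
    "SimulationConfig",
    "StepEvent",
    "DriftModel",
    "render_phantom",
    "simulate_longitudinal",
    "ct_preset",
    "cbct_preset",
    "cbct_halffan_preset",
    "PRESETS",
]


@dataclass
class CrescentSpec:
    """A localized annular-arc artifact in the uniformity module."""

    amplitude_hu: float = 40.0
    radius_mm: float = 80.0
    angle_deg: float = 90.0
    span_deg: float = 40.0
    width_mm: float = 8.0


def _default_plug_hu() -> dict[str, float]:
    return {
        "air": -1000.0,
        "polyethylene": -95.0,
        "water": 0.0,
        "acrylic": 120.0,
        "bone": 955.0,
    }


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one rendered phantom volume."""

    geometry: PhantomGeometry = field(default_factory=default_geometry)
    plug_hu: dict[str, float] = field(default_factory=_default_plug_hu)
    background_hu: float = 0.0  # water-equivalent body
    outside_hu: float = -1000.0
    noise_sigma: float = 3.5  # HU
    psf_sigma_mm: float = 0.45
    cupping_hu: float = 0.0  # center-vs-edge-ROI depression amplitude
    crescent: CrescentSpec | None = None
    bb_hu: float = 3000.0
    bb_blob_sigma_mm: float = 1.0
    wire_contrast_hu: float = 700.0
    wire_blob_sigma_mm: float = 0.7
    rod_contrast_hu: float = 6.0
    bar_amplitude_hu: float = 1000.0
    pixel_spacing: float = 0.65  # mm, isotropic in-plane
    matrix: int = 384
    slice_thickness: float = 2.5  # mm
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # phantom shift (mm)
    roll_deg: float = 0.0
    hu_offset: float = 0.0  # global in-phantom calibration shift
    z_range: tuple[float, float] | None = None  # restrict rendered z (mm)
    modality: str = "CT"
    protocol: str = "synthetic"
    machine: str = "SIM-1"
    acquisition_date: str = "2024-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.psf_sigma_mm < 0:
            raise ValueError("noise_sigma and psf_sigma_mm must be >= 0")
        if self.matrix < 128:
            raise ValueError("matrix must be >= 128")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_spacing and slice_thickness must be positive")
        if self.matrix * self.pixel_spacing < self.geometry.phantom_diameter:
            raise ValueError(
                "phantom does not fit in the field of view: "
                f"{self.matrix} px x {self.pixel_spacing} mm < "
                f"{self.geometry.phantom_diameter} mm"
            )


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------


def _rot(p: tuple[float, float], deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return (c * p[0] - s * p[1], s * p[0] + c * p[1])


class _Frame:
    """Pixel grid plus the rigid transform of the phantom within it."""

    def __init__(self, cfg: SimulationConfig):
        n = cfg.matrix
        sp = cfg.pixel_spacing
        self.origin = (-(n - 1) / 2.0 * sp, -(n - 1) / 2.0 * sp)
        x = self.origin[0] + np.arange(n) * sp
        y = self.origin[1] + np.arange(n) * sp
        self.X, self.Y = np.meshgrid(x, y)  # (rows, cols); Y varies by row
        self.dx, self.dy, self.dz = cfg.offset
        self.roll = cfg.roll_deg
        self.sp = sp
        self.n = n

    def place(self, p: tuple[float, float]) -> tuple[float, float]:
        """Nominal phantom coordinates -> absolute mm."""
        rx, ry = _rot(p, self.roll)
        return (rx + self.dx, ry + self.dy)

    def disc_mask(self, center_nominal, radius) -> np.ndarray:
        cx, cy = self.place(center_nominal)
        return (self.X - cx) ** 2 + (self.Y - cy) ** 2 <= radius**2

    def add_blob(self, img, center_abs, sigma_mm, amplitude) -> None:
        """Add a Gaussian blob in a local window (cheap for many blobs)."""
        cx, cy = center_abs
        half = 5.0 * sigma_mm
        c0 = max(int((cx - half - self.origin[0]) / self.sp), 0)
        c1 = min(int((cx + half - self.origin[0]) / self.sp) + 2, self.n)
        r0 = max(int((cy - half - self.origin[1]) / self.sp), 0)
        r1 = min(int((cy + half - self.origin[1]) / self.sp) + 2, self.n)
        if c0 >= c1 or r0 >= r1:
            return
        xs = self.X[r0:r1, c0:c1]
        ys = self.Y[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma_mm**2)
        )


def _slice_centers(cfg: SimulationConfig) -> np.ndarray:
    g = cfg.geometry
    dz = cfg.offset[2]
    zmin = dz - g.module_length / 2.0
    zmax = dz + (g.n_modules - 0.5) * g.module_length
    if cfg.z_range is not None:
        zmin = max(zmin, cfg.z_range[0])
        zmax = min(zmax, cfg.z_range[1])
    t = cfg.slice_thickness
    k0 = math.ceil((zmin + t / 2.0) / t - 1e-9)
    k1 = math.floor((zmax - t / 2.0) / t + 1e-9)
    if k1 < k0:
        raise ValueError("z_range too narrow for a single slice")
    return np.arange(k0, k1 + 1) * t


def _module_base(cfg: SimulationConfig, frame: _Frame, module: int) -> np.ndarray:
    """Ideal (pre-blur) 2D HU map of a module's z-invariant content."""
    g = cfg.geometry
    img = np.full((cfg.matrix, cfg.matrix), cfg.outside_hu, dtype=np.float64)
    body = frame.disc_mask((0.0, 0.0), g.radius)
    img[body] = cfg.background_hu + cfg.hu_offset
    if module == 1:
        for plug in g.plugs:
            hu = cfg.plug_hu.get(plug.name, plug.nominal_hu) + cfg.hu_offset
            img[frame.disc_mask(plug.center, plug.diameter / 2.0)] = hu
    elif module == 2:
        lc = g.low_contrast
        img[frame.disc_mask(lc.cylinder_center, lc.cylinder_diameter / 2.0)] += (
            cfg.rod_contrast_hu
        )
        for a in lc.rod_angles_deg:
            ar = math.radians(a)
            c = (lc.rod_radius_mm * math.cos(ar), lc.rod_radius_mm * math.sin(ar))
            img[frame.disc_mask(c, lc.rod_diameter / 2.0)] += cfg.rod_contrast_hu
    elif module == 4:
        bp = g.bar_patterns
        half = bp.size_mm / 2.0
        # pixel-aperture averaging across the pixel width: a reconstructed
        # CT pixel integrates over its area rather than point-sampling, and
        # point-sampling a square wave would alias full-amplitude patterns
        # at any frequency
        n_sub = 8
        sub = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * frame.sp
        for f_lp_cm, center in zip(bp.frequencies_lp_cm, bp.pattern_centers()):
            cx, cy = frame.place(center)
            region = (np.abs(frame.X - cx) <= half) & (np.abs(frame.Y - cy) <= half) & body
            bar_width = 5.0 / f_lp_cm  # mm; a line pair is 10/f mm
            xs = frame.X[region]
            duty = np.zeros_like(xs)
            for off in sub:
                duty += np.floor((xs + off - cx) / bar_width).astype(int) % 2 == 0
            img[region] += cfg.bar_amplitude_hu * duty / n_sub
    return img


def _bb_truth(cfg: SimulationConfig, frame: _Frame) -> list[dict]:
    """Absolute (x, y, z) of every BB with its label and module."""
    g = cfg.geometry
    dz = cfg.offset[2]
    planes = {m: dz + (m - 1) * g.module_length for m in range(1, g.n_modules + 1)}
    bbs = []
    for m in g.alignment_bb_modules:
        for a in g.alignment_bb_angles_deg:
            ar = math.radians(a)
            nominal = (
                g.alignment_bb_radius_mm * math.cos(ar),
                g.alignment_bb_radius_mm * math.sin(ar),
            )
            x, y = frame.place(nominal)
            bbs.append(
                {
                    "label": f"align_m{m}_{a:g}",
                    "kind": "alignment",
                    "module": m,
                    "xyz": (x, y, planes[m]),
                }
            )
    for i, p in enumerate(g.distance_bb_positions):
        x, y = frame.place(p)
        bbs.append(
            {
                "label": f"distance_{i}",
                "kind": "distance",
                "module": 3,
                "xyz": (x, y, planes[3]),
            }
        )
    return bbs


def _cupping_field(cfg: SimulationConfig, frame: _Frame) -> np.ndarray | None:
    if cfg.cupping_hu == 0.0:
        return None
    g = cfg.geometry
    cx, cy = frame.place((0.0, 0.0))
    r2 = (frame.X - cx) ** 2 + (frame.Y - cy) ** 2
    rref2 = g.uniformity_edge_radius_mm**2
    field = -cfg.cupping_hu * (1.0 - r2 / rref2)
    field[r2 > g.radius**2] = 0.0
    return field


def _crescent_field(cfg: SimulationConfig, frame: _Frame) -> np.ndarray | None:
    cr = cfg.crescent
    if cr is None or cr.amplitude_hu == 0.0:
        return None
    cx, cy = frame.place((0.0, 0.0))
    xr = frame.X - cx
    yr = frame.Y - cy
    r = np.hypot(xr, yr)
    ang = np.degrees(np.arctan2(yr, xr))
    dang = (ang - (cr.angle_deg + frame.roll) + 180.0) % 360.0 - 180.0
    mask = (np.abs(r - cr.radius_mm) <= cr.width_mm / 2.0) & (
        np.abs(dang) <= cr.span_deg / 2.0
    )
    field = np.zeros_like(frame.X)
    field[mask] = cr.amplitude_hu
    return field


def crescent_mask(cfg: SimulationConfig) -> np.ndarray | None:
    """2D boolean mask of the configured crescent artifact (or None).

    This is the ground-truth artifact extent, usable as the
    ``artifact_mask`` input of the ROI statistics so that analysis can
    avoid the artifact the way a human observer would.
    """
    frame = _Frame(cfg)
    field = _crescent_field(cfg, frame)
    return None if field is None else field != 0


def cupping_roi_mean(cfg: SimulationConfig, roi_center, roi_radius: float) -> float:
    """Analytic mean of the cupping field over a circular ROI.

    ``roi_center`` is in nominal phantom coordinates (mm from the axis).
    The mean of r^2 over a disc of radius a centered at distance d from
    the axis is d^2 + a^2/2, so the mean field is
    ``-A * (1 - (d^2 + a^2/2) / r_ref^2)``.
    """
    if cfg.cupping_hu == 0.0:
        return 0.0
    d2 = roi_center[0] ** 2 + roi_center[1] ** 2
    rref2 = cfg.geometry.uniformity_edge_radius_mm**2
    return -cfg.cupping_hu * (1.0 - (d2 + roi_radius**2 / 2.0) / rref2)


def expected_uniformity(cfg: SimulationConfig) -> float:
    """Analytic |edge - center| uniformity value implied by the artifacts."""
    g = cfg.geometry
    a = math.sqrt(g.roi_area_uniformity_mm2 / math.pi)
    centers = g.uniformity_roi_centers()
    cm = cupping_roi_mean(cfg, centers["center"], a)
    return max(
        abs(cupping_roi_mean(cfg, c, a) - cm)
        for k, c in centers.items()
        if k != "center"
    )


def render_phantom(cfg: SimulationConfig) -> tuple[PhantomImageSeries, dict]:
    """Render one phantom volume; returns (series, ground-truth log)."""
    g = cfg.geometry
    frame = _Frame(cfg)
    z_centers = _slice_centers(cfg)
    dz = cfg.offset[2]
    t = cfg.slice_thickness
    rng = np.random.default_rng(cfg.seed)

    bbs = _bb_truth(cfg, frame)
    wire_sites = []  # (x_abs, y_abs, z_abs) per wire of each ramp
    for ramp in g.ramps:
        sites = []
        for (x, y, dzw) in ramp.wire_positions():
            ax, ay = frame.place((x, y))
            sites.append((ax, ay, dz + dzw))
        wire_sites.append(sites)

    bases = {}
    psf_px = cfg.psf_sigma_mm / cfg.pixel_spacing
    cup = _cupping_field(cfg, frame)
    cres = _crescent_field(cfg, frame)
    half_len = g.module_length / 2.0
    volume = np.empty((len(z_centers), cfg.matrix, cfg.matrix), dtype=np.float64)
    bb_r = g.bb_diameter / 2.0

    for i, zc in enumerate(z_centers):
        zr = zc - dz  # relative to module-1 plane
        module = int(min(max(math.floor((zr + half_len) / g.module_length), 0), 3)) + 1
        if module not in bases:
            bases[module] = _module_base(cfg, frame, module)
        img = bases[module].copy()
        lo, hi = zc - t / 2.0, zc + t / 2.0
        if module == 1:
            for sites in wire_sites:
                for (ax, ay, zw) in sites:
                    if lo < zw <= hi:
                        frame.add_blob(
                            img, (ax, ay), cfg.wire_blob_sigma_mm, cfg.wire_contrast_hu
                        )
        for bb in bbs:
            bx, by, bz = bb["xyz"]
            overlap = min(hi, bz + bb_r) - max(lo, bz - bb_r)
            if overlap <= 0:
                continue
            w = overlap / (2.0 * bb_r)
            frame.add_blob(
                img,
                (bx, by),
                cfg.bb_blob_sigma_mm,
                (cfg.bb_hu - cfg.background_hu) * w,
            )
        if psf_px > 0:
            img = ndimage.gaussian_filter(img, psf_px, mode="nearest")
        if cup is not None:
            img += cup
        if cres is not None:
            img += cres
        if cfg.noise_sigma > 0:
            img += rng.normal(0.0, cfg.noise_sigma, img.shape)
        volume[i] = np.rint(img)

    series = PhantomImageSeries(
        hu=volume,
        pixel_spacing=(cfg.pixel_spacing, cfg.pixel_spacing),
        slice_thickness=t,
        z_positions=z_centers,
        modality=cfg.modality,
        protocol=cfg.protocol,
        machine=cfg.machine,
        acquisition_date=cfg.acquisition_date,
        origin=frame.origin,
    )

    roi_r = math.sqrt(g.roi_area_hu_mm2 / math.pi)
    truth = {
        "center_xy": (cfg.offset[0], cfg.offset[1]),
        "roll_deg": cfg.roll_deg,
        "module_planes_z": {m: dz + (m - 1) * g.module_length for m in (1, 2, 3, 4)},
        "bbs": bbs,
        "distance_mm": (
            math.dist(
                frame.place(g.distance_bb_positions[0]),
                frame.place(g.distance_bb_positions[1]),
            )
            if len(g.distance_bb_positions) >= 2
            else None
        ),
        "slice_thickness_mm": t,
        "noise_sigma": cfg.noise_sigma,
        "expected_plug_means": {
            p.name: cfg.plug_hu.get(p.name, p.nominal_hu)
            + cfg.hu_offset
            + cupping_roi_mean(cfg, p.center, roi_r)
            for p in g.plugs
        },
        "expected_uniformity_hu": expected_uniformity(cfg),
        "rod_contrast_hu": cfg.rod_contrast_hu,
        "psf_sigma_mm": cfg.psf_sigma_mm,
    }
    return series, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def ct_preset(**overrides) -> SimulationConfig:
    """Fan-beam CT-simulator-like conditions: low noise, sharp, no cupping.

    sigma = 3.5 HU reproduces plug noise (per the +1000 HU rescaled
    definition) of ~0.4%, the scale measured on clinical CT protocols;
    the 0.45 mm PSF yields 6 lp/cm, inside the measured 6-7 lp/cm band.
    """
    cfg = dict(
        noise_sigma=3.5,
        psf_sigma_mm=0.45,
        cupping_hu=0.0,
        modality="CT",
        protocol="ct-sim",
        machine="CTSIM-1",
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def cbct_preset(**overrides) -> SimulationConfig:
    """Full-fan head CBCT-like conditions: heavy noise plus cupping.

    sigma = 30 HU gives plug noise ~3.3% and plug CNR ~3, matching the
    magnitudes measured on standard-dose head CBCT; cupping 20 HU puts
    uniformity in the measured tens-of-HU range, and the low-contrast
    rods (6 HU contrast) drown in the noise as observed on linac CBCT.
    """
    cfg = dict(
        noise_sigma=30.0,
        psf_sigma_mm=0.4,
        cupping_hu=20.0,
        modality="CBCT",
        protocol="standard dose head",
        machine="LINAC-1",
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def cbct_halffan_preset(**overrides) -> SimulationConfig:
    """Half-fan (body) CBCT-like conditions: blurrier, strong cupping."""
    cfg = dict(
        noise_sigma=30.0,
        psf_sigma_mm=0.8,
        cupping_hu=30.0,
        modality="CBCT",
        protocol="pelvis",
        machine="LINAC-1",
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


PRESETS = {
    "ct-sim": ct_preset,
    "cbct-head": cbct_preset,
    "cbct-pelvis": cbct_halffan_preset,
}


# ---------------------------------------------------------------------------
# longitudinal simulation
# ---------------------------------------------------------------------------


@dataclass
class StepEvent:
    """A sudden machine change at a given session (0-based index).

    ``plug_hu_delta`` is added to the affected plugs' true HU from this
    session onward; ``triggers_reset`` marks that the clinic would
    re-baseline after investigating (maintenance/recalibration).
    """

    session: int
    plug_hu_delta: dict[str, float] = field(default_factory=dict)
    hu_offset_delta: float = 0.0
    triggers_reset: bool = True


@dataclass
class DriftModel:
    """Deterministic session-to-session change of the simulated machine."""

    plug_hu_per_session: dict[str, float] = field(default_factory=dict)
    hu_offset_per_session: float = 0.0
    steps: list[StepEvent] = field(default_factory=list)


def session_config(
    cfg: SimulationConfig, drift: DriftModel, session: int, seed: int
) -> SimulationConfig:
    """Config for one session with drift and step events applied."""
    plug_hu = dict(cfg.plug_hu)
    hu_offset = cfg.hu_offset + drift.hu_offset_per_session * session
    for name, rate in drift.plug_hu_per_session.items():
        plug_hu[name] = plug_hu.get(name, 0.0) + rate * session
    for step in drift.steps:
        if session >= step.session:
            hu_offset += step.hu_offset_delta
            for name, delta in step.plug_hu_delta.items():
                plug_hu[name] = plug_hu.get(name, 0.0) + delta
    quarter = session % 4
    date = f"{2023 + session // 4}-{3 * quarter + 1:02d}-15"
    return replace(
        cfg,
        plug_hu=plug_hu,
        hu_offset=hu_offset,
        acquisition_date=date,
        seed=int(seed) % (2**31),
    )


def simulate_longitudinal(
    cfg: SimulationConfig,
    drift: DriftModel | None = None,
    n_sessions: int = 8,
    seed: int = 0,
) -> list[tuple[PhantomImageSeries, dict]]:
    """Render one series per quarterly session with drift applied.

    Returns a list of (series, truth) pairs; each truth log additionally
    records the session index, date and whether a step event (and hence
    an expected baseline reset) occurred at that session.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    drift = drift or DriftModel()
    out = []
    for s in range(n_sessions):
        scfg = session_config(cfg, drift, s, seed + s)
        series, truth = render_phantom(scfg)
        truth["session"] = s
        truth["date"] = scfg.acquisition_date
        truth["step_here"] = any(st.session == s for st in drift.steps)
        truth["reset_here"] = any(
            st.session == s and st.triggers_reset for st in drift.steps
        )
        out.append((series, truth))
    return out
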