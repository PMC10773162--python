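"""Synthetic acquisitions: every input the analysis pipeline needs.

This module emulates the study conditions of a longitudinal two-lumen
aortic-dissection experiment imaged with velocity-encoded (4D-flow) MRI:

* pulsatile inlet waveforms for the two measured cardiac states
  (S1-like: 0.78 s cycle; S2-like: 1.08 s cycle),
* time-resolved voxel velocity fields with true-lumen / false-lumen
  label masks on MRI-like grids (default 2 mm isotropic voxels, 20
  frames/cycle, VENC 150 cm/s, Gaussian velocity noise),
* lumped dissection network case definitions for the three tear
  scenarios (entry tear at 7 cm; created re-entry tears at 21 and
  26 cm; natural distal re-entry tear at 32 cm from the arch),
* label volumes for slice-wise lumen morphometry.

The velocity profile is quasi-parabolic (Poiseuille-shaped) and scaled
frame-by-frame so the discrete cross-section flow equals the prescribed
inlet waveform exactly, which gives closed-form oracles for all
downstream flow metrics.  Womersley profiles are out of scope.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .fields import VelocityField4D, LABEL_TL, LABEL_FL
from .rheology import PowerLawParams
from .units import LMIN_TO_M3S
from .waveform import FlowWaveform

__all__ = [
    "AcquisitionParams",
    "PhantomSpec",
    "CaseDefinition",
    "make_inlet_waveform",
    "make_phantom_field",
    "make_segmentation_stack",
    "make_case",
    "power_law_poiseuille_field",
    "SCENARIOS",
]

SCENARIOS = ("S1-like", "S2-like", "S2mod-like")


@dataclass(frozen=True)
class AcquisitionParams:
    """MRI-like acquisition settings for the synthetic velocity fields."""

    temporal_resolution_s: float = 0.0392
    frames_per_cycle: int = 20
    voxel_size_mm: float = 2.0
    velocity_encoding_cm_s: float = 150.0
    noise_sd_fraction_of_venc: float = 0.05

    def __post_init__(self) -> None:
        if self.frames_per_cycle < 2:
            raise ValueError("frames_per_cycle must be >= 2")
        if self.temporal_resolution_s <= 0 or self.voxel_size_mm <= 0 \
                or self.velocity_encoding_cm_s <= 0:
            raise ValueError("acquisition sizes must be > 0")
        if not (0 <= self.noise_sd_fraction_of_venc < 1):
            raise ValueError("noise fraction must be in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and flow programme of a synthetic flow phantom.

    ``two_lumen_dissection`` splits a circular tube into a true lumen
    (x < -septum/2, label 1) and a false lumen (x > +septum/2, label 2)
    separated by a septum (flap) of the given thickness, and divides the
    inlet flow between them with ``tl_flow_fraction``.
    """

    kind: str = "straight_tube"  # or "two_lumen_dissection"
    radius_mm: float = 10.0
    length_mm: float = 40.0
    septum_thickness_mm: float = 2.0
    tl_flow_fraction: float = 0.56
    tear_positions_mm: tuple = (70.0, 210.0, 260.0, 320.0)
    tear_diameters_mm: tuple = (10.0, 5.0, 5.0, 9.0)
    cycle_period_s: float = 0.78
    peak_inlet_flow_L_min: float = 15.0
    systolic_fraction: float = 0.35
    diastolic_flow_L_min: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("straight_tube", "two_lumen_dissection"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if np.any(np.diff(self.tear_positions_mm) <= 0):
            raise ValueError("tear positions must be strictly increasing")
        if any(d <= 0 for d in self.tear_diameters_mm):
            raise ValueError("tear diameters must be > 0")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic_fraction must be in (0, 1)")
        if not (0 < self.tl_flow_fraction < 1):
            raise ValueError("tl_flow_fraction must be in (0, 1)")


def make_inlet_waveform(period_s: float, peak_flow_L_min: float,
                        systolic_fraction: float, frames: int,
                        diastolic_flow_L_min: float = 0.0) -> FlowWaveform:
    """Half-sine systolic pulse followed by a low/zero diastolic plateau.

    Systole lasts ``systolic_fraction * period`` with a half-sine of
    amplitude ``peak_flow_L_min`` (so the cycle mean of a pure half-sine
    over half the period is ``peak / pi``); diastole is constant at
    ``diastolic_flow_L_min``.  Sampled at ``frames`` uniformly spaced
    times on ``[0, T)``.
    """
    if period_s <= 0:
        raise ValueError("period must be > 0")
    if peak_flow_L_min < 0:
        raise ValueError("peak flow must be >= 0")
    if frames < 4:
        raise ValueError("need at least 4 frames per cycle")
    t = period_s * np.arange(frames) / frames
    t_sys = systolic_fraction * period_s
    q = np.where(t < t_sys,
                 peak_flow_L_min * np.sin(np.pi * t / t_sys),
                 float(diastolic_flow_L_min))
    q = np.maximum(q, 0.0)
    return FlowWaveform(t, q, period_s)


def _cross_section(radius_mm: float, voxel_mm: float, pad_voxels: int = 2):
    """Centered square in-plane grid covering the tube plus a pad."""
    n_across = 2.0 * radius_mm / voxel_mm
    if n_across < 8:
        raise ValueError(
            f"grid too coarse: only {n_across:.1f} voxels across the tube "
            "diameter; at least 8 are required to resolve the profile")
    n = int(np.ceil((2 * radius_mm + 2 * pad_voxels * voxel_mm) / voxel_mm))
    coords = (np.arange(n) - (n - 1) / 2) * voxel_mm
    return coords


def make_phantom_field(spec: PhantomSpec, acq: AcquisitionParams
                       ) -> tuple[VelocityField4D, np.ndarray]:
    """Generate a pulsatile voxel velocity field and its lumen mask.

    The axial (z) velocity carries a parabolic profile scaled per frame
    so the discrete cross-section flow equals the inlet waveform; the
    two-lumen kind splits the flow ``tl_flow_fraction : 1 - fraction``
    between the lumina.  Gaussian noise with standard deviation
    ``noise_sd_fraction_of_venc * VENC`` is then added to every
    component of every voxel (background included, as in a real
    velocity-encoded acquisition).  Returns ``(field, mask)``.
    """
    vox = acq.voxel_size_mm
    xy = _cross_section(spec.radius_mm, vox)
    n = xy.size
    nz = max(int(round(spec.length_mm / vox)) + 1, 3)
    X, Y = np.meshgrid(xy, xy, indexing="ij")
    r2 = X**2 + Y**2
    inside = r2 < spec.radius_mm**2

    mask2d = np.zeros((n, n), dtype=np.uint8)
    if spec.kind == "straight_tube":
        mask2d[inside] = LABEL_TL
    else:
        half_sep = spec.septum_thickness_mm / 2.0
        mask2d[inside & (X < -half_sep)] = LABEL_TL
        mask2d[inside & (X > half_sep)] = LABEL_FL

    profile = np.where(inside, 1.0 - r2 / spec.radius_mm**2, 0.0)

    waveform = make_inlet_waveform(
        spec.cycle_period_s, spec.peak_inlet_flow_L_min,
        spec.systolic_fraction, acq.frames_per_cycle,
        spec.diastolic_flow_L_min)

    dA_m2 = (vox * 1e-3) ** 2
    lumen_flow = {}
    if spec.kind == "straight_tube":
        lumen_flow[LABEL_TL] = waveform.flow_L_min
    else:
        lumen_flow[LABEL_TL] = spec.tl_flow_fraction * waveform.flow_L_min
        lumen_flow[LABEL_FL] = (1 - spec.tl_flow_fraction) * waveform.flow_L_min

    nt = acq.frames_per_cycle
    v = np.zeros((nt, n, n, nz, 3))
    for label, q_lmin in lumen_flow.items():
        sel = mask2d == label
        if not sel.any():
            raise ValueError("lumen cross-section resolved no voxels")
        denom = profile[sel].sum() * dA_m2  # m^2 weighted profile sum
        plane = np.where(sel, profile, 0.0)
        for k, q in enumerate(q_lmin):
            scale = (q * LMIN_TO_M3S) / denom
            v[k, :, :, :, 2] += (plane * scale)[:, :, None]

    mask = np.repeat(mask2d[:, :, None], nz, axis=2)
    # velocity is exactly zero on background voxels before noise
    if acq.noise_sd_fraction_of_venc > 0:
        rng = np.random.default_rng(spec.rng_seed)
        sd = acq.noise_sd_fraction_of_venc * acq.velocity_encoding_cm_s / 100.0
        v = v + rng.normal(0.0, sd, size=v.shape)

    affine = np.diag([vox, vox, vox, 1.0])
    affine[0, 3] = xy[0]
    affine[1, 3] = xy[0]
    affine[2, 3] = 0.0
    fieldobj = VelocityField4D(v, mask, affine, waveform.time_s,
                               spec.cycle_period_s)
    return fieldobj, mask


def power_law_poiseuille_field(radius_mm: float = 10.0,
                               voxels_across: int = 16,
                               wall_shear_rate: float = 100.0,
                               params: PowerLawParams | None = None,
                               length_mm: float = 20.0,
                               frames: int = 2,
                               exterior: str = "zero") -> VelocityField4D:
    """Steady fully developed power-law pipe flow on a voxel grid.

    The axial profile is ``u(r) = u_max (1 - (r/R)**m)`` with
    ``m = (n+1)/n`` and ``u_max = gamma_w R n / (n+1)``, the exact
    laminar solution whose wall shear rate is ``wall_shear_rate``.
    Used as the validation phantom for wall-shear estimation.

    ``exterior`` controls voxels outside the lumen: ``"zero"`` (masked
    acquisition-like background) or ``"extend"`` (the analytic profile
    continued smoothly past the wall, for isolating gradient truncation
    error from interpolation across the masked boundary).
    """
    if params is None:
        params = PowerLawParams()
    if exterior not in ("zero", "extend"):
        raise ValueError("exterior must be 'zero' or 'extend'")
    n_exp = params.exponent_n
    m = (n_exp + 1.0) / n_exp
    R = radius_mm * 1e-3
    u_max = wall_shear_rate * R * n_exp / (n_exp + 1.0)

    vox = 2.0 * radius_mm / voxels_across
    # wide pad: cubic-spline probes near the wall must not feel the
    # grid boundary
    xy = _cross_section(radius_mm, vox, pad_voxels=6)
    n = xy.size
    nz = max(int(round(length_mm / vox)) + 1, 5)
    X, Y = np.meshgrid(xy, xy, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    inside = r < radius_mm
    u = u_max * (1.0 - (r / radius_mm) ** m)
    if exterior == "zero":
        u = np.where(inside, u, 0.0)

    v = np.zeros((frames, n, n, nz, 3))
    v[..., 2] = u[None, :, :, None]
    mask = np.where(inside, LABEL_TL, 0).astype(np.uint8)
    mask = np.repeat(mask[:, :, None], nz, axis=2)
    affine = np.diag([vox, vox, vox, 1.0])
    affine[0, 3] = xy[0]
    affine[1, 3] = xy[0]
    times = np.arange(frames, dtype=float) / frames
    return VelocityField4D(v, mask, affine, times, 1.0)


def make_segmentation_stack(shape: str, radius_mm: float, length_mm: float,
                            slice_thickness_mm: float, pixel_mm: float,
                            fl_radius_mm: float | None = None,
                            ) -> tuple[np.ndarray, float, float]:
    """Voxelized label stack for morphometry: ``(labels, pixel, thickness)``.

    ``shape="cylinder"`` rasterizes one circular lumen (label 1);
    ``shape="two_lumen"`` adds a second, disjoint circular lumen
    (label 2, radius ``fl_radius_mm``).  Pixel membership follows the
    center-sampling convention.  The slice count is
    ``round(length / thickness)`` so the analytic volume of a cylinder
    is ``pi r^2 length``.
    """
    if radius_mm < 0 or length_mm < 0:
        raise ValueError("dimensions must be >= 0")
    if slice_thickness_mm <= 0 or pixel_mm <= 0:
        raise ValueError("thickness and pixel size must be > 0")
    if shape not in ("cylinder", "two_lumen"):
        raise ValueError(f"unknown stack shape {shape!r}")
    r2 = fl_radius_mm if fl_radius_mm is not None else radius_mm
    if shape == "two_lumen":
        # disjoint circles side by side with a 2-pixel flap gap
        cx_tl = -(radius_mm + pixel_mm)
        cx_fl = r2 + pixel_mm
        x_lo = cx_tl - radius_mm - 2 * pixel_mm
        x_hi = cx_fl + r2 + 2 * pixel_mm
        half_y = max(radius_mm, r2) + 2 * pixel_mm
    else:
        cx_tl = cx_fl = 0.0
        x_lo, x_hi = -(radius_mm + 2 * pixel_mm), radius_mm + 2 * pixel_mm
        half_y = radius_mm + 2 * pixel_mm
    xs = np.arange(x_lo, x_hi + pixel_mm / 2, pixel_mm)
    ny = int(np.ceil(2 * half_y / pixel_mm))
    ys = (np.arange(ny) - (ny - 1) / 2) * pixel_mm
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    plane = np.zeros(X.shape, dtype=np.uint8)
    plane[(X - cx_tl) ** 2 + Y**2 < radius_mm**2] = LABEL_TL
    if shape == "two_lumen":
        plane[(X - cx_fl) ** 2 + Y**2 < r2**2] = LABEL_FL
    nslices = int(round(length_mm / slice_thickness_mm))
    labels = np.repeat(plane[:, :, None], nslices, axis=2)
    return labels, pixel_mm, slice_thickness_mm


# ---------------------------------------------------------------------------
# Dissection network case definitions (S1-like / S2-like / S2mod-like)
# ---------------------------------------------------------------------------

# Tear stations, mm from the arch: entry 70, created re-entries 210 and
# 260, natural distal re-entry 320.  Created tears are 5 mm.  The entry
# and distal orifices are effective circular diameters: the measured
# axial calipers (~20 / ~12 mm) describe elongated slits, so the entry
# is modelled with a smaller equivalent orifice.
TEAR_LAYOUT = (
    {"name": "entry", "from": "T0", "to": "F0", "position_mm": 70.0,
     "diameter_mm": 14.0, "kind": "entry"},
    {"name": "reentry1", "from": "T1", "to": "F1", "position_mm": 210.0,
     "diameter_mm": 5.0, "kind": "re-entry"},
    {"name": "reentry2", "from": "T2", "to": "F2", "position_mm": 260.0,
     "diameter_mm": 5.0, "kind": "re-entry"},
    {"name": "distal", "from": "T3", "to": "F3", "position_mm": 320.0,
     "diameter_mm": 12.0, "kind": "re-entry"},
)

_OPEN_TEARS = {
    "S1-like": ("entry", "distal"),
    "S2-like": ("entry", "reentry1", "reentry2", "distal"),
    "S2mod-like": ("entry", "reentry2", "distal"),
}

_SEGMENTS = (
    # name, from, to, length_mm, radius_mm, lumen
    ("AO",   "ARCH", "T0", 70.0, 12.0, "TL"),
    ("BR1",  "ARCH", "B1", 30.0, 5.05, "TL"),
    ("BR2",  "ARCH", "B2", 30.0, 3.09, "TL"),
    ("BR3",  "ARCH", "B3", 30.0, 2.52, "TL"),
    ("TL1a", "T0", "Tm1", 70.0, 7.0, "TL"),
    ("TL1b", "Tm1", "T1", 70.0, 7.0, "TL"),
    ("TL2",  "T1", "T2", 50.0, 7.0, "TL"),
    ("TL3a", "T2", "Tm2", 30.0, 7.0, "TL"),
    ("TL3b", "Tm2", "T3", 30.0, 7.0, "TL"),
    ("TL4",  "T3", "T4", 100.0, 8.0, "TL"),
    ("FL1a", "F0", "Fm1", 70.0, 10.0, "FL"),
    ("FL1b", "Fm1", "F1", 70.0, 10.0, "FL"),
    ("FL2",  "F1", "F2", 50.0, 10.0, "FL"),
    ("FL3a", "F2", "Fm2", 30.0, 10.0, "FL"),
    ("FL3b", "Fm2", "F3", 30.0, 10.0, "FL"),
)

# Arch branches: cross-sectional areas (mm^2) determine the area-
# proportional split of arch outflow; each ends in an RCR outlet.
_BRANCHES = (
    {"name": "branch1", "node": "B1", "area_mm2": 80.0},
    {"name": "branch2", "node": "B2", "area_mm2": 30.0},
    {"name": "branch3", "node": "B3", "area_mm2": 20.0},
)

# Analysis stations: pressure node and through-flow element per lumen.
_STATIONS = {
    "P1": {"tl_node": "ARCH", "fl_node": None,
           "tl_element": "AO", "fl_element": None},
    "P2": {"tl_node": "T0", "fl_node": "F0",
           "tl_element": "TL1a", "fl_element": "FL1a"},
    "P3": {"tl_node": "Tm1", "fl_node": "Fm1",
           "tl_element": "TL1b", "fl_element": "FL1b"},
    "P4": {"tl_node": "T1", "fl_node": "F1",
           "tl_element": "TL2", "fl_element": "FL2"},
    "P5": {"tl_node": "T2", "fl_node": "F2",
           "tl_element": "TL3a", "fl_element": "FL3a"},
    "P6": {"tl_node": "Tm2", "fl_node": "Fm2",
           "tl_element": "TL3b", "fl_element": "FL3b"},
    "P7": {"tl_node": "T3", "fl_node": None,
           "tl_element": "TL4", "fl_element": None},
}

_INLET_STATE = {
    # cardiac state per scenario: the second state has a longer cycle and
    # higher peak flow, and a larger share of inlet flow reaches the
    # descending aorta (descending_fraction; the rest exits the arch
    # branches).  S2mod reuses the S2 state with one tear occluded.
    "S1-like": {"period_s": 0.78, "peak_flow_L_min": 15.0,
                "systolic_fraction": 0.35, "frames": 20,
                "descending_fraction": 0.349},
    "S2-like": {"period_s": 1.08, "peak_flow_L_min": 16.0,
                "systolic_fraction": 0.30, "frames": 25,
                "descending_fraction": 0.486},
    "S2mod-like": {"period_s": 1.08, "peak_flow_L_min": 16.0,
                   "systolic_fraction": 0.30, "frames": 25,
                   "descending_fraction": 0.486},
}


@dataclass
class CaseDefinition:
    """One dissection-network scenario: geometry, tears, inlet state."""

    scenario: str
    segments: list
    tears: list
    branches: list
    inlet_node: str
    distal_outlet_node: str
    stations: dict
    inlet: dict

    def open_tears(self) -> list:
        return [t for t in self.tears if t["open"]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CaseDefinition":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def make_case(scenario: str) -> CaseDefinition:
    """Build the dissection network case for one tear scenario.

    S1-like opens the entry and distal tears only (2 open tears);
    S2-like opens all four; S2mod-like equals S2-like with the 21 cm
    re-entry tear closed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"expected one of {SCENARIOS}")
    open_set = _OPEN_TEARS[scenario]
    tears = []
    for t in TEAR_LAYOUT:
        t = dict(t)
        t["open"] = t["name"] in open_set
        tears.append(t)
    segments = [
        {"name": s[0], "from": s[1], "to": s[2], "length_mm": s[3],
         "radius_mm": s[4], "lumen": s[5]}
        for s in _SEGMENTS
    ]
    return CaseDefinition(
        scenario=scenario,
        segments=segments,
        tears=tears,
        branches=[dict(b) for b in _BRANCHES],
        inlet_node="ARCH",
        distal_outlet_node="T4",
        stations={k: dict(v) for k, v in _STATIONS.items()},
        inlet=dict(_INLET_STATE[scenario]),
    )
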