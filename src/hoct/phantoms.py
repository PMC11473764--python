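"""Synthetic CT phantoms with ground truth.

Three generators emulate the experimental objects of the quantification
protocol so that calibration, quantification and dosimetry can be exercised
end to end without scanner data:

* a *calibration tube phantom* — parallel tubes of known Ho concentration
  whose voxel HU follows the forward model HU = m + b·c plus Gaussian
  noise, clipped to the scanner's representable range;
* an *injection sample phantom* — a pre/post scan pair of a tissue block
  with a localized Ho-MS deposit of known mass (uniform sphere, Gaussian
  blob or multifocal), optionally with a baseline radiodensity shift
  between the scans;
* a *patient-like phantom* — an ellipsoidal tumor carrying multifocal
  deposits planned at a fixed mg per cm³, with hyperdense bone-like
  distractor structures outside the quantification VOI.

All randomness is controlled by a seed; identical parameters and seed give
bit-identical volumes.  Deposit concentration maps are scaled so that the
voxelized total equals the requested injected mass exactly, which makes
noise-free recovery oracles exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from hoct.calibration import CalibrationCurve, CalibrationPoint
from hoct.nuclide import HO_MS_CONTENT_FRACTION
from hoct.quantification import ellipsoid_volume
from hoct.volumes import CTVolume, VOIMask, VoxelGrid, make_cylinder_mask, voi_stats

__all__ = [
    "GroundTruth",
    "default_calibration_curve",
    "simulate_calibration_phantom",
    "simulate_injection_phantom",
    "simulate_patient_like",
]


def default_calibration_curve() -> CalibrationCurve:
    """The reference soft-tissue-kernel calibration line, HU = 26.36 + 29.89·c."""
    return CalibrationCurve(
        intercept_m=26.36,
        slope_b=29.89,
        forced_zero=False,
        metadata={"scanner": "synthetic", "kvp": 120, "kernel": "soft"},
    )


@dataclass
class GroundTruth:
    """Everything a recovery test needs to know about a simulated phantom."""

    conc_map: np.ndarray | None = None  # mg elemental Ho per mL, per voxel
    ho_mg: float | None = None
    ms_mg: float | None = None
    masks: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None
    detection_limit_hu: float | None = None
    saturated: list | None = None


def _clip_volume(
    values: np.ndarray, grid: VoxelGrid, hu_limits: tuple[float, float], metadata: dict
) -> CTVolume:
    clipped = np.clip(values, hu_limits[0], hu_limits[1])
    return CTVolume(grid, clipped, hu_limits[0], hu_limits[1], metadata)


def simulate_calibration_phantom(
    concentrations,
    curve: CalibrationCurve | None = None,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tube_diameter_mm: float = 17.0,
    mask_diameter_mm: float = 11.0,
    tube_length_mm: float = 30.0,
    tube_pitch_mm: float = 25.0,
    background_hu: float = 0.0,
    noise_sd: float = 15.0,
    hu_limits: tuple[float, float] = (-1024.0, 3071.0),
    seed: int = 0,
) -> tuple[CTVolume, GroundTruth]:
    """Simulate a tube calibration phantom and its ground truth.

    Tubes (⌀ 17 mm, 30 mm long by default) are laid out on a rectangular
    lattice; each tube's interior HU is m + b·c plus independent Gaussian
    noise, clipped to ``hu_limits``.  The truth carries ⌀ 11 mm analysis
    masks per tube and the saturation status against the detection limit
    (one HU below the representable ceiling, so any clipped tube is flagged).
    """
    curve = curve or default_calibration_curve()
    concentrations = [float(c) for c in concentrations]
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    n = len(concentrations)
    if n < 1:
        raise ValueError("need at least one tube")
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    if tube_pitch_mm < tube_diameter_mm:
        raise ValueError("tube pitch smaller than tube diameter: tubes would overlap")
    margin = tube_diameter_mm / 2.0 + 4.0
    size_x = (ncols - 1) * tube_pitch_mm + 2 * margin
    size_y = (nrows - 1) * tube_pitch_mm + 2 * margin
    size_z = tube_length_mm + 8.0
    shape = tuple(int(round(s / sp)) + 1 for s, sp in zip((size_x, size_y, size_z), spacing_mm))
    grid = VoxelGrid(spacing_mm, (0.0, 0.0, 0.0), shape)
    zc = size_z / 2.0

    rng = np.random.default_rng(seed)
    clean = np.full(grid.shape, float(background_hu))
    conc_map = np.zeros(grid.shape)
    tube_masks, analysis_masks, centers = [], [], []
    for i, c in enumerate(concentrations):
        col, row = i % ncols, i // ncols
        center = (margin + col * tube_pitch_mm, margin + row * tube_pitch_mm, zc)
        tube = make_cylinder_mask(grid, center, tube_diameter_mm, tube_length_mm, "z")
        analysis = make_cylinder_mask(grid, center, mask_diameter_mm, tube_length_mm, "z")
        clean[tube.included] = curve.intercept_m + curve.slope_b * c
        conc_map[tube.included] = c
        tube_masks.append(tube)
        analysis_masks.append(analysis)
        centers.append(center)

    noisy = clean + rng.normal(0.0, noise_sd, grid.shape) if noise_sd > 0 else clean
    detection_limit = hu_limits[1] - 1.0
    saturated = [bool(noisy[m.included].max() > detection_limit) for m in analysis_masks]
    volume = _clip_volume(
        noisy, grid, hu_limits,
        {"phantom": "calibration_tubes", "seed": seed, **curve.metadata},
    )
    table = pd.DataFrame(
        {
            "tube": range(n),
            "concentration_mg_per_ml": concentrations,
            "saturated": saturated,
            "center_x_mm": [c[0] for c in centers],
            "center_y_mm": [c[1] for c in centers],
            "center_z_mm": [c[2] for c in centers],
        }
    )
    truth = GroundTruth(
        conc_map=conc_map,
        masks={
            **{f"tube_{i}": m for i, m in enumerate(tube_masks)},
            **{f"analysis_{i}": m for i, m in enumerate(analysis_masks)},
        },
        table=table,
        detection_limit_hu=detection_limit,
        saturated=saturated,
    )
    return volume, truth


def measure_calibration_points(
    volume: CTVolume, truth: GroundTruth
) -> list[CalibrationPoint]:
    """VOI statistics per analysis mask, paired with true concentrations."""
    pts = []
    for i, c in enumerate(truth.table["concentration_mg_per_ml"]):
        stats = voi_stats(volume, truth.masks[f"analysis_{i}"])
        pts.append(CalibrationPoint(float(c), stats))
    return pts


def _deposit_concentration(
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    deposit_volume_ml: float,
    model: str,
    rng: np.random.Generator,
    n_foci: int = 3,
) -> np.ndarray:
    """Unnormalized spatial weight field for the deposit (scaled later)."""
    xs, ys, zs = grid.center_coords()
    r_mm = (3.0 * deposit_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if model == "uniform_sphere":
        r2 = (xs - center_mm[0]) ** 2 + (ys - center_mm[1]) ** 2 + (zs - center_mm[2]) ** 2
        w = (r2 <= r_mm**2).astype(float)
    elif model == "gaussian_blob":
        sigma = r_mm / 1.5
        r2 = (xs - center_mm[0]) ** 2 + (ys - center_mm[1]) ** 2 + (zs - center_mm[2]) ** 2
        w = np.exp(-r2 / (2.0 * sigma**2))
        w = np.broadcast_to(w, grid.shape).copy()
        w[w < 1e-4 * w.max()] = 0.0
    elif model == "multifocal":
        w = np.zeros(grid.shape)
        sigma = r_mm / 1.8
        for _ in range(n_foci):
            off = rng.uniform(-r_mm, r_mm, 3)
            r2 = (
                (xs - center_mm[0] - off[0]) ** 2
                + (ys - center_mm[1] - off[1]) ** 2
                + (zs - center_mm[2] - off[2]) ** 2
            )
            w = w + np.exp(-r2 / (2.0 * sigma**2))
        w[w < 1e-4 * w.max()] = 0.0
    else:
        raise ValueError(f"unknown deposit model {model!r}")
    w = np.broadcast_to(w, grid.shape).copy()
    if not w.any():
        raise ValueError("deposit contains no voxels on this grid")
    return w


def simulate_injection_phantom(
    deposit_ms_mg: float = 7.5,
    deposit_volume_ml: float = 0.3,
    curve: CalibrationCurve | None = None,
    size_mm: tuple[float, float, float] = (50.0, 50.0, 40.0),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    background_hu: float | None = None,
    noise_sd: float = 10.0,
    baseline_shift_hu: float = 0.0,
    deposit_model: str = "uniform_sphere",
    edge_blur_sigma_mm: float = 0.0,
    ho_content_fraction: float = HO_MS_CONTENT_FRACTION,
    hu_limits: tuple[float, float] = (-1024.0, 3071.0),
    seed: int = 0,
) -> tuple[CTVolume, CTVolume, GroundTruth]:
    """Simulate a pre/post-injection scan pair of a tissue sample.

    The post scan adds b·c(voxel) HU on top of the (optionally shifted)
    baseline; c is scaled so the voxelized deposit mass equals
    ``deposit_ms_mg`` exactly.  ``background_hu`` defaults to the
    calibration intercept m, which makes both the subtraction and the
    threshold intercept conventions exact on noise-free data.

    Returns (pre, post, truth); the truth masks include the deposit, a
    quantification VOI around it, and a deposit-free reference VOI.
    """
    if deposit_ms_mg <= 0:
        raise ValueError("deposit mass must be positive")
    curve = curve or default_calibration_curve()
    if background_hu is None:
        background_hu = curve.intercept_m
    shape = tuple(int(round(s / sp)) + 1 for s, sp in zip(size_mm, spacing_mm))
    grid = VoxelGrid(spacing_mm, (0.0, 0.0, 0.0), shape)
    center = tuple(s / 2.0 for s in size_mm)
    rng = np.random.default_rng(seed)

    w = _deposit_concentration(grid, center, deposit_volume_ml, deposit_model, rng)
    if edge_blur_sigma_mm > 0:
        w = ndimage.gaussian_filter(w, [edge_blur_sigma_mm / s for s in spacing_mm])
    ho_mg = deposit_ms_mg * ho_content_fraction
    conc = w * (ho_mg / (w.sum() * grid.voxel_volume_ml))  # mg/mL, exact total

    pre_clean = np.full(grid.shape, float(background_hu))
    post_clean = pre_clean + baseline_shift_hu + curve.slope_b * conc
    if noise_sd > 0:
        pre_noisy = pre_clean + rng.normal(0.0, noise_sd, grid.shape)
        post_noisy = post_clean + rng.normal(0.0, noise_sd, grid.shape)
    else:
        pre_noisy, post_noisy = pre_clean, post_clean

    meta = {"phantom": "injection_sample", "seed": seed, **curve.metadata}
    pre = _clip_volume(pre_noisy, grid, hu_limits, dict(meta, scan="pre"))
    post = _clip_volume(post_noisy, grid, hu_limits, dict(meta, scan="post"))

    deposit_mask = VOIMask(grid, conc > 0)
    r_dep = (3.0 * deposit_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    xs, ys, zs = grid.center_coords()
    r2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
    voi = VOIMask(grid, np.broadcast_to(r2 <= (r_dep + 8.0) ** 2, grid.shape).copy())
    ref_box = (
        (xs >= 2.0) & (xs <= 12.0) & (ys >= 2.0) & (ys <= 12.0)
        & (zs >= 2.0) & (zs <= size_mm[2] - 2.0)
    )
    ref = VOIMask(grid, np.broadcast_to(ref_box, grid.shape) & ~voi.included & ~deposit_mask.included)
    truth = GroundTruth(
        conc_map=conc,
        ho_mg=float(conc.sum() * grid.voxel_volume_ml),
        ms_mg=float(conc.sum() * grid.voxel_volume_ml / ho_content_fraction),
        masks={"deposit": deposit_mask, "voi": voi, "reference": ref},
    )
    return pre, post, truth


def simulate_patient_like(
    tumor_axes_cm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    planned_ms_mg_per_cm3: float = 5.0,
    curve: CalibrationCurve | None = None,
    background_hu: float | None = None,
    noise_sd: float = 10.0,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_foci: int = 3,
    ho_content_fraction: float = HO_MS_CONTENT_FRACTION,
    hu_limits: tuple[float, float] = (-1024.0, 3071.0),
    seed: int = 0,
) -> tuple[CTVolume, CTVolume, GroundTruth]:
    """Simulate a patient-like case: ellipsoidal tumor, multifocal deposit,
    bone-like distractors outside the VOI.

    The planned microsphere mass is ``planned_ms_mg_per_cm3`` times the
    analytic ellipsoid tumor volume (π/6 · l·w·h); the deposited truth mass
    equals the plan exactly.
    """
    curve = curve or default_calibration_curve()
    if background_hu is None:
        background_hu = curve.intercept_m
    axes_mm = tuple(a * 10.0 for a in tumor_axes_cm)
    size_mm = tuple(a + 40.0 for a in axes_mm)
    shape = tuple(int(round(s / sp)) + 1 for s, sp in zip(size_mm, spacing_mm))
    grid = VoxelGrid(spacing_mm, (0.0, 0.0, 0.0), shape)
    center = tuple(s / 2.0 for s in size_mm)
    rng = np.random.default_rng(seed)

    xs, ys, zs = grid.center_coords()
    ell = (
        ((xs - center[0]) / (axes_mm[0] / 2.0)) ** 2
        + ((ys - center[1]) / (axes_mm[1] / 2.0)) ** 2
        + ((zs - center[2]) / (axes_mm[2] / 2.0)) ** 2
    ) <= 1.0
    tumor = VOIMask(grid, np.broadcast_to(ell, grid.shape).copy())

    tumor_volume_cm3 = ellipsoid_volume(*tumor_axes_cm)
    planned_ms_mg = planned_ms_mg_per_cm3 * tumor_volume_cm3
    ho_mg = planned_ms_mg * ho_content_fraction

    # multifocal deposit constrained to the tumor
    sigma = min(axes_mm) / 6.0
    w = np.zeros(grid.shape)
    for _ in range(n_foci):
        off = rng.uniform(-0.25, 0.25, 3) * np.array(axes_mm)
        r2 = (
            (xs - center[0] - off[0]) ** 2
            + (ys - center[1] - off[1]) ** 2
            + (zs - center[2] - off[2]) ** 2
        )
        w = w + np.exp(-r2 / (2.0 * sigma**2))
    w[~tumor.included] = 0.0
    w[w < 1e-4 * w.max()] = 0.0
    if not w.any():
        raise ValueError("deposit weight field is empty")
    conc = w * (ho_mg / (w.sum() * grid.voxel_volume_ml))

    pre_clean = np.full(grid.shape, float(background_hu))
    # bone-like distractors: two spheres near the volume edge, outside the VOI
    bone = np.zeros(grid.shape, dtype=bool)
    for bc in ((8.0, 8.0, center[2]), (size_mm[0] - 8.0, size_mm[1] - 8.0, center[2])):
        r2 = (xs - bc[0]) ** 2 + (ys - bc[1]) ** 2 + (zs - bc[2]) ** 2
        bone |= np.broadcast_to(r2 <= 5.0**2, grid.shape)
    bone &= ~tumor.included
    pre_clean[bone] = 1000.0
    post_clean = pre_clean + curve.slope_b * conc
    if noise_sd > 0:
        pre_noisy = pre_clean + rng.normal(0.0, noise_sd, grid.shape)
        post_noisy = post_clean + rng.normal(0.0, noise_sd, grid.shape)
    else:
        pre_noisy, post_noisy = pre_clean, post_clean

    meta = {"phantom": "patient_like", "seed": seed, **curve.metadata}
    pre = _clip_volume(pre_noisy, grid, hu_limits, dict(meta, scan="pre"))
    post = _clip_volume(post_noisy, grid, hu_limits, dict(meta, scan="post"))

    ref_box = (
        (xs >= 2.0) & (xs <= 14.0) & (ys >= size_mm[1] - 14.0) & (ys <= size_mm[1] - 2.0)
        & (zs >= 2.0) & (zs <= size_mm[2] - 2.0)
    )
    ref = VOIMask(grid, np.broadcast_to(ref_box, grid.shape) & ~tumor.included & ~bone)
    truth = GroundTruth(
        conc_map=conc,
        ho_mg=float(conc.sum() * grid.voxel_volume_ml),
        ms_mg=float(conc.sum() * grid.voxel_volume_ml / ho_content_fraction),
        masks={
            "tumor": tumor,
            "voi": tumor,
            "deposit": VOIMask(grid, conc > 0),
            "bone": VOIMask(grid, bone),
            "reference": ref,
        },
        table=pd.DataFrame(
            {
                "tumor_volume_cm3": [tumor_volume_cm3],
                "planned_ms_mg": [planned_ms_mg],
                "planned_ho_mg": [ho_mg],
            }
        ),
    )
    return pre, post, truth
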