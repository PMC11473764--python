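"""Subtraction and threshold quantification of Ho deposits on CT.

Two families of operators extract the microsphere-attributable radiodensity
HU_Ho from a post-injection scan given the baseline radiodensity
HU_reference of tissue without microspheres:

*Subtraction* removes the single reference value from every voxel of the
quantification VOI, ``HU_Ho = post − HU_reference``, in three variants that
differ in how negative values are treated:

- ``s-minus`` (S−): all values kept, including negatives;
- ``s`` (S): post values below 0 HU are set to 0 before subtracting, so
  HU_Ho ≥ −HU_reference (air-like voxels are treated as empty tissue);
- ``s-plus`` (S+): voxels with HU_Ho < 0 are dropped from the contributing
  mask entirely.

*Thresholding* keeps voxels whose post HU strictly exceeds a threshold —
the reference mean (T), the mean plus k·SD (T1SD..T3SD), or a fixed 50 or
100 HU — and converts their *full* HU value.  Because conversion subtracts
the calibration intercept, a threshold below the intercept would yield
negative concentrations; the intercept therefore acts as a floor on the
effective threshold whenever it is applied.

Converted concentration maps are turned into radioactivity maps via the
microsphere Ho content and specific activity, and compared with the
injected amount (dose-calibrator readings decay-corrected to scan time) as
a recovery percentage; 70–130% is the protocol's sufficiency band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Literal

import numpy as np

from hoct.calibration import CalibrationCurve
from hoct.nuclide import DECAY_CONSTANT_PER_S, HO_MS_CONTENT_FRACTION
from hoct.volumes import CTVolume, VOIMask, VoxelGrid

__all__ = [
    "ReferenceStats",
    "InjectionRecord",
    "QuantResult",
    "SUBTRACTION_VARIANTS",
    "THRESHOLD_KINDS",
    "quantify_subtraction",
    "quantify_threshold",
    "concentration_map",
    "activity_map",
    "decay_correct",
    "injected_amount",
    "recovery",
    "volume_fraction",
    "ellipsoid_volume",
    "quantify",
]

SUBTRACTION_VARIANTS = ("s-minus", "s", "s-plus")
THRESHOLD_KINDS = ("t", "t1sd", "t2sd", "t3sd", "t50", "t100")


@dataclass(frozen=True)
class ReferenceStats:
    """Baseline tissue radiodensity from a reference VOI without Ho-MS."""

    hu_reference: float
    sd: float
    source: Literal["pre", "post"] = "pre"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("reference SD must be non-negative")


def _to_seconds(t) -> float:
    if isinstance(t, datetime):
        return t.timestamp()
    if isinstance(t, str):
        return datetime.fromisoformat(t).timestamp()
    return float(t)


@dataclass
class InjectionRecord:
    """Dose-calibrator measurements bracketing an injection.

    ``activity_before``/``activity_after`` are the vial activities (Bq) at
    ``time_before``/``time_after``; their decay-corrected difference at scan
    time is the injected activity.  ``specific_activity`` is Bq per mg of
    microspheres at ``specific_activity_time`` (defaults to scan time), and
    ``ho_content_fraction`` the elemental-Ho mass fraction of the
    microspheres (0.197 for Ho-PLLA microspheres).

    Times may be datetimes, ISO strings, or plain seconds.
    """

    activity_before: float
    activity_after: float
    time_before: object
    time_after: object
    scan_time: object
    specific_activity: float  # Bq / mg microspheres
    specific_activity_time: object | None = None
    ho_content_fraction: float = HO_MS_CONTENT_FRACTION
    decay_constant: float = DECAY_CONSTANT_PER_S

    def __post_init__(self) -> None:
        if not (0.0 < self.ho_content_fraction <= 1.0):
            raise ValueError("ho_content_fraction must be in (0, 1]")
        if self.activity_after < 0 or self.activity_before < self.activity_after:
            raise ValueError("need activity_before >= activity_after >= 0")
        if self.specific_activity <= 0:
            raise ValueError("specific activity must be positive")

    def specific_activity_at_scan(self) -> float:
        """Specific activity (Bq/mg) decayed to scan time (mass is stable)."""
        t_ref = self.specific_activity_time
        if t_ref is None:
            return self.specific_activity
        dt = _to_seconds(self.scan_time) - _to_seconds(t_ref)
        return self.specific_activity * math.exp(-self.decay_constant * dt)


@dataclass
class QuantResult:
    """Per-voxel quantification maps plus summary totals.

    ``huho_map`` holds HU_Ho on contributing voxels (0 elsewhere);
    ``concentration_map`` is mg elemental Ho per mL; ``activity_map`` is Bq
    per voxel (present only when an injection record was supplied).
    Totals carry units in their names: elemental-Ho mg, microsphere mg, Bq.
    """

    method: str
    grid: VoxelGrid
    huho_map: np.ndarray
    contributing: VOIMask
    voi: VOIMask
    concentration_map: np.ndarray | None = None
    activity_map: np.ndarray | None = None
    total_ho_mg: float | None = None
    total_ms_mg: float | None = None
    total_bq: float | None = None
    effective_threshold: float | None = None


def quantify_subtraction(
    post: CTVolume,
    voi: VOIMask,
    ref: ReferenceStats,
    variant: str = "s-minus",
) -> QuantResult:
    """Subtraction quantifier: HU_Ho = post HU − HU_reference over the VOI."""
    if variant not in SUBTRACTION_VARIANTS:
        raise ValueError(f"unknown subtraction variant {variant!r}")
    if voi.grid != post.grid:
        raise ValueError("VOI grid does not match volume grid")
    if voi.n_voxels == 0:
        raise ValueError("quantification VOI is empty")
    post_vals = post.values
    if variant == "s":
        post_vals = np.maximum(post_vals, 0.0)
    huho = np.zeros(post.grid.shape)
    huho[voi.included] = post_vals[voi.included] - ref.hu_reference
    contributing = voi.included.copy()
    if variant == "s-plus":
        contributing &= huho >= 0.0
        huho[~contributing] = 0.0
    return QuantResult(
        method=variant,
        grid=post.grid,
        huho_map=huho,
        contributing=VOIMask(post.grid, contributing),
        voi=voi,
    )


def quantify_threshold(
    post: CTVolume,
    voi: VOIMask,
    kind: str,
    curve: CalibrationCurve,
    ref: ReferenceStats | None = None,
) -> QuantResult:
    """Threshold quantifier: keep VOI voxels with post HU > threshold.

    The effective threshold is raised to the calibration intercept when the
    intercept is applied (not forced to zero), which guarantees non-negative
    converted concentrations.  Contributing voxels keep their full post HU
    as HU_Ho.  An all-excluded VOI is a valid empty result.
    """
    if kind not in THRESHOLD_KINDS:
        raise ValueError(f"unknown threshold kind {kind!r}")
    if voi.grid != post.grid:
        raise ValueError("VOI grid does not match volume grid")
    if kind == "t50":
        threshold = 50.0
    elif kind == "t100":
        threshold = 100.0
    else:
        if ref is None:
            raise ValueError(f"threshold kind {kind!r} requires reference stats")
        k = {"t": 0, "t1sd": 1, "t2sd": 2, "t3sd": 3}[kind]
        threshold = ref.hu_reference + k * ref.sd
    intercept = 0.0 if curve.forced_zero else curve.intercept_m
    effective = max(threshold, intercept)
    contributing = voi.included & (post.values > effective)
    huho = np.zeros(post.grid.shape)
    huho[contributing] = post.values[contributing]
    return QuantResult(
        method=kind,
        grid=post.grid,
        huho_map=huho,
        contributing=VOIMask(post.grid, contributing),
        voi=voi,
        effective_threshold=float(effective),
    )


def concentration_map(result: QuantResult, curve: CalibrationCurve) -> np.ndarray:
    """Convert HU_Ho to mg Ho/mL per contributing voxel.

    Threshold methods convert the full voxel HU via (HU − m)/b (m = 0 for
    forced-zero curves).  Subtraction methods convert via HU_Ho/b only: the
    measured reference already removed the baseline, and subtracting the
    fitted intercept as well would remove baseline twice.
    """
    conc = np.zeros(result.grid.shape)
    inc = result.contributing.included
    if result.method in THRESHOLD_KINDS:
        m = 0.0 if curve.forced_zero else curve.intercept_m
        conc[inc] = (result.huho_map[inc] - m) / curve.slope_b
    else:
        conc[inc] = result.huho_map[inc] / curve.slope_b
    result.concentration_map = conc
    result.total_ho_mg = float(conc[inc].sum() * result.grid.voxel_volume_ml)
    result.total_ms_mg = None
    return conc


def activity_map(
    conc_map: np.ndarray,
    grid: VoxelGrid,
    record: InjectionRecord,
    contributing: VOIMask | None = None,
) -> np.ndarray:
    """Per-voxel ¹⁶⁶Ho-MS activity A = c·V_voxel / Ho-content × specific activity.

    ``c·V_voxel`` is the elemental-Ho mass in the voxel; dividing by the
    microsphere Ho content fraction converts it to microsphere mass, which
    the specific activity (Bq/mg at scan time) turns into becquerels.
    """
    conc = np.asarray(conc_map, dtype=float)
    ho_mg = conc * grid.voxel_volume_ml
    ms_mg = ho_mg / record.ho_content_fraction
    act = ms_mg * record.specific_activity_at_scan()
    if contributing is not None:
        act = np.where(contributing.included, act, 0.0)
    return act


def decay_correct(
    activity_bq: float,
    elapsed_s: float,
    direction: Literal["forward", "back"] = "forward",
    decay_constant: float = DECAY_CONSTANT_PER_S,
) -> float:
    """Physical-decay correction over ``elapsed_s`` seconds.

    ``forward`` propagates an activity later in time (A·e^{−λt}); ``back``
    refers it to an earlier time (A·e^{+λt}).
    """
    if elapsed_s < 0:
        raise ValueError("elapsed time must be non-negative")
    sign = -1.0 if direction == "forward" else 1.0
    return float(activity_bq * math.exp(sign * decay_constant * elapsed_s))


def injected_amount(record: InjectionRecord) -> tuple[float, float]:
    """Injected microsphere mass (mg) and activity (Bq) at scan time.

    Both dose-calibrator readings are decay-corrected to the scan moment
    before subtracting; the mass conversion uses the specific activity at
    scan time so that mg and Bq stay consistent.
    """
    lam = record.decay_constant
    t_scan = _to_seconds(record.scan_time)
    before = record.activity_before * math.exp(-lam * (t_scan - _to_seconds(record.time_before)))
    after = record.activity_after * math.exp(-lam * (t_scan - _to_seconds(record.time_after)))
    injected_bq = before - after
    if injected_bq < 0:
        raise ValueError(
            "decay-corrected injected activity is negative; "
            "check measurement times and values"
        )
    injected_ms_mg = injected_bq / record.specific_activity_at_scan()
    return injected_ms_mg, injected_bq


def recovery(result: QuantResult, injected_ms_mg: float) -> tuple[float, bool]:
    """Recovered fraction, 100 × quantified / injected microsphere mg.

    The accompanying flag is True when recovery lies in the 70–130%
    sufficiency band.
    """
    if injected_ms_mg <= 0:
        raise ValueError("injected mass must be positive")
    if result.total_ms_mg is None:
        if result.total_ho_mg is None:
            raise ValueError("result has no concentration totals; run concentration_map first")
        quantified = result.total_ho_mg / HO_MS_CONTENT_FRACTION
    else:
        quantified = result.total_ms_mg
    pct = 100.0 * quantified / injected_ms_mg
    return pct, bool(70.0 <= pct <= 130.0)


def volume_fraction(result: QuantResult, voi: VOIMask | None = None) -> float:
    """Percent of quantification-VOI voxels contributing to the recovery."""
    voi = voi if voi is not None else result.voi
    if voi.n_voxels == 0:
        raise ValueError("VOI is empty")
    inc = (result.contributing.included & voi.included).sum()
    return 100.0 * float(inc) / voi.n_voxels


def ellipsoid_volume(length_cm: float, width_cm: float, height_cm: float) -> float:
    """Tumor volume (cm³) from the three largest diameters: (π/6)·l·w·h."""
    if length_cm <= 0 or width_cm <= 0 or height_cm <= 0:
        raise ValueError("all ellipsoid dimensions must be positive")
    return math.pi / 6.0 * length_cm * width_cm * height_cm


def quantify(
    post: CTVolume,
    voi: VOIMask,
    method: str,
    curve: CalibrationCurve,
    ref: ReferenceStats | None = None,
    record: InjectionRecord | None = None,
) -> QuantResult:
    """One-call quantification: HU_Ho map → concentration → activity → totals."""
    if method in SUBTRACTION_VARIANTS:
        if ref is None:
            raise ValueError("subtraction methods require reference stats")
        result = quantify_subtraction(post, voi, ref, method)
    elif method in THRESHOLD_KINDS:
        result = quantify_threshold(post, voi, method, curve, ref)
    else:
        raise ValueError(f"unknown quantification method {method!r}")
    concentration_map(result, curve)
    result.total_ms_mg = (
        result.total_ho_mg / (record.ho_content_fraction if record else HO_MS_CONTENT_FRACTION)
    )
    if record is not None:
        result.activity_map = activity_map(
            result.concentration_map, result.grid, record, result.contributing
        )
        result.total_bq = float(result.activity_map.sum())
    return result
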