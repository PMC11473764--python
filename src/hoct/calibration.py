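"""Linear HU-vs-concentration calibration.

A calibration phantom holds tubes of known Ho concentration; the mean HU of
a cylindrical analysis VOI in each tube responds linearly to concentration,

    HU = m + b · c(mg Ho/mL),

so an ordinary least-squares fit of tube mean HU on concentration yields
the intercept ``m`` and slope ``b`` used to convert voxel HU values to
concentrations.  Two protocol rules accompany the fit: tubes whose maximum
HU exceeds the scanner's detection limit are excluded (the response clips
and is no longer linear), and the line is refit through the origin when the
intercept's standard error exceeds the intercept itself (the intercept is
then statistically indistinguishable from zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from hoct.volumes import VOIStats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "exclude_saturated",
    "fit_calibration",
    "predict_hu",
    "hu_to_concentration",
    "points_to_table",
    "points_from_table",
    "save_curve",
    "load_curve",
]


@dataclass
class CalibrationPoint:
    """One calibration tube: its true concentration and measured VOI stats."""

    concentration: float  # mg elemental Ho per mL
    stats: VOIStats
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class CalibrationCurve:
    """Fitted linear map between HU and mg Ho/mL with OLS diagnostics.

    For forced-zero fits ``r_squared`` follows the uncentered convention
    (1 − RSS/Σy²), as is standard for through-origin regression.
    """

    intercept_m: float
    slope_b: float
    forced_zero: bool = False
    r_squared: float = float("nan")
    f_stat: float = float("nan")
    std_error_m: float = float("nan")
    std_error_b: float = float("nan")
    p_value: float = float("nan")
    n_points: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("calibration slope must be positive")
        if self.forced_zero and self.intercept_m != 0.0:
            raise ValueError("forced-zero curve must have zero intercept")

    # convenience wrappers
    def predict_hu(self, concentration: float) -> float:
        return predict_hu(self, concentration)

    def hu_to_concentration(self, hu):
        return hu_to_concentration(self, hu)


def exclude_saturated(
    points: list[CalibrationPoint], hu_max_limit: float
) -> list[CalibrationPoint]:
    """Drop tubes whose HU_max exceeds the detection limit (strictly).

    Returns the retained points; excluded ones are flagged ``saturated``
    in place.  At least two points must survive for a fit to be possible.
    """
    if not points:
        raise ValueError("no calibration points supplied")
    kept: list[CalibrationPoint] = []
    for p in points:
        if p.stats.max_hu > hu_max_limit:
            p.saturated = True
        else:
            p.saturated = False
            kept.append(p)
    if len(kept) < 2:
        raise ValueError(
            f"fewer than 2 calibration points remain below the detection limit "
            f"{hu_max_limit} HU"
        )
    return kept


def _ols_normal_equations(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-parameter OLS via the normal equations, with textbook diagnostics."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    b = sxy / sxx
    m = ybar - b * xbar
    resid = y - (m + b * x)
    rss = (resid**2).sum()
    tss = ((y - ybar) ** 2).sum()
    dof = n - 2
    if dof > 0:
        sigma2 = rss / dof
        se_b = float(np.sqrt(sigma2 / sxx))
        se_m = float(np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx)))
    else:
        sigma2, se_b, se_m = 0.0, 0.0, 0.0
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if dof > 0 and rss > 0:
        f = (tss - rss) / (rss / dof)
        p = float(sps.f.sf(f, 1, dof))
    else:
        f, p = float("inf"), 0.0
    return dict(m=m, b=b, se_m=se_m, se_b=se_b, r2=r2, f=f, p=p)


def _ols_through_origin(x: np.ndarray, y: np.ndarray) -> dict:
    n = x.size
    sxx = (x**2).sum()
    b = (x * y).sum() / sxx
    resid = y - b * x
    rss = (resid**2).sum()
    tss_uncentered = (y**2).sum()
    dof = n - 1
    sigma2 = rss / dof if dof > 0 else 0.0
    se_b = float(np.sqrt(sigma2 / sxx))
    r2 = 1.0 - rss / tss_uncentered if tss_uncentered > 0 else float("nan")
    if dof > 0 and rss > 0:
        f = (tss_uncentered - rss) / (rss / dof)
        p = float(sps.f.sf(f, 1, dof))
    else:
        f, p = float("inf"), 0.0
    return dict(b=b, se_b=se_b, r2=r2, f=f, p=p)


def fit_calibration(
    points: list[CalibrationPoint], metadata: dict | None = None
) -> CalibrationCurve:
    """OLS fit of tube mean HU on concentration, with the forced-zero rule.

    If the intercept's standard error exceeds its magnitude, the line is
    refit through the origin and ``forced_zero`` is set; the through-origin
    R² uses the uncentered total sum of squares.
    """
    pts = [p for p in points if not p.saturated]
    if len(pts) < 2:
        raise ValueError("need at least 2 unsaturated calibration points")
    x = np.array([p.concentration for p in pts], dtype=float)
    y = np.array([p.stats.mean_hu for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all concentrations are equal; slope is not identifiable")
    fit = _ols_normal_equations(x, y)
    forced = fit["se_m"] > abs(fit["m"])
    if forced:
        fz = _ols_through_origin(x, y)
        return CalibrationCurve(
            intercept_m=0.0,
            slope_b=float(fz["b"]),
            forced_zero=True,
            r_squared=float(fz["r2"]),
            f_stat=float(fz["f"]),
            std_error_m=0.0,
            std_error_b=float(fz["se_b"]),
            p_value=float(fz["p"]),
            n_points=len(pts),
            metadata=dict(metadata or {}),
        )
    return CalibrationCurve(
        intercept_m=float(fit["m"]),
        slope_b=float(fit["b"]),
        forced_zero=False,
        r_squared=float(fit["r2"]),
        f_stat=float(fit["f"]),
        std_error_m=float(fit["se_m"]),
        std_error_b=float(fit["se_b"]),
        p_value=float(fit["p"]),
        n_points=len(pts),
        metadata=dict(metadata or {}),
    )


def predict_hu(curve: CalibrationCurve, concentration) -> float:
    """Forward model HU = m + b·c for c ≥ 0."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = curve.intercept_m + curve.slope_b * c
    return float(out) if out.ndim == 0 else out


def hu_to_concentration(curve: CalibrationCurve, hu):
    """Inverse model c = (HU − m)/b; may be negative (callers decide clamping)."""
    h = np.asarray(hu, dtype=float)
    out = (h - curve.intercept_m) / curve.slope_b
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# I/O: CSV calibration tables and JSON curves
# ---------------------------------------------------------------------------

def points_to_table(points: list[CalibrationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "concentration_mg_per_ml": [p.concentration for p in points],
            "mean_hu": [p.stats.mean_hu for p in points],
            "sd_hu": [p.stats.sd_hu for p in points],
            "min_hu": [p.stats.min_hu for p in points],
            "max_hu": [p.stats.max_hu for p in points],
            "n_voxels": [p.stats.n_voxels for p in points],
        }
    )


def points_from_table(table: pd.DataFrame | str | Path) -> list[CalibrationPoint]:
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    pts = []
    for _, row in table.iterrows():
        mean = float(row["mean_hu"])
        sd = float(row["sd_hu"])
        n = int(row.get("n_voxels", 1))
        half = 1.96 * sd / np.sqrt(max(n, 1))
        stats = VOIStats(
            mean_hu=mean,
            sd_hu=sd,
            min_hu=float(row.get("min_hu", mean)),
            max_hu=float(row["max_hu"]),
            ci95=(mean - half, mean + half),
            n_voxels=n,
        )
        pts.append(CalibrationPoint(float(row["concentration_mg_per_ml"]), stats))
    return pts


def save_curve(curve: CalibrationCurve, path: str | Path) -> None:
    payload = {
        "intercept_m_hu": curve.intercept_m,
        "slope_b_hu_per_mg_ml": curve.slope_b,
        "forced_zero": curve.forced_zero,
        "r_squared": curve.r_squared,
        "f_stat": curve.f_stat,
        "std_error_m": curve.std_error_m,
        "std_error_b": curve.std_error_b,
        "p_value": curve.p_value,
        "n_points": curve.n_points,
        "metadata": curve.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_curve(path: str | Path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(
        intercept_m=float(d["intercept_m_hu"]),
        slope_b=float(d["slope_b_hu_per_mg_ml"]),
        forced_zero=bool(d["forced_zero"]),
        r_squared=float(d["r_squared"]),
        f_stat=float(d["f_stat"]),
        std_error_m=float(d["std_error_m"]),
        std_error_b=float(d["std_error_b"]),
        p_value=float(d["p_value"]),
        n_points=int(d["n_points"]),
        metadata=dict(d.get("metadata", {})),
    )
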