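"""¹⁶⁶Ho dose-point-kernel generation, convolution dosimetry and DVHs.

The dose point kernel (DPK) is the expected energy (eV) deposited per decay
in each voxel of a grid around a point source in uniform soft tissue.
Convolving the voxel radioactivity map A (Bq = decays/s) with the DPK gives
the energy deposition rate E (eV/s); dividing by the decay constant λ
integrates the exponentially decaying activity to infinite time, and the
usual unit conversions turn deposited energy per voxel mass into absorbed
dose in gray:

    E(eV/s)      = A(s⁻¹) ⊗ DPK(eV)
    D_voxel(Gy)  = E/λ × 1.602e−19 (J/eV) / (ρ(kg/L) × V_voxel(L))

The built-in kernel generator is a condensed-history Monte Carlo: beta
energies are sampled from allowed-shape spectra per branch, electrons lose
energy continuously along 0.1 mm steps of a CSDA range–energy relation
(Katz–Penfold in water) down to a 1 keV cutoff while their direction
diffuses by Fermi–Eyges multiple scattering (Rossi scattering power), and
photons fly exponential free paths with a water-like attenuation
coefficient and deposit at their first interaction.  Conversion/Auger
electrons and x-rays are lumped as a local deposit at the source voxel.
Bremsstrahlung is neglected.  A loader accepts externally computed
high-fidelity kernels for production use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from hoct.nuclide import (
    BETA_BRANCHES,
    DECAY_CONSTANT_PER_S,
    ENERGY_CUTOFF_KEV,
    LOCAL_COMPONENT,
    PHOTON_LINES,
)
from hoct.volumes import VOIMask, VoxelGrid, resample_trilinear

__all__ = [
    "EmissionSpectrum",
    "DosePointKernel",
    "DoseMap",
    "DVHCurve",
    "ho166_spectrum",
    "generate_dpk",
    "save_dpk",
    "load_dpk",
    "match_to_kernel_grid",
    "convolve_dose_rate",
    "cumulative_dose_map",
    "dvh",
    "kernel_radial_fraction",
]

EV_PER_MEV = 1.0e6
J_PER_EV = 1.602176634e-19
_ELECTRON_REST_MEV = 0.511
_RADIATION_LENGTH_WATER_G_CM2 = 36.08
_ROSSI_ES_MEV = 21.2  # scattering-power constant
_MU_PER_RHO_80KEV_CM2_G = 0.1837  # water, total attenuation at 80 keV
_STEP_MM = 0.1


@dataclass(frozen=True)
class EmissionSpectrum:
    """Decay emissions: beta branches, photon lines, lumped local component.

    ``beta_branches`` and ``photon_lines`` are sequences of
    (energy MeV, yield per decay); for betas the energy is the branch
    endpoint.  ``local_component`` is a (mean MeV, yield) pair deposited at
    the source voxel (sub-voxel-range conversion/Auger electrons and
    x-rays).
    """

    beta_branches: tuple[tuple[float, float], ...]
    photon_lines: tuple[tuple[float, float], ...] = ()
    local_component: tuple[float, float] = (0.0, 0.0)
    cutoff_kev: float = ENERGY_CUTOFF_KEV

    def __post_init__(self) -> None:
        for e, y in (*self.beta_branches, *self.photon_lines, self.local_component):
            if e < 0 or y < 0:
                raise ValueError("energies and yields must be non-negative")
        if self.cutoff_kev < 1.0:
            raise ValueError("transport cutoff below 1 keV is not supported")

    def total_emitted_mev_per_decay(self) -> float:
        """Mean emitted energy per decay (beta branches use the spectrum mean)."""
        total = 0.0
        for q, y in self.beta_branches:
            total += y * _allowed_spectrum_mean(q)
        for e, y in self.photon_lines:
            total += y * e
        total += self.local_component[0] * self.local_component[1]
        return total


def ho166_spectrum() -> EmissionSpectrum:
    """The ¹⁶⁶Ho emission model used throughout the package."""
    return EmissionSpectrum(
        beta_branches=BETA_BRANCHES,
        photon_lines=PHOTON_LINES,
        local_component=LOCAL_COMPONENT,
        cutoff_kev=ENERGY_CUTOFF_KEV,
    )


@dataclass
class DosePointKernel:
    """Expected energy deposition per decay (eV per voxel) around a point source."""

    energy_ev: np.ndarray
    grid: VoxelGrid
    center_index: tuple[int, int, int]
    medium_density: float  # kg/L
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy_ev = np.asarray(self.energy_ev, dtype=float)
        if tuple(self.energy_ev.shape) != self.grid.shape:
            raise ValueError("kernel array shape does not match grid")
        if np.any(self.energy_ev < 0):
            raise ValueError("kernel energies must be non-negative")
        if self.medium_density <= 0:
            raise ValueError("medium density must be positive")
        expected_center = tuple(n // 2 for n in self.grid.shape)
        if tuple(self.center_index) != expected_center:
            raise ValueError(
                f"center_index {self.center_index} is not the array center {expected_center}"
            )

    @property
    def total_energy_ev(self) -> float:
        return float(self.energy_ev.sum())


@dataclass
class DoseMap:
    """Cumulative absorbed dose (Gy) per voxel in a uniform-density medium."""

    dose_gy: np.ndarray
    grid: VoxelGrid
    density: float

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if tuple(self.dose_gy.shape) != self.grid.shape:
            raise ValueError("dose array shape does not match grid")
        if np.any(self.dose_gy < 0):
            raise ValueError("dose must be non-negative everywhere")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: % of VOI at or above each dose."""

    dose_gy: np.ndarray
    volume_percent: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_percent = np.asarray(self.volume_percent, dtype=float)
        if np.any(np.diff(self.volume_percent) > 1e-9):
            raise ValueError("DVH volume percentages must be non-increasing")


# ---------------------------------------------------------------------------
# Electron range–energy relation and beta spectra
# ---------------------------------------------------------------------------

def _katz_penfold_range_g_cm2(energy_mev: np.ndarray) -> np.ndarray:
    """Empirical CSDA range in low-Z media (g/cm²), valid 0.01–2.5 MeV."""
    e = np.asarray(energy_mev, dtype=float)
    n = 1.265 - 0.0954 * np.log(np.maximum(e, 1e-6))
    return 0.412 * np.maximum(e, 0.0) ** n


_E_TABLE = np.linspace(1e-4, 3.0, 30001)
_R_TABLE = _katz_penfold_range_g_cm2(_E_TABLE)


def _energy_from_range(range_g_cm2: np.ndarray) -> np.ndarray:
    return np.interp(range_g_cm2, _R_TABLE, _E_TABLE, left=0.0)


def _allowed_beta_pdf(e: np.ndarray, q: float) -> np.ndarray:
    """Unnormalized allowed beta shape N(E) ∝ p·W·(Q−E)², no Fermi correction."""
    w = e + _ELECTRON_REST_MEV
    p = np.sqrt(np.maximum(w**2 - _ELECTRON_REST_MEV**2, 0.0))
    return np.where((e >= 0) & (e <= q), p * w * (q - e) ** 2, 0.0)


def _allowed_spectrum_mean(q: float) -> float:
    e = np.linspace(0.0, q, 4000)
    w = _allowed_beta_pdf(e, q)
    return float(np.trapezoid(w * e, e) / np.trapezoid(w, e))


def _sample_allowed_beta(q: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample kinetic energies from the allowed spectrum of endpoint q."""
    if n == 0:
        return np.empty(0)
    grid = np.linspace(0.0, q, 2000)
    wmax = _allowed_beta_pdf(grid, q).max() * 1.01
    out = np.empty(0)
    while out.size < n:
        m = max(2 * (n - out.size), 1000)
        e = rng.uniform(0.0, q, m)
        keep = rng.uniform(0.0, wmax, m) < _allowed_beta_pdf(e, q)
        out = np.concatenate([out, e[keep]])
    return out[:n]


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - u**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def _deposit(grid: VoxelGrid, tally: np.ndarray, pos_mm: np.ndarray, energy_mev: np.ndarray) -> None:
    """Bin point deposits (positions relative to grid origin) into the tally."""
    idx = np.empty((pos_mm.shape[0], 3), dtype=np.int64)
    inside = np.ones(pos_mm.shape[0], dtype=bool)
    for a in range(3):
        f = (pos_mm[:, a] - grid.origin_mm[a]) / grid.spacing_mm[a]
        i = np.rint(f).astype(np.int64)
        idx[:, a] = i
        inside &= (i >= 0) & (i < grid.shape[a])
    if not inside.any():
        return
    flat = np.ravel_multi_index(
        (idx[inside, 0], idx[inside, 1], idx[inside, 2]), grid.shape
    )
    np.add.at(tally.reshape(-1), flat, energy_mev[inside])


def _transport_electrons(
    energies_mev: np.ndarray,
    grid: VoxelGrid,
    tally_mev: np.ndarray,
    density: float,
    cutoff_kev: float,
    rng: np.random.Generator,
) -> None:
    """Condensed-history electron transport from the grid center.

    Fixed 0.1 mm geometric steps; energy loss per step from the residual
    CSDA range; direction diffused each step by a multiple-scattering
    deflection with Rayleigh-distributed polar angle of scale
    θ₀ = E_s/(βpc)·√(ℓ/X₀) (Rossi), which reproduces the strong lateral
    diffusion that confines ~90% of the ¹⁶⁶Ho beta energy within 3 mm.
    """
    n = energies_mev.size
    if n == 0:
        return
    cutoff_mev = cutoff_kev * 1e-3
    step_g = _STEP_MM / 10.0 * density  # density kg/L == g/cm³
    pos = np.zeros((n, 3))
    d = _isotropic_directions(n, rng)
    e = energies_mev.copy()
    res_range = _katz_penfold_range_g_cm2(e)
    alive = e > cutoff_mev
    # sub-cutoff starters deposit locally
    if (~alive).any():
        _deposit(grid, tally_mev, pos[~alive], e[~alive])
    while alive.any():
        idx = np.where(alive)[0]
        new_range = res_range[idx] - step_g
        new_e = _energy_from_range(np.maximum(new_range, 0.0))
        below = new_e <= cutoff_mev
        new_e = np.where(below, 0.0, new_e)  # dump residual energy this step
        dep = e[idx] - new_e
        mid = pos[idx] + d[idx] * (_STEP_MM / 2.0)
        _deposit(grid, tally_mev, mid, dep)
        pos[idx] += d[idx] * _STEP_MM
        e[idx] = new_e
        res_range[idx] = np.maximum(new_range, 0.0)
        alive[idx] = ~below
        live = idx[~below]
        if live.size == 0:
            break
        # multiple-scattering deflection for survivors
        w = e[live] + _ELECTRON_REST_MEV
        pc = np.sqrt(np.maximum(w**2 - _ELECTRON_REST_MEV**2, 1e-12))
        beta = pc / w
        theta0 = _ROSSI_ES_MEV / (beta * pc) * np.sqrt(step_g / _RADIATION_LENGTH_WATER_G_CM2)
        theta0 = np.clip(theta0, 0.0, 1.0)
        u = rng.uniform(1e-12, 1.0, live.size)
        theta = np.clip(theta0 * np.sqrt(-2.0 * np.log(u)), 0.0, np.pi)
        phi = rng.uniform(0.0, 2.0 * np.pi, live.size)
        dz = d[live]
        helper = np.where(
            np.abs(dz[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
        )
        e1 = np.cross(dz, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(dz, e1)
        nd = (
            dz * np.cos(theta)[:, None]
            + (e1 * np.cos(phi)[:, None] + e2 * np.sin(phi)[:, None]) * np.sin(theta)[:, None]
        )
        d[live] = nd / np.linalg.norm(nd, axis=1, keepdims=True)


def _transport_photons(
    energy_mev: float,
    n: int,
    grid: VoxelGrid,
    tally_mev: np.ndarray,
    density: float,
    rng: np.random.Generator,
) -> None:
    """First-interaction photon deposition with a water-like μ scaled by density."""
    if n == 0 or energy_mev <= 0:
        return
    mu_per_mm = _MU_PER_RHO_80KEV_CM2_G * density / 10.0  # density kg/L == g/cm³
    d = _isotropic_directions(n, rng)
    path = rng.exponential(1.0 / mu_per_mm, n)
    pos = d * path[:, None]
    _deposit(grid, tally_mev, pos, np.full(n, energy_mev))


def generate_dpk(
    spectrum: EmissionSpectrum,
    grid: VoxelGrid | None = None,
    density: float = 1.06,
    n_histories: int = 1_000_000,
    seed: int = 0,
    batch_size: int = 200_000,
) -> DosePointKernel:
    """Monte Carlo dose-point-kernel on an odd-sized grid centered on the source.

    Defaults follow the reference kernel geometry: a 121 × 121 × 61 matrix
    at 0.5 × 0.5 × 1.0 mm³ in 1.06 kg/L soft tissue.  Identical
    ``(seed, n_histories, spectrum, grid)`` yield identical kernels.
    """
    if grid is None:
        grid = default_kernel_grid()
    if n_histories < 1:
        raise ValueError("need at least one decay history")
    if any(n % 2 == 0 for n in grid.shape):
        raise ValueError(f"kernel grid must be odd-sized in all dimensions, got {grid.shape}")
    center = tuple(n // 2 for n in grid.shape)
    # source sits at the center voxel's center; use a grid whose origin puts it at 0
    local_grid = VoxelGrid(
        grid.spacing_mm,
        tuple(-grid.spacing_mm[a] * center[a] for a in range(3)),
        grid.shape,
    )
    rng = np.random.default_rng(seed)
    tally_mev = np.zeros(grid.shape)
    done = 0
    while done < n_histories:
        m = min(batch_size, n_histories - done)
        for q_mev, br_yield in spectrum.beta_branches:
            n_b = rng.binomial(m, min(br_yield, 1.0))
            e_b = _sample_allowed_beta(q_mev, n_b, rng)
            _transport_electrons(e_b, local_grid, tally_mev, density, spectrum.cutoff_kev, rng)
        for e_ph, ph_yield in spectrum.photon_lines:
            n_p = rng.binomial(m, min(ph_yield, 1.0))
            _transport_photons(e_ph, n_p, local_grid, tally_mev, density, rng)
        e_loc, y_loc = spectrum.local_component
        if y_loc > 0 and e_loc > 0:
            n_l = rng.binomial(m, min(y_loc, 1.0))
            tally_mev[center] += n_l * e_loc
        done += m
    energy_ev = tally_mev * EV_PER_MEV / n_histories
    return DosePointKernel(
        energy_ev=energy_ev,
        grid=grid,
        center_index=center,
        medium_density=density,
        provenance={
            "generator": "hoct condensed-history MC",
            "seed": int(seed),
            "n_histories": int(n_histories),
            "beta_branches": list(map(list, spectrum.beta_branches)),
            "photon_lines": list(map(list, spectrum.photon_lines)),
            "local_component": list(spectrum.local_component),
            "cutoff_kev": spectrum.cutoff_kev,
        },
    )


def default_kernel_grid() -> VoxelGrid:
    """121 × 121 × 61 voxels at 0.5 × 0.5 × 1.0 mm³, source in the center."""
    shape = (121, 121, 61)
    spacing = (0.5, 0.5, 1.0)
    origin = tuple(-spacing[a] * (shape[a] // 2) for a in range(3))
    return VoxelGrid(spacing, origin, shape)


# ---------------------------------------------------------------------------
# Kernel I/O: NIfTI array + JSON sidecar
# ---------------------------------------------------------------------------

def save_dpk(kernel: DosePointKernel, path: str | Path) -> None:
    """Write kernel as NIfTI (<path>.nii) plus a JSON sidecar (<path>.json)."""
    import nibabel as nib

    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".nii", ".json") else path
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = kernel.grid.spacing_mm
    aff[:3, 3] = kernel.grid.origin_mm
    nib.save(nib.Nifti1Image(kernel.energy_ev, aff), str(base.with_suffix(".nii")))
    sidecar = {
        "spacing_mm": list(kernel.grid.spacing_mm),
        "origin_mm": list(kernel.grid.origin_mm),
        "shape": list(kernel.grid.shape),
        "center_index": list(kernel.center_index),
        "medium_density_kg_per_l": kernel.medium_density,
        "provenance": kernel.provenance,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_dpk(path: str | Path) -> DosePointKernel:
    """Load a kernel written by :func:`save_dpk`; density metadata is required."""
    import nibabel as nib

    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".nii", ".json") else path
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"kernel sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    if "medium_density_kg_per_l" not in meta or meta["medium_density_kg_per_l"] is None:
        raise ValueError("kernel sidecar lacks medium density; refusing to assume a default")
    img = nib.load(str(base.with_suffix(".nii")))
    arr = np.asarray(img.get_fdata(), dtype=float)
    grid = VoxelGrid(tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]), tuple(meta["shape"]))
    if tuple(arr.shape) != grid.shape:
        raise ValueError(
            f"kernel array shape {arr.shape} disagrees with sidecar shape {grid.shape}"
        )
    return DosePointKernel(
        energy_ev=arr,
        grid=grid,
        center_index=tuple(meta["center_index"]),
        medium_density=float(meta["medium_density_kg_per_l"]),
        provenance=dict(meta.get("provenance", {})),
    )


# ---------------------------------------------------------------------------
# Convolution dosimetry
# ---------------------------------------------------------------------------

def match_to_kernel_grid(
    activity_bq: np.ndarray, grid: VoxelGrid, kernel: DosePointKernel
) -> tuple[np.ndarray, VoxelGrid]:
    """Resample an activity map to the kernel resolution, conserving total Bq."""
    if np.allclose(grid.spacing_mm, kernel.grid.spacing_mm):
        return np.asarray(activity_bq, dtype=float), grid
    ks = kernel.grid.spacing_mm
    shape = tuple(
        max(int(np.ceil(grid.spacing_mm[a] * (grid.shape[a] - 1) / ks[a])) + 1, 1)
        for a in range(3)
    )
    target = VoxelGrid(ks, grid.origin_mm, shape)
    out = resample_trilinear(activity_bq, grid, target, conserve_total=True)
    return out, target


def convolve_dose_rate(
    activity_bq: np.ndarray, grid: VoxelGrid, kernel: DosePointKernel
) -> np.ndarray:
    """Energy deposition rate map (eV/s) = activity ⊗ kernel.

    Linear (zero-padded) convolution via FFT; the output grid equals the
    activity grid.  Negative activities are refused — quantification maps
    fed to dosimetry must come from S+/threshold methods, whose
    concentrations are non-negative.
    """
    activity_bq = np.asarray(activity_bq, dtype=float)
    if tuple(activity_bq.shape) != grid.shape:
        raise ValueError("activity array shape does not match grid")
    if not np.allclose(grid.spacing_mm, kernel.grid.spacing_mm, rtol=1e-6):
        raise ValueError(
            f"activity resolution {grid.spacing_mm} differs from kernel "
            f"{kernel.grid.spacing_mm}; resample with match_to_kernel_grid first"
        )
    if np.any(activity_bq < 0):
        raise ValueError(
            "activity map contains negative values; dose estimation requires "
            "non-negative input (use S+ or a threshold method)"
        )
    out = signal.fftconvolve(activity_bq, kernel.energy_ev, mode="same")
    # FFT round-off can leave tiny negative values
    floor = -1e-9 * max(out.max(), 1.0)
    if out.min() < floor:
        raise RuntimeError("convolution produced significantly negative energy rates")
    return np.maximum(out, 0.0)


def cumulative_dose_map(
    energy_rate_ev_s: np.ndarray,
    grid: VoxelGrid,
    density: float = 1.06,
    decay_constant: float = DECAY_CONSTANT_PER_S,
    elapsed_s: float | None = None,
) -> DoseMap:
    """Absorbed dose (Gy) from the energy rate map, integrated over decay.

    With ``elapsed_s=None`` the activity decays to infinity (factor 1/λ);
    a finite ``elapsed_s`` multiplies by (1 − e^{−λt}) for partial-time
    dose.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if decay_constant <= 0:
        raise ValueError("decay constant must be positive")
    rate = np.asarray(energy_rate_ev_s, dtype=float)
    if tuple(rate.shape) != grid.shape:
        raise ValueError("energy rate array shape does not match grid")
    v_litre = grid.voxel_volume_mm3 * 1e-6
    integral = 1.0 / decay_constant
    if elapsed_s is not None:
        integral *= 1.0 - np.exp(-decay_constant * elapsed_s)
    dose = rate * integral * J_PER_EV / (density * v_litre)
    return DoseMap(dose_gy=dose, grid=grid, density=density)


def dvh(dose: DoseMap, mask: VOIMask, n_bins: int = 100) -> DVHCurve:
    """Cumulative dose-volume histogram over a VOI.

    ``volume_percent[i]`` is the percentage of VOI voxels with dose ≥
    ``dose_gy[i]``; bins span [0, max dose].
    """
    if n_bins < 2:
        raise ValueError("need at least 2 DVH bins")
    if mask.grid != dose.grid:
        raise ValueError("mask grid does not match dose grid")
    vals = dose.dose_gy[mask.included]
    if vals.size == 0:
        raise ValueError("DVH mask selects no voxels")
    dmax = float(vals.max())
    edges = np.linspace(0.0, dmax if dmax > 0 else 1.0, n_bins)
    vol = np.array([100.0 * np.mean(vals >= d) for d in edges])
    return DVHCurve(dose_gy=edges, volume_percent=vol)


def dvh_mean_dose(curve: DVHCurve) -> float:
    """Mean dose implied by a DVH: ∫ P(D ≥ d) dd (trapezoid rule)."""
    return float(np.trapezoid(curve.volume_percent / 100.0, curve.dose_gy))


def kernel_radial_fraction(kernel: DosePointKernel, radius_mm: float) -> float:
    """Fraction of kernel energy within ``radius_mm`` of the source center."""
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    g = kernel.grid
    cx = [g.axis_coords(a)[kernel.center_index[a]] for a in range(3)]
    xs, ys, zs = g.center_coords()
    r2 = (xs - cx[0]) ** 2 + (ys - cx[1]) ** 2 + (zs - cx[2]) ** 2
    total = kernel.total_energy_ev
    if total == 0:
        return 0.0
    return float(kernel.energy_ev[r2 <= radius_mm**2].sum() / total)
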