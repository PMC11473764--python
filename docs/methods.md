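# Methods

This note documents the models, conventions and numerical choices behind
`hoct`, in the order of the processing chain.

## Geometry and statistics conventions

Volumes live on regular axis-aligned grids; voxel indices are 0-based and
a voxel's value sits at its center, with world coordinates in mm
(`origin + index·spacing`). Oblique orientations are not supported —
phantom and sample scans are acquired axis-aligned, and supporting
rotation matrices would buy nothing for this protocol. Masks are boolean
volumes, not contours: geometric VOIs (cylinders, ellipsoids) include a
voxel iff its center lies inside the shape. This makes mask volumes
converge to the analytic shape volume as spacing shrinks (tested), but
means partial edge voxels are all-or-nothing; at the 0.5–1 mm spacings
used here the cylinder-mask volume error is below 2%.

All VOI standard deviations use the sample convention (n−1). The 95%
confidence interval uses the normal approximation mean ± 1.96·SD/√n,
justified because per-VOI n is thousands of voxels.

DICOM reading applies the affine rescale (RescaleSlope/Intercept) and
requires a single series with uniform slice spacing; NIfTI-1 is the
interchange format for volumes, masks and maps. Since NIfTI headers
cannot carry acquisition provenance, scanner/kVp/kernel metadata travels
in a small `.meta.json` sidecar; the CLI uses it to refuse applying a
calibration curve to a volume from a different scanner or protocol,
since calibration parameters are scanner- and kernel-specific.

## Calibration

Tube mean HU is regressed on concentration (mg elemental Ho per mL) by
unweighted OLS on the tube means — per-voxel regression would only
re-weight tubes by voxel count, and tube means are what the protocol
records. Diagnostics (R², F, coefficient standard errors, p) come from
the standard normal-equations formulas and are cross-checked against
statsmodels in the tests.

Two protocol rules:

* **Saturation exclusion.** A tube is excluded when its maximum HU
  exceeds (strictly) the detection limit. On a clipped scanner the
  representable ceiling itself (e.g. 3071 HU on 12-bit systems) is
  attainable by clipping, so the pipeline convention sets the detection
  limit one HU below the ceiling: any tube containing a clipped voxel is
  then flagged, with no boundary ambiguity. The synthetic phantom's
  ground-truth saturation flag uses the same rule on the pre-clip voxel
  values, making truth and exclusion provably identical.
* **Forced zero.** When the intercept's standard error exceeds the
  intercept's magnitude (strict `>`), the line is refit through the
  origin. The through-origin R² is reported in the uncentered convention
  (1 − RSS/Σy²), the standard choice for no-intercept models, and the
  curve is labelled `forced_zero`.

## Quantification

`HU_Ho` is extracted by subtraction or thresholding:

* **Subtraction** (`s-minus`, `s`, `s-plus`): `HU_Ho = post − HU_ref`
  over every VOI voxel. `s` floors *post* values at 0 HU before
  subtracting (so `HU_Ho ≥ −HU_ref`), modelling the assumption that
  tissue without microspheres cannot be less dense than water/air
  boundary artefacts; `s-plus` removes voxels with negative `HU_Ho` from
  the contributing mask. Negative totals under `s-minus`/`s` are
  reported as-is — under-recovery from negative outliers is a real
  behaviour of the method, not an error to clamp.
* **Thresholding** (`t`, `t1sd`–`t3sd`, `t50`, `t100`): voxels with post
  HU strictly greater than the threshold contribute with their *full*
  HU value. A voxel exactly at the threshold is excluded. When the
  calibration intercept is applied (curve not forced through zero), the
  effective threshold is `max(threshold, m)`, which guarantees
  non-negative converted concentrations.

**Intercept handling differs by method**, a deliberate design choice:
threshold methods convert the full voxel HU via `(HU − m)/b`;
subtraction methods convert via `HU_Ho/b` only, because the measured
reference already removed the baseline and subtracting the fitted
intercept as well would remove baseline twice. Both behaviours follow
from requiring that a noise-free phantom whose background equals the
calibration intercept is recovered exactly by either method family.

Voxel concentration × voxel volume gives elemental-Ho mass; dividing by
the microsphere Ho content (19.7% for Ho-PLLA microspheres) gives
microsphere mass, and multiplying by the specific activity (Bq/mg,
decay-corrected to scan time) gives voxel activity. All reported fields
carry units in their names (`…_ho_mg`, `…_ms_mg`, `…_bq`) because the
elemental-vs-microsphere mass distinction is a classic source of ×5
errors.

Decay corrections use λ = ln2 / 26.82 h = 7.179×10⁻⁶ s⁻¹ (the commonly
printed 7.18×10⁻⁶ is accepted as an override). Injected amount is the
difference of the decay-corrected before/after dose-calibrator readings,
referred to scan time; the mg conversion uses the specific activity at
scan time so mass and activity stay consistent. The reference time of
the specific activity is explicit in `InjectionRecord` rather than
assumed.

Recovery is 100 × quantified/injected microsphere mass, flagged
sufficient in [70%, 130%]; the volume fraction is the percentage of
quantification-VOI voxels contributing. Tumor volumes from the three
largest diameters use the ellipsoid formula (π/6)·l·w·h.

## Dose point kernel

The kernel is the expected energy (eV) deposited per decay in each voxel
around a point source in uniform 1.06 kg/L soft tissue, on a default
121 × 121 × 61 grid at 0.5 × 0.5 × 1.0 mm³ with the source at the center
voxel. (Matrix × resolution gives a 60.5 × 60.5 × 61 mm physical extent;
the grid is defined by matrix and resolution, not by a rounded extent.)

The generator is a deliberately simplified condensed-history Monte
Carlo, not a general-purpose transport code:

* **Beta spectra**: allowed shape `p·W·(Q−E)²` per branch (endpoints
  1.77 MeV at 49.9%/decay, 1.85 MeV at 48.8%/decay), sampled by
  rejection; no Fermi Coulomb correction. This overweights low energies
  slightly less than the true spectrum but is accurate to a few percent
  in mean energy.
* **Electron transport**: fixed 0.1 mm geometric steps. Energy loss per
  step comes from the residual Katz–Penfold CSDA range–energy relation
  for low-Z media (valid 0.01–2.5 MeV), scaled by density; below the
  1 keV cutoff the residual energy is deposited locally. Each step the
  direction is deflected by a multiple-scattering polar angle sampled
  from the Rayleigh distribution with scale
  θ₀ = E_s/(βpc)·√(ℓ/X₀), E_s = 21.2 MeV, X₀ = 36.08 g/cm² (Fermi–Eyges
  small-angle theory with the Rossi scattering power). The lateral
  diffusion this produces is essential: energy deposition along
  *straight* CSDA tracks would place ~27% of the beta energy beyond a
  3 mm radius, whereas the physical ¹⁶⁶Ho kernel confines ~90% within
  3 mm; with multiple scattering the generated kernel deposits ~95%
  within 3 mm. No energy-loss straggling, no large-angle single
  scattering, no bremsstrahlung (radiative yield is ~1% at these
  energies).
* **Photons** (0.08 MeV at 6.6%/decay): exponential free path with the
  water mass-attenuation coefficient at 80 keV (0.1837 cm²/g) scaled by
  density, full energy deposited at the first interaction; photons
  leaving the grid escape. At 5.3 keV/decay this component is <1% of the
  ~666 keV/decay beta energy.
* **Local component**: conversion/Auger electrons and x-rays have
  sub-voxel ranges at this resolution and are lumped as a deposit at the
  source voxel. Their per-decay energy is not printed in the protocol
  source; the default (mean 0.030 MeV, yield 0.15/decay ≈ 4.5 keV/decay,
  <1% of the total) is an order-of-magnitude stand-in and is documented
  in the kernel provenance.

Each kernel records its full provenance (seed, histories, spectrum) and
is bitwise reproducible from them. For production dosimetry an
externally computed high-fidelity kernel (e.g. from a full Monte Carlo
transport code) can be loaded from NIfTI + JSON sidecar; the loader
refuses kernels without an explicit medium density.

## Convolution dosimetry

Activity maps are resampled to the kernel resolution by trilinear
interpolation with exact renormalization of the total (total Bq is a
physical invariant; plain interpolation does not preserve it). The
convolution is linear (zero-padded), computed spectrally via
`scipy.signal.fftconvolve`; agreement with a direct shifted-kernel
summation is required to 1e−9 relative in tests, not bit-exactness.
Round-off can leave tiny negative rates, which are clamped at zero after
checking they are below 1e−9 of the maximum.

Negative activities are refused at the convolution boundary: dose maps
are only meaningful for S+/threshold quantifications, and silently
convolving negative "activity" would produce undisplayable negative
doses.

Cumulative dose integrates the exponentially decaying activity to
infinite time (division by λ); a partial-time option multiplies by
(1 − e^{−λt}). Density is uniform (1.06 kg/L, liver-like soft tissue);
CT-driven density heterogeneity correction is out of scope.

DVHs are cumulative (% of VOI voxels at or above each dose level,
non-increasing from 100%), with bin edges spanning [0, max dose]; the
curve's integral over dose reproduces the mean dose (tested), which
pins down the binning convention.

## Synthetic phantoms

The generators define the study conditions used throughout the tests:

* **Calibration tubes**: ⌀ 17 mm tubes, 30 mm long, on a 25 mm pitch,
  with ⌀ 11 mm (~100 mm²) analysis masks; default 1 mm isotropic grid
  (≈ 2 850 voxels per analysis mask); forward model HU = m + b·c with
  independent Gaussian voxel noise (default SD 15 HU) and clipping at
  the 12-bit limits (−1024, 3071 HU). The reference line is
  HU = 26.36 + 29.89·c.
* **Injection samples**: 5 × 5 × 4 cm blocks, 0.3 mL deposits of 7.5 mg
  Ho-MS (uniform sphere, Gaussian blob or multifocal), noise SD 10 HU,
  optional pre/post baseline shift emulating scanner drift between
  scans, optional Gaussian edge blur emulating partial-volume effects.
  Background defaults to the calibration intercept so that noise-free
  recovery is exact under both intercept conventions.
* **Patient-like**: ellipsoidal tumor (default 2 × 2 × 2 cm → 4.19 cm³)
  with multifocal deposits planned at 5.0 mg Ho-MS per cm³ tumor, plus
  1000 HU bone-like distractor spheres outside the quantification VOI.

Deposit concentration fields are renormalized after voxelization (and
after optional blurring) so the voxel-sum mass equals the requested mass
exactly; this is what makes the forward–inverse recovery oracles exact
rather than approximate.

What the phantoms do **not** emulate — and what passing tests therefore
do not demonstrate about real data: correlated reconstruction-kernel
noise texture, beam hardening and metal artefacts, contrast agent,
patient motion and pre/post misregistration, heterogeneous real
microsphere clustering, and hyperdense anatomy *inside* the VOI (the
protocol excludes bone/calcifications by manual contouring, which is out
of scope here).

## Problem sizes and tolerances

Default test and acceptance problem sizes were chosen to make the
statistical checks stable: ~2 850 voxels per calibration tube and 18
tubes put the fitted R² above 0.999; 10⁶ kernel histories give the 3 mm
energy fraction a standard error far below the 90% margin. Noise-free
oracles assert exact equality to 1e−9; stochastic recovery checks assert
a <2% bias over 20 seeds. Convolution agreement is 1e−9 relative;
conserved totals 1e−12 relative.

## Known limitations

* The kernel generator trades transport fidelity for simplicity; its 3 mm
  confinement and total-energy bookkeeping are validated, but its fine
  radial shape is not benchmarked against a full transport code. Use an
  imported kernel when absolute voxel-level dose accuracy matters.
* Pre/post registration is not provided; the subtraction methods use a
  single scalar reference, which is exactly the regime the protocol's
  S−/S/S+ variants were designed for.
* Quantification assumes the linear HU response holds at deposit
  concentrations; above the scanner detection limit it cannot (that is
  the saturation-exclusion rule's job at calibration time, but no
  per-voxel saturation handling is applied in quantification VOIs).
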