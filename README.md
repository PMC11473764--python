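# hoct — CT quantification and voxel dosimetry of ¹⁶⁶Ho microspheres

Holmium-166 microbrachytherapy destroys solid tumors by injecting
radioactive ¹⁶⁶Ho-loaded poly(L-lactic acid) microspheres (¹⁶⁶Ho-MS)
directly into the tumor. ¹⁶⁶Ho emits high-energy beta radiation
(E<sub>β,max</sub> = 1.77 MeV at 49.9%/decay and 1.85 MeV at 48.8%/decay)
that deposits ~90% of its energy within 3 mm of tissue, plus a low-yield
0.08 MeV gamma (6.6%), and has a 26.82 h half-life. Because holmium is a
strong photon attenuator, the microsphere biodistribution is visible as a
radiodensity increase on ordinary CT — which makes intra-operative
quantification and dose monitoring possible without nuclear imaging.

`hoct` implements that imaging chain as a tested Python library and CLI
for medical physicists and imaging researchers:

1. **Calibration** — ordinary least squares of tube mean HU on Ho
   concentration in a phantom, `HU = m + b·c`, with exclusion of tubes
   saturating the scanner's detection limit and a forced-through-zero
   refit when the intercept's standard error exceeds the intercept.
2. **Quantification** — subtraction methods
   (`HU_Ho = post HU − HU_reference`; variants S−/S/S+ differing in the
   treatment of negative values) and threshold methods (T, T1SD–T3SD,
   T50, T100; voxels with post HU strictly above the threshold, floored
   at the calibration intercept). Voxel concentrations
   `c = (HU_Ho − m)/b` are converted to microsphere mass and
   radioactivity `A_voxel = c·V_voxel / Ho-content × specific activity`,
   and compared with the decay-corrected injected amount as a recovery
   percentage (70–130% deemed sufficient).
3. **Dosimetry** — a Monte Carlo ¹⁶⁶Ho dose point kernel (energy per
   decay per voxel on a 121×121×61 grid at 0.5×0.5×1.0 mm³ in 1.06 kg/L
   soft tissue), convolved with the voxel activity map,
   `E(eV/s) = A(s⁻¹) ⊗ DPK(eV)`, and integrated over complete decay,
   `D_voxel(Gy) = E/λ × 1.602×10⁻¹⁹ / (ρ·V_voxel)`, plus cumulative
   dose-volume histograms.
4. **Synthetic phantoms** — calibration-tube, injection-sample and
   patient-like generators with exact ground truth, so the whole chain is
   testable without scanner data.

## Worked example

```python
import numpy as np
from hoct import phantoms as ph, dosimetry as dos
from hoct.calibration import exclude_saturated, fit_calibration
from hoct.quantification import (InjectionRecord, ReferenceStats, activity_map,
                                 quantify, recovery, volume_fraction)
from hoct.volumes import voi_stats

# calibrate on a simulated 18-tube phantom (truth line: 26.36 + 29.89 c)
line = ph.default_calibration_curve()
vol, truth = ph.simulate_calibration_phantom(np.linspace(0, 40, 18), line,
                                             noise_sd=15, seed=1)
pts = ph.measure_calibration_points(vol, truth)
curve = fit_calibration(exclude_saturated(pts, truth.detection_limit_hu))
# -> calibration: m = 26.23 HU, b = 29.89 HU/(mg/mL), R^2 = 1.0000

# quantify a simulated 7.5 mg injection with the T2SD threshold
pre, post, t = ph.simulate_injection_phantom(deposit_ms_mg=7.5, noise_sd=10,
                                             curve=line, seed=2)
stats = voi_stats(pre, t.masks["reference"])
ref = ReferenceStats(stats.mean_hu, stats.sd_hu, "pre")
res = quantify(post, t.masks["voi"], "t2sd", curve, ref=ref)
pct, ok = recovery(res, t.ms_mg)
# -> T2SD: effective threshold 46.39 HU, quantified 8.13 mg Ho-MS,
#    recovery 108.4% (sufficient), volume fraction 6.2%

# absorbed dose by kernel convolution (15 MBq/mg specific activity)
rec = InjectionRecord(1.2e8, 0.0, 0.0, 0.0, 0.0, 1.5e7)
act = activity_map(res.concentration_map, res.grid, rec, res.contributing)
kernel = dos.generate_dpk(dos.ho166_spectrum(), n_histories=200_000, seed=3)
act_k, grid_k = dos.match_to_kernel_grid(act, res.grid, kernel)
dose = dos.cumulative_dose_map(dos.convolve_dose_rate(act_k, grid_k, kernel),
                               grid_k, density=1.06)
# -> dose: total 122.0 MBq, peak 5950 Gy
```

The recovery of 108.4% reflects image noise entering through the
threshold segmentation; the quantified mass stays inside the 70–130%
sufficiency band. The extreme peak dose is characteristic of
microbrachytherapy: essentially all beta energy is absorbed inside a
0.3 mL deposit.

The same chain is scriptable from the shell:

```sh
hoct simulate --kind injection --out sim --seed 3 --noise-sd 0
hoct quantify --post sim/post.nii --voi sim/mask_voi.nii \
     --curve sim/curve.json --method t --pre sim/pre.nii \
     --ref-voi sim/mask_reference.nii --out out
hoct dose --activity out/activity_bq.nii --kernel kern --out out
hoct dvh  --dose out/dose_gy.nii --mask sim/mask_deposit.nii --out dvh.csv
```

(`hoct run --config cfg.json` executes the whole chain; `hoct calibrate`
fits a curve from a CSV tube table. The CLI refuses to apply a
calibration curve whose scanner/kVp/kernel metadata disagrees with the
volume's, because calibration parameters are not interchangeable between
scanners; `--force` overrides.)

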