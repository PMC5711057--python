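# mlcport

Simplified Monte Carlo photon transport through Varian multileaf
collimators (HD120 and Millennium 120), with the downstream computations
needed for patient-specific VMAT plan QA: meterset-synchronized dynamic
delivery, absolute-dose conversion, adaptive Savitzky–Golay denoising, and
3D gamma analysis.

## Who this is for

Medical physicists and researchers who want a desk-scale, fully scriptable
model of MLC leakage and dynamic-delivery fluence — for studying
transmission, tongue-and-groove and rounded-tip effects, for generating
and sequencing MLC test patterns, and for exercising the QA analysis chain
(denoise → absolute dose → gamma) end to end without a linac, a cluster,
or vendor phase-space files.

## The model

**MLC transport.** Photons are transported through a fully parameterized
two-bank leaf geometry with exactly two interaction channels in tungsten:

- *deterministic primary attenuation*: each photon's statistical weight is
  multiplied by `exp(-(μ/ρ)(E) · ρ t)` over its tungsten radiological path
  `t`, computed through intraleaf thickness variation, interleaf gaps,
  tongue-and-groove steps, and the rounded (HD120) or faceted (Millennium)
  leaf tips;
- *forced first Compton scatter*: one Klein–Nishina-sampled scattered
  photon per attenuated primary, weighted by the interaction probability
  times the Compton share of the cross section, attenuated over its
  residual tungsten path.

Electrons, photoelectric absorption, pair production and higher-order
scatter are not transported. Dose is scored as collision kerma in water at
depth (CPE assumption), the minimal physics valid beyond the buildup
region.

**Dynamic delivery.** A plan is an ordered list of control points indexed
by cumulative meterset fraction `u ∈ [0, 1]`. Each history draws `u`
uniformly and interpolates gantry angle, jaws and every leaf linearly in
meterset — so fluence per control-point interval is proportional to its
meterset width (the VMAT synchronization contract).

**QA chain.** Raw dose `D` (per unit incident fluence) converts to
absolute dose via the linear calibration
`D_abs = D × (D_cal^meas / D_cal^MC) × U` with the monitor-backscatter
term set to zero; noisy grids are denoised by a locally adaptive
Savitzky–Golay filter (largest 3D window whose order-2 weighted fit passes
a reduced-χ² test, per voxel); agreement is quantified by a global 3%/3 mm
gamma index over a >20%-of-maximum ROI.

## Worked example

```python
import mlcport as m

geometry = m.hd120()                     # packaged HD120 model
source = m.SourceModel.preset("6X")      # 6 MV flattened beam preset
t = m.simulated_transmission(geometry, source, n_histories=200_000, seed=1)
print(f"HD120 6X mean transmission: {100*t:.2f}%")
```

prints

```
HD120 6X mean transmission: 1.21%
```

— the blocked-bank to open-field kerma ratio at 5 cm depth in a
15×17 cm² field, averaged over a 12 cm span across the leaves. Film
measurements of this quantity on a TrueBeam STx are ≈1.2%, and the leaf
density/interleaf geometry of the packaged model is calibrated to that
measurement (see `docs/methods.md`). Denoising a synthetic noisy grid:

```python
from mlcport.patterns import make_synthetic_noisy_dose
import numpy as np

grid, truth = make_synthetic_noisy_dose(n=50, noise_rel=0.02, seed=123)
out = m.sg_denoise(grid)
high = truth > 0.5 * truth.max()
rms = np.sqrt(np.mean(((out.dose[high] - truth[high]) / truth[high])**2))
print(f"denoised high-dose RMS deviation: {100*rms:.2f}%")
```

prints `denoised high-dose RMS deviation: 0.37%` — a 2% noisy grid comes
out well under 1%.

## Command line

```sh
mlcport make-pattern multibar --out plan.json
mlcport simulate plan.json --out dose.3ddose --histories 200000 --seed 1
mlcport denoise dose.3ddose --out dose_dn.3ddose
mlcport gamma reference.3ddose dose_dn.3ddose --dose 3 --dta 3
mlcport transmission --geometry hd120 --beam 6X
mlcport calibrate-density --geometry hd120 --target 0.012
```

Dose grids use a 3ddose-style text dialect (voxel counts, boundary lists,
dose values, relative errors) with `# key: value` provenance headers;
plans are plain JSON. Both formats are documented in the module
docstrings of `mlcport.io`.

## MLC configuration files

A geometry is three text files (see `src/mlcport/data/` for the packaged
HD120 and Millennium 120 instances):

- `*_upperhalf.table` / `*_lowerhalf.table` — rows of
  `leaf_number  y_breakpoint_cm  thickness_cm`, a piecewise-constant
  cross-leaf thickness profile per leaf half at the MLC plane (including
  tongue-and-groove steps and interleaf gaps);
- `*_particledmlc.config` — `key = value` lines for `density`,
  `tip_radius`, `tip_angle`, `tip_max_thickness`, `leaf_offset`,
  `z_upper`, `physical_thickness` and `leaf_widths_iso`.

The packaged tables are synthesized (vendor drawings are proprietary) and
carry that provenance in their headers; every value is overridable.

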