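# tracerflow

Does transport of a high-molecular-weight tracer through brain interstitial
tissue involve convective bulk flow, or is diffusion alone sufficient? This
package implements, and validates end to end on synthetic ground truth, the
computational chain behind that question as posed for contrast-enhanced MRI
of an intra-striatal Gd-albumin (70 kD) infusion in the rat brain:

1. **Front-tracking pseudo-ADC (ADC\*)** — serial T1-weighted volumes show
   an expanding hyperintense region around the infusion site. Inside a
   rough ROI each volume is split by Otsu's threshold into tracer and
   background tissue, the 6-connected boundary voxels of the tracer region
   form surfaces S₁, S₂, …, and the nearest-point travel distance from each
   point of an earlier surface to the next surface enters

   &nbsp;&nbsp;&nbsp;&nbsp;ADC\* = Dist² / (2 · d · t),&nbsp;&nbsp;&nbsp; d = 3,

   averaged over surface points. ADC\* responds to *both* diffusion and
   bulk flow.

2. **Diffusion-only reference from DTI** — the diffusion tensor is fit
   voxelwise by log-linear least squares on S = S₀·exp(−b gᵀDg); the water
   ADC = (λ₁+λ₂+λ₃)/3 over the ROI is converted to extracellular tortuosity
   λ² = D_free,water / ADC_water (D_free,water = 3×10⁻⁶ mm²/ms), and the
   tracer's diffusion-only tissue ADC predicted as
   ADC_tracer = D_free,BSA / λ² with D_free,BSA = 8.29×10⁻⁸ mm²/ms (bovine
   serum albumin standing in for Gd-albumin). By construction this estimate
   is blind to convection.

3. **Group comparison** — per subject, one pooled ADC\* and one
   tortuosity-scaled DTI ADC enter a pooled two-sample t-test
   (two-tailed, α = 0.05), and the gap between group means is reported as
   a percent difference, 100·(a−b)/((a+b)/2).

Because no in-vivo data ship with the package, a synthetic-data module
provides the ground truth: an advection–diffusion simulation
∂c/∂t = D∇²c − v·∇c + source of the 20-minute infusion on a 64×64×48 grid
at the acquisition's 0.125×0.125×0.167 mm spacing, with linear-enhancement
T1WI synthesis and Rician-noise DWI synthesis on matched tissue phantoms.
The simulator is verified against the closed-form 3-D heat kernel and exact
mass conservation.

## Worked example

```python
from tracerflow import experiment
from tracerflow.dti import tortuosity_from_water, scale_adc_to_tracer

# one synthetic subject, tracer D = 2e-8 mm^2/ms, bulk flow 9 um/min
still  = experiment.subject_adcstar(seed=2, flow_speed=0.0)
moving = experiment.subject_adcstar(seed=2, flow_speed=1.5e-7)
print(f"{still.pooled_adcstar_mean:.3e}  {moving.pooled_adcstar_mean:.3e}")
# 2.083e-09  2.813e-09   <- flow inflates the front-tracking estimate

# the diffusion-only arm: DTI water ADC -> tortuosity -> tracer ADC
lam = tortuosity_from_water(7.2376e-7)   # water ADC in tissue, mm^2/ms
print(f"{lam:.3f}  {scale_adc_to_tracer(lam):.3e}")
# 2.036  2.000e-08       <- recovers the ground-truth tracer diffusivity
```

The first two numbers are pooled ADC\* values (mm²/ms) for the same noise
realisation without and with bulk flow: convection raises the front speed,
and therefore ADC\*, by ~35% here. The last line shows the tortuosity
(λ ≈ 2, a typical hindrance factor for brain extracellular space) and the
diffusion-only tracer ADC it implies, which matches the simulation's
ground-truth D of 2×10⁻⁸ mm²/ms.

The numbered scripts under `analysis/` run the same study as a cohort
(five subjects per arm), writing per-subject tables and the two-group
comparisons under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_track_fronts.py
python analysis/03_fit_dti.py
python analysis/04_compare_groups.py
```

A thin CLI wraps the same library calls (`tracerflow simulate|adcstar|
dtifit|scale|compare|end2end`); `tracerflow end2end --config study.yaml
--outdir out/` runs the whole synthetic experiment from one config file.

## Layout

- `src/tracerflow/` — the library: `simulate` (ground truth + MRI
  synthesis), `adcstar` (front tracking), `dti` (tensor fit, scalar maps,
  tortuosity scaling), `stats` (group comparison), `io`/`cli` (NIfTI,
  bvals/bvecs, JSON dialects and the command line), `experiment` (study
  conditions and cohort drivers).
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and known limitations (including the front surrogate's bias).
- `tests/` — oracle-based unit, property and end-to-end tests.
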