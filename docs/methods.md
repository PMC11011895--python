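# Methods

## The question and the two estimators

A high-molecular-weight tracer (70 kD protein) moves slowly by diffusion;
if its front in brain tissue advances faster than diffusion allows, some of
the transport must be convective. The package quantifies both sides of that
comparison.

**Front-tracking pseudo-ADC (ADC\*).** Serial contrast-enhanced T1-weighted
volumes are segmented inside a rough ROI with Otsu's threshold (256-bin
histogram over the ROI-interior intensity range; the variance-maximizing
*bin edge* is returned and the class strictly above it is the tracer).
Boundary voxels — mask voxels with at least one of their six face
neighbours outside the mask, grid edges counting as outside — form the
tracer surface in physical coordinates (voxel index × spacing, mm). For
each point of the earlier surface, the Euclidean distance to the nearest
point of the later surface is the tracer's travel distance, and

    ADC* = dist^2 / (2 d Δt),   d = 3,

is evaluated per point. By default the per-point values of all consecutive
surface pairs are pooled with equal weight (mean ± SE over pooled points);
averaging per-pair means first is available as `pooling="pairs"`, since
"averaged over the surface points" admits both readings. Distances are
measured from the earlier to the later surface; overlapping fronts yield
zeros, which are retained — a front that did not move is evidence, not a
failure.

ADC\* is a *front-speed surrogate*, not an unbiased estimator of D: for a
Gaussian-spreading bolus an iso-intensity level set at radius ασ advances
as α·dσ/dt, so ADC\*/D ≈ (α²/3)·(σ₂−σ₁)/(σ₂+σ₁), well below 1 for
realistic thresholds (α ≈ 1–2) and scan intervals. Under the default study
conditions the tests measure pooled ADC\* ≈ 2×10⁻⁹ mm²/ms for true
D = 2×10⁻⁸. The estimator's value lies in its *response*: bulk flow adds a
coherent displacement v·Δt to the leading front, inflating ADC\*
systematically (a ~30% rise at 9 μm/min in the default geometry; detected
in 10/10 paired seeds), while ADC\* remains monotone in the true D. The
suite therefore asserts response properties and documents the absolute
bias rather than claiming unbiasedness.

**DTI arm.** The diffusion tensor is estimated voxelwise by ordinary least
squares on ln(S₀/S) = b gᵀDg, with S₀ the mean of the b=0 volumes and
signals floored at 10⁻⁶·S₀ before the log; S₀ ≤ 0 marks a voxel invalid.
OLS on the log-linearised model is the minimal choice; a weighted or
nonlinear fit would change noisy-voxel behaviour but not the noiseless
round trip, which is exact to ~10⁻¹⁴ relative. Eigenvalues are sorted
descending (ties broken by a stable sort for reproducibility), negative
eigenvalues are clamped to zero for map evaluation but retained in the
tensor field, and the all-zero voxel gets FA = 0 by convention. Scalar
maps follow the standard definitions: FA (normalised eigenvalue
dispersion, clipped to [0,1]), ADC = trace/3, D_axi = λ₁,
D_rad = (λ₂+λ₃)/2.

Tortuosity scaling: λ = sqrt(D_free,water / ADC_water) with
D_free,water = 3×10⁻⁶ mm²/ms, then ADC_tracer = D_free,BSA / λ² with
D_free,BSA = 8.29×10⁻⁸ mm²/ms. λ < 1 is physically implausible and warns
rather than errors, because noise can push a measured ADC above the free
coefficient. Tortuosity is computed from the ROI-*mean* water ADC (matching
a single reported value per region); a voxelwise route would simply map
the same algebra over the ADC volume and average afterwards, which differs
only at second order in the ROI variance.

## Units

All diffusivities are mm²/ms and all times ms, so ADC\* and the scaled
tracer ADC come out on the 10⁻⁸ mm²/ms scale on which results for 70 kD
tracers are usually quoted. b-values are kept in the field's customary
s/mm², so the DWI exponent b·gᵀDg carries an explicit 1000 ms/s factor;
with tissue water ADC ≈ 0.72×10⁻⁶ mm²/ms, b = 900 s/mm² gives the usual
e⁻⁰·⁶⁵ attenuation. One caution for readers of the phantom examples: the
conventional "×10⁻³" white-matter eigenvalues are mm²/s magnitudes; in this
package's ms-based units tissue water sits near 10⁻⁶. FA and the other
scalar maps are scale-invariant, so phantoms quoted at either magnitude
give identical anisotropy values.

## The synthetic-data generator

The generator emulates the study conditions rather than the scanner: a
64×64×48 grid at 0.125 × 0.125 × 0.167 mm (the acquisition's interpolated
T1WI resolution), a constant-rate infusion for 20 min deposited through a
Gaussian kernel (σ = 0.3 mm) around the infusion centre — the spatial
extent of deposition at a catheter tip is not physically constrained, so a
smooth compact kernel is the artifact's own choice — and snapshots 4.5 and
28.5 min after the end of infusion (Δt = 24 min between the two tracked
fronts).

The PDE ∂c/∂t = D∇²c − v·∇c + source is integrated by explicit forward
Euler with a flux-form central-difference Laplacian (zero-flux boundaries,
hence exactly mass-conserving in the closed source-free case — measured
drift ~10⁻¹⁶ relative) and first-order upwind advection with
edge-replicated boundaries. Sub-stepping enforces
dt ≤ 0.5·min(dx²/6D, dx/|v|max). Against the closed-form 3-D heat kernel
the impulse response agrees to 0.04% RMSE of the analytic peak once the
bolus spans a few voxels, and an impulse advected by uniform v lands
within one voxel of v·t.

MRI synthesis is deliberately minimal. T1WI: S = baseline + gain·c +
Gaussian noise (baseline 100, gain 4×10⁴ mapping the simulated peak
concentration to a strong hyperintensity, noise SD 2) — the front tracker
uses only hyperintensity geometry, so no relaxometry, k-space or motion is
modelled, and the motion-correction hook ships as the identity. DWI:
monoexponential attenuation with Rician noise sqrt((S+n₁)² + n₂²)
(S₀ = 1000, noise SD 50, i.e. SNR 20), the standard magnitude-MRI noise
model. What passing tests consequently do *not* show: robustness to
motion, bias fields, partial-volume effects at the front, or segmentation
behaviour at the low contrast-to-noise of late in-vivo scans.

Ground-truth coupling of the two arms: the tracer's tissue diffusivity
defaults to D = 2×10⁻⁸ mm²/ms, and the DTI phantom's water diffusivity is
derived from it through the *same* tortuosity,
ADC_water = D_free,water·D / D_free,BSA ≈ 0.72×10⁻⁶ mm²/ms (λ ≈ 2.04, a
realistic hindrance factor). With zero flow both arms therefore describe
one consistent tissue, and the DTI chain demonstrably closes the loop,
recovering 2.00×10⁻⁸ mm²/ms. The bulk-flow arm adds a uniform
1.5×10⁻⁷ mm/ms (9 μm/min) velocity — a literature-scale interstitial
bulk-flow magnitude — along +x.

## Statistics

Percent difference is taken relative to the mean of the two group means,
100·(a−b)/((a+b)/2): it is the only common variant consistent with both
reported rounded values (70 from 3.64 vs 1.75, 30 from 2.67 vs 1.97; the
difference-over-smaller and difference-over-larger variants match
neither). The two-sample t-test defaults to the pooled-variance two-tailed
form (df = n₁+n₂−2), with Welch available by flag; both groups constant
and equal gives p = 1 by convention, constant and unequal is an error.
Monte-Carlo calibration over 1000 seeded null replicates puts the type-I
error at the nominal 0.05 (measured 0.04–0.06 across seeds). Two ROI
comparisons are reported without multiple-testing correction, mirroring
the analysis design being reproduced.

## Numerical and interface choices

- Coordinates: 0-based voxel indices, physical position = index × spacing;
  orientation matrices are preserved on NIfTI write but never used for
  resampling — all volumes of one analysis share a grid by contract.
- Otsu ties resolve to the lowest maximizing bin edge; the scikit-image
  cross-check agrees to within one histogram bin (edge vs centre
  convention).
- Surface connectivity is the 6-neighbourhood, the most conservative
  boundary for anisotropic voxels.
- The gradient table is the dual-gradient 6-direction set plus one b=0;
  directions are interpreted in the voxel-index frame (FSL dialect).
- Problem sizes in the test suite and the acceptance script (64×64×48
  transport grids, 10 paired seeds for flow detection, 100 tensors for the
  round trip, 1000 t-test replicates) were chosen as the smallest sizes at
  which each quantity's Monte-Carlo spread is well below the margin being
  asserted.

## Known limitations

- ADC\* bias (above) is geometry- and threshold-dependent; the reported
  response properties hold for the compact single-bolus geometry and need
  not transfer to sheet-like spread along fibre tracts.
- The uniform velocity field is the simplest convection model; real
  perivascular flow is spatially structured.
- The tensor fit is unweighted log-linear OLS; at low SNR its eigenvalues
  carry the usual sorting-repulsion bias, which is why ROI summaries
  should average tensors before eigendecomposition (the test suite does).
- The tortuosity transfer assumes the tracer experiences the water
  tortuosity; a larger true tortuosity would lower the diffusion-only
  reference and strengthen, not weaken, a flow inference.
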