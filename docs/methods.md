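# Methods

This note documents the models, numerical choices and limitations behind
`demist`: a detection-task-specific denoiser for low-count myocardial
perfusion (MPI) SPECT together with the task-based evaluation machinery
needed to measure whether denoising actually helps the clinical task —
detecting perfusion defects — rather than merely improving pixel fidelity.

## Problem setting

A SPECT system measures Poisson-distributed projection counts
`g = H f + n` of a tracer distribution `f`; a reconstruction operator `R`
yields the image `f̂ = R g`.  The task is binary: classify `f̂` as
defect-absent (background `f_b`) or defect-present (`f_b + f_s`, with the
perfusion defect a *cold*, negative-valued signal in the left-ventricular
wall).  Lowering injected dose or acquisition time scales counts down by a
fraction `p`, degrading detectability.  The denoiser `D_Θ` maps a low-dose
reconstruction `f̂_LD` to a predicted normal-dose image
`f̂_ND^pred = D_Θ(f̂_LD)`.

## Hybrid training loss

Conventional denoisers minimise per-voxel MSE and are known to wash out
the very features observers use for detection.  The task-specific loss
used here augments fidelity with a channel-feature term:

    L(Θ) = L_fid(Θ) + λ · L_task(Θ)

* `L_fid = (1/(J·N2D·Z)) Σ_j ‖f̂_ND^j − f̂_ND^pred,j‖²` — voxel MSE over
  the J training pairs.
* `L_task = (1/(J·C·n_s)) Σ_j Σ_s ‖(S_j U)ᵀ (f̂_ND,s^j − f̂_ND,s^pred,j)‖²`
  — MSE between *channel vectors* `v = (S U)ᵀ f̂_2D` of the actual and
  predicted normal-dose slices, where `U` holds C rotationally symmetric
  frequency channels emulating the human visual system's frequency-selective
  processing and `S_j` is the acyclic 2-D shift centring the channels on
  sample j's defect centroid.  Defect-absent samples reuse the centroid of
  the location where their paired synthetic defect was inserted.
* λ = 0 recovers the task-agnostic baseline ("TADL") used for comparison.

Loss-term units: the task normalisation divides by `C·n_s` (a few tens)
while the fidelity one divides by `N3D` (~10⁵), so with L2-normalised
channels a unit λ would weight channel components thousands of times more
strongly than fidelity.  The trainer therefore scales its loss-channel
matrix by `sqrt(C·n_s/N3D)`, putting both terms in common per-voxel MSE
units; λ = 1 then doubles the weight on channel components and the
default grid λ ∈ {0, 0.1, 0.3, 1, 3, 10} spans gentle to strong task
emphasis.  The public `task_loss` keeps the printed normalisation for
whatever channel set it is given.

Slice range: the channels are applied to the slices intersecting the
defect's axial extent (centroid slice ± half the 42-mm axial length) —
the method leaves the range free, and this localises the task term where
the signal lives.  When per-sample ranges differ, each sample's slice sum
is normalised by its own slice count before averaging over the batch;
this reduces to the global form when ranges coincide.

## Channels

Channel c (1-based) has frequency-domain indicator support on radial
frequencies `[0.1838·2^(c−1), 0.1838·2^c)` cycles/cm — the first channel's
start frequency equals its bandwidth (0.1838 cycles/cm) and every
subsequent channel doubles both.  Spatial profiles are the real inverse
DFTs of the indicators, centred on the grid and L2-normalised (the CHO and
the rank order of the task loss are invariant to per-channel scale).  The
default of C = 4 octave channels is the standard anthropomorphic
configuration for this channel family.  Two caveats are deliberate:

* At the default 0.442-cm pixels the 4th octave band extends beyond the
  axis Nyquist frequency (1.131 cycles/cm) but still captures the corner
  bins of the 2-D DFT grid (radial frequencies up to 1.60); construction
  only fails when a passband has *no* DFT support.
* The channel set has exactly zero DC response; an *acyclic* shift
  truncates profiles at the grid edge and can reintroduce a very small DC
  sensitivity for off-centre defects.  This is a property of the shift
  formalism, not of the channels.

## Denoiser architecture and training

No deep-learning framework is assumed: the network is a small residual
three-level 2-D U-net (full/half/quarter resolution, `n_filters` and
`2·n_filters` feature maps, 3×3 kernels, ReLU, additive skip connections,
bottleneck dropout; ~1.5k parameters at width 4, ~6k at width 8) with forward
and backward passes written directly (numba-compiled convolution kernels)
and trained with ADAM (β = (0.9, 0.999); defaults lr 1e-3, batch 4
volumes, 20 epochs).  It is applied independently to each of the 48
short-axis slices, so the 48³→48³ volume contract is preserved; the
output is the input slice plus a learned correction.  A slice-wise 2-D
network was chosen over a full 3-D encoder–decoder to keep CPU training
of the scaled-down experiments in the minutes range; the loss formalism
is unchanged and the architecture is configurable in width and dropout.

Intensity handling: volumes enter after `[0, x_LV]` windowing; inputs and
targets are normalised by separate cohort-level scales (mean per-volume
maximum), because even count-rate-normalised low-dose images need not
share the normal-dose scale exactly.  Predictions are mapped back to the
target scale and clipped at 0.

λ selection follows the validation-set rule: train one network per
candidate λ (default grid {0, 0.1, 0.3, 1, 3, 10}), denoise the
validation cohort, and keep the λ with the highest observer AUC; ties
break toward the smallest λ (the least deviation from pure fidelity).

## Synthetic study chain

No clinical data ship with the package; every stage is exercised on a
synthetic chain that emulates the structure (not the physics) of a
clinical MPI protocol:

* **Phantom** — an annular LV wall (inner/outer radius 24/34 mm, axial
  extent 66 mm, uptake 100) on a 10% background confined to a 100-mm body
  cylinder, on a 48³ grid of 4.42-mm isotropic voxels.  One phantom seed
  is one "study"; seeded jitter of the wall midline radius (0.5 mm), the
  in-plane centre (1 mm) and the uptake (5%) emulates patient variability.
  Jitter is deliberately small so that task performance at the study dose
  levels is dominated by count noise rather than anatomy — the regime the
  dose levels are chosen to probe.  The wall midline is jittered with a
  single draw so the wall thickness never degenerates.
* **Projector** — slice-parallel 2-D parallel-beam ray sums realised as a
  sparse matrix (linear detector-bin splitting, 64 views over 180°, 48
  bins, optional Gaussian detector blur), exactly linear with an exact
  adjoint.  Sensitivity (0.3 expected counts per unit activity over the
  sinogram) makes a default-uptake wall voxel contribute ~30 counts in
  total, i.e. a few hundred thousand counts per normal-dose study — the
  clinically realistic level at which 6.25% thinning visibly degrades
  detectability.  No attenuation or scatter is modelled.
* **Low dose** — binomial thinning `B(n, p)` of the measured counts,
  which maps Poisson(μ) bins to Poisson(p·μ) exactly.
* **Defects** — wall voxels inside a polar-angle wedge about the LV
  centroid ([80−θ, 80]° anterior, [−80, −80+θ]° inferior, x-axis along
  the image rows, anterior = upper wall), replicated across the slices
  spanning the 42-mm axial length centred on the centroid slice.
  Severity s removes `s · mean LV uptake` inside the mask.  Defect-present
  *measured* data are produced by thinning the defect-absent counts with
  the per-bin ratio of noise-free defect-present to defect-absent
  projections (binomial per bin, keeping counts integral and the original
  noise texture; exact Poisson statistics are not guaranteed after this
  scaling).  Extents 30°/60°, severities 10/17.5/25%, two walls; the 45°
  extent appears only in test cohorts.
* **Reconstruction** — OSEM (8 subsets of strided views, 4 iterations,
  uniform positive initialisation; 1 subset = MLEM), then an order-5 3-D
  Butterworth low-pass at 0.44 cycles/cm, then windowing to
  `[0, x_LV]` with `x_LV` the maximum inside the (known) wall mask.
  Low-dose reconstructions are divided by the dose fraction (count-rate
  normalisation) so all methods live on one intensity scale.

What this chain does **not** emulate: attenuation, scatter,
collimator-detector response differences between detector materials,
anatomical sex differences, extra-cardiac hot organs, reorientation
interpolation.  Passing the task-based surrogate therefore shows that the
*method logic* behaves as designed under controlled count statistics, not
that clinical effect sizes are reproduced.

## Observer study

For each case a 32×32 region of interest centred on the (known) defect
centroid is extracted from the centroid slice and its two neighbours;
each slice is independently min–max mapped to [0, 255] (a constant slice
maps to 0).  Channel vectors of the three slices are concatenated
(3C = 12 features by default; per-slice averaging is available).  The
channelized Hotelling observer template `w = K_v⁻¹ Δv̄` uses the pooled,
equally weighted two-class covariance and is learned leave-one-out via
exact sufficient-statistic downdating, so no case contributes to its own
template; near-singular covariances receive a ridge of `1e-6·tr(K)/d`
with a warning.

Performance is the area under the empirical ROC curve (Mann–Whitney,
ties ½), with DeLong structural-component variance, Wald confidence
intervals clipped to [0, 1], the two-sided paired DeLong z-test for
correlated AUCs, and Bonferroni correction (m = 3 for the three method
comparisons).  For equal-covariance Gaussian features the empirical AUC
converges to the exact binormal value `1/2 + 1/2·erf(SNR/2)`
(= Φ(SNR/√2)); this anchors the whole scoring path analytically.
Fidelity is reported as whole-volume RMSE, SSIM, and RMSE inside the LV
wall against the normal-dose reconstruction.

## SNR eigenanalysis

The observer SNR, `SNR² = Δv̄ᵀ K_v⁻¹ Δv̄`, decomposes over the
eigenpairs (γ_m, u_m) of K_v as `SNR² = Σ_m α_m²/γ_m` with
`α_m = u_mᵀ Δv̄`.  Tracking (α_m, γ_m) across methods separates the two
ways a denoiser can act: shrinking noise eigenvalues γ_m (good) versus
shrinking signal coefficients |α_m| (bad).  Eigenvalues are sorted
descending; each eigenvector's largest-magnitude entry is made positive
(eigenvectors are sign-ambiguous); singular K_v receives a ridge of
`1e-8·tr(K)/d` with a warning.  The identity between the direct and
spectral forms is asserted on every decomposition.

## Scaled-down headline experiment

`demist.pipeline.headline_experiment` runs the end-to-end comparison at
desk scale: 8 training studies × 4 defect types × {present, absent} = 64
training pairs; 10 + 10 test studies × 4 types = 40 + 40 test cases;
dose fraction 0.125; λ ∈ {0, 1}; network width 8, trained 12 epochs at
lr 2e-3.  The four defect types are spread evenly across the 12-type
table so both walls, both extents and the severity range are
represented.  Problem sizes were chosen so a full three-seed replication
trains in minutes on one CPU core.  The SNR eigenreports are computed
from C-dimensional channel vectors of the *raw* centroid slice with
per-case shifted channels (the mean-difference-image formalism); the
observer's [0, 255] ROI mapping belongs to the scoring path only — a
per-slice min–max remapping would rescale case contrast and distort the
γ comparison.  The acceptance tests assert the qualitative pattern of
the full-scale result: AUC ordering task-specific ≥ task-agnostic >
low dose (majority of seeds), channel-noise power reduced by both
denoisers, and |α_m| preserved better by the task-specific loss.

Honest caveats about what the desk-scale surrogate can and cannot show.
The noise-power reduction reproduces robustly.  The AUC ordering and the
per-channel α pattern are underpowered at this scale: with 40+40 test
cases the per-seed AUC standard error (~0.06) is comparable to the true
method differences, and a 64-case training cohort (vs thousands at full
scale) leaves both networks weak enough that their differences are
small.  These two claims can therefore fail in any given seed set even
though the machinery is correct; they are kept as strict assertions
rather than being loosened.  Separately, after the Butterworth
post-filter the low-dose image is already close to MSE-optimal
smoothness at this count level, so *pixel* fidelity gains from denoising
are modest in the surrogate even where task behaviour moves.

## Numerical conventions

* All randomness flows through explicit seeded `numpy.random.Generator`
  instances (PCG64); no global RNG state.  Any seeded generator passing
  the distributional tests satisfies the contract — bit-compatibility
  with any particular legacy generator is not a goal.
* OSEM guards: expected projections are floored at 1e-12 in the ratio;
  voxels with zero subset sensitivity are left unchanged.
* The Butterworth filter uses the DFT frequency grid in cycles/cm derived
  from the voxel size; DC gain is exactly 1 by construction.
* Half-open channel passbands `[f_start, f_end)`: a bin on a boundary
  belongs to the lower channel.
* The empty defect wedge (θ = 0, or a wedge missing the wall) returns an
  empty mask with a warning rather than an error, because sweeping θ → 0
  is a legitimate degenerate limit.
* ROI extraction pads with zeros (with a warning) when the 32×32 window
  leaves the grid; a centroid on the first/last slice is an error because
  the two adjacent slices are required.
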