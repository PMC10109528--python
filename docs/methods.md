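# Methods

`nervoct` models, end to end, a quantitative PSOCT study of
electrostimulation-induced peripheral nerve injury: a digital nerve
phantom is imaged by a simulated polarization-diverse swept-source OCT
system, six data channels are reconstructed per voxel, fascicle-level and
angiographic metrics are extracted, and group statistics test for injected
injury effects. Because every stage consumes synthetic data with known
ground truth, correctness is established by parameter recovery rather than
by comparison with deposited data (none exist for this study design).

## The digital nerve phantom

The scene mirrors the imaged preparation: a sciatic nerve held in a
stabilizer with two embedded birefringent calibration stripes whose optic
axes are 0° and 45°, resting on a scattering tissue bed. Per-voxel ground
truth on a (z depth, x fast, y slow) grid:

| quantity | symbol | default (fascicles L/C/R) | units |
|---|---|---|---|
| one-way birefringent retardance rate | δ | 0.22 / 0.28 / 0.33 | deg/µm |
| optic-axis orientation | θ | 25 / 90 / 140 | deg mod 180 |
| attenuation coefficient | µ | 2.6 / 3.0 / 3.5 | mm⁻¹ |
| depolarization fraction | p | 0 (fascicles), 0.3 deep band | — |
| inter-repeat speckle correlation | ρ | 1 static, 0.3–0.4 in vessels | — |

Defaults sit in the range reported for myelinated nerve at 1310 nm
(birefringence Δn ≈ 10⁻³ ↔ ≈0.27 deg/µm one way; scattering 2–4 mm⁻¹).
The three fascicles are disjoint ellipses inside a weakly birefringent
epineurium (δ = 0.02 deg/µm, collagen); the rightmost fascicle "R" is, as
in the study layout, the one nearest the stimulation lead. Vessels are
tubes along the nerve with optional sinusoidal wiggle. The full-size grid
is 256 × 200 × 250 voxels at 3.5 µm axial / 10 µm lateral pitch
(≈0.9 × 2 × 2.5 mm); a half-scale desk phantom (160 × 100 × n_y) is used
throughout the test suite so the whole validation runs in minutes on one
core. The methods below are pitch-agnostic; nothing is tuned to a grid
size.

Three phantom choices are deliberate modeling decisions, not conveniences:

* **Backscatter is coupled to scattering** (b = µ/µ_ref). Depth-resolved
  attenuation estimation from intensity assumes a fixed backscattered
  fraction of the attenuated light; a phantom that decouples the two would
  make every intensity-based estimator inconsistent by construction, which
  says nothing about the estimator.
* **A tissue bed lies under the nerve.** A nerve floating in air ends the
  OCT decay at a curved boundary where most remaining light exits forward;
  on a bed the decay continues to the bottom of the grid, as it does on
  muscle in vivo.
* **Depolarization lives in a deep epineurial band**, emulating
  multiple-scattering depolarization at depth. Placing depolarization at
  the tissue surface would corrupt the surface reference matrix that every
  surface-relative polarization quantity is built on — physically that
  corresponds to an unusable preparation, not a harder test.

## Forward model

Simulation starts at complex-valued tomograms (post-FFT); spectral
resampling and dispersion are hardware-specific and add no testable
content. Per tissue column the one-way cumulative Jones matrix is the
ordered product of thin linear-retarder slabs (δ·dz at axis θ);
reciprocity gives the round-trip matrix J_rt = J_owᵀ·J_ow. The measured
field for input state e is

    E(z) = U_det · J_rt(z) · e · √b(z) · exp(−∫₀ᶻ µ dz′) · s(z)

with s(z) unit circular complex Gaussian speckle per voxel (so intensity
in a homogeneous region is exponentially distributed and ⟨|E|²⟩ decays as
exp(−2∫µ dz)). The complex field is then convolved axially with a Gaussian
of FWHM (2 ln 2/π)·λ₀²/Δλ (6.88 µm for the 1310 nm / 110 nm source) and
complex Gaussian detector noise is added at a configured surface SNR
(default 30 dB). Input polarization alternates between two states on
adjacent A-lines; both A-lines of a pair sample the same tissue column.
Across the five repeated frames per slow-axis location, static voxels keep
their speckle realization while vessel voxels evolve by an AR(1) redraw
with correlation ρ — the quantity OCT angiography estimates.

Two instrument imperfections are modeled separately: a general SU(2)
detection unitary U_det (fiber birefringence; cancels exactly in every
surface-relative quantity) and an instrument-frame axis offset/chirality
(what the 0°/45° stripe calibration genuinely recovers). A single
two-sided general unitary would turn the retarder eigenstates elliptical
and make a global-offset calibration impossible; the split keeps the
calibration contract meaningful while still exercising unitary invariance.

The default input-state pair is the orthonormal (H, V). Any non-degenerate
pair reconstructs the Jones matrix, but a non-orthogonal pair (e.g. H and
+45°, provided as `H45_INPUT_STATES`) makes the detector-noise covariance
anisotropic after the basis inversion and biases the optic-axis estimate
by several degrees at 30 dB; the orthonormal pair removes that bias at the
source.

## Channel reconstruction

* **Jones assembly.** J_meas = [r_A | r_B]·[e_A | e_B]⁻¹ per voxel from
  the even/odd A-line pair; independent of the input pair used.
* **Reflectance.** 10·log₁₀ Σ|J_ij|², floored; the noise floor is
  estimated from above-tissue voxels. Surface = first depth with
  reflectance > floor + 10 dB for 3 consecutive pixels.
* **Cumulative retardation.** For N(z) = J(z_surf)⁻¹·J(z) the eigenvalue
  phase split folded into [0°, 180°] is 2·arccos(|tr N|/2√|det N|) — a
  closed form with no eigen-ordering ambiguity. The folded value is
  unfolded along depth by tracking the branch 360k ± φ nearest a
  velocity-extrapolated prediction (plain nearest-branch tracking stalls
  at the 180° fold). Reported as round-trip degrees relative to the first
  tissue pixel; exactly invariant to U_det.
* **Jones averaging.** Before the fold/eigen step the relative matrices
  are normalized to unit determinant, sign-aligned on Re(tr) and averaged
  over a 3×3 lateral kernel: same-retarder matrices add coherently while
  noise averages down. This suppresses the rectified (√-sensitive) upward
  bias of the split estimate at low retardance; it is the difference
  between ≈8° and ≈1° of error at the fascicle top at 30 dB.
* **Optic axis.** Stokes orientation of the leading-phase eigenvector of
  N(z), mod 180°; masked where the split is within 10° of 0/360° (axis
  undefined as δ→0); the 90° eigen-order swap past 180° of round-trip
  retardation is undone using the unwrapped retardation. Calibration maps
  the 0° stripe's circular mean to 0° and picks the chirality that makes
  the 45° stripe read +45°.
* **Attenuation.** Depth-resolved estimator µ̂ᵢ = ln(1 + Iᵢ/Σ_{j>i}Iⱼ)/(2Δz),
  exact for a discretely sampled exponential, after noise-floor
  subtraction. The finite tail is completed per A-line: the last depth with
  signal is located, the local decay rate is fitted in the log domain on
  laterally pooled intensity (pooling matters — a speckled rate estimate
  passed through the convex q/(1−q) continuation biases µ̂ downward), and
  the fit is extrapolated through a 4-pixel guard zone that the axial PSF
  boundary contaminates. The last 20 pixels above the signal end are
  masked. Residual partial-volume mixing confines the remaining bias to
  ≈4 pixels around tissue boundaries, which the recovery evaluation
  erodes away.
* **DOPU.** Norm of the kernel-averaged unit Stokes vector of the H-input
  response; default kernel 3(z)×9(x)×1(y). Combined with a reflectance
  margin it defines the polarization-validity mask: in scattering nerve
  only the upper part of the structurally visible depth is
  polarization-valid, as in real preparations.
* **BwOA.** HSV composite — hue = axis/180° on a cyclic map, saturation =
  local one-way retardance (slope of the cumulative map) up to a 0.4
  deg/µm display cap, value = reflectance over a 40 dB display range,
  zeroed outside the validity mask.

## Angiography

Decorrelation per adjacent repeat pair: 1 − |⟨E_r·E*_{r+1}⟩|/√(⟨|E_r|²⟩⟨|E_{r+1}|²⟩)
with the inner products summed over the detection channels *and* a 3-voxel
spatial kernel, averaged over the four pairs. The kernel is not optional:
per voxel the speckle field is one complex number whose change is
invisible to a normalized single-sample correlation; over a kernel of
independent speckle cells the statistic estimates ρ (verified within
±0.05). En-face maps are mean projections over a configurable depth window
below the detected surface; horizontal motion lines are flattened by
dividing each row by the ratio of its mean to a median-smoothed row-mean
profile. Registration is integer-pixel masked NCC (overlap-normalized via
FFT running sums, overlap ≥ 25% enforced, failure below NCC 0.2);
rotation/stretch are deliberately not corrected — the crop-to-overlap
strategy absorbs them. Vessel diameter is the linearly interpolated FWHM
of a sampled perpendicular profile with background taken from the outer
20% of samples; vessel fraction is percentile rescale → Otsu (or fixed)
threshold → opening/closing → percent of the density ROI covered.

## Fascicle metrics and statistics

Per timepoint, five analysis regions are placed at the midpoints of five
equal sub-spans of the stimulation span; in each, frames are averaged
(arithmetic, or coherent on the doubled-angle circle for the axis, masking
resultants < 0.3), a fascicle-ROI mean is taken over valid pixels (centers
inside the polygon, ≥50 valid pixels), and regions are averaged per
animal. The study statistic is Δmetric = per-animal (D7 − baseline)
averaged within each arm; a derived percent-vs-sham column
100·(Δ_g − Δ_SC)/|Δ_SC| is labeled as one defensible normalization of a
"percent change vs control" figure and is never asserted to equal any
published number. Group testing is a two-way (group × fascicle) ANOVA on
per-animal Δ values with Tukey-adjusted pairwise group contrasts per
fascicle; time-course vessel metrics use repeated-measures ANOVA across
the six timepoints with Tukey post hoc (statsmodels throughout).

## Cohort simulation

`run_cohort` simulates the three study arms (sham SC n=5, SL1 n=5, SL2
n=4 — fourteen animals, mirroring the one exclusion) at the five day-1
timepoints plus a day-7 tile, with per-animal biological jitter (4%
fractional SD on δ and µ) and injected day-7 effects expressed as
fractional changes of the underlying tissue parameter (e.g. −20% δ in
fascicle R of SL2 for the demyelination-like pattern). One master seed
fans out to per-animal, per-timepoint substreams so any stage can be
replayed. Failures quarantine the animal and continue. The cohort runs on
a 160×100×30 desk phantom (~2 minutes on one core for 84
simulate+reconstruct passes).

For power and type-I replication, `simulate_cohort_records` draws
per-animal Δ values directly from the same effect model, with noise scales
calibrated on the full-pipeline cohort (per-animal Δ SD ≈ 0.55° of
retardation, 0.13 mm⁻¹ of attenuation — speckle and noise realizations
change between timepoints, biological jitter cancels in the difference).
These record-level replicates represent reruns of the phantom cohort, not
real-animal variability, which is far larger and is exactly why the
published percent-change magnitudes are not reproducible from a desk.

## What the synthetic data does and does not show

The generator reproduces the features the estimators rely on: fully
developed speckle, exponential depth decay, reciprocal round-trip
polarization transfer, instrument-frame ambiguity, repeat-to-repeat flow
decorrelation, noise-limited imaging depth. It does not model multiple
scattering (depolarization is injected parametrically instead), bands of
Fontana, galvanometer distortion, tissue rotation/compression between
days, or electrode field physics. Passing recovery tests therefore
demonstrates the correctness of the estimators under their stated physics,
not robustness to every artifact of a live preparation.

## Known limitations

* The apparent (cumulative) optic axis is reported, as in standard Jones
  PSOCT; under an overlying birefringent layer with a different axis it is
  pulled a degree or two away from the local fiber axis.
* Retardation beyond a few full 360° wraps relies on the branch tracker;
  the default phantom keeps fascicle round trips under ~180° plus margin.
* The attenuation tail completion assumes the decay continues at the
  locally fitted rate; abrupt sub-resolution terminations would defeat it.
* Registration is integer-pixel translation only.
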