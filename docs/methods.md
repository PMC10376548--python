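# Methods

This note records the models and procedures behind each module, the
defaults that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real data.

## Pulse schedules

A session is a sequence of alternating on/off segments with integer
millisecond durations that sum exactly to the session length; the final
segment is clipped at the session boundary and its clipped remainder
counts toward its own state.  Conservation (on + off = session) therefore
holds exactly for every mode.

- **CV** is a single on segment.  **RP** alternates a fixed pulse and
  interval starting with a pulse; when the session is an integer multiple
  of the period, the duty cycle is exactly pulse/(pulse + interval).
- **VP** draws each duration as `lower + U{0 .. upper-lower-1}` ms, i.e.
  uniformly on the half-open range [lower, upper).  The generator is
  NumPy's seeded PCG64; a given seed reproduces the schedule
  byte-for-byte.  Only the distributional properties of the original
  Max/MSP-style construction (uniform integer offset added to the lower
  limit) are reproduced, not any particular archived sequence.  At the
  default limits (1000/1500 ms) the expected duty cycle is 50%, so a
  900 s session accumulates ≈ 450 s of pulse time; any single realization
  deviates by a few seconds.

Rendering gates a unit sine at the carrier frequency (default 50 Hz,
sample rate 8000 Hz, Nyquist enforced).  The phase resets to zero at each
pulse onset, producing the hard on/off envelope a switched signal chain
generates; a `continuous_phase` option keeps a free-running carrier
instead.

**Randomness diagnostics.**  The runs test is the two-sided
Wald–Wolfowitz normal approximation, dichotomizing about the median with
median ties dropped (requires n ≳ 20).  Its empirical type-I error is
calibrated to α ± 0.02 in the suite.  Entropy is Shannon entropy in nats
of the empirical distribution over distinct observed values, with
maximum ln n (5.89 for n = 360) attained when all values are distinct;
no binning is applied, so sequences with repeated values score lower.
Autocorrelation is the standard normalized sample estimator with
confidence half-width z(α)/√n.

## Accelerometer characterization

All quantities are computed on the mean-removed signal (the mean absorbs
the static gravity offset of each axis).  Peak is max |a|, RMS is over
the **full trace including silences** (this is what makes pulsed
conditions show crest factors near 4 while a continuous sine shows √2),
and crest factor is their ratio.

**Spectral integration.**  Velocity and displacement come from dividing
the rFFT of the SI-converted acceleration (g → m/s², g = 9.81) by (iω)
once or twice, zeroing DC and all bins below a 5 Hz high-pass cutoff to
suppress drift, and inverse transforming.  For a pure sine this is exact:
v_RMS · 2πf = a_RMS holds to better than 1%, which the suite asserts as
the integration oracle, alongside a Parseval identity check on the
spectrum scaling.

**Fundamental.**  Arg-max magnitude bin in a search band (default
20–200 Hz) refined by three-point parabolic interpolation.

**Activity segmentation.**  Coarse detection thresholds a moving-RMS
envelope (window = one carrier period) at 10% of the trace peak by
default, and merges runs or gaps shorter than 50 ms.  Each coarse
boundary is then refined by intersecting the two asymptotes of the
cumulative signal energy around it: flat in the silence, linear inside
the pulse.  The cumulative energy is first smoothed with a one-period
boxcar, which cancels the sin 2ωt energy ripple exactly when the sample
rate is an integer multiple of twice the carrier; the intersection then
locates the gate edge to a fraction of a sample for pulses spanning whole
carrier cycles (the suite checks 450 s ± 50 ms on a rendered 900 s RP
trace).  When a boundary is too close to the trace ends for the
asymptote windows, the coarse boundary is kept.  Vibration plus silence
time equals the trace duration exactly by construction.

**Amplitude distributions.**  Histogram of |a| over caller-supplied
edges; values beyond the outermost edge are counted in the outermost bin
so counts always sum to the sample count.  A signed histogram over
mirrored edges is returned alongside.

## Particle tracking velocimetry

Coordinates put the origin at the bottom-left of the imaged plane with y
up and pixel centers at half-integers.  Detection thresholds the frame
(Otsu by default), labels connected components, discards those below
`min_area`, and takes intensity-weighted centroids; two particles merged
into one blob yield one centroid (documented limitation of blob-based
PTV).  Linking is greedy nearest-neighbour per frame pair, injective,
with links beyond `max_disp` (default 10 px) rejected — adequate at the
sparse seeding this technique needs; global assignment is out of scope.

Velocities are per-track finite differences (Δposition × frame rate,
divided by the frame gap when frames are skipped), located at step
midpoints, averaged per grid cell; empty cells are NaN, never zero.  A
camera running far below the vibration carrier samples stroboscopically,
so these are mean drift (streaming) velocities, not oscillatory motion.

**Boundary shear.**  τ(x) = μ·u(x, y₀)/y₀ with y₀ the center height of
the lowest grid row holding a cell with at least `min_count` (default 5)
samples — the lowest height where velocity is reliably measured.  τ is
signed with the flow direction.  μ is a required physical parameter; the
default 0.00094 Pa·s corresponds to DMEM-like culture media at 37 °C and
**must be set to the medium actually used** — shear scales linearly
with it.  On a noise-free linear (Couette) profile sampled at cell
centers the estimate equals μγ exactly; with random sampling the
within-cell mean-height offset adds a bias of order cell-height/2y₀,
which shrinks with grid refinement.

**Motiongram / QoM.**  Consecutive frames are differenced; absolute
differences at or below the noise floor are zeroed.  The motiongram
collapses each difference image along one axis (mean) and stacks over
time; QoM is the per-frame sum of supra-threshold |difference| divided by
pixel count, zero exactly when frames agree to within the floor.

## Actin Analyzer

The segmentation criterion keeps pixels whose Laplacian response is at
least the image mean minus one standard deviation of that response.  A
discrete Laplacian is negative at the center of a bright ridge, so the
response is computed as the **negated** 5-point Laplacian
(`laplacian_sign = -1`), making ridge centers score high; the raw sign is
available as a switch.  Because background has near-zero Laplacian and
the threshold sits one standard deviation *below* the mean, the criterion
alone admits flat background; the mask is therefore intersected with a
foreground guard (intensity ≥ Otsu threshold).  A constant image warns
and returns an empty mask.

Skeletons are thinned to one pixel, connected skeletons below
`min_skeleton_px` (default 5) are dropped as noise, and branched
skeletons are split at junction pixels, joining the two longest branches
through each junction.  Gap bridging joins endpoint pairs within
`bridge_max_dist` (default 5 px) whose local orientations (line through
the terminal 5 skeleton pixels, axial, mod 180°) differ by at most
`bridge_max_angle_diff` (default 20°), greedily by ascending distance
with each endpoint used once per pass; passes repeat to a fixpoint, so
the operation is idempotent.  These defaults are exposed, not canonical:
suitable values depend on magnification and staining quality.

**Measurements.**
- *Length*: chain-code step sum (1 axial, √2 diagonal) by default — this
  is the measure with exact closed forms on clean paths.  The batch
  pipeline uses the Vossepoel–Smeulders calibrated estimator
  (0.980·n_axial + 1.406·n_diag − 0.091·n_corners), which removes the
  systematic staircase overestimate (up to +8% near 22.5°) of the plain
  chain code for digitized straight lines.
- *Thickness*: 2 × mean Euclidean distance transform along the skeleton
  minus one pixel, times the pixel size.  The EDT at a skeleton pixel
  measures to the nearest *background pixel center*, half a pixel beyond
  the physical edge on each side; the −1 px correction makes a 5-px-wide
  bar measure 5 px and keeps the 1-px-line → 1-px identity.
- *Angle*: orientation of the endpoint-to-endpoint chord, degrees in
  (−90, 90], 0 along the image x-axis, y up.  Only 2D orientation is
  meaningful; direction is not.

The outlier filter removes filaments strictly longer than 100 µm
(exactly 100 µm is retained) as segmentation artifacts — at SIM
resolution such lengths are merged structures, not single filaments.

**Accuracy on synthetic scenes.**  On rendered scenes of straight,
well-separated filaments (see below) the pipeline recovers ≥ 90% of
planted filaments with length error within max(5%, 2 px), angle within
3° and thickness within 25%.  Two residual biases are known: (i) the
skeleton extends ~1–2 px into the PSF tail beyond each bar tip, partially
cancelled by the medial axis stopping one half-width short of the mask
tip — on very short filaments the net effect can reach +5–7% of length;
(ii) thinning is not exactly rotation-equivariant, so individual lengths
move by up to ~5% under a 90° image rotation while scene-level means stay
within 2%.

## Statistics

Skewed features (lengths, thicknesses) use Kruskal–Wallis as omnibus and
pairwise Wilcoxon rank-sum post hocs; approximately normal features
(angles) use one-way ANOVA and pairwise Welch t tests (the
unequal-variance form, since per-condition variances need not match).
Routing is caller-declared, not auto-tested.  No multiplicity correction
is applied by default; a Holm option exists.  Pooling is selectable:
filaments as units (large n, anticonservative if images are the true
replicates) or per-image medians.  Pearson correlation operates on
condition-level summaries against mechanical parameters and refuses
zero-variance input; with only a handful of conditions it is descriptive,
not inferential.

## Synthetic fixtures

- *Filament scenes* render anti-aliased bars (sub-pixel coverage from
  distance to the bar's center segment), blur with an isotropic Gaussian
  PSF (default σ = 1 px), and add Gaussian noise (Poisson optional).
  Default calibration 0.04 µm/px with filaments of 1.5–3.5 µm ×
  0.12–0.24 µm at SNR ≈ 100:2 — resolvable, well-separated structures so
  that recovery errors are attributable to the algorithm rather than to
  scene ambiguity.  Real phalloidin/SIM images are dense, curved,
  crossing meshes with structured background; passing the recovery suite
  shows the pipeline's geometry is correct, not that its output on real
  meshes is unbiased.
- *Accelerometer traces* gate a sine carrier (default 51 Hz, matching a
  typical measured fundamental pulled slightly above a 50 Hz drive by
  mechanical resonance) with a schedule, add optional odd-harmonic
  components and Gaussian noise; x/y axes carry noise only.  The default
  amplitude 2.39 g makes the continuous-carrier RMS 2.39/√2 ≈ 1.69 g,
  a realistic magnitude for this class of rig.
- *Particle videos* advect tracers in the steady stream function
  ψ = Ψ sin(2πx/W) sin(πy/H) — the simplest field with two
  counter-rotating vortexes, zero normal flow at the walls, and a
  near-wall flow direction that splits between the left and right halves.
  Integration is classical RK4 at the frame interval with reflective
  walls (particle count conserved); an optional gating schedule freezes
  the flow during off segments.  The amplitude Ψ is a free parameter;
  the model makes no claim of fidelity to acoustic streaming magnitudes.

All generators are deterministic under a fixed seed.

## Problem sizes and degenerate inputs

The suite runs on deliberately small instances: 10–900 s schedules,
traces at 3200 Hz, 384² filament scenes with 20 filaments, 60–200-frame
128² videos with 80–150 particles, 1000-replicate calibration loops —
sizes at which every oracle is computable in seconds while leaving the
algorithms' asymptotics untouched.  Degenerate inputs fail loudly:
constant images, all-zero signals, zero-variance sequences, empty bands,
groups with n < 2 and unmeasurable single-pixel paths all raise (or warn
and return empty) rather than returning silent zeros.
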