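# Methods

`dotiqa` simulates frequency-domain diffuse optical tomography (FD-DOT) on
a breast-mimicking disc phantom, reconstructs absorption and reduced
scattering images by Tikhonov-damped Gauss–Newton inversion, and scores
the reconstructions with four structural-similarity metrics — MSSIM,
MS-SSIM, MISSIM-S and the multiscale improved SSIM with sharpness
(MS-ISSIM-S) — whose agreement with observer opinion is quantified by
tie-corrected Spearman rank correlation.  This note records the model, the
parameter choices and their rationale, the numerical conventions, and what
the synthetic pipeline does and does not establish.

## Geometry and meshes

The domain is a disc of radius 40 mm (80 mm diameter) centred at the
origin.  Meshes are structured: a fan of `f` triangles sharing the centre
node, refined uniformly 1:4 `k` times, with every midpoint of a boundary
edge projected radially onto the circle.  Node ordering is deterministic
(centre, initial ring, then refinement order), so meshes are
bit-reproducible.  Two instances are used:

* forward mesh: `f = 8, k = 5` → 4225 nodes, 8192 elements, 256 boundary
  nodes;
* inverse mesh: `f = 6, k = 4` → 817 nodes, 1536 elements, 96 boundary
  nodes.

Using different discretizations for data generation and inversion avoids
the inverse crime.  Sixteen sources and sixteen detectors are interleaved
on the boundary: sources every 22.5° starting at 0° (east, counter-
clockwise), detectors offset by 11.25°.  Both boundary node counts are
multiples of 32, so every optode coincides exactly with a boundary node.
The source start angle is a convention (the physical layout fixes only the
spacings) and is configurable.

## Forward model

The photon fluence Φ(r, ω) obeys the frequency-domain diffusion equation

    −∇·(D ∇Φ) + (μa + iω/c) Φ = S0,     D = 1 / (3 (μs′ + μa)),

with the Robin condition −D ∂Φ/∂n = αΦ on the boundary.  The sign of the
iω/c term follows the standard FD convention (phase lag grows with
distance); the opposite literal sign is available via
`FDSettings.literal_paper_sign` for comparison.  Galerkin P1 elements give
a complex-symmetric sparse system; element coefficients are the means of
the three nodal values, which keeps the parameter Jacobian of the operator
exact and cheap.  Sources are unit point loads at boundary nodes; one
sparse LU factorization per optical-property state serves all sixteen
sources and, via symmetry, the sixteen detector adjoints.

Defaults (none is dictated by the physics alone; all are configurable):
modulation frequency 100 MHz, refractive index 1.4 (soft tissue), and
α = (1 − R_eff)/(2(1 + R_eff)) with R_eff = 0.493 from the standard
internal-reflection approximation, giving α ≈ 0.170.  Internally lengths
are mm and times ns, so ω/c ≈ 2.93 × 10⁻³ mm⁻¹ at 100 MHz.

Verification: the interior amplitude of a homogeneous disc tracks the 2-D
infinite-medium kernel K0(kr), k = √((μa + iω/c)/D).  Over nodes at least
10 mm from both the source and the boundary the RMS relative amplitude
deviation after one proportionality fit is ≈ 9%; the RMS statistic is used
because the Robin boundary genuinely suppresses the field near the rim
(pointwise deviations reach ~25% at the 10 mm margin in any bounded
domain — a property of the geometry, not a solver error).

## Measurements and calibration

Each acquisition records 256 (source, detector) pairs of log amplitude
ln|Φ| and phase arg Φ, the phase unwrapped along each source's detector
sequence.  A unit point load is not perfectly comparable across
discretizations: the coarse mesh under-resolves the near-source
singularity, producing a systematic per-record offset between fine-mesh
data and the coarse model (≈ 0.10 mean in log amplitude — an order of
magnitude above the 1% noise floor).  The study therefore calibrates
measured data by subtracting the offset computed once from the homogeneous
background on both meshes, the numerical analogue of calibrating an
instrument on a homogeneous reference phantom (standard DOT practice).
The heterogeneity signal still originates on the fine mesh.

## Inverse solver

Gauss–Newton iterations minimize χ² = ‖Δ(log amp, phase)‖² over nodal
(μa, D) with damped normal equations (JᵀJ + λ²I)Δχ = JᵀΔΦ.  The Jacobian
is assembled by the adjoint method and validated against central finite
differences (≤ 10⁻³ relative).  For the wide systems arising here the
update is computed through the exact dual identity
Δχ = Jᵀ(JJᵀ + λ²I)⁻¹ΔΦ (512×512 instead of 1634×1634).

Numerical conventions:

* Column scaling — Jacobian columns are normalized by the background
  parameter magnitudes so the μa (~0.01 mm⁻¹) and D (~0.33 mm) blocks share
  one damping scale.
* Damping — λ² = λ0 · max diag(JᵀJ) with λ0 = 0.01 halved per iteration to
  a floor of 10⁻⁴ (Levenberg–Marquardt style).
* Stopping — whichever comes first: relative χ² improvement < 2%, 20
  iterations, or the discrepancy principle: χ² at or below the expected
  noise level of the applied noise model (n·f_amp² + Σ(f_phase·phase)²).
  The discrepancy stop is the operative one under noise; without it the
  loop drives χ² several-fold below the statistical noise floor and the
  artifact level becomes an artifact of the random seed rather than of the
  phantom.
* Positivity — after each accepted update, fields are clipped to
  [0.2×, 5×] background; χ² is non-increasing over accepted iterates (step
  halving on increase; a stall after the first iteration is reported as
  convergence at the residual floor, a failure to decrease at the first
  iteration as divergence).
* μs′ recovery — μs′ = 1/(3D) − μa, with the unphysical case 1/(3D) ≤ μa
  raised as an error (the clip range prevents it in practice).

## Phantoms, study grid and noise

Background μa = 0.01 mm⁻¹, μs′ = 1 mm⁻¹.  One circular inclusion sits at
90° (north), its centre 20 mm from the domain centre — the half-radius
keeps even the largest (10 mm) inclusion 10 mm clear of the boundary; the
centre distance is a package choice, exposed in the spec of each phantom.
Demonstration cases: A1 (invisible 2.5 mm, μa 0.02 / μs′ 2; visible 10 mm,
μa 0.02 / μs′ 3) and A2 (invisible 2.5 mm, μa 0.02 / μs′ 0.89; visible
10 mm, μa 0.03 / μs′ 0.89).  Assessment grids: B1 — radii
2.5/3.75/5/6.25/7.5/8.75/10 mm × μs′ ∈ {2, 2.5, 3} at μa = 0.02; B2 — the
same radii × μa ∈ {0.02, 0.025, 0.03} at μs′ = 0.89.  Two cases × two
noise conditions × 21 phantoms × two properties = 168 images, hence 672
metric evaluations.

Noise conditions: "1%" applies multiplicative Gaussian amplitude noise
|Φ|(1+ε), ε ~ N(0, 0.01²); "10%" applies 10% amplitude noise, additive
phase noise with σ = 0.1·|phase| (proportional scaling is a package
reading of an under-specified magnitude; an absolute-radians variant would
be a one-line change), and a 10% relative perturbation of the homogeneous
initial guess (one draw per property).  Perturbing the initial guess — not
the true phantom — keeps the ground truth fixed while degrading the
inversion's starting information.  A master seed is split deterministically
per (case, noise, radius, contrast), so any single reconstruction is
reproducible in isolation.

## Imaging

Nodal fields are interpolated barycentrically onto a 160×160 pixel grid
(0.5 mm/pixel); pixels outside the mesh take the background value, which
avoids a spurious high-contrast rim.  The side must be a multiple of
2^(K−1) = 16 so the K = 5 dyadic downsamplings are exact, and the coarsest
scale (160/16 = 10 px) must still admit the 9×9 analysis window — this is
why the grid is 160 rather than the superficially natural 128 (128/16 = 8
cannot hold a 9×9 window).  Reference and test images are quantized to
L = 255 gray levels with one shared affine scale — in a study, the global
range of that property over all images of the condition — because
per-image scaling would erase exactly the contrast differences the metrics
must detect.

## Metrics

All four metrics slide a 9×9 Gaussian window (σ = 1.5, unit sum, stride 1,
windows fully inside the image — no boundary padding is fabricated) and
use C1 = (K1 L)², C2 = (K2 L)², C3 = C2/2 with K1 = 0.01, K2 = 0.03
(standard SSIM constants; the originals are only constrained to be ≪ 1).

* MSSIM: mean over windows of l·c·s (luminance, contrast, structure, unit
  exponents).
* MS-SSIM: contrast and structure pooled at K = 5 scales obtained by 2×2
  mean filtering and decimation, luminance at the coarsest scale only,
  combined with exponent weights β = (0.0448, 0.2856, 0.3001, 0.2363,
  0.1333) (βk = γk = αk; the printed weights sum to 1.0001).
* MISSIM-S: per-window l·c·s̃·h where s̃ splits each window's standard
  deviation into below-mean and at-or-above-mean parts (strictly-below
  defines the "−" subset; subset weights renormalized; deviations about
  the full-window weighted mean; an empty subset contributes σ = 0) and h
  compares the scalar magnitudes λ of the mean-removed windows,
  h = (2λxλy + C2)/(λx² + λy² + C2).
* MS-ISSIM-S: the MS-SSIM pooled combination multiplied by the across-
  scale *mean* of the pooled sharpness term h̄k.

Two printed formulas required a reading.  The sharpness comparison as
printed has the product denominator (∇²x)²(∇²y)², which is dimensionally
inconsistent and unbounded; the package interprets ∇²x = x − μx as a
mean-removed window whose scalar magnitude is its weighted RMS and uses
the standard bounded similarity form (equal to 1 at identity).  The
multiscale prefactor is printed as a sum Σh̄k but described as a mean; the
mean is adopted so identical images score exactly 1.  Both literal
variants remain available (`SSIMConfig.sharpness_literal`,
`SSIMConfig.ms_prefactor = "sum"`).

Every metric is symmetric, bounded above by 1, equals 1 exactly on
identical images, and is non-increasing under growing additive noise
(verified over seeds).  The sliding-window implementation is checked
against an independent ndimage-based evaluation and, with a matched 11-px
window, against scikit-image's SSIM to machine precision.

## Evaluation

Spearman's ρ between metric scores and mean opinion scores (MOS) is
computed per (case, noise, property) group of n = 21 images.  Two tie
policies: the printed difference-of-ranks formula with (m³ − m)/12
corrections from both variables added to the Σd² sum, and the exact
Pearson correlation of average ranks, which serves as its oracle (they
coincide without ties).  Scores are correlated with MOS directly, so a
metric whose similarity *falls* as detectability rises yields ρ near −1
against a detectability-increasing MOS; the magnitude carries the
association.  MOS means are not rounded before ranking.  Visibility
classification thresholds each group at its median score: images strictly
below the median (less similar to the homogeneous reference) are called
visible; ties at the median fall on the invisible side — the conservative
direction, fewer false "detectable" calls.

No human observer data ships with the package.  `synth_mos` generates a
synthetic panel of 20 subjects: latent detectability
1 + 4·logistic((radius × contrast − 6)/2) with contrast the largest
relative optical deviation of the inclusion from background, rounded and
jittered by {−1, 0, +1} (probabilities 0.2/0.6/0.2), clipped to [1, 5];
zero detectability scores exactly 1 from every subject.  The generator
emulates a monotone psychometric response with inter-subject variability.
It does not emulate real observer biases (learning, criterion drift,
display dependence), so correlations computed against it certify the
evaluation machinery, not human agreement; published correlation values
against real observers depend on observer data that is not public.  One
structural difference matters at high noise: the synthetic panel rates the
*phantom specification* (radius × contrast), whereas a human rates the
*rendered image*.  Under the 10% condition, where reconstruction noise
dominates small-inclusion images, metric scores and the spec-driven
synthetic MOS therefore decorrelate even though a human shown the same
noisy images would remain correlated with the metrics.

## Problem sizes and determinism

The default study (84 reconstructions on the 817-node mesh, 168 images,
672 metric evaluations) completes in minutes on one CPU; the test suite
exercises a single (case, noise) condition — 21 reconstructions — plus
cheap module-level oracles.  Every stage output is a function of the
configuration and master seed; a stored config reproduces measurement
CSVs, field files, PNGs and score tables byte-for-byte.

## Limitations

2-D geometry, single circular inclusion, unit point sources, absolute
(non-spectral) optical properties, no spatially varying regularization or
L-curve selection, and synthetic observers as discussed above.  Passing
tests show the pipeline is internally consistent and reproduces the
stated geometric, numerical and trend properties of the simulated study;
they do not validate against physical measurements or clinical readers.
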