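# Methods

## Forward model and problem setting

A compact complex-valued object ρ(r) on an N×N grid (optionally 3D) is
observed through the squared modulus of its far-field diffraction
pattern: the detector records photon counts I_i^obs drawn from a
Poisson law with mean proportional to |F_i|², F = FT(ρ).  The pattern
is *oversampled* — the grid extent exceeds the object extent by the
oversampling ratio (≥ 2, typically 3–4) — which is what makes the
phase-retrieval problem well-posed up to its intrinsic ambiguities:
translation, a global phase factor, and the twin image ρ*(−r).

All Fourier transforms use the orthonormal (`norm="ortho"`) convention,
so Parseval's identity holds without bookkeeping factors and a converged
solution satisfies |F^calc| ≈ √I^obs directly.  Fourier-space arrays are
kept in FFT layout (zero frequency at index 0, distances computed with
wrap-around); files store the human-readable centered layout and the
I/O layer shifts on read/write, bit-exactly.

## Iterative projection algorithms

With P_F the Fourier-magnitude projection and P_S the support
projection onto Ω (optionally with positivity: pixels with negative
real part are zeroed and imaginary parts dropped — the real-part
convention), one cycle of each algorithm maps the iterate ρ to:

* **ER**: ρ' = P_S P_F ρ.
* **HIO**: ρ' = P_F ρ on the constraint-satisfying region (inside Ω,
  and Re ≥ 0 under positivity); ρ' = ρ − β P_F ρ elsewhere.  β = 0.9 by
  default (community-standard value; the protocols this package mirrors
  do not state one).
* **RAAR**: ρ' = ½β(ρ + R_S R_F ρ) + (1−β) P_F ρ with reflectors
  R = 2P − I, which reduces elementwise to P_F ρ on the satisfying
  region and βρ + (1−2β) P_F ρ elsewhere.  β = 0.75 by default.

**Free-set-aware Fourier update.** P_F replaces the calculated
amplitude by √I^obs (calculated phase kept; zero-amplitude pixels get
zero phase — a measure-zero event) on *working* pixels only.  Pixels in
the free set and unmeasured pixels (beamstop, dead areas) keep their
calculated complex value, bit-unchanged.  This is the property that
makes the free log-likelihood unbiased: the optimisation never sees the
withheld data.

**Shrinkwrap.** Every `update_every` cycles (default 20) the support is
re-estimated as the region where a Gaussian blur (σ = 2 px by default,
constant; an optional linear decay is available) of the amplitude of
the support-projected Fourier estimate exceeds `threshold` × its
maximum.  Thresholds between 0.1 and 0.4 are typical; the multi-start
runner draws one per run from a configurable interval.

**Detwinning.** The support is cut by the hyperplane through its
centroid perpendicular to its longest axis, keeping the half with the
larger |ρ|² mass (ties go to the lower-index half), and the object is
masked accordingly.  This breaks the twin ambiguity early in a run; the
exact procedure used by published protocols is not standardised, and
this half-space cut is the package's documented choice.

**Initialisation and reproducibility.** Runs start from a random object
(amplitudes uniform in [0,1), phases uniform in [0,2π)) inside the
initial support.  Every source of randomness flows from a single seed
through `numpy` SeedSequence spawning, so single runs are bit-reproducible
and multi-start runs are independent and reproducible as a set.

**Presets.** `logo` = 400 HIO + 200 ER (compact high-contrast objects);
`cell` = 2000 HIO with positivity and detwinning after cycle 1000, then
2000 HIO and 2000 RAAR without positivity, then 200 ER (low-contrast
specimens where the support is hard to pin down).

## Figures of merit

For a solution with support Ω (N = number of pixels in the evaluated
subset; the package counts the subset actually used, working or free):

* E_o² = Σ_{i∉Ω} |ρ_i|² / Σ_i |ρ_i|², computed on the raw (un-projected)
  final iterate — the support-projected object has E_o² ≡ 0 by
  construction, so the free-running iterate is what carries information.
* E_F² = Σ (|F_i^calc| − √I_i^obs)² / Σ I_i^obs on the working set
  (amplitude comparison, since observed phases are unknown; an
  intensity-based variant is exposed as an option).
* LLK = (1/N) Σ [I^calc − I^obs log I^calc + log(I^obs!)] on the working
  set; log-factorials via log-gamma; the I^obs = I^calc = 0 term is 0;
  I^calc = 0 with I^obs > 0 is floored at 1e−20.  By default no global
  rescaling is applied (the Fourier projection already pins the scale);
  `scale="working_flux"` rescales I^calc to the working-set flux for
  un-projected models.
* LLK_free — the same quantity on the free set.  Rankings by LLK_free
  are only comparable across solutions scored against the *same* free
  mask; the selection routine enforces this via a mask digest.

F^calc is the FT of the support-projected object, so LLK, LLK_free and
E_F² refer to the density the support actually allows.

## Free-set construction

Free pixels are grouped in Euclidean balls (radius 3 px by default)
around centres drawn uniformly without replacement from valid pixels
outside a central exclusion zone (5% of the maximum centre-to-pixel
distance), until the marked fraction of valid pixels first reaches the
5% target; islands may overlap (not double-counted) and are clipped by
the valid mask and the exclusion zone.  The island size matches the
typical oversampling ratio, keeping the free set statistically
independent of the working set despite pixel-to-pixel correlation;
"radius 3" is interpreted as a discrete Euclidean disk (diameter 7).
The mask is generated once per comparison campaign and persisted with
the pattern; per-solution re-randomisation is available as an explicit
option, but ranking requires a fixed mask.

## Combination and PRTF

The stack of selected solutions is aligned to the solution with the
lowest LLK_free: for each solution, both the original and the twin are
registered by upsampled cross-correlation of |ρ| (default precision
1/20 px), the global phase θ = arg Σ ρ·ρ_ref* is removed, and the
candidate with the higher normalized correlation wins.

The eigen-decomposition flattens each aligned solution into a row of a
matrix A and computes its SVD through the n×n Gram matrix A·Aᴴ
(mathematically identical to the full SVD).  Mode m is the σ_m-scaled
right singular vector, so Σ_m ‖mode_m‖² = Σ_k ‖solution_k‖² (total
squared amplitude is conserved) and weight_m = σ_m²/Σσ² × 100%.  A
first-mode weight near 100% indicates consensus; a single outlier is
absorbed by secondary modes rather than contaminating the first mode,
which is why the first mode is preferred over the plain average.

PRTF(r) = Σ_{i∈ring∩working} |⟨F_i⟩| / Σ_{i∈ring∩working} √I_i^obs with
the average complex across solutions, rings linear in spatial frequency
(50 by default) up to the Nyquist fraction 0.5; free and unmeasured
pixels are excluded, empty rings skipped.  The cutoff is the first ring
centre below 50%.  The per-ring sum-ratio (rather than averaging
per-pixel ratios) is the package's documented convention.

## Synthetic data

The generator emulates the experimental data model end to end: a
phantom confined to the central grid/oversampling box (binary block
glyphs drawn procedurally; random non-overlapping binary disks; or a
smooth elliptical "cell" with Gaussian granules and an optional smooth
phase of ≤ π/2 span), an expected photon budget over the whole detector
(default 10⁸, comparable to high-quality 2D CDI data; a sentinel
disables noise entirely), a circular beamstop of configurable radius
marking low-q pixels invalid, and optional centro-symmetrization.

What it does **not** emulate: partial coherence, detector point-spread
and gaps, flat-field errors, multi-frame 3D merging, background
scattering.  Passing tests therefore demonstrate the correctness of the
algorithms and the cross-validation machinery under ideal counting
statistics, not robustness to every experimental systematic.

`oracle_compare` scores a reconstruction against ground truth by the
normalized inner product after registration, twin and phase matching —
1.0 means perfect recovery up to the intrinsic ambiguities.

## Study conditions of the shipped experiments

The flagship recovery experiment (also what `scripts/acceptance.py`
re-runs) uses a 128×128 disks phantom at oversampling 4, 10⁸ photons,
no beamstop, a 5% free set (radius-3 islands, 5% central exclusion), 20
multi-start `logo` runs from the true support dilated by 7 px with
shrinkwrap thresholds drawn in [0.25, 0.4], selection of the best 4 by
LLK_free, eigen-combination and PRTF.  These sizes run in minutes on a
single CPU while leaving the recovery far from trivial (the initial
support is ~4× the true one).

The over-fitting experiment dilates the true support by 0/1/2/4/7 px,
phases each with 200 HIO + 100 ER at 10⁷ photons against a fixed free
mask and compares metrics across dilations.  These runs use the
positivity constraint (the phantom is real and nonnegative): the
over-fitting signal — working LLK decreasing monotonically with support
size while LLK_free picks the tight support — only emerges once each
fixed-support optimisation converges near its own optimum, and
unconstrained HIO at this cycle budget stagnates on the loose supports,
which would measure stagnation noise instead of over-fitting.

## Numerical choices and edge cases

* Zero-amplitude working pixels in P_F take phase 0.
* Centro-symmetrization fills an unmeasured pixel from its partner
  (2c − k mod n per axis); where both partners are measured the
  measured value is kept (no averaging — minimal modification of data);
  self-partnered pixels are untouched.  The operation is idempotent and
  never reduces the number of valid pixels.
* Metrics raise explicit errors on empty subsets or zero-power objects
  rather than returning NaN; the one deliberate NaN is LLK_free on a
  pattern with no free set.
* Support updates guarantee a non-empty support or raise; divergence
  (non-finite iterates) raises with the cycle index.
* Eigen-mode weights are clipped at 0 before normalisation to absorb
  eigh round-off on rank-deficient stacks.

## Known limitations

* Poisson is the only noise model (photon-counting detectors); the
  ranking machinery itself is noise-model agnostic but no Gaussian
  variant is provided.
* No GPU or FFTW backend; `numpy.fft` is adequate at the grid sizes the
  package targets (≤ 512², small 3D volumes).
* Anisotropic free-set islands (per-direction radii) are not
  implemented.
* The detwinning cut assumes a simply-connected object; exotic
  multi-part objects may need manual support intervention.
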