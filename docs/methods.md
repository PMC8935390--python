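# Methods

This note records the models, estimators, numerical choices and known
limitations behind `cryovalid`, at the level of detail a user needs to
judge what a passing test suite does and does not establish.

## Grid and transform conventions

A map is a real scalar field on an orthogonal grid, `data[ix, iy, iz]`,
with voxel (0,0,0) centred at the map origin and spacing `pixel_size` Å per
axis. Files with permuted axis order (MAPC/MAPR/MAPS) are normalized to
(x, y, z) on read; integer MRC modes are promoted to float32; writes always
emit MRC2014 mode 2. Non-orthogonal cells are rejected — the methods assume
Cartesian FFT grids. When a header's ORIGIN record and NXSTART-style offsets
disagree, the ORIGIN record wins and the conflict is logged. The forward
FFT is the plain unnormalized DFT; the inverse carries 1/N.

Rigid transforms act about the geometric grid centre,
x ← m·R(x − c) + c + t, with R parameterized by an axis–angle vector and m
a scalar magnification (1 for rigid moves). `fit_transform` returns the
transform that carries the *moving* map onto the *static* one; if the
moving map was produced by applying T to the static map, the fit returns
T⁻¹ (same rotation angle and translation magnitude).

## Resolution shells, FSC and signal/noise estimation

Shells are uniform in |s| between 0 and 1/resolution; points beyond the
limit are excluded everywhere. The default shell count is half the largest
grid dimension; shells with fewer than 5 coefficients are flagged
unreliable. FSC uses the real part of the cross term (maps are real). Half
pairs are modelled as common signal plus independent noise: per shell,
signal S = ⟨Re F₁F₂*⟩ (clamped ≥ 0), total T = (⟨|F₁|²⟩+⟨|F₂|²⟩)/2, noise
σ² = max(T − S, 0). This direct decomposition is used instead of an
FSC-derived σ² because it is numerically stabler and equivalent in
expectation. The per-shell signal standard deviation √S stands in for the
(unobservable) blurring factor and is stored for downstream use.

Normalization divides each coefficient by the per-shell total standard
deviation √(S+σ²); weighting multiplies by √(full-map FSC), with
non-positive-FSC shells zeroed. Model-derived maps carry no noise term and
are normalized against their own per-shell power instead.

## Local correlation

The kernel is flat (1/Z) inside r₀, raised-cosine to zero at r₁ (default
r₀+2 voxels), zero outside, with Z fixed by the *discrete* sum so the
weights add to exactly 1. Local moments are circular FFT convolutions,
identical to direct windowed sums to ~1e-15; edge voxels therefore mix
density from opposite faces, so maps whose signal reaches the box edge
should be padded or masked first. Voxels whose local variance falls below
1e-12 × the largest local variance are reported as undefined rather than
0/0. The kernel radius is a user choice (CLI default r₀ = 3 voxels): too
small gives unstable statistics, too large blurs locality.

For map–model comparison both inputs pass through the shell normalization
and FSC weighting above, which is what makes `CCmap,model` and `CCfull`
comparable. Two statistical facts matter when interpreting them:

- the perfect-model equality `CCmap,model ≈ CCfull` holds where the signal
  is solid; in weak-signal voxels both quantities are noise-dominated
  estimates and their ratio is meaningless. The test suite evaluates the
  perfect-model median ratio where `CCfull > 0.5` for this reason.
- `CCfull = 2c/(1+c)` amplifies the sampling noise of the half-map
  correlation c in low-signal regions (the slope 2/(1+c)² diverges as
  c → −1). Voxel-wise comparisons must therefore use a delta-method
  standard error, with the effective number of independent samples in the
  kernel reduced by the band-occupancy fraction of the FSC-weighted
  spectrum (the weighted maps are low-passed, so neighbouring voxels are
  correlated). Both corrections are implemented in the acceptance tests.

## Model-derived density

One isotropic Gaussian per atom: ρ(x) ∝ occ·amp·exp(−4π²|x−xₐ|²/B′) with
B′ = B + a per-element base width (10 Å²) and amplitude proportional to the
atomic number. Synthesis happens in Fourier space (a Gaussian transforms to
a Gaussian), hard low-passed at the requested resolution, which avoids
real-space truncation artifacts. This is deliberately a coarse density
model — the correlation machinery needs a spectrally plausible model map,
not a scattering-factor tabulation; anisotropic B, solvent and proper
electron form factors are out of scope.

## Likelihood overlay

The optimized functional is the weighted cross-term
Σₛ w(|s|)·Re[F₁*(s)·F₂moved(s)]. Per shell, w is the positive off-diagonal
of the inverse 2×2 correlation matrix of the pair, ρ/(1−ρ²), divided by the
geometric-mean power so coefficients enter normalized; shells with ρ ≤ 0 or
fewer than 5 points get zero weight, and ρ is capped at 0.99 so near-perfect
shells cannot dominate without bound. Weights are re-estimated from the
data at the current alignment at every outer iteration.

Off-lattice evaluation of F₂ is the accuracy-critical step and went through
three designs worth recording:

1. Raw trilinear interpolation of the coefficient lattice fails outright:
   a density far from the array origin imprints a phase ramp on its
   transform with period comparable to the reciprocal lattice spacing.
   Pre-phasing by exp(+2πi s·c) — implicitly recentring the map at the
   origin — removes the ramp.
2. Trilinear interpolation of the recentred field still leaves a ~2–4%
   error floor whose structure depends on how the sampled points fall
   against the lattice. That floor acts as a systematic attractor toward
   lattice-aligned orientations and scales — strong enough to swallow a
   few-degree rotation of a masked domain or to bias a scale estimate by
   several tenths of a percent.
3. The production path therefore zero-pads the moving map 3×, recentres,
   and stores the field as prefiltered cubic B-splines. Interpolation error
   drops to ~1e-4 relative, and the spline's analytic gradient is smooth
   and exact, which the quasi-Newton steps need.

Rotation gradients are taken in the local chart (R·exp([δ]×) at δ = 0,
where dq/dδₖ = m(u × eₖ) with u = Rᵀs) and mapped to the absolute
axis–angle parameters via the SO(3) right Jacobian; translation and
magnification gradients are the corresponding phase and frequency-scaling
terms. The inner solve is L-BFGS with restart-on-stall; convergence is
declared when the functional changes by less than 1e-6 relative across an
outer iteration. A two-stage resolution schedule (first at twice the target
cutoff) guards the basin for large initial offsets.

Residual accuracy: a self-fit of a 48³ phantom returns a rotation of
~0.03° rather than exactly zero. With a smooth objective the tiny
asymmetry left by periodized blob tails (≤ e⁻⁴·⁵ of the peak at the box
faces) displaces the maximum measurably; the displacement shrinks with
larger margins and is far below the parameter-recovery tolerances. The
translation component of a self-fit is exact to < 0.01 voxel.

## Magnification refinement

A magnification acts on the frequency lattice (coefficients sampled at
m·Rᵀs), never by real-space zoom. The m³ Jacobian of a physical
magnification is *excluded* from the fitted score: the likelihood operates
on per-shell-normalized coefficients, and a uniform scale factor in a raw
cross-term would reward inflating m irrespective of alignment.

Because a scale error about an arbitrary fixed point equals a scale about
the grid centre plus a translation, neither m nor t can leave the identity
alone — (m=1, t=0) is a genuine local maximum for pixel-size-error data.
The refinement therefore starts with a global bootstrap: a coarse scan over
m in [0.88, 1.14], each candidate given its best translation from an FFT
cross-correlation peak and scored by a per-shell normalized correlation
sum. Refinement then alternates a rigid likelihood fit at fixed m with a
bounded Brent search on the same per-shell correlation score at fixed rigid
part. The per-shell score normalizes both maps within each shell *at the
evaluated m*, so resampling attenuation cancels and the score peaks at the
true scale (verified against analytically scaled phantoms to ±0.02% on the
48³ grid).

Conventions: if m is the scale applied to the moving map to match the
reference, the moving map's relative magnification is 1/m, the reported
percent error is (1/m − 1)·100, and the corrected pixel size is the
*declared* moving pixel size × m. A 1.05 Å map mislabelled as 0.9975 Å
(−5%) is reported at −5.0% with corrected pixel size 1.05 Å.

Limitation: with *independent* noise on both maps, the correlation score
acquires a bias of order the noise fraction times the log-slope of the
signal spectrum (sampling deeper into a decaying spectrum changes the
per-shell signal share), ~2 percentage points at SNR 5 on the test phantom.
The pixel-size-error scenario the package validates — a map refined against
its own rescaled copy, as when a deposition's pixel size is checked against
the original — shares the noise between the two inputs, and the estimate is
then unbiased to ±0.01%. Comparing two independently reconstructed maps at
low SNR calls for half-map-based noise correction, which is not implemented.

## Posterior map estimation

Per shell: diagonals (S, σ², FSC) come from each map's half pair — with the
observed full map's noise taken as half the per-half estimate, since it is
the average of two halves — and cross-map covariances from the full maps.
ρₒ is ridge-regularized (ε = 1e-4 on the diagonal) so duplicated maps stay
invertible; ρₛ entries are clipped to |ρ| ≤ 1 and shells without enough
coefficients or with non-PSD ρₒ are dropped (their output coefficients are
zero). The per-frequency linear map ⟨F_t⟩ = ρₛ·fsc·ρₒ⁻¹·Eₒ uses real
matrices only, so Hermitian symmetry — and hence the realness of the output
maps — is preserved. For N = 1 the product collapses exactly to √fsc·Eₒ.
An optional rescale multiplies the normalized output back by the per-shell
signal standard deviation for viewing on the input scale (off by default).

## The synthetic fixtures, and what passing tests do not show

The canonical phantom is a sum of 14 Gaussian blobs (widths 2–3 Å,
amplitudes 0.5–1) drawn within ±30% of the box extent around the centre of
a 48³, 1 Å-pixel grid, with every blob centre clamped so 3σ of its tails
stay inside the box — emulating a globular particle whose density fills a
molecular envelope (orientation well determined) while respecting the
periodic-grid assumption that density decays at the faces. Smaller test
grids use proportionally fewer blobs to avoid overcrowding. Half maps add
independent white Gaussian noise; SNR is the ratio of the map's spatial
variance to the noise variance, and white noise is used because every
estimator in the package is per-shell, so a flat spectrum exercises them
fully while keeping analytic expectations simple (a power-law colored
option exists for stress tests). Transformed and magnified copies are made
by real-space cubic-spline resampling — deliberately a different code path
from the Fourier-space engine, so recovery tests are not self-confirming;
its own accuracy (~1e-4–1e-2 depending on feature width) bounds how
sharply recovery can be tested.

Real data differ in ways the phantoms do not probe: colored noise,
CTF-shaped spectra, masking-induced FSC inflation, symmetry, and model
errors beyond a deleted blob. Passing tests establish the correctness of
the estimators and the optimizers under the stated model, not robustness
to those effects.

## Problem sizes and determinism

All simulations run on 32³–64³ grids (48³ for the headline recoveries),
where brute-force oracles (direct windowed moments, explicit per-shell
matrix products, lattice enumerations) complete in seconds. Every generator
is deterministic under its seed; the acceptance script derives all noise
seeds from a single `--seed` argument, while the injected ground-truth
transformations and the phantom geometry are fixed by the experiment
definitions. At these sizes the recovered rotation scatters by ~0.03°
(whole map) to ~0.07° (masked domain) across noise realizations at SNR 5,
and the magnification estimate by ~0.01 percentage points in the
shared-noise scenario.
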