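# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `ktpca`, and what the synthetic experiments do and do not
demonstrate.

## Conventions

All spatial Fourier transforms are unitary and DC-centered: the
zero-frequency sample of an axis of length n sits at index n//2, and
phase-encode index 0 is the most negative ky. The temporal transform is a
unitary FFT of the frame axis with a DC-centered frequency axis; the time
origin is frame 0. These conventions are implemented once in
`ktpca.transforms` and used everywhere, so "x-f space" always means inverse
FFT along both spatial axes followed by a forward FFT along time.

## Sampling model

`make_sheared_grid(n_pe, n_frames, R, shift)` acquires, in frame t, the
lines k with k ≡ t·shift (mod R). The default shift of 1 is the classic
sheared grid; the lattice phase is configurable. When R divides both grid
sizes the point spread function of the mask in (y, f) space is a point
lattice: R peaks at offsets (i·n_pe/R, i·shift·n_frames/R mod n_frames).
`psf_offsets` returns these analytically and `psf_weights` additionally
evaluates the mask's exact transform at those points. The weights have unit
modulus but are not always +1 — the centered-grid convention introduces
alias-dependent phases for some sizes (e.g. n_pe = 8, R = 8) — and using the
numerically evaluated weights makes the encoding model exact for every
lattice rather than only for the common even-sized cases. Masks that are not
sheared-grid lattices are rejected; a generic-PSF reconstruction is out of
scope.

For sizes not divisible by R the last lattice coset is smaller; per-frame
line counts then vary between floor and ceil of n_pe/R and the coverage
guarantee weakens to "any R consecutive frames cover all lines". The
reconstruction itself requires divisibility (it enumerates one reduced-FOV
row per lattice coset).

Training profiles are an independent, fully sampled central band (default
11 lines, DC included) kept at full temporal resolution. They are used only
to fit the basis and signal covariance, never merged back into the
undersampled data.

## Reconstruction

The temporal basis is the set of top right singular vectors of the training
x-f matrix (voxels × frequency bins), without mean subtraction: removing the
temporal average is exactly what the residual variant does, so the standard
path keeps the DC component in data and basis. The per-coil basis follows
the channel-by-channel reconstruction; a shared basis can be obtained by
passing precomputed bases.

The unfolding solve per location (x, reduced y) is

    W_x = M² Eᴴ (E M² Eᴴ + λI)⁺ P_alias,x

with E column-ordered alias-major/component-minor, M² the entrywise squared
magnitude of the training weights at the aliased locations, and the
pseudo-inverse truncated at rcond = n_f·ε relative to the largest singular
value. The zero-filling intensity loss of 1/R is compensated when forming
P_alias so the encoding uses unit-magnitude alias weights. All readout
positions of a reduced-FOV row are solved in one batched call.

### Regularization default

λ defaults to the noise-matched level λ = R·σ̂², where σ̂ is the per-sample
complex noise standard deviation estimated from the acquired samples in the
outer k-space corners (both spatial frequencies beyond 35% of the band;
Rayleigh-median estimator, robust to residual signal). Rationale: the
diagonal loading in the regularized unfolding plays the role of the noise
covariance of the aliased data vector, whose variance is R·σ² after the
1/R-scale compensation, making the solve a matched (Wiener-type) filter. A
signal-scaled alternative (λ proportional to trace(E M² Eᴴ)) was evaluated
and rejected: it is statistically mismatched, and in the sparse variant's
second pass — whose input is noise-dominated by construction — it collapses
along with the signal scale and passes noise straight through, inverting the
methods' expected ranking. `lam_scale` rescales the default; an explicit
`lam` overrides it (units: squared signal amplitude).

### Variants

Residual k-t PCA estimates the DC k-space by averaging each line over the
frames in which it was acquired (n_frames/R samples per line on the
lattice), subtracts it at acquired locations, reconstructs, and adds the DC
image back. The training data's own temporal average (not the lattice DC) is
subtracted from the training set so both data sources describe the same
residual signal.

Sparse k-t PCA performs one correction pass by default (an `iterations`
knob exists). The second-pass training data is the acquired training minus
the first-pass reconstruction resampled at the training locations, so the
second-pass basis is tailored to the error signal; `refit_basis=False`
reuses the first-pass basis instead. The subtraction is done in k-t space,
at acquired locations only.

Sensitivity maps are self-calibrated from the DC images, S_j = dc_j/RSS(dc),
normalized to unit root-sum-of-squares before a light Gaussian smoothing
(σ = 1 px, configurable), with a support mask at 5% of the peak RSS. The
coil combination I = Σ_j I_j·S_j* is then an unbiased matched filter. A
self-calibrated map inevitably inherits the object's own smooth phase
(common to all coils and physically indistinguishable from coil phase);
comparisons against ground-truth maps remove that common pixelwise phase.

## Phantom

The phantom emulates a first-pass myocardial perfusion series: a static
body ellipse, a myocardial ring and two ventricle-like cavities on a
224×192 default grid (any size works), 32 frames, 4 coils, 20 dB SNR.
Enhancement is gamma-variate, y(τ) = τ^α·exp(α(1−τ)) with τ normalized to
the peak time: right ventricle first (arrival frame 2, peak 9, on the
32-frame scale), left ventricle later (6/15), myocardium last and weaker
(10/21, amplitude 0.25 against cavity amplitudes 0.9–1.0). `temporal_rank`
sets the number of independent curves; beyond the three base curves,
additional rank models bolus transit by splitting each blood pool into
contiguous bands with arrival delayed 0.7 frames per band. The noiseless
pixel×frame matrix therefore has exact rank ≤ temporal_rank + 1 (static
level + curves). The default rank of 12 reflects that measured perfusion
series are not spanned by a 6-component basis — the operating point
deliberately truncates — while rank 3 gives the degenerate in-span case
used by the exact-recovery tests. A smooth static phase map makes the
object genuinely complex. Coil maps are broad Gaussian lobes centered
outside the FOV with gentle linear phases, normalized to unit
root-sum-of-squares.

SNR is defined in amplitude decibels as (mean coil-image magnitude over the
object support and all frames) / (per-pixel complex noise standard
deviation); noise of that variance is added i.i.d. to every acquired
k-space sample (the spatial transform is unitary, so k-space and image
noise levels coincide). `snr_db = inf` disables noise.

What the phantom does *not* model: respiration and cardiac motion, Bloch
simulation and sequence physics, pharmacokinetics beyond gamma-variate
curves, coil coupling and non-Gaussian noise. Passing tests therefore show
that the implementations are correct and that the artificial-sparsity
mechanisms behave as designed under controlled low-rank-plus-noise
conditions — not that the same error magnitudes would be obtained on
scanner data.

## Evaluation

NRMSE is computed on complex images by default (a magnitude mode exists for
in vivo-style comparisons); m-NRMSE is its arithmetic mean over frames. The
default reference is the fully sampled noisy reconstruction, with the
noiseless truth available for simulations (`reference="truth"`).

Pseudo-multiple-replica maps rerun the reconstruction on copies of the
acquired data with fresh complex Gaussian noise (σ given, typically the
acquisition level), keeping the training data and sensitivity maps fixed so
the maps isolate noise propagation through the unfolding. SNR is
|mean|/std over replicas per pixel (frames averaged into one 2-D map), and
g = SNR_full/(SNR_R·√R) with the reference branch running the same
reconstruction on the fully sampled data. Pixels with zero replica variance
are NaN. With the noise-matched λ the g-factor median sits slightly below 1
even for the traditional method (regularization trades noise for bias), so
comparisons should read g as relative noise amplification between methods
rather than against the classical g ≥ 1 bound. Replica counts of 50 give
medians stable to ~2% at 64×64×16; 200 replicas is the full-study setting.

## Desk-scale experiment sizes

The shipped tests and the acceptance script use 64×64 grids with 16–32
frames, 3–5 seeds and 50 replicas so the whole suite runs in minutes on one
CPU; the pipeline preset `fullscale-sim` holds the full-size 224×192/32-frame/
200-replica configuration. The m-NRMSE values at desk scale (~5–5.5%) are
smaller than full-scale in vivo values — the phantom is smoother and
noise-limited — so the meaningful desk-scale result is the *ordering* of
the methods (both artificial-sparsity variants below traditional, the
sparse correction also lowering the median g-factor), not the absolute
percentages.

## Known limitations

* Only Cartesian sheared-grid lattices; no variable-density or random
  sampling, and no generic-PSF unfolding.
* The exact-recovery regime requires λ several orders below the signal
  covariance scale; with 4 aliases and an effective rank-4 signal on a
  16-frame grid the unfolding system is square and its conditioning
  amplifies the Tikhonov bias to ~10⁴·λ, so "negligible" λ means ≲1e-10 on
  unit-scale data there (32-frame grids are 2:1 overdetermined and far more
  forgiving).
* The noise estimator assumes the object's k-space energy is negligible in
  the outer corners (true for smooth anatomy; pass `lam` explicitly for
  pathological inputs).
* Sensitivity maps come from the lattice DC; with strong dynamics the DC
  image is enhancement-weighted, which cancels in method comparisons that
  share maps but is not a calibrated coil measurement.
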