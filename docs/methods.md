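# Methods

## Problem and approach

Single-particle cryo-EM micrographs have signal-to-noise ratios well below 1;
shot noise dominates at all spatial frequencies. Because a noiseless
reference image of a radiation-sensitive specimen cannot exist, a denoiser
cannot be trained on noisy/clean pairs. The noise2noise scheme sidesteps
this: dose-fractionated movies are split into even-frame and odd-frame sums,
giving two images of the same signal with noise that is statistically
uncorrelated given that signal, and a convolutional network is trained to
map one half to the other. Under an L2 loss, the minimizer of the expected
noise2noise objective coincides with the minimizer of the noisy→clean
objective, so the trained network behaves as an estimator of the conditional
mean of the signal.

The package implements the full pipeline around that idea — CTF phase
flipping, Fourier-crop binning, patch-based U-net training, full-image
inference with soft-mask unbinning — together with an evaluation framework
that decomposes the denoised image's spectral power into *signal*, *bias*
(correlated false signal the denoiser invents) and *residual noise*, per
frequency ring and as scalar SNR and SNBR summaries.

## Preprocessing

**Phase flipping.** The CTF multiplies the image spectrum by an oscillating,
sign-alternating transfer function; a denoiser would otherwise need to learn
all defocus-dependent contrast inversions. Multiplying the Fourier transform
by sign(CTF) makes contrast consistently signed without touching amplitudes.
The CTF convention is CTFFIND-style: positive defocus = underfocus,
CTF = −[(1−A²)^½ sin χ + A cos χ] with χ = πλk²Δf − (π/2)Cs λ³k⁴ + φ, so
low-frequency contrast is negative and CTF(0) = −A. Coherence envelopes and
detector MTF are not modelled — only the sign matters here. sign(0) is
defined as +1 (a measure-zero set). On the conjugate-redundant columns of
the half-plane FFT grid the sign map is symmetrized explicitly, since
rounding near CTF zeros could otherwise assign opposite signs to a conjugate
pair and the inverse real FFT would average those coefficients to zero.
Flipping is applied to full micrographs *before* cropping, using the native
Nyquist. A `--no-phase-flip` switch is provided; with very low defocus or a
phase plate near 90° the first CTF zero can lie beyond the binned band
limit, making flipping a no-op in practice.

**Fourier-crop binning.** Training images are binned by keeping the central
block of the Fourier transform (typically to 1.5–3 Å/px from ~1 Å data; the
`--bin-to` parameter, no universal default claimed). This discards
frequencies where the spectral SNR is too low for any method to recover
signal, and reduces compute. Convention: mean intensity is preserved (the
DC coefficient is rescaled by the pixel-count ratio), so per-pixel
mean-square power on the shared band is preserved exactly. Odd target
dimensions are rounded down to even. The new Nyquist shell of an even output
grid has no conjugate partners inside the crop; it is set to zero so the
cropped spectrum is exactly Hermitian, the output exactly real, and Parseval
holds on the retained band to machine precision. (Content strictly below
the new Nyquist is untouched.) The same reasoning applies in reverse when
zero-padding: a source Nyquist shell would sit unpaired in the padded grid
and is dropped — in practice the soft mask removes it anyway.

**Patches and normalization.** Training samples are square patches (192 px
default) at uniformly random positions, identical positions for the even
and odd members; random-with-seed sampling decorrelates batches while
keeping runs reproducible. Each patch is normalized by its own mean and
standard deviation (input and target independently); the removed statistics
are returned so inference can restore the original intensity scale.
Whole-image inference normalizes with the image's own statistics for the
same scale-invariance reason.

## Network and training

The denoiser is a U-net in which each conventional convolution block is
replaced by a *wide-activation* block — a 1×1 convolution expanding the
channel width by an expansion factor, a ReLU, and a k×k convolution back to
the base width — and decoder upsampling is *depth-to-space* (pixel shuffle
fed by a 1×1 convolution producing 4× channels), which avoids the
checkerboard aliasing of transposed convolutions. Encoder levels downsample
by 2×2 average pooling; skip connections concatenate the encoder feature
map of the matching scale; a final linear k×k convolution produces the
output. Defaults: depth 3, base 32 channels, expansion 4, kernel 3 — the
exact reference layer sizes are not published, so these are this package's
own choice, recorded in the checkpoint metadata and freely configurable.

All convolutions use weight normalization (w = g·v/‖v‖ per output channel,
initialized with g = ‖v‖ over He-normal v) and are trained with Adam
(lr 10⁻³, β₁ 0.9, β₂ 0.999). The loss is the mean squared error by default
(an L1 option exists); L2 is what makes the noise2noise fixed point the
conditional mean under zero-mean noise, and is the loss under which the
bias analysis below is interpretable. Both pair orientations (even→odd and
odd→even) are used as training examples — symmetric and free. The
train/validation split is 95/5 by micrograph with a fixed seed and no early
stopping (a fixed epoch count is part of the protocol; 100 epochs by
default). A non-finite loss raises a training-divergence error naming the
epoch. Everything — initialization, patch positions, batch order — derives
from one seed; identical seeds reproduce the loss history bit-for-bit on a
platform.

The network stack (convolutions, backpropagation, weight normalization,
Adam) is implemented directly on numpy arrays in float32; convolutions are
evaluated as k² shifted GEMMs so the inner loops run in BLAS. Gradients are
verified against finite differences in the test suite.

**Inference** processes the full micrograph with the training-time
preprocessing (flip, crop, normalize), pads reflectively to dimensions
divisible by 2^depth, applies the network, crops back, de-normalizes, and
optionally unbins by zero-padding the Fourier transform back to the
original shape through a soft radial mask — a raised cosine from 1 to 0
across a rolloff band. The mask's exact profile is this package's choice
(default width: 10 Fourier pixels of the binned grid; default cutoff: the
binned Nyquist minus half the rolloff). The output has the original shape
and pixel size and is band-limited at the binned Nyquist, with exactly zero
power above the mask's outer edge. For downstream use that needs the
original high frequencies, `merge_frequencies` blends the denoised
low-frequency content with the original image's high-frequency content
through the same raised-cosine crossover.

## Evaluation: signal, bias, noise

Writing each noisy half as x = s + n, the ring-averaged real cross-spectrum
of the two halves, C_nn = ⟨Re X_e X̄_o⟩, estimates the signal power S(k)
unbiasedly (the noises are uncorrelated), and P_x − C_nn estimates the
noise power N(k). The Fourier ring correlation of the halves relates to
the spectral SNR as SSNR = FRC/(1 − FRC); for the scalar version the
real-space Pearson correlation gives SNR = ρ/(1 − ρ).

Denoised halves y = f(x), with the same operator applied independently to
each half, share both retained signal and whatever deterministic-given-
signal structure the operator invents (bias), while y and the *opposite*
noisy half share only the signal. Three measurable cross-spectra therefore
separate three components:

    C_dn = ½⟨Re Y_e X̄_o + Re Y_o X̄_e⟩   (symmetrized over the two pairings)
    C_dd = ⟨Re Y_e Ȳ_o⟩

    retained signal  Ŝ_d = C_dn² / C_nn
    bias             B̂   = C_dd − Ŝ_d
    residual noise   N̂_d = P_y − C_dd

Ŝ_d is the part of the shared denoised power explained by the true signal
(a per-ring regression of y on s); B̂ is the shared power orthogonal to the
signal. For any linear filter H these reduce to |H|²S, 0, |H|²N; for a
denoiser that outputs a fixed pattern, Ŝ_d → 0 and B̂ → the pattern's
power — both limits are verified against brute-force projections on
simulated ensembles in the test suite. The C_nn in the denominator is
guarded by ε = 10⁻⁶ of the ring's total power.

Scalar summaries are ring-population-weighted sums excluding the DC ring
(mean offsets are normalization artifacts): SNR = ΣnS/ΣnN for the noisy and
denoised images, and SNBR = ΣnŜ_d / Σn(B̂ + N̂_d), the power of true signal
against everything else in the denoised image. One deliberate numerical
choice: the *scalar* sums use the raw (unclamped) ring estimates. Each ring
estimate is unbiased but noisy, and can legitimately be negative where the
true power is ~0; clamping before summation would convert that zero-mean
sampling noise into a systematic positive offset (measured: ≈ +0.026
absolute on a true SNR of 0.1 at 128², a ~25% relative error). The
*reported curves* are clamped at 0, since a negative power is not
presentable; the scalar ratios are floored at 0 and the bias/noise sums
floored individually so SNBR ≤ SNR_denoised always holds. Rings beyond the
Nyquist radius (grid corners) are excluded from all ring statistics;
conjugate-redundant coefficients are counted once.

Note that, as in the original protocol, the denoiser is typically trained
on the same micrographs it is evaluated on (training data are abundant and
overfitting unlikely at scale, but at desk scale held-out pairs are used
where ground truth comparisons matter).

## Synthetic data

Phantoms are sums of soft-edged discs (logistic edge, default width 2 Å) at
uniform random non-clipping positions — a stand-in for particle projections
with a broadband, edge-dominated spectrum — on a constant background.
Defaults: 256² px at 1 Å/px, 40 discs of radius 6–16 Å and amplitude
0.5–1.5. Half-pairs add two independent white Gaussian noise fields to one
(optionally CTF-modulated) signal; a Poisson (scaled counts) option exists,
and the estimators require only zero-mean noise uncorrelated between halves.
The generating spectra are recorded analytically (white noise power =
σ²·N_pix per Fourier coefficient in the unnormalized FFT convention), and
for evaluation suites σ is solved in closed form so the ring-weighted
scalar SNR equals a requested target exactly.

What the phantoms do *not* emulate: structured background (ice gradients,
carbon edges), motion-blur residuals, detector MTF, dose-dependent
frequency weighting, and the spatial correlations of real protein
projections. Passing tests therefore demonstrate the correctness of the
estimators and the training mechanics under the stated noise model, not
performance on real micrographs.

## Desk-scale study conditions

The self-contained training study used by the acceptance checks runs at
desk scale on one CPU: 8 phantom pairs at 256², noise σ = 3× the signal's
standard deviation (scalar SNR ≈ 0.1, matching typical raw cryo-EM images),
Fourier-crop binning to 2 Å — the pipeline's prescribed preprocessing —
64² patches, a depth-2/base-16 net, 30 epochs of 16 patch positions per
pair (both orientations, batch 16), with 2 pairs held out. Under these
conditions the denoised held-out images reach a clean-reference MSE of
~0.03× the noisy MSE and a higher mean even/odd-FRC across the band. Two
honest caveats about per-ring comparisons at this scale: where the raw
image already correlates with the truth at FRC ≥ 0.99 (the phantoms' strong
low frequencies), no imperfect denoiser can improve the ring further; and
where the phantoms carry no signal at all, both before/after SSNR estimates
are sampling noise around zero, so strict per-ring orderings there are coin
flips rather than measurements. Problem sizes
are deliberately small; the estimator checks use 128² images and tens of
seeds, which keeps Monte Carlo tolerances (3× the observed sampling error)
meaningful without long runtimes.

## Known limitations

* CPU-only, float32; training beyond desk scale is slow compared to GPU
  implementations of the same architecture.
* The bias decomposition assumes the same operator was applied
  independently to the two halves; feeding it halves denoised jointly (or
  two different models) voids the signal/bias separation.
* FRC-derived quantities are undefined on empty rings and unstable on
  rings with a handful of coefficients; the DC ring is reported but
  excluded from scalars.
* MRC I/O covers single 2-D images (modes 0/1/2/6 read, mode 2 written);
  movie stacks, volumes and EER are out of scope.
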