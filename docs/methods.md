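# Methods

`radialmri` compares two reconstruction philosophies for sparse-view dynamic
radial MRI on synthetic data with a known ground truth: an iterative Bayesian
method that regularizes jointly in space (total variation) and time, and a
non-iterative filtered-backprojection (FBP) pipeline that first synthesizes
the missing radial views from the measured ones at the same time frame.  The
scientific question is one of bias: a temporal prior makes images look
cleaner, but when the object genuinely changes between frames it drags the
reconstruction towards its temporal neighbours and away from the truth.

## Acquisition model

A frame is a complex image m on an N×N grid (pixel (N//2, N//2) is the
rotation center).  The scanner measures the continuous 2D Fourier transform
of m along `n_views` diameters ("spokes") through the k-space origin at
angles uniformly covering [0°, 180°); each spoke carries `n_samples`
samples at signed radii (k − n_samples//2)·Δk with Δk = 1/FOV, DC at index
n_samples//2.  The simulator evaluates the nonuniform DFT

    K(k⃗) = Σ_{x⃗} m(x⃗) · exp(−2πi k⃗·(x⃗ − c⃗)/N)

exactly, by a per-view semi-separable factorization (two matrix products per
view, identical to the direct pixel sum up to rounding; the direct sum is
kept as the slow reference path).  I.i.d. complex Gaussian noise of standard
deviation `noise_sigma` per real/imaginary component is added to every
k-space sample.  Undersampling keeps every third view; in a dynamic series
the retained subset is rotated frame by frame (offset = t mod 3,
interleaved), so three consecutive frames jointly cover all 72 angles — the
sampling regime in which a temporal constraint can recruit "assisting" views
from adjacent frames, which is precisely the bias mechanism under study.

## The dynamic phantom

The generator renders a cardiac-perfusion-like field of view: mostly dark
background, a dim torso ellipse (baseline 0.12), a myocardial region (0.22),
left- and right-ventricular blood pools, a small descending-aorta disk, and
three small bright static chest-wall/fat markers (0.70–0.80).  Dynamic
regions follow the gamma-variate bolus model

    g(t) = A · ((t − t0)/β)^α · exp(α(1 − (t − t0)/β)),   t > t0,

normalized so the curve peaks at t = t0 + β with value exactly A.  Defaults
(desk scale 128×128, 20 frames): RV A=2.0 arriving at frame 1, aorta A=2.5
at frame 2, LV A=2.5 at frame 3, myocardium A=0.8 at frame 6 with a slower
wash-out — a compressed but physiologically ordered first-pass sequence.  A
fixed low-order polynomial phase (default amplitude 0.5 rad) makes the
object complex so the real/imaginary processing paths are exercised.

`noise_sigma` defaults to 0.5, which puts the sample SNR at the outer ends
of a spoke near 10 and makes the error budget artifact-dominated (streaks
from 24-view undersampling exceed thermal noise), the regime in which
sparse-view methods are meaningfully compared.  The phantom is piecewise
constant with smooth bolus kinetics and no motion; real cardiac data adds
respiratory/cardiac motion, coil sensitivity structure and richer texture,
so passing tests demonstrate the mechanics of the methods, not clinical
performance.

## Non-iterative pipeline (view extension + regularized FBP)

Between two adjacent measured spokes L1 (θ1) and L4 (θ4), each sample of L1
is matched to a close-valued sample of L4.  The match is the monotone
non-decreasing index map with pinned endpoints and pinned DC that minimizes
the sum of squared magnitude differences, found by an O(n²) dynamic program;
ties are broken towards the identity map (secondary cost Σ|j(i) − i|,
resolved exactly with integer arithmetic).  A missing spoke at θ between θ1
and θ4 is filled by moving along each correspondence path: signed radius and
complex value are both interpolated linearly in the angular fraction
s = (θ−θ1)/(θ4−θ1), and the scattered (radius, value) pairs are resampled
onto the uniform radial grid (real and imaginary parts independently).  The
linear-in-polar path makes radially consistent data an exact fixed point:
identical spokes reproduce identically, which a straight chord through the
k-plane would not (its intersection with the intermediate ray sits at a
slightly smaller radius).  The wrap gap between the last spoke and the first
one rotated by 180° uses the half-turn identity K(r, θ+180°) = K(−r, θ) —
pure sample reversal, valid for complex images (conjugation would additionally
require a real-valued object).

Reconstruction then filters every spoke by H(ω) = |ω|/(1 + β|ω|) with ω the
radial frequency in cycles/sample (|ω| ≤ 1/2); β = 0 is the exact ramp, and
β = 1, 2 are mild lowpasses (gain at Nyquist 0.75×, 0.5× of the ramp) that
trade resolution for noise.  On this axis the regularized and ramp variants
produce images on the same intensity scale, which is what makes their RMSE
values directly comparable.  After a per-spoke inverse FFT the real and
imaginary filtered projections are backprojected separately (pixel-driven,
linear interpolation, scale π/n_views) and combined elementwise into the
norm image sqrt(re² + im²) as the final step.  Four versions are exposed:
V1 (24 views extended to 72, regularized filter), V2 (24 raw views,
regularized), V3 (24 raw views, ramp), V4 (72 raw views, ramp — the gold
standard all sparse reconstructions are scored against).

## Iterative Bayesian reconstruction

The 24-view spokes of each frame are scattered onto the Cartesian grid with
bilinear weights (weight-normalized averaging; a cell is "measured" when its
accumulated weight exceeds 1e−8; no density compensation), giving data d_t
and binary masks W_t.  The complex series m is then estimated jointly by
gradient descent on

    C(m) = Σ_t ‖W_t ∘ F m_t − d_t‖²
         + α₁ Σ_t ‖m_{t+1} − m_t‖²
         + α₂ Σ_t Σ_j sqrt(|∇x m_{t,j}|² + |∇y m_{t,j}|² + ε),

with F the unitary centered 2D DFT (its adjoint equals its inverse, so the
fidelity gradient is exactly 2 F⁻¹(W ∘ (W ∘ F m − d)) and finite-difference
checks of the analytic gradient hold to rounding; gridded data are stored in
unitary-DFT units to match).  Spatial gradients are forward differences with
Neumann boundaries; the temporal term uses forward differences with
one-sided ends; the TV magnitude couples the real and imaginary channels
through one shared denominator.  Defaults: α₁ = 0.04 (0.004 as the low-bias
variant), α₂ = 0.006, ε = 1e−8, 1000 iterations.  Descent starts from the
zero-filled inverse transform (which is exactly data-consistent), with step
0.2/L where L is a power-iteration estimate of the fidelity Hessian bound
(exactly 2 for a unitary F and any nonempty binary mask); backtracking
halves the step whenever a trial step would increase the objective and
cautiously re-grows it (×1.2) after success, making the objective provably
non-increasing.  A non-finite objective aborts with the iteration number.
The final magnitude image is the elementwise norm of the complex result.

## Evaluation protocol

All magnitude images pass a 3×3 median filter (reflected edges; the kernel
size is configurable) before scoring.  RMSE is pooled over all pixels and
frames — one number per method per study.  SSIM uses the standard
Gaussian-weighted form (σ = 1.5, 11-tap window, K1 = 0.01, K2 = 0.03,
population covariance), scored per frame against the gold standard and
averaged, with the dynamic range fixed by the gold series (max − min).  The
gold column therefore scores exactly RMSE 0 and SSIM 1.  A full comparison
(one seed) runs the V4 gold standard, the raw-24-view column (ramp or β = 1),
the V1 extension column and one iterative column per α₁ value, and emits
RMSE and SSIM tables; identical configuration and seed reproduce the tables
byte for byte.

## Numerical choices and conventions

- All k-space arrays are DC-centered; one helper module owns the
  fftshift bookkeeping for both reconstruction paths.
- Even sample counts follow the standard FFT layout: the most-negative
  radius has no positive partner.  Consequences: the half-turn reversal
  fixes that one sample by convention, and for a real object the
  imaginary-channel image vanishes exactly only with an odd sample count.
- H(0) = 0 removes the DC bin, so every FBP image loses its mean; the
  resulting background depression scales with the frame integral and is
  shared by all FBP variants but not by the iterative method.  The default
  phantom keeps the bright area small (as a cardiac FOV does), which keeps
  this shared systematic below the under-sampling artifact level.
- Radial spokes only reach the inscribed k-space disk, so the Cartesian
  mask coverage saturates near π/4, never 1.
- The deformation DP is O(n²) per spoke pair with exact lexicographic
  tie-breaking (float primary cost, integer secondary cost).
- The backprojector and the pixel-driven forward projector are exact
  adjoints up to the π/n_views normalization, verified as explicit matrices
  in the tests.

## Known limitations

- The gold standard is itself a 72-view FBP reconstruction: it carries its
  own angular-undersampling texture, interpolation point-spread and DC-bin
  depression.  Methods from the FBP family share much of that error
  coherently, while the iterative method does not — so RMSE-against-gold
  systematically flatters FBP variants relative to RMSE-against-truth.
  At this desk scale the measured α₁ effect on pooled RMSE is small
  (~0.1%), though consistent in direction across seeds; the bias mechanism
  itself is asserted more sharply by the step-phantom test on region means.
- Single coil, no parallel imaging, no motion, no kinetic-parameter
  estimation; 256-sample spokes (the clinical matrix) are supported but the
  defaults run at 128 for desk-scale runtimes.
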