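# Methods

This note records the models, conventions and numerical choices behind
`koopgait`, and what the synthetic validation does and does not show.

## Model and assumptions

The package assumes the observed d-channel angle series
y_0, …, y_τ (radians, fixed Δt) is generated by an autonomous dynamical
system on or near an attracting limit cycle, observed through smooth
functions of the state. Under that assumption the Koopman operator has
discrete spectrum on the attractor; its eigenvalues come in conjugate
pairs on (or near) the unit circle at harmonics of the cycle frequency,
and the argument of each eigenfunction is a well-defined phase. All
decompositions estimate a finite section of that spectrum by linear
least squares on snapshot pairs; nothing requires the underlying
dynamics to be linear, but the estimates are only meaningful when the
delay embedding is rich enough (see below) and the motion is
approximately stationary over the analysed window.

## DMD variants and their contracts

**Exact DMD.** X ≈ UΣV* truncated to p columns; F̂ = U*YVΣ⁻¹;
eigenpairs (λ_j, w_j) of F̂; modes ψ_j = λ_j⁻¹YVΣ⁻¹w_j. The truncation
is fixed-p (not energy-based): singular values below 1e−12·σ_max are
considered numerical zeros and p is clamped to the resulting rank with
a warning. If an eigenvalue is numerically zero the mode formula's
λ_j⁻¹ is undefined and the projected mode U·w_j is substituted, flagged
in the result. Each mode's global phase is fixed by making its
largest-magnitude entry real positive (the amplitude absorbs the
rotation), so repeated runs are bitwise identical. With plain snapshots
of d channels the estimate can return at most d eigenvalues — the
structural limitation that motivates delay embedding.

**Companion-matrix DMD.** The coefficient vector c solves
min‖Xc − y_N‖₂; when X is rank deficient in the coefficient direction
(rank < N, the normal situation for d ≪ N) the minimum-norm solution is
taken and a warning issued. The companion matrix (ones on the
subdiagonal, c in the last column) supplies p = N eigenvalues; modes
are recovered as Ψ = X·T⁺ with T the p × N Vandermonde matrix of the
eigenvalues, pseudo-inverted (shared 1e−12 relative cutoff) because T
is ill-conditioned whenever eigenvalues nearly repeat. With short or
noisy data most companion eigenvalues are spurious and spread almost
uniformly around the unit circle; this fragility is a finding the
evaluation reproduces, not a defect to be patched.

**Hankel assemblies.** Per channel i, H_{i,1} has entry (r, c) equal to
sample r+c and H_{i,2} the same advanced one frame; m rows, n+1
columns, requiring m+n+1 frames. Row type concatenates blocks
horizontally (m × d(n+1)); column type is the entrywise transpose
(d(n+1) × m). No per-channel scaling factors are applied by default —
angle channels share units and comparable magnitudes — but
`scale_channels=True` enables unit-variance scaling for heterogeneous
observables. Dual projection for the row-type observable modes uses
ψ_j† = rows of pinv([χ_1…χ_p]); the per-channel weight is read at each
channel's first column (window starting at frame 0). When m exceeds the
cycle length the choice of which window represents "the initial value"
is a convention; frame 0 is used throughout.

**Reconstruction.** ŷ_t = Σ_j ψ_j λ_j^t b_{j,0} with b_0 = pinv(Ψ)y_0,
using discrete eigenvalue powers on the sampling grid (the only
dimensionally consistent reading of the continuous-frequency form). The
imaginary residue is discarded after summation; over a conjugate-closed
subset it is at rounding level. A guard refuses reconstructions where
|λ|^t exceeds 1e12. For the row type, reconstruction of the original
channels uses the observable modes with amplitudes χ_j(0), since
y_{i,t} ≈ Σ_j a_{ij}·χ_j(0)·λ_j^t by eigenfunction linearity; for the
column type the exact-DMD amplitudes apply directly and channels are
read at the delay-0 rows.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| p | SVD truncation / retained modes | 50 | keeps the first ~25 conjugate pairs; acts as a low-pass on the retained spectrum while covering 5 harmonics with margin |
| n | Hankel window shifts | T (one cycle) | one full cycle determines the periodic spectrum |
| m | delay-embedding rows | T (column) / 2T (row) | row-type eigenfunction convergence needs a long sample path; column-type needs m snapshots ≥ p |
| cutoff | low-pass corner | 8 Hz | contains the gait band (≤ 5·1.6 Hz); 4th-order Butterworth, zero-phase forward–backward (biomechanics default; the filter design beyond the corner frequency is a documented choice) |
| pinv cutoff | relative tolerance | 1e−12 | single shared constant for every pseudo-inverse and rank decision |
| harmonic window | matching band | ±f₀/2 | prevents one eigenvalue matching two harmonics; matching is greedy by ascending k, each eigenvalue used once |
| visibility | spectral significance | 5% of peak | a line below 5% of the maximum of a peak-normalised spectrum is not a visible peak; a harmonic with no visible peak in its window counts as missing |

The harmonic-visibility rule deserves a word: companion DMD retains
p = T eigenvalues spread over the whole band, so some eigenvalue is
almost always within ±f₀/2 of any harmonic. What fails at the higher
harmonics is the *magnitude* — the channel-averaged |mode·amplitude|
decays — so missing-ness is a property of the visible spectrum, not of
the bare eigenvalue set. The 5% rule is applied identically to every
method; measured margins on the synthetic gait data are comfortable
(companion's harmonics 3–5 fall below 2% of peak, the Hankel types'
fifth harmonic sits near 8%).

## Phase estimation

Phases are arguments of the sampled eigenfunctions, wrapped to (−π, π];
samples with |χ| < 1e−12 are marked undefined (NaN). Unwrapping uses
standard ±π jump correction. Optional initial-phase alignment
circularly time-shifts each series by the integer shift (searched over
one oscillation period of that mode) that brings the frame-0 phase
nearest zero. Phase comparison removes the frame-0 offset circularly
and averages the wrapped absolute difference; both the raw mean (rad)
and the duration-normalised value (rad/s) are reported, since either
normalisation is defensible and the defining computation is in radians.
The Fourier-average oracle demodulates one designated scalar observable
(first channel by default, configurable, optionally via its analytic
signal) at a known frequency; it is exact for data containing that
frequency and serves as the independent reference for the estimated
phases.

## Synthetic ground truth

The gait generator produces d (default 3) zero-mean channels as sums of
K = 5 harmonics of f₀ = 0.8 Hz at 100 Hz sampling, with fixed complex
coefficients whose magnitudes decay with harmonic order and are largest
for the distal (foot-like) channel, plus seeded white Gaussian noise
(the 20 dB SNR setting puts the noise sd at one tenth of the mean
channel RMS, ≈ 0.029 rad). It emulates the *spectral* structure of
segmental elevation angles — a periodic signal with decaying harmonics
and correlated channels — but not their waveform details, cycle-length
variability, within-subject drift, or event-detection noise; passing
tests therefore demonstrate correctness of the spectral machinery on
signals of realistic dimension, bandwidth and SNR, not performance on
real motion capture. The double pendulum (unit masses and lengths,
g = 9.81 m/s², angles from the downward vertical, fixed-step RK4 at
1 ms with decimation, energy drift checked below 1% for undamped runs)
provides analytic normal modes √((2∓√2)g/l)/2π = 0.3815 / 0.9211 Hz for
a 0.01 rad initial displacement; the Van der Pol oscillator provides a
genuinely nonlinear limit cycle. Linear systems y_{t+1} = Ay_t are the
eigenvalue oracle: DMD must reproduce eig(A) to numerical precision.

## Evaluation conventions

VAF and reconstruction error are computed over one cycle (T frames)
against the mean-posture-subtracted data, reconstructing with the
VAF-ranked dominant conjugate pairs — one pair for exact DMD (which has
at most one genuine pair at d = 3) and three pairs otherwise. Ranking
scores each conjugate-pair group by its solo-reconstruction VAF, stable
sort, ties broken by |Im ω| ascending. The DMD spectrum places one
point per conjugate-collapsed mode at |Im ω_j| with magnitude
meanᵢ|mode_{i,j}·b_{j,0}|, chosen for comparability with the
channel-averaged single-sided Fourier amplitudes (2|X_k|/N, rectangular
window, no padding). The SVD baseline is PCA of the centered
channel-by-time matrix with a deterministic sign convention
(largest-magnitude entry of each basis vector positive); the planar
deviation is the maximal |coordinate| along the third principal axis.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
to make every property measurable with wide margins: 30 s of synthetic
gait (24 cycles; one cycle analysed per method comparison), 40 s of
double-pendulum data, 50-snapshot linear-system oracles, and windows of
m+n+1 ≤ 376 frames. The full suite completes in well under a minute.

## Known limitations

- Segmentation consumes supplied event frames; heel-contact detection
  from raw kinematics is out of scope.
- Single-window analysis per cycle: no stitching of multiple cycles
  into one decomposition, and no handling of phase resets or
  perturbations (asymptotic-phase analysis of perturbed gait is future
  work).
- Fixed-p truncation only; no energy-threshold or optimised-rank
  selection.
- The companion variant is deliberately the textbook formulation; its
  numerical fragility on noisy data is part of the phenomenon under
  study.
- Real motion-capture cohorts (the setting in which VAF ≈ 76% figures
  arise for Hankel DMD) involve marker noise, soft-tissue artifact and
  inter-subject variability that the generators do not emulate; no
  claim about absolute real-data performance follows from the synthetic
  results here.
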