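# koopgait

Koopman spectral analysis of periodic biological motion via Hankel
dynamic mode decomposition (DMD).

Periodic movement — walking above all — is produced by a redundant,
partly unknown dynamical system. Classical dimensionality reduction
(PCA/SVD of segment angles) finds low-dimensional *coordinative
structures* such as the planar law of intersegmental coordination, but
those structures carry no dynamical meaning: no frequencies, no
growth/decay rates, no phase. `koopgait` treats the motion as a
nonlinear limit-cycle oscillation and extracts its dynamics from data
through the spectrum of the Koopman (composition) operator, estimated
with DMD. It is written for movement scientists, biomechanists and
dynamical-systems researchers working with multichannel angle time
series (and, more generally, with any low-dimensional periodic signal).

## The method

For a dynamical system x_{t+1} = f(x_t) observed through
y_t = g(x_t) ∈ ℝ^d, the Koopman operator 𝒦 advances observables:
𝒦g = g∘f. Its eigendecomposition 𝒦φ_j = λ_j φ_j expands the data as

    y_t = Σ_j λ_j^t φ_j(x_0) ψ_j ,

where ψ_j are the Koopman modes (spatial weights over channels) and
arg λ_j / Im ω_j the oscillation frequency, with
ω_j = ln(λ_j)/(2πΔt). DMD estimates this from the snapshot pair
X = [y_0 … y_{τ−1}], Y = [y_1 … y_τ] via the least-squares propagator
F = YX⁺. Four variants are implemented:

- **exact DMD** — eigendecomposition of the SVD-rank-reduced
  F̂ = U*YVΣ⁻¹ with modes ψ_j = λ_j⁻¹YVΣ⁻¹w_j; limited to at most d
  modes on d-channel data;
- **companion-matrix DMD** — the last snapshot is fitted as a linear
  combination of the preceding ones (minimum-norm least squares) and
  the spectrum read off the companion matrix; unconstrained by d but
  numerically fragile;
- **row-type Hankel DMD** — exact DMD on horizontally concatenated
  per-channel Hankel (delay-embedding) blocks, m × d(n+1). Its modes
  χ_j are length-m sample paths of the Koopman *eigenfunctions*, so the
  phase of the limit cycle is read off directly as θ′ = ∠χ_j. A
  biorthogonal construction (ψ_i*χ_j = δ_ij) then recovers per-channel
  observable modes — the coordinative structure — from the dual
  projection ψ_j*X_H1;
- **column-type Hankel DMD** — exact DMD on the transposed assembly,
  d(n+1) × m; modes live in delay space and are de-duplicated to
  per-channel weights at the delay-0 rows.

The evaluation suite provides variability accounted for
(VAF_p = 1 − ‖Θ−Θ̂_p‖²_F/‖Θ‖²_F), mean absolute reconstruction error,
channel-averaged DMD and Fourier amplitude spectra with gait-relative
normalisation, normalised harmonic-frequency deviation, the
Fourier-average eigenfunction oracle ϕ_l (exact for a known frequency,
used to validate the estimated phases), a conventional SVD/PCA
baseline, and the PC3 planar deviation. Synthetic ground truth comes
from a planar double pendulum (analytic normal modes), a harmonic
limit-cycle "gait" generator, a Van der Pol oscillator and explicit
linear systems.

## Worked example

Generate a 30 s gait-like signal (3 channels, 5 harmonics of 0.8 Hz,
100 Hz sampling, 20 dB SNR) and decompose one gait cycle per event with
row-type Hankel DMD at the defaults p = 50, n = T, m = 2T:

```sh
koopgait simulate gait --snr-db 20 --duration 30 --seed 1 \
    --out gait.csv --events-out events.csv
koopgait decompose --input gait.csv --events events.csv \
    --method hankel-row --outdir out
```

which prints, per segmented cycle,

```
cycle 0: VAF 0.9822, error 0.0331 rad
cycle 1: VAF 0.9854, error 0.0308 rad
...
```

meaning the three VAF-ranked conjugate mode pairs reconstruct 98% of
the cycle's variance with a 0.033 rad mean absolute error. The report
(`out/report.json`) also lists the normalised harmonic deviations of
the retained spectrum, here

```
[0.0031, 0.0010, 0.0040, 0.0017, 0.0001]
```

— all five harmonics of the gait frequency recovered to a fraction of a
percent. Alongside it, per cycle, the pipeline writes eigenvalue,
observable-mode and spectrum CSVs plus the sampled eigenfunctions
(`cycle0_eigenfunctions.csv`: real/imaginary parts and wrapped phase
per retained mode). The same analyses are available as library
functions (`koopgait.row_type_hankel_dmd`, `koopgait.harmonic_deviation`,
…) for scripted use.

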