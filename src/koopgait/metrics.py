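"""Evaluation metrics for the decompositions.

Variability accounted for (VAF), mean absolute reconstruction error,
DMD and Fourier amplitude spectra with gait-relative normalisation,
harmonic-frequency deviation, the Fourier-average eigenfunction oracle,
circular phase-difference, the conventional SVD/PCA baseline, and the
planar (PC3) deviation used to relate DMD reconstructions to the planar
law of intersegmental coordination.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .series import AngleSeries

__all__ = [
    "SpectrumTable",
    "vaf",
    "reconstruction_error",
    "dmd_spectrum",
    "fourier_spectrum",
    "normalize_and_rescale_spectrum",
    "harmonic_deviation",
    "fourier_average_eigenfunction",
    "phase_difference",
    "svd_baseline",
    "planar_deviation",
    "wrap_phase",
]


@dataclass(frozen=True)
class SpectrumTable:
    """(frequency, magnitude) pairs from DMD or Fourier analysis."""

    frequency: np.ndarray
    magnitude: np.ndarray
    normalized: bool = False
    relative: bool = False
    source: str = "dmd"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        mag = np.asarray(self.magnitude, dtype=float)
        if f.shape != mag.shape or f.ndim != 1:
            raise ValueError("frequency and magnitude must be 1-D, same length")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not (np.isfinite(mag).all() and (mag >= 0).all()):
            raise ValueError("magnitudes must be finite and non-negative")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "magnitude", mag)


def vaf(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Variability accounted for: 1 − ‖Θ − Θ̂‖²_F / ‖Θ‖²_F.

    Can be negative when the reconstruction is worse than predicting
    zero (as happens for severely truncated decompositions).
    """
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.shape != reconstructed.shape:
        raise ValueError("original and reconstructed shapes differ")
    denom = np.linalg.norm(original) ** 2
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero original")
    return float(1.0 - np.linalg.norm(original - reconstructed) ** 2 / denom)


def reconstruction_error(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean absolute elementwise deviation (radians for angle data)."""
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.shape != reconstructed.shape:
        raise ValueError("original and reconstructed shapes differ")
    return float(np.mean(np.abs(original - reconstructed)))


def dmd_spectrum(result, observable_modes: np.ndarray) -> SpectrumTable:
    """Discrete DMD amplitude spectrum, channel-averaged.

    One point per conjugate-collapsed mode at |Im ω_j| with magnitude
    meanᵢ |mode_{i,j}·b_{j,0}|; conjugate partners carry equal magnitude
    and are merged onto the non-negative frequency axis.
    """
    from .dmd import conjugate_pair_groups

    observable_modes = np.atleast_2d(np.asarray(observable_modes))
    mags = np.mean(
        np.abs(observable_modes * result.amplitudes[None, :]), axis=0
    )
    freqs = np.abs(result.frequencies.imag)
    points: dict[float, float] = {}
    for group in conjugate_pair_groups(result.eigenvalues):
        g = list(group)
        f = float(np.min(freqs[g]))
        mag = float(np.mean(mags[g]))
        if not np.isfinite(f):
            continue
        points[f] = points.get(f, 0.0) + mag
    order = np.array(sorted(points))
    return SpectrumTable(order, np.array([points[f] for f in order]), source="dmd")


def fourier_spectrum(series: AngleSeries) -> SpectrumTable:
    """Channel-averaged discrete Fourier amplitude spectrum.

    Rectangular window, no padding; single-sided amplitudes 2|X_k|/N
    (|X_0|/N at DC) averaged over channels on the FFT frequency grid.
    """
    values = series.values
    N = values.shape[1]
    spec = np.fft.rfft(values, axis=1)
    amp = np.abs(spec) / N
    amp[:, 1:] *= 2.0
    if N % 2 == 0:
        amp[:, -1] /= 2.0  # the Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(N, d=series.dt)
    return SpectrumTable(freqs, amp.mean(axis=0), source="fourier")


def normalize_and_rescale_spectrum(
    spec: SpectrumTable, gait_freq: float
) -> SpectrumTable:
    """Peak-normalise magnitudes and put frequencies on a gait-relative axis."""
    if gait_freq <= 0:
        raise ValueError("gait frequency must be positive")
    if spec.frequency.size == 0:
        raise ValueError("empty spectrum")
    peak = spec.magnitude.max()
    if peak == 0:
        raise ValueError("cannot normalise an all-zero spectrum")
    return replace(
        spec,
        frequency=spec.frequency / gait_freq,
        magnitude=spec.magnitude / peak,
        normalized=True,
        relative=True,
    )


#: Relative magnitude below which a mode is not a visible spectral peak.
HARMONIC_VISIBILITY = 0.05


def harmonic_deviation(
    result,
    gait_freq: float,
    K: int,
    magnitudes: np.ndarray | None = None,
    min_rel_magnitude: float = 0.0,
) -> np.ndarray:
    """Normalised deviation of the spectrum from harmonics k·f₀, k=1..K.

    For each harmonic the nearest still-unused eigenvalue frequency
    within a half-harmonic window (±f₀/2) is matched greedily by
    ascending k; deviation_k = ||Im ω| − k·f₀| / (k·f₀).  A harmonic
    with no eigenvalue in its window is reported as NaN (missing).

    With per-mode ``magnitudes`` and ``min_rel_magnitude`` set, modes
    below that fraction of the peak magnitude are excluded first, so a
    harmonic also counts as missing when no *visible* spectral peak
    falls in its window — the characteristic failure of companion DMD,
    whose magnitudes decay at the higher harmonics.
    """
    if gait_freq <= 0:
        raise ValueError("gait frequency must be positive")
    if K < 1:
        raise ValueError("K must be at least 1")
    freqs = np.abs(np.asarray(result.frequencies).imag)
    available = np.isfinite(freqs)
    if magnitudes is not None and min_rel_magnitude > 0:
        mags = np.asarray(magnitudes, dtype=float)
        if mags.max(initial=0.0) > 0:
            available &= mags >= min_rel_magnitude * mags.max()
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        target = k * gait_freq
        cand = np.flatnonzero(available)
        if cand.size == 0:
            continue
        dist = np.abs(freqs[cand] - target)
        j = cand[int(np.argmin(dist))]
        if dist.min() <= gait_freq / 2.0:
            out[k - 1] = abs(freqs[j] - target) / target
            available[j] = False
    return out


def fourier_average_eigenfunction(
    series: AngleSeries,
    freq: float,
    channel: int = 0,
    analytic: bool = False,
) -> np.ndarray:
    """Koopman eigenfunction path at a known frequency via Fourier average.

    The harmonic average a = (1/N)Σ_t e^{−i2πf·tΔt}·s(t) of a scalar
    observable s (one channel, or its analytic signal) estimates the
    eigenfunction value at frame 0; the returned ideal-oscillator path
    is ϕ(t) = e^{i2πf·tΔt}·a — unit-modulus phase evolution scaled by
    |a|, with no growth/decay dynamics.
    """
    if freq < 0:
        raise ValueError("frequency must be non-negative")
    s = series.values[channel].astype(complex)
    if analytic:
        from scipy.signal import hilbert

        s = hilbert(series.values[channel])
    t = np.arange(series.n_frames) * series.dt
    carrier = np.exp(1j * 2.0 * np.pi * freq * t)
    a = np.mean(np.conj(carrier) * s)
    if abs(a) < 1e-10:
        raise ValueError(
            f"frequency {freq:g} Hz not present in the observable "
            f"(|average| = {abs(a):.3g})"
        )
    return carrier * a


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (−π, π]."""
    x = np.asarray(x, dtype=float)
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


def phase_difference(theta_a, theta_b, dt: float):
    """Mean absolute circular difference of two phase series.

    The frame-0 difference is removed circularly first (initial-phase
    adjustment), then the mean over frames of the wrapped absolute
    difference is returned along with its per-second variant (mean
    divided by the spanned duration).  NaN (undefined-phase) frames are
    excluded.
    """
    a = np.asarray(theta_a, dtype=float).ravel()
    b = np.asarray(theta_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("phase series lengths differ")
    diff = wrap_phase(a - b)
    valid = np.isfinite(diff)
    if not valid.any():
        raise ValueError("no valid (finite) phase samples")
    first = diff[valid][0]
    adjusted = wrap_phase(diff - first)
    mean_abs = float(np.mean(np.abs(adjusted[valid])))
    duration = (a.size - 1) * dt
    per_second = mean_abs / duration if duration > 0 else np.nan
    return mean_abs, per_second


def svd_baseline(series: AngleSeries, k: int):
    """Conventional SVD/PCA decomposition of the centered angle matrix.

    Returns the first ``k`` spatial basis vectors (d × k), the scaled
    temporal coordinates ΣVᵀ (k × τ+1) and the per-component explained
    variance fractions.  Sign convention: the largest-magnitude entry of
    each basis vector is made positive.
    """
    values = series.values
    if k < 1 or k > min(values.shape):
        raise ValueError(f"k must be in 1..{min(values.shape)}")
    centered = values - values.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    total = np.sum(s**2)
    explained = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    temporal = s[:k, None] * Vt[:k]
    return U[:, :k], temporal, explained


def planar_deviation(trajectory: np.ndarray, basis: np.ndarray) -> float:
    """Maximal |coordinate| of a trajectory along the third basis vector.

    Measures how far a d-channel trajectory strays from the plane of the
    first two components (the planar law of intersegmental coordination).
    """
    trajectory = np.atleast_2d(np.asarray(trajectory, dtype=float))
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] < 3 or basis.shape[0] < 3:
        raise ValueError("basis must be d × 3 with d ≥ 3")
    gram = basis.T @ basis
    if np.max(np.abs(gram - np.eye(basis.shape[1]))) > 1e-8:
        raise ValueError("basis columns must be orthonormal")
    coords = basis[:, 2] @ trajectory
    return float(np.max(np.abs(coords)))
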