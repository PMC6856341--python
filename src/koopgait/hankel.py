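"""Delay-embedding (Hankel) DMD variants.

A scalar channel y_i is lifted into an m × (n+1) Hankel matrix whose
entry (r, c) is the sample y_{r+c,i}; the one-step-advanced partner
holds y_{r+c+1,i}.  Two assemblies of the per-channel blocks give the
two Hankel-DMD variants:

* **row type** concatenates the blocks horizontally (m × d(n+1)); exact
  DMD on this pair yields eigenvalues and, as its modes χ_j of length m,
  sample paths of the Koopman eigenfunctions along the trajectory — the
  phase of a limit cycle is read off as ∠χ_j.  Coordinative weights of
  the original channels are recovered by the biorthogonal observable-
  mode construction (:func:`row_type_observable_modes`).
* **column type** stacks the transposed concatenation (d(n+1) × m);
  exact DMD yields delay-augmented modes, de-duplicated to per-channel
  weights by taking the delay-0 rows.

No per-channel scaling factors are applied to the blocks by default
(angle channels share units and comparable magnitude); unit-variance
scaling can be enabled for heterogeneous observables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .dmd import DMDResult, PINV_RTOL, SnapshotPair, exact_dmd
from .series import AngleSeries

__all__ = [
    "HankelEmbedding",
    "EigenfunctionSet",
    "hankel_block",
    "embed",
    "assemble_row_type",
    "assemble_column_type",
    "row_type_hankel_dmd",
    "row_type_observable_modes",
    "column_type_hankel_dmd",
    "eigenfunction_phase",
]

#: |χ| below this is treated as an undefined phase sample.
PHASE_EPS = 1e-12


@dataclass(frozen=True)
class HankelEmbedding:
    """Per-channel Hankel blocks H_{i,1}, H_{i,2} sharing (m, n)."""

    blocks_1: tuple[np.ndarray, ...]
    blocks_2: tuple[np.ndarray, ...]
    m: int
    n: int
    d: int
    dt: float


@dataclass(frozen=True)
class EigenfunctionSet:
    """Sampled Koopman eigenfunctions χ_j and their phases.

    ``chi`` is m × p (column j the eigenfunction sample path for λ_j),
    ``phases`` its elementwise argument wrapped to (−π, π] with NaN
    where |χ| is numerically zero, and ``oracle`` optionally holds
    Fourier-average eigenfunction paths for comparison.
    """

    chi: np.ndarray
    frequencies: np.ndarray
    phases: np.ndarray
    dt: float
    oracle: np.ndarray | None = None


def hankel_block(channel: np.ndarray, m: int, n: int):
    """Hankel pair (H₁, H₂) of one channel: m rows × (n+1) columns.

    ``H₁[r, c] = y[r + c]`` and ``H₂`` is the same shifted one frame.
    """
    channel = np.asarray(channel, dtype=float).ravel()
    need = m + n + 1
    if m < 1 or n < 0:
        raise ValueError("need m ≥ 1 and n ≥ 0")
    if channel.size < need:
        raise ValueError(
            f"channel has {channel.size} samples; m={m}, n={n} needs "
            f"at least {need}"
        )
    H1 = scipy.linalg.hankel(channel[:m], channel[m - 1 : m + n])
    H2 = scipy.linalg.hankel(channel[1 : m + 1], channel[m : m + n + 1])
    return H1, H2


def embed(
    series: AngleSeries, m: int, n: int, scale_channels: bool = False
) -> HankelEmbedding:
    """Hankel blocks for every channel of ``series``.

    With ``scale_channels`` each channel is divided by its standard
    deviation before embedding (for observables of unlike units).
    """
    values = series.values
    if scale_channels:
        sd = values.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        values = values / sd[:, None]
    b1, b2 = [], []
    for i in range(series.d):
        H1, H2 = hankel_block(values[i], m, n)
        b1.append(H1)
        b2.append(H2)
    return HankelEmbedding(tuple(b1), tuple(b2), m, n, series.d, series.dt)


def assemble_row_type(embedding: HankelEmbedding) -> SnapshotPair:
    """X_H1 = [H_{1,1} … H_{d,1}]: horizontal concat, m × d(n+1)."""
    _check_blocks(embedding)
    X = np.hstack(embedding.blocks_1)
    Y = np.hstack(embedding.blocks_2)
    return SnapshotPair(
        X, Y, embedding.dt, "hankel-row", (embedding.d, embedding.m, embedding.n)
    )


def assemble_column_type(embedding: HankelEmbedding) -> SnapshotPair:
    """X_H2 = [H_{1,1} … H_{d,1}]ᵀ: transposed concat, d(n+1) × m."""
    _check_blocks(embedding)
    X = np.hstack(embedding.blocks_1).T
    Y = np.hstack(embedding.blocks_2).T
    return SnapshotPair(
        X, Y, embedding.dt, "hankel-col", (embedding.d, embedding.m, embedding.n)
    )


def row_type_hankel_dmd(
    series: AngleSeries,
    m: int,
    n: int,
    p: int,
    scale_channels: bool = False,
):
    """Exact DMD on the row-type Hankel pair.

    Returns the :class:`~koopgait.dmd.DMDResult` (whose modes are the
    conventional Hankel DMD modes χ_j = λ_j⁻¹ Y_H V_H Σ_H⁻¹ w_j, i.e.
    length-m Koopman-eigenfunction sample paths) together with an
    :class:`EigenfunctionSet` holding χ and its phase series.
    """
    pair = assemble_row_type(embed(series, m, n, scale_channels))
    result = exact_dmd(pair, p)
    chi = result.modes
    phases = _wrapped_phases(chi)
    eset = EigenfunctionSet(chi, result.frequencies, phases, series.dt)
    return result, eset, pair


def row_type_observable_modes(
    result: DMDResult, pair: SnapshotPair
) -> np.ndarray:
    """Per-channel (d × p) row-type observable modes.

    The dual vectors ψ_j† are the rows of pinv([χ_1 … χ_p]), so that
    ψ_i*χ_j = δ_ij.  Projecting the data, ψ_j*X_H1 has one entry per
    (channel, delay-window) column; the observable-mode weight of
    channel i is the entry of the window starting at frame 0, i.e.
    column i(n+1).
    """
    if pair.assembly != "hankel-row":
        raise ValueError("pair must be a row-type Hankel assembly")
    d, _, n = pair.dims
    chi = result.modes
    dual = np.linalg.pinv(chi, rcond=PINV_RTOL)  # p × m
    coeff = dual @ pair.X  # p × d(n+1)
    first_cols = np.arange(d) * (n + 1)
    return coeff[:, first_cols].T  # d × p


def column_type_hankel_dmd(
    series: AngleSeries,
    m: int,
    n: int,
    p: int,
    scale_channels: bool = False,
):
    """Exact DMD on the column-type Hankel pair.

    Full modes live in the delay-augmented space (length d(n+1)); the
    returned observable modes take the delay-0 row of each channel
    (row indices i(n+1), i = 0..d−1), de-duplicating the embedding.
    """
    pair = assemble_column_type(embed(series, m, n, scale_channels))
    result = exact_dmd(pair, p)
    d, _, n_ = pair.dims
    delay0 = np.arange(d) * (n_ + 1)
    observable = result.modes[delay0, :]
    return result, observable, pair


def observable_result(
    result: DMDResult,
    observable_modes: np.ndarray,
    amplitudes: np.ndarray | None = None,
) -> DMDResult:
    """DMD result restated over the original d channels.

    Swaps the delay-space modes for per-channel observable modes so that
    :func:`koopgait.dmd.reconstruct` and VAF ranking act on the original
    signal.  For the column type the exact-DMD amplitudes already apply;
    for the row type pass ``amplitudes=chi[0, :]`` (the frame-0
    eigenfunction values), since y_{i,t} ≈ Σ_j a_{ij}·χ_j(0)·λ_j^t.
    """
    observable_modes = np.atleast_2d(np.asarray(observable_modes))
    if amplitudes is None:
        amplitudes = result.amplitudes
    return DMDResult(
        result.eigenvalues,
        observable_modes,
        np.asarray(amplitudes),
        result.frequencies,
        result.p,
        result.method + "-observable",
        result.dt,
        result.flags,
    )


def eigenfunction_phase(eset: EigenfunctionSet, align: bool = False) -> np.ndarray:
    """Per-mode wrapped phase series ∠χ_j, optionally time-aligned.

    With ``align`` each series is circularly time-shifted by the integer
    shift (searched over one oscillation period) that brings the frame-0
    phase nearest zero, mirroring the initial-phase alignment used when
    overlaying cycles.
    """
    if eset.chi.size == 0:
        raise ValueError("empty eigenfunction set")
    phases = _wrapped_phases(eset.chi)
    if not align:
        return phases
    m = phases.shape[0]
    aligned = np.empty_like(phases)
    for j in range(phases.shape[1]):
        period = _mode_period_frames(eset.frequencies[j], eset.dt, m)
        col = phases[:, j]
        candidates = np.abs(col[:period])
        candidates = np.where(np.isnan(candidates), np.inf, candidates)
        shift = int(np.argmin(candidates))
        aligned[:, j] = np.roll(col, -shift)
    return aligned


def _mode_period_frames(freq: complex, dt: float, m: int) -> int:
    f = abs(np.imag(freq))
    if not np.isfinite(f) or f <= 0:
        return m
    return int(np.clip(round(1.0 / (f * dt)), 1, m))


def _wrapped_phases(chi: np.ndarray) -> np.ndarray:
    phases = np.angle(chi)
    phases[np.abs(chi) < PHASE_EPS] = np.nan
    return phases


def _check_blocks(embedding: HankelEmbedding) -> None:
    shapes = {b.shape for b in embedding.blocks_1} | {
        b.shape for b in embedding.blocks_2
    }
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous Hankel block shapes: {sorted(shapes)}")
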