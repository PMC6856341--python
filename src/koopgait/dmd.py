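"""Core dynamic mode decomposition machinery.

Implements the shared DMD building blocks: snapshot-pair construction,
exact (SVD-based) DMD, companion-matrix DMD, the eigenvalue-to-frequency
transform ω = ln(λ)/(2πΔt), mode amplitudes b₀ = Ψ⁺y₀, reconstruction
ŷ_t = Σ_j ψ_j λ_j^t b_{j,0}, and VAF-based ranking of conjugate mode
pairs.

All decompositions approximate the spectrum of the Koopman (composition)
operator of the underlying dynamical system from a least-squares linear
propagator fitted to snapshot data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .series import AngleSeries

__all__ = [
    "PINV_RTOL",
    "SnapshotPair",
    "DMDResult",
    "build_snapshot_pair",
    "exact_dmd",
    "companion_dmd",
    "eigen_to_frequency",
    "mode_amplitudes",
    "reconstruct",
    "conjugate_pair_groups",
    "rank_conjugate_pairs_by_vaf",
]

#: Shared relative cutoff for every pseudo-inverse / rank decision.
PINV_RTOL = 1e-12

#: Tolerance for deciding two eigenvalues are a conjugate pair.
CONJ_TOL = 1e-8


@dataclass(frozen=True)
class SnapshotPair:
    """Paired data matrices (X, Y) with Y one step ahead of X.

    ``assembly`` records how the pair was built: ``"plain"`` (raw
    snapshots), ``"hankel-row"`` or ``"hankel-col"`` (delay embeddings);
    ``dims`` carries ``(d, m, n)`` for the Hankel assemblies.
    """

    X: np.ndarray
    Y: np.ndarray
    dt: float
    assembly: str = "plain"
    dims: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if X.shape != Y.shape:
            raise ValueError("X and Y must have identical shape")
        if X.shape[1] < 1:
            raise ValueError("need at least one snapshot column")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def state_dim(self) -> int:
        return self.X.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class DMDResult:
    """Spectrum of one DMD run.

    ``eigenvalues`` λ_j, ``modes`` ψ_j (columns), ``amplitudes`` b_{j,0},
    and ``frequencies`` ω_j = ln(λ_j)/(2πΔt) whose imaginary part is the
    oscillation frequency in Hz and real part the growth/decay rate.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    amplitudes: np.ndarray
    frequencies: np.ndarray
    p: int
    method: str
    dt: float
    flags: tuple[str, ...] = field(default=())

    @property
    def state_dim(self) -> int:
        return self.modes.shape[0]

    def subset(self, indices) -> "DMDResult":
        """Restriction of the result to the given mode indices."""
        idx = np.asarray(list(indices), dtype=int)
        return DMDResult(
            self.eigenvalues[idx],
            self.modes[:, idx],
            self.amplitudes[idx],
            self.frequencies[idx],
            len(idx),
            self.method,
            self.dt,
            self.flags,
        )


def build_snapshot_pair(series: AngleSeries) -> SnapshotPair:
    """Split y_0..y_τ into X = [y_0..y_{τ-1}] and Y = [y_1..y_τ]."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to form a snapshot pair")
    return SnapshotPair(
        series.values[:, :-1], series.values[:, 1:], series.dt, "plain"
    )


def eigen_to_frequency(lam, dt: float):
    """Complex frequency ω = ln(λ)/(2πΔt) on the principal branch.

    ``Im ω`` is the oscillation frequency in Hz; ``Re ω`` the per-unit
    growth/decay rate.  λ = 0 has no logarithm and raises.
    """
    lam = np.asarray(lam, dtype=complex)
    if np.any(lam == 0):
        raise ValueError("eigenvalue 0 has no defined frequency")
    return np.log(lam) / (2.0 * np.pi * dt)


def mode_amplitudes(modes: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """Initial amplitudes b₀ = pinv(Ψ)·y₀ (least-squares fit of y₀)."""
    modes = np.atleast_2d(np.asarray(modes))
    y0 = np.asarray(y0).ravel()
    if y0.shape[0] != modes.shape[0]:
        raise ValueError("y0 length must equal the mode state dimension")
    return np.linalg.pinv(modes, rcond=PINV_RTOL) @ y0


def exact_dmd(pair: SnapshotPair, p: int) -> DMDResult:
    """Exact DMD: eigendecomposition of the rank-reduced propagator.

    X ≈ UΣV*; F̂ = U*YVΣ⁻¹ is decomposed as F̂w_j = λ_j w_j and modes are
    projected back as ψ_j = λ_j⁻¹ Y V Σ⁻¹ w_j.  ``p`` is clamped to the
    numerical rank of X (singular values below ``PINV_RTOL·σ_max`` are
    dropped) with a warning.
    """
    if p < 1:
        raise ValueError("truncation p must be a positive integer")
    X, Y = pair.X, pair.Y
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("X is identically zero; DMD is undefined")
    rank = int(np.sum(s > PINV_RTOL * s[0]))
    flags: list[str] = []
    if p > min(rank, X.shape[0], X.shape[1]):
        clamped = min(rank, X.shape[0], X.shape[1])
        warnings.warn(
            f"truncation p={p} exceeds numerical rank {clamped}; clamped",
            stacklevel=2,
        )
        p = clamped
        flags.append("rank-clamped")
    U = U[:, :p]
    s = s[:p]
    V = Vh[:p].conj().T
    B = (Y @ V) / s  # Y V Σ⁻¹, state_dim × p
    Fhat = U.conj().T @ B
    lam, W = np.linalg.eig(Fhat)
    modes = np.empty((X.shape[0], p), dtype=complex)
    for j in range(p):
        if abs(lam[j]) > PINV_RTOL:
            modes[:, j] = (B @ W[:, j]) / lam[j]
        else:
            # λ=0 leaves the exact-mode formula undefined; fall back to
            # the projected (POD) mode U·w_j.
            modes[:, j] = U @ W[:, j]
            if "zero-eigenvalue-projected-mode" not in flags:
                flags.append("zero-eigenvalue-projected-mode")
    # deterministic phase convention: largest-|entry| of each mode made
    # real positive (the amplitude absorbs the inverse rotation)
    anchor = modes[np.argmax(np.abs(modes), axis=0), np.arange(p)]
    phase = np.where(np.abs(anchor) > 0, anchor / np.abs(anchor), 1.0)
    modes = modes / phase[None, :]
    amplitudes = mode_amplitudes(modes, X[:, 0])
    freqs = _safe_frequencies(lam, pair.dt)
    return DMDResult(
        lam, modes, amplitudes, freqs, p, "exact", pair.dt, tuple(flags)
    )


def companion_dmd(pair: SnapshotPair) -> DMDResult:
    """Companion-matrix DMD.

    Fits the last snapshot as a linear combination of the previous ones,
    c = argmin‖Xc − y_N‖₂ (minimum-norm when X is rank deficient), forms
    the companion matrix with ones on the subdiagonal and c in the last
    column, and recovers modes as Ψ = X·T⁺ with T the Vandermonde matrix
    of the eigenvalues.  Returns all p = N eigenvalues; with short or
    noisy data many of them are spurious, which is the numerically
    fragile behaviour this variant is known for.
    """
    X, Y = pair.X, pair.Y
    N = X.shape[1]
    if N < 2:
        raise ValueError("companion DMD needs at least 2 snapshots")
    y_last = Y[:, -1]
    c, _, rank, _ = np.linalg.lstsq(X, y_last, rcond=PINV_RTOL)
    flags: list[str] = []
    if rank < N:
        warnings.warn(
            "rank-deficient X; companion coefficients are the minimum-norm "
            "least-squares solution",
            stacklevel=2,
        )
        flags.append("rank-deficient-min-norm")
    C = np.zeros((N, N))
    C[np.arange(1, N), np.arange(N - 1)] = 1.0
    C[:, -1] = c
    lam = np.linalg.eigvals(C)
    # Vandermonde T[j, k] = λ_j^k; modes Ψ = X·T⁺.
    T = lam[:, None] ** np.arange(N)[None, :]
    if _has_near_repeats(lam):
        warnings.warn(
            "near-repeated companion eigenvalues; Vandermonde inversion "
            "regularized by pseudo-inverse",
            stacklevel=2,
        )
        flags.append("repeated-eigenvalues")
    modes = X @ np.linalg.pinv(T, rcond=PINV_RTOL)
    amplitudes = mode_amplitudes(modes, X[:, 0])
    freqs = _safe_frequencies(lam, pair.dt)
    return DMDResult(
        lam, modes, amplitudes, freqs, N, "companion", pair.dt, tuple(flags)
    )


def reconstruct(result: DMDResult, mode_subset=None, t_range=None) -> np.ndarray:
    """Sum of mode contributions ŷ_t = Σ_{j∈subset} ψ_j λ_j^t b_{j,0}.

    ``t_range`` is an integer frame count or an explicit array of frame
    indices.  The imaginary residue is discarded after summation, so a
    conjugate-closed subset of a real-data decomposition returns a real
    matrix up to rounding.
    """
    if t_range is None:
        raise ValueError("t_range (frame count or indices) is required")
    t = (
        np.arange(int(t_range))
        if np.isscalar(t_range)
        else np.asarray(t_range, dtype=float)
    )
    if mode_subset is None:
        idx = np.arange(result.p)
    else:
        idx = np.asarray(sorted(mode_subset), dtype=int)
    if idx.size == 0:
        return np.zeros((result.state_dim, t.size))
    if np.any(idx < 0) or np.any(idx >= result.p):
        raise IndexError("mode_subset indices outside 0..p-1")
    lam = result.eigenvalues[idx]
    t_max = float(t.max(initial=0.0))
    growth = np.abs(lam).max() ** t_max
    if not np.isfinite(growth) or growth > 1e12:
        raise OverflowError(
            f"|λ|max^tmax ≈ {growth:.3g} over t ≤ {t_max:g}: reconstruction "
            "would overflow; restrict t_range or the mode subset"
        )
    dyn = lam[None, :] ** t[:, None]  # (len(t), k)
    out = (result.modes[:, idx] * result.amplitudes[idx]) @ dyn.T
    return np.real(out)


def conjugate_pair_groups(eigenvalues: np.ndarray, tol: float = CONJ_TOL):
    """Group eigenvalue indices into conjugate pairs.

    Real eigenvalues (|Im λ| ≤ tol) form singleton groups; an unpaired
    complex eigenvalue is kept as a singleton with a warning.
    """
    lam = np.asarray(eigenvalues)
    used = np.zeros(lam.size, dtype=bool)
    groups: list[tuple[int, ...]] = []
    for j in range(lam.size):
        if used[j]:
            continue
        used[j] = True
        scale = max(1.0, abs(lam[j]))
        if abs(lam[j].imag) <= tol * scale:
            groups.append((j,))
            continue
        rest = np.flatnonzero(~used)
        if rest.size:
            dist = np.abs(lam[rest] - np.conj(lam[j]))
            k = rest[int(np.argmin(dist))]
            if dist.min() <= tol * scale:
                used[k] = True
                groups.append((j, int(k)))
                continue
        warnings.warn(
            f"complex eigenvalue {lam[j]:.6g} has no conjugate partner; "
            "treated as a singleton group",
            stacklevel=2,
        )
        groups.append((j,))
    return groups


def rank_conjugate_pairs_by_vaf(
    result: DMDResult, original: np.ndarray
) -> list[tuple[int, ...]]:
    """Conjugate-pair groups sorted by descending single-group VAF.

    Each group is scored by the VAF of its solo reconstruction against
    ``original`` (state_dim × frames).  Ties break by |Im ω| ascending;
    the sort is stable.
    """
    from .metrics import vaf  # local import avoids a module cycle

    original = np.atleast_2d(np.asarray(original, dtype=float))
    if original.shape[0] != result.state_dim:
        raise ValueError("original state dimension does not match modes")
    n_frames = original.shape[1]
    groups = conjugate_pair_groups(result.eigenvalues)
    scored = []
    for g in groups:
        rec = reconstruct(result, g, n_frames)
        score = vaf(original, rec)
        imw = float(np.min(np.abs(result.frequencies[list(g)].imag)))
        scored.append((g, score, imw))
    scored.sort(key=lambda item: (-round(item[1], 12), item[2]))
    return [g for g, _, _ in scored]


def _safe_frequencies(lam: np.ndarray, dt: float) -> np.ndarray:
    """ω for each eigenvalue; NaN where λ = 0 (undefined log)."""
    lam = np.asarray(lam, dtype=complex)
    freqs = np.full(lam.shape, np.nan + 0j)
    nz = lam != 0
    if np.any(nz):
        freqs[nz] = np.log(lam[nz]) / (2.0 * np.pi * dt)
    return freqs


def _has_near_repeats(lam: np.ndarray, tol: float = 1e-10) -> bool:
    lam = np.sort_complex(np.asarray(lam))
    return bool(np.any(np.abs(np.diff(lam)) < tol)) if lam.size > 1 else False
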