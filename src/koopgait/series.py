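"""Multichannel angle time-series container.

An :class:`AngleSeries` holds a ``d × (τ+1)`` real matrix of angles
(radians) sampled at a fixed interval ``dt`` (seconds), with optional
cycle-start events (e.g. heel-contact frames in gait data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AngleSeries"]


@dataclass(frozen=True)
class AngleSeries:
    """A finite observation sequence y_0, …, y_τ of d angle channels.

    Parameters
    ----------
    values
        Real matrix of shape ``(d, τ+1)``; angles in radians.
    dt
        Sampling interval in seconds, strictly positive.
    labels
        Channel names; defaults to ``ch0..ch{d-1}``.
    events
        Optional strictly increasing frame indices of cycle starts
        (0-based, within ``[0, τ]``).
    """

    values: np.ndarray
    dt: float
    labels: tuple[str, ...] = field(default=())
    events: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[None, :]
        if values.ndim != 2:
            raise ValueError("values must be a d × (τ+1) matrix")
        if values.shape[1] < 2:
            raise ValueError("an AngleSeries needs at least 2 frames (τ ≥ 1)")
        if not np.isfinite(values).all():
            raise ValueError("values must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", values)
        labels = tuple(self.labels) if self.labels else tuple(
            f"ch{i}" for i in range(values.shape[0])
        )
        if len(labels) != values.shape[0]:
            raise ValueError("labels length must match channel count")
        object.__setattr__(self, "labels", labels)
        if self.events is not None:
            ev = tuple(int(e) for e in self.events)
            if any(b <= a for a, b in zip(ev, ev[1:])):
                raise ValueError("events must be strictly increasing")
            if ev and (ev[0] < 0 or ev[-1] > self.tau):
                raise ValueError("events must lie within [0, τ]")
            object.__setattr__(self, "events", ev)

    # -- basic geometry -------------------------------------------------
    @property
    def d(self) -> int:
        """Number of channels."""
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def tau(self) -> int:
        """Index of the last frame (frames are 0..τ)."""
        return self.values.shape[1] - 1

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        return self.tau * self.dt

    # -- derived series -------------------------------------------------
    def with_values(self, values: np.ndarray) -> "AngleSeries":
        """Copy of this series with ``values`` replaced (same dt/labels)."""
        return replace(self, values=values)

    def window(self, start: int, length: int) -> "AngleSeries":
        """Contiguous sub-series of ``length`` frames starting at ``start``."""
        if start < 0 or start + length > self.n_frames:
            raise ValueError(
                f"window [{start}, {start + length}) outside series of "
                f"{self.n_frames} frames"
            )
        return AngleSeries(
            self.values[:, start : start + length], self.dt, self.labels
        )
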