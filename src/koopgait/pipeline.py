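"""I/O, preprocessing and the end-to-end decomposition pipeline.

The processing order mirrors a standard gait-analysis workflow: low-pass
filter the angle series, segment it into gait cycles at the supplied
events, subtract the mean posture over each cycle, decompose, evaluate.

CSV dialect: comma-separated with a mandatory header, one time column in
seconds followed by one column per angle channel (radians); frame
indices are 0-based everywhere.  Events travel in a one-column sidecar
CSV of cycle-start frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from . import dmd, hankel, metrics
from .series import AngleSeries

__all__ = [
    "RunConfig",
    "CycleWindow",
    "read_angle_csv",
    "write_angle_csv",
    "read_events_csv",
    "write_events_csv",
    "lowpass_filter",
    "subtract_mean_posture",
    "segment_cycles",
    "gait_frequency",
    "resolve_window_params",
    "decompose_window",
    "run_decompose",
    "complex_to_pairs",
]

log = logging.getLogger("koopgait")

METHODS = ("exact", "companion", "hankel-row", "hankel-col", "svd")

#: Default truncation dimension of the Hankel SVD.
DEFAULT_P = 50


@dataclass
class RunConfig:
    """Configuration of one end-to-end decomposition run."""

    input: str
    method: str = "hankel-row"
    outdir: str = "koopgait-out"
    events: str | None = None
    p: int = DEFAULT_P
    m: int | str = "auto"  # delay-embedding rows; "auto" = T (col) / 2T (row)
    n: int | str = "auto"  # window shifts; "auto" = one gait cycle T
    cutoff_hz: float | None = 8.0
    harmonics: int = 5
    svd_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        for name in ("p", "m", "n"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a positive integer or 'auto'")
            elif int(v) < 1:
                raise ValueError(f"{name} must be positive")
        if self.p == "auto":
            raise ValueError("p must be numeric")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass(frozen=True)
class CycleWindow:
    """One gait cycle plus the extra frames needed for delay embedding."""

    series: AngleSeries
    T: int  # frames per cycle
    m: int
    n: int
    start: int  # frame index of the cycle start in the source series


# -- CSV I/O ------------------------------------------------------------


def read_angle_csv(path, events_path=None) -> AngleSeries:
    """Read a time + d-channel angle CSV; dt inferred from the time column."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one channel")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value in row {row}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 rows")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 1e-6:
        raise ValueError(f"{path}: non-uniform sampling (tolerance 1e-6 s)")
    events = read_events_csv(events_path) if events_path else None
    return AngleSeries(
        df.iloc[:, 1:].to_numpy(dtype=float).T,
        dt,
        labels=tuple(df.columns[1:]),
        events=events,
    )


def write_angle_csv(series: AngleSeries, path, events_path=None) -> None:
    """Write the standard angle CSV (lossless to double precision)."""
    df = pd.DataFrame(series.values.T, columns=list(series.labels))
    df.insert(0, "time", series.times)
    df.to_csv(path, index=False, float_format="%.17g")
    if events_path and series.events is not None:
        write_events_csv(series.events, events_path)


def read_events_csv(path) -> tuple[int, ...]:
    df = pd.read_csv(path)
    return tuple(int(v) for v in df.iloc[:, 0])


def write_events_csv(events, path) -> None:
    pd.DataFrame({"frame": list(events)}).to_csv(path, index=False)


# -- preprocessing ------------------------------------------------------


def lowpass_filter(series: AngleSeries, cutoff: float, order: int = 4) -> AngleSeries:
    """Zero-phase Butterworth low-pass (forward-backward) per channel."""
    nyquist = 0.5 / series.dt
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must be in (0, {nyquist:g}) Hz")
    sos = scipy.signal.butter(order, cutoff, fs=1.0 / series.dt, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, series.values, axis=1)
    return series.with_values(filtered)


def subtract_mean_posture(series: AngleSeries, window=None) -> AngleSeries:
    """Subtract each channel's mean over ``window`` (default: all frames).

    ``window`` is a (start, stop) frame range, stop exclusive.
    """
    if window is None:
        start, stop = 0, series.n_frames
    else:
        start, stop = int(window[0]), int(window[1])
    if not (0 <= start < stop <= series.n_frames):
        raise ValueError("empty or out-of-range mean-posture window")
    mean = series.values[:, start:stop].mean(axis=1, keepdims=True)
    return series.with_values(series.values - mean)


def gait_frequency(T: int, dt: float) -> float:
    """Gait frequency = reciprocal of the cycle duration, Hz."""
    if T < 1:
        raise ValueError("cycle length must be at least 1 frame")
    return 1.0 / (T * dt)


def resolve_window_params(method: str, T: int, m="auto", n="auto"):
    """Apply the delay-embedding defaults n = T, m = T (col) / 2T (row)."""
    n_res = T if n == "auto" else int(n)
    if m == "auto":
        m_res = 2 * T if method == "hankel-row" else T
    else:
        m_res = int(m)
    return m_res, n_res


def segment_cycles(
    series: AngleSeries, method: str, m="auto", n="auto"
) -> list[CycleWindow]:
    """Cut one window per gait cycle: m + n + 1 frames from each event.

    The cycle length T is the spacing to the next event; windows that
    run past the end of the series are skipped with a log entry.
    """
    if series.events is None or len(series.events) < 2:
        raise ValueError(
            "cycle segmentation needs at least 2 events; pass numeric (m, n) "
            "and analyse the whole series instead"
        )
    windows = []
    for start, nxt in zip(series.events, series.events[1:]):
        T = nxt - start
        m_res, n_res = resolve_window_params(method, T, m, n)
        length = (
            m_res + n_res + 1 if method.startswith("hankel") else T + 1
        )
        if start + length > series.n_frames:
            log.info(
                "skipping cycle at frame %d: needs %d frames, %d available",
                start,
                length,
                series.n_frames - start,
            )
            continue
        windows.append(
            CycleWindow(series.window(start, length), T, m_res, n_res, start)
        )
    return windows


# -- decomposition + evaluation ----------------------------------------


def decompose_window(
    window: CycleWindow, method: str, p: int = DEFAULT_P, harmonics: int = 5
) -> dict:
    """Decompose one cycle window and evaluate it.

    Returns a dict with the DMDResult (full and per-channel observable
    forms where applicable), VAF and reconstruction error of the
    VAF-ranked dominant conjugate pairs (one pair for exact DMD, three
    for the others, following the dominant-mode evaluation convention),
    harmonic deviations, and the DMD spectrum.
    """
    series = window.series
    T = window.T
    f0 = gait_frequency(T, series.dt)
    cycle = subtract_mean_posture(series, (0, T)).values[:, :T]
    out: dict = {"method": method, "T": T, "gait_freq": f0}

    if method == "svd":
        sub = subtract_mean_posture(series.window(0, T + 1), (0, T))
        basis, temporal, explained = metrics.svd_baseline(
            sub, min(3, series.d)
        )
        rec = basis @ temporal[:, :T]
        out.update(
            basis=basis,
            temporal=temporal,
            explained=explained,
            vaf=metrics.vaf(cycle, rec),
            recon_error=metrics.reconstruction_error(cycle, rec),
        )
        return out

    centered = subtract_mean_posture(series, (0, T))
    if method == "exact":
        pair = dmd.build_snapshot_pair(centered.window(0, T + 1))
        result = dmd.exact_dmd(pair, min(p, series.d))
        observable = result
        n_pairs = 1
    elif method == "companion":
        pair = dmd.build_snapshot_pair(centered.window(0, T + 1))
        result = dmd.companion_dmd(pair)
        observable = result
        n_pairs = 3
    elif method == "hankel-row":
        result, eset, pair = hankel.row_type_hankel_dmd(
            centered, window.m, window.n, p
        )
        obs_modes = hankel.row_type_observable_modes(result, pair)
        observable = hankel.observable_result(
            result, obs_modes, amplitudes=result.modes[0, :]
        )
        out["eigenfunctions"] = eset
        n_pairs = 3
    elif method == "hankel-col":
        result, obs_modes, pair = hankel.column_type_hankel_dmd(
            centered, window.m, window.n, p
        )
        observable = hankel.observable_result(result, obs_modes)
        n_pairs = 3
    else:  # pragma: no cover - guarded by RunConfig
        raise ValueError(f"unknown method {method}")

    ranked = dmd.rank_conjugate_pairs_by_vaf(observable, cycle)
    top = [i for group in ranked[:n_pairs] for i in group]
    rec = dmd.reconstruct(observable, top, T)
    out.update(
        result=result,
        observable=observable,
        ranked_groups=ranked,
        top_indices=top,
        vaf=metrics.vaf(cycle, rec),
        recon_error=metrics.reconstruction_error(cycle, rec),
        harmonic_deviations=metrics.harmonic_deviation(
            result,
            f0,
            harmonics,
            magnitudes=np.mean(
                np.abs(observable.modes * observable.amplitudes[None, :]), axis=0
            ),
            min_rel_magnitude=metrics.HARMONIC_VISIBILITY,
        ),
        spectrum=metrics.dmd_spectrum(observable, observable.modes),
    )
    return out


def run_decompose(config: RunConfig) -> dict:
    """End-to-end run: read, preprocess, decompose, evaluate, export.

    Writes per-cycle eigenvalue/mode/eigenfunction/spectrum CSVs and a
    machine-readable ``report.json`` into ``config.outdir``; returns the
    report dict.  Deterministic for a fixed config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = read_angle_csv(config.input, config.events)
    log.info("read %d channels × %d frames (dt=%g s)", series.d, series.n_frames, series.dt)
    if config.cutoff_hz is not None:
        series = lowpass_filter(series, config.cutoff_hz)
    if series.events is not None and len(series.events) >= 2:
        windows = segment_cycles(series, config.method, config.m, config.n)
    else:
        if config.n == "auto" or (
            config.method.startswith("hankel") and config.m == "auto"
        ):
            raise ValueError(
                "no events supplied: numeric m and n are required to analyse "
                "the whole series"
            )
        n_num = int(config.n)
        m_num = int(config.m) if config.m != "auto" else n_num
        length = (
            m_num + n_num + 1
            if config.method.startswith("hankel")
            else n_num + 1
        )
        if length > series.n_frames:
            raise ValueError("series shorter than the requested window")
        windows = [CycleWindow(series.window(0, length), n_num, m_num, n_num, 0)]
    if not windows:
        raise ValueError("no usable cycles in the input")

    report = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_cycles": len(windows),
        "cycles": [],
    }
    for c, window in enumerate(windows):
        res = decompose_window(window, config.method, config.p, config.harmonics)
        report["cycles"].append(_export_cycle(outdir, c, res, config.method))
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("wrote %s", outdir / "report.json")
    return report


def _export_cycle(outdir: Path, c: int, res: dict, method: str) -> dict:
    """Write one cycle's artifacts; return its JSON-safe summary."""
    tag = f"cycle{c}"
    summary = {
        "cycle": c,
        "T": res["T"],
        "gait_freq_hz": res["gait_freq"],
        "vaf": res["vaf"],
        "recon_error_rad": res["recon_error"],
    }
    if method == "svd":
        np.savetxt(outdir / f"{tag}_basis.csv", res["basis"], delimiter=",")
        np.savetxt(outdir / f"{tag}_temporal.csv", res["temporal"], delimiter=",")
        np.savetxt(outdir / f"{tag}_explained.csv", res["explained"], delimiter=",")
        summary["explained"] = [float(v) for v in res["explained"]]
        return summary

    result = res["result"]
    observable = res["observable"]
    pd.DataFrame(
        {
            "eigenvalue_re": result.eigenvalues.real,
            "eigenvalue_im": result.eigenvalues.imag,
            "freq_re": result.frequencies.real,
            "freq_im_hz": result.frequencies.imag,
        }
    ).to_csv(outdir / f"{tag}_eigenvalues.csv", index=False)
    mode_df = {}
    for i in range(observable.state_dim):
        mode_df[f"ch{i}_mag"] = np.abs(observable.modes[i])
        mode_df[f"ch{i}_arg"] = np.angle(observable.modes[i])
    pd.DataFrame(mode_df).to_csv(outdir / f"{tag}_modes.csv", index=False)
    spec = res["spectrum"]
    pd.DataFrame(
        {"frequency_hz": spec.frequency, "magnitude": spec.magnitude}
    ).to_csv(outdir / f"{tag}_spectrum.csv", index=False)
    if "eigenfunctions" in res:
        eset = res["eigenfunctions"]
        cols = {"frame": np.arange(eset.chi.shape[0])}
        for j in range(eset.chi.shape[1]):
            cols[f"mode{j}_re"] = eset.chi[:, j].real
            cols[f"mode{j}_im"] = eset.chi[:, j].imag
            cols[f"mode{j}_phase"] = eset.phases[:, j]
        pd.DataFrame(cols).to_csv(
            outdir / f"{tag}_eigenfunctions.csv", index=False
        )
    dev = res["harmonic_deviations"]
    summary["harmonic_deviations"] = [
        None if np.isnan(v) else float(v) for v in dev
    ]
    summary["flags"] = list(result.flags)
    summary["top_mode_indices"] = [int(i) for i in res["top_indices"]]
    return summary


def complex_to_pairs(values: np.ndarray):
    """JSON-friendly [re, im] pairs for a complex vector/matrix."""
    arr = np.asarray(values, dtype=complex)
    return np.stack([arr.real, arr.imag], axis=-1).tolist()
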