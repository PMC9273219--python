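"""dF/F0 normalization, SNR metrics, and frame downsampling.

Two baseline dialects are provided. Whole-head recordings use the
``lowest_percentile`` dialect: for each neuron, F0 is the mean of the lowest
1% of its measurements, so the baseline tracks the quietest state the neuron
visits. Single-neuron bistable traces (AVA-style) use the ``trace_mean``
dialect, where F0 is simply the trace mean.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import BaselineError, UndefinedSNRError
from .trace import CalciumTraceSet, DFFTraceSet, SNRResult


def normalize_dff(traces: CalciumTraceSet, mode: str = "lowest_percentile",
                  percentile: float = 0.01) -> DFFTraceSet:
    """Normalize raw fluorescence to dF/F0 = (F - F0) / F0, row-wise.

    mode="lowest_percentile": per-neuron F0 is the mean of the lowest
    ``ceil(percentile * frames)`` samples (at least one). mode="trace_mean":
    F0 is the per-neuron mean. Raises :class:`BaselineError` if any F0 <= 0.
    """
    values = traces.values
    if mode == "lowest_percentile":
        k = max(1, math.ceil(percentile * traces.n_frames))
        lowest = np.sort(values, axis=1)[:, :k]
        f0 = lowest.mean(axis=1)
    elif mode == "trace_mean":
        f0 = values.mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(f0 <= 0):
        bad = np.nonzero(f0 <= 0)[0]
        raise BaselineError(f"non-positive F0 for neurons {bad.tolist()}")
    dff = (values - f0[:, None]) / f0[:, None]
    return DFFTraceSet(dff=dff, f0=f0, mode=mode,
                       sampling_rate=traces.sampling_rate,
                       percentile=percentile, trial_id=traces.trial_id,
                       condition=traces.condition)


def compute_snr(trace: np.ndarray, method: str, sampling_rate: float,
                window_s: float = 10.0,
                signal_window: tuple[int, int] | None = None,
                noise_window: tuple[int, int] | None = None) -> SNRResult:
    """Signal-to-noise ratio of a 1-D dF/F0 series, in dB.

    method="manual_amplitude" mirrors per-trace inspection: the caller
    supplies frame ranges for the largest sustained transient and for a quiet
    stretch; SNR = 20*log10(peak signal amplitude / mean noise amplitude),
    where noise amplitude is the mean absolute deviation around the noise
    window's mean.

    method="automated_power" tiles the trace with non-overlapping windows of
    ``window_s`` seconds, takes the mean squared value per window, and returns
    10*log10(max window power / min window power) — >= 0 dB by construction.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if method == "manual_amplitude":
        if signal_window is None or noise_window is None:
            raise ValueError("manual_amplitude requires signal and noise windows")
        sig = trace[signal_window[0]:signal_window[1]]
        noi = trace[noise_window[0]:noise_window[1]]
        if sig.size == 0 or noi.size == 0:
            raise ValueError("empty signal or noise window")
        s = float(np.max(np.abs(sig)))
        n = float(np.mean(np.abs(noi - noi.mean())))
        if n <= 0:
            raise UndefinedSNRError("zero noise amplitude")
        return SNRResult(snr_db=20.0 * np.log10(s / n), method=method,
                         window_s=float("nan"))
    if method == "automated_power":
        w = int(round(window_s * sampling_rate))
        if w < 1 or trace.size < w:
            raise ValueError("trace shorter than one SNR window")
        n_win = trace.size // w
        windows = trace[: n_win * w].reshape(n_win, w)
        power = np.mean(windows**2, axis=1)
        pmin = float(power.min())
        if pmin <= 0:
            raise UndefinedSNRError("zero minimal window power")
        return SNRResult(snr_db=10.0 * np.log10(float(power.max()) / pmin),
                         method=method, window_s=window_s)
    raise ValueError(f"unknown SNR method {method!r}")


def downsample(traces: CalciumTraceSet, factor: int) -> CalciumTraceSet:
    """Keep every ``factor``-th frame and divide the sampling rate."""
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor == 1:
        return traces
    values = traces.values[:, ::factor]
    if values.shape[1] < 2:
        raise ValueError("downsampling would leave fewer than 2 frames")
    return CalciumTraceSet(values=values,
                           sampling_rate=traces.sampling_rate / factor,
                           trial_id=traces.trial_id,
                           condition=traces.condition)
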