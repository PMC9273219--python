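"""ON/OFF transition kinetics of bistable command-interneuron traces.

AVA-style neurons switch between a low and a high calcium state. Each
transition is fit with a four-parameter hyperbolic tangent

    F(t) = baseline + amplitude/2 * (1 + s * tanh((t - t0) / tau)),

s = +1 for ON, -1 for OFF. The 5->95% rise time (ON) or 95->5% fall time
(OFF) follows analytically from the fit as ``2 * tau * atanh(0.9)``, so the
kinetics read-out is noise-free by construction. Duty ratio and transient
frequency are computed from bouts formed by pairing each ON onset with the
next OFF onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyResultError, OrderingError

#: 5% -> 95% span of the unit tanh step, in units of tau.
TANH_5_95 = 2.0 * np.arctanh(0.9)


@dataclass
class TransitionEvent:
    """One fitted activity-state transition."""

    direction: str            # "on" | "off"
    t0: float                 # fit midpoint, s
    tau: float                # tanh time constant, s
    baseline: float           # dF/F0
    amplitude: float          # dF/F0, max fluorescence above baseline
    onset_frame: int          # first frame of the transition
    transition_time: float    # 5->95% (on) or 95->5% (off), s
    fit_rmse: float
    ok: bool = True           # False when the fit diverged / tau out of range
    window: tuple[int, int] = (0, 0)


@dataclass
class TransientBout:
    onset_frame: int
    offset_frame: int
    duration: float           # s


@dataclass
class KineticsSummary:
    mean_rise_time: float
    mean_fall_time: float
    duty_ratio: float
    transient_frequency: float   # bouts per minute
    n_on: int
    n_off: int
    bouts: list[TransientBout] = field(default_factory=list)
    trailing_open: bool = False


@dataclass
class DetectionParams:
    """Hysteresis detector configuration (fractions of dynamic range)."""

    high: float = 0.7
    low: float = 0.3
    min_amplitude: float = 0.1   # dF/F0 dynamic range below which no events
    smooth_s: float = 1.0        # moving-average width
    pad_s: float = 15.0          # candidate window half-width cap


def _tanh_model(t, baseline, amplitude, t0, tau, s):
    return baseline + amplitude / 2.0 * (1.0 + s * np.tanh((t - t0) / tau))


def detect_transitions(dff: np.ndarray, sampling_rate: float,
                       params: DetectionParams | None = None
                       ) -> list[dict]:
    """Hysteresis threshold-crossing candidate detector.

    Smooths the trace, rescales it to its dynamic range, and emits an ON
    candidate whenever the trace crosses up through ``high`` after having
    been below ``low`` (and symmetrically for OFF). Returns time-ordered
    candidate dicts with keys ``direction``, ``cross_frame``, ``window``.
    A flat trace yields an empty list.
    """
    params = params or DetectionParams()
    x = np.asarray(dff, dtype=float).ravel()
    n = x.size
    w = max(1, int(round(params.smooth_s * sampling_rate)))
    kernel = np.ones(w) / w
    padded = np.concatenate([np.full(w, x[0]), x, np.full(w, x[-1])])
    sm = np.convolve(padded, kernel, mode="same")[w:w + n]
    rng_lo, rng_hi = sm.min(), sm.max()
    if rng_hi - rng_lo < params.min_amplitude:
        return []
    z = (sm - rng_lo) / (rng_hi - rng_lo)

    crossings: list[tuple[str, int]] = []
    # armed_on: we have been below `low` since the last ON; armed_off likewise
    armed_on = z[0] < params.low
    armed_off = z[0] > params.high
    for i in range(1, n):
        if z[i] < params.low:
            armed_on = True
        if z[i] > params.high:
            armed_off = True
        if armed_on and z[i - 1] <= params.high < z[i]:
            crossings.append(("on", i))
            armed_on = False
        elif armed_off and z[i - 1] >= params.low > z[i]:
            crossings.append(("off", i))
            armed_off = False

    pad = int(round(params.pad_s * sampling_rate))
    out = []
    for j, (direction, frame) in enumerate(crossings):
        lo = frame - pad
        hi = frame + pad
        if j > 0:
            lo = max(lo, (crossings[j - 1][1] + frame) // 2)
        if j + 1 < len(crossings):
            hi = min(hi, (crossings[j + 1][1] + frame) // 2)
        lo = max(0, lo)
        hi = min(n, hi)
        out.append({"direction": direction, "cross_frame": frame,
                    "window": (lo, hi)})
    return out


def fit_transition_tanh(dff: np.ndarray, window: tuple[int, int],
                        direction: str, sampling_rate: float
                        ) -> TransitionEvent:
    """Least-squares tanh fit of one transition within ``window`` (frames)."""
    x = np.asarray(dff, dtype=float).ravel()
    lo, hi = int(window[0]), int(window[1])
    seg = x[lo:hi]
    if seg.size < 8:
        raise ValueError("transition window must span at least 8 frames")
    dt = 1.0 / sampling_rate
    t = (lo + np.arange(seg.size)) * dt
    s = 1.0 if direction == "on" else -1.0

    grad = np.gradient(seg)
    t0_init = t[int(np.argmax(s * grad))]
    span = seg.size * dt
    p0 = [float(seg.min()), float(seg.max() - seg.min()),
          t0_init, max(span / 10.0, dt)]
    bounds = ([-np.inf, 1e-12, t[0] - span, dt / 10.0],
              [np.inf, np.inf, t[-1] + span, 10.0 * span])
    ok = True
    try:
        popt, _ = curve_fit(
            lambda tt, b, a, t0, tau: _tanh_model(tt, b, a, t0, tau, s),
            t, seg, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-12, ftol=1e-12)
    except RuntimeError:
        popt = p0
        ok = False
    baseline, amplitude, t0, tau = (float(v) for v in popt)
    if not (dt < tau < span):
        ok = False
    fitted = _tanh_model(t, baseline, amplitude, t0, tau, s)
    rmse = float(np.sqrt(np.mean((fitted - seg) ** 2)))
    transition_time = TANH_5_95 * tau
    # first frame of the transition: the fitted curve's 5% point (on) or
    # 95% point (off); both sit at t0 - tau*atanh(0.9)
    t_start = t0 - tau * np.arctanh(0.9)
    onset_frame = int(np.clip(np.ceil(t_start * sampling_rate), 0, x.size - 1))
    return TransitionEvent(direction=direction, t0=t0, tau=tau,
                           baseline=baseline, amplitude=amplitude,
                           onset_frame=onset_frame,
                           transition_time=transition_time, fit_rmse=rmse,
                           ok=ok, window=(lo, hi))


def extract_transitions(dff: np.ndarray, sampling_rate: float,
                        params: DetectionParams | None = None
                        ) -> list[TransitionEvent]:
    """Detect candidates and fit each one; convenience composition."""
    events = []
    for cand in detect_transitions(dff, sampling_rate, params):
        ev = fit_transition_tanh(dff, cand["window"], cand["direction"],
                                 sampling_rate)
        events.append(ev)
    return events


def summarize_kinetics(events: list[TransitionEvent], trace_length: float,
                       sampling_rate: float) -> KineticsSummary:
    """Pair ON onsets with the next OFF onset and summarize kinetics.

    ``duty_ratio`` is the summed bout duration divided by ``trace_length``
    (seconds); an unpaired trailing ON extends to the trace end and is
    flagged via ``trailing_open``. ``transient_frequency`` counts bouts per
    minute. An OFF with no preceding ON raises :class:`OrderingError`.
    """
    ons = [e for e in events if e.direction == "on"]
    offs = [e for e in events if e.direction == "off"]
    if offs and (not ons or offs[0].onset_frame < ons[0].onset_frame):
        raise OrderingError("OFF transition precedes any ON transition")

    bouts: list[TransientBout] = []
    trailing_open = False
    off_iter = iter(sorted(offs, key=lambda e: e.onset_frame))
    next_off = next(off_iter, None)
    end_frame = int(round(trace_length * sampling_rate))
    for on in sorted(ons, key=lambda e: e.onset_frame):
        while next_off is not None and next_off.onset_frame <= on.onset_frame:
            next_off = next(off_iter, None)
        if next_off is None:
            bouts.append(TransientBout(
                onset_frame=on.onset_frame, offset_frame=end_frame,
                duration=(end_frame - on.onset_frame) / sampling_rate))
            trailing_open = True
        else:
            bouts.append(TransientBout(
                onset_frame=on.onset_frame,
                offset_frame=next_off.onset_frame,
                duration=(next_off.onset_frame - on.onset_frame)
                / sampling_rate))

    total = sum(b.duration for b in bouts)
    duty = total / trace_length if trace_length > 0 else 0.0
    freq = len(bouts) / (trace_length / 60.0) if trace_length > 0 else 0.0
    rise = float(np.mean([e.transition_time for e in ons])) if ons else float("nan")
    fall = float(np.mean([e.transition_time for e in offs])) if offs else float("nan")
    return KineticsSummary(mean_rise_time=rise, mean_fall_time=fall,
                           duty_ratio=duty, transient_frequency=freq,
                           n_on=len(ons), n_off=len(offs), bouts=bouts,
                           trailing_open=trailing_open)


def average_aligned_transitions(events: list[TransitionEvent],
                                dff: np.ndarray, direction: str,
                                pre_s: float, post_s: float,
                                sampling_rate: float
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- SEM waveform of transitions aligned at their onset frame.

    ON events align at the fitted 5% crossing, OFF events at the fitted 95%
    crossing (both are the event's ``onset_frame``). Windows reaching past
    the trace bounds are padded with NaN and excluded from the per-frame
    statistics. Returns ``(mean, sem)`` arrays of length
    ``round((pre_s + post_s) * fs) + 1``.
    """
    x = np.asarray(dff, dtype=float).ravel()
    sel = [e for e in events if e.direction == direction]
    if not sel:
        raise EmptyResultError(f"no {direction} events to average")
    pre = int(round(pre_s * sampling_rate))
    post = int(round(post_s * sampling_rate))
    length = pre + post + 1
    stack = np.full((len(sel), length), np.nan)
    for i, ev in enumerate(sel):
        lo = ev.onset_frame - pre
        hi = ev.onset_frame + post + 1
        src_lo, src_hi = max(lo, 0), min(hi, x.size)
        stack[i, src_lo - lo: src_hi - lo] = x[src_lo:src_hi]
    counts = np.sum(~np.isnan(stack), axis=0)
    if not np.any(counts > 0):
        raise EmptyResultError("no usable frames across events")
    mean = np.nanmean(stack, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(stack, axis=0, ddof=0) / np.sqrt(counts)
    return mean, sem
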