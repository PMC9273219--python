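"""Global neural quiescence: per-frame classification, bout statistics,
and quiescent/non-quiescent subset extraction.

A trial-level "high activity" reference is the mean dF/F0 (averaged over
neurons) of the 25% of frames with the highest mean fluorescence. A neuron
is quiescent at a frame when its dF/F0 is below one third of that reference,
and a frame is globally quiescent when more than 70% of neurons are
quiescent — both strict inequalities. Because every threshold is relative,
the classification is invariant to rescaling all traces by a positive
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTrialError, EmptyResultError
from .trace import CalciumTraceSet, DFFTraceSet


@dataclass
class QuiescenceProfile:
    active_value: float
    frame_quiescent_fraction: np.ndarray
    global_quiescent: np.ndarray
    time_in_quiescence: float
    top_frame_fraction: float = 0.25
    quiescence_ratio: float = 1.0 / 3.0
    global_threshold: float = 0.70


def quiescence_profile(dff: DFFTraceSet | np.ndarray,
                       top_frame_fraction: float = 0.25,
                       quiescence_ratio: float = 1.0 / 3.0,
                       global_threshold: float = 0.70,
                       reference: str = "trial") -> QuiescenceProfile:
    """Classify per-frame quiescence for one trial.

    reference="trial" (default): one active value for the whole trial, the
    mean of the ``top_frame_fraction`` highest frame-mean dF/F0 values.
    reference="neuron": each neuron gets its own active value from its own
    top frames (an alternative reading of the frame-ranking rule).
    Raises :class:`DegenerateTrialError` when the active value is <= 0.
    """
    data = dff.dff if isinstance(dff, DFFTraceSet) else \
        np.atleast_2d(np.asarray(dff, dtype=float))
    n_neurons, n_frames = data.shape
    if n_frames < 8:
        raise ValueError("need at least 8 frames")
    if not (0 < top_frame_fraction < 1 and 0 < quiescence_ratio < 1
            and 0 < global_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    k = max(1, math.ceil(top_frame_fraction * n_frames))
    if reference == "trial":
        frame_vals = data.mean(axis=0)
        top = np.sort(frame_vals)[-k:]
        active_value = float(top.mean())
        if active_value <= 0:
            raise DegenerateTrialError("non-positive active fluorescence value")
        cutoff = active_value * quiescence_ratio
        quiescent = data < cutoff
    elif reference == "neuron":
        top = np.sort(data, axis=1)[:, -k:]
        active_per_neuron = top.mean(axis=1)
        if np.any(active_per_neuron <= 0):
            raise DegenerateTrialError("non-positive per-neuron active value")
        active_value = float(active_per_neuron.mean())
        quiescent = data < (active_per_neuron * quiescence_ratio)[:, None]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    frac = quiescent.mean(axis=0)
    glob = frac > global_threshold
    return QuiescenceProfile(active_value=active_value,
                             frame_quiescent_fraction=frac,
                             global_quiescent=glob,
                             time_in_quiescence=float(glob.mean()),
                             top_frame_fraction=top_frame_fraction,
                             quiescence_ratio=quiescence_ratio,
                             global_threshold=global_threshold)


def quiescent_fraction_distribution(profiles: list[QuiescenceProfile],
                                    bins: int = 20
                                    ) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram over [0, 1] of the pooled per-frame quiescent
    fractions across trials. Returns ``(probabilities, bin_edges)``."""
    if not profiles:
        raise EmptyResultError("no quiescence profiles supplied")
    pooled = np.concatenate([p.frame_quiescent_fraction for p in profiles])
    counts, edges = np.histogram(pooled, bins=bins, range=(0.0, 1.0))
    return counts / counts.sum(), edges


def extract_subset(traces: CalciumTraceSet, profile: QuiescenceProfile,
                   segment_frames: int = 700,
                   want_quiescence: bool = True
                   ) -> CalciumTraceSet | None:
    """Extract one contiguous segment with or without global quiescence.

    want_quiescence=True: the window maximizing the number of globally
    quiescent frames (earliest among ties); returns None if no window
    contains any quiescence. want_quiescence=False: the earliest window with
    zero globally quiescent frames; None if every window contains some.
    """
    n = traces.n_frames
    if n < segment_frames:
        return None
    g = profile.global_quiescent.astype(int)
    csum = np.concatenate([[0], np.cumsum(g)])
    window_counts = csum[segment_frames:] - csum[: n - segment_frames + 1]
    if want_quiescence:
        best = int(np.argmax(window_counts))
        if window_counts[best] == 0:
            return None
        start = best
    else:
        zeros = np.nonzero(window_counts == 0)[0]
        if zeros.size == 0:
            return None
        start = int(zeros[0])
    return CalciumTraceSet(
        values=traces.values[:, start:start + segment_frames].copy(),
        sampling_rate=traces.sampling_rate,
        trial_id=f"{traces.trial_id}[{start}:{start + segment_frames}]",
        condition=traces.condition)
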