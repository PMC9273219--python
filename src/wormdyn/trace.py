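"""Core trace containers.

A :class:`CalciumTraceSet` holds one trial's raw fluorescence matrix
(neurons x frames) plus acquisition metadata. ``DFFTraceSet`` holds the
dF/F0-normalized version together with the baseline vector and the
normalization dialect used, and ``DerivativeTraceSet`` the TV-regularized
time differentials. All are thin dataclasses over numpy arrays; validation
happens at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class CalciumTraceSet:
    """Raw fluorescence traces for one trial.

    Parameters
    ----------
    values : ndarray, shape (neurons, frames)
        Fluorescence in arbitrary units; finite and non-negative.
    sampling_rate : float
        Acquisition rate in Hz (2 Hz for whole-head volumetric trials,
        4 Hz for single-neuron AVA trials).
    trial_id : str
        Identifier of the recording.
    condition : str
        Group label, e.g. ``"day1"`` or a genotype.
    """

    values: np.ndarray
    sampling_rate: float
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[None, :]
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValidationError("trace matrix must be 2-D with >= 1 neuron")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("fluorescence values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("fluorescence values must be >= 0")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.values.shape[1] < 1:
            raise ValidationError("trial must contain at least one frame")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds (frames / sampling_rate)."""
        return self.n_frames / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate


@dataclass
class DFFTraceSet:
    """dF/F0-normalized traces: ``dff = (values - f0) / f0`` row-wise.

    ``mode`` records the baseline dialect: ``"lowest_percentile"`` (each
    neuron's F0 is the mean of its lowest ``percentile`` fraction of
    measurements; the multi-neuron convention) or ``"trace_mean"`` (F0 is
    the trace mean; the single-neuron AVA convention).
    """

    dff: np.ndarray
    f0: np.ndarray
    mode: str
    sampling_rate: float
    percentile: float = 0.01
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim == 1:
            self.dff = self.dff[None, :]
        self.f0 = np.atleast_1d(np.asarray(self.f0, dtype=float))
        if self.f0.shape[0] != self.dff.shape[0]:
            raise ValidationError("f0 must have one entry per neuron")
        if np.any(self.f0 <= 0):
            raise ValidationError("f0 must be positive for every neuron")
        if self.mode not in ("lowest_percentile", "trace_mean"):
            raise ValidationError(f"unknown normalization mode {self.mode!r}")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate

    def unnormalize(self) -> np.ndarray:
        """Reconstruct the raw fluorescence matrix (dff * f0 + f0)."""
        return self.dff * self.f0[:, None] + self.f0[:, None]


@dataclass
class DerivativeTraceSet:
    """TV-regularized time differentials of a dF/F0 matrix, in 1/s."""

    ddt: np.ndarray
    alpha: float
    iterations: int
    sampling_rate: float
    converged: bool = True
    trial_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.ddt = np.asarray(self.ddt, dtype=float)
        if self.ddt.ndim == 1:
            self.ddt = self.ddt[None, :]

    @property
    def n_neurons(self) -> int:
        return self.ddt.shape[0]

    @property
    def n_frames(self) -> int:
        return self.ddt.shape[1]


@dataclass
class SNRResult:
    """Signal-to-noise ratio of one trace, in decibels."""

    snr_db: float
    method: str
    window_s: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValidationError("snr_db must be finite")
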