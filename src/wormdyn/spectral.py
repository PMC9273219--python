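"""Power spectral densities and the q-quantile spectral edge.

Each neuron's PSD is the one-sided full-length periodogram of its
mean-removed dF/F0 trace (boxcar window, no segmentation), so for a 10-min
trial at 2 Hz the frequency resolution is 1/600 Hz. The DC bin is dropped
everywhere: the mean is removed before transforming, so DC carries no
information and would otherwise dominate quantile edges. Condition-level
spectra average PSDs within worm, then across worms, and are rescaled to
unit total power so that an overall change in indicator brightness cannot
masquerade as a change in dynamics. The q-quantile spectral edge (default
q = 0.40) is the lowest grid frequency below which at least a fraction q of
the total power resides; a higher edge means faster dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .errors import GridMismatchError
from .trace import DerivativeTraceSet, DFFTraceSet


@dataclass
class PSDSet:
    """One-sided PSDs (neurons x frequencies), DC excluded."""

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool
    source: str                 # "dff" | "derivative"
    sampling_rate: float
    zero_power_neurons: tuple[int, ...] = ()

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 \
            else float(self.freqs[0])


@dataclass
class SpectralEdge:
    q: float
    edge_hz: float


def compute_psd(traces: DFFTraceSet | DerivativeTraceSet | np.ndarray,
                sampling_rate: float | None = None) -> PSDSet:
    """Per-neuron periodogram of the full trace; deterministic.

    The per-neuron mean is removed before the transform and the DC bin is
    excluded from the returned grid. All-zero neurons yield an (allowed)
    zero power row, recorded in ``zero_power_neurons``.
    """
    if isinstance(traces, DFFTraceSet):
        data, fs, source = traces.dff, traces.sampling_rate, "dff"
    elif isinstance(traces, DerivativeTraceSet):
        data, fs, source = traces.ddt, traces.sampling_rate, "derivative"
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw array input")
        data, fs, source = np.atleast_2d(np.asarray(traces, float)), \
            sampling_rate, "dff"
    if data.shape[1] < 64:
        raise ValueError("need at least 64 frames for a meaningful PSD")
    freqs, pxx = periodogram(data, fs=fs, window="boxcar",
                             detrend="constant", axis=1,
                             scaling="density")
    freqs, pxx = freqs[1:], pxx[:, 1:]
    zero_rows = tuple(int(i) for i in
                      np.nonzero(pxx.sum(axis=1) == 0.0)[0])
    return PSDSet(freqs=freqs, power=pxx, normalized=False, source=source,
                  sampling_rate=fs, zero_power_neurons=zero_rows)


def mean_normalized_psd(psdsets: list[PSDSet]
                        ) -> tuple[PSDSet, np.ndarray]:
    """Condition-mean PSD with unit total power, plus its cumulative curve.

    Averages per-neuron PSDs within each worm, then across worms, then
    rescales so that ``sum(power) * df == 1``. The cumulative curve is the
    running integral of the normalized mean: monotone from ~0 to 1.
    """
    if not psdsets:
        raise ValueError("need at least one PSDSet")
    ref = psdsets[0].freqs
    for p in psdsets[1:]:
        if p.freqs.shape != ref.shape or not np.allclose(p.freqs, ref):
            raise GridMismatchError("PSD frequency grids differ")
    worm_means = np.stack([p.power.mean(axis=0) for p in psdsets])
    mean = worm_means.mean(axis=0)
    df = psdsets[0].df
    total = mean.sum() * df
    if total <= 0:
        raise ValueError("total power is zero; cannot normalize")
    mean = mean / total
    cumulative = np.cumsum(mean) * df
    out = PSDSet(freqs=ref.copy(), power=mean[None, :], normalized=True,
                 source=psdsets[0].source,
                 sampling_rate=psdsets[0].sampling_rate)
    return out, cumulative


def spectral_edge(psd: PSDSet | np.ndarray, q: float = 0.40,
                  freqs: np.ndarray | None = None) -> SpectralEdge:
    """Smallest grid frequency with cumulative power fraction >= q.

    Accepts a PSDSet (its mean across rows is used) or a raw 1-D power
    vector with an explicit ``freqs`` grid. No interpolation: the edge is
    reported on the frequency grid, so it is resolved to one bin width.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    if isinstance(psd, PSDSet):
        power = psd.power.mean(axis=0)
        freqs = psd.freqs
    else:
        power = np.asarray(psd, dtype=float).ravel()
        if freqs is None:
            raise ValueError("freqs grid required for raw power input")
    total = power.sum()
    if total <= 0:
        raise ValueError("total power must be positive")
    frac = np.cumsum(power) / total
    idx = int(np.argmax(frac >= q))
    return SpectralEdge(q=q, edge_hz=float(freqs[idx]))


def per_neuron_edges(psd: PSDSet, q: float = 0.40) -> np.ndarray:
    """Spectral edge of every neuron's own PSD (pooled-histogram support).

    Zero-power neurons yield NaN.
    """
    out = np.full(psd.power.shape[0], np.nan)
    for i, row in enumerate(psd.power):
        if row.sum() > 0:
            out[i] = spectral_edge(row, q=q, freqs=psd.freqs).edge_hz
    return out
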