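"""Population state-space analysis: PCA trajectories, angular-change
stochasticity, and time-time recurrence maps.

PCA treats neurons as variables and frames as observations; scores are kept
on their natural scale (no whitening), so the 3-D trajectory of the first
three components is the activity-manifold picture. Trajectory smoothness is
quantified per frame as the absolute angle between the displacement over the
past ``window_s`` seconds and that over the next ``window_s`` seconds: a
smooth manifold yields mostly small angles, a randomized trajectory a flat
distribution over [0, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import EmptyResultError
from .trace import DFFTraceSet


@dataclass
class PCATrajectory:
    """Unnormalized PC scores (frames x k), loadings, explained variance.

    ``explained_var`` holds the fraction of variance for *every* component
    (summing to 1); only the first ``k`` columns of scores/loadings are
    retained for plotting and angle analysis.
    """

    scores: np.ndarray
    explained_var: np.ndarray
    loadings: np.ndarray


@dataclass
class AngularChangeSeries:
    """Per-frame angular direction changes, degrees in [0, 180].

    Frames whose past or future window leaves the trial, or whose
    displacement vanishes, carry NaN; ``n_undefined`` counts the latter.
    """

    angles: np.ndarray
    window_s: float
    n_undefined: int


@dataclass
class RecurrenceMap:
    """Frame-by-frame Euclidean distances, normalized to [0, 1]."""

    dist: np.ndarray
    degenerate: bool = False


def run_pca(dff: DFFTraceSet | np.ndarray, k: int = 3) -> PCATrajectory:
    """PCA of the dF/F0 matrix with neurons as variables.

    Per-neuron means are removed; no variance scaling is applied. Component
    sign is fixed so that each loading vector's largest-magnitude entry is
    positive, making results deterministic.
    """
    data = dff.dff if isinstance(dff, DFFTraceSet) else \
        np.atleast_2d(np.asarray(dff, dtype=float))
    n_neurons = data.shape[0]
    if k > n_neurons:
        raise ValueError("k exceeds the number of neurons")
    X = data.T - data.mean(axis=1)  # frames x neurons, column-centered
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    loadings = Vt[:k].T.copy()        # neurons x k
    scores = (U[:, :k] * S[:k]).copy()  # frames x k
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCATrajectory(scores=scores, explained_var=explained,
                         loadings=loadings)


def angular_changes(traj: PCATrajectory | np.ndarray, sampling_rate: float,
                    window_s: float = 3.0) -> AngularChangeSeries:
    """Angle between past and future displacement vectors at each frame.

    At frame t with window w frames, ``v_past = P(t) - P(t-w)`` and
    ``v_future = P(t+w) - P(t)``; the angle is
    ``arccos(v_past . v_future / (|v_past| |v_future|))`` in degrees.
    Zero-length displacements give NaN (counted, excluded from histograms).
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    P = traj.scores if isinstance(traj, PCATrajectory) else \
        np.asarray(traj, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = P.shape[0]
    w = max(1, int(round(window_s * sampling_rate)))
    if n <= 2 * w:
        raise ValueError("trajectory shorter than twice the window")
    vp = P[w:n - w] - P[:n - 2 * w]
    vf = P[2 * w:] - P[w:n - w]
    np_norm = np.linalg.norm(vp, axis=1)
    nf_norm = np.linalg.norm(vf, axis=1)
    ok = (np_norm > 0) & (nf_norm > 0)
    cosang = np.full(vp.shape[0], np.nan)
    cosang[ok] = np.einsum("ij,ij->i", vp[ok], vf[ok]) / (
        np_norm[ok] * nf_norm[ok])
    cosang = np.clip(cosang, -1.0, 1.0)
    core = np.degrees(np.arccos(cosang))
    angles = np.full(n, np.nan)
    angles[w:n - w] = core
    return AngularChangeSeries(angles=angles, window_s=window_s,
                               n_undefined=int((~ok).sum()))


def angle_histogram(series: list[AngularChangeSeries] | AngularChangeSeries,
                    bins: int = 18) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram of pooled angular changes over [0, 180] deg.

    Pooling concatenates defined angles across trials before binning.
    Returns ``(probabilities, bin_edges)``; probabilities sum to 1.
    """
    if isinstance(series, AngularChangeSeries):
        series = [series]
    if not series:
        raise EmptyResultError("no angle series supplied")
    pooled = np.concatenate([s.angles[~np.isnan(s.angles)] for s in series])
    if pooled.size == 0:
        raise EmptyResultError("no defined angles to histogram")
    counts, edges = np.histogram(pooled, bins=bins, range=(0.0, 180.0))
    return counts / counts.sum(), edges


def low_angle_mass(series: AngularChangeSeries, cutoff_deg: float = 30.0
                   ) -> float:
    """Fraction of defined angular changes below ``cutoff_deg``."""
    defined = series.angles[~np.isnan(series.angles)]
    if defined.size == 0:
        raise EmptyResultError("no defined angles")
    return float(np.mean(defined < cutoff_deg))


def recurrence_map(dff: DFFTraceSet | np.ndarray) -> RecurrenceMap:
    """Pairwise Euclidean distance between frame vectors, unit-max scaled.

    All neurons contribute; the map is symmetric with a zero diagonal. An
    all-identical-frames input yields an all-zero map flagged degenerate.
    """
    data = dff.dff if isinstance(dff, DFFTraceSet) else \
        np.atleast_2d(np.asarray(dff, dtype=float))
    if data.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    d = pdist(data.T, metric="euclidean")
    dmax = d.max() if d.size else 0.0
    if dmax == 0:
        return RecurrenceMap(dist=squareform(d), degenerate=True)
    return RecurrenceMap(dist=squareform(d / dmax), degenerate=False)
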