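"""Pairwise correlation structure of the most dynamically active neurons.

Functional coupling is read out as the zero-lag Pearson correlation between
the TV-regularized time differentials of neuron pairs, restricted to the
``n_sel`` (default 40 of 120) neurons with the greatest dF/F0 standard
deviation. The proportions of pairs with r < -0.2 (anti-correlated; a proxy
for inhibitory coupling) and r > 0.2 (correlated; excitatory coupling) are
the per-animal summary statistics. Thresholds are strict inequalities, so
boundary values count in neither tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyResultError
from .trace import DerivativeTraceSet, DFFTraceSet

NEG_THRESHOLD = -0.2
POS_THRESHOLD = 0.2


@dataclass
class PairCorrelationSet:
    """Condensed upper-triangle Pearson coefficients of selected neurons.

    ``r`` has length ``n_sel * (n_sel - 1) / 2`` in row-major condensed
    order; undefined pairs (a zero-variance member) are NaN and excluded
    from proportions but counted in ``n_undefined``.
    """

    selected: np.ndarray
    r: np.ndarray
    selection_rule: str = "top_sd_dff"

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.r).sum())


@dataclass
class CorrelationProportions:
    neg_prop: float
    pos_prop: float
    n_defined: int
    neg_threshold: float = NEG_THRESHOLD
    pos_threshold: float = POS_THRESHOLD


def select_active_neurons(dff: DFFTraceSet | np.ndarray,
                          n_sel: int = 40) -> np.ndarray:
    """Indices of the ``n_sel`` neurons with largest dF/F0 standard deviation.

    Ties break toward the lower neuron index (stable sort on -sd).
    """
    data = dff.dff if isinstance(dff, DFFTraceSet) else np.atleast_2d(dff)
    if n_sel < 2:
        raise ValueError("n_sel must be >= 2")
    if n_sel > data.shape[0]:
        raise ValueError("n_sel exceeds the number of neurons")
    sd = data.std(axis=1)
    order = np.argsort(-sd, kind="stable")
    return np.sort(order[:n_sel])


def pairwise_correlations(ddt: DerivativeTraceSet | np.ndarray,
                          indices: np.ndarray) -> PairCorrelationSet:
    """Pearson r for every pair of selected differential traces.

    Pairs involving a zero-variance series are flagged NaN (undefined)
    rather than raising; they are excluded from downstream proportions.
    """
    data = ddt.ddt if isinstance(ddt, DerivativeTraceSet) else \
        np.atleast_2d(np.asarray(ddt, dtype=float))
    indices = np.asarray(indices, dtype=int)
    if indices.size < 2:
        raise ValueError("need at least 2 selected neurons")
    sub = data[indices]
    sd = sub.std(axis=1)
    valid = sd > 0
    n = sub.shape[0]
    rmat = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        cc = np.corrcoef(sub[valid])
        vi = np.nonzero(valid)[0]
        rmat[np.ix_(vi, vi)] = cc
    iu, ju = np.triu_indices(n, k=1)
    r = rmat[iu, ju]
    return PairCorrelationSet(selected=indices, r=r)


def correlation_proportions(pairs: PairCorrelationSet
                            ) -> CorrelationProportions:
    """Fractions of defined pairs beyond the +/-0.2 thresholds (strict)."""
    defined = pairs.r[~np.isnan(pairs.r)]
    if defined.size == 0:
        raise EmptyResultError("no defined correlation pairs")
    neg = float(np.mean(defined < NEG_THRESHOLD))
    pos = float(np.mean(defined > POS_THRESHOLD))
    return CorrelationProportions(neg_prop=neg, pos_prop=pos,
                                  n_defined=int(defined.size))


def pooled_correlation_histogram(sets: list[PairCorrelationSet],
                                 bins: int = 40
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram of pooled r values over [-1, 1].

    Pooling concatenates the defined coefficients of all sets before
    binning, so each set contributes in proportion to its pair count.
    Returns ``(probabilities, bin_edges)`` with probabilities summing to 1.
    """
    if not sets:
        raise EmptyResultError("no correlation sets to pool")
    pooled = np.concatenate([s.r[~np.isnan(s.r)] for s in sets])
    if pooled.size == 0:
        raise EmptyResultError("no defined correlation pairs to pool")
    counts, edges = np.histogram(pooled, bins=bins, range=(-1.0, 1.0))
    return counts / counts.sum(), edges
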