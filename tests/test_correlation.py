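"""Neuron selection, pairwise correlations, and tail proportions."""

import numpy as np
import pytest

from wormdyn import (correlation_proportions, pairwise_correlations,
                     pooled_correlation_histogram, select_active_neurons,
                     tv_differentiate)
from wormdyn.correlation import PairCorrelationSet
from wormdyn.errors import EmptyResultError
from wormdyn.synthetic import PopulationConfig, generate_population
from wormdyn.preprocess import normalize_dff
from dataclasses import replace


class TestSelection:
    def test_largest_sd_selected(self, rng):
        base = rng.normal(0, 1, 300)
        dff = np.vstack([0.1 * base, 0.5 * base, 0.3 * base])
        np.testing.assert_array_equal(
            select_active_neurons(dff, 2), [1, 2])

    def test_tie_breaks_to_lower_index(self):
        dff = np.tile(np.sin(np.linspace(0, 10, 100)), (4, 1))
        np.testing.assert_array_equal(select_active_neurons(dff, 2), [0, 1])

    def test_driven_neurons_found_among_near_silent(self):
        cfg = replace(PopulationConfig(seed=5), background_amplitude=0.0)
        traces, truth = generate_population(cfg)
        sel = select_active_neurons(normalize_dff(traces), 40)
        np.testing.assert_array_equal(sel, truth.active_neurons)

    def test_too_few_rejected(self, rng):
        with pytest.raises(ValueError):
            select_active_neurons(rng.normal(0, 1, (3, 50)), 1)


class TestPairwise:
    def test_sign_extremes(self):
        x = np.sin(np.linspace(0, 20, 500))
        r = pairwise_correlations(np.vstack([x, -x]), np.array([0, 1])).r
        assert r[0] == pytest.approx(-1.0)
        r = pairwise_correlations(np.vstack([x, x]), np.array([0, 1])).r
        assert r[0] == pytest.approx(1.0)

    def test_four_sinusoid_enumeration(self):
        x = np.sin(np.linspace(0, 20, 500))
        mat = np.vstack([x, -x, x, -x])
        r = pairwise_correlations(mat, np.arange(4)).r
        np.testing.assert_allclose(r, [-1, 1, -1, -1, 1, -1], atol=1e-12)

    def test_zero_variance_pairs_flagged(self):
        x = np.sin(np.linspace(0, 20, 500))
        mat = np.vstack([x, np.zeros(500), -x])
        pairs = pairwise_correlations(mat, np.arange(3))
        assert pairs.n_undefined == 2
        assert pairs.r[1] == pytest.approx(-1.0)  # pair (0, 2)


class TestProportions:
    def test_four_sinusoid_proportions(self):
        x = np.sin(np.linspace(0, 20, 500))
        pairs = pairwise_correlations(np.vstack([x, -x, x, -x]),
                                      np.arange(4))
        props = correlation_proportions(pairs)
        assert props.neg_prop == pytest.approx(4 / 6)
        assert props.pos_prop == pytest.approx(2 / 6)

    def test_all_zero_r(self):
        pairs = PairCorrelationSet(selected=np.arange(3), r=np.zeros(3))
        props = correlation_proportions(pairs)
        assert props.neg_prop == 0.0 and props.pos_prop == 0.0

    def test_boundary_values_in_neither_tail(self):
        pairs = PairCorrelationSet(selected=np.arange(3),
                                   r=np.array([-0.2, 0.2, 0.0]))
        props = correlation_proportions(pairs)
        assert props.neg_prop == 0.0 and props.pos_prop == 0.0

    def test_empty_error(self):
        pairs = PairCorrelationSet(selected=np.arange(2),
                                   r=np.array([np.nan]))
        with pytest.raises(EmptyResultError):
            correlation_proportions(pairs)

    def test_white_noise_null_rate(self):
        # |r| > 0.2 is many sd out for n=1200 independent samples
        rng = np.random.default_rng(17)
        negs = []
        for _ in range(100):
            mat = rng.normal(0, 1, (40, 1200))
            props = correlation_proportions(
                pairwise_correlations(mat, np.arange(40)))
            negs.append(props.neg_prop)
        assert np.mean(negs) < 0.01

    def test_affine_rescaling_invariance(self, rng):
        mat = rng.normal(0, 1, (5, 400))
        a = pairwise_correlations(mat, np.arange(5)).r
        scaled = mat * rng.uniform(0.5, 3, (5, 1)) + rng.normal(0, 1, (5, 1))
        b = pairwise_correlations(scaled, np.arange(5)).r
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestHistogram:
    def test_all_plus_one_in_top_bin(self):
        s = PairCorrelationSet(selected=np.arange(3), r=np.ones(3))
        h, edges = pooled_correlation_histogram([s], bins=40)
        assert h[-1] == 1.0 and h[:-1].sum() == 0.0

    def test_pooling_weights_by_pair_count(self):
        a = PairCorrelationSet(selected=np.arange(2), r=np.array([0.5]))
        b = PairCorrelationSet(selected=np.arange(3),
                               r=np.array([-0.5, -0.5, -0.5]))
        h, edges = pooled_correlation_histogram([a, b], bins=4)
        # edges at -1,-0.5,0,0.5,1: r=-0.5 lands in bin 1, r=0.5 in bin 3
        np.testing.assert_allclose(h, [0, 0.75, 0, 0.25])

    def test_symmetric_r_gives_mirror_histogram(self):
        s = PairCorrelationSet(selected=np.arange(2),
                               r=np.array([-0.55, 0.55]))
        h, _ = pooled_correlation_histogram([s], bins=8)
        np.testing.assert_allclose(h, h[::-1])

    def test_sums_to_one_and_tails_match_proportions(self, rng):
        r = rng.uniform(-1, 1, 200)
        s = PairCorrelationSet(selected=np.arange(21), r=r)
        h, edges = pooled_correlation_histogram([s], bins=40)
        assert h.sum() == pytest.approx(1.0)
        props = correlation_proportions(s)
        # +-0.2 falls on bin edges with 40 bins of 0.05
        assert h[edges[:-1] < -0.2 - 1e-9].sum() == pytest.approx(
            props.neg_prop, abs=1e-12)
        assert h[edges[1:] > 0.2 + 1e-9].sum() == pytest.approx(
            props.pos_prop, abs=1e-12)


def test_neg_prop_monotone_in_inhibition_scale():
    """The aging signature at generator level: scaling inhibitory loadings
    from 1 to 0 must strictly erode the anti-correlated tail while leaving
    the positive tail roughly unchanged."""
    from scipy.stats import spearmanr

    levels = [1.0, 0.75, 0.5, 0.25, 0.0]
    seeds = range(10)
    neg_means, pos_means = [], []
    for level in levels:
        negs, poss = [], []
        for seed in seeds:
            cfg = replace(PopulationConfig(seed=seed),
                          inhibition_scale=level)
            traces, _ = generate_population(cfg)
            dff = normalize_dff(traces)
            sel = select_active_neurons(dff, 40)
            pairs = pairwise_correlations(tv_differentiate(dff), sel)
            props = correlation_proportions(pairs)
            negs.append(props.neg_prop)
            poss.append(props.pos_prop)
        neg_means.append(np.mean(negs))
        pos_means.append(np.mean(poss))
    rho, _ = spearmanr(levels, neg_means)
    assert rho > 0.9  # neg_prop falls as inhibition is scaled away
    assert max(pos_means) - min(pos_means) <= 0.05
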