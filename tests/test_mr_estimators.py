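"""Causal estimators against hand-computed and simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutbrainmr import (
    CausalScenario,
    InsufficientInstrumentsError,
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
)
from gutbrainmr.sensitivity import cochran_q

from conftest import instrument_pairs, make_pairs


def test_wald_ratio_fixtures():
    """beta_out/beta_exp = 0.02/0.1 -> 0.2 with se 0.05/0.1 = 0.5."""
    p = make_pairs([0.1], [0.02], [0.05]).pairs[0]
    est = wald_ratio(p)
    assert est.beta == pytest.approx(0.2, rel=1e-12)
    assert est.se == pytest.approx(0.5, rel=1e-12)
    null = wald_ratio(make_pairs([0.1], [0.0], [0.05]).pairs[0])
    assert null.beta == 0.0 and null.or_ == 1.0
    ident = wald_ratio(make_pairs([1.0], [0.037], [0.05]).pairs[0])
    assert ident.beta == 0.037
    with pytest.raises(ZeroDivisionError):
        wald_ratio(make_pairs([0.0], [0.02], [0.05]).pairs[0])


def test_ivw_hand_fixture(hand_pairs):
    """Ratios {0.1, 0.2, 0.3}, equal ratio SEs 0.1: beta = 0.2; Q = 2 does
    not exceed k-1 so the random-effects SE stays 0.1/sqrt(3)."""
    est = ivw(hand_pairs)
    assert est.beta == pytest.approx(0.2, abs=1e-12)
    assert est.se == pytest.approx(0.1 / np.sqrt(3), abs=1e-12)
    assert est.n_snp == 3


def test_ivw_k1_equals_wald_ratio():
    pairs = make_pairs([0.1], [0.02], [0.05])
    assert ivw(pairs).beta == wald_ratio(pairs.pairs[0]).beta
    assert ivw(pairs).se == wald_ratio(pairs.pairs[0]).se
    with pytest.raises(InsufficientInstrumentsError):
        ivw(make_pairs([], [], []))


def test_ivw_invariant_to_pair_order():
    rng = np.random.default_rng(3)
    bx, by, sy = rng.normal(0.1, 0.02, 8), rng.normal(0.02, 0.01, 8), rng.uniform(0.01, 0.03, 8)
    a = ivw(make_pairs(bx, by, sy))
    perm = rng.permutation(8)
    b = ivw(make_pairs(bx[perm], by[perm], sy[perm]))
    assert a.beta == pytest.approx(b.beta, rel=1e-14)
    assert a.se == pytest.approx(b.se, rel=1e-14)


def test_ivw_random_effects_inflation_consistent_with_q(hand_pairs):
    """RE se = fixed se * max(1, sqrt(Q/(k-1))) with the same Q as the
    heterogeneity test."""
    rng = np.random.default_rng(5)
    pairs = make_pairs(
        rng.normal(0.1, 0.03, 10), rng.normal(0.0, 0.05, 10), rng.uniform(0.005, 0.02, 10)
    )
    q, df, _ = cochran_q(pairs)
    fixed = ivw(pairs, random_effects=False)
    re = ivw(pairs)
    assert re.se == pytest.approx(fixed.se * max(1.0, np.sqrt(q / df)), rel=1e-12)


def test_noise_free_identity(noise_free_pairs):
    """Exact simulated data, no pleiotropy: IVW and Egger recover the
    causal effect exactly and the Egger intercept is 0."""
    pairs, truth = noise_free_pairs
    assert ivw(pairs).beta == pytest.approx(0.17, rel=1e-10)
    slope, intercept = egger(pairs)
    assert slope.beta == pytest.approx(0.17, rel=1e-8)
    assert intercept.beta == pytest.approx(0.0, abs=1e-10)
    # with a zero intercept the Egger slope coincides with fixed-effect IVW
    assert slope.beta == pytest.approx(ivw(pairs, random_effects=False).beta, rel=1e-8)


def test_egger_three_point_fixture():
    """(0.1,0.02),(0.2,0.03),(0.3,0.04), equal weights: OLS slope 0.1,
    intercept 0.01."""
    pairs = make_pairs([0.1, 0.2, 0.3], [0.02, 0.03, 0.04], [0.05, 0.05, 0.05])
    slope, intercept = egger(pairs)
    assert slope.beta == pytest.approx(0.1, abs=1e-10)
    assert intercept.beta == pytest.approx(0.01, abs=1e-10)
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_pairs([0.1, 0.2], [0.01, 0.02], [0.05, 0.05]))


def test_weighted_median_fixtures():
    """Equal weights, odd k: the plain median. Weights {.25, .5, .25} on
    ratios {1, 2, 10}: cumulative weight crosses 0.5 inside the middle SNP."""
    eq = weighted_median(make_pairs([1, 1, 1], [0.1, 0.3, 0.2], [0.1, 0.1, 0.1]), seed=0)
    assert eq.beta == pytest.approx(0.2, abs=1e-12)
    # w_j = beta_exp^2 / se_out^2 = 1/se_out^2 at beta_exp = 1
    sy = 1.0 / np.sqrt([0.25, 0.5, 0.25])
    wm = weighted_median(make_pairs([1, 1, 1], [1, 2, 10], sy), seed=0)
    assert wm.beta == pytest.approx(2.0, abs=1e-12)


def test_bootstrap_se_reproducible_and_seed_sensitive(hand_pairs):
    a = weighted_median(hand_pairs, boot_reps=200, seed=42)
    b = weighted_median(hand_pairs, boot_reps=200, seed=42)
    c = weighted_median(hand_pairs, boot_reps=200, seed=43)
    assert a.se == b.se
    assert a.se != c.se
    m1 = mode_estimate(hand_pairs, boot_reps=100, seed=7)
    m2 = mode_estimate(hand_pairs, boot_reps=100, seed=7)
    assert m1.se == m2.se


def test_mode_cluster_ignores_outlier():
    """Ratios {0.2, 0.21, 0.19, 5.0}: the mode sits in the tight cluster."""
    pairs = make_pairs([1, 1, 1, 1], [0.2, 0.21, 0.19, 5.0], [0.1] * 4)
    est = mode_estimate(pairs, weighted=False, boot_reps=10, seed=0)
    assert 0.17 <= est.beta <= 0.23
    ident = mode_estimate(make_pairs([1, 1, 1], [0.4, 0.4, 0.4], [0.1] * 3),
                          boot_reps=10, seed=0)
    assert ident.beta == pytest.approx(0.4, abs=1e-12)


def test_weighted_vs_simple_mode_differ_when_outlier_dominates_weight():
    """If the outlying ratio carries most of the weight the weighted mode
    follows it while the simple mode stays with the majority cluster."""
    bx = np.array([1.0, 1.0, 1.0, 1.0])
    by = np.array([0.2, 0.21, 0.19, 5.0])
    sy = np.array([1.0, 1.0, 1.0, 0.01])  # outlier is overwhelmingly precise
    pairs = make_pairs(bx, by, sy)
    simple = mode_estimate(pairs, weighted=False, boot_reps=10, seed=0)
    weighted = mode_estimate(pairs, weighted=True, boot_reps=10, seed=0)
    assert 0.15 <= simple.beta <= 0.25
    assert weighted.beta > 2.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_or_and_ci_invariants(seed):
    """or_ = exp(beta) exactly; CI = exp(beta -+ 1.96 se) contains the OR;
    estimates are equivariant under joint sign flip of both betas."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 12))
    bx = rng.normal(0.1, 0.05, k)
    bx[np.abs(bx) < 1e-3] = 0.05
    by = rng.normal(0.02, 0.03, k)
    sy = rng.uniform(0.005, 0.05, k)
    pairs = make_pairs(bx, by, sy)
    for est in (ivw(pairs), egger(pairs)[0], weighted_median(pairs, boot_reps=20, seed=1)):
        assert est.or_ == np.exp(est.beta)
        assert est.ci_low <= est.or_ <= est.ci_high
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.96 * est.se), rel=1e-12)
    flipped = make_pairs(-bx, -by, sy)
    assert ivw(flipped).beta == pytest.approx(ivw(pairs).beta, rel=1e-12)
    assert egger(flipped)[0].beta == pytest.approx(egger(pairs)[0].beta, rel=1e-12)
    assert weighted_median(flipped, boot_reps=20, seed=1).beta == pytest.approx(
        weighted_median(pairs, boot_reps=20, seed=1).beta, rel=1e-12
    )


def test_egger_intercept_tracks_directional_pleiotropy():
    """With pleiotropy oriented along the exposure-increasing allele the
    intercept recovers its mean direction and magnitude approximately."""
    intercepts = []
    for rep in range(100):
        sc = CausalScenario(
            m_snps=50, m_instruments=50, beta_causal=0.15,
            pleio_mean=0.05, pleio_sd=0.001, seed=40_000 + rep,
        )
        pairs, _ = instrument_pairs(sc)
        intercepts.append(egger(pairs)[1].beta)
    mean_int = np.mean(intercepts)
    assert 0.5 * 0.05 < mean_int < 1.2 * 0.05
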