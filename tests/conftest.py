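"""Shared fixtures and simulation-study helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gutbrainmr import CausalScenario, HarmonizedPair, HarmonizedPairSet, harmonize
from gutbrainmr.synthetic_data import simulate_pair


def make_pairs(bx, by, sy, sx=None, ids=None) -> HarmonizedPairSet:
    """Hand-built harmonized pair set for estimator fixtures."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    ids = ids or [f"snp{i:03d}" for i in range(len(bx))]
    pairs = [
        HarmonizedPair(
            snp_id=ids[i], beta_exp=bx[i], se_exp=sx[i],
            beta_out=by[i], se_out=sy[i], action="unchanged",
        )
        for i in range(len(bx))
    ]
    return HarmonizedPairSet(exposure_id="E", outcome_id="O", pairs=pairs)


def instrument_pairs(scenario: CausalScenario):
    """Simulate a pair study and harmonize the true-instrument SNPs.

    Instruments are chosen by true status (not by p), which side-steps
    winner's curse in benchmark replicates.
    """
    exposure, outcome, truth = simulate_pair(scenario)
    instr = truth.table.loc[truth.table["is_instrument"], "snp_id"].tolist()
    return harmonize(exposure.subset(instr), outcome), truth


def plant_outlier(pairs: HarmonizedPairSet, se_multiple: float = 10.0) -> str:
    """Add a pleiotropic offset to the highest-weight instrument in place.

    The offset lands on the instrument with the largest IVW weight
    (|beta_exp|/se_out) so that it actually distorts the pooled estimate;
    returns the corrupted snp_id.
    """
    j = int(np.argmax([abs(p.beta_exp) / p.se_out for p in pairs.pairs]))
    p = pairs.pairs[j]
    pairs.pairs[j] = dataclasses.replace(p, beta_out=p.beta_out + se_multiple * p.se_out)
    return p.snp_id


def add_directional_pleiotropy(
    pairs: HarmonizedPairSet, snp_indices, offset: float
) -> None:
    """Shift beta_out by ``offset`` oriented with the exposure-increasing allele."""
    for i in snp_indices:
        p = pairs.pairs[i]
        pairs.pairs[i] = dataclasses.replace(
            p, beta_out=p.beta_out + offset * np.sign(p.beta_exp)
        )


@pytest.fixture
def hand_pairs() -> HarmonizedPairSet:
    """Ratios {0.1, 0.2, 0.3} with equal ratio SEs of 0.1 (beta_exp = 1)."""
    return make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])


@pytest.fixture
def noise_free_pairs():
    """Exact-mode simulated study: no pleiotropy, no measurement noise."""
    scenario = CausalScenario(
        m_snps=12, m_instruments=12, beta_causal=0.17, exact=True, seed=7
    )
    pairs, truth = instrument_pairs(scenario)
    return pairs, truth
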