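"""End-to-end screening: thresholds, single pairs, full screens."""

import dataclasses

import numpy as np
import pytest

from gutbrainmr import (
    CausalScenario,
    ScreenConfig,
    bonferroni_threshold,
    run_pair,
    run_screen,
    simulate_ld,
    simulate_pair,
)
from gutbrainmr.screen_pipeline import mediation_table
from gutbrainmr.sumstats_io import SummaryDataset
from gutbrainmr.synthetic_data import simulate_mediation_triple


def test_bonferroni_family_thresholds():
    """0.05/211, 0.05/206 and 0.05/41 at their printed precision."""
    assert bonferroni_threshold(211) == pytest.approx(2.37e-4, rel=5e-3)
    assert bonferroni_threshold(206) == pytest.approx(2.43e-4, rel=5e-3)
    assert bonferroni_threshold(41) == pytest.approx(0.0012, rel=5e-2)
    assert bonferroni_threshold(1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_threshold(0)


def _rename(ds, trait_id, snp_prefix=None):
    records = ds.records
    if snp_prefix:
        records = records.copy()
        records["snp_id"] = snp_prefix + records["snp_id"]
    return SummaryDataset(trait_id, ds.trait_role, records)


def _small_config(**kw):
    defaults = dict(presso_sims=200, boot_reps=50, seed=3, missing_ld="independent",
                    methods=("ivw", "egger", "weighted_median"))
    defaults.update(kw)
    return ScreenConfig(**defaults)


def test_run_pair_noise_free_recovers_effect_and_flags_significant():
    """12 noise-free instruments at beta_causal = 0.17: IVW returns 0.17
    exactly and passes the forward family threshold."""
    sc = CausalScenario(m_snps=40, m_instruments=12, beta_causal=0.17,
                        gamma_sd=0.1, exact=True, seed=21)
    exposure, outcome, _ = simulate_pair(sc)
    ld = simulate_ld(sc)
    res = run_pair(exposure, outcome, ld, _small_config(), direction="forward")
    assert not res.skipped
    assert res.estimates["ivw"].beta == pytest.approx(0.17, rel=1e-10)
    assert res.significant
    counts = res.stage_counts
    stages = ["input", "p_threshold", "clumped", "f_filter", "harmonized"]
    values = [counts[s] for s in stages]
    assert values == sorted(values, reverse=True)


def test_run_pair_skips_gracefully_without_instruments():
    sc = CausalScenario(m_snps=20, m_instruments=2, gamma_sd=0.01, seed=22)
    exposure, outcome, _ = simulate_pair(sc)
    ld = simulate_ld(sc)
    res = run_pair(exposure, outcome, ld, _small_config(), direction="forward")
    assert res.skipped and "no instruments" in res.skip_reason


def test_run_pair_deterministic_given_seeds():
    sc = CausalScenario(m_snps=40, m_instruments=12, beta_causal=0.17,
                        gamma_sd=0.1, seed=23)
    exposure, outcome, _ = simulate_pair(sc)
    ld = simulate_ld(sc)
    cfg = _small_config()
    a = run_pair(exposure, outcome, ld, cfg)
    b = run_pair(exposure, outcome, ld, cfg)
    assert {k: v.beta for k, v in a.estimates.items()} == {
        k: v.beta for k, v in b.estimates.items()
    }
    assert {k: v.se for k, v in a.estimates.items()} == {
        k: v.se for k, v in b.estimates.items()
    }
    assert a.sensitivity.presso_global_pval == b.sensitivity.presso_global_pval


def test_screen_cardinality_and_planted_signal():
    """2 exposures x 3 outcomes; exactly one true causal pair is flagged."""
    causal_sc = CausalScenario(m_snps=40, m_instruments=12, beta_causal=0.25,
                               gamma_sd=0.1, seed=31)
    null_sc = dataclasses.replace(causal_sc, beta_causal=0.0)
    exp_c, out_c, _ = simulate_pair(causal_sc)
    ld = simulate_ld(causal_sc)
    exposures = [_rename(exp_c, "taxonA")]
    outcomes = [_rename(out_c, "brain1")]
    for i, seed in enumerate((32, 33)):
        e, o, _ = simulate_pair(dataclasses.replace(null_sc, seed=seed))
        if i == 0:
            # the null taxon has its own variants, disjoint from taxonA's
            exposures.append(_rename(e, "taxonB", snp_prefix="b_"))
        outcomes.append(_rename(o, f"brain{i + 2}"))
    result = run_screen(exposures, outcomes, ld, _small_config())
    fwd = result["forward"]
    assert fwd["exposure"].nunique() <= 2 and fwd["outcome"].nunique() <= 3
    flagged = fwd.loc[fwd["significant"] & (fwd["method"] == "ivw")]
    assert set(zip(flagged["exposure"], flagged["outcome"])) == {("taxonA", "brain1")}
    # every forward pair is either reported or logged as skipped
    reported = set(zip(fwd["exposure"], fwd["outcome"]))
    skipped = result["skipped"]
    fwd_skipped = skipped.loc[skipped["direction"] == "forward"] if len(skipped) else skipped
    n_skipped = len(fwd_skipped)
    assert len(reported) + n_skipped == 6


def test_reverse_direction_of_one_way_causal_pair_not_significant():
    """Forward causation only (study-scale effect): the outcome-as-exposure
    screen almost never finds reverse instruments, and when it does the
    pair is not flagged."""
    hits = 0
    for rep in range(20):
        sc = CausalScenario(m_snps=40, m_instruments=12, seed=41_000 + rep)
        exposure, outcome, _ = simulate_pair(sc)
        ld = simulate_ld(sc)
        res = run_pair(outcome, exposure, ld, _small_config(), direction="reverse")
        hits += (not res.skipped) and res.significant
    assert hits <= 1


def test_mediation_rows_only_for_triples_passing_all_gates():
    sc = CausalScenario(
        m_snps=40, m_instruments=12, gamma_sd=0.15,
        beta1=0.8, beta2=0.5, beta_direct=0.1, beta_causal=0.5,
        exact=True, seed=51,
    )
    exposure, mediator, outcome, _ = simulate_mediation_triple(sc)
    ld = simulate_ld(sc)
    # inert mediator: same variants and frequencies, null associations
    rng = np.random.default_rng(52)
    inert_records = mediator.records.copy()
    inert_records["beta"] = rng.normal(0.0, inert_records["se"])
    from scipy import stats as sps

    inert_records["pval"] = 2 * sps.norm.sf(
        np.abs(inert_records["beta"] / inert_records["se"])
    )
    inert = SummaryDataset("inert", "mediator", inert_records)
    result = run_screen(
        [_rename(exposure, "taxon")],
        [_rename(outcome, "brain")],
        ld,
        _small_config(),
        mediators=[_rename(mediator, "cytokine"), inert],
    )
    med = mediation_table(result["mediation"])
    assert set(med["mediator"]) == {"cytokine"}
    # the mediator's instruments overlap the exposure's, so step 2 absorbs
    # the direct path: slope b2 + direct/b1, hence proportion
    # 100*(b1*b2 + direct)/total = 100% in this noise-free fixture
    assert med["proportion_pct"].iloc[0] == pytest.approx(100.0, rel=0.05)
    reasons = result["mediation_screened_out"]
    assert all("p >=" in r for r in reasons.values())


def test_rerun_outputs_identical_tables():
    sc = CausalScenario(m_snps=40, m_instruments=12, beta_causal=0.2,
                        gamma_sd=0.1, seed=61)
    exposure, outcome, _ = simulate_pair(sc)
    ld = simulate_ld(sc)
    cfg = _small_config()
    r1 = run_screen([exposure], [outcome], ld, cfg)
    r2 = run_screen([exposure], [outcome], ld, cfg)
    assert r1["forward"].equals(r2["forward"])
    assert r1["reverse"].equals(r2["reverse"])
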