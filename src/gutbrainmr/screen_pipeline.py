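"""Orchestration of forward, reverse and mediation screens over many
trait pairs, with family-wise Bonferroni thresholds.

One ``run_pair`` call is the full per-pair pipeline: p-threshold ->
LD clumping -> instrument-strength filter -> harmonization -> all
estimators -> sensitivity battery -> significance flag.  The flag is
driven by the IVW p-value alone, against the Bonferroni threshold of the
direction's test family (forward: number of exposure taxa; reverse:
number of connectivity traits; mediator legs: number of cytokines).
``run_screen`` composes forward, reverse and mediation screens and
returns tables shaped like the consortium-screen reports, with
instrument-poor pairs recorded in a skip log rather than dropped
silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .harmonization import HarmonizedPairSet, harmonize
from .instruments import (
    CONNECTIVITY_PARAMS,
    MICROBIOTA_PARAMS,
    ClumpParams,
    select_instruments,
)
from .mediation import MediationGates, MediationResult, mediation_screen
from .mr_estimators import MREstimate, run_methods
from .sensitivity import SensitivityReport, full_report

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


def bonferroni_threshold(family_size: int, alpha: float = 0.05) -> float:
    """Family-wise significance cutoff alpha / family_size."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration for a full bidirectional + mediation screen."""

    forward_params: ClumpParams = MICROBIOTA_PARAMS
    reverse_params: ClumpParams = CONNECTIVITY_PARAMS
    mediator_params: ClumpParams = CONNECTIVITY_PARAMS
    methods: tuple[str, ...] = DEFAULT_METHODS
    f_min: float = 10.0
    alpha: float = 0.05
    n_forward: int = 211
    n_reverse: int = 206
    n_mediator: int = 41
    presso_sims: int = 1000
    boot_reps: int = 1000
    seed: int = 0
    missing_ld: str = "error"

    def __post_init__(self) -> None:
        for size in (self.n_forward, self.n_reverse, self.n_mediator):
            if size < 1:
                raise ValueError("Bonferroni family sizes must be >= 1")

    @property
    def forward_threshold(self) -> float:
        return bonferroni_threshold(self.n_forward, self.alpha)

    @property
    def reverse_threshold(self) -> float:
        return bonferroni_threshold(self.n_reverse, self.alpha)

    @property
    def mediator_threshold(self) -> float:
        return bonferroni_threshold(self.n_mediator, self.alpha)


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair in one direction."""

    exposure_id: str
    outcome_id: str
    direction: str  # forward | reverse
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: Optional[SensitivityReport] = None
    pairs: Optional[HarmonizedPairSet] = None
    significant: bool = False
    stage_counts: dict[str, int] = field(default_factory=dict)
    skip_reason: Optional[str] = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


def run_pair(
    exposure,
    outcome,
    ld,
    config: ScreenConfig,
    direction: str = "forward",
) -> PairResult:
    """Full single-pair pipeline; never raises on instrument-poor pairs.

    Stage record counts are monotone non-increasing from the raw
    exposure SNPs down to the harmonized pairs that feed the estimators.
    """
    params = config.forward_params if direction == "forward" else config.reverse_params
    threshold = (
        config.forward_threshold if direction == "forward" else config.reverse_threshold
    )
    result = PairResult(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id, direction=direction
    )
    selected, _, counts = select_instruments(
        exposure, ld, params, f_min=config.f_min, missing_ld=config.missing_ld
    )
    result.stage_counts = counts
    if len(selected) < 1:
        result.skip_reason = "no instruments survive selection"
        return result
    pairs = harmonize(selected, outcome)
    result.pairs = pairs
    result.stage_counts["harmonized"] = len(pairs)
    if len(pairs) < 1:
        result.skip_reason = "no harmonizable instrument SNPs"
        return result
    result.estimates = run_methods(
        pairs, methods=config.methods, boot_reps=config.boot_reps, seed=config.seed
    )
    result.sensitivity = full_report(
        pairs, n_sim=config.presso_sims, seed=config.seed
    )
    ivw_est = result.estimates.get("ivw")
    result.significant = ivw_est is not None and ivw_est.pval < threshold
    return result


def _estimates_row(result: PairResult, threshold: float) -> list[dict]:
    rows = []
    for name, est in result.estimates.items():
        rows.append(
            {
                "exposure": result.exposure_id,
                "outcome": result.outcome_id,
                "direction": result.direction,
                "method": name,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "significant": result.significant,
                "family_threshold": threshold,
            }
        )
    return rows


def run_screen(
    exposures: Sequence,
    outcomes: Sequence,
    ld,
    config: ScreenConfig = ScreenConfig(),
    mediators: Optional[Sequence] = None,
) -> dict[str, object]:
    """Forward, reverse and (optionally) mediation screens.

    Returns a dict with ``forward`` / ``reverse`` estimate tables,
    ``mediation`` results, ``skipped`` pair log, and the per-pair
    :class:`PairResult` objects for downstream inspection.  Supplied
    collection sizes override configured family sizes with a warning on
    mismatch.
    """
    config = _reconcile_family_sizes(config, exposures, outcomes, mediators)
    forward_rows: list[dict] = []
    reverse_rows: list[dict] = []
    skipped: list[dict] = []
    forward_results: dict[tuple[str, str], PairResult] = {}

    for exp in exposures:
        for out in outcomes:
            res = run_pair(exp, out, ld, config, direction="forward")
            forward_results[(exp.trait_id, out.trait_id)] = res
            if res.skipped:
                skipped.append(
                    {"exposure": exp.trait_id, "outcome": out.trait_id,
                     "direction": "forward", "reason": res.skip_reason}
                )
            else:
                forward_rows.extend(_estimates_row(res, config.forward_threshold))

    for out in outcomes:
        for exp in exposures:
            res = run_pair(out, exp, ld, config, direction="reverse")
            if res.skipped:
                skipped.append(
                    {"exposure": out.trait_id, "outcome": exp.trait_id,
                     "direction": "reverse", "reason": res.skip_reason}
                )
            else:
                reverse_rows.extend(_estimates_row(res, config.reverse_threshold))

    mediation_results: list[MediationResult] = []
    screened_out: dict = {}
    if mediators:
        step1: dict[tuple[str, str], MREstimate] = {}
        step2: dict[tuple[str, str], MREstimate] = {}
        totals: dict[tuple[str, str], MREstimate] = {}
        for (exp_id, out_id), res in forward_results.items():
            if "ivw" in res.estimates:
                totals[(exp_id, out_id)] = res.estimates["ivw"]
        for exp in exposures:
            for med in mediators:
                res = run_pair(exp, med, ld, config, direction="forward")
                if "ivw" in res.estimates:
                    step1[(exp.trait_id, med.trait_id)] = res.estimates["ivw"]
        med_config = replace(config, forward_params=config.mediator_params)
        for med in mediators:
            for out in outcomes:
                res = run_pair(med, out, ld, med_config, direction="forward")
                if "ivw" in res.estimates:
                    step2[(med.trait_id, out.trait_id)] = res.estimates["ivw"]
        gates = MediationGates(
            alpha=config.alpha,
            n_step1=config.n_forward,
            n_step2=config.n_mediator,
            n_total=config.n_forward,
        )
        # restrict to triples whose totals were actually estimated
        step1 = {k: v for k, v in step1.items()
                 if any((k[0], o.trait_id) in totals for o in outcomes)}
        mediation_results, screened_out = mediation_screen(step1, step2, totals, gates)

    return {
        "forward": pd.DataFrame(forward_rows),
        "reverse": pd.DataFrame(reverse_rows),
        "mediation": mediation_results,
        "mediation_screened_out": screened_out,
        "skipped": pd.DataFrame(skipped),
        "pair_results": forward_results,
        "config": config,
    }


def _reconcile_family_sizes(config, exposures, outcomes, mediators):
    updates = {}
    if len(exposures) != config.n_forward:
        logger.warning(
            "forward family size %d != supplied %d exposures; using supplied",
            config.n_forward, len(exposures),
        )
        updates["n_forward"] = len(exposures)
    if len(outcomes) != config.n_reverse:
        logger.warning(
            "reverse family size %d != supplied %d outcomes; using supplied",
            config.n_reverse, len(outcomes),
        )
        updates["n_reverse"] = len(outcomes)
    if mediators is not None and len(mediators) != config.n_mediator:
        logger.warning(
            "mediator family size %d != supplied %d mediators; using supplied",
            config.n_mediator, len(mediators),
        )
        updates["n_mediator"] = len(mediators)
    return replace(config, **updates) if updates else config


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Mediation results as a report-shaped table."""
    return pd.DataFrame(
        [
            {
                "exposure": r.exposure_id,
                "mediator": r.mediator_id,
                "outcome": r.outcome_id,
                "total_effect": r.beta_total,
                "direct_a": r.beta1,
                "direct_b": r.beta2,
                "mediation_effect": r.mediation_effect,
                "mediation_se": r.mediation_se,
                "mediation_ci_low": r.mediation_ci[0],
                "mediation_ci_high": r.mediation_ci[1],
                "proportion_pct": r.proportion,
                "proportion_ci_low": r.proportion_ci[0],
                "proportion_ci_high": r.proportion_ci[1],
            }
            for r in results
        ]
    )
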