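"""Two-step MR mediation: product-of-coefficients decomposition with
delta-method uncertainty.

Step 1 estimates the exposure -> mediator effect (beta1), step 2 the
mediator -> outcome effect (beta2), and the total exposure -> outcome
effect (beta_total) comes from the primary IVW screen.  The indirect
(mediation) effect is the product beta1 * beta2; its first-order
delta-method variance is beta1^2 se2^2 + beta2^2 se1^2, with an exact
product-variance mode (adds se1^2 se2^2) available by flag.  The
mediated proportion is 100 * beta1 * beta2 / beta_total; its interval is
the mediation-effect interval scaled by 1/beta_total with beta_total
treated as fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mr_estimators import MREstimate, Z_95

logger = logging.getLogger(__name__)


class DegenerateTotalEffectError(ZeroDivisionError):
    """Mediated proportion undefined because the total effect is zero."""


@dataclass(frozen=True)
class MediationResult:
    """Product-method decomposition for one exposure-mediator-outcome triple."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_total: float
    se_total: float
    mediation_effect: float
    mediation_se: float
    mediation_ci: tuple[float, float]
    proportion: float  # percent of the total effect
    proportion_ci: tuple[float, float]


def delta_se(beta1: float, se1: float, beta2: float, se2: float, exact: bool = False) -> float:
    """Delta-method SE of the product beta1 * beta2."""
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if exact:
        var += se1**2 * se2**2
    return float(np.sqrt(var))


def two_step_mediation(
    step1: MREstimate,
    step2: MREstimate,
    total: MREstimate,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    exact_variance: bool = False,
) -> MediationResult:
    """Combine the three IVW estimates of a mediation triple.

    Raises :class:`DegenerateTotalEffectError` when the total effect is
    zero.  Proportions outside [0, 100]% (inconsistent mediation, where
    direct and indirect paths oppose) are reported with a warning rather
    than clipped.
    """
    if total.beta == 0:
        raise DegenerateTotalEffectError("total effect is 0; mediated proportion undefined")
    effect = step1.beta * step2.beta
    se = delta_se(step1.beta, step1.se, step2.beta, step2.se, exact=exact_variance)
    ci = (effect - Z_95 * se, effect + Z_95 * se)
    proportion = 100.0 * effect / total.beta
    scaled = (100.0 * ci[0] / total.beta, 100.0 * ci[1] / total.beta)
    proportion_ci = (min(scaled), max(scaled))  # order-normalized for negative totals
    if not 0.0 <= proportion <= 100.0:
        logger.warning(
            "%s -> %s -> %s: mediated proportion %.1f%% outside [0, 100]%% "
            "(inconsistent mediation)",
            exposure_id, mediator_id, outcome_id, proportion,
        )
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=step1.beta,
        se1=step1.se,
        beta2=step2.beta,
        se2=step2.se,
        beta_total=total.beta,
        se_total=total.se,
        mediation_effect=effect,
        mediation_se=se,
        mediation_ci=ci,
        proportion=proportion,
        proportion_ci=proportion_ci,
    )


@dataclass(frozen=True)
class MediationGates:
    """Bonferroni gates for the three legs of the mediation screen."""

    alpha: float = 0.05
    n_step1: int = 211  # exposure family (taxa)
    n_step2: int = 41  # mediator family (cytokines)
    n_total: int = 211  # forward-screen family

    @property
    def step1_threshold(self) -> float:
        return self.alpha / self.n_step1

    @property
    def step2_threshold(self) -> float:
        return self.alpha / self.n_step2

    @property
    def total_threshold(self) -> float:
        return self.alpha / self.n_total


def mediation_screen(
    step1_estimates: dict[tuple[str, str], MREstimate],
    step2_estimates: dict[tuple[str, str], MREstimate],
    total_estimates: dict[tuple[str, str], MREstimate],
    gates: MediationGates = MediationGates(),
    exact_variance: bool = False,
) -> tuple[list[MediationResult], dict[tuple[str, str, str], str]]:
    """Screen every assembled (exposure, mediator, outcome) triple.

    ``step1_estimates`` is keyed by (exposure, mediator), ``step2`` by
    (mediator, outcome), ``total`` by (exposure, outcome).  A triple is
    emitted only when step 1 passes its Bonferroni family, step 2 passes
    its family, and the total effect passes the forward family; triples
    failing a gate are returned in the screened-out map with the failing
    gate named.  A candidate triple whose total estimate is missing is an
    orphan and raises ``KeyError``.
    """
    results: list[MediationResult] = []
    screened_out: dict[tuple[str, str, str], str] = {}
    for (exp_id, med_id), est1 in step1_estimates.items():
        for (med_id2, out_id), est2 in step2_estimates.items():
            if med_id2 != med_id:
                continue
            key = (exp_id, med_id, out_id)
            if (exp_id, out_id) not in total_estimates:
                raise KeyError(
                    f"orphan mediation triple {key}: no total estimate for "
                    f"({exp_id}, {out_id})"
                )
            total = total_estimates[(exp_id, out_id)]
            if total.pval >= gates.total_threshold:
                screened_out[key] = (
                    f"total p >= {gates.alpha}/{gates.n_total}"
                )
                continue
            if est1.pval >= gates.step1_threshold:
                screened_out[key] = f"step1 p >= {gates.alpha}/{gates.n_step1}"
                continue
            if est2.pval >= gates.step2_threshold:
                screened_out[key] = f"step2 p >= {gates.alpha}/{gates.n_step2}"
                continue
            results.append(
                two_step_mediation(
                    est1, est2, total,
                    exposure_id=exp_id, mediator_id=med_id, outcome_id=out_id,
                    exact_variance=exact_variance,
                )
            )
    return results, screened_out
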