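"""Sensitivity battery: heterogeneity, pleiotropy, outlier and influence
diagnostics for a harmonized exposure-outcome pair.

* Cochran's Q over the per-SNP ratios (chi-square, k-1 df).
* MR-Egger intercept t-test for directional pleiotropy.
* MR-PRESSO: a simulation-based residual-sum-of-squares global
  heterogeneity test, a per-SNP outlier test (Bonferroni over k), and a
  distortion test comparing the estimate before and after outlier
  removal against random same-size removals.
* Leave-one-out IVW to expose single-SNP leverage.
* Plot-ready scatter and funnel tables (no figure rendering here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .harmonization import HarmonizedPairSet
from .mr_estimators import (
    InsufficientInstrumentsError,
    MREstimate,
    cochran_q_components,
    egger,
    ivw,
)


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome pair."""

    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    presso_global_pval: Optional[float] = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_raw_beta: Optional[float] = None
    presso_corrected_beta: Optional[float] = None
    presso_distortion_pval: Optional[float] = None
    loo_table: Optional[pd.DataFrame] = None


def cochran_q(pairs: HarmonizedPairSet) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP ratios around the fixed-effect IVW estimate.

    Q = sum_j w_j (ratio_j - beta_IVW)^2 with first-order IVW weights;
    p is the upper chi-square tail on k - 1 degrees of freedom.
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q requires >= 2 instruments, got {k}")
    q, _ = cochran_q_components(pairs)
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, max(p, np.finfo(float).tiny)


def egger_intercept_test(pairs: HarmonizedPairSet) -> tuple[float, float, float]:
    """Directional-pleiotropy test: (intercept, se, t-test p-value)."""
    _, intercept = egger(pairs)
    return intercept.beta, intercept.se, intercept.pval


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (weighted regression through the origin)."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(
    pairs: HarmonizedPairSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """MR-PRESSO global, outlier and distortion tests.

    Global test: the observed residual sum of squares uses leave-one-out
    IVW slopes, RSS_obs = sum_j w_j (beta_out_j - slope_{-j} beta_exp_j)^2
    with w_j = 1/se_out_j^2.  The null distribution is built from n_sim
    parametric draws beta_out* ~ N(slope_{-j} beta_exp_j, se_out_j^2),
    beta_exp* ~ N(beta_exp_j, se_exp_j^2); the Monte-Carlo p-value is
    (1 + #{RSS* >= RSS_obs}) / (1 + n_sim), never zero.

    Outlier test: each SNP's observed weighted squared residual is
    compared with its own simulated distribution; empirical p-values are
    Bonferroni-corrected over k and flagged below ``outlier_alpha``.

    Distortion test: the relative change of the IVW slope after removing
    the flagged outliers is compared with the distribution of the same
    change after removing random subsets of equal size.  Fields are None
    when no outliers are flagged.
    """
    k = len(pairs)
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 instruments, got {k}")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = pairs.arrays()
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - loo * bx) ** 2
    rss_obs = float(np.sum(res_obs))

    # parametric null: (n_sim, k) draws around the leave-one-out predictions
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, k))
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim * bx_sim)
    res_sim = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = np.sum(res_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    p_outlier = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (1 + n_sim)
    p_outlier_bonf = np.minimum(p_outlier * k, 1.0)
    snp_ids = pairs.snp_ids
    outliers = [snp_ids[j] for j in range(k) if p_outlier_bonf[j] < outlier_alpha]

    report = SensitivityReport(
        presso_global_pval=global_p,
        presso_outliers=outliers,
        presso_raw_beta=ivw(pairs).beta,
    )
    if outliers and len(outliers) < k - 1:
        corrected = ivw(pairs.drop_snps(outliers))
        report.presso_corrected_beta = corrected.beta
        d_obs = (corrected.beta - report.presso_raw_beta) / abs(report.presso_raw_beta)
        n_out = len(outliers)
        d_null = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            keep = np.ones(k, dtype=bool)
            keep[drop] = False
            slope = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(w[keep] * bx[keep] ** 2)
            d_null[i] = (slope - report.presso_raw_beta) / abs(report.presso_raw_beta)
        report.presso_distortion_pval = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_sim)
        )
    return report


def leave_one_out(pairs: HarmonizedPairSet) -> pd.DataFrame:
    """IVW re-estimated with each SNP left out in turn.

    Columns: left_out_snp, beta, se, pval, n_snp.
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(f"leave-one-out requires >= 2 instruments, got {k}")
    rows = []
    for p in pairs.pairs:
        est = ivw(pairs.drop_snps({p.snp_id}))
        rows.append(
            {
                "left_out_snp": p.snp_id,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "n_snp": est.n_snp,
            }
        )
    return pd.DataFrame(rows)


def full_report(
    pairs: HarmonizedPairSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """Every diagnostic the instrument count permits, in one report."""
    report = SensitivityReport()
    k = len(pairs)
    if k >= 2:
        report.q_stat, report.q_df, report.q_pval = cochran_q(pairs)
        report.loo_table = leave_one_out(pairs)
    if k >= 3:
        (
            report.egger_intercept,
            report.egger_intercept_se,
            report.egger_intercept_pval,
        ) = egger_intercept_test(pairs)
    if k >= 4:
        presso = mr_presso(pairs, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
        report.presso_global_pval = presso.presso_global_pval
        report.presso_outliers = presso.presso_outliers
        report.presso_raw_beta = presso.presso_raw_beta
        report.presso_corrected_beta = presso.presso_corrected_beta
        report.presso_distortion_pval = presso.presso_distortion_pval
    return report


def diagnostic_tables(
    pairs: HarmonizedPairSet, estimates: dict[str, MREstimate]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready scatter and funnel tables.

    scatter: per-SNP (beta_exp, se_exp, beta_out, se_out) plus one column
    of fitted slope (and intercept for Egger) per method.
    funnel: per-SNP Wald ratio against instrument precision 1/ratio_se,
    with each method's estimate as a vertical reference.
    """
    bx, sx, by, sy = pairs.arrays()
    scatter = pd.DataFrame(
        {"snp_id": pairs.snp_ids, "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}
    )
    ratios = by / bx
    precision = np.abs(bx) / sy
    funnel = pd.DataFrame({"snp_id": pairs.snp_ids, "ratio": ratios, "precision": precision})
    for name, est in estimates.items():
        scatter[f"slope_{name}"] = est.beta
        funnel[f"vertical_{name}"] = est.beta
    return scatter, funnel
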