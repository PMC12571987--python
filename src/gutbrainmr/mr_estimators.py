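"""Causal-effect estimators for two-sample MR on harmonized pairs.

Implements the Wald ratio, inverse-variance weighted (IVW) estimator,
MR-Egger regression (slope + pleiotropy intercept), the weighted median,
and kernel-mode estimators (simple and weighted).  Every estimator
returns the effect on the log scale together with exp(beta) ("OR" in the
reporting convention of consortium MR screens, retained even for
continuous traits) and a 95% Wald confidence interval.

Conventions, chosen to mirror the dominant two-sample MR toolkit:

* IVW uses multiplicative random effects — the fixed-effect SE is
  inflated by max(1, sqrt(Q / (k - 1))) when k >= 2; a fixed-effect
  variant is available by flag.
* Per-SNP weights are first-order: w_j = beta_exp_j^2 / se_out_j^2,
  i.e. exposure-side sampling error is ignored.
* Egger regression reorients each pair so beta_exp >= 0 before fitting
  (the intercept is orientation-dependent) and uses t-tests on k - 2
  degrees of freedom with residual variance factor max(1, estimated).
* Median/mode standard errors come from a parametric bootstrap with a
  mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonization import HarmonizedPair, HarmonizedPairSet

Z_95 = 1.96


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate for an exposure-outcome pair."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z_95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z_95 * self.se))

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_snp": self.n_snp,
        }


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(max(p, np.finfo(float).tiny))


def _ratios_and_weights(pairs: HarmonizedPairSet):
    bx, sx, by, sy = pairs.arrays()
    if np.any(bx == 0):
        bad = [p.snp_id for p in pairs.pairs if p.beta_exp == 0]
        raise ZeroDivisionError(f"zero exposure beta for {bad[:5]}")
    ratios = by / bx
    ratio_se = sy / np.abs(bx)  # first-order
    weights = bx**2 / sy**2  # = 1 / ratio_se^2
    return ratios, ratio_se, weights


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp with first-order SE."""
    if pair.beta_exp == 0:
        raise ZeroDivisionError(f"{pair.snp_id}: exposure beta is 0, ratio undefined")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MREstimate("wald_ratio", float(beta), float(se), _norm_p(beta, se), 1)


def cochran_q_components(pairs: HarmonizedPairSet) -> tuple[float, float]:
    """(Q, fixed-effect IVW beta) with first-order weights."""
    ratios, _, weights = _ratios_and_weights(pairs)
    beta_fixed = float(np.sum(weights * ratios) / np.sum(weights))
    q = float(np.sum(weights * (ratios - beta_fixed) ** 2))
    return q, beta_fixed


def ivw(pairs: HarmonizedPairSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance weighted estimate over all harmonized pairs.

    Equivalent to weighted regression of beta_out on beta_exp through the
    origin with weights 1/se_out².  With ``random_effects`` (default) the
    fixed-effect SE is scaled by max(1, sqrt(Q/(k-1))) for k >= 2.
    """
    k = len(pairs)
    if k == 0:
        raise InsufficientInstrumentsError("IVW requires at least one pair")
    if k == 1:
        est = wald_ratio(pairs.pairs[0])
        return MREstimate("ivw", est.beta, est.se, est.pval, 1)
    ratios, _, weights = _ratios_and_weights(pairs)
    q, beta = cochran_q_components(pairs)
    se = float(1.0 / np.sqrt(np.sum(weights)))
    if random_effects:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MREstimate("ivw", beta, se, _norm_p(beta, se), k)


def egger(pairs: HarmonizedPairSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression with a free intercept.

    Returns (slope, intercept) estimates; the intercept's t-test is the
    directional-pleiotropy test.  Pairs are reoriented to beta_exp >= 0,
    weights are 1/se_out², and the residual variance factor is bounded
    below by 1 so SEs are never deflated below the fixed-effect level.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {k}")
    bx, sx, by, sy = pairs.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2
    # closed-form WLS with intercept
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise InsufficientInstrumentsError("MR-Egger degenerate: no spread in beta_exp")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    df = k - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2) / df))
    se_slope = float(np.sqrt(sigma2 / sxx))
    se_int = float(np.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx)))
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df)) if se_slope > 0 else 1.0
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df)) if se_int > 0 else 1.0
    return (
        MREstimate("egger_slope", slope, se_slope, max(p_slope, np.finfo(float).tiny), k),
        MREstimate("egger_intercept", intercept, se_int, max(p_int, np.finfo(float).tiny), k),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weight crosses 0.5."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(
    pairs: HarmonizedPairSet, boot_reps: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP ratios; consistent when valid instruments
    carry at least half the weight.

    The SE is a parametric bootstrap: each ratio is resampled from
    N(ratio_j, ratio_se_j²) with fixed weights, the weighted median is
    recomputed, and the SD over ``boot_reps`` replicates is reported.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 instruments, got {k}")
    ratios, ratio_se, weights = _ratios_and_weights(pairs)
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_se, size=(boot_reps, k))
    boots = np.array([_weighted_median(d, weights) for d in draws])
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), k)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of the weighted normal-kernel density of the ratios.

    Bandwidth is phi times the modified Silverman rule
    0.9 * min(sd, mad/1.4826... scaled MAD) * k^(-1/5) on the ratios.
    """
    k = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad if mad > 0 else sd) * k ** (-1.0 / 5.0)
    h = phi * s
    if h == 0 or not np.isfinite(h):  # all ratios identical
        return float(ratios[0])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    pairs: HarmonizedPairSet,
    weighted: bool = True,
    phi: float = 1.0,
    boot_reps: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: the peak of the smoothed ratio density.

    ``weighted`` weights each ratio by its inverse variance (weighted
    mode); otherwise all ratios count equally (simple mode).  SE by the
    same parametric bootstrap as the weighted median.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(f"mode estimator requires >= 3 instruments, got {k}")
    ratios, ratio_se, ivw_weights = _ratios_and_weights(pairs)
    weights = ivw_weights if weighted else np.ones(k)
    weights = weights / np.sum(weights)
    beta = _mode_point(ratios, weights, phi)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ratio_se, size=(boot_reps, k))
    boots = np.array([_mode_point(d, weights, phi) for d in draws])
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, _norm_p(beta, se), k)


#: method name -> callable returning one or two MREstimates
def run_methods(
    pairs: HarmonizedPairSet,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"),
    boot_reps: int = 1000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """Run every requested estimator that has enough instruments.

    Methods whose instrument-count preconditions fail are silently
    omitted from the result dict (the caller sees which ran).
    """
    out: dict[str, MREstimate] = {}
    k = len(pairs)
    for method in methods:
        try:
            if method == "ivw":
                out["ivw"] = ivw(pairs)
            elif method == "egger":
                slope, intercept = egger(pairs)
                out["egger_slope"] = slope
                out["egger_intercept"] = intercept
            elif method == "weighted_median":
                out["weighted_median"] = weighted_median(pairs, boot_reps=boot_reps, seed=seed)
            elif method == "simple_mode":
                out["simple_mode"] = mode_estimate(
                    pairs, weighted=False, boot_reps=boot_reps, seed=seed
                )
            elif method == "weighted_mode":
                out["weighted_mode"] = mode_estimate(
                    pairs, weighted=True, boot_reps=boot_reps, seed=seed
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        except InsufficientInstrumentsError:
            continue
    return out
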