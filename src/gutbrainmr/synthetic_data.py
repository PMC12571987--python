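"""Simulation of two-sample (and three-trait mediation) GWAS summary statistics.

Summary statistics are simulated directly at the summary level: for each
SNP j with minor-allele frequency f_j, the true per-allele instrument
effect on the standardized exposure is gamma_j ~ N(0, gamma_sd^2) (zero
for non-instruments), a direct pleiotropic effect on the outcome is
alpha_j ~ N(pleio_mean, pleio_sd^2), and the true outcome effect is

    Gamma_j = beta_causal * gamma_j + alpha_j          (two traits)
    delta_j = beta1 * gamma_j                          (mediator)
    Gamma_j = beta_direct * gamma_j + beta2 * delta_j + alpha_j   (triple)

Estimated betas add independent N(0, se^2) measurement noise with the
standardized-trait standard error se = 1 / sqrt(2 f (1 - f) n), and
p-values come from the two-sided normal Wald test.  This is the standard
generative design for benchmarking two-sample MR estimators; it skips
individual-level genotypes entirely, which is sufficient for every
estimator in this package and orders of magnitude faster.

The default scenario mirrors the consortium-scale studies this pipeline
targets: an exposure GWAS of 18,340, an outcome GWAS of 26,333 and a
mediator GWAS of 8,293 participants, with about a dozen genuine
instruments per exposure trait.

All randomness flows from the single scenario seed through
``numpy.random.SeedSequence`` spawning, so each output component (allele
assignment, true effects, per-trait noise, dialect corruption) draws from
an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import COLUMNS, LDMatrix, SummaryDataset

_P_FLOOR = np.finfo(float).tiny

#: allele pairs that are unambiguous under strand flips
_NON_PALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScenarioError(ValueError):
    """The simulation scenario violates its invariants."""


@dataclass(frozen=True)
class CausalScenario:
    """Ground-truth configuration for one synthetic two-sample MR study.

    beta_causal is the total exposure->outcome effect.  When mediation is
    enabled (beta1/beta2 nonzero) the identity
    ``beta_causal = beta_direct + beta1 * beta2`` is enforced; leave
    beta_direct as None to have it derived from the other three.
    """

    m_snps: int = 200
    m_instruments: int = 12
    beta_causal: float = 0.15
    beta1: float = 0.0
    beta2: float = 0.0
    beta_direct: Optional[float] = None
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    gamma_sd: float = 0.06
    n_exposure: int = 18340
    n_outcome: int = 26333
    n_mediator: int = 8293
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: Optional[Sequence[tuple[int, float]]] = None
    dialect_corruption: float = 0.0
    exact: bool = False  # betas equal truth (no measurement noise)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.m_instruments <= self.m_snps):
            raise ScenarioError("need 0 < m_instruments <= m_snps")
        if self.pleio_sd < 0:
            raise ScenarioError("pleio_sd must be >= 0")
        if self.gamma_sd <= 0:
            raise ScenarioError("gamma_sd must be > 0")
        for n in (self.n_exposure, self.n_outcome, self.n_mediator):
            if n < 2:
                raise ScenarioError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ScenarioError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.dialect_corruption <= 1:
            raise ScenarioError("dialect_corruption must be in [0, 1]")
        if self.beta_direct is not None:
            implied = self.beta_direct + self.beta1 * self.beta2
            if abs(implied - self.beta_causal) > 1e-9:
                raise ScenarioError(
                    "beta_causal must equal beta_direct + beta1*beta2 "
                    f"(got {self.beta_causal} vs {implied})"
                )

    @property
    def direct_effect(self) -> float:
        """Exposure->outcome effect not through the mediator."""
        if self.beta_direct is not None:
            return self.beta_direct
        return self.beta_causal - self.beta1 * self.beta2

    @property
    def true_mediated_proportion(self) -> float:
        """beta1*beta2 / beta_total, as a percentage."""
        if self.beta_causal == 0:
            raise ScenarioError("mediated proportion undefined: total effect is 0")
        return 100.0 * self.beta1 * self.beta2 / self.beta_causal


@dataclass
class TruthManifest:
    """Per-SNP ground truth for one simulated scenario."""

    scenario: CausalScenario
    table: pd.DataFrame  # snp_id, is_instrument, gamma, alpha, delta, Gamma, maf, corruption

    def __post_init__(self) -> None:
        if self.table["snp_id"].duplicated().any():
            raise ScenarioError("truth manifest must cover each SNP exactly once")

    @property
    def corrupted(self) -> dict[str, str]:
        sub = self.table.loc[self.table["corruption"] != "none"]
        return dict(zip(sub["snp_id"], sub["corruption"]))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def wald_se(maf: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Standard error of a per-allele beta on a standardized trait."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * np.asarray(n, dtype=float))


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _P_FLOOR)


def _assemble(
    trait_id: str,
    trait_role: str,
    snp_ids: list[str],
    ea: np.ndarray,
    oa: np.ndarray,
    eaf: np.ndarray,
    true_beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
    exact: bool,
) -> SummaryDataset:
    se = wald_se(eaf, n)
    if exact:
        beta = true_beta.copy()
    else:
        beta = true_beta + rng.normal(0.0, se)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _wald_p(beta, se),
            "n": n,
        },
        columns=list(COLUMNS),
    )
    return SummaryDataset(trait_id=trait_id, trait_role=trait_role, records=df)


def _draw_variants(scenario: CausalScenario):
    rng_var, rng_truth, rng_exp, rng_out, rng_med, rng_cor = _rngs(scenario.seed, 6)
    m = scenario.m_snps
    snp_ids = [f"snp{i:05d}" for i in range(m)]
    pair_idx = rng_var.integers(0, len(_NON_PALINDROMIC_PAIRS), size=m)
    ea = np.array([_NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx])
    lo, hi = scenario.maf_range
    maf = rng_var.uniform(lo, hi, size=m)
    is_instr = np.zeros(m, dtype=bool)
    is_instr[: scenario.m_instruments] = True
    gamma = np.where(is_instr, rng_truth.normal(0.0, scenario.gamma_sd, size=m), 0.0)
    if scenario.pleio_sd > 0 or scenario.pleio_mean != 0:
        # directional pleiotropy is directional relative to the
        # exposure-increasing allele: orient alpha with sign(gamma) so a
        # nonzero pleio_mean shifts every instrument the same way after
        # the conventional beta_exp >= 0 reorientation (allele coding is
        # otherwise arbitrary and a constant shift would cancel out)
        alpha_raw = rng_truth.normal(scenario.pleio_mean, scenario.pleio_sd, size=m)
        alpha = np.where(gamma != 0, np.sign(gamma), 1.0) * alpha_raw
    else:
        alpha = np.zeros(m)
    return snp_ids, ea, oa, maf, is_instr, gamma, alpha, (rng_exp, rng_out, rng_med, rng_cor)


def simulate_pair(
    scenario: CausalScenario,
) -> tuple[SummaryDataset, SummaryDataset, TruthManifest]:
    """Simulate exposure and outcome summary statistics with known truth."""
    snp_ids, ea, oa, maf, is_instr, gamma, alpha, (rng_exp, rng_out, _, _) = _draw_variants(
        scenario
    )
    Gamma = scenario.beta_causal * gamma + alpha
    exposure = _assemble(
        "synthetic_exposure", "exposure", snp_ids, ea, oa, maf, gamma,
        scenario.n_exposure, rng_exp, scenario.exact,
    )
    outcome = _assemble(
        "synthetic_outcome", "outcome", snp_ids, ea, oa, maf, Gamma,
        scenario.n_outcome, rng_out, scenario.exact,
    )
    truth = TruthManifest(
        scenario=scenario,
        table=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "is_instrument": is_instr,
                "gamma": gamma,
                "alpha": alpha,
                "delta": 0.0,
                "Gamma": Gamma,
                "maf": maf,
                "corruption": "none",
            }
        ),
    )
    return exposure, outcome, truth


def simulate_mediation_triple(
    scenario: CausalScenario,
) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset, TruthManifest]:
    """Simulate exposure, mediator and outcome statistics for two-step MR.

    The implied true mediated proportion is beta1*beta2 / beta_causal.
    """
    if scenario.beta_causal == 0:
        raise ScenarioError(
            "degenerate mediation scenario: total effect beta_direct + beta1*beta2 is 0"
        )
    snp_ids, ea, oa, maf, is_instr, gamma, alpha, (rng_exp, rng_out, rng_med, _) = (
        _draw_variants(scenario)
    )
    delta = scenario.beta1 * gamma
    Gamma = scenario.direct_effect * gamma + scenario.beta2 * delta + alpha
    exposure = _assemble(
        "synthetic_exposure", "exposure", snp_ids, ea, oa, maf, gamma,
        scenario.n_exposure, rng_exp, scenario.exact,
    )
    mediator = _assemble(
        "synthetic_mediator", "mediator", snp_ids, ea, oa, maf, delta,
        scenario.n_mediator, rng_med, scenario.exact,
    )
    outcome = _assemble(
        "synthetic_outcome", "outcome", snp_ids, ea, oa, maf, Gamma,
        scenario.n_outcome, rng_out, scenario.exact,
    )
    truth = TruthManifest(
        scenario=scenario,
        table=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "is_instrument": is_instr,
                "gamma": gamma,
                "alpha": alpha,
                "delta": delta,
                "Gamma": Gamma,
                "maf": maf,
                "corruption": "none",
            }
        ),
    )
    return exposure, mediator, outcome, truth


_CORRUPTION_KINDS = ("allele_swap", "strand_flip", "palindromic")


def corrupt_dialect(
    dataset: SummaryDataset, truth: TruthManifest
) -> tuple[SummaryDataset, TruthManifest]:
    """Re-emit ``dataset`` in a corrupted allele dialect.

    A ``dialect_corruption`` fraction of records is rewritten as one of:
    effect/other alleles swapped (beta negated, eaf complemented), both
    alleles strand-complemented (statistics unchanged), or the allele
    pair replaced by a palindromic A/T or C/G pair (unresolvable, so it
    must be dropped at harmonization).  The returned manifest records
    which SNPs were corrupted and how.
    """
    scenario = truth.scenario
    frac = scenario.dialect_corruption
    df = dataset.records.copy()
    table = truth.table.copy()
    if frac > 0:
        rng = _rngs(scenario.seed, 6)[5]
        m = len(df)
        n_corrupt = int(round(frac * m))
        chosen = rng.choice(m, size=n_corrupt, replace=False)
        kinds = rng.integers(0, len(_CORRUPTION_KINDS), size=n_corrupt)
        corruption = table["corruption"].to_numpy(dtype=object)
        for i, kind_idx in zip(chosen, kinds):
            kind = _CORRUPTION_KINDS[kind_idx]
            corruption[i] = kind
            if kind == "allele_swap":
                ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
                df.at[i, "effect_allele"], df.at[i, "other_allele"] = oa, ea
                df.at[i, "beta"] = -df.at[i, "beta"]
                df.at[i, "eaf"] = 1.0 - df.at[i, "eaf"]
            elif kind == "strand_flip":
                df.at[i, "effect_allele"] = _COMPLEMENT[df.at[i, "effect_allele"]]
                df.at[i, "other_allele"] = _COMPLEMENT[df.at[i, "other_allele"]]
            else:  # palindromic replacement
                ea, oa = _PALINDROMIC_PAIRS[rng.integers(0, len(_PALINDROMIC_PAIRS))]
                df.at[i, "effect_allele"], df.at[i, "other_allele"] = ea, oa
        table["corruption"] = corruption
    corrupted = SummaryDataset(dataset.trait_id, dataset.trait_role, df)
    return corrupted, TruthManifest(scenario=scenario, table=table)


def simulate_ld(scenario: CausalScenario) -> LDMatrix:
    """Block-diagonal LD fixture for clumping tests.

    Each (size, r2) block is internally exchangeable with the stated r²
    and independent of everything else; block members sit 10 kb apart so
    every block fits inside one clumping window, and consecutive blocks
    are separated by 50,000 kb — beyond any window used here.  SNPs not
    covered by a block are singletons.
    """
    m = scenario.m_snps
    snp_ids = [f"snp{i:05d}" for i in range(m)]
    r2 = np.eye(m)
    positions = np.zeros(m)
    blocks = list(scenario.ld_blocks or [])
    i = 0
    block_origin = 0.0
    for size, block_r2 in blocks:
        if i + size > m:
            raise ScenarioError("ld_blocks cover more SNPs than m_snps")
        sl = slice(i, i + size)
        r2[sl, sl] = block_r2
        np.fill_diagonal(r2[sl, sl], 1.0)
        positions[sl] = block_origin + 10.0 * np.arange(size)
        block_origin += 50_000.0
        i += size
    # remaining SNPs: independent singletons, each in its own far-away window
    for j in range(i, m):
        positions[j] = block_origin
        block_origin += 50_000.0
    return LDMatrix(snp_ids=snp_ids, r2=r2, positions_kb=positions)
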