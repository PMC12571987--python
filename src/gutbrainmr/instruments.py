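"""Instrument selection: p-value thresholding, greedy LD clumping, and
instrument-strength (R²/F) screening.

The selection conventions follow standard microbiome-MR practice: a
relaxed exposure threshold (p < 1e-5, clumping r² = 0.1 within 500 kb)
for highly polygenic microbial taxa, a stricter one (p < 5e-6,
r² = 0.01 within 10,000 kb) for brain-connectivity and cytokine traits,
and exclusion of weak instruments with F < 10.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .sumstats_io import LDMatrix, SummaryDataset, SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpParams:
    """Greedy clumping configuration.

    p_threshold: instrument significance cutoff (strict <).
    r2_max: SNPs with r² above this to a better index SNP are discarded.
    window_kb: physical window within which r² pruning applies.
    """

    p_threshold: float = 1e-5
    r2_max: float = 0.1
    window_kb: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")


#: defaults per trait family (exposure = microbiota; outcome/mediator = imaging & cytokines)
MICROBIOTA_PARAMS = ClumpParams(p_threshold=1e-5, r2_max=0.1, window_kb=500.0)
CONNECTIVITY_PARAMS = ClumpParams(p_threshold=5e-6, r2_max=0.01, window_kb=10_000.0)
CYTOKINE_PARAMS = CONNECTIVITY_PARAMS


@dataclass(frozen=True)
class InstrumentRecord:
    """A selected instrument with its variance explained and F statistic."""

    record: SummaryStatRecord
    r2_explained: float
    f_stat: float


def threshold_by_p(dataset: SummaryDataset, p_threshold: float) -> SummaryDataset:
    """Retain records with pval strictly below ``p_threshold``; order preserved."""
    keep = dataset.records["pval"] < p_threshold
    out = SummaryDataset(dataset.trait_id, dataset.trait_role, dataset.records.loc[keep])
    if len(out) == 0:
        logger.info("%s: no records pass p < %.3g", dataset.trait_id, p_threshold)
    return out


def clump(
    dataset: SummaryDataset,
    ld: LDMatrix,
    params: ClumpParams,
    missing_ld: str = "error",
) -> SummaryDataset:
    """Greedy LD clumping.

    Repeatedly take the smallest-p unassigned SNP as an index SNP and
    discard unassigned SNPs with r² > r2_max to it that lie within
    window_kb of it; iterate until every SNP is assigned.  Index SNPs are
    returned sorted by p-value, ties broken lexicographically by snp_id.

    ``missing_ld`` controls SNPs absent from the LD matrix: ``"error"``
    (default) raises, ``"independent"`` keeps them as their own index
    SNPs with a warning.
    """
    if missing_ld not in ("error", "independent"):
        raise ValueError("missing_ld must be 'error' or 'independent'")
    df = dataset.records
    absent = [s for s in df["snp_id"] if s not in ld]
    if absent:
        if missing_ld == "error":
            raise KeyError(f"SNPs missing from LD matrix: {absent[:5]}")
        logger.warning("%d SNPs absent from LD matrix treated as independent", len(absent))

    order = sorted(
        range(len(df)),
        key=lambda i: (df["pval"].iat[i], df["snp_id"].iat[i]),
    )
    snp_ids = df["snp_id"].tolist()
    assigned: set[str] = set()
    index_snps: list[str] = []
    for i in order:
        sid = snp_ids[i]
        if sid in assigned:
            continue
        assigned.add(sid)
        index_snps.append(sid)
        if sid not in ld:
            continue
        pos = ld.position(sid)
        for j in order:
            other = snp_ids[j]
            if other in assigned or other not in ld:
                continue
            if (
                ld.lookup(sid, other) > params.r2_max
                and abs(ld.position(other) - pos) <= params.window_kb
            ):
                assigned.add(other)
    keep = df["snp_id"].isin(index_snps)
    clumped = df.loc[keep].copy()
    clumped = clumped.sort_values(
        by=["pval", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    result = SummaryDataset(dataset.trait_id, dataset.trait_role, clumped)
    _assert_pairwise_valid(result, ld, params)
    return result


def _assert_pairwise_valid(dataset: SummaryDataset, ld: LDMatrix, params: ClumpParams) -> None:
    ids = [s for s in dataset.snp_ids if s in ld]
    for a, b in itertools.combinations(ids, 2):
        if (
            abs(ld.position(a) - ld.position(b)) <= params.window_kb
            and ld.lookup(a, b) > params.r2_max
        ):
            raise AssertionError(f"clump output invalid: {a}/{b} exceed r2_max in window")


def compute_strength(record: SummaryStatRecord, pve_mode: str = "maf_beta") -> InstrumentRecord:
    """Per-SNP variance explained and F statistic.

    ``pve_mode='maf_beta'`` (default) uses R² = 2 f (1 - f) β² — exact for
    a standardized trait and matched to the simulator's generative model.
    ``pve_mode='z2'`` uses the approximation R² = z² / (z² + N).
    The F statistic is F = R² (N - 2) / (1 - R²).
    """
    if pve_mode == "maf_beta":
        r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
    elif pve_mode == "z2":
        z2 = (record.beta / record.se) ** 2
        r2 = z2 / (z2 + record.n)
    else:
        raise ValueError("pve_mode must be 'maf_beta' or 'z2'")
    if r2 >= 1.0:
        raise ValueError(f"{record.snp_id}: variance explained >= 1 ({r2:.3f})")
    f_stat = r2 * (record.n - 2) / (1.0 - r2)
    return InstrumentRecord(record=record, r2_explained=r2, f_stat=f_stat)


def filter_weak(
    instruments: list[InstrumentRecord], f_min: float = 10.0
) -> list[InstrumentRecord]:
    """Exclude weak instruments: F strictly below ``f_min`` (F = f_min kept)."""
    kept = [ins for ins in instruments if ins.f_stat >= f_min]
    n_dropped = len(instruments) - len(kept)
    if n_dropped:
        logger.info("excluded %d weak instruments (F < %g)", n_dropped, f_min)
    return kept


def select_instruments(
    dataset: SummaryDataset,
    ld: LDMatrix,
    params: ClumpParams,
    f_min: float = 10.0,
    pve_mode: str = "maf_beta",
    missing_ld: str = "error",
) -> tuple[SummaryDataset, list[InstrumentRecord], dict[str, int]]:
    """Full selection pipeline: threshold -> clump -> strength filter.

    Returns the surviving dataset, per-instrument strength records, and a
    per-stage record count log.
    """
    counts = {"input": len(dataset)}
    sig = threshold_by_p(dataset, params.p_threshold)
    counts["p_threshold"] = len(sig)
    if len(sig) == 0:
        return sig, [], counts
    clumped = clump(sig, ld, params, missing_ld=missing_ld)
    counts["clumped"] = len(clumped)
    strengths = [compute_strength(r, pve_mode=pve_mode) for r in clumped.to_records()]
    strong = filter_weak(strengths, f_min=f_min)
    counts["f_filter"] = len(strong)
    keep_ids = [ins.record.snp_id for ins in strong]
    final = clumped.subset(keep_ids)
    return final, strong, counts
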