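"""Allele harmonization between exposure instruments and outcome statistics.

Two-sample MR requires the exposure and outcome effects to refer to the
same effect allele.  For each instrument SNP found in the outcome file we
either keep the outcome record as-is, swap its alleles (negating the beta
and complementing the frequency), or recognise it as the strand
complement of the exposure pair.  Palindromic SNPs (A/T or C/G), whose
strand cannot be resolved from the alleles alone, are dropped
unconditionally by default; a frequency-rescue mode that keeps
palindromic SNPs whose allele frequencies are far from 0.5 is available
for comparison but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import SummaryDataset

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome statistics aligned to one shared effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str  # unchanged | allele_swapped | strand_flipped | strand_flipped_and_swapped

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


@dataclass
class HarmonizedPairSet:
    """Aligned pairs plus an audit of everything that was dropped.

    ``pairs`` follows the exposure instrument order; ``dropped`` maps each
    removed snp_id to one of {palindromic, allele_mismatch,
    absent_in_outcome}.  Together they partition the input instruments.
    """

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair]
    dropped: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        return (
            np.array([p.beta_exp for p in self.pairs]),
            np.array([p.se_exp for p in self.pairs]),
            np.array([p.beta_out for p in self.pairs]),
            np.array([p.se_out for p in self.pairs]),
        )

    def drop_snps(self, snp_ids: set[str] | list[str]) -> "HarmonizedPairSet":
        """A copy without the given SNPs (used for outlier-corrected fits)."""
        snp_ids = set(snp_ids)
        return HarmonizedPairSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            pairs=[p for p in self.pairs if p.snp_id not in snp_ids],
            dropped=dict(self.dropped),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": p.snp_id,
                    "beta_exp": p.beta_exp,
                    "se_exp": p.se_exp,
                    "beta_out": p.beta_out,
                    "se_out": p.se_out,
                    "action": p.action,
                }
                for p in self.pairs
            ]
        )


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_rescue: bool = False,
    rescue_eaf_window: float = 0.08,
) -> HarmonizedPairSet:
    """Align outcome records to the exposure effect alleles.

    For each exposure instrument present in the outcome: direct allele
    match keeps the record unchanged; swapped alleles negate beta_out;
    strand-complement matches (with or without swap) are recoded first.
    Palindromic allele pairs on either side are dropped unless
    ``palindromic_rescue`` is set and both frequencies are at least
    ``rescue_eaf_window`` away from 0.5 (in which case the orientation is
    inferred from frequency agreement).
    """
    out_by_id = {}
    for row in outcome.records.itertuples(index=False):
        out_by_id[row.snp_id] = row

    pairs: list[HarmonizedPair] = []
    dropped: dict[str, str] = {}
    for exp in exposure.records.itertuples(index=False):
        sid = exp.snp_id
        out = out_by_id.get(sid)
        exp_pal = is_palindromic(exp.effect_allele, exp.other_allele)
        if out is None:
            # an exposure-side palindrome is unusable regardless of the
            # outcome file, so it takes precedence over absence
            dropped[sid] = "palindromic" if exp_pal else "absent_in_outcome"
            continue
        out_pal = is_palindromic(out.effect_allele, out.other_allele)
        if exp_pal or out_pal:
            keep = False
            if palindromic_rescue and exp_pal and out_pal:
                keep = _rescue_orientation(exp, out, rescue_eaf_window, pairs)
            if not keep:
                dropped[sid] = "palindromic"
            continue

        ea, oa = out.effect_allele, out.other_allele
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (ea, oa) == (exp.effect_allele, exp.other_allele):
            pairs.append(_pair(exp, out.beta, out.se, "unchanged"))
        elif (ea, oa) == (exp.other_allele, exp.effect_allele):
            pairs.append(_pair(exp, -out.beta, out.se, "allele_swapped"))
        elif (cea, coa) == (exp.effect_allele, exp.other_allele):
            pairs.append(_pair(exp, out.beta, out.se, "strand_flipped"))
        elif (cea, coa) == (exp.other_allele, exp.effect_allele):
            pairs.append(_pair(exp, -out.beta, out.se, "strand_flipped_and_swapped"))
        else:
            dropped[sid] = "allele_mismatch"
    return HarmonizedPairSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        pairs=pairs,
        dropped=dropped,
    )


def _pair(exp, beta_out: float, se_out: float, action: str) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=float(exp.beta),
        se_exp=float(exp.se),
        beta_out=float(beta_out),
        se_out=float(se_out),
        action=action,
    )


def _rescue_orientation(exp, out, window: float, pairs: list[HarmonizedPair]) -> bool:
    """Frequency-based orientation for a palindromic SNP; True if kept."""
    if abs(exp.eaf - 0.5) < window or abs(out.eaf - 0.5) < window:
        return False
    same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
    if same_side:
        pairs.append(_pair(exp, out.beta, out.se, "unchanged"))
    else:
        pairs.append(_pair(exp, -out.beta, out.se, "allele_swapped"))
    return True
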