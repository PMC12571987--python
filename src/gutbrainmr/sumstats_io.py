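"""Data model and text I/O for GWAS summary statistics.

Every stage of the pipeline consumes and produces per-SNP association
statistics: effect allele, other allele, effect-allele frequency, beta,
standard error, p-value and sample size.  Files are GWAS-SSF-like
tab-separated text with a header row; the column mapping is configurable
because microbiome, brain-imaging and cytokine consortia all ship
different headers.

Floats are serialized in scientific notation with 17 significant digits so
that a write/read round trip is bit-exact — sign flips introduced during
allele harmonization survive serialization without drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: canonical column order of the on-disk dialect
COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

_FLOAT_COLS = ("eaf", "beta", "se", "pval")


class SumstatsFormatError(ValueError):
    """A mandatory column is missing or the file is not parseable."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association statistics for a single trait.

    Only single-base SNVs are modelled; indels are rejected.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def is_valid(self) -> bool:
        return (
            self.effect_allele in VALID_ALLELES
            and self.other_allele in VALID_ALLELES
            and self.effect_allele != self.other_allele
            and 0.0 < self.eaf < 1.0
            and np.isfinite(self.beta)
            and self.se > 0.0
            and 0.0 < self.pval <= 1.0
            and self.n >= 1
        )


@dataclass
class SummaryDataset:
    """Ordered per-SNP summary statistics for one trait.

    ``records`` is a DataFrame with the canonical :data:`COLUMNS`; row
    order is meaningful and snp_id is unique.
    """

    trait_id: str
    trait_role: str  # exposure | outcome | mediator
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise SumstatsFormatError(f"dataset missing columns: {missing}")
        self.records = self.records.loc[:, list(COLUMNS)].reset_index(drop=True)
        if self.records["snp_id"].duplicated().any():
            dups = self.records.loc[self.records["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate snp_id in {self.trait_id!r}: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return self.records["snp_id"].tolist()

    def to_records(self) -> list[SummaryStatRecord]:
        return [
            SummaryStatRecord(
                snp_id=row.snp_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )
            for row in self.records.itertuples(index=False)
        ]

    @classmethod
    def from_records(
        cls, trait_id: str, trait_role: str, records: Sequence[SummaryStatRecord]
    ) -> "SummaryDataset":
        df = pd.DataFrame([r.__dict__ for r in records], columns=list(COLUMNS))
        return cls(trait_id=trait_id, trait_role=trait_role, records=df)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        """Rows for ``snp_ids``, preserving this dataset's record order."""
        keep = self.records["snp_id"].isin(set(snp_ids))
        return SummaryDataset(self.trait_id, self.trait_role, self.records.loc[keep])


@dataclass
class LDMatrix:
    """Pairwise r-squared among a set of SNPs plus physical coordinates (kb)."""

    snp_ids: list[str]
    r2: np.ndarray
    positions_kb: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.positions_kb = np.asarray(self.positions_kb, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if self.positions_kb.shape != (k,):
            raise ValueError("positions_kb length must match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def position(self, snp_id: str) -> float:
        return float(self.positions_kb[self._index[snp_id]])


def _valid_mask(df: pd.DataFrame) -> pd.Series:
    return (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"] > 0.0)
        & (df["eaf"] < 1.0)
        & np.isfinite(df["beta"])
        & (df["se"] > 0.0)
        & (df["pval"] > 0.0)
        & (df["pval"] <= 1.0)
        & (df["n"] >= 1)
    )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_role: str = "exposure",
) -> SummaryDataset:
    """Read a whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps canonical field names (:data:`COLUMNS`) to the
    file's column headers; fields absent from the map are assumed to use
    the canonical name.  Rows violating record invariants (non-SNV
    alleles, se <= 0, p outside (0, 1], eaf outside (0, 1)) are dropped
    with a logged count; record order is otherwise preserved.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    try:
        # read as text and convert via float() so parsing is correctly
        # rounded; pandas' fast float parser is not and would break the
        # bit-exact round-trip guarantee
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} has no header or data") from exc
    rename = {column_map.get(field, field): field for field in COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SumstatsFormatError(f"{path} missing mandatory columns: {missing}")
    df = raw.rename(columns=rename).loc[:, list(COLUMNS)]
    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    def _to_float(value):
        try:
            return float(value)
        except (TypeError, ValueError):
            return np.nan

    for col in _FLOAT_COLS:
        df[col] = df[col].map(_to_float)
    df["n"] = pd.to_numeric(df["n"], errors="coerce").fillna(0).astype(float).astype(int)
    ok = _valid_mask(df)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows of %d", path.name, n_dropped, len(df))
    df = df.loc[ok]
    return SummaryDataset(
        trait_id=trait_id if trait_id is not None else path.stem,
        trait_role=trait_role,
        records=df,
    )


def write_sumstats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write ``dataset`` as tab-separated text in the canonical column order.

    Floats use ``%.16e`` (17 significant digits), which round-trips IEEE
    doubles exactly.
    """
    out = dataset.records.copy()
    for col in _FLOAT_COLS:
        out[col] = out[col].map(lambda x: format(float(x), ".16e"))
    out["n"] = out["n"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_ld(matrix_path: str | Path, positions_path: str | Path) -> LDMatrix:
    """Read a square r² TSV (header = snp ids) plus a snp_id/position_kb TSV."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in mat.columns]
    pos = pd.read_csv(positions_path, sep="\t")
    pos_map = dict(zip(pos["snp_id"].astype(str), pos["position_kb"].astype(float)))
    missing = [s for s in snp_ids if s not in pos_map]
    if missing:
        raise SumstatsFormatError(f"positions file missing SNPs: {missing[:5]}")
    return LDMatrix(
        snp_ids=snp_ids,
        r2=mat.to_numpy(dtype=float),
        positions_kb=np.array([pos_map[s] for s in snp_ids]),
    )


def write_ld(ld: LDMatrix, matrix_path: str | Path, positions_path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(matrix_path, sep="\t")
    pd.DataFrame({"snp_id": ld.snp_ids, "position_kb": ld.positions_kb}).to_csv(
        positions_path, sep="\t", index=False
    )
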