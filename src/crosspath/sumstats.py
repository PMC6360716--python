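"""GWAS summary statistics: loading, QC filters and writing.

The on-disk format is the tab-separated table ``SNP CHR BP A1 A2 MAF P``
(one file per trait), the common denominator of consortium summary-statistic
releases.  Records are filtered on minor allele frequency (default: drop
MAF < 0.05, the usual common-variant convention) and optionally on the
association p-value (nominal prefilter, retained inclusively at the bound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "MAF", "P"]


@dataclass
class SummaryStats:
    """Per-trait SNP association records, sorted by (chromosome, position)."""

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if self.table["SNP"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary statistics")
        self.table = (
            self.table.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    def pvalues(self, snp_ids) -> pd.Series:
        return self.table.set_index("SNP").loc[list(snp_ids), "P"]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.table[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)
        return path


def load_sumstats(
    path: str | Path,
    maf_min: float = 0.05,
    p_max: float = 1.0,
    trait: str | None = None,
) -> SummaryStats:
    """Read a summary-statistics file and apply the record-level filters.

    Records with ``MAF < maf_min`` are removed (strict inequality: a record
    at exactly the bound is kept).  When ``p_max < 1`` is requested, records
    with ``P > p_max`` are removed — retention is inclusive at the stated
    threshold, so a record at exactly ``p_max`` survives.  Records with a
    p-value outside (0, 1] are rejected with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: empty summary statistics file", path)
        return SummaryStats(df, trait=trait or path.stem)

    bad_p = ~((df["P"] > 0) & (df["P"] <= 1))
    if bad_p.any():
        logger.warning("%s: rejected %d records with p outside (0, 1]", path, bad_p.sum())
        df = df[~bad_p]

    n0 = len(df)
    df = df[df["MAF"] >= maf_min]
    if len(df) < n0:
        logger.info("%s: removed %d records with MAF < %g", path, n0 - len(df), maf_min)

    if p_max < 1.0:
        n0 = len(df)
        df = df[df["P"] <= p_max]
        logger.info("%s: removed %d records with p > %g", path, n0 - len(df), p_max)

    return SummaryStats(df.reset_index(drop=True), trait=trait or path.stem)
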