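"""Gene annotation table: BED-like, 0-based half-open intervals.

Columns: ``chrom start end name score strand``.  The transcription start
site (TSS) is the ``start`` coordinate for +-strand genes and ``end`` for
−-strand genes (converted to 1-based positions for window arithmetic).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=GENE_COLUMNS, dtype={"chrom": str}
    )
    _validate(df)
    return df


def write_genes(genes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    genes[GENE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    return path


def _validate(genes: pd.DataFrame) -> None:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("degenerate gene interval (end <= start)")
    if genes["name"].duplicated().any():
        raise ValueError("duplicate gene names")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-' (TSS undefined otherwise)")


def tss_1based(genes: pd.DataFrame) -> np.ndarray:
    """1-based TSS per gene: start+1 for '+' strand, end for '-' strand."""
    _validate(genes)
    return np.where(genes["strand"] == "+", genes["start"] + 1, genes["end"]).astype(int)
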