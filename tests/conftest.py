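"""Shared synthetic fixtures (session-scoped; everything generated in memory)."""

import numpy as np
import pandas as pd
import pytest

from crosspath.genes import GENE_COLUMNS
from crosspath.panel import GenotypePanel
from crosspath.simulate import (
    GenomeSpec,
    TraitSpec,
    simulate_annotations,
    simulate_reference_panel,
    simulate_trait_sumstats,
)
from crosspath.sumstats import SUMSTATS_COLUMNS, SummaryStats


@pytest.fixture(scope="session")
def genome_small() -> GenomeSpec:
    return GenomeSpec(
        n_chromosomes=1,
        chrom_length_bp=500_000,
        snp_spacing_bp=5_000,
        block_size_snps=10,
        within_block_r=0.8,
    )


@pytest.fixture(scope="session")
def panel_small(genome_small) -> GenotypePanel:
    return simulate_reference_panel(genome_small, n_samples=500, seed=1)


@pytest.fixture(scope="session")
def genome_medium() -> GenomeSpec:
    return GenomeSpec(
        n_chromosomes=2,
        chrom_length_bp=8_000_000,
        snp_spacing_bp=10_000,
        block_size_snps=10,
        within_block_r=0.6,
    )


@pytest.fixture(scope="session")
def panel_medium(genome_medium) -> GenotypePanel:
    return simulate_reference_panel(genome_medium, n_samples=300, seed=7)


@pytest.fixture(scope="session")
def annotations_medium(genome_medium):
    return simulate_annotations(
        genome_medium, n_genes=100, n_pathways=40, genes_per_pathway=(5, 10), seed=8
    )


@pytest.fixture(scope="session")
def null_sumstats_medium(panel_medium, annotations_medium) -> SummaryStats:
    genes, coll = annotations_medium
    return simulate_trait_sumstats(
        panel_medium, genes, coll, TraitSpec("null", seed=21)
    )


def make_panel(dosages: np.ndarray, chrom: str = "1", spacing: int = 1000) -> GenotypePanel:
    """GenotypePanel from a raw samples x SNPs dosage matrix."""
    n_snps = dosages.shape[1]
    freq = dosages.mean(axis=0) / 2.0
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": [(i + 1) * spacing for i in range(n_snps)],
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return GenotypePanel(dosages=dosages.astype(np.int8), snps=snps)


def make_sumstats(rows, trait="t") -> SummaryStats:
    """SummaryStats from (snp_id, chrom, pos, maf, p) tuples."""
    table = pd.DataFrame(
        [
            {"SNP": s, "CHR": str(c), "BP": b, "A1": "A", "A2": "G", "MAF": m, "P": p}
            for s, c, b, m, p in rows
        ],
        columns=SUMSTATS_COLUMNS,
    )
    return SummaryStats(table, trait=trait)


def make_genes(rows) -> pd.DataFrame:
    """Gene table from (chrom, start, end, name, strand) tuples."""
    return pd.DataFrame(
        [
            {"chrom": str(c), "start": s, "end": e, "name": n, "score": 0, "strand": st}
            for c, s, e, n, st in rows
        ],
        columns=GENE_COLUMNS,
    )
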