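"""Canonical simulation experiments validating the pipeline's statistics.

These are the package's built-in calibration and power benchmarks, run on
synthetic fixtures whose sizes keep them desk-scale:

* ``null_gene_score_calibration`` — type-I error of the LD-aware gene score
  on traits with no signal (block-LD panel, 500 samples, 5,000 SNPs):
  the fraction of genes at p < 0.05 should sit near 0.05.
* ``interval_null_calibration`` — the matched-null empirical p-value of the
  interval engine under the null: the fraction of pathway tests at
  p < 0.05 should also sit near 0.05 (slightly conservative, as the
  add-one estimator is discrete).
* ``planted_recovery_run`` — full-pipeline power and specificity: two
  traits share five planted causal pathways (z-score shift 6 on half the
  SNPs of every member-gene window), a third trait is null; planted
  pathways should reach the combined significance threshold, and the
  trait network should connect exactly the two sharing traits.

All randomness derives from the ``seed`` arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genescore import score_genes
from .intervals import run_interval_enrichment
from .pathways import filter_by_size, prune_redundant
from .pipeline import run_pipeline
from .simulate import (
    GenomeSpec,
    TraitSpec,
    simulate_annotations,
    simulate_reference_panel,
    simulate_trait_sumstats,
)

#: Genome of the null-calibration fixture: 2 chromosomes, 5,000 SNPs at 5 kb
#: spacing, AR(1) blocks of 20 SNPs targeting dosage r = 0.7.
NULL_GENOME = GenomeSpec(
    n_chromosomes=2,
    chrom_length_bp=12_500_000,
    snp_spacing_bp=5_000,
    block_size_snps=20,
    within_block_r=0.7,
)

#: Genome of the recovery fixture: sparser genes (no window spill-over
#: between neighbours) on 2 x 25 Mb with 10 kb SNP spacing.
RECOVERY_GENOME = GenomeSpec(
    n_chromosomes=2,
    chrom_length_bp=25_000_000,
    snp_spacing_bp=10_000,
    block_size_snps=20,
    within_block_r=0.7,
)


def null_gene_score_calibration(
    n_traits: int = 10,
    n_samples: int = 500,
    n_genes: int = 500,
    seed: int = 0,
) -> dict:
    """Gene-score p-values on null traits; returns the pooled p-values.

    ``n_traits`` independent null summary-statistic draws are scored on one
    shared panel, giving ``n_traits * n_genes`` gene tests.
    """
    panel = simulate_reference_panel(NULL_GENOME, n_samples=n_samples, seed=seed)
    genes, coll = simulate_annotations(
        NULL_GENOME, n_genes=n_genes, n_pathways=10, genes_per_pathway=(5, 10),
        seed=seed + 1,
    )
    pvals = []
    for k in range(n_traits):
        ss = simulate_trait_sumstats(
            panel, genes, coll, TraitSpec(f"null{k}", seed=seed + 100 + k)
        )
        scores, _ = score_genes(ss, panel, genes)
        pvals.append(scores["p_gene"].to_numpy())
    pvals = np.concatenate(pvals)
    return {
        "p_gene": pvals,
        "n_tests": int(pvals.size),
        "frac_below_05": float((pvals < 0.05).mean()),
    }


def interval_null_calibration(
    n_traits: int = 3,
    n_samples: int = 400,
    replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Empirical pathway p-values of the interval engine on null traits."""
    panel = simulate_reference_panel(RECOVERY_GENOME, n_samples=n_samples, seed=seed)
    genes, coll = simulate_annotations(
        RECOVERY_GENOME, n_genes=400, n_pathways=200, genes_per_pathway=(10, 15),
        seed=seed + 1,
    )
    ps = []
    for k in range(n_traits):
        ss = simulate_trait_sumstats(
            panel, genes, coll, TraitSpec(f"null{k}", seed=seed + 200 + k)
        )
        results = run_interval_enrichment(
            ss, panel, coll, genes, replicates=replicates, seed=seed + 300 + k
        )
        ps.append([r.p_empirical for r in results])
    ps = np.concatenate(ps)
    return {
        "p_empirical": ps,
        "n_tests": int(ps.size),
        "frac_below_05": float((ps < 0.05).mean()),
    }


@dataclass
class RecoveryOutcome:
    planted: list
    n_planted_significant: dict   # causal trait -> count of planted at p_combined < alpha
    sharing_edge_found: bool      # (trait1, trait2) connected at adjusted p < alpha
    null_trait_isolated: bool     # no edge touches the null trait


def planted_recovery_run(
    seed: int,
    n_samples: int = 400,
    n_genes: int = 400,
    n_pathways: int = 200,
    n_planted: int = 5,
    effect_size: float = 6.0,
    replicates: int = 200,
    alpha: float = 0.01,
) -> RecoveryOutcome:
    """One seeded run of the full pipeline on a 3-trait planted fixture.

    Traits ``t1`` and ``t2`` share ``n_planted`` causal pathways (drawn from
    the size-filtered, redundancy-pruned collection so pruning cannot remove
    them); ``t3`` carries no signal.
    """
    panel = simulate_reference_panel(RECOVERY_GENOME, n_samples=n_samples, seed=seed)
    genes, coll = simulate_annotations(
        RECOVERY_GENOME, n_genes=n_genes, n_pathways=n_pathways,
        genes_per_pathway=(10, 15), seed=seed + 1,
    )
    pruned, _ = prune_redundant(filter_by_size(coll))
    rng = np.random.default_rng(seed + 2)
    planted = sorted(rng.choice(pruned.names, size=n_planted, replace=False))

    traits = [
        TraitSpec("t1", causal_pathways=tuple(planted), effect_size=effect_size,
                  fraction_causal_snps_per_gene=0.5, seed=seed + 11),
        TraitSpec("t2", causal_pathways=tuple(planted), effect_size=effect_size,
                  fraction_causal_snps_per_gene=0.5, seed=seed + 12),
        TraitSpec("t3", seed=seed + 13),
    ]
    ss = {t.trait_name: simulate_trait_sumstats(panel, genes, coll, t) for t in traits}
    result = run_pipeline(
        ss, panel, genes, coll, replicates=replicates, seed=seed + 20, alpha=alpha,
        net_thresholds=(alpha,),
    )
    comb = result.combined
    n_sig = {}
    for trait in ("t1", "t2"):
        sub = comb[(comb["trait"] == trait) & comb["pathway"].isin(planted)]
        n_sig[trait] = int((sub["p_combined"] < alpha).sum())
    g = result.networks[alpha]
    edge = g.has_edge("t1", "t2")
    isolated = g.degree("t3") == 0 if "t3" in g else True
    return RecoveryOutcome(
        planted=list(planted),
        n_planted_significant=n_sig,
        sharing_edge_found=bool(edge),
        null_trait_isolated=bool(isolated),
    )
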