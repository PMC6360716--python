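"""Interval-based enrichment: clump significant SNPs, test pathway overlap.

Clumps SNPs at p <= 0.01 into LD-independent intervals (r^2 >= 0.2 with the
index SNP, within 1 Mb), counts for each pathway the intervals hitting a
member gene (statistic E), and calibrates E against matched null intervals
resampled over the genome.
"""

from crosspath import (
    ClumpParams,
    GenomeSpec,
    TraitSpec,
    clump,
    run_interval_enrichment,
    simulate_annotations,
    simulate_reference_panel,
    simulate_trait_sumstats,
)
from crosspath.intervals import enrichment_frame

genome = GenomeSpec(2, 12_000_000, 10_000, 10, 0.6)
panel = simulate_reference_panel(genome, n_samples=300, seed=20)
genes, pathways = simulate_annotations(
    genome, n_genes=120, n_pathways=40, genes_per_pathway=(8, 12), seed=21
)
target = pathways.names[0]
trait = TraitSpec("demo", causal_pathways=(target,), effect_size=6, seed=22)
ss = simulate_trait_sumstats(panel, genes, pathways, trait)

intervals = clump(ss, panel, ClumpParams())
print(f"{len(intervals)} LD-independent intervals from "
      f"{(ss.table['P'] <= 0.01).sum()} significant SNPs; first three:")
for iv in intervals[:3]:
    print(f"  chr{iv.chrom}:{iv.start_bp}-{iv.end_bp}  index={iv.index_snp}  "
          f"snps={iv.n_snps}")

results = run_interval_enrichment(
    ss, panel, pathways, genes, replicates=200, seed=23
)
table = enrichment_frame(results)
print("\nTop pathways by empirical p (planted pathway is", target + "):")
print(table.nsmallest(5, "p_empirical").to_string(index=False))
print(
    "\nE_obs counts intervals overlapping >= 1 member gene; p_empirical is\n"
    "the add-one rank of E_obs among 200 matched-null replicates, so its\n"
    "smallest attainable value here is 1/201 ~ 0.005."
)
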