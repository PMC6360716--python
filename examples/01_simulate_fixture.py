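"""Generate a complete synthetic GWAS fixture and inspect its parts.

Builds a block-LD reference panel, non-overlapping gene annotations, a GMT
pathway collection, and summary statistics for three traits — two sharing
a planted causal pathway, one null — then prints what was written.
"""

from pathlib import Path

from crosspath import GenomeSpec, TraitSpec, load_sumstats, simulate_fixture

genome = GenomeSpec(
    n_chromosomes=2,
    chrom_length_bp=8_000_000,
    snp_spacing_bp=10_000,
    block_size_snps=10,
    within_block_r=0.6,
)
traits = [
    TraitSpec("height_like", causal_pathways=("PW0001",), effect_size=6, seed=1),
    TraitSpec("bmd_like", causal_pathways=("PW0001",), effect_size=6, seed=2),
    TraitSpec("unrelated", seed=3),
]
outdir = Path("scratch/example_fixture")
bundle = simulate_fixture(
    outdir, genome, traits, n_samples=300, n_genes=120, n_pathways=40,
    genes_per_pathway=(8, 12), seed=0,
)

print(f"panel:     {bundle.panel_prefix}.geno.tsv / .snps.tsv")
print(f"genes:     {bundle.genes_path}")
print(f"pathways:  {bundle.gmt_path}")
print(f"truth:     {bundle.truth_path}  (the planted trait->pathway pairs)")
for trait, path in bundle.sumstats_paths.items():
    ss = load_sumstats(path)
    n_sig = (ss.table["P"] <= 0.01).sum()
    print(f"sumstats {trait}: {len(ss)} SNPs, {n_sig} at p <= 0.01")
print(
    "\nThe two causal traits carry an excess of significant SNPs inside the\n"
    "planted pathway's gene windows; the unrelated trait sits at the ~1%\n"
    "null rate."
)
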