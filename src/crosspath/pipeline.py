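"""End-to-end orchestration: simulate -> score -> enrich -> combine -> cross-trait.

``run_pipeline`` drives the whole analysis on in-memory objects and returns
every intermediate product; ``run_all`` is the file-based front: it reads a
YAML configuration, simulates the fixture (or loads existing files), runs
both engines for every trait and writes all result tables under an output
directory with logged seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import combine as combine_mod
from . import crosstrait as ct
from .genes import read_genes
from .genescore import score_genes, score_pathways
from .intervals import ClumpParams, enrichment_frame, run_interval_enrichment
from .panel import GenotypePanel
from .pathways import PathwayCollection, filter_by_size, prune_redundant, read_gmt
from .simulate import GenomeSpec, TraitSpec, simulate_fixture
from .sumstats import SummaryStats, load_sumstats

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    gene_scores: dict = field(default_factory=dict)        # trait -> DataFrame
    pathway_scores_gs: dict = field(default_factory=dict)  # trait -> DataFrame
    enrichment: dict = field(default_factory=dict)         # trait -> DataFrame
    combined: pd.DataFrame | None = None
    pairs: list = field(default_factory=list)
    pair_table: pd.DataFrame | None = None
    networks: dict = field(default_factory=dict)           # threshold -> Graph
    mds: pd.DataFrame | None = None
    newick: str | None = None


def run_pipeline(
    sumstats_by_trait: dict,
    panel: GenotypePanel,
    genes: pd.DataFrame,
    pathways: PathwayCollection,
    window_bp: int = 50_000,
    clump_params: ClumpParams | None = None,
    replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    net_thresholds: tuple = (1e-3, 0.01),
    snp_p_max: float = 1.0,
    prune: bool = True,
) -> PipelineResult:
    """Run both engines for every trait, combine, and derive cross-trait outputs.

    ``sumstats_by_trait`` maps trait name -> SummaryStats.  ``snp_p_max`` < 1
    applies the nominal-significance SNP prefilter before gene scoring (with
    a warning: truncating the null inflates gene scores; the default scores
    all retained SNPs).  When ``prune`` is true the pathway collection is
    size-filtered (10-200) and redundancy-pruned (>30% overlap) first.
    """
    if prune:
        pathways, _log = prune_redundant(filter_by_size(pathways))
    if snp_p_max < 1.0:
        logger.warning(
            "SNP prefilter p <= %g truncates the gene-score null; interpret "
            "gene p-values comparatively, not as calibrated tail probabilities",
            snp_p_max,
        )

    result = PipelineResult()
    gs_rows, iv_rows = [], []
    for ti, (trait, ss) in enumerate(sorted(sumstats_by_trait.items())):
        ss_gs = ss
        if snp_p_max < 1.0:
            keep = ss.table["P"] <= snp_p_max
            ss_gs = SummaryStats(ss.table[keep].reset_index(drop=True), trait=ss.trait)
        gene_scores, windows = score_genes(ss_gs, panel, genes, window_bp=window_bp)
        result.gene_scores[trait] = gene_scores
        pw_gs = score_pathways(gene_scores, windows, pathways, ss_gs, panel)
        result.pathway_scores_gs[trait] = pw_gs
        gs_rows.append(pw_gs.assign(trait=trait))

        enr = run_interval_enrichment(
            ss, panel, pathways, genes,
            params=clump_params, replicates=replicates, seed=seed + 1000 + ti,
        )
        enr_df = enrichment_frame(enr, trait=trait)
        result.enrichment[trait] = enr_df
        iv_rows.append(enr_df.rename(columns={"p_empirical": "p"})[["trait", "pathway", "p"]])

    res1 = pd.concat(gs_rows, ignore_index=True)[["trait", "pathway", "p"]]
    res2 = pd.concat(iv_rows, ignore_index=True)
    result.combined = combine_mod.combine_matrix(res1, res2, pathways, alpha_robust=alpha)

    result.pairs, result.pair_table = ct.all_trait_pairs(result.combined, alpha=alpha)
    sig = ct.significant_sets(result.combined, alpha=alpha)
    node_meta = {t: {"n_significant_pathways": len(s)} for t, s in sig.items()}
    for thr in net_thresholds:
        result.networks[thr] = ct.build_network(result.pairs, node_meta, threshold=thr)
    if len(sumstats_by_trait) >= 3:
        result.mds, _dist = ct.mds_embed(result.combined)
    if result.pairs:
        fetm = ct.fet_p_matrix(result.pairs)
        if len(fetm) >= 2:
            _Z, result.newick = ct.cluster_traits(fetm)
    return result


def run_all(config: dict | str | Path, outdir: str | Path | None = None) -> PipelineResult:
    """File-based pipeline driven by a YAML configuration.

    The configuration either points at existing inputs (``panel_prefix`` or
    ``panel_vcf``, ``genes``, ``gmt``, ``sumstats: {trait: path}``) or asks
    for a simulation (``simulate:`` block with genome/trait settings).  All
    tables are written under ``outdir``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir or config.get("outdir", "crosspath_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    logger.info("run_all: seed=%d outdir=%s", seed, outdir)

    if "simulate" in config:
        sim = config["simulate"]
        genome = GenomeSpec(**sim.get("genome", {}))
        traits = [TraitSpec(**t) for t in sim["traits"]]
        bundle = simulate_fixture(
            outdir / "fixture", genome, traits,
            n_samples=sim.get("n_samples", 500),
            n_genes=sim.get("n_genes", 200),
            n_pathways=sim.get("n_pathways", 50),
            genes_per_pathway=tuple(sim.get("genes_per_pathway", (10, 30))),
            seed=seed,
        )
        panel = GenotypePanel.read_tsv(bundle.panel_prefix)
        genes = read_genes(bundle.genes_path)
        coll = read_gmt(bundle.gmt_path)
        ss = {t: load_sumstats(p, trait=t) for t, p in bundle.sumstats_paths.items()}
    else:
        if "panel_vcf" in config:
            panel = GenotypePanel.read_vcf(config["panel_vcf"])
        else:
            panel = GenotypePanel.read_tsv(config["panel_prefix"])
        genes = read_genes(config["genes"])
        coll = read_gmt(config["gmt"])
        ss = {t: load_sumstats(p, trait=t) for t, p in config["sumstats"].items()}

    params = ClumpParams(**config.get("clump", {}))
    result = run_pipeline(
        ss, panel, genes, coll,
        window_bp=config.get("window_bp", 50_000),
        clump_params=params,
        replicates=config.get("replicates", 1000),
        seed=seed,
        alpha=config.get("alpha", 0.01),
        net_thresholds=tuple(config.get("net_thresholds", (1e-3, 0.01))),
        snp_p_max=config.get("snp_p_max", 1.0),
        prune=config.get("prune", True),
    )

    for trait, df in result.gene_scores.items():
        df.to_csv(outdir / f"{trait}.gene_scores.tsv", sep="\t", index=False)
    for trait, df in result.enrichment.items():
        df.to_csv(outdir / f"{trait}.interval_enrichment.tsv", sep="\t", index=False)
    result.combined.to_csv(outdir / "combined.tsv", sep="\t", index=False)
    if result.pair_table is not None:
        result.pair_table.to_csv(outdir / "trait_pairs.tsv", sep="\t", index=False)
    import networkx as nx

    for thr, g in result.networks.items():
        ct.network_edge_table(g).to_csv(
            outdir / f"network_edges_{thr:g}.tsv", sep="\t", index=False
        )
        nx.write_graphml(g, outdir / f"network_{thr:g}.graphml")
    if result.mds is not None:
        result.mds.to_csv(outdir / "mds.tsv", sep="\t", index=False)
    if result.newick is not None:
        (outdir / "traits.nwk").write_text(result.newick + "\n")
    return result
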