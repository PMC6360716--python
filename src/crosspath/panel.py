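"""Reference genotype panel and LD computation.

A :class:`GenotypePanel` holds additive dosages (0/1/2 copies of the minor
allele) for a set of reference samples, together with a SNP map.  It is the
stand-in for an external LD reference (e.g. a 1000 Genomes population) and
is the single source of SNP-SNP correlation (r, r^2) for both enrichment
engines.

Two plain-text representations are supported: a genotype-matrix TSV with a
SNP-map sidecar, and a minimal GT-only VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "maf"]


@dataclass
class GenotypePanel:
    """Reference genotypes: ``dosages`` is samples x SNPs, int8 in {0,1,2}."""

    dosages: np.ndarray
    snps: pd.DataFrame
    _col: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} SNPs but the map has {len(self.snps)}"
            )
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP map missing columns: {missing}")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate snp_id in SNP map")
        self.snps = self.snps.reset_index(drop=True)
        self._col = {s: i for i, s in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._col

    def columns(self, snp_ids) -> np.ndarray:
        """Dosage sub-matrix for the given SNP ids (samples x len(snp_ids))."""
        idx = [self._col[s] for s in snp_ids]
        return self.dosages[:, idx].astype(float)

    def ld(self, snp_ids) -> np.ndarray:
        """Pearson correlation matrix between the dosage vectors of ``snp_ids``."""
        x = self.columns(snp_ids)
        if x.shape[1] == 1:
            return np.ones((1, 1))
        r = np.corrcoef(x, rowvar=False)
        return np.atleast_2d(r)

    def r2_with(self, index_snp: str, snp_ids) -> np.ndarray:
        """r^2 between one index SNP and each SNP in ``snp_ids``."""
        x = self.columns([index_snp])[:, 0]
        y = self.columns(snp_ids)
        x = x - x.mean()
        y = y - y.mean(axis=0)
        denom = np.sqrt((x @ x) * (y * y).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (y.T @ x) / denom, 0.0)
        return r**2

    # ------------------------------------------------------------------ IO

    def write_tsv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.geno.tsv`` (SNPs x samples) and ``<prefix>.snps.tsv``."""
        prefix = Path(prefix)
        geno_path = prefix.with_suffix(".geno.tsv")
        map_path = prefix.with_suffix(".snps.tsv")
        geno = pd.DataFrame(
            self.dosages.T,
            index=pd.Index(self.snps["snp_id"], name="snp_id"),
            columns=[f"S{i + 1}" for i in range(self.n_samples)],
        )
        geno.to_csv(geno_path, sep="\t")
        # keep auxiliary columns (e.g. simulator block ids) in the sidecar
        cols = SNP_MAP_COLUMNS + [c for c in self.snps.columns if c not in SNP_MAP_COLUMNS]
        self.snps[cols].to_csv(map_path, sep="\t", index=False)
        return geno_path, map_path

    @classmethod
    def read_tsv(cls, prefix: str | Path) -> "GenotypePanel":
        prefix = Path(prefix)
        geno = pd.read_csv(prefix.with_suffix(".geno.tsv"), sep="\t", index_col="snp_id")
        snps = pd.read_csv(
            prefix.with_suffix(".snps.tsv"), sep="\t", dtype={"chrom": str}
        )
        if list(geno.index) != list(snps["snp_id"]):
            raise ValueError("genotype matrix and SNP map disagree on SNP order")
        return cls(dosages=geno.to_numpy(dtype=np.int8).T, snps=snps)

    def write_vcf(self, path: str | Path) -> Path:
        """Write a minimal GT-only VCF.  a1 is emitted as ALT, so the ALT
        dosage in the VCF equals the stored minor-allele dosage."""
        path = Path(path)
        chroms = self.snps["chrom"].astype(str)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=crosspath\n")
            for chrom in dict.fromkeys(chroms):  # preserve order
                maxpos = int(self.snps.loc[chroms == chrom, "pos"].max())
                fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(f"S{i + 1}" for i in range(self.n_samples))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, row in self.snps.iterrows():
                gts = "\t".join(gt_codes[int(g)] for g in self.dosages[:, j])
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t{row['a2']}\t"
                    f"{row['a1']}\t.\tPASS\t.\tGT\t{gts}\n"
                )
        return path

    @classmethod
    def read_vcf(cls, path: str | Path) -> "GenotypePanel":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        rows, cols = [], []
        for v in vcf:
            g = np.asarray(v.gt_types, dtype=np.int8)
            if (g == 3).any():
                raise ValueError(f"missing genotypes at {v.ID}; panel must be complete")
            cols.append(g)
            freq = g.mean() / 2.0
            rows.append(
                {
                    "snp_id": v.ID,
                    "chrom": str(v.CHROM),
                    "pos": int(v.POS),
                    "a1": v.ALT[0] if v.ALT else "N",
                    "a2": v.REF,
                    "maf": min(freq, 1.0 - freq),
                }
            )
        if not rows:
            raise ValueError(f"no variants in {path}")
        return cls(dosages=np.column_stack(cols), snps=pd.DataFrame(rows))
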