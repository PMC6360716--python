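"""LD-aware gene and pathway scoring from summary statistics.

Each gene is scored on the SNPs falling within +/- ``window_bp`` of its
transcription start site.  The statistic is the sum of the per-SNP 1-df
chi-square quantiles,

    T = sum_i  F_chi2(1)^{-1}(1 - p_i),

whose null distribution under LD is the weighted sum sum_j lambda_j chi2_1
with lambda the eigenvalues of the SNPs' correlation matrix R in a
reference panel.  The survival function of that quadratic form is evaluated
by numerical inversion of its characteristic function (Imhof's method),
with Satterthwaite moment matching as fallback.  With independent SNPs
(R = I) this reduces to the ordinary chi-square tail with one degree of
freedom per SNP; with perfectly correlated SNPs the duplicated evidence is
absorbed into a single eigenvalue, so redundant SNPs are not double
counted.

Pathway scores aggregate member genes: genes whose windows overlap on the
same chromosome are fused into a single meta-gene scored jointly over the
union of their SNPs (their scores would otherwise be treated as independent
evidence despite shared LD); the remaining units are combined by summing
their 1-df quantiles against a chi-square with one degree of freedom per
unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import chi2, ncx2

from .genes import tss_1based
from .panel import GenotypePanel
from .pathways import Pathway, PathwayCollection
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

P_FLOOR_DEFAULT = 1e-30


@dataclass
class GeneWindow:
    gene_name: str
    chrom: str
    window_start: int
    window_end: int
    member_snps: list


@dataclass
class LdMatrix:
    snp_ids: list
    R: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class GeneScore:
    gene_name: str
    n_snps: int
    T: float
    p_gene: float


# ----------------------------------------------------------- SNP mapping


def map_snps_to_genes(
    sumstats: SummaryStats, genes: pd.DataFrame, window_bp: int = 50_000
) -> list:
    """Assign SNPs to genes within +/- window_bp of each TSS.

    Windows are [TSS - window_bp, TSS + window_bp] clipped at position 1;
    a SNP may fall in several overlapping windows.  Genes whose window
    contains no SNP are omitted.
    """
    tss = tss_1based(genes)
    out = []
    by_chrom = {
        chrom: grp.sort_values("BP")
        for chrom, grp in sumstats.table.groupby("CHR", sort=False)
    }
    for (_, row), t in zip(genes.iterrows(), tss):
        grp = by_chrom.get(str(row["chrom"]))
        if grp is None:
            continue
        lo = max(1, t - window_bp)
        hi = t + window_bp
        pos = grp["BP"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi + 1])
        if i1 <= i0:
            continue
        out.append(
            GeneWindow(
                gene_name=row["name"],
                chrom=str(row["chrom"]),
                window_start=lo,
                window_end=hi,
                member_snps=list(grp["SNP"].iloc[i0:i1]),
            )
        )
    return out


def ld_for_window(
    panel: GenotypePanel, window: GeneWindow, eig_floor: float = 1e-8
) -> LdMatrix:
    """Empirical dosage correlation for a window's SNPs, with clipped spectrum."""
    present = [s for s in window.member_snps if s in panel]
    dropped = len(window.member_snps) - len(present)
    if dropped:
        logger.warning(
            "%s: %d window SNPs absent from the panel", window.gene_name, dropped
        )
    if not present:
        raise ValueError(f"{window.gene_name}: no window SNPs present in the panel")
    R = panel.ld(present)
    lam = np.linalg.eigvalsh(R)[::-1].copy()
    lam[lam < eig_floor] = 0.0
    return LdMatrix(snp_ids=present, R=R, eigenvalues=lam)


# ------------------------------------------------ weighted chi-square tail


def _imhof_sf(x: float, lam: np.ndarray, env_eps: float = 1e-8, max_pts: int = 2**20) -> float | None:
    """Imhof characteristic-function inversion on a fixed oscillation-scaled grid.

    The integrand sin(theta(u)) / (u * rho(u)) is integrated by Simpson's
    rule up to the point U where its envelope 1/(u rho(u)) drops below
    ``env_eps``, with an integration-by-parts correction for the oscillatory
    tail beyond U.  Returns None when no usable cutoff exists or the point
    budget is insufficient for the oscillation frequency.
    """
    ug = np.logspace(-3, 10, 500)
    log_env = -(np.log(ug) + 0.25 * np.log1p(np.outer(ug, lam) ** 2).sum(axis=1))
    idx = int(np.searchsorted(-log_env, -np.log(env_eps)))
    if idx >= ug.size:
        return None
    U = float(ug[idx])
    freq = 0.5 * (lam.sum() + x)
    n_needed = 16.0 * U * freq / np.pi
    if n_needed > max_pts:
        return None
    n = int(max(n_needed, 3001)) | 1
    u = np.linspace(0.0, U, n)
    theta = 0.5 * np.arctan(np.outer(u, lam)).sum(axis=1) - 0.5 * x * u
    log_rho = 0.25 * np.log1p(np.outer(u, lam) ** 2).sum(axis=1)
    f = np.empty(n)
    f[1:] = np.sin(theta[1:]) / (u[1:] * np.exp(log_rho[1:]))
    f[0] = 0.5 * (lam.sum() - x)  # analytic limit at u = 0
    val = integrate.simpson(f, x=u)
    g_U = 1.0 / (U * np.exp(log_rho[-1]))
    dtheta_U = 0.5 * np.sum(lam / (1.0 + (lam * U) ** 2)) - 0.5 * x
    val += g_U * np.cos(theta[-1]) / dtheta_U
    return 0.5 + val / np.pi


def _liu_sf(x: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang four-moment non-central chi-square approximation."""
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1 * s1 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 * s1 - s2))
        d = s1 * a**3 - a * a
        df = a * a - 2.0 * d
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        d = 0.0
    t = (x - c1) / np.sqrt(2.0 * c2) * np.sqrt(2.0) * np.sqrt(df + 2.0 * d) + df + d
    if d > 0:
        return float(ncx2.sf(t, df, d))
    return float(chi2.sf(t, df))


def weighted_chi2_sf(x: float, lam) -> float:
    """P(sum_j lambda_j chi2_1 > x) for non-negative weights ``lam``.

    Equal weights are handled in closed form (a scaled chi-square, covering
    the identity-LD and rank-one cases exactly).  Otherwise Imhof's
    characteristic-function inversion is used; in the deep tail, where the
    oscillatory integral's absolute error floor (~1e-8) swamps the result,
    the Liu-Tang-Zhang four-moment approximation takes over, and
    Satterthwaite moment matching (scale = sum lam^2 / sum lam,
    df = (sum lam)^2 / sum lam^2) remains the fallback when the inversion
    cannot be evaluated at all.
    """
    lam = np.asarray(lam, dtype=float)
    if (lam < 0).any():
        raise ValueError("weights must be non-negative")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all-zero weight vector")
    if x < 0:
        raise ValueError("x must be non-negative")
    if x == 0:
        return 1.0

    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(chi2.sf(x / lam[0], df=lam.size))

    try:
        p = _imhof_sf(x, lam)
    except FloatingPointError:
        p = None
    if p is None or not np.isfinite(p):
        s1 = lam.sum()
        s2 = (lam**2).sum()
        return float(chi2.sf(x * s1 / s2, df=s1 * s1 / s2))
    if p < 1e-7:
        return float(min(max(_liu_sf(x, lam), 1e-300), 1.0))
    return float(min(p, 1.0))


# ------------------------------------------------------------ gene scores


def gene_score(
    window: GeneWindow,
    sumstats: SummaryStats,
    ld: LdMatrix,
    p_floor: float = P_FLOOR_DEFAULT,
) -> GeneScore:
    """Score one gene: T = sum of chi2_1 quantiles at 1 - p_i, p from the LD spectrum."""
    pvals = sumstats.pvalues(ld.snp_ids).to_numpy(dtype=float)
    if (pvals <= 0).any():
        logger.warning("%s: p=0 input clipped to %g", window.gene_name, p_floor)
        pvals = np.clip(pvals, p_floor, 1.0)
    q = chi2.isf(pvals, df=1)
    T = float(q.sum())
    p_gene = weighted_chi2_sf(T, ld.eigenvalues)
    return GeneScore(gene_name=window.gene_name, n_snps=len(ld.snp_ids), T=T, p_gene=p_gene)


def score_genes(
    sumstats: SummaryStats,
    panel: GenotypePanel,
    genes: pd.DataFrame,
    window_bp: int = 50_000,
    p_floor: float = P_FLOOR_DEFAULT,
) -> tuple[pd.DataFrame, list]:
    """Score every gene with >=1 window SNP.

    Returns (table with columns ``gene n_snps T p_gene``, list of GeneWindow).
    """
    windows = map_snps_to_genes(sumstats, genes, window_bp=window_bp)
    rows = []
    kept_windows = []
    for w in windows:
        try:
            ld = ld_for_window(panel, w)
        except ValueError:
            logger.warning("%s: skipped (no panel SNPs)", w.gene_name)
            continue
        gs = gene_score(w, sumstats, ld, p_floor=p_floor)
        rows.append({"gene": gs.gene_name, "n_snps": gs.n_snps, "T": gs.T, "p_gene": gs.p_gene})
        kept_windows.append(w)
    return pd.DataFrame(rows, columns=["gene", "n_snps", "T", "p_gene"]), kept_windows


# --------------------------------------------------------- pathway scores


def _fuse_units(windows: list) -> list:
    """Group windows into meta-gene units: overlapping windows on one chromosome fuse."""
    units = []
    by_chrom: dict = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.window_start, w.window_end))
        current = [ws[0]]
        cur_end = ws[0].window_end
        for w in ws[1:]:
            if w.window_start <= cur_end:  # overlap -> same unit
                current.append(w)
                cur_end = max(cur_end, w.window_end)
            else:
                units.append(current)
                current = [w]
                cur_end = w.window_end
        units.append(current)
    return units


def pathway_score_genescore(
    gene_scores: pd.DataFrame,
    pathway: Pathway,
    windows: list,
    sumstats: SummaryStats,
    panel: GenotypePanel,
    p_floor: float = P_FLOOR_DEFAULT,
) -> tuple[float, int] | None:
    """Pathway p-value from gene scores with meta-gene fusion.

    Member genes with scores are grouped into units (see module docstring);
    a multi-gene unit is re-scored jointly over the union of its SNPs.  The
    pathway statistic is the sum over units of the chi2_1 quantile at
    1 - p_unit, referred to a chi-square with df = number of units.
    Returns (p_value, n_units), or None when no member gene was scored.
    """
    scored = gene_scores.set_index("gene")["p_gene"]
    member_windows = [
        w for w in windows if w.gene_name in pathway.genes and w.gene_name in scored.index
    ]
    if not member_windows:
        return None
    unit_ps = []
    for unit in _fuse_units(member_windows):
        if len(unit) == 1:
            unit_ps.append(float(scored[unit[0].gene_name]))
        else:
            snp_union = sorted(set().union(*(w.member_snps for w in unit)))
            fused = GeneWindow(
                gene_name="+".join(w.gene_name for w in unit),
                chrom=unit[0].chrom,
                window_start=min(w.window_start for w in unit),
                window_end=max(w.window_end for w in unit),
                member_snps=snp_union,
            )
            ld = ld_for_window(panel, fused)
            unit_ps.append(gene_score(fused, sumstats, ld, p_floor=p_floor).p_gene)
    q = chi2.isf(np.clip(unit_ps, p_floor, 1.0), df=1)
    stat = float(q.sum())
    return float(chi2.sf(stat, df=len(unit_ps))), len(unit_ps)


def score_pathways(
    gene_scores: pd.DataFrame,
    windows: list,
    collection: PathwayCollection,
    sumstats: SummaryStats,
    panel: GenotypePanel,
    p_floor: float = P_FLOOR_DEFAULT,
) -> pd.DataFrame:
    """Pathway p-values for a whole collection: columns ``pathway n_units p``.

    Pathways with no scored member gene are reported with missing values
    (untested), not p = 1.
    """
    rows = []
    for pw in collection:
        res = pathway_score_genescore(
            gene_scores, pw, windows, sumstats, panel, p_floor=p_floor
        )
        if res is None:
            rows.append({"pathway": pw.name, "n_units": np.nan, "p": np.nan})
        else:
            p, n_units = res
            rows.append({"pathway": pw.name, "n_units": n_units, "p": p})
    return pd.DataFrame(rows, columns=["pathway", "n_units", "p"])
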