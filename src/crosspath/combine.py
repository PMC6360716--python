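"""Fisher's combined probability test across the two enrichment engines.

Both engines test the same hypothesis — that a pathway is associated with
the trait — so their p-values are merged per pathway per trait with
Fisher's method:

    chi2_{2k} = -2 * sum_i ln(p_i),    here k = 2,

referred to a chi-square distribution with 2k = 4 degrees of freedom.  A
pathway missing from either engine keeps its single available p-value but
gets no combined value (one-engine and two-engine evidence are never
mixed); such cells are excluded from downstream significance sets.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pathways import PathwayCollection

logger = logging.getLogger(__name__)

P_CLIP = 1e-30

COMBINED_COLUMNS = [
    "trait", "pathway", "p_method1", "p_method2", "chi2_stat", "p_combined", "robust",
]


def fisher_combine(p1: float, p2: float) -> float:
    """Combined p-value of two independent tests of one hypothesis (df = 4)."""
    for p in (p1, p2):
        if not math.isfinite(p) or p > 1 or p < 0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p1 == 0 or p2 == 0:
        logger.warning("p = 0 input clipped to %g before combining", P_CLIP)
    p1 = max(p1, P_CLIP)
    p2 = max(p2, P_CLIP)
    stat = -2.0 * (math.log(p1) + math.log(p2))
    return float(chi2.sf(stat, df=4))


def combine_matrix(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    pathways: PathwayCollection,
    alpha_robust: float = 0.01,
) -> pd.DataFrame:
    """Merge two per-(trait, pathway) p-value tables into the association matrix.

    Inputs need columns ``trait pathway p``.  Output is long format with
    ``trait pathway p_method1 p_method2 chi2_stat p_combined robust``; cells
    with only one engine's p keep it but have a missing combined value, and
    pathways outside the (pruned) collection are dropped with a warning.
    The ``robust`` flag marks pathways significant in BOTH engines at
    ``alpha_robust``.
    """
    frames = []
    for df, col in ((results1, "p_method1"), (results2, "p_method2")):
        f = df.rename(columns={"p": col})[["trait", "pathway", col]]
        frames.append(f.dropna(subset=[col]))
    merged = frames[0].merge(frames[1], on=["trait", "pathway"], how="outer")

    unknown = ~merged["pathway"].isin(pathways.names)
    if unknown.any():
        logger.warning(
            "%d result rows reference pathways outside the collection; dropped",
            unknown.sum(),
        )
        merged = merged[~unknown]
    both = merged["p_method1"].notna() & merged["p_method2"].notna()
    if not both.any():
        logger.warning("no (trait, pathway) cell has p-values from both engines")
    p1 = merged["p_method1"].clip(lower=P_CLIP)
    p2 = merged["p_method2"].clip(lower=P_CLIP)
    stat = np.where(both, -2.0 * (np.log(p1) + np.log(p2)), np.nan)
    merged["chi2_stat"] = stat
    merged["p_combined"] = np.where(both, chi2.sf(stat, df=4), np.nan)
    merged["robust"] = both & (merged["p_method1"] < alpha_robust) & (merged["p_method2"] < alpha_robust)
    return merged[COMBINED_COLUMNS].sort_values(["trait", "pathway"]).reset_index(drop=True)
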