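"""Trait-trait association from shared significant pathways.

For each trait the significant pathway set is {pathway : p_combined < alpha}
(default alpha = 0.01, strict).  For a pair of traits (a, b) with sets A and
B over a common universe of N pathways (pathways with a combined p-value in
BOTH traits), the 2x2 contingency table

        | in B        | not in B
  in A  | |A n B|     | |A n !B|
 not A  | |!A n B|    | |!A n !B|

is tested with a one-sided (enrichment) Fisher's Exact Test — the exact
hypergeometric tail P(X >= |A n B|).  Raw p-values are Benjamini–Hochberg
adjusted over all tested pairs.  The resulting trait-trait network has one
node per trait (annotated with its significant-pathway count) and an edge
wherever the adjusted p-value clears a threshold, weighted by
-log10(adjusted p) and labelled with the shared-pathway count.

Two unsupervised views of the same structure are provided: classical
(Torgerson) multidimensional scaling of the traits' -log10 p_combined
profiles under a Spearman-correlation distance, and Ward hierarchical
clustering of the trait-by-trait FET p-value matrix under the same
distance, exported as a Newick tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TraitPathwaySets:
    trait_a: str
    trait_b: str
    universe: frozenset
    set_a: frozenset
    set_b: frozenset
    alpha: float

    def __post_init__(self) -> None:
        if not self.set_a <= self.universe or not self.set_b <= self.universe:
            raise ValueError("significant sets must be subsets of the universe")


@dataclass
class TraitPairAssociation:
    trait_a: str
    trait_b: str
    n_shared: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    p_fet: float
    shared_pathways: list
    p_fet_adjusted: float | None = None

    @property
    def N(self) -> int:
        return self.n_shared + self.n_a_only + self.n_b_only + self.n_neither


# ---------------------------------------------------------- significance


def significant_sets(matrix: pd.DataFrame, alpha: float = 0.01) -> dict:
    """Per-trait significant pathway sets {pathway : p_combined < alpha}.

    ``matrix`` is the long-format combined table (``trait pathway
    p_combined`` columns required).  Traits with zero tested (non-missing)
    pathways are excluded with a warning.  Pair universes are computed
    separately (see :func:`fet_pair`) from pathways tested in both traits.
    """
    sets = {}
    for trait, grp in matrix.groupby("trait", sort=False):
        tested = grp.dropna(subset=["p_combined"])
        if tested.empty:
            logger.warning("trait %s has no tested pathways; excluded", trait)
            continue
        sets[trait] = frozenset(tested.loc[tested["p_combined"] < alpha, "pathway"])
    return sets


def pair_universe(matrix: pd.DataFrame, trait_a: str, trait_b: str) -> frozenset:
    """Pathways with a non-missing combined p-value in both traits."""
    tested = matrix.dropna(subset=["p_combined"])
    a = set(tested.loc[tested["trait"] == trait_a, "pathway"])
    b = set(tested.loc[tested["trait"] == trait_b, "pathway"])
    return frozenset(a & b)


# ------------------------------------------------------------------- FET


def fet_pair(sets: TraitPathwaySets) -> TraitPairAssociation:
    """One-sided (enrichment) Fisher's Exact Test on the pair's 2x2 table.

    Exact hypergeometric tail P(X >= |A n B|); a degenerate table (either
    set empty) yields p = 1.
    """
    N = len(sets.universe)
    if N < 1:
        raise ValueError("empty pathway universe for this pair")
    A = sets.set_a
    B = sets.set_b
    shared = sorted(A & B)
    k = len(shared)
    if not A or not B:
        p = 1.0
    else:
        p = float(hypergeom.sf(k - 1, N, len(A), len(B)))
    return TraitPairAssociation(
        trait_a=sets.trait_a,
        trait_b=sets.trait_b,
        n_shared=k,
        n_a_only=len(A) - k,
        n_b_only=len(B) - k,
        n_neither=N - len(A) - len(B) + k,
        p_fet=min(p, 1.0),
        shared_pathways=shared,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def all_trait_pairs(
    matrix: pd.DataFrame, alpha: float = 0.01
) -> tuple[list, pd.DataFrame]:
    """FET across every trait pair, BH-adjusted over all tested pairs.

    Returns the list of :class:`TraitPairAssociation` (adjusted p filled in)
    and the pair table (``trait_a trait_b n_shared nA nB N p_fet
    p_fet_adjusted shared_pathways``).
    """
    sig = significant_sets(matrix, alpha=alpha)
    traits = sorted(sig)
    pairs = []
    for a, b in combinations(traits, 2):
        universe = pair_universe(matrix, a, b)
        if not universe:
            logger.warning("pair (%s, %s) shares no tested pathways; skipped", a, b)
            continue
        sets = TraitPathwaySets(
            trait_a=a, trait_b=b, universe=universe,
            set_a=frozenset(sig[a] & universe), set_b=frozenset(sig[b] & universe),
            alpha=alpha,
        )
        pairs.append(fet_pair(sets))
    adj = bh_adjust([p.p_fet for p in pairs])
    for p, q in zip(pairs, adj):
        p.p_fet_adjusted = float(q)
    table = pd.DataFrame(
        {
            "trait_a": [p.trait_a for p in pairs],
            "trait_b": [p.trait_b for p in pairs],
            "n_shared": [p.n_shared for p in pairs],
            "nA": [p.n_shared + p.n_a_only for p in pairs],
            "nB": [p.n_shared + p.n_b_only for p in pairs],
            "N": [p.N for p in pairs],
            "p_fet": [p.p_fet for p in pairs],
            "p_fet_adjusted": [p.p_fet_adjusted for p in pairs],
            "shared_pathways": [";".join(p.shared_pathways) for p in pairs],
        }
    )
    return pairs, table


# ---------------------------------------------------------------- network


def build_network(
    pairs: list,
    node_meta: pd.DataFrame | dict | None = None,
    threshold: float = 0.01,
) -> nx.Graph:
    """Trait-trait network at one adjusted-p threshold.

    Every trait appearing in ``pairs`` becomes a node (isolated nodes are
    kept); ``node_meta`` may map trait -> dict of attributes (e.g. group,
    n_significant_pathways).  Edges require adjusted p < threshold AND a
    positive shared-pathway count; weight = -log10(adjusted p).
    """
    g = nx.Graph(threshold=threshold)
    traits = sorted({p.trait_a for p in pairs} | {p.trait_b for p in pairs})
    meta = {}
    if isinstance(node_meta, pd.DataFrame):
        meta = node_meta.set_index("trait").to_dict(orient="index")
    elif isinstance(node_meta, dict):
        meta = node_meta
    for t in traits:
        g.add_node(t, **meta.get(t, {}))
    for p in pairs:
        if p.p_fet_adjusted is None:
            raise ValueError("pairs must be BH-adjusted before network construction")
        if p.p_fet_adjusted < threshold and p.n_shared > 0:
            g.add_edge(
                p.trait_a,
                p.trait_b,
                p_adjusted=p.p_fet_adjusted,
                weight=float(-np.log10(p.p_fet_adjusted)),
                n_shared=p.n_shared,
            )
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"trait_a": a, "trait_b": b, **attrs} for a, b, attrs in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "p_adjusted", "weight", "n_shared"])


# -------------------------------------------------------------- embedding


def _spearman_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman correlation between rows, pairwise-complete; undefined -> 1."""
    corr = profiles.T.corr(method="spearman")  # pandas is pairwise-complete
    if corr.isna().any().any():
        logger.warning("undefined Spearman correlation (constant profile); distance set to 1")
    dist = 1.0 - corr.fillna(0.0)
    np.fill_diagonal(dist.values, 0.0)
    return dist


def mds_embed(matrix: pd.DataFrame, dimensions: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classical MDS of traits from their -log10 p_combined profiles.

    The trait-trait distance is 1 - rho with rho the Spearman correlation of
    -log10 p_combined vectors over the common pathway universe (missing
    values pairwise-complete).  Returns (coordinates, distance matrix).
    """
    wide = matrix.pivot(index="trait", columns="pathway", values="p_combined")
    if len(wide) < 3:
        raise ValueError("MDS needs at least 3 traits")
    profiles = -np.log10(wide)
    dist = _spearman_distance(profiles)

    D2 = dist.to_numpy() ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dimensions]
    coords = V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    out = pd.DataFrame(
        coords, index=wide.index, columns=[f"dim{i + 1}" for i in range(dimensions)]
    ).reset_index()
    return out, dist


# -------------------------------------------------------------- clustering


def cluster_traits(fet_matrix: pd.DataFrame) -> tuple[np.ndarray, str]:
    """Ward clustering of traits on rows of the symmetric FET p-value matrix.

    Row distance is 1 - Spearman correlation (constant rows -> distance 1
    with a warning).  Returns (scipy linkage matrix, Newick string with
    branch lengths from the merge heights).
    """
    if fet_matrix.shape[0] != fet_matrix.shape[1]:
        raise ValueError("FET matrix must be square")
    if not np.allclose(fet_matrix.to_numpy(), fet_matrix.to_numpy().T, equal_nan=True):
        raise ValueError("FET matrix must be symmetric")
    if fet_matrix.shape[0] < 2:
        raise ValueError("need at least 2 traits to cluster")
    dist = _spearman_distance(fet_matrix)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = linkage(condensed, method="ward")
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, id_list=list(fet_matrix.index))
    return Z, str(tree).strip()


def fet_p_matrix(pairs: list) -> pd.DataFrame:
    """Symmetric trait x trait matrix of raw FET p-values.

    The diagonal is set to the minimum observed p (a trait is maximally
    associated with itself without introducing zeros).
    """
    traits = sorted({p.trait_a for p in pairs} | {p.trait_b for p in pairs})
    m = pd.DataFrame(1.0, index=traits, columns=traits)
    for p in pairs:
        m.loc[p.trait_a, p.trait_b] = p.p_fet
        m.loc[p.trait_b, p.trait_a] = p.p_fet
    np.fill_diagonal(m.values, min((p.p_fet for p in pairs), default=1.0))
    return m
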