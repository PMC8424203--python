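"""Taxonomic and phylogenetic alpha- and beta-diversity.

Alpha diversity covers richness, Shannon entropy (natural log by
default) and Faith's phylogenetic diversity.  The two beta-diversity
metrics — Bray-Curtis dissimilarity and the beta mean nearest taxon
distance (betaMNTD) — are the observed statistics that the downstream
null models (RC_bray, betaNTI) standardise against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd

from .community_data import CountTable, PairwiseMatrix, patristic_distances

__all__ = ["alpha_diversity", "bray_curtis", "beta_mntd", "beta_mntd_from_distances"]


def alpha_diversity(
    table: CountTable,
    tree: TreeNode | None = None,
    log_base: float | None = None,
    include_root: bool = True,
) -> pd.DataFrame:
    """Per-sample richness, Shannon diversity, and (with a tree) Faith's PD.

    Shannon is H = -sum(p ln p) in nats unless ``log_base`` is given.
    Faith's PD is the total branch length of the minimal subtree spanning
    the sample's observed tips; by rooted convention the path to the root
    is included (``include_root=False`` drops the stem above the tips'
    most recent common ancestor).
    """
    counts = table.counts().astype(float)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    if log_base is not None:
        shannon = shannon / np.log(log_base)
    out = pd.DataFrame(
        {
            "richness": (counts > 0).sum(axis=1).astype(int),
            "shannon": shannon,
        },
        index=table.sample_ids,
    )
    if tree is not None:
        pds = []
        for i in range(table.n_samples):
            pds.append(faith_pd(counts[i], taxa=table.taxon_ids, tree=tree))
        out["faith_pd"] = pds
        if not include_root:
            # subtract the stem: distance from root to the observed tips' MRCA
            stems = []
            for i in range(table.n_samples):
                tips = [table.taxon_ids[k] for k in np.nonzero(counts[i])[0]]
                node = tree.lca(tips) if len(tips) > 1 else tree.find(tips[0])
                stems.append(node.accumulate_to_ancestor(tree))
            out["faith_pd"] = out["faith_pd"] - np.asarray(stems)
    return out


def bray_curtis(table: CountTable, normalize: bool = False) -> PairwiseMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC_ij = 1 - 2 sum_k min(x_ik, x_jk) / sum_k (x_ik + x_jk).  With
    ``normalize=True`` counts are converted to relative abundances first
    (making the metric scale-invariant per sample); the default uses the
    counts as given, which is appropriate after rarefaction.
    """
    x = table.relative_abundance() if normalize else table.counts().astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    return PairwiseMatrix(table.sample_ids, d, "bray_curtis")


def _nearest_taxon_mins(d: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """mins[k, j] = min over taxa l present in sample j of d[k, l]."""
    n_taxa, n_samples = d.shape[0], presence.shape[0]
    mins = np.empty((n_taxa, n_samples))
    for j in range(n_samples):
        mins[:, j] = d[:, presence[j]].min(axis=1)
    return mins


def beta_mntd_from_distances(
    weights: np.ndarray, presence: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """betaMNTD for all sample pairs given taxon-taxon distances ``d``.

    ``weights`` is the (samples x taxa) abundance-weight matrix (zero for
    absent taxa, rows summing to 1); ``presence`` the boolean occurrence
    matrix.  Returns the symmetric (samples x samples) matrix
    0.5 * (W @ mins + (W @ mins)^T) where mins[k, j] is the distance from
    taxon k to its nearest neighbour present in sample j.
    """
    mins = _nearest_taxon_mins(d, presence)
    half = weights @ mins
    return 0.5 * (half + half.T)


def beta_mntd(table: CountTable, tree: TreeNode, weighted: bool = True) -> PairwiseMatrix:
    """Beta mean nearest taxon distance between all sample pairs.

    For samples i, j:
    betaMNTD_ij = 0.5 * [ sum_k f_ik min_{l in j} d_kl
                        + sum_k f_jk min_{l in i} d_kl ]
    with f the relative abundance if ``weighted`` else 1/richness, and d
    the patristic distance.  A taxon shared by both samples has nearest
    neighbour distance 0 (itself).
    """
    d = patristic_distances(tree, table.taxon_ids).values
    presence = table.presence()
    if weighted:
        weights = table.relative_abundance()
    else:
        weights = presence / presence.sum(axis=1, keepdims=True)
    vals = beta_mntd_from_distances(weights, presence, d)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(table.sample_ids, vals, "beta_mntd")
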