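"""Stochasticity quantification: NST, Sloan neutral model, niche breadth,
and the phylogenetic-signal Mantel correlogram.

The normalized stochasticity ratio (NST) compares observed pairwise
dissimilarity with its null expectation under a richness- and
abundance-constrained null (the same engine as RC_bray) and maps the
result onto [0, 1], with 50% as the conventional boundary between more
deterministic (<50%) and more stochastic (>50%) assembly.

The Sloan neutral community model predicts a taxon's occurrence
frequency across local communities from its mean relative abundance,
with a single free parameter Nm (community size x migration rate);
the fit is by nonlinear least squares on the frequency curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from statsmodels.stats.proportion import proportion_confint

from .community_data import CountTable, PairwiseMatrix, patristic_distances
from .null_models import NullEnsembleSpec, null_community_ensemble, _bray_curtis_rows

logger = logging.getLogger(__name__)

__all__ = [
    "NSTResult",
    "NeutralFit",
    "NicheBreadthResult",
    "CorrelogramResult",
    "nst",
    "sloan_fit",
    "sloan_frequency",
    "levins_breadth",
    "niche_values",
    "mantel_correlogram",
    "phylo_signal_correlogram",
]


# ---------------------------------------------------------------------
# NST
# ---------------------------------------------------------------------

@dataclass
class NSTResult:
    pairs: pd.DataFrame        # sample_i, sample_j, group, observed, expected, nst
    group_nst: dict[str, float]  # percent, mean over within-group pairs
    metric: str
    n_null: int
    seed: int
    n_excluded: int


def _jaccard_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    pa, pb = a > 0, b > 0
    union = (pa | pb).sum(axis=1)
    inter = (pa & pb).sum(axis=1)
    return 1.0 - inter / union


_ROW_METRICS = {"bray_curtis": _bray_curtis_rows, "jaccard": _jaccard_rows}


def nst(
    table: CountTable,
    groups: dict[str, list[str]] | pd.Series,
    metric: str = "bray_curtis",
    spec: NullEnsembleSpec | None = None,
    pool: str = "group",
) -> NSTResult:
    """Normalized stochasticity ratio per within-group sample pair.

    For each pair: D is the observed dissimilarity and E the mean
    dissimilarity over null community pairs that preserve each sample's
    richness and total abundance (taxa drawn proportionally to regional
    occupancy, abundance proportional to regional relative abundance).
    The selection strength is

        SS = (D - E) / (D_max - E)   if D >= E   (D_max = 1)
        SS = (E - D) / E             if D <  E

    and NST = 1 - SS, in [0, 1].  The group NST is the arithmetic mean
    of within-group pairwise values, reported in percent.  Pairs where
    E is 0 or 1 are undefined and excluded with a warning.

    ``pool`` controls where the null's occupancy and abundance weights
    come from: each group's own samples (``"group"``, the default — a
    group is judged against its own species pool, as in the standard
    NST convention) or the whole table (``"whole"``).
    """
    spec = spec or NullEnsembleSpec()
    if metric not in _ROW_METRICS:
        raise ValueError(f"metric must be one of {sorted(_ROW_METRICS)}")
    if pool not in ("group", "whole"):
        raise ValueError("pool must be 'group' or 'whole'")
    dissim = _ROW_METRICS[metric]

    if isinstance(groups, pd.Series):
        groups = {g: list(idx) for g, idx in groups.groupby(groups).groups.items()}
    for g, members in groups.items():
        if len(members) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    counts = table.counts()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    index = {s: k for k, s in enumerate(table.sample_ids)}

    def pool_weights(member_rows: np.ndarray):
        occ = (member_rows > 0).mean(axis=0)
        ab = member_rows.sum(axis=0).astype(float)
        return occ, ab / ab.sum()

    whole_occ, whole_ab = pool_weights(counts)

    rows = []
    n_excluded = 0
    pair_index = 0
    for g in sorted(groups):
        members = list(groups[g])
        if pool == "group":
            occupancy, rel_abundance = pool_weights(
                counts[[index[m] for m in members]])
        else:
            occupancy, rel_abundance = whole_occ, whole_ab
        for a_pos in range(len(members)):
            for b_pos in range(a_pos + 1, len(members)):
                i, j = index[members[a_pos]], index[members[b_pos]]
                rng = spec.pair_rng(pair_index)
                pair_index += 1
                null_i = null_community_ensemble(
                    rng, int(richness[i]), int(totals[i]),
                    occupancy, rel_abundance, spec.n_null,
                )
                null_j = null_community_ensemble(
                    rng, int(richness[j]), int(totals[j]),
                    occupancy, rel_abundance, spec.n_null,
                )
                e = float(dissim(null_i, null_j).mean())
                d = float(dissim(counts[i:i + 1], counts[j:j + 1])[0])
                if e <= 0.0 or e >= 1.0:
                    n_excluded += 1
                    logger.warning(
                        "nst: pair (%s, %s) has degenerate null expectation %.3f; excluded",
                        members[a_pos], members[b_pos], e,
                    )
                    continue
                ss = (d - e) / (1.0 - e) if d >= e else (e - d) / e
                rows.append((members[a_pos], members[b_pos], g, d, e, 1.0 - ss))

    pairs = pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "group", "observed", "expected", "nst"]
    )
    group_nst = {
        g: float(sub["nst"].mean() * 100.0) for g, sub in pairs.groupby("group")
    }
    return NSTResult(
        pairs=pairs, group_nst=group_nst, metric=metric,
        n_null=spec.n_null, seed=spec.seed, n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------

@dataclass
class NeutralFit:
    nm: float                 # N * m
    m: float                  # migration probability (Nm / N)
    r2: float
    n_samples: int
    community_size: float     # N = mean total counts per sample
    detection_limit: float
    taxa: pd.DataFrame        # p, freq_obs, freq_pred, lower, upper, position
    fraction_inside: float


def sloan_frequency(p: np.ndarray, nm: float, d: float) -> np.ndarray:
    """Predicted occurrence frequency for mean relative abundance ``p``.

    F(p) = 1 - I_d(Nm*p, Nm*(1-p)) where I is the regularized incomplete
    beta function (the Beta CDF at the detection limit d): the stationary
    local abundance of a taxon under neutral drift with immigration is
    Beta(Nm*p, Nm*(1-p)), and the taxon is detected when its local
    relative abundance exceeds d.
    """
    p = np.asarray(p, dtype=float)
    a = np.maximum(nm * p, 1e-12)
    b = np.maximum(nm * (1.0 - p), 1e-12)
    return 1.0 - special.betainc(a, b, d)


def sloan_fit(table: CountTable, detection_limit: float | str = "auto") -> NeutralFit:
    """Fit the Sloan neutral community model to occurrence frequencies.

    Taxa are characterised by mean relative abundance p (over samples)
    and observed occurrence frequency (fraction of samples occupied).
    Nm is fitted by least squares of observed vs predicted frequency,
    searched on a log scale within [1e-3 * N, 1e6].  The 95% prediction
    band is the Wilson binomial interval for the predicted frequency at
    the realised number of samples.
    """
    counts = table.counts().astype(float)
    n_samples, n_taxa = counts.shape
    if n_taxa < 10:
        raise ValueError("need at least 10 taxa for a neutral-model fit")
    community_size = float(counts.sum(axis=1).mean())
    d = 1.0 / community_size if detection_limit == "auto" else float(detection_limit)

    rel = counts / counts.sum(axis=1, keepdims=True)
    p = rel.mean(axis=0)
    freq = (counts > 0).mean(axis=0)
    if np.allclose(freq, 1.0):
        raise ValueError("every taxon occurs in every sample; frequency variance is zero")

    def sse(log_nm: float) -> float:
        resid = freq - sloan_frequency(p, np.exp(log_nm), d)
        return float(resid @ resid)

    lo, hi = np.log(1e-3 * community_size), np.log(1e6)
    res = optimize.minimize_scalar(
        sse, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"Sloan fit did not converge in Nm bracket [{np.exp(lo):.3g}, {np.exp(hi):.3g}]"
        )
    nm = float(np.exp(res.x))
    pred = sloan_frequency(p, nm, d)
    ss_res = float(np.sum((freq - pred) ** 2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    lower, upper = proportion_confint(
        pred * n_samples, n_samples, alpha=0.05, method="wilson"
    )
    position = np.where(freq > upper, "above", np.where(freq < lower, "below", "inside"))
    taxa = pd.DataFrame(
        {
            "p": p, "freq_obs": freq, "freq_pred": pred,
            "lower": lower, "upper": upper, "position": position,
        },
        index=table.taxon_ids,
    )
    return NeutralFit(
        nm=nm, m=nm / community_size, r2=r2,
        n_samples=n_samples, community_size=community_size,
        detection_limit=d, taxa=taxa,
        fraction_inside=float((position == "inside").mean()),
    )


# ---------------------------------------------------------------------
# Levins' niche breadth
# ---------------------------------------------------------------------

@dataclass
class NicheBreadthResult:
    per_taxon: pd.Series
    bcom: float


def levins_breadth(table: CountTable) -> NicheBreadthResult:
    """Levins' niche breadth B per taxon and the community mean Bcom.

    For taxon i with distribution q_ij = x_ij / sum_j x_ij across
    samples j, B_i = 1 / sum_j q_ij^2 (inverse Simpson concentration of
    the taxon across habitats): 1 for a taxon confined to one sample, up
    to the number of samples for a uniformly spread taxon.
    """
    x = table.counts().astype(float)
    present = x.sum(axis=0) > 0
    if not present.all():
        raise ValueError("table contains all-zero taxa; drop them first")
    q = x / x.sum(axis=0, keepdims=True)
    b = 1.0 / (q**2).sum(axis=0)
    per_taxon = pd.Series(b, index=table.taxon_ids, name="levins_b")
    return NicheBreadthResult(per_taxon=per_taxon, bcom=float(per_taxon.mean()))


# ---------------------------------------------------------------------
# Phylogenetic-signal Mantel correlogram
# ---------------------------------------------------------------------

@dataclass
class CorrelogramResult:
    classes: pd.DataFrame   # lower, upper, midpoint, n_pairs, r, p, p_corrected
    n_perm: int
    seed: int
    n_taxa: int
    defined: bool


def _mantel_r_classes(cond_niche: np.ndarray, class_of_pair: np.ndarray,
                      n_classes: int) -> np.ndarray:
    """Mantel r of the niche-distance vector against each class indicator.

    The sign is flipped so that, as in a spatial correlogram, a positive
    value at short phylogenetic distance means close relatives have
    similar niches.
    """
    z = (cond_niche - cond_niche.mean()) / cond_niche.std()
    out = np.empty(n_classes)
    for k in range(n_classes):
        ind = (class_of_pair == k).astype(float)
        sd = ind.std()
        if sd == 0:
            out[k] = np.nan
            continue
        zi = (ind - ind.mean()) / sd
        out[k] = -float(np.mean(z * zi))
    return out


def niche_values(table: CountTable, env: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean environment per taxon (taxa x variables).

    Environmental columns are z-scored first; the niche value of taxon
    i for variable v is sum_j (x_ij / sum_j x_ij) * env_jv.  Taxa
    occurring in fewer than 2 samples are excluded with a warning.
    """
    occ = (table.counts() > 0).sum(axis=0)
    keep = occ >= 2
    if not keep.all():
        logger.warning("niche_values: excluding %d taxa occurring in < 2 samples",
                       int((~keep).sum()))
    sub = CountTable(table.data.loc[:, table.data.columns[keep]])
    sd = env.std(ddof=0)
    envz = (env - env.mean()) / sd.where(sd > 0, 1.0)  # constant column -> all 0
    envz = envz.loc[sub.sample_ids]
    x = sub.counts().astype(float)
    w = x / x.sum(axis=0, keepdims=True)           # per-taxon distribution over samples
    return pd.DataFrame(w.T @ envz.to_numpy(), index=sub.taxon_ids,
                        columns=env.columns)


def phylo_signal_correlogram(
    table: CountTable,
    tree: TreeNode,
    env: pd.DataFrame,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
    min_pairs: int = 30,
) -> CorrelogramResult:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Environmental variables are z-scored per column; the niche value of
    taxon i for variable v is its abundance-weighted mean of env_v over
    samples.  Taxon-taxon niche distance is Euclidean over variables.
    Phylogenetic distances are binned into equal-width classes (Sturges'
    rule by default; classes with fewer than ``min_pairs`` pairs are
    dropped), and for each class a Mantel correlation between the niche
    distance matrix and the class-membership indicator is computed with
    a two-sided taxon-label permutation test and progressive Holm
    correction across classes (shortest class first).
    """
    niche = niche_values(table, env)
    return mantel_correlogram(niche, tree, n_classes=n_classes, n_perm=n_perm,
                              seed=seed, min_pairs=min_pairs)


def mantel_correlogram(
    niche: pd.DataFrame,
    tree: TreeNode,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
    min_pairs: int = 30,
) -> CorrelogramResult:
    """Per-distance-class Mantel test of niche vs phylogenetic distance.

    ``niche`` holds one row per taxon (tree tip) and one column per
    niche axis; see :func:`phylo_signal_correlogram` for the binning,
    permutation and correction conventions.
    """
    n_tax = niche.shape[0]
    cond_niche = pdist(niche.to_numpy(), metric="euclidean")
    if cond_niche.std() == 0:
        logger.warning("correlogram: zero variance in niche distances; undefined")
        return CorrelogramResult(
            classes=pd.DataFrame(), n_perm=n_perm, seed=seed,
            n_taxa=n_tax, defined=False,
        )

    d_phylo = patristic_distances(tree, list(niche.index)).values
    iu = np.triu_indices(n_tax, k=1)
    cond_phylo = d_phylo[iu]
    n_pairs_total = cond_phylo.size
    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(n_pairs_total)))   # Sturges
    edges = np.linspace(cond_phylo.min(), cond_phylo.max(), n_classes + 1)
    class_of_pair = np.clip(np.searchsorted(edges, cond_phylo, side="right") - 1,
                            0, n_classes - 1)

    counts = np.bincount(class_of_pair, minlength=n_classes)
    kept_classes = [k for k in range(n_classes) if counts[k] >= min_pairs]
    if not kept_classes:
        raise ValueError(
            f"no distance class holds >= {min_pairs} pairs; lower min_pairs or n_classes"
        )

    r_obs = _mantel_r_classes(cond_niche, class_of_pair, n_classes)

    rng = np.random.default_rng(seed)
    n = n_tax
    niche_sq = squareform(cond_niche)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cond_perm = niche_sq[np.ix_(perm, perm)][iu]
        r_perm = _mantel_r_classes(cond_perm, class_of_pair, n_classes)
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-15
    p = (exceed + 1.0) / (n_perm + 1.0) if n_perm > 0 else np.full(n_classes, np.nan)

    rows = []
    p_kept = [p[k] for k in kept_classes]
    for rank, k in enumerate(kept_classes):
        if n_perm > 0:
            # progressive Holm: adjust p_k within the family of classes 1..k
            family = p_kept[: rank + 1]
            order = np.argsort(family)
            adj = np.maximum.accumulate(
                [family[o] * (len(family) - r) for r, o in enumerate(order)]
            )
            holm = np.empty(len(family))
            holm[order] = np.minimum(adj, 1.0)
            p_corr = float(holm[rank])
        else:
            p_corr = np.nan
        rows.append(
            (edges[k], edges[k + 1], 0.5 * (edges[k] + edges[k + 1]),
             int(counts[k]), float(r_obs[k]),
             float(p[k]) if n_perm > 0 else np.nan, p_corr)
        )
    classes = pd.DataFrame(
        rows, columns=["lower", "upper", "midpoint", "n_pairs", "r", "p", "p_corrected"]
    )
    return CorrelogramResult(
        classes=classes, n_perm=n_perm, seed=seed, n_taxa=n_tax, defined=True
    )
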