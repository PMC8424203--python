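"""Null-model statistics for community assembly inference.

Implements the two pairwise null-model statistics and the five-way
ecological process classification built on them:

* **betaNTI** — the z-score of observed betaMNTD against an ensemble of
  tip-label-shuffled phylogenies.  |betaNTI| > 2 indicates phylogenetic
  turnover significantly different from the stochastic expectation:
  betaNTI > 2 is variable selection, betaNTI < -2 homogeneous selection.
* **RC_bray** — Bray-Curtis-based Raup-Crick.  Null communities fix each
  sample's observed richness and total abundance; taxa enter the null
  sample with probability proportional to region-wide occupancy, and
  the remaining individuals are allocated proportionally to region-wide
  relative abundance.  RC_bray beyond +/-0.95 indicates turnover
  dominated by dispersal limitation (+) or homogenizing dispersal (-).

Pairs with |betaNTI| < 2 and |RC_bray| < 0.95 are "undominated".
Boundary values fall on the non-significant side (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community_data import CountTable, PairwiseMatrix, patristic_distances
from .diversity import beta_mntd_from_distances, bray_curtis

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsembleSpec",
    "ProcessSummary",
    "beta_nti",
    "raup_crick_bray",
    "classify_processes",
    "null_community_ensemble",
    "PROCESSES",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class NullEnsembleSpec:
    """Size and seeding of a null ensemble.

    ``n_null`` must be at least 99 for process classification; 999 is the
    conventional default.  The seed is recorded in every output so runs
    are reproducible.
    """

    n_null: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be positive")

    def pair_rng(self, pair_index: int) -> np.random.Generator:
        """Generator for one sample pair, independent of pair ordering."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(pair_index,))
        )


@dataclass
class ProcessSummary:
    """Per-pair process labels and group-level fractions.

    ``fractions`` are floats for convenience; ``fractions_exact`` holds
    the same ratios as :class:`fractions.Fraction` so they sum to 1
    exactly (every labeled pair is counted exactly once).
    """

    labels: pd.DataFrame  # columns: sample_i, sample_j, bnti, rc, process
    fractions: dict[str, float]
    fractions_exact: dict[str, Fraction]
    counts: dict[str, int]
    n_pairs: int
    n_excluded: int
    excluded_pairs: list = field(default_factory=list)

    @property
    def stochastic_fraction(self) -> float:
        return (
            self.fractions["dispersal_limitation"]
            + self.fractions["homogenizing_dispersal"]
            + self.fractions["undominated"]
        )

    @property
    def deterministic_fraction(self) -> float:
        return (
            self.fractions["variable_selection"]
            + self.fractions["homogeneous_selection"]
        )


# -- betaNTI -----------------------------------------------------------

def beta_nti(
    table: CountTable,
    tree: TreeNode,
    spec: NullEnsembleSpec | None = None,
    weighted: bool = True,
) -> PairwiseMatrix:
    """Beta nearest taxon index for all sample pairs.

    betaNTI_ij = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)
    where the null shuffles tip labels across all tips of the (matched)
    tree, leaving abundances untouched.  Each permutation is applied to
    the whole distance matrix at once, so every pair sees the same null
    ensemble and results do not depend on pair ordering.  Pairs whose
    null spread is zero (e.g. a star phylogeny) are undefined (NaN).

    The returned matrix carries ``obs``, ``null_mean`` and ``null_sd``
    in its ``extra`` dict.
    """
    spec = spec or NullEnsembleSpec()
    d = patristic_distances(tree, table.taxon_ids).values
    presence = table.presence()
    if weighted:
        weights = table.relative_abundance()
    else:
        weights = presence / presence.sum(axis=1, keepdims=True)

    obs = beta_mntd_from_distances(weights, presence, d)
    rng = np.random.default_rng(spec.seed)
    n_taxa = d.shape[0]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(spec.n_null):
        perm = rng.permutation(n_taxa)
        null = beta_mntd_from_distances(weights, presence, d[np.ix_(perm, perm)])
        total += null
        total_sq += null * null
    mean = total / spec.n_null
    var = total_sq / spec.n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = sd <= 1e-12
    z[degenerate] = np.nan
    np.fill_diagonal(z, np.nan)
    n_bad = int(np.triu(degenerate, k=1).sum())
    if n_bad:
        logger.warning("beta_nti: %d pairs with zero null spread flagged undefined", n_bad)
    return PairwiseMatrix(
        table.sample_ids,
        z,
        "beta_nti",
        extra={
            "obs": obs,
            "null_mean": mean,
            "null_sd": sd,
            "n_null": spec.n_null,
            "seed": spec.seed,
        },
    )


# -- RC_bray -----------------------------------------------------------

def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int, n_draws: int
) -> np.ndarray:
    """(n_draws, k) indices drawn without replacement, P(i) ~ weights.

    Uses the Gumbel top-k trick: adding i.i.d. Gumbel noise to log-weights
    and taking the k largest keys samples without replacement with the
    required probabilities.
    """
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    keys = logw + rng.gumbel(size=(n_draws, weights.size))
    return np.argpartition(-keys, k - 1, axis=1)[:, :k]


def null_community_ensemble(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occupancy: np.ndarray,
    rel_abundance: np.ndarray,
    n_null: int,
) -> np.ndarray:
    """Draw ``n_null`` null communities constrained to a sample's shape.

    Each null community has exactly ``richness`` taxa and ``total``
    individuals.  Taxa are first drawn without replacement with
    probability proportional to dataset-wide occupancy, seeded with one
    individual each; the remaining individuals are allocated to the
    drawn taxa multinomially with probability proportional to
    dataset-wide relative abundance.
    """
    n_taxa = occupancy.size
    chosen = _weighted_sample_without_replacement(rng, occupancy, richness, n_null)
    counts = np.zeros((n_null, n_taxa), dtype=np.int64)
    p = rel_abundance[chosen]
    p = p / p.sum(axis=1, keepdims=True)
    extra = rng.multinomial(total - richness, p)
    np.put_along_axis(counts, chosen, 1 + extra, axis=1)
    return counts


def _bray_curtis_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    shared = np.minimum(a, b).sum(axis=1)
    return 1.0 - 2.0 * shared / (a.sum(axis=1) + b.sum(axis=1))


def raup_crick_bray(
    table: CountTable,
    spec: NullEnsembleSpec | None = None,
    pool: CountTable | None = None,
) -> PairwiseMatrix:
    """Bray-Curtis-based Raup-Crick metric for all sample pairs.

    For each pair, ``n_null`` null community pairs are drawn (see
    :func:`null_community_ensemble`) and

    RC_bray = 2 * [ #(BC_null < BC_obs) + 0.5 * #(BC_null = BC_obs) ]
              / n_null - 1

    so RC_bray lies in [-1, 1], with ties counted at half weight to keep
    the statistic centred under the null.  Occupancy and abundance
    weights come from the whole analysed table ("regional pool"
    semantics); pass ``pool`` to use a different table as the pool.
    """
    spec = spec or NullEnsembleSpec()
    src = pool if pool is not None else table
    occupancy = src.presence().mean(axis=0)
    abund = src.counts().sum(axis=0).astype(float)
    rel_abundance = abund / abund.sum()
    # restrict the pool to taxa that can actually be drawn
    if (occupancy == 0).any():
        occupancy = np.where(occupancy > 0, occupancy, 0.0)

    counts = table.counts()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    obs_bc = bray_curtis(table).values

    n = table.n_samples
    rc = np.full((n, n), np.nan)
    pair_index = 0
    for i in range(n):
        for j in range(i + 1, n):
            rng = spec.pair_rng(pair_index)
            null_i = null_community_ensemble(
                rng, int(richness[i]), int(totals[i]), occupancy, rel_abundance, spec.n_null
            )
            null_j = null_community_ensemble(
                rng, int(richness[j]), int(totals[j]), occupancy, rel_abundance, spec.n_null
            )
            bc_null = _bray_curtis_rows(null_i, null_j)
            below = np.sum(bc_null < obs_bc[i, j] - 1e-12)
            ties = np.sum(np.abs(bc_null - obs_bc[i, j]) <= 1e-12)
            rc[i, j] = rc[j, i] = 2.0 * (below + 0.5 * ties) / spec.n_null - 1.0
            pair_index += 1
    return PairwiseMatrix(
        table.sample_ids,
        rc,
        "rc_bray",
        extra={"n_null": spec.n_null, "seed": spec.seed},
    )


# -- classification ----------------------------------------------------

def _label_pair(bnti: float, rc: float) -> str:
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_processes(
    bnti: PairwiseMatrix,
    rc: PairwiseMatrix,
    pairs: list[tuple[str, str]] | None = None,
) -> ProcessSummary:
    """Assign each sample pair to one of five assembly processes.

    Selection dominates when |betaNTI| > 2 (variable if positive,
    homogeneous if negative); otherwise RC_bray beyond +/-0.95 assigns
    dispersal limitation (+) or homogenizing dispersal (-); remaining
    pairs are undominated.  Boundary values are non-significant.  Pairs
    with undefined betaNTI are excluded and counted separately.

    ``pairs`` restricts the summary (e.g. to within-treatment pairs);
    default is all pairs.
    """
    if bnti.ids != rc.ids:
        raise ValueError("betaNTI and RC matrices must share sample ids")
    ids = bnti.ids
    if pairs is None:
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]

    rows = []
    excluded = []
    for a, b in pairs:
        z = bnti.pair(a, b)
        r = rc.pair(a, b)
        if np.isnan(z):
            excluded.append((a, b))
            continue
        rows.append((a, b, z, r, _label_pair(z, r)))
    if excluded:
        logger.warning("classify_processes: %d pairs excluded (undefined betaNTI)",
                       len(excluded))
    labels = pd.DataFrame(rows, columns=["sample_i", "sample_j", "bnti", "rc", "process"])
    counts = {p: int((labels["process"] == p).sum()) for p in PROCESSES}
    n = len(labels)
    fractions = {p: (counts[p] / n if n else np.nan) for p in PROCESSES}
    exact = {p: (Fraction(counts[p], n) if n else Fraction(0)) for p in PROCESSES}
    return ProcessSummary(
        labels=labels,
        fractions=fractions,
        fractions_exact=exact,
        counts=counts,
        n_pairs=n,
        n_excluded=len(excluded),
        excluded_pairs=excluded,
    )
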