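"""Synthetic communities under known assembly regimes.

Generates phylogenies (Yule), phylogenetically conserved traits
(Brownian motion), and OTU tables under four regimes with known ground
truth, emulating a 2-site x 2-treatment x n-replicate field design:

* ``neutral`` — local communities are Dirichlet(N*m*p) draws around a
  log-series metacommunity, the stationary distribution of Sloan's
  neutral model, followed by multinomial sampling of N individuals.
* ``homogeneous_selection`` — a Brownian trait on the tree is filtered
  by a Gaussian kernel around one shared environmental optimum, pulling
  all communities toward the same clade.  Ecological drift (a Dirichlet
  layer around the filtered expectation) and a trickle of immigrants
  from the unfiltered metacommunity keep compositional turnover and the
  full regional taxon pool in play, as in real filtered communities.
* ``variable_selection`` — as above, but each sample has its own
  optimum along an environmental gradient, pushing communities apart.
* ``dispersal_limited`` — neutral dynamics, but sample clusters draw
  from isolated (independently shuffled) metacommunities.

Because traits evolve by Brownian motion, close relatives have similar
environmental preferences by construction — the phylogenetic-signal
precondition that the betaNTI framework requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community_data import CountTable

__all__ = [
    "RegimeSpec",
    "simulate_tree",
    "brownian_trait",
    "simulate_community",
    "simulate_study",
    "DEFAULT_CELL_REGIMES",
]

REGIMES = ("neutral", "homogeneous_selection", "variable_selection", "dispersal_limited")


@dataclass
class RegimeSpec:
    """Parameters of one simulated community set.

    ``community_size`` is the number of individuals per local community
    (multinomial size N); ``migration`` the immigration probability m of
    the neutral model (Nm = N * m); ``sigma`` the width of the Gaussian
    environmental filter in trait units; ``trait_rate`` the Brownian
    rate; ``env_gradient`` the per-sample selection optima (scalar =
    identical everywhere).  ``logseries_theta`` shapes the metacommunity
    species-abundance distribution.
    """

    regime: str = "neutral"
    n_samples: int = 12
    community_size: int = 5000
    migration: float = 0.3
    sigma: float = 0.25
    trait_rate: float = 1.0
    trait_depth_bias: float = 0.2
    env_gradient: float | np.ndarray = 0.0
    env_noise: float = 0.0
    immigration: float = 0.02
    drift_concentration: float = 20.0
    n_clusters: int = 3
    logseries_theta: float = 0.995
    metacommunity: np.ndarray | None = None   # shared SAD (else drawn from seed)
    trait: np.ndarray | None = None           # shared z-scored trait per tip
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if not 0 < self.migration <= 1:
            raise ValueError("migration must lie in (0, 1]")
        if self.regime.endswith("selection") and self.sigma <= 0:
            raise ValueError("sigma must be > 0 for selection regimes")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def simulate_tree(n_tips: int, model: str = "yule", seed: int = 0,
                  birth_rate: float = 1.0) -> TreeNode:
    """Simulate a rooted ultrametric Yule (pure-birth) tree.

    Tips are labelled t0001, t0002, ... in order of appearance.  The
    same seed always yields an identical Newick string.
    """
    if model != "yule":
        raise ValueError("only the Yule model is implemented")
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)

    root = TreeNode(name=None, length=None)
    active: list[tuple[TreeNode, float]] = []   # (node, birth time)
    for _ in range(2):
        child = TreeNode(length=0.0)
        root.append(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.length = t - born
        for _ in range(2):
            child = TreeNode(length=0.0)
            node.append(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))   # extend to the present
    for i, (node, born) in enumerate(active):
        node.length = t - born
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:04d}"
    return root


def brownian_trait(tree: TreeNode, rate: float = 1.0, seed: int = 0,
                   root_value: float = 0.0, depth_bias: float = 1.0) -> pd.Series:
    """Evolve a continuous trait along the tree by Brownian motion.

    Each branch adds a N(0, rate * branch_length) increment, so trait
    covariance between tips equals ``rate`` times shared path length —
    close relatives get similar values.

    ``depth_bias`` (Pagel's delta-style exponent on relative node
    depth) reshapes where divergence happens: values < 1 concentrate
    trait change on deep branches, so trait extremes coincide with
    whole clades rather than with convergent tips scattered over the
    tree; 1 leaves plain Brownian motion.
    """
    rng = np.random.default_rng(seed)
    depth = {id(tree): 0.0}
    total = 0.0
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + max(node.length or 0.0, 0.0)
        if node.is_tip():
            total = max(total, depth[id(node)])
    total = total or 1.0

    def eff(x: float) -> float:
        return (x / total) ** depth_bias * total

    values = {id(tree): root_value}
    for node in tree.preorder(include_self=False):
        length = eff(depth[id(node)]) - eff(depth[id(node.parent)])
        values[id(node)] = values[id(node.parent)] + rng.normal(
            0.0, np.sqrt(rate * max(length, 0.0))
        )
    return pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})


def _metacommunity(rng: np.random.Generator, n_taxa: int, theta: float) -> np.ndarray:
    """Log-series relative abundances (a realistic skewed SAD)."""
    raw = rng.logseries(theta, size=n_taxa).astype(float)
    return raw / raw.sum()


class _WindowScorer:
    """Scores how clade-like a trait filter window is.

    The score of a window is the mean nearest-neighbour patristic
    distance among its taxa divided by the same quantity for random
    taxon sets of equal size — below 1 means the window is more
    phylogenetically coherent than chance.
    """

    def __init__(self, tree: TreeNode, taxa: list[str], seed: int):
        from .community_data import patristic_distances

        self.d = patristic_distances(tree, taxa).values
        self.n_taxa = len(taxa)
        self.rng = np.random.default_rng(seed)
        self._random_cache: dict[int, float] = {}

    def mean_nnd(self, idx: np.ndarray) -> float:
        dv = self.d[np.ix_(idx, idx)] + np.diag(np.full(idx.size, np.inf))
        return float(dv.min(axis=1).mean())

    def random_nnd(self, k: int) -> float:
        key = max(10, int(round(k / 10.0)) * 10)
        if key not in self._random_cache:
            self._random_cache[key] = float(np.mean([
                self.mean_nnd(self.rng.choice(self.n_taxa, key, replace=False))
                for _ in range(6)
            ]))
        return self._random_cache[key]

    def best_window(self, trait: np.ndarray, sigma: float) -> tuple[float | None, float]:
        """Most coherent off-centre optimum for this trait, with its score.

        The window must hold 5-30% of the taxa: coherent AND large
        enough that communities can drift apart within it.
        """
        candidates = np.unique(trait[np.abs(trait) > 0.8])
        if candidates.size == 0:
            candidates = trait[np.argsort(-np.abs(trait))[:5]]
        if candidates.size > 25:
            candidates = candidates[
                np.linspace(0, candidates.size - 1, 25).astype(int)
            ]
        k_min = max(10, int(0.05 * self.n_taxa))
        k_max = max(k_min + 10, int(0.30 * self.n_taxa))
        best, best_score = None, np.inf
        for c in candidates:
            viable = np.abs(trait - c) < sigma
            k = int(viable.sum())
            if not k_min <= k <= k_max:
                continue
            score = self.mean_nnd(viable.nonzero()[0]) / self.random_nnd(k)
            if score < best_score:
                best, best_score = float(c), score
        return best, best_score


def _conserved_trait(
    tree: TreeNode,
    taxa: list[str],
    spec: RegimeSpec,
    rng: np.random.Generator,
    n_draws: int = 6,
) -> tuple[np.ndarray, float]:
    """Draw a conserved trait and locate a clade-level optimum for it.

    Selection regimes presuppose a phylogenetically conserved
    preference, so the generator conditions the Brownian realization on
    actually exhibiting one: several independent trait draws are scored
    by how phylogenetically coherent their best filter window is, and
    the most coherent draw wins.  Returns the z-scored trait and the
    chosen off-centre optimum.
    """
    scorer = _WindowScorer(tree, taxa, seed=spec.seed)
    best_trait, best_opt, best_score = None, 1.5, np.inf
    for _ in range(n_draws):
        trait = brownian_trait(
            tree, rate=spec.trait_rate, seed=int(rng.integers(2**31 - 1)),
            depth_bias=spec.trait_depth_bias,
        ).loc[taxa].to_numpy()
        trait = (trait - trait.mean()) / trait.std()
        opt, score = scorer.best_window(trait, spec.sigma)
        if opt is not None and score < best_score:
            best_trait, best_opt, best_score = trait, opt, score
    if best_trait is None:
        best_trait = trait
    return best_trait, best_opt


def simulate_community(
    tree: TreeNode,
    spec: RegimeSpec,
    sample_prefix: str = "s",
) -> tuple[CountTable, pd.DataFrame]:
    """Simulate one set of communities on ``tree`` under ``spec``.

    Returns a CountTable (rows summing exactly to ``community_size``)
    and per-sample metadata with the selection optimum (``env``),
    correlated soil covariates (``pH``, ``NO3``) and the regime label.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = [t.name for t in tree.tips()]
    n_taxa = len(taxa)
    n, big_n = spec.n_samples, spec.community_size
    if spec.metacommunity is not None:
        meta_p = np.asarray(spec.metacommunity, dtype=float)
        if meta_p.shape != (n_taxa,):
            raise ValueError("metacommunity must have one entry per tree tip")
        meta_p = meta_p / meta_p.sum()
    else:
        meta_p = _metacommunity(rng, n_taxa, spec.logseries_theta)

    env = np.broadcast_to(
        np.asarray(spec.env_gradient, dtype=float), (n,)
    ).copy() if np.ndim(spec.env_gradient) == 0 else np.asarray(spec.env_gradient, float)
    if env.shape != (n,):
        raise ValueError("env_gradient must be scalar or length n_samples")

    counts = np.zeros((n, n_taxa), dtype=np.int64)
    if spec.regime in ("neutral", "dispersal_limited"):
        if spec.regime == "dispersal_limited":
            cluster_of = np.arange(n) % spec.n_clusters
            pools = []
            for _ in range(spec.n_clusters):
                pools.append(meta_p[rng.permutation(n_taxa)])
        else:
            cluster_of = np.zeros(n, dtype=int)
            pools = [meta_p]
        nm = big_n * spec.migration
        for j in range(n):
            alpha = nm * pools[cluster_of[j]]
            pi = rng.dirichlet(np.maximum(alpha, 1e-10))
            counts[j] = rng.multinomial(big_n, pi)
    else:
        if spec.trait is not None:
            trait = np.asarray(spec.trait, dtype=float)
            if trait.shape != (n_taxa,):
                raise ValueError("trait must have one value per tree tip")
            best_opt, _ = _WindowScorer(tree, taxa, seed=spec.seed).best_window(
                trait, spec.sigma)
            if best_opt is None:
                best_opt = 1.5
        else:
            trait, best_opt = _conserved_trait(tree, taxa, spec, rng)
        if np.ptp(env) == 0:
            if spec.regime == "variable_selection":
                env = np.linspace(-1.5, 1.5, n)  # divergent optima
            elif np.all(env == 0):
                env = np.full(n, best_opt)
        # micro-habitat jitter: samples see slightly different conditions,
        # so abundances respond to the environment within a cell and taxa
        # acquire measurable realized niches
        if spec.env_noise > 0:
            env = env + rng.normal(0.0, spec.env_noise, n)
        n_resident = int(round(big_n * (1.0 - spec.immigration)))
        for j in range(n):
            fitness = np.exp(-((trait - env[j]) ** 2) / (2.0 * spec.sigma**2))
            total = fitness.sum()
            if total <= 0:
                raise ValueError("selection filter left no viable taxa; widen sigma")
            # trait matching sets the expected abundance of viable taxa;
            # sparse Dirichlet drift reshuffles which of them dominate in
            # each sample.  Immigrants arrive afterwards as a thin layer
            # proportional to the metacommunity SAD, keeping the regional
            # pool observable without ever drifting to dominance.
            pi = rng.dirichlet(np.maximum(spec.drift_concentration * fitness / total, 1e-10))
            counts[j] = rng.multinomial(n_resident, pi) + rng.multinomial(
                big_n - n_resident, meta_p
            )

    sample_ids = [f"{sample_prefix}{j + 1:02d}" for j in range(n)]
    table = CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxa)
    ).drop_empty_taxa()
    metadata = pd.DataFrame(
        {
            "env": env,
            "pH": 3.93 + 0.25 * env + rng.normal(0.0, 0.01, n),
            "NO3": 10.0 + 4.0 * env + rng.normal(0.0, 0.15, n),
            "regime": spec.regime,
        },
        index=sample_ids,
    )
    return table, metadata


def simulate_sloan_table(
    n_samples: int,
    n_taxa: int,
    nm: float,
    community_size: int = 1000,
    read_depth: int = 50000,
    logseries_theta: float = 0.995,
    seed: int = 0,
) -> CountTable:
    """Simulate counts exactly under the Sloan neutral model's law.

    Each sample's relative abundances are a Dirichlet(Nm * p) draw (so
    every taxon's marginal is the model's Beta(Nm*p, Nm*(1-p))).  A
    taxon is physically present when its local relative abundance
    reaches 1/community_size — exactly the model's detection
    assumption — and present taxa are observed at ``read_depth``
    (counts = round(pi * read_depth)), deep enough that mean relative
    abundance is estimated accurately.  Fit with
    ``detection_limit = 1 / community_size``.  Used as the
    parameter-recovery oracle for
    :func:`assemblyscope.stochasticity.sloan_fit`.
    """
    rng = np.random.default_rng(seed)
    meta_p = _metacommunity(rng, n_taxa, logseries_theta)
    pi = rng.dirichlet(np.maximum(nm * meta_p, 1e-10), size=n_samples)
    pi = np.where(pi >= 1.0 / community_size, pi, 0.0)
    counts = np.round(pi * read_depth).astype(np.int64)
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{j + 1:02d}" for j in range(n_samples)],
            columns=[f"t{k + 1:04d}" for k in range(n_taxa)],
        )
    ).drop_empty_taxa()


DEFAULT_CELL_REGIMES = {
    ("short", "control"): "homogeneous_selection",
    ("short", "N"): "neutral",
    ("long", "control"): "neutral",
    ("long", "N"): "homogeneous_selection",
}


def simulate_study(
    n_per_cell: int = 6,
    n_taxa: int = 600,
    cell_regimes: dict | None = None,
    community_size: int = 5000,
    selection_community_size: int = 1000,
    migration: float = 0.3,
    sigma: float = 0.25,
    env_noise: float = 0.15,
    ph_shift: float = -0.1,
    no3_shift: float = 0.56,
    seed: int = 0,
) -> tuple[CountTable, TreeNode, pd.DataFrame]:
    """Simulate a 2-site x 2-treatment study on a shared phylogeny.

    Each of the four cells (site x treatment) gets ``n_per_cell``
    samples under its configured regime; the default configuration
    makes N addition at the short-term site more neutral than its
    control, and mirrors it at the long-term site.  Neutral cells use
    ``community_size`` individuals per sample; selection cells use the
    smaller ``selection_community_size`` (sparser communities carry
    the clearer phylogenetic-clustering signal).  ``ph_shift`` is the
    additive pH effect of N addition and ``no3_shift`` the relative
    NO3 increase.  Returns (table, tree, metadata) with metadata
    columns site, treatment, env, pH, NO3, regime.
    """
    if n_per_cell < 3:
        raise ValueError("need at least 3 samples per cell")
    cell_regimes = dict(DEFAULT_CELL_REGIMES if cell_regimes is None else cell_regimes)
    root_seed = np.random.SeedSequence(seed)
    tree_seed, shared_seed, *cell_seeds = root_seed.spawn(len(cell_regimes) + 2)
    tree = simulate_tree(n_taxa, seed=int(tree_seed.generate_state(1)[0] % 2**31))

    # one regional species pool and one conserved trait span the whole
    # study, so taxa keep consistent identities (and realized niches)
    # across cells — the precondition for a dataset-level phylogenetic
    # signal, as in a real multi-site survey
    shared = int(shared_seed.generate_state(1)[0] % 2**31)
    shared_rng = np.random.default_rng(shared)
    taxa = [t.name for t in tree.tips()]
    meta_p = _metacommunity(shared_rng, n_taxa, 0.995)
    trait, _ = _conserved_trait(
        tree, taxa,
        RegimeSpec(regime="homogeneous_selection", sigma=sigma, seed=shared),
        shared_rng,
    )

    frames, metas = [], []
    for k, ((site, treatment), regime) in enumerate(sorted(cell_regimes.items())):
        cell_seed = int(cell_seeds[k].generate_state(1)[0] % 2**31)
        spec = RegimeSpec(
            regime=regime,
            n_samples=n_per_cell,
            community_size=(
                community_size
                if regime in ("neutral", "dispersal_limited")
                else selection_community_size
            ),
            migration=migration,
            sigma=sigma,
            env_gradient=0.0,
            env_noise=env_noise,
            metacommunity=meta_p,
            trait=trait,
            seed=cell_seed,
        )
        prefix = f"{site}_{treatment}_"
        table, meta = simulate_community(tree, spec, sample_prefix=prefix)
        rng = np.random.default_rng(cell_seed + 1)
        meta["site"] = site
        meta["treatment"] = treatment
        meta["cell"] = f"{site}_{treatment}"
        if treatment == "N":
            meta["pH"] = meta["pH"] + ph_shift
            meta["NO3"] = meta["NO3"] * (1.0 + no3_shift) + rng.normal(0, 0.2, len(meta))
        frames.append(table.data)
        metas.append(meta)

    combined = pd.concat(frames, axis=0).fillna(0).astype(np.int64)
    # restore tree tip order for stable column layout
    tip_order = [t.name for t in tree.tips() if t.name in combined.columns]
    table = CountTable(combined[tip_order])
    metadata = pd.concat(metas, axis=0).loc[table.sample_ids]
    return table, tree, metadata
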