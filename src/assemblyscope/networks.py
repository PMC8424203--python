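"""RMT-thresholded co-association networks and their topology.

Pipeline: square-root-transform the count table and keep only taxa
detected in more than half of the samples (majority rule); compute a
taxon-taxon correlation matrix; pick the similarity threshold St where
the eigenvalue nearest-neighbour spacing distribution (NNSD) of the
thresholded matrix transitions from Wigner-Dyson (correlated, random-
matrix-like) to Poisson (uncorrelated) statistics; build the signed
network from |r| >= St; summarise topology, compare against degree-
preserving randomizations, and classify node roles in Zi-Pi space
(module hubs, connectors, network hubs = putative keystone taxa).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community_data import CountTable, PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssocNetwork",
    "TopologyRecord",
    "prepare_nodes",
    "correlation_matrix",
    "rmt_threshold",
    "build_network",
    "topology",
    "zi_pi",
    "random_ensemble",
]


@dataclass
class AssocNetwork:
    """Signed undirected co-association network with module partition."""

    graph: nx.Graph               # edge attr: weight (signed r), sign (+1/-1)
    st: float
    modules: dict[str, int]       # node -> module id

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def module_sets(self) -> list[set]:
        out: dict[int, set] = {}
        for node, m in self.modules.items():
            out.setdefault(m, set()).add(node)
        return [out[m] for m in sorted(out)]


@dataclass
class TopologyRecord:
    metrics: dict[str, float]
    random_reference: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.metrics.items()]
        for k, (m, s) in self.random_reference.items():
            rows.append((f"random_{k}", f"{m:.3f} ({s:.3f})"))
        return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------
# node preparation and correlation
# ---------------------------------------------------------------------

def prepare_nodes(table: CountTable, min_fraction: float = 0.5) -> pd.DataFrame:
    """Square-root-transform counts and apply the majority rule.

    Only taxa detected in strictly more than ``min_fraction`` of the
    samples are kept (with the default 0.5, a taxon in 5 of 12 samples
    is removed, one in 7 of 12 retained).  Returns the transformed
    samples x taxa matrix used for correlation.
    """
    if table.n_samples < 6:
        raise ValueError("network construction needs at least 6 samples")
    frac = table.presence().mean(axis=0)
    keep = frac > min_fraction
    if keep.sum() < 2:
        raise ValueError("fewer than 2 taxa survive the majority rule")
    kept = table.data.loc[:, table.data.columns[keep]]
    return np.sqrt(kept.astype(float))


def correlation_matrix(prepared: pd.DataFrame, method: str = "pearson") -> PairwiseMatrix:
    """Taxon-taxon correlation of the prepared (transformed) table."""
    if method == "pearson":
        r = np.corrcoef(prepared.to_numpy().T)
    elif method == "spearman":
        ranks = stats.rankdata(prepared.to_numpy(), axis=0)
        r = np.corrcoef(ranks.T)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    np.fill_diagonal(r, 1.0)
    return PairwiseMatrix(list(prepared.columns), r, f"{method}_correlation")


# ---------------------------------------------------------------------
# RMT threshold
# ---------------------------------------------------------------------

def _nnsd_poisson_pvalue(
    eigenvalues: np.ndarray,
    dedup_tol: float = 1e-8,
    window: int = 5,
    s_max: float = 3.0,
    n_bins: int = 20,
) -> tuple[float, int]:
    """Chi-square goodness of fit of the NNSD to the Poisson form e^-s.

    Eigenvalues are deduplicated (degenerate levels carry no spacing
    information), locally unfolded with a ``window``-point moving mean
    of the raw spacings so the unfolded spacings have unit local mean,
    then binned on [0, s_max].  Returns (p_value, n_spacings); with
    fewer than 20 usable spacings the spectrum is treated as structure-
    free (p = 1).
    """
    lam = np.sort(eigenvalues)
    keep = np.concatenate(([True], np.diff(lam) > dedup_tol))
    lam = lam[keep]
    gaps = np.diff(lam)
    if gaps.size < 20:
        return 1.0, int(gaps.size)
    # local unfolding: divide each gap by the mean gap in its window
    half = window // 2
    local = np.array(
        [gaps[max(0, i - half): i + half + 1].mean() for i in range(gaps.size)]
    )
    s = np.where(local > 0, gaps / local, 0.0)
    s = s[s <= s_max]
    if s.size < 20:
        return 1.0, int(s.size)
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(s, bins=edges)
    probs = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    probs /= probs.sum()                      # exponential truncated to [0, s_max]
    expected = probs * s.size
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=n_bins - 1))
    return p, int(s.size)


def rmt_threshold(
    corr: PairwiseMatrix,
    scan: tuple[float, float, float] = (0.3, 0.9, 0.01),
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Select the similarity threshold St by random-matrix theory.

    For each candidate t in ``scan`` = (start, stop, step), entries with
    |r| < t are zeroed and the NNSD of the resulting matrix is tested
    against the Poisson form e^-s.  St is the smallest t whose NNSD is
    consistent with Poisson statistics (chi-square p > ``alpha``): below
    St the matrix retains random-matrix (Wigner-Dyson) level repulsion
    driven by noise correlations; at St only genuine block structure
    remains.  Returns (St, per-threshold trace).
    """
    n = len(corr.ids)
    if n < 30:
        logger.warning("rmt_threshold: only %d nodes; RMT statistics are unreliable", n)
    start, stop, step = scan
    if not (0 < start < stop < 1):
        raise ValueError("scan must lie within (0, 1)")
    thresholds = np.arange(start, stop + step / 2, step)

    rows = []
    st = None
    for t in thresholds:
        a = np.where(np.abs(corr.values) >= t, corr.values, 0.0)
        np.fill_diagonal(a, 1.0)
        eig = np.linalg.eigvalsh(a)
        p, n_spacings = _nnsd_poisson_pvalue(eig)
        poisson = p > alpha
        rows.append((float(t), n_spacings, p, poisson))
        if poisson and st is None:
            st = float(t)
    trace = pd.DataFrame(rows, columns=["threshold", "n_spacings", "p_poisson", "poisson"])
    if st is None:
        raise ValueError(
            f"no threshold in [{start}, {stop}] gives Poisson NNSD; widen the scan"
        )
    return st, trace


# ---------------------------------------------------------------------
# network construction, modules, topology
# ---------------------------------------------------------------------

def build_network(corr: PairwiseMatrix, st: float) -> AssocNetwork:
    """Build the signed network with edges |r| >= St and find modules.

    Isolated nodes are dropped.  Modules are found by greedy modularity
    maximization (Clauset-Newman-Moore agglomeration) on the unweighted
    graph, with nodes pre-sorted by id for a deterministic result.
    """
    if not 0 < st < 1:
        raise ValueError("St must lie in (0, 1)")
    ids = corr.ids
    g = nx.Graph()
    n = len(ids)
    r = corr.values
    for i in range(n):
        for j in range(i + 1, n):
            if abs(r[i, j]) >= st:
                g.add_edge(ids[i], ids[j], weight=float(r[i, j]),
                           abs_weight=abs(float(r[i, j])),
                           sign=1 if r[i, j] > 0 else -1)
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges at St = {st}")
    g = nx.Graph(g.subgraph(sorted(g.nodes)))
    # association strength |r| weights the partition search; topology
    # metrics elsewhere treat edges as unweighted
    communities = nx.community.greedy_modularity_communities(g, weight="abs_weight")
    modules: dict[str, int] = {}
    for m, members in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node in members:
            modules[node] = m
    return AssocNetwork(graph=g, st=st, modules=modules)


def _shortest_path_counts(g: nx.Graph):
    """BFS distances and shortest-path counts between all node pairs."""
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = {v: list(g.neighbors(v)) for v in nodes}
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        queue = deque([s])
        while queue:
            v = queue.popleft()
            vi = idx[v]
            for w in adj[v]:
                wi = idx[w]
                if np.isinf(dist[si, wi]):
                    dist[si, wi] = dist[si, vi] + 1
                    queue.append(w)
                if dist[si, wi] == dist[si, vi] + 1:
                    sigma[si, wi] += sigma[si, vi]
    return nodes, dist, sigma


def _stress_centrality(g: nx.Graph) -> dict[str, float]:
    """Stress centrality: number of shortest paths passing through a node."""
    nodes, dist, sigma = _shortest_path_counts(g)
    n = len(nodes)
    stress = {}
    for vi, v in enumerate(nodes):
        on_path = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        count = sigma[:, vi][:, None] * sigma[vi, :][None, :] * on_path
        count[vi, :] = 0
        count[:, vi] = 0
        np.fill_diagonal(count, 0)
        stress[v] = float(np.triu(count, k=1).sum())
    return stress


def _freeman_centralization(values: dict[str, float], denominator: float) -> float:
    v = np.array(list(values.values()))
    return float((v.max() - v).sum() / denominator) if denominator > 0 else 0.0


def topology(net: AssocNetwork) -> TopologyRecord:
    """Topology metrics of one network (the standard pipeline summary set).

    Geodesics are averaged over connected pairs only; geodesic
    efficiency averages 1/d over all ordered pairs with unreachable
    pairs contributing 0 (so it is defined for disconnected, modular
    networks); the harmonic geodesic distance is its reciprocal.
    Centralizations use Freeman's formula with the star-graph maximum
    as denominator.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    degrees = dict(g.degree)
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)

    nodes, dist, _ = _shortest_path_counts(g)
    finite = np.isfinite(dist) & (dist > 0)
    gd = float(dist[finite].mean()) if finite.any() else np.nan
    diameter = float(dist[finite].max()) if finite.any() else 0.0
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / dist, 0.0)
    efficiency = float(inv.sum() / (n * (n - 1)))
    hd = 1.0 / efficiency if efficiency > 0 else np.inf

    q = (nx.community.modularity(g, net.module_sets(), weight=None)
         if net.modules else np.nan)

    bet = nx.betweenness_centrality(g, normalized=True)
    stress = _stress_centrality(g)
    star_stress_max = (n - 1) * (n - 1) * (n - 2) / 2.0

    metrics = {
        "n_nodes": float(n),
        "n_links": float(e),
        "positive_links_pct": 100.0 * pos / e,
        "negative_links_pct": 100.0 * (e - pos) / e,
        "similarity_threshold": net.st,
        "avg_connectivity": 2.0 * e / n,
        "avg_clustering": float(nx.average_clustering(g, count_zeros=True)),
        "avg_path_distance": gd,
        "modularity": float(q),
        "n_modules": float(len(net.module_sets())),
        "diameter": diameter,
        "density": 2.0 * e / (n * (n - 1)),
        "geodesic_efficiency": efficiency,
        "harmonic_geodesic_distance": hd,
        "max_degree": float(max(degrees.values())),
        "centralization_degree": _freeman_centralization(
            degrees, (n - 1) * (n - 2)),
        "centralization_betweenness": _freeman_centralization(bet, n - 1),
        "centralization_stress": _freeman_centralization(stress, star_stress_max),
    }
    return TopologyRecord(metrics=metrics)


# ---------------------------------------------------------------------
# Zi-Pi roles
# ---------------------------------------------------------------------

def zi_pi(
    net: AssocNetwork, zi_threshold: float = 2.5, pi_threshold: float = 0.62
) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against its module's
    mean and sd (sd = 0 gives Zi = 0); Pi = 1 - sum_m (k_im / k_i)^2
    over modules m.  Roles: network hub (Zi > 2.5 and Pi > 0.62),
    module hub (Zi > 2.5 only), connector (Pi > 0.62 only), else
    peripheral.
    """
    g, modules = net.graph, net.modules
    within = {}
    for v in g.nodes:
        within[v] = sum(1 for w in g.neighbors(v) if modules[w] == modules[v])
    module_stats = {}
    for m in set(modules.values()):
        k = np.array([within[v] for v in g.nodes if modules[v] == m], dtype=float)
        module_stats[m] = (k.mean(), k.std())

    rows = []
    for v in sorted(g.nodes):
        mean, sd = module_stats[modules[v]]
        zi = (within[v] - mean) / sd if sd > 0 else 0.0
        k_i = g.degree(v)
        per_module: dict[int, int] = {}
        for w in g.neighbors(v):
            per_module[modules[w]] = per_module.get(modules[w], 0) + 1
        pi = 1.0 - sum((k / k_i) ** 2 for k in per_module.values())
        if zi > zi_threshold and pi > pi_threshold:
            role = "network_hub"
        elif zi > zi_threshold:
            role = "module_hub"
        elif pi > pi_threshold:
            role = "connector"
        else:
            role = "peripheral"
        rows.append((v, modules[v], k_i, within[v], zi, pi, role))
    return pd.DataFrame(
        rows, columns=["node", "module", "degree", "within_degree", "zi", "pi", "role"]
    ).set_index("node")


# ---------------------------------------------------------------------
# random reference ensemble
# ---------------------------------------------------------------------

def random_ensemble(
    net: AssocNetwork, n: int = 100, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Degree-preserving (Maslov-Sneppen) randomization reference.

    Each replicate rewires the graph with 10 * E double-edge swaps and
    recomputes average clustering, average path distance (over connected
    pairs) and greedy modularity.  Returns {metric: (mean, sd)}.
    """
    g = net.graph
    e = g.number_of_edges()
    if g.number_of_nodes() < 4:
        raise ValueError("rewiring needs at least 4 nodes / 2 independent edge pairs")
    rng = np.random.default_rng(seed)
    cc, gd, q = [], [], []
    for _ in range(n):
        h = nx.Graph(g)
        try:
            nx.double_edge_swap(h, nswap=10 * e, max_tries=1000 * e,
                                seed=int(rng.integers(2**31 - 1)))
        except nx.NetworkXException as exc:
            raise ValueError(
                f"degree-preserving rewiring failed ({exc}); the graph is too "
                "small or dense to randomize"
            ) from exc
        cc.append(nx.average_clustering(h, count_zeros=True))
        total, count = 0.0, 0
        for comp in nx.connected_components(h):
            sub = h.subgraph(comp)
            if sub.number_of_nodes() < 2:
                continue
            for _, lengths in nx.all_pairs_shortest_path_length(sub):
                for dd in lengths.values():
                    if dd > 0:
                        total += dd
                        count += 1
        gd.append(total / count if count else np.nan)
        comms = nx.community.greedy_modularity_communities(h, weight=None)
        q.append(nx.community.modularity(h, comms, weight=None))
    return {
        "avg_clustering": (float(np.mean(cc)), float(np.std(cc, ddof=1))),
        "avg_path_distance": (float(np.mean(gd)), float(np.std(gd, ddof=1))),
        "modularity": (float(np.mean(q)), float(np.std(q, ddof=1))),
    }
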