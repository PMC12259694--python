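"""Co-occurrence networks of methanogen ASVs and their complexity.

A network is built per habitat from pairwise Spearman correlations of ASV
abundances across that habitat's samples: an edge is a pair with |rho|
strictly above an r threshold and a p-value strictly below a p threshold
(defaults 0.6 and 0.01).  Ten topological properties summarize a network;
min-max standardizing each property across a sample set and averaging the
ten standardized scores yields a per-sample network-complexity index.
Keystone taxa are classified from the within-module degree z-score (Zi)
and among-module participation coefficient (Pi).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CoocNetwork",
    "TopologyProfile",
    "TOPOLOGY_METRICS",
    "spearman_matrix",
    "build_network",
    "topology",
    "sample_subnetwork",
    "complexity_index",
    "zi_pi",
]

#: metric order used by the complexity index (ten properties)
TOPOLOGY_METRICS = [
    "nn", "ne", "connectance", "ad", "gcc", "acc", "an", "adc", "dc",
    "n_positive_edges",
]


@dataclass
class CoocNetwork:
    """Undirected correlation network over ASV nodes.

    ``rho`` holds the signed Spearman coefficient for kept edges and 0.0
    elsewhere; correlations are symmetric, so the graph is undirected.
    """

    asv_ids: list[str]
    rho: np.ndarray                       # (n, n) signed weights, 0 = no edge
    build_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = len(self.asv_ids)
        if self.rho.shape != (n, n):
            raise ValueError("rho must be square and match asv_ids")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")
        np.fill_diagonal(self.rho, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.asv_ids)

    @property
    def adjacency(self) -> np.ndarray:
        return self.rho != 0.0

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edges(self) -> pd.DataFrame:
        """Edge list with signed rho, one row per unordered pair."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            {
                "source": [self.asv_ids[a] for a in i],
                "target": [self.asv_ids[b] for b in j],
                "rho": self.rho[i, j],
                "sign": np.where(self.rho[i, j] > 0, "positive", "negative"),
            }
        )

    def edge_set(self) -> set[frozenset]:
        return {
            frozenset((r.source, r.target)) for r in self.edges().itertuples()
        }

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.asv_ids)
        for row in self.edges().itertuples():
            g.add_edge(row.source, row.target, rho=row.rho, sign=row.sign)
        return g

    def subset(self, keep: np.ndarray) -> "CoocNetwork":
        keep = np.asarray(keep)
        ids = [self.asv_ids[i] for i in np.nonzero(keep)[0]] if keep.dtype == bool else [
            self.asv_ids[i] for i in keep
        ]
        idx = np.nonzero(keep)[0] if keep.dtype == bool else keep
        return CoocNetwork(ids, self.rho[np.ix_(idx, idx)], dict(self.build_params))


@dataclass(frozen=True)
class TopologyProfile:
    """Ten topological properties of one network.

    nn    node count
    ne    edge count
    connectance  realized fraction of possible edges, ne / (nn*(nn-1)/2)
    ad    average degree, 2*ne/nn
    gcc   global clustering coefficient (transitivity)
    acc   average local clustering coefficient
    an    average neighborhood connectivity (mean over nodes of the average
          degree of their neighbors; nodes without neighbors contribute 0)
    adc   average degree centrality, ad/(nn-1)
    dc    Freeman degree centralization
    n_positive_edges  count of positively signed edges

    Degenerate networks (nn < 3) return 0 for gcc/acc/dc by convention and
    are flagged with ``degenerate=True``.
    """

    nn: int
    ne: int
    connectance: float
    ad: float
    gcc: float
    acc: float
    an: float
    adc: float
    dc: float
    n_positive_edges: int
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series({m: getattr(self, m) for m in TOPOLOGY_METRICS}, dtype=float)


def spearman_matrix(
    table: pd.DataFrame,
    min_occurrence_frac: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p over ASV columns of a sample-by-ASV table.

    ASVs present (count > 0) in fewer than ``min_occurrence_frac`` of the
    samples are excluded before correlating, as are constant columns (rank
    correlation is undefined for them); exclusions are logged.  p-values use
    the t-distribution approximation with n - 2 degrees of freedom; ties get
    average ranks.
    """
    if table.shape[0] < 5:
        raise ValueError(f"need >= 5 samples for correlation, got {table.shape[0]}")
    occ = (table > 0).mean(axis=0)
    kept = table.loc[:, occ >= min_occurrence_frac]
    dropped = table.shape[1] - kept.shape[1]
    if dropped:
        log.info("occurrence filter (>=%.0f%% of samples) removed %d ASVs",
                 100 * min_occurrence_frac, dropped)
    const = kept.nunique(axis=0) <= 1
    if const.any():
        log.info("excluding %d constant ASV columns: %s", int(const.sum()),
                 list(kept.columns[const])[:10])
        kept = kept.loc[:, ~const]
    if kept.shape[1] < 2:
        raise ValueError("fewer than 2 ASVs left after occurrence filtering")

    n = kept.shape[0]
    ranks = kept.rank(axis=0).to_numpy()
    ranks -= ranks.mean(axis=0)
    ranks /= np.sqrt((ranks**2).sum(axis=0))
    rho = np.clip(ranks.T @ ranks, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    # two-sided p from t = rho * sqrt((n-2)/(1-rho^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |rho| == 1
    np.fill_diagonal(p, 0.0)
    cols = list(kept.columns)
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    drop_isolated: bool = True,
    fdr: bool = False,
    n_samples: int | None = None,
) -> CoocNetwork:
    """Threshold correlation matrices into a co-occurrence network.

    An edge is kept iff |rho| > r_threshold AND p < p_threshold, both
    strict.  ``fdr=True`` applies Benjamini-Hochberg correction to the
    pairwise p-values before thresholding (off by default: the convention
    here filters on raw p).  Isolated nodes are dropped from the node set
    unless ``drop_isolated=False``.  An empty result is returned with a
    warning, never an error.
    """
    if rho.shape != p.shape or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices must be conformable")
    r = rho.to_numpy().copy()
    pv = p.to_numpy().copy()
    np.fill_diagonal(r, 0.0)
    if fdr:
        iu = np.triu_indices_from(pv, k=1)
        flat = pv[iu]
        order = np.argsort(flat)
        m = flat.size
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((flat[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        pv[iu] = np.clip(adj, 0, 1)
        pv.T[iu] = pv[iu]
    keep = (np.abs(r) > r_threshold) & (pv < p_threshold)
    keep &= keep.T
    w = np.where(keep, r, 0.0)
    net = CoocNetwork(
        list(rho.columns), w,
        {"r_threshold": r_threshold, "p_threshold": p_threshold,
         "fdr": fdr, "n_samples": n_samples, "drop_isolated": drop_isolated},
    )
    if drop_isolated:
        degree = net.adjacency.sum(axis=0)
        net = CoocNetwork(
            [a for a, k in zip(net.asv_ids, degree) if k > 0],
            net.rho[np.ix_(degree > 0, degree > 0)],
            net.build_params,
        )
    if net.n_edges == 0:
        warnings.warn("co-occurrence network is empty at the given thresholds",
                      stacklevel=2)
    return net


def topology(network: CoocNetwork) -> TopologyProfile:
    """The ten topological properties of a (possibly empty) network."""
    a = network.adjacency.astype(float)
    n = network.n_nodes
    k = a.sum(axis=0)
    ne = int(k.sum() // 2)
    n_pos = int((np.triu(network.rho, k=1) > 0).sum())
    if n < 2:
        return TopologyProfile(n, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, True)
    connectance = ne / (n * (n - 1) / 2)
    ad = 2.0 * ne / n
    adc = ad / (n - 1)
    # average neighborhood connectivity: mean over nodes of mean neighbor degree
    with np.errstate(invalid="ignore", divide="ignore"):
        neigh = np.where(k > 0, (a @ k) / np.where(k > 0, k, 1), 0.0)
    an = float(neigh.mean())
    if n < 3:
        return TopologyProfile(n, ne, connectance, ad, 0.0, 0.0, an, adc, 0.0,
                               n_pos, True)
    a2 = a @ a
    closed = float((a2 * a).sum())          # = sum_i diag(A^3)_i, 6x triangles
    triples = float((k * (k - 1)).sum())
    gcc = closed / triples if triples > 0 else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(k > 1, np.einsum("ii->i", a @ a2) / (k * (k - 1)), 0.0)
    acc = float(local.mean())
    dc = float((k.max() - k).sum() / ((n - 1) * (n - 2)))
    return TopologyProfile(n, ne, connectance, ad, gcc, acc, an, adc, dc, n_pos)


def sample_subnetwork(network: CoocNetwork, sample_counts: pd.Series) -> CoocNetwork:
    """Induced subgraph on the ASVs with nonzero abundance in one sample.

    ``sample_counts`` is one row of the habitat's count table; network ASVs
    missing from it are treated as absent.
    """
    present = {a for a, c in sample_counts.items() if c > 0}
    keep = np.array([a in present for a in network.asv_ids], dtype=bool)
    if not keep.any():
        warnings.warn("sample shares no ASVs with the network; empty subnetwork",
                      stacklevel=2)
    return network.subset(keep)


def complexity_index(profiles: dict[str, TopologyProfile] | pd.DataFrame) -> pd.DataFrame:
    """Per-sample network complexity: mean of min-max standardized metrics.

    For each of the ten topological properties, scores are standardized to
    [0, 1] across all samples as (x - min) / (max - min); the complexity
    index is the unweighted mean of the ten standardized scores.  Metrics
    with zero range across samples contribute 0 and are flagged in the
    ``zero_range`` attribute of the returned frame.
    """
    if isinstance(profiles, dict):
        raw = pd.DataFrame({s: p.as_series() for s, p in profiles.items()}).T
    else:
        raw = profiles.loc[:, TOPOLOGY_METRICS].astype(float)
    if raw.shape[0] < 2:
        raise ValueError("complexity standardization needs >= 2 samples")
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    rng = hi - lo
    zero_range = list(rng.index[rng == 0])
    if len(zero_range) == len(TOPOLOGY_METRICS):
        raise ValueError("all topology metrics constant across samples")
    if zero_range:
        log.info("metrics with zero range contribute 0 to complexity: %s", zero_range)
    std = (raw - lo).div(rng.where(rng > 0, 1.0), axis=1)
    std.loc[:, zero_range] = 0.0
    out = std.copy()
    out["complexity"] = std.mean(axis=1)
    out.attrs["zero_range"] = zero_range
    return out


_CATEGORIES = {
    (False, False): "peripheral",
    (False, True): "connector",
    (True, False): "module_hub",
    (True, True): "network_hub",
}


def zi_pi(
    network: CoocNetwork,
    zi_threshold: float = 2.5,
    pi_threshold: float = 0.62,
    seed: int | None = None,
) -> pd.DataFrame:
    """Within-module connectivity (Zi) and participation (Pi) per node.

    Modules are found by greedy modularity maximization (deterministic for
    a given graph; the method is recorded in the result attrs).  For node i
    in module s with k_is links into module s: zi is the z-score of k_is
    among module-s members (sd 0 -> zi 0 by convention) and
    pi = 1 - sum_s (k_is / k_i)^2.  Categories follow the four-quadrant
    rule with boundaries belonging to the "<=" class: peripheral
    (zi <= 2.5, pi <= 0.62), connector (zi <= 2.5, pi > 0.62), module hub
    (zi > 2.5, pi <= 0.62), network hub (zi > 2.5, pi > 0.62).  Isolated
    nodes get zi = pi = 0, peripheral, flagged.
    """
    if network.n_edges < 1:
        raise ValueError("zi_pi needs a network with at least one edge")
    g = network.to_networkx()
    communities = nx.community.greedy_modularity_communities(g)
    module_of = {}
    for m, members in enumerate(communities):
        for node in sorted(members):
            module_of[node] = m
    ids = network.asv_ids
    mod = np.array([module_of[a] for a in ids])
    a = network.adjacency.astype(float)
    k = a.sum(axis=0)
    n_modules = len(communities)
    # k_is: links of node i into module s
    member = np.zeros((len(ids), n_modules))
    member[np.arange(len(ids)), mod] = 1.0
    kis = a @ member
    own = kis[np.arange(len(ids)), mod]
    zi = np.zeros(len(ids))
    for s in range(n_modules):
        in_s = mod == s
        mu, sd = own[in_s].mean(), own[in_s].std(ddof=0)
        if sd > 0:
            zi[in_s] = (own[in_s] - mu) / sd
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(k > 0, 1.0 - ((kis / np.where(k > 0, k, 1)[:, None]) ** 2).sum(axis=1), 0.0)
    isolated = k == 0
    zi[isolated] = 0.0
    cat = [
        "peripheral" if iso else _CATEGORIES[(z > zi_threshold, p > pi_threshold)]
        for z, p, iso in zip(zi, pi, isolated)
    ]
    out = pd.DataFrame(
        {"asv_id": ids, "module": mod, "zi": zi, "pi": pi, "category": cat,
         "degree": k.astype(int), "isolated": isolated}
    ).set_index("asv_id")
    out.attrs["module_method"] = "greedy_modularity"
    out.attrs["n_modules"] = n_modules
    return out


def classify_zi_pi(zi: float, pi: float,
                   zi_threshold: float = 2.5, pi_threshold: float = 0.62) -> str:
    """Quadrant category for a single (zi, pi) pair."""
    return _CATEGORIES[(zi > zi_threshold, pi > pi_threshold)]
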