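"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (double loops, exhaustive
enumeration) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def naive_topology(adj: np.ndarray, signs: np.ndarray | None = None) -> dict:
    """Ten topological properties by explicit double/triple loops."""
    n = adj.shape[0]
    adj = adj.astype(bool)
    deg = [int(adj[i].sum()) for i in range(n)]
    ne = sum(deg) // 2
    out = {"nn": n, "ne": ne}
    out["connectance"] = ne / (n * (n - 1) / 2) if n > 1 else 0.0
    out["ad"] = 2 * ne / n if n > 0 else 0.0
    out["adc"] = out["ad"] / (n - 1) if n > 1 else 0.0
    # average neighborhood connectivity
    an_terms = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        an_terms.append(sum(deg[j] for j in nbrs) / len(nbrs) if nbrs else 0.0)
    out["an"] = float(np.mean(an_terms)) if n else 0.0
    if n < 3:
        out.update({"gcc": 0.0, "acc": 0.0, "dc": 0.0})
    else:
        closed = 0
        triples = 0
        local = []
        for i in range(n):
            nbrs = [j for j in range(n) if adj[i, j]]
            k = len(nbrs)
            links = sum(
                1 for x in range(len(nbrs)) for y in range(x + 1, len(nbrs))
                if adj[nbrs[x], nbrs[y]]
            )
            closed += 2 * links
            triples += k * (k - 1)
            local.append(2 * links / (k * (k - 1)) if k > 1 else 0.0)
        out["gcc"] = closed / triples if triples else 0.0
        out["acc"] = float(np.mean(local))
        kmax = max(deg)
        out["dc"] = sum(kmax - k for k in deg) / ((n - 1) * (n - 2))
    if signs is None:
        out["n_positive_edges"] = ne
    else:
        out["n_positive_edges"] = sum(
            1 for i in range(n) for j in range(i + 1, n)
            if adj[i, j] and signs[i, j] > 0
        )
    return out


def naive_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average ranks and the t-approximation p-value."""
    from scipy.stats import t as tdist

    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i: j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_rank(x), avg_rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * tdist.sf(abs(tstat), df=n - 2))


def naive_permanova_f(dist: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from raw squared dissimilarities."""
    n = dist.shape[0]
    groups = np.unique(labels)
    ss_total = (dist[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        sub = dist[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_among = ss_total - ss_within
    df_a = len(groups) - 1
    df_w = n - len(groups)
    return (ss_among / df_a) / (ss_within / df_w)


def exhaustive_permanova_p(dist: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p-value over every relabelling of the samples."""
    f_obs = naive_permanova_f(dist, labels)
    count = 0
    total = 0
    for perm in permutations(range(len(labels))):
        total += 1
        if naive_permanova_f(dist, labels[list(perm)]) >= f_obs - 1e-12:
            count += 1
    return count / total


def modular_graph_with_connectors(
    rng: np.random.Generator,
    n_modules: int = 4,
    module_size: int = 8,
    p_in: float = 0.85,
    n_connectors: int = 2,
    edges_per_module: int = 3,
) -> tuple[np.ndarray, list[int]]:
    """Random modular graph plus connector nodes wired across modules.

    Returns (adjacency, connector node indices).  Connectors link into
    every module with ``edges_per_module`` edges each, so their
    participation coefficient exceeds the 0.62 connector threshold.
    """
    n = n_modules * module_size + n_connectors
    adj = np.zeros((n, n), dtype=bool)
    for m in range(n_modules):
        lo = m * module_size
        for i in range(lo, lo + module_size):
            for j in range(i + 1, lo + module_size):
                if rng.random() < p_in:
                    adj[i, j] = adj[j, i] = True
    connectors = list(range(n_modules * module_size, n))
    for cnode in connectors:
        for m in range(n_modules):
            lo = m * module_size
            targets = rng.choice(module_size, size=edges_per_module, replace=False)
            for t in targets:
                adj[cnode, lo + t] = adj[lo + t, cnode] = True
    return adj, connectors
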