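"""Community-table hygiene and community-level statistics.

Count tables are pandas DataFrames with samples as rows and ASVs as
columns (nonnegative integers, unique identifiers on both axes).  The
operations here mirror a standard amplicon workflow: drop rare ASVs,
rarefy to even depth, alpha diversity, Bray-Curtis dissimilarity,
PERMANOVA, distance-based RDA with forward selection of environmental
terms, a PCA community index, and one-way ANOVA with a Tukey compact
letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)

__all__ = [
    "read_count_table", "write_count_table", "validate_count_table",
    "filter_rare_asvs", "rarefy", "alpha_diversity", "bray_curtis",
    "PermanovaResult", "permanova",
    "OrdinationResult", "forward_select_dbrda",
    "community_pca", "GroupCompareResult", "group_compare",
]


# ---------------------------------------------------------------- table I/O

def validate_count_table(table: pd.DataFrame) -> None:
    if table.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in count table")
    if table.columns.duplicated().any():
        raise ValueError("duplicate ASV identifiers in count table")
    vals = table.to_numpy()
    if (vals < 0).any():
        raise ValueError("count table contains negative values")


def read_count_table(path) -> pd.DataFrame:
    """Read a sample-by-ASV TSV (first column sample IDs, header ASV IDs)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.index.name = "sample_id"
    validate_count_table(table)
    return table.astype(np.int64)


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table)
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------- filter / rarefy

def filter_rare_asvs(table: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Remove ASVs with fewer than ``min_reads`` total reads across samples."""
    validate_count_table(table)
    keep = table.sum(axis=0) >= min_reads
    if not keep.any():
        raise ValueError(f"no ASV reaches {min_reads} total reads; table would be empty")
    removed = int((~keep).sum())
    if removed:
        log.info("removed %d ASVs with < %d total reads", removed, min_reads)
    return table.loc[:, keep]


def rarefy(table: pd.DataFrame, depth: int = 1016, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped (logged).  Sampling
    is multivariate-hypergeometric per sample, deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    validate_count_table(table)
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    shallow = totals < depth
    if shallow.any():
        log.info("dropping %d samples below rarefaction depth %d: %s",
                 int(shallow.sum()), depth, list(table.index[shallow])[:10])
    kept = table.loc[~shallow]
    rows = [
        rng.multivariate_hypergeometric(row, depth)
        for row in kept.to_numpy(dtype=np.int64)
    ]
    return pd.DataFrame(np.array(rows, dtype=np.int64), index=kept.index,
                        columns=kept.columns)


# ------------------------------------------------------------- alpha / beta

def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Observed richness and Shannon index (natural log) per sample."""
    validate_count_table(table)
    totals = table.sum(axis=1).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = list(table.index[table.sum(axis=1) == 0])
        raise ValueError(f"zero-sum samples: {bad}")
    counts = table.to_numpy(dtype=float)
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {"richness": (counts > 0).sum(axis=1), "shannon": -plogp.sum(axis=1)},
        index=table.index,
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity (square, symmetric)."""
    validate_count_table(table)
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ----------------------------------------------------------------- PERMANOVA

def _gower_center(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    return a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


@dataclass(frozen=True)
class PermanovaResult:
    f: float
    p_value: float
    df_among: int
    df_within: int
    n_perm: int


def permanova(
    dist: pd.DataFrame,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA pseudo-F on a dissimilarity matrix.

    ``grouping`` is either a per-sample label sequence (one-way design) or
    a numeric model matrix (columns are predictors; an intercept is added).
    The pseudo-F uses among/within sums of squared dissimilarities via the
    Gower-centered inner-product matrix; the p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) under row/column permutation.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    g = _gower_center(d)

    grouping_arr = np.asarray(grouping)
    if grouping_arr.ndim == 1:
        labels, inverse = np.unique(grouping_arr, return_inverse=True)
        counts = np.bincount(inverse)
        if (counts < 2).any():
            small = [str(labels[i]) for i in np.nonzero(counts < 2)[0]]
            raise ValueError(f"groups of size < 2: {small}")
        x = np.zeros((n, len(labels)))
        x[np.arange(n), inverse] = 1.0
        df_among = len(labels) - 1
    else:
        x = np.column_stack([np.ones(n), grouping_arr.astype(float)])
        df_among = int(np.linalg.matrix_rank(x)) - 1
        if df_among < 1:
            raise ValueError("model matrix has no non-constant predictors")
    df_within = n - df_among - 1
    h = _hat(x)

    def pseudo_f(gm: np.ndarray) -> float:
        # tr(HGH) = tr(HG) because H is symmetric idempotent
        ss_among = float((h * gm).sum())
        ss_total = float(gm.trace())
        ss_within = ss_total - ss_among
        return (ss_among / df_among) / (ss_within / df_within)

    f_obs = pseudo_f(g)
    rng = np.random.default_rng(seed)
    # tolerance keeps permutations numerically tied with the observed
    # statistic on the "as extreme" side
    cutoff = f_obs - 1e-10 * (1.0 + abs(f_obs))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(g[np.ix_(perm, perm)]) >= cutoff:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(f_obs, p, df_among, df_within, n_perm)


# --------------------------------------------------- db-RDA forward selection

@dataclass
class OrdinationResult:
    """Forward-selection result of a distance-based RDA.

    ``selected`` holds environmental terms in selection order with their
    pseudo-F and permutation p; ``axes`` are the first two constrained axis
    scores of the final model (empty if nothing was selected).
    """

    selected: list[str]
    f_values: list[float]
    p_values: list[float]
    axes: pd.DataFrame
    total_inertia: float
    constrained_inertia: float
    negative_eigenvalues_dropped: int
    note: str = "PCoA embedding; negative eigenvalue axes dropped (no Lingoes correction)"


def _pcoa_embed(dist: np.ndarray) -> tuple[np.ndarray, int]:
    g = _gower_center(dist)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-8 * abs(eigval[0]))
    pos = eigval > tol
    n_neg = int((eigval < -tol).sum())
    return eigvec[:, pos] * np.sqrt(eigval[pos]), n_neg


def forward_select_dbrda(
    dist: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> OrdinationResult:
    """Constrained analysis of principal coordinates with forward selection.

    The dissimilarity matrix is embedded by principal coordinates (negative
    eigenvalue axes are dropped and their count reported); environmental
    columns are z-scored.  At each step the candidate adding the most
    explained inertia among those with permutation p <= alpha is added;
    candidate p-values use reduced-model residual permutation.  Stops when
    no candidate passes.
    """
    env = env.copy().astype(float)
    const = env.nunique(axis=0) <= 1
    if const.any():
        raise ValueError(f"constant environmental columns: {list(env.columns[const])}")
    if list(dist.index) != list(env.index):
        raise ValueError("distance matrix and env table must share sample order")
    z = (env - env.mean()) / env.std(ddof=1)

    y, n_neg = _pcoa_embed(dist.to_numpy(dtype=float))
    n = y.shape[0]
    total_inertia = float((y**2).sum())
    rng = np.random.default_rng(seed)

    selected: list[str] = []
    fvals: list[float] = []
    pvals: list[float] = []
    remaining = list(z.columns)
    while remaining:
        x0 = np.column_stack([np.ones(n)] + ([z[selected].to_numpy()] if selected else []))
        q0, _ = np.linalg.qr(x0)
        c0 = q0.T @ y
        fit0 = q0 @ c0
        resid0 = y - fit0
        ss0 = float((c0**2).sum())
        ss_resid0 = float((resid0**2).sum())
        df_resid = n - len(selected) - 2

        # one shared set of residual permutations for all candidates this step
        perms = [rng.permutation(n) for _ in range(n_perm)]

        stats_by_term: dict[str, tuple[float, float, float]] = {}
        for term in remaining:
            x = z[term].to_numpy()
            q = x - q0 @ (q0.T @ x)
            norm = np.linalg.norm(q)
            if norm < 1e-8 * np.linalg.norm(x):
                continue  # collinear with already-selected terms
            q /= norm
            added = float(((q @ y) ** 2).sum())
            f_obs = added / ((total_inertia - ss0 - added) / df_resid)
            # reduced-model permutation of residuals: y_perm = fit0 + P resid0;
            # q is orthogonal to the reduced model, so its added SS under a
            # permutation is ||q^T (P resid0)||^2
            exceed = 0
            for perm in perms:
                ep = resid0[perm]
                addedp = float(((q @ ep) ** 2).sum())
                ssp0 = float(((c0 + q0.T @ ep) ** 2).sum())
                ss_tot_p = ss0 + 2.0 * float((fit0 * ep).sum()) + ss_resid0
                fp = addedp / ((ss_tot_p - ssp0 - addedp) / df_resid)
                if fp >= f_obs:
                    exceed += 1
            stats_by_term[term] = (added, f_obs, (1 + exceed) / (1 + n_perm))
        passing = {t: v for t, v in stats_by_term.items() if v[2] <= alpha}
        if not passing:
            break
        best = max(passing, key=lambda t: passing[t][0])
        selected.append(best)
        fvals.append(passing[best][1])
        pvals.append(passing[best][2])
        remaining.remove(best)

    if selected:
        h = _hat(np.column_stack([np.ones(n), z[selected].to_numpy()]))
        fitted = h @ y
        constrained = float((fitted**2).sum())
        u, s, _ = np.linalg.svd(fitted - fitted.mean(axis=0), full_matrices=False)
        k = min(2, (s > 1e-10).sum())
        axes = pd.DataFrame(
            u[:, :k] * s[:k], index=dist.index,
            columns=[f"CAP{i + 1}" for i in range(k)],
        )
    else:
        constrained = 0.0
        axes = pd.DataFrame(index=dist.index)
    return OrdinationResult(selected, fvals, pvals, axes, total_inertia,
                            constrained, n_neg)


# ------------------------------------------------------------------ PCA index

def community_pca(table: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA community index on relative abundances.

    Counts are converted to relative abundances per sample and column-
    centered (no unit-variance scaling); returns per-sample scores for the
    first ``n_components`` axes and the explained-variance fractions.
    """
    validate_count_table(table)
    if table.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = table.to_numpy(dtype=float)
    rel = x / x.sum(axis=1, keepdims=True)
    centered = rel - rel.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (table.shape[0] - 1)
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=table.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, explained[:k]


# ----------------------------------------------------------- ANOVA + letters

@dataclass(frozen=True)
class GroupCompareResult:
    f: float
    p_value: float
    letters: dict[str, str]
    group_means: dict[str, float]


def _compact_letters(groups: list[str], sig_pairs: set[frozenset],
                     means: dict[str, float]) -> dict[str, str]:
    """Greedy insert-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Starts from
    one set containing everything and splits on each significant pair;
    letter order follows descending group means.
    """
    sets: list[set[str]] = [set(groups)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(p)):
        i, j = sorted(pair)
        new_sets: list[set[str]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = [s for s in new_sets if not any(s < t for t in new_sets)]
        # dedupe
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: -max(means[g] for g in s) if s else 0)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in sorted(s, key=lambda g: -means[g]):
            letters[g] += letter
    return letters


def group_compare(values, grouping, alpha: float = 0.05) -> GroupCompareResult:
    """One-way ANOVA with a Tukey HSD compact letter display."""
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping).astype(str)
    labels = sorted(set(grouping))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[grouping == g] for g in labels]
    if any(len(v) < 2 for v in by_group):
        raise ValueError("every group needs >= 2 observations")
    if all(np.ptp(v) == 0 for v in by_group):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f, p = stats.f_oneway(*by_group)
    means = {g: float(np.mean(v)) for g, v in zip(labels, by_group)}
    tukey = pairwise_tukeyhsd(values, grouping, alpha=alpha)
    pairs = list(combinations([str(g) for g in tukey.groupsunique], 2))
    sig_pairs = {
        frozenset(pair) for pair, reject in zip(pairs, tukey.reject) if reject
    }
    letters = _compact_letters(labels, sig_pairs, means)
    return GroupCompareResult(float(f), float(p), letters, means)
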