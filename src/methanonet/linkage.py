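"""Linking biotic and abiotic drivers to potential methane production.

Four statistical routes are provided, mirroring how soil-function studies
attribute variation in a rate to community and environmental predictors:
simple regression (with an optional log10 predictor transform and both
Pearson and Spearman association reported), random-forest permutation
importance (percent increase in out-of-bag MSE), variation partitioning
of adjusted R-squared between two predictor sets, and partial least
squares path modeling (PLS-PM) over latent blocks with bootstrap
confidence intervals and a goodness-of-fit statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

log = logging.getLogger(__name__)

__all__ = [
    "RegressionResult", "fit_regression",
    "forest_importance",
    "VpaResult", "variation_partition",
    "PathModelSpec", "PathModelResult", "fit_plspm", "default_path_spec",
]


# ------------------------------------------------------------- regression

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_pearson: float       # on the (transformed x, y) scale
    p_pearson: float
    r_spearman: float      # on the raw (x, y) ranks
    p_spearman: float
    n: int
    transform: str


def fit_regression(x, y, x_transform: str | None = None) -> RegressionResult:
    """OLS of y on (optionally log10-transformed) x.

    Association is reported twice: Pearson r on the transformed scale (the
    regression-line fit) and Spearman rho on the raw values (rank
    association); neither is privileged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 finite pairs, got {x.size}")
    if x_transform == "log10":
        if (x <= 0).any():
            raise ValueError("log10 transform requires strictly positive x")
        xt = np.log10(x)
    elif x_transform in (None, "identity"):
        xt = x
    else:
        raise ValueError(f"unknown x_transform {x_transform!r}")
    if np.ptp(xt) == 0:
        raise ValueError("zero variance in x")
    lr = stats.linregress(xt, y)
    rho, p_s = stats.spearmanr(x, y)
    return RegressionResult(
        slope=float(lr.slope), intercept=float(lr.intercept),
        r_pearson=float(lr.rvalue), p_pearson=float(lr.pvalue),
        r_spearman=float(rho), p_spearman=float(p_s),
        n=int(x.size), transform=x_transform or "identity",
    )


# ------------------------------------------------- random-forest importance

def forest_importance(
    features: pd.DataFrame,
    response,
    n_trees: int = 500,
    seed: int | None = None,
    n_null: int = 100,
    alpha: float = 0.05,
    max_features: float | str = 0.3334,
) -> pd.DataFrame:
    """Permutation importance of each feature for a regression forest.

    The forest is a bagged ensemble of regression trees (bootstrap
    resampling of samples, random feature subsets per split, the p/3
    convention by default).  Importance is the percent increase in
    out-of-bag MSE when the feature is permuted among each tree's
    out-of-bag rows.  Significance comes from a response-permutation null:
    the whole procedure is repeated ``n_null`` times on permuted responses
    and each feature's p-value is the fraction of null importances at
    least as large.
    """
    y = np.asarray(response, dtype=float)
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    if n < 20:
        raise ValueError(f"need >= 20 samples, got {n}")
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("features and response must be complete and finite")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)

    def raw_importance(yv: np.ndarray, gen: np.random.Generator) -> np.ndarray:
        err_perm = np.zeros(p)
        base = np.zeros(p)
        for _ in range(n_trees):
            boot = gen.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size < 2:
                continue
            tree = DecisionTreeRegressor(
                max_features=max_features,
                random_state=int(gen.integers(0, 2**31 - 1)),
            )
            tree.fit(x[boot], yv[boot])
            pred = tree.predict(x[oob])
            e0 = float(np.mean((pred - yv[oob]) ** 2))
            for j in range(p):
                xp = x[oob].copy()
                xp[:, j] = xp[gen.permutation(oob.size), j]
                ep = float(np.mean((tree.predict(xp) - yv[oob]) ** 2))
                err_perm[j] += ep
                base[j] += e0
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * (err_perm - base) / base

    observed = raw_importance(y, rng)
    null = np.empty((n_null, p))
    for b in range(n_null):
        null[b] = raw_importance(y[rng.permutation(n)], rng)
    pvals = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n_null)
    out = pd.DataFrame(
        {"importance_pct_inc_mse": observed, "p_value": pvals,
         "significant": pvals <= alpha},
        index=features.columns,
    ).sort_values("importance_pct_inc_mse", ascending=False)
    return out


# --------------------------------------------------- variation partitioning

def _adj_r2(y: np.ndarray, x: np.ndarray) -> float:
    n = y.size
    xd = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(xd)
    if rank < xd.shape[1]:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    resid = y - xd @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    p = xd.shape[1] - 1
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class VpaResult:
    """Adjusted-R2 variation partitioning between two predictor sets.

    Fractions are reported unclipped (adjusted R2 can make individual
    fractions slightly negative); ``clipped()`` gives a display copy with
    negatives set to 0.  pure_a + pure_b + shared + unexplained == 1.
    """

    pure_a: float
    pure_b: float
    shared: float
    unexplained: float

    def clipped(self) -> dict[str, float]:
        return {k: max(0.0, v) for k, v in
                {"pure_a": self.pure_a, "pure_b": self.pure_b,
                 "shared": self.shared, "unexplained": self.unexplained}.items()}


def variation_partition(response, x_a: pd.DataFrame, x_b: pd.DataFrame) -> VpaResult:
    """Partition response variation between predictor sets A and B.

    pure_a = adjR2(A+B) - adjR2(B); pure_b symmetric;
    shared = adjR2(A) + adjR2(B) - adjR2(A+B);
    unexplained = 1 - adjR2(A+B).
    """
    y = np.asarray(response, dtype=float)
    a = x_a.to_numpy(dtype=float)
    b = x_b.to_numpy(dtype=float)
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("both predictor sets must be non-empty")
    total_p = a.shape[1] + b.shape[1]
    if y.size <= total_p + 2:
        raise ValueError(f"need n > p + 2 (n={y.size}, p={total_p})")
    try:
        r2_ab = _adj_r2(y, np.column_stack([a, b]))
    except ValueError:
        cols = list(x_a.columns) + list(x_b.columns)
        raise ValueError(f"combined design is rank deficient; check columns {cols}")
    r2_a = _adj_r2(y, a)
    r2_b = _adj_r2(y, b)
    return VpaResult(
        pure_a=r2_ab - r2_b,
        pure_b=r2_ab - r2_a,
        shared=r2_a + r2_b - r2_ab,
        unexplained=1.0 - r2_ab,
    )


# --------------------------------------------------------------- PLS-PM

@dataclass
class PathModelSpec:
    """Latent-block structure for a PLS path model.

    ``blocks`` maps latent-variable names to indicator column lists;
    ``paths`` maps each endogenous block to its list of predecessor
    blocks.  The inner relations must form a DAG.
    """

    blocks: dict[str, list[str]]
    paths: dict[str, list[str]]

    def validate(self, data: pd.DataFrame) -> list[str]:
        """Checks the spec and returns block names in topological order."""
        for block, cols in self.blocks.items():
            missing = [c for c in cols if c not in data.columns]
            if missing:
                raise ValueError(f"block {block!r}: missing indicator columns {missing}")
            if not cols:
                raise ValueError(f"block {block!r} has no indicators")
        for target, sources in self.paths.items():
            for name in [target] + list(sources):
                if name not in self.blocks:
                    raise ValueError(f"path references unknown block {name!r}")
        order: list[str] = []
        pending = dict(self.paths)
        names = list(self.blocks)
        while names:
            free = [b for b in names
                    if all(s in order for s in pending.get(b, []))]
            if not free:
                raise ValueError("inner path relations contain a cycle")
            order.extend(free)
            names = [b for b in names if b not in free]
        return order


@dataclass
class PathModelResult:
    path_coefficients: pd.DataFrame   # source, target, coefficient (+ bootstrap cols)
    r_squared: dict[str, float]
    outer_loadings: pd.DataFrame      # block, indicator, loading, communality
    gof: float
    scores: pd.DataFrame
    effects: pd.DataFrame             # direct, indirect, total per (source, target)
    n_iterations: int
    scheme: str

    def path(self, source: str, target: str) -> float:
        df = self.path_coefficients
        row = df[(df["source"] == source) & (df["target"] == target)]
        if row.empty:
            raise KeyError(f"no path {source} -> {target}")
        return float(row["coefficient"].iloc[0])


def default_path_spec(community_pc2: bool = True) -> PathModelSpec:
    """The wetland-methanogen inner model used by the pipeline.

    Soil nutrition (TOC, TN) and non-nutrition (pH, EC) drive methanogen
    abundance, diversity, community structure and network complexity, and
    all six drive CH4 production (PMPR).  ``community_pc2`` controls
    whether the community block carries PC1+PC2 or PC1 alone.
    """
    community = ["PC1", "PC2"] if community_pc2 else ["PC1"]
    blocks = {
        "nutrition": ["TOC", "TN"],
        "non_nutrition": ["pH", "EC"],
        "abundance": ["log10_mcrA"],
        "diversity": ["richness", "shannon"],
        "community": community,
        "complexity": ["complexity"],
        "ch4": ["pmpr"],
    }
    mediators = ["abundance", "diversity", "community", "complexity"]
    paths = {m: ["nutrition", "non_nutrition"] for m in mediators}
    paths["ch4"] = ["nutrition", "non_nutrition"] + mediators
    return PathModelSpec(blocks, paths)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant indicator column")
    return (x - x.mean(axis=0)) / sd


def _fit_plspm_once(
    xb: dict[str, np.ndarray],
    order: list[str],
    neighbors: dict[str, list[str]],
    paths: dict[str, list[str]],
    scheme: str,
    tol: float,
    max_iter: int,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], int]:
    """Core alternating outer/inner approximation (mode A)."""
    n = next(iter(xb.values())).shape[0]
    weights = {b: np.ones(x.shape[1]) for b, x in xb.items()}
    scores = {}
    for b in order:
        s = xb[b] @ weights[b]
        scores[b] = s / s.std(ddof=0)
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        new_scores = dict(scores)
        for b in order:
            inner = np.zeros(n)
            for nb in neighbors[b]:
                r = float(np.corrcoef(new_scores[b], new_scores[nb])[0, 1])
                e = np.sign(r) if scheme == "centroid" else r
                inner += e * new_scores[nb]
            if not inner.any():
                inner = new_scores[b]
            # mode A outer update: weights proportional to cov(x_j, inner)
            w = xb[b].T @ inner / n
            s = xb[b] @ w
            sd = s.std(ddof=0)
            if sd == 0:
                raise ValueError(f"degenerate latent score for block {b!r}")
            w = w / sd
            # sign convention: latent positively associated with its indicators
            if (xb[b].T @ (xb[b] @ w)).sum() < 0:
                w = -w
            delta = np.abs(w - weights[b]).max()
            max_delta = max(max_delta, delta)
            weights[b] = w
            new_scores[b] = xb[b] @ w
        scores = new_scores
        if max_delta < tol:
            break
    else:
        raise RuntimeError(
            f"PLS-PM did not converge in {max_iter} iterations "
            f"(last max weight change {max_delta:.2e})"
        )
    return weights, scores, it


def fit_plspm(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 1000,
    seed: int | None = None,
    scheme: str = "centroid",
    tol: float = 1e-6,
    max_iter: int = 300,
) -> PathModelResult:
    """Partial least squares path modeling with reflective (mode A) blocks.

    Indicators are standardized internally.  Outer estimation weights each
    indicator by its covariance with the block's inner approximation; the
    inner approximation combines neighboring latent scores by the sign
    (centroid scheme, default) or value (factorial) of their correlations;
    the two alternate until the largest weight change is below ``tol``.
    Path coefficients are per-endogenous-block OLS on the latent scores;
    bootstrap (sampling rows with replacement) gives percentile CIs and
    significance stars.  GoF = sqrt(mean communality x mean R2).
    """
    if scheme not in ("centroid", "factorial"):
        raise ValueError(f"unknown inner scheme {scheme!r}")
    order = spec.validate(data)
    paths = {t: list(s) for t, s in spec.paths.items()}
    neighbors: dict[str, list[str]] = {b: [] for b in spec.blocks}
    for target, sources in paths.items():
        for s in sources:
            neighbors[target].append(s)
            neighbors[s].append(target)

    xb_raw = {b: data[cols].to_numpy(dtype=float) for b, cols in spec.blocks.items()}
    xb = {b: _standardize(x) for b, x in xb_raw.items()}
    n = data.shape[0]

    weights, scores, n_iter = _fit_plspm_once(
        xb, order, neighbors, paths, scheme, tol, max_iter)

    def path_table(sc: dict[str, np.ndarray]) -> pd.DataFrame:
        rows = []
        r2 = {}
        for target, sources in paths.items():
            if not sources:
                continue
            xmat = np.column_stack([sc[s] for s in sources])
            yv = sc[target]
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(n), xmat]), yv, rcond=None)
            fitted = np.column_stack([np.ones(n), xmat]) @ beta
            r2[target] = 1.0 - float(((yv - fitted) ** 2).sum()) / float(((yv - yv.mean()) ** 2).sum())
            for s, b in zip(sources, beta[1:]):
                rows.append({"source": s, "target": target, "coefficient": float(b)})
        return pd.DataFrame(rows), r2

    coef_df, r2 = path_table(scores)

    # effects: direct + all indirect chains (B + B^2 + ...)
    names = order
    idx = {b: i for i, b in enumerate(names)}
    bmat = np.zeros((len(names), len(names)))
    for row in coef_df.itertuples():
        bmat[idx[row.source], idx[row.target]] = row.coefficient
    total = np.zeros_like(bmat)
    power = np.eye(len(names))
    for _ in range(len(names)):
        power = power @ bmat
        total += power
    eff_rows = []
    for s in names:
        for t in names:
            if s == t or total[idx[s], idx[t]] == 0:
                continue
            direct = bmat[idx[s], idx[t]]
            eff_rows.append({"source": s, "target": t, "direct": direct,
                             "indirect": total[idx[s], idx[t]] - direct,
                             "total": total[idx[s], idx[t]]})
    effects = pd.DataFrame(eff_rows)

    loadings_rows = []
    for b, cols in spec.blocks.items():
        for j, c in enumerate(cols):
            ld = float(np.corrcoef(xb[b][:, j], scores[b])[0, 1])
            loadings_rows.append({"block": b, "indicator": c,
                                  "loading": ld, "communality": ld**2})
    outer = pd.DataFrame(loadings_rows)
    gof = float(np.sqrt(outer["communality"].mean() * np.mean(list(r2.values()))))

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.full((n_boot, len(coef_df)), np.nan)
        done = 0
        for b_i in range(n_boot):
            rows_idx = rng.integers(0, n, n)
            try:
                xb_b = {b: _standardize(x[rows_idx]) for b, x in xb_raw.items()}
                _, sc_b, _ = _fit_plspm_once(
                    xb_b, order, neighbors, paths, scheme, tol, max_iter)
                cdf, _ = path_table(sc_b)
                boot[b_i] = cdf["coefficient"].to_numpy()
                done += 1
            except (ValueError, RuntimeError):
                continue
        if done < max(10, n_boot // 2):
            raise RuntimeError(f"bootstrap failed in {n_boot - done}/{n_boot} resamples")
        coef_df["boot_mean"] = np.nanmean(boot, axis=0)
        coef_df["boot_se"] = np.nanstd(boot, axis=0, ddof=1)
        coef_df["ci_low"] = np.nanpercentile(boot, 2.5, axis=0)
        coef_df["ci_high"] = np.nanpercentile(boot, 97.5, axis=0)

        def star(lo99, hi99, lo999, hi999, lo, hi):
            if lo999 > 0 or hi999 < 0:
                return "***"
            if lo99 > 0 or hi99 < 0:
                return "**"
            if lo > 0 or hi < 0:
                return "*"
            return ""

        lo99 = np.nanpercentile(boot, 0.5, axis=0)
        hi99 = np.nanpercentile(boot, 99.5, axis=0)
        lo999 = np.nanpercentile(boot, 0.05, axis=0)
        hi999 = np.nanpercentile(boot, 99.95, axis=0)
        coef_df["stars"] = [
            star(a, b, c, d, e, f)
            for a, b, c, d, e, f in zip(lo99, hi99, lo999, hi999,
                                        coef_df["ci_low"], coef_df["ci_high"])
        ]

    score_df = pd.DataFrame({b: scores[b] for b in order}, index=data.index)
    return PathModelResult(coef_df, r2, outer, gof, score_df, effects,
                           n_iter, scheme)
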