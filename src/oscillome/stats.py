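"""Feature-wise group comparison and cohort-table statistics.

The inference stack applied to every feature family (band power per
region, PEC per region pair) is: two-sample pooled-variance t-test,
label-permutation p-values (1000 permutations, permutations shared
across features so the feature correlation structure is preserved),
Benjamini-Hochberg FDR at q = 0.05, and a subsample-robustness screen
(100 replicates of 95% of each group; a feature is robust when it
survives FDR in a configurable fraction of replicates, all of them by
default).  Network-level summaries average t-values over region pairs
grouped by functional-network membership.

Cohort demographics use Pearson chi-square on count tables and one-way
ANOVA reconstructed from per-group summary statistics (mean, SD, n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def _as_two_groups(features: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    X = np.asarray(features, dtype=float)
    return X[labels == uniq[0]], X[labels == uniq[1]], uniq


def feature_ttest(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample pooled-variance t and two-sided parametric p per feature.

    The sign convention is mean(A) - mean(B).  Features with zero
    pooled variance get t = 0, p = 1 with a warning.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    dead = se == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} feature(s) with zero pooled variance: t=0, p=1",
            stacklevel=2,
        )
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(dead, 0.0, diff / np.where(dead, 1.0, se))
    df = na + nb - 2
    p = np.where(dead, 1.0, 2.0 * sps.t.sf(np.abs(t), df))
    return t, p


def permutation_pvalues(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Label-permutation p-values for |t|, shared permutations across features.

    p = (1 + #{permuted |t| >= observed |t|}) / (n_perm + 1), so the
    smallest attainable value is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    a, b, uniq = _as_two_groups(features, labels)
    t_obs, _ = feature_ttest(a, b)
    X = np.asarray(features, dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    na = a.shape[0]
    count = np.zeros(X.shape[1])
    idx = np.arange(X.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_perm, _ = feature_ttest(X[perm[:na]], X[perm[na:]])
        count += np.abs(t_perm) >= np.abs(t_obs)
    return (1.0 + count) / (n_perm + 1.0)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals <= 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class RobustnessConfig:
    """Subsample-robustness screen settings."""

    n_replicates: int = 100
    subsample_fraction: float = 0.95
    alpha: float = 0.05
    min_selection_fraction: float = 1.0   # tau: survive this fraction of replicates

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0 < self.min_selection_fraction <= 1:
            raise ValueError("min_selection_fraction must be in (0, 1]")


@dataclass
class RobustnessResult:
    robust: np.ndarray               # bool per feature
    selection_frequency: np.ndarray  # fraction of replicates FDR-significant
    mean_p: np.ndarray               # mean parametric p over replicates


def subsample_robustness(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: RobustnessConfig = RobustnessConfig(),
    seed: int | np.random.Generator | None = None,
) -> RobustnessResult:
    """Repeated 95%-of-each-group subsampling with per-replicate FDR.

    Also returns the mean parametric p per feature across replicates,
    the ranking used for CPM candidate features.
    """
    labels = np.asarray(labels)
    X = np.asarray(features, dtype=float)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    idx_by_group = [np.flatnonzero(labels == g) for g in uniq]
    sizes = [int(np.floor(cfg.subsample_fraction * len(ix))) for ix in idx_by_group]
    if min(sizes) < 2:
        raise ValueError("groups too small for the requested subsample fraction")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_feat = X.shape[1]
    hits = np.zeros(n_feat)
    p_sum = np.zeros(n_feat)
    for _ in range(cfg.n_replicates):
        take = np.concatenate(
            [
                rng.choice(ix, size=s, replace=False)
                for ix, s in zip(idx_by_group, sizes)
            ]
        )
        sub_labels = labels[take]
        a = X[take][sub_labels == uniq[0]]
        b = X[take][sub_labels == uniq[1]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = feature_ttest(a, b)
        reject, _ = fdr_bh(p, q=cfg.alpha)
        hits += reject
        p_sum += p
    freq = hits / cfg.n_replicates
    return RobustnessResult(
        robust=freq >= cfg.min_selection_fraction - 1e-12,
        selection_frequency=freq,
        mean_p=p_sum / cfg.n_replicates,
    )


@dataclass
class GroupComparison:
    """Per-feature comparison between two groups, full inference stack."""

    group_a: str
    group_b: str
    t: np.ndarray
    p_param: np.ndarray
    p_perm: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    robust: np.ndarray | None
    n_perm: int = 1000
    alpha: float = 0.05
    selection_frequency: np.ndarray | None = None
    mean_p: np.ndarray | None = None

    def to_frame(self, feature_names=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "p_param": self.p_param,
                "p_perm": self.p_perm,
                "p_fdr": self.p_fdr,
                "significant": self.significant,
            }
        )
        if self.robust is not None:
            df["robust"] = self.robust
            df["selection_frequency"] = self.selection_frequency
        if feature_names is not None:
            df.insert(0, "feature", list(feature_names))
        return df


def compare_groups(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    robustness: RobustnessConfig | None = RobustnessConfig(),
    seed: int | None = 0,
) -> GroupComparison:
    """t-test + permutation p + BH-FDR (+ optional robustness screen).

    FDR is applied to the permutation p-values of the feature family
    passed in — callers decide the correction scope (the default
    pipeline corrects within each band and feature family).
    """
    rng = np.random.default_rng(seed)
    a, b, uniq = _as_two_groups(features, labels)
    t, p_param = feature_ttest(a, b)
    p_perm = permutation_pvalues(features, labels, n_perm=n_perm, seed=rng)
    significant, p_fdr = fdr_bh(p_perm, q=alpha)
    rob = freq = mean_p = None
    if robustness is not None:
        res = subsample_robustness(features, labels, robustness, seed=rng)
        rob, freq, mean_p = res.robust, res.selection_frequency, res.mean_p
    return GroupComparison(
        group_a=str(uniq[0]),
        group_b=str(uniq[1]),
        t=t,
        p_param=p_param,
        p_perm=p_perm,
        p_fdr=p_fdr,
        significant=significant,
        robust=rob,
        n_perm=n_perm,
        alpha=alpha,
        selection_frequency=freq,
        mean_p=mean_p,
    )


def network_average_t(
    t_matrix: np.ndarray, network_labels
) -> pd.DataFrame:
    """Average a region x region t-matrix over network x network blocks.

    Within-network entries average the unique off-diagonal pairs;
    between-network entries average all cross pairs.  Blocks with no
    eligible pair (single-region networks) are NaN.
    """
    t = np.asarray(t_matrix, dtype=float)
    labels = np.asarray(network_labels)
    if t.shape[0] != t.shape[1] or len(labels) != t.shape[0]:
        raise ValueError("t_matrix must be square and match network_labels")
    nets = list(pd.unique(labels))
    out = np.full((len(nets), len(nets)), np.nan)
    for ai, a in enumerate(nets):
        ia = np.flatnonzero(labels == a)
        for bi, b in enumerate(nets):
            ib = np.flatnonzero(labels == b)
            if ai == bi:
                if len(ia) < 2:
                    continue
                iu = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1:]]
                out[ai, bi] = np.mean([t[i, j] for i, j in iu])
            else:
                out[ai, bi] = t[np.ix_(ia, ib)].mean()
    return pd.DataFrame(out, index=nets, columns=nets)


def chi_square_counts(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table: (chi2, df, p)."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    if (expected == 0).any():
        raise ValueError(
            "a cell has expected count 0; an exact test would be required"
        )
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def anova_from_summary(
    means, sds, ns
) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group (mean, SD, n).

    Returns (F, df_between, df_within, p).  SS_between comes from the
    group means around the grand mean; SS_within from the (n-1)*SD^2.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    k, N = len(means), ns.sum()
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(N - k)
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2, float(sps.f.sf(F, df1, df2))
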