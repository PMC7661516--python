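"""Permutation-based one-way ANOVA and pairwise permutation post-hoc tests.

The one-way permutation ANOVA permutes group labels uniformly at random and
compares the permuted F statistics with the observed one; it requires
neither normality nor homogeneity of variances, which suits strongly
zero-inflated census densities.  P-values use the add-one estimator
``(1 + #{F_perm >= F_obs}) / (iterations + 1)`` so they are never exactly
zero.  Pairwise contrasts are two-sample permutation tests on the
difference of means, adjusted for multiplicity, and summarised as a compact
letter display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PermAnovaResult:
    ss_between: float
    df_between: int
    mss_between: float
    ss_within: float
    df_within: int
    f_obs: float
    iterations: int
    p_value: float

    def as_table(self) -> pd.DataFrame:
        """One-row ANOVA table (the shape journals print in captions)."""
        return pd.DataFrame([{
            "ss_between": self.ss_between, "df": self.df_between,
            "mss": self.mss_between, "ss_within": self.ss_within,
            "df_within": self.df_within, "F": self.f_obs,
            "iterations": self.iterations, "p": self.p_value,
        }])


@dataclass(frozen=True)
class PairwiseResult:
    table: pd.DataFrame            # columns: group_a, group_b, p_raw, p_adj
    letters: dict[str, str]        # compact letter display per group
    alpha: float
    adjust_method: str
    iterations: int = field(default=0)


def _group_arrays(values, groups, expected_groups=None):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels, codes = np.unique(groups, return_inverse=True)
    if expected_groups is not None:
        empty = sorted(set(expected_groups) - set(labels))
        if empty:
            raise ValueError(f"group(s) with zero observations: {empty}")
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    return values, labels, codes, np.bincount(codes, minlength=len(labels))


def _f_components(values, codes, counts, n_groups):
    """Between/within sums of squares and F for a fixed labelling."""
    n = len(values)
    grand = values.mean()
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    means = sums / counts
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_within = ss_total - ss_between
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 1e-300:
        f = 0.0 if ss_between <= 1e-300 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    return ss_between, ss_within, df_b, df_w, f


def perm_anova(values, groups, iterations: int = 5000,
               seed: int | None = 0,
               expected_groups=None) -> PermAnovaResult:
    """One-way permutation ANOVA across group labels.

    Permutes the observations' group labels uniformly at random
    ``iterations`` times (sampled, not exhaustive) and reports
    ``p = (1 + #{F_perm >= F_obs}) / (iterations + 1)``.  Deterministic for
    a given ``seed``.  Passing ``expected_groups`` raises a named error for
    any declared group with no observations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    values, labels, codes, counts = _group_arrays(values, groups,
                                                  expected_groups)
    G = len(labels)
    ssb, ssw, df_b, df_w, f_obs = _f_components(values, codes, counts, G)

    rng = np.random.default_rng(seed)
    n = len(values)
    # Permuting values against fixed labels == permuting labels.
    # Vectorised in chunks to bound memory at a few MB.
    exceed = 0
    chunk = max(1, min(iterations, int(2_000_000 // max(n, 1)) or 1))
    done = 0
    onehot = np.zeros((n, G))
    onehot[np.arange(n), codes] = 1.0
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    while done < iterations:
        b = min(chunk, iterations - done)
        order = rng.random((b, n)).argsort(axis=1)
        perm_vals = values[order]                       # (b, n)
        sums = perm_vals @ onehot                       # (b, G)
        means = sums / counts
        ssb_p = np.sum(counts * (means - grand) ** 2, axis=1)
        ssw_p = ss_total - ssb_p
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ssb_p / df_b) / (ssw_p / df_w)
        f_p = np.where(ssw_p <= 1e-300,
                       np.where(ssb_p <= 1e-300, 0.0, np.inf), f_p)
        exceed += int(np.sum(f_p >= f_obs)) if np.isfinite(f_obs) \
            else int(np.sum(np.isinf(f_p)))
        done += b
    p = (1 + exceed) / (iterations + 1)
    return PermAnovaResult(
        ss_between=ssb, df_between=df_b, mss_between=ssb / df_b,
        ss_within=ssw, df_within=df_w, f_obs=f_obs,
        iterations=iterations, p_value=p)


def _two_sample_perm_p(x, y, iterations, rng):
    """Two-sided permutation p for a difference of means (add-one estimator)."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    obs = abs(x.mean() - y.mean())
    total = pooled.sum()
    order = rng.random((iterations, n)).argsort(axis=1)
    perm = pooled[order]
    mean_x = perm[:, :nx].mean(axis=1)
    mean_y = (total - perm[:, :nx].sum(axis=1)) / (n - nx)
    exceed = np.sum(np.abs(mean_x - mean_y) >= obs - 1e-12)
    return (1 + int(exceed)) / (iterations + 1)


def adjust_pvalues(p: np.ndarray, method: str = "holm") -> np.ndarray:
    """Multiplicity adjustment: 'none', 'holm' or 'BH' (Benjamini–Hochberg)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "none" or m == 0:
        return p.copy()
    order = np.argsort(p)
    out = np.empty(m)
    if method == "holm":
        adj = np.maximum.accumulate((m - np.arange(m)) * p[order])
        out[order] = np.minimum(adj, 1.0)
    elif method in ("BH", "bh", "fdr_bh"):
        ranked = p[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out[order] = np.minimum(adj, 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


def compact_letters(groups: list[str], pairs: pd.DataFrame,
                    alpha: float = 0.05,
                    group_order: list[str] | None = None) -> dict[str, str]:
    """Compact letter display from adjusted pairwise p-values.

    Builds the graph whose edges join groups that are *not* significantly
    different (adjusted p > alpha) and letters its maximal cliques; a
    group's display is the concatenation of the letters of the cliques it
    belongs to.  Cliques are lettered in the order given by ``group_order``
    (default: input order), which conventionally is descending group mean.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for row in pairs.itertuples():
        if row.p_adj > alpha:
            g.add_edge(row.group_a, row.group_b)
    order = {name: i for i, name in enumerate(group_order or groups)}
    cliques = sorted((sorted(c, key=order.get) for c in nx.find_cliques(g)),
                     key=lambda c: min(order[m] for m in c))
    letters = {name: "" for name in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for member in clique:
            letters[member] += letter
    return letters


def pairwise_perm_test(values, groups, iterations: int = 5000,
                       seed: int | None = 0, adjust_method: str = "holm",
                       alpha: float = 0.05) -> PairwiseResult:
    """All pairwise two-sample permutation tests with multiplicity adjustment."""
    values, labels, codes, _ = _group_arrays(values, groups)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = _two_sample_perm_p(values[codes == i], values[codes == j],
                                   iterations, rng)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), adjust_method)
    means = pd.Series(values).groupby(pd.Series(codes)).mean()
    by_mean = [labels[i] for i in means.sort_values(ascending=False).index]
    letters = compact_letters(list(labels), table, alpha=alpha,
                              group_order=by_mean)
    return PairwiseResult(table=table, letters=letters, alpha=alpha,
                          adjust_method=adjust_method, iterations=iterations)


def anova_from_printed(ss_between: float, n_groups: int) -> tuple[int, float]:
    """Degrees of freedom and mean sum of squares from a printed ANOVA line."""
    df = n_groups - 1
    return df, ss_between / df
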