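"""Distance-based variance partitioning and rank-based group comparisons.

PERMANOVA partitions the total sum of squares of a distance matrix into
sequential (Type-I) terms — here subject, then collection method, then storage
time — with significance from unrestricted permutations of sample labels.
The rank-based family (Wilcoxon rank-sum, Kruskal-Wallis, Dunn's post hoc with
Benjamini-Hochberg adjustment) compares collection methods at one timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PERMANOVA",
    "PermanovaResults",
    "GroupTestResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "dunn_posthoc",
    "bh_adjust",
]


@dataclass
class PermanovaResults:
    """Sequential PERMANOVA table: SS, df, pseudo-F, R^2 and permutation p."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


class PERMANOVA:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    distance : square symmetric DataFrame with zero diagonal, sample-labeled.
    factors : DataFrame of per-sample categorical labels, sample-indexed.
    terms : order of factor columns for the sequential decomposition; Type-I
        sums of squares depend on this order.
    """

    def __init__(self, distance: pd.DataFrame, factors: pd.DataFrame, terms: list[str] | None = None):
        d = distance.to_numpy(dtype=float)
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be square and symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.sample_ids = list(distance.index)
        if set(self.sample_ids) - set(factors.index):
            raise ValueError("factors missing samples present in the distance matrix")
        self.factors = factors.loc[self.sample_ids]
        self.terms = list(terms) if terms is not None else list(factors.columns)
        for t in self.terms:
            if self.factors[t].nunique() < 2:
                raise ValueError(f"term {t!r} has a single level: zero degrees of freedom")
        n = d.shape[0]
        # Gower-centered inner-product matrix G = -1/2 C (D o D) C
        a = -0.5 * d**2
        self._g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
        self._n = n
        # Cumulative hat matrices for the sequential decomposition.
        x = np.ones((n, 1))
        self._hats = [x @ np.linalg.pinv(x)]
        self._dfs = []
        rank_prev = 1
        for t in self.terms:
            dummies = pd.get_dummies(self.factors[t], drop_first=False).to_numpy(dtype=float)
            x = np.hstack([x, dummies])
            rank = np.linalg.matrix_rank(x)
            self._dfs.append(rank - rank_prev)
            rank_prev = rank
            self._hats.append(x @ np.linalg.pinv(x))
        self._df_res = n - rank_prev

    def _ss_terms(self, g: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([np.sum(h * g.T) for h in self._hats])
        ss = np.diff(traces)
        ss_res = float(np.trace(g) - traces[-1])
        return ss, ss_res

    def fit(self, n_perm: int = 999, seed: int | None = None) -> PermanovaResults:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        g = self._g
        ss, ss_res = self._ss_terms(g)
        ss_total = float(np.trace(g))
        dfs = np.array(self._dfs, dtype=float)
        f_obs = (ss / dfs) / (ss_res / self._df_res)

        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(self.terms))
        hats = np.stack(self._hats)  # (n_terms+1, n, n)
        diag = np.diag(g)
        chunk = max(1, int(2**22 // (self._n * self._n)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perms = np.stack([rng.permutation(self._n) for _ in range(m)])
            gp = g[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
            traces = np.einsum("hij,pji->ph", hats, gp)
            ss_p = np.diff(traces, axis=1)
            ss_res_p = diag.sum() - traces[:, -1]
            f_p = (ss_p / dfs) / (ss_res_p / self._df_res)[:, None]
            exceed += (f_p >= f_obs).sum(axis=0)
            done += m
        pvals = (exceed + 1.0) / (n_perm + 1.0)

        rows = []
        for i, t in enumerate(self.terms):
            rows.append(
                {
                    "df": self._dfs[i],
                    "SS": ss[i],
                    "F": f_obs[i],
                    "R2": ss[i] / ss_total,
                    "p": pvals[i],
                }
            )
        rows.append({"df": self._df_res, "SS": ss_res, "F": np.nan, "R2": ss_res / ss_total, "p": np.nan})
        rows.append({"df": self._n - 1, "SS": ss_total, "F": np.nan, "R2": 1.0, "p": np.nan})
        table = pd.DataFrame(rows, index=self.terms + ["Residual", "Total"])
        return PermanovaResults(table=table, n_permutations=n_perm, seed=seed)


@dataclass
class GroupTestResult:
    """One rank-test outcome; ``p_adjusted`` is filled by BH where applicable."""

    test: str
    statistic: float
    p: float
    groups: tuple = ()
    p_adjusted: float | None = None


def wilcoxon_rank_sum(x, y, method: str = "auto") -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    ``auto`` uses the exact null when there are no ties and min(n) <= 8, else
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return GroupTestResult("wilcoxon", float(len(x) * len(y) / 2.0), 1.0)
    if method == "auto":
        ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (not ties and min(len(x), len(y)) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return GroupTestResult("wilcoxon", float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups: list) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction, chi-square p on g-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return GroupTestResult("kruskal", 0.0, 1.0)
    h, p = stats.kruskal(*groups)
    return GroupTestResult("kruskal", float(h), float(p))


def dunn_posthoc(groups: list, labels: list | None = None, adjust: str = "bh") -> list[GroupTestResult]:
    """Dunn's pairwise z tests on mean ranks after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values,
    BH-adjusted across all g(g-1)/2 pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    labels = labels if labels is not None else list(range(len(groups)))
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            results.append(GroupTestResult("dunn", float(z), p, groups=(labels[i], labels[j])))
    if adjust == "bh":
        adj = bh_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = a
    return results


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(a) for a in adj]
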