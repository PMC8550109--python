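"""Consistency intraclass correlation: the study's core reliability statistic.

The estimand is the two-way mixed-effects, single-measures, consistency ICC
(ICC(C,1), equivalently ICC3 in the Shrout-Fleiss taxonomy): subjects are rows,
the k measurement occasions (evaluated method vs reference) are columns, and a
systematic column shift — a preservative biasing every subject equally — does
not count against agreement. From the two-way ANOVA without interaction,

    ICC = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

with F = MS_rows / MS_error on (n-1, (n-1)(k-1)) degrees of freedom and an
upper-tail p-value. ICCs are read as poor (<0.4), fair-to-good (0.4-0.75) or
excellent (>=0.75). Spearman rank correlation is the secondary, distribution-
free analysis for the two-column case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ComparisonMode, SampleManifest, select_pairs

__all__ = [
    "ICCModel",
    "ICCResults",
    "classify_icc",
    "spearman",
    "evaluate_features",
    "FeaturePanelResult",
]

CATEGORIES = ("POOR", "FAIR_GOOD", "EXCELLENT")


def classify_icc(icc: float):
    """Map an ICC to POOR (<0.4), FAIR_GOOD (0.4-0.75) or EXCELLENT (>=0.75)."""
    if icc is None or (isinstance(icc, float) and np.isnan(icc)):
        return np.nan
    if icc < 0.4:
        return "POOR"
    if icc < 0.75:
        return "FAIR_GOOD"
    return "EXCELLENT"


@dataclass
class ICCResults:
    """Fitted consistency ICC with its ANOVA decomposition and F test."""

    icc: float
    ms_rows: float
    ms_error: float
    ms_cols: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n: int
    k: int
    transform: str = "none"
    metric: str | None = None
    category: str | float = field(init=False)

    def __post_init__(self):
        self.category = classify_icc(self.icc)

    def summary(self) -> str:
        lines = [
            "Consistency ICC (two-way mixed, single measures)",
            "=" * 48,
            f"metric:     {self.metric or '-'}   transform: {self.transform}",
            f"n subjects: {self.n}   k measurements: {self.k}",
            f"MS rows:    {self.ms_rows:.6g}   MS error: {self.ms_error:.6g}",
            f"ICC:        {np.nan if self.icc is None else self.icc:.4f}"
            if np.isfinite(self.icc)
            else "ICC:        NA",
            f"F({self.df1}, {self.df2}) = {self.f_stat:.4g},  p = {self.p_value:.4g}"
            if np.isfinite(self.f_stat)
            else f"F({self.df1}, {self.df2}) = NA",
            f"category:   {self.category}",
        ]
        return "\n".join(lines)


class ICCModel:
    """Consistency-ICC model for an n x k matrix of paired measurements.

    Rows are subjects; columns are measurement occasions (k=2 in the
    collection-method design: evaluated method first, reference second).
    Subjects with missing members must have been dropped upstream.
    """

    def __init__(self, values, subject_ids=None, transform: str = "none", metric: str | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be an n x k matrix")
        n, k = values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 measurements")
        if not np.isfinite(values).all():
            raise ValueError("values must be finite (drop incomplete subjects upstream)")
        self.values = values
        self.subject_ids = list(subject_ids) if subject_ids is not None else list(range(n))
        self.transform = transform
        self.metric = metric

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ICCModel":
        return cls(df.to_numpy(), subject_ids=list(df.index), **kwargs)

    def fit(self) -> ICCResults:
        y = self.values
        n, k = y.shape
        grand = y.mean()
        row_means = y.mean(axis=1)
        col_means = y.mean(axis=0)
        ss_rows = k * ((row_means - grand) ** 2).sum()
        ss_cols = n * ((col_means - grand) ** 2).sum()
        resid = y - row_means[:, None] - col_means[None, :] + grand
        ss_err = (resid**2).sum()
        df1, dfc, df2 = n - 1, k - 1, (n - 1) * (k - 1)
        ms_rows = ss_rows / df1
        ms_cols = ss_cols / dfc
        ms_err = ss_err / df2

        if ms_rows + (k - 1) * ms_err == 0:
            warnings.warn("all values identical: ICC undefined")
            icc = np.nan
            f = np.nan
            p = np.nan
        else:
            icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
            f = np.inf if ms_err == 0 else ms_rows / ms_err
            p = float(stats.f.sf(f, df1, df2)) if n >= 3 else np.nan
        return ICCResults(
            icc=float(icc),
            ms_rows=float(ms_rows),
            ms_error=float(ms_err),
            ms_cols=float(ms_cols),
            f_stat=float(f),
            df1=df1,
            df2=df2,
            p_value=p,
            n=n,
            k=k,
            transform=self.transform,
            metric=self.metric,
        )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a margin: Spearman undefined")
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _icc_vectorized(a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Per-feature consistency ICC for k=2, vectorized over rows of a/b.

    a, b: (n_features, n_subjects) evaluated / reference values.
    """
    n = a.shape[1]
    row_means = (a + b) / 2.0
    grand = row_means.mean(axis=1, keepdims=True)
    ss_rows = 2.0 * ((row_means - grand) ** 2).sum(axis=1)
    d = a - b
    ss_err = ((d - d.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / 2.0
    df1 = n - 1
    df2 = n - 1
    ms_rows = ss_rows / df1
    ms_err = ss_err / df2
    denom = ms_rows + ms_err
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (ms_rows - ms_err) / denom, np.nan)
        f = np.where(ms_err > 0, ms_rows / ms_err, np.where(ms_rows > 0, np.inf, np.nan))
    p = stats.f.sf(f, df1, df2) if n >= 3 else np.full(len(icc), np.nan)
    return pd.DataFrame({"icc": icc, "f": f, "df1": df1, "df2": df2, "p": p})


@dataclass
class FeaturePanelResult:
    """Per-feature ICC + Spearman panel for one comparison, with summary."""

    table: pd.DataFrame
    comparison: ComparisonMode
    transform: str = "none"

    @property
    def median_icc(self) -> float:
        return float(self.table["icc"].median())

    @property
    def iqr_icc(self) -> tuple[float, float]:
        q = self.table["icc"].quantile([0.25, 0.75])
        return float(q.iloc[0]), float(q.iloc[1])

    @property
    def n_na(self) -> int:
        return int(self.table["icc"].isna().sum())

    def summary(self) -> pd.Series:
        q1, q3 = self.iqr_icc
        return pd.Series(
            {
                "mode": self.comparison.mode.value,
                "method": self.comparison.method_id,
                "n_features": len(self.table),
                "n_na": self.n_na,
                "median_icc": self.median_icc,
                "icc_q1": q1,
                "icc_q3": q3,
            }
        )


def evaluate_features(
    data: pd.DataFrame,
    manifest: SampleManifest,
    comparison: ComparisonMode,
    feature_subset: list[str] | None = None,
    transform: str = "none",
) -> FeaturePanelResult:
    """Per-feature consistency ICC + Spearman for one comparison mode.

    ``data`` is a features x samples DataFrame already on the analysis scale
    (sqrt abundances, log10-imputed intensities, or raw diversity metrics).
    Features constant across all pairs yield NA rows and are counted in the
    summary. The returned table carries one row per feature with the ICC, its
    F test, the category and the Spearman secondary statistic.
    """
    pairs = select_pairs(manifest, comparison)
    if pairs.empty:
        raise ValueError("no complete pairs for this comparison")
    feats = feature_subset if feature_subset is not None else list(data.index)
    missing = [f for f in feats if f not in data.index]
    if missing:
        raise KeyError(f"features not in data: {missing[:5]}")
    a = data.loc[feats, pairs["evaluated"]].to_numpy(dtype=float)
    b = data.loc[feats, pairs["reference"]].to_numpy(dtype=float)
    out = _icc_vectorized(a, b)
    out.index = feats
    out.insert(0, "feature_id", feats)
    out.insert(1, "mode", comparison.mode.value)
    out.insert(2, "method", comparison.method_id)
    out["category"] = [classify_icc(v) for v in out["icc"]]

    scc = np.full(len(feats), np.nan)
    scc_p = np.full(len(feats), np.nan)
    if a.shape[1] >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(feats)):
                if np.ptp(a[i]) > 0 and np.ptp(b[i]) > 0:
                    scc[i], scc_p[i] = stats.spearmanr(a[i], b[i])
    out["scc"] = scc
    out["scc_p"] = scc_p
    return FeaturePanelResult(table=out, comparison=comparison, transform=transform)
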