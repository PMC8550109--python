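"""Untargeted-metabolomics preprocessing for collection-method comparisons.

The fixed chain is: QC relative-standard-deviation profiling -> adduct
collapse (keep the lowest-RSD ion per metabolite) -> removal of features
missing in >50% of QC injections -> per-method detectability accounting ->
restriction to well-detected features -> half-minimum imputation and log10.
Re-running the chain on its own output is a no-op.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .design import SampleManifest
from .tables import MetaboliteMatrix

__all__ = [
    "QCProfile",
    "DetectabilityReport",
    "qc_rsd",
    "collapse_adducts",
    "filter_qc_missing",
    "detectability",
    "restrict_by_detectability",
    "impute_and_log",
    "overlap_with_reference",
]

log = logging.getLogger(__name__)


@dataclass
class QCProfile:
    """Per-feature QC statistics: RSD (NaN when <2 present values or zero mean)
    and the fraction of QC injections in which the feature is missing."""

    table: pd.DataFrame  # columns: rsd, qc_missing_fraction

    @property
    def rsd(self) -> pd.Series:
        return self.table["rsd"]

    @property
    def qc_missing_fraction(self) -> pd.Series:
        return self.table["qc_missing_fraction"]


def qc_rsd(matrix: MetaboliteMatrix) -> QCProfile:
    """RSD = sample SD / arithmetic mean over present pooled-QC values."""
    if not matrix.qc_columns:
        raise ValueError("matrix has no QC columns")
    qc = matrix.qc_data
    n_present = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    rsd = sd / mean
    rsd[n_present < 2] = np.nan
    zero_mean = (mean == 0) & (n_present >= 2)
    if zero_mean.any():
        warnings.warn(f"{int(zero_mean.sum())} feature(s) with zero QC mean: RSD undefined")
        rsd[zero_mean] = np.nan
    missing_frac = qc.isna().sum(axis=1) / qc.shape[1]
    return QCProfile(pd.DataFrame({"rsd": rsd, "qc_missing_fraction": missing_frac}))


def collapse_adducts(matrix: MetaboliteMatrix, qc: QCProfile) -> MetaboliteMatrix:
    """Keep one ion per adduct group: the one with the lowest QC RSD.

    When every member's RSD is undefined the member with the fewest missing
    values is kept; remaining ties go to the lexically smaller feature id.
    """
    if matrix.annotations is None or "adduct_group" not in matrix.annotations.columns:
        raise ValueError("adduct collapse requires an adduct_group annotation")
    groups = matrix.annotations["adduct_group"].reindex(matrix.feature_ids)
    n_missing = matrix.data.isna().sum(axis=1)
    keep: list[str] = []
    dropped: list[str] = []
    for _, members in groups.groupby(groups, sort=False):
        ids = list(members.index)
        rsds = qc.rsd.reindex(ids)
        if rsds.notna().any():
            best = min(ids, key=lambda f: (not np.isfinite(rsds[f]), rsds[f] if np.isfinite(rsds[f]) else np.inf, f))
        else:
            best = min(ids, key=lambda f: (n_missing[f], f))
        keep.append(best)
        dropped.extend(f for f in ids if f != best)
    if dropped:
        log.info("collapse_adducts dropped %d ions: %s", len(dropped), dropped[:10])
    return matrix.subset_features(keep)


def filter_qc_missing(matrix: MetaboliteMatrix, max_missing: float = 0.5) -> MetaboliteMatrix:
    """Remove features missing in more than ``max_missing`` of QC injections
    (strict >, so exactly 50% missing survives the default)."""
    frac = matrix.qc_data.isna().sum(axis=1) / len(matrix.qc_columns)
    keep = [f for f, v in frac.items() if v <= max_missing]
    return matrix.subset_features(keep)


@dataclass
class DetectabilityReport:
    """Per feature x method detection fractions plus banded method counts.

    A feature counts as detected for a subject if it is present in at least
    one of that subject's samples for the method (``scope='subject'``); the
    per-timepoint scope uses the single sample at that timepoint.
    """

    fractions: pd.DataFrame  # features x methods
    scope: str = "subject"

    def feature_set(self, method: str, level: float) -> set[str]:
        col = self.fractions[method]
        return set(col.index[col >= level])

    def level_counts(self, levels: tuple[float, ...] = (0.5, 0.8, 1.0)) -> pd.DataFrame:
        """Number of features per method meeting each detectability level;
        monotone non-increasing in the level by construction."""
        return pd.DataFrame(
            {f">={int(lv * 100)}%": (self.fractions >= lv).sum(axis=0) for lv in levels}
        )


def detectability(
    matrix: MetaboliteMatrix,
    manifest: SampleManifest,
    scope: str = "subject",
    timepoint: str | None = None,
) -> DetectabilityReport:
    """Fraction of subjects in which each feature is detected, per method."""
    meta = manifest.records.set_index("sample_id")
    cols = [c for c in matrix.study_columns if c in meta.index]
    if not cols:
        raise ValueError("no study columns map to manifest records")
    if scope == "timepoint":
        if timepoint is None:
            raise ValueError("timepoint scope requires a timepoint")
        cols = [c for c in cols if meta.loc[c, "timepoint"] == timepoint]
    present = matrix.data[cols].notna()
    out = {}
    for method, meth_meta in meta.loc[cols].groupby("method"):
        meth_cols = list(meth_meta.index)
        by_subject = present[meth_cols].T.groupby(meth_meta["subject_id"]).any()
        out[method] = by_subject.mean(axis=0)
    missing_methods = set(meta["method"].unique()) - set(out)
    if missing_methods:
        warnings.warn(f"methods with no matrix columns: {sorted(missing_methods)}")
    return DetectabilityReport(pd.DataFrame(out), scope=scope)


def restrict_by_detectability(
    matrix: MetaboliteMatrix, report: DetectabilityReport, method: str, level: float
) -> MetaboliteMatrix:
    """Keep features with detectability >= ``level`` in the method of interest."""
    keep = [f for f in matrix.feature_ids if f in report.feature_set(method, level)]
    return matrix.subset_features(keep)


def impute_and_log(matrix: MetaboliteMatrix, scope: list[str] | None = None) -> pd.DataFrame:
    """Half-minimum imputation within ``scope`` columns, then log10.

    ``scope`` defaults to all study columns; it is normally the comparison set
    (the two sample groups entering one ICC), so the same feature may impute
    differently in different comparisons. Features entirely missing in scope
    are excluded with a warning. Returns a plain DataFrame (features x scope).
    """
    cols = list(scope) if scope is not None else matrix.study_columns
    sub = matrix.data[cols]
    mins = sub.min(axis=1)
    all_missing = mins.isna()
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} feature(s) entirely missing in scope: excluded"
        )
        sub = sub.loc[~all_missing]
        mins = mins.loc[~all_missing]
    filled = sub.T.fillna(mins / 2.0).T
    return np.log10(filled)


def overlap_with_reference(method_features: set[str] | int, gs_features: set[str] | int,
                           shared: int | None = None) -> tuple[int, float]:
    """Shared feature count with the reference set and percent-of-reference.

    Accepts either the two id sets, or printed counts (``gs_features`` = |GS|,
    ``shared`` = |intersection|) for checking published tallies. The percent is
    rounded half-up to one decimal.
    """
    if isinstance(gs_features, (set, frozenset)):
        if not gs_features:
            raise ValueError("empty reference set: percent undefined")
        shared_n = len(set(method_features) & set(gs_features))
        gs_n = len(gs_features)
    else:
        if shared is None:
            raise ValueError("printed-count form requires shared=")
        gs_n, shared_n = int(gs_features), int(shared)
        if gs_n <= 0:
            raise ValueError("empty reference set: percent undefined")
    pct = float((Decimal(100 * shared_n) / Decimal(gs_n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return shared_n, pct
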